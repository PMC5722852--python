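"""Preprocessing: ocular-artifact orthogonalization, band-limiting,
epoching into labeled trials, and min-max scaling to [-1, 1].

The artifact removal is a two-step Gram-Schmidt procedure: each scalp
channel is projected against the normalized vertical EOG reference, then
the residual against the normalized horizontal reference.  All integrals
are discretized with the rectangle rule (dt = 1/fs), which makes the
stated orthogonality exact in the discrete inner product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .synthgen import Recording, validate_event_log

#: References with quadrature norm below this are considered degenerate.
DEGENERATE_NORM_TOL = 1e-12


@dataclass
class Trial:
    """One stimulus-locked epoch: P channels x N samples plus its metadata."""

    data: np.ndarray            # (P, N)
    label: str                  # 'L' or 'R'
    g: float                    # wireframe contrast in [0, 1]
    subject_id: int
    fs: float
    onset_sample: int = 0

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def _window_slice(n: int, fs: float, t1: float, T: float | None) -> slice:
    if T is None:
        return slice(int(round(t1 * fs)), n)
    i0 = int(round(t1 * fs))
    i1 = i0 + int(round(T * fs))
    if i0 < 0 or i1 > n or i1 <= i0:
        raise ValueError("orthogonalization window outside the signal")
    return slice(i0, i1)


def quadrature_norm(c: np.ndarray, fs: float) -> float:
    """L2 norm under the rectangle rule: sqrt(sum c^2 * dt)."""
    return float(np.sqrt(np.sum(np.square(c)) / fs))


def normalize_reference(
    c: np.ndarray, fs: float, t1: float = 0.0, T: float | None = None
) -> np.ndarray:
    """Scale a reference signal to unit quadrature norm on [t1, t1+T].

    The whole signal is divided by the window norm, so the returned signal
    has L2 norm 1 on the window under the discrete rectangle rule.  A
    (near-)zero-norm reference raises ``ValueError``.
    """
    c = np.asarray(c, dtype=float)
    sl = _window_slice(c.size, fs, t1, T)
    norm = quadrature_norm(c[sl], fs)
    if norm < DEGENERATE_NORM_TOL:
        raise ValueError("degenerate EOG reference: near-zero norm on the window")
    return c / norm


def remove_eog(
    x: np.ndarray,
    c_v: np.ndarray,
    c_h: np.ndarray,
    fs: float,
    t1: float = 0.0,
    T: float | None = None,
) -> np.ndarray:
    """Remove ocular contamination from one channel by sequential projection.

    ``x' = x - c_v0 <c_v0, x>`` then ``x~ = x' - c_h0 <c_h0, x'>`` with
    inner products taken over [t1, t1+T] under the rectangle rule.  The
    result is exactly orthogonal to the normalized horizontal reference on
    the window (and to the vertical one whenever the two references are
    themselves orthogonal).  Accepts a (P, S) matrix for ``x`` and cleans
    each row.
    """
    x = np.asarray(x, dtype=float)
    c_v = np.asarray(c_v, dtype=float)
    c_h = np.asarray(c_h, dtype=float)
    n = x.shape[-1]
    if c_v.shape != (n,) or c_h.shape != (n,):
        raise ValueError("signal and EOG references must have the same length")
    sl = _window_slice(n, fs, t1, T)
    cv0 = normalize_reference(c_v, fs, t1, T)
    ch0 = normalize_reference(c_h, fs, t1, T)
    dt = 1.0 / fs

    single = x.ndim == 1
    xm = np.atleast_2d(x)
    x1 = xm - np.outer(xm[:, sl] @ cv0[sl] * dt, cv0)
    x2 = x1 - np.outer(x1[:, sl] @ ch0[sl] * dt, ch0)
    return x2[0] if single else x2


def remove_eog_recording(
    recording: Recording, t1: float = 0.0, T: float | None = None
) -> Recording:
    """Apply :func:`remove_eog` to every scalp channel of a recording."""
    out = recording.copy()
    out.signal = remove_eog(
        recording.signal, recording.eog_v, recording.eog_h, recording.fs, t1, T
    )
    return out


def bandlimit(
    recording: Recording,
    hp: float = 1.0,
    lp: float = 100.0,
    notch: float = 50.0,
    zero_phase: bool = True,
) -> Recording:
    """Band-pass plus notch on every scalp and EOG channel.

    Fourth-order Butterworth band-pass and a second-order IIR notch,
    mirroring the acquisition hardware's filter corners in software.  The
    default is zero-phase (forward-backward), which preserves the shape
    and timing of stimulus-locked components; its known trade-off is that
    evoked energy is smeared symmetrically in time, so a little of it
    leaks into pre-stimulus samples.  ``zero_phase=False`` gives causal
    single-pass filtering (no backward leakage, like an online hardware
    chain) at the cost of frequency-dependent delay that distorts
    component waveforms.
    """
    fs = recording.fs
    if not 0 < hp < lp < fs / 2:
        raise ValueError(f"need 0 < hp < lp < fs/2, got hp={hp}, lp={lp}, fs={fs}")
    sos = sps.butter(4, [hp, lp], btype="bandpass", fs=fs, output="sos")
    b_n, a_n = sps.iirnotch(notch, Q=30.0, fs=fs)

    def _apply(sig: np.ndarray) -> np.ndarray:
        if zero_phase:
            out = sps.sosfiltfilt(sos, sig, axis=-1)
            return sps.filtfilt(b_n, a_n, out, axis=-1)
        out = sps.sosfilt(sos, sig, axis=-1)
        return sps.lfilter(b_n, a_n, out, axis=-1)

    out = recording.copy()
    out.signal = _apply(out.signal)
    out.eog_v = _apply(out.eog_v)
    out.eog_h = _apply(out.eog_h)
    return out


def extract_trials(
    recording: Recording, events: pd.DataFrame, T: float = 1.0
) -> list[Trial]:
    """Cut one stimulus-locked trial per event.

    Windows are half-open ``[onset, onset + round(fs*T))`` (0-based
    indexing), so T = 1 s at 250 Hz gives exactly 250 samples.  Sample
    values are copied bit-exactly.  Events whose window does not fit in
    the recording are skipped (their count is reported via the returned
    list length versus ``len(events)``).
    """
    if T <= 0:
        raise ValueError("trial duration T must be positive")
    validate_event_log(events)
    n = recording.n_samples
    n_trial = int(round(recording.fs * T))
    trials = []
    for row in events.itertuples(index=False):
        onset = int(row.onset_sample)
        if onset < 0 or onset + n_trial > n:
            continue
        trials.append(
            Trial(
                data=recording.signal[:, onset : onset + n_trial].copy(),
                label=str(row.label),
                g=float(row.g),
                subject_id=recording.subject_id,
                fs=recording.fs,
                onset_sample=onset,
            )
        )
    return trials


def scale_trials(
    trials: list[Trial], per_trial: bool = False
) -> list[Trial]:
    """Affine min-max scaling of each electrode to [-1, 1].

    By default the map is computed per electrode over that electrode's
    samples pooled across all trials (one map per electrode per subject),
    sending the pooled minimum to -1 and maximum to +1; ``per_trial=True``
    instead rescales each trial independently.  Constant channels map to 0.
    """
    if not trials:
        raise ValueError("cannot scale an empty trial list")

    def _scale_block(block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = block.min(axis=-1, keepdims=True)
        hi = block.max(axis=-1, keepdims=True)
        span = hi - lo
        mid = (hi + lo) / 2.0
        safe = np.where(span > 0, span, 1.0)
        return mid, safe / 2.0

    if per_trial:
        out = []
        for tr in trials:
            mid, half = _scale_block(tr.data)
            scaled = np.where(
                (tr.data.max(axis=-1, keepdims=True) - tr.data.min(axis=-1, keepdims=True)) > 0,
                (tr.data - mid) / half,
                0.0,
            )
            out.append(Trial(scaled, tr.label, tr.g, tr.subject_id, tr.fs, tr.onset_sample))
        return out

    pooled = np.concatenate([tr.data for tr in trials], axis=1)
    lo = pooled.min(axis=1, keepdims=True)
    hi = pooled.max(axis=1, keepdims=True)
    span = hi - lo
    mid = (hi + lo) / 2.0
    half = np.where(span > 0, span / 2.0, 1.0)
    constant = span <= 0
    out = []
    for tr in trials:
        scaled = (tr.data - mid) / half
        scaled = np.where(constant, 0.0, scaled)
        out.append(Trial(scaled, tr.label, tr.g, tr.subject_id, tr.fs, tr.onset_sample))
    return out


def preprocess_session(
    recording: Recording,
    events: pd.DataFrame,
    T: float = 1.0,
    hp: float = 1.0,
    lp: float = 100.0,
    notch: float = 50.0,
    per_trial_scaling: bool = False,
    zero_phase: bool = True,
) -> list[Trial]:
    """Full preprocessing chain: band-limit, orthogonalize, epoch, scale."""
    rec = bandlimit(recording, hp=hp, lp=lp, notch=notch, zero_phase=zero_phase)
    try:
        rec = remove_eog_recording(rec)
    except ValueError:
        # flat EOG references (e.g. artifact-free synthetic sessions):
        # nothing to project out
        pass
    trials = extract_trials(rec, events, T=T)
    if not trials:
        return []
    return scale_trials(trials, per_trial=per_trial_scaling)
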