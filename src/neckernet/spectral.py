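"""Morlet time-frequency analysis of peristimulus EEG epochs.

The continuous wavelet transform uses the Morlet mother wavelet

    psi(f, t) = pi^(-1/4) sqrt(f) exp(j w0 f (t - t0)) exp(-(f (t - t0))^2 / 2)

with center frequency w0 = 2*pi, in the frequency-parametrized convention
where the wavelet at analysis frequency f (Hz) has temporal width 1/f.
Coefficients are

    W(f, t) = sqrt(f) * integral of x(t') psi*(f, t') dt'

over t' in [t - 4/f, t + 4/f]; the kernel is truncated at exactly those
limits, edges are zero-padded, and samples inside the cone of influence
(within 4/f of either edge) are flagged rather than renormalized.  The
wavelet energy is E(f, t) = |W(f, t)|^2.

Class-averaged spectra <A_L> and <A_R> are means of E over an occipital
channel subset and over the epochs of each percept class, and the contrast
coefficient <dA> is the 2-D quadrature of their difference over a
frequency band and peristimulus time window (optionally normalized by the
integrated grand-mean spectrum).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .synthgen import Recording, validate_event_log

#: Default analysis band, Hz.
DEFAULT_FREQS = np.arange(1.0, 35.0 + 1e-9, 0.25)

#: Default peristimulus window relative to stimulus onset, seconds.
EPOCH_PRE = 1.0
EPOCH_POST = 2.0

OMEGA0 = 2.0 * np.pi


@dataclass
class CWTResult:
    """Complex Morlet coefficients on a frequency x time grid."""

    coefficients: np.ndarray     # (..., F, T) complex
    freqs: np.ndarray            # (F,) Hz
    times: np.ndarray            # (T,) s
    coi: np.ndarray              # (F, T) bool, True inside the cone of influence


@dataclass
class TimeFreqMap:
    """Wavelet energy on a frequency x time grid with group metadata."""

    energy: np.ndarray           # (F, T), >= 0
    freq_axis: np.ndarray        # (F,) Hz, strictly increasing
    time_axis: np.ndarray        # (T,) s relative to stimulus onset
    n_averaged: int = 1
    group: str = "single"

    def __post_init__(self) -> None:
        self.energy = np.asarray(self.energy, dtype=float)
        self.freq_axis = np.asarray(self.freq_axis, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if self.energy.shape != (self.freq_axis.size, self.time_axis.size):
            raise ValueError("energy grid shape must match the axes")
        if np.any(np.diff(self.freq_axis) <= 0) or np.any(np.diff(self.time_axis) <= 0):
            raise ValueError("axes must be strictly increasing")
        if np.any(self.energy < 0):
            raise ValueError("energy must be non-negative")


def morlet_kernel(f: float, fs: float) -> np.ndarray:
    """Discretized psi*(f, .) on [-4/f, 4/f], including the dt factor.

    Returns the array h with h[m] = psi*(f, m*dt) * dt for m in [-M, M],
    M = round(4 f_s / f), such that W[t] = sqrt(f) * sum_m x[t+m] h[m].
    """
    dt = 1.0 / fs
    m = int(round(4.0 * fs / f))
    tau = np.arange(-m, m + 1) * dt
    return (
        np.pi ** (-0.25)
        * np.sqrt(f)
        * np.exp(-1j * OMEGA0 * f * tau)
        * np.exp(-((f * tau) ** 2) / 2.0)
        * dt
    )


def morlet_cwt(
    x: np.ndarray, fs: float, freqs: np.ndarray | None = None
) -> CWTResult:
    """Continuous Morlet wavelet transform of one or more signals.

    ``x`` may be 1-D (samples,) or 2-D (signals, samples); coefficients
    come back with a matching leading axis.  Edges are zero-padded, and
    ``coi`` marks the samples lying within 4/f of either signal edge.
    """
    x = np.asarray(x, dtype=float)
    freqs = DEFAULT_FREQS if freqs is None else np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0) or np.any(freqs >= fs / 2):
        raise ValueError("analysis frequencies must lie in (0, fs/2)")
    single = x.ndim == 1
    xm = np.atleast_2d(x)
    n = xm.shape[1]
    times = np.arange(n) / fs

    coeffs = np.empty((xm.shape[0], freqs.size, n), dtype=complex)
    coi = np.zeros((freqs.size, n), dtype=bool)
    for i, f in enumerate(freqs):
        h = morlet_kernel(f, fs)
        # W[t] = sqrt(f) sum_m x[t+m] h[m]  (correlation with the kernel)
        coeffs[:, i, :] = np.sqrt(f) * fftconvolve(
            xm, h[::-1][None, :], mode="same", axes=1
        )
        edge = (len(h) - 1) // 2
        if edge > 0:
            coi[i, :min(edge, n)] = True
            coi[i, max(n - edge, 0):] = True

    return CWTResult(
        coefficients=coeffs[0] if single else coeffs,
        freqs=freqs,
        times=times,
        coi=coi,
    )


def energy_spectrum(w: CWTResult, time_axis: np.ndarray | None = None) -> TimeFreqMap:
    """Wavelet energy E = |W|^2 for a single-signal transform."""
    coeffs = np.asarray(w.coefficients)
    if coeffs.ndim != 2:
        raise ValueError("energy_spectrum expects a single-signal coefficient map")
    return TimeFreqMap(
        energy=np.abs(coeffs) ** 2,
        freq_axis=w.freqs,
        time_axis=w.times if time_axis is None else time_axis,
    )


@dataclass
class Epoch:
    """A peristimulus multichannel snippet with its percept label."""

    data: np.ndarray             # (P, S)
    label: str
    channel_labels: tuple[str, ...]
    fs: float
    time_axis: np.ndarray        # (S,) s relative to onset


def extract_epochs(
    recording: Recording,
    events: pd.DataFrame,
    pre: float = EPOCH_PRE,
    post: float = EPOCH_POST,
) -> list[Epoch]:
    """Cut ~3-s peristimulus epochs: ``pre`` s before onset to ``post`` s
    after (1 s before + presentation + 1 s after by default).  Epochs that
    do not fit in the recording are skipped."""
    validate_event_log(events)
    fs = recording.fs
    n_pre, n_post = int(round(pre * fs)), int(round(post * fs))
    time_axis = np.arange(-n_pre, n_post) / fs
    epochs = []
    for row in events.itertuples(index=False):
        onset = int(row.onset_sample)
        if onset - n_pre < 0 or onset + n_post > recording.n_samples:
            continue
        epochs.append(
            Epoch(
                data=recording.signal[:, onset - n_pre : onset + n_post].copy(),
                label=str(row.label),
                channel_labels=tuple(recording.channel_labels),
                fs=fs,
                time_axis=time_axis,
            )
        )
    return epochs


def averaged_spectrum(
    epochs: list[Epoch],
    channels: tuple[str, ...],
    group: str,
    freqs: np.ndarray | None = None,
) -> TimeFreqMap:
    """Mean wavelet energy over a channel subset and the epochs of a group.

    ``group`` selects epochs by label ('L' or 'R'); any other value uses
    every epoch.  All selected channel signals are transformed and their
    energies averaged; ``n_averaged`` records the epoch count.
    """
    selected = [ep for ep in epochs if group not in ("L", "R") or ep.label == group]
    if not selected:
        raise ValueError(f"no epochs in group {group!r}")
    if not channels:
        raise ValueError("channel subset must be non-empty")
    fs = selected[0].fs
    idx = [selected[0].channel_labels.index(ch) for ch in channels]
    stack = np.concatenate([ep.data[idx] for ep in selected], axis=0)
    w = morlet_cwt(stack, fs, freqs)
    energy = np.mean(np.abs(w.coefficients) ** 2, axis=0)
    return TimeFreqMap(
        energy=energy,
        freq_axis=w.freqs,
        time_axis=selected[0].time_axis,
        n_averaged=len(selected),
        group=group if group in ("L", "R") else "single",
    )


def _grid_quadrature(
    tfmap_values: np.ndarray,
    freq_axis: np.ndarray,
    time_axis: np.ndarray,
    f_band: tuple[float, float],
    t_window: tuple[float, float],
) -> float:
    fi = (freq_axis >= f_band[0] - 1e-12) & (freq_axis <= f_band[1] + 1e-12)
    ti = (time_axis >= t_window[0] - 1e-12) & (time_axis <= t_window[1] + 1e-12)
    if fi.sum() < 2 or ti.sum() < 2:
        raise ValueError("band/window must contain at least two grid points")
    block = tfmap_values[np.ix_(fi, ti)]
    inner = np.trapezoid(block, x=time_axis[ti], axis=1)
    return float(np.trapezoid(inner, x=freq_axis[fi]))


def delta_a(
    a_l: TimeFreqMap,
    a_r: TimeFreqMap,
    f_band: tuple[float, float] | None = None,
    t_window: tuple[float, float] | None = None,
    normalize: bool = False,
) -> float:
    """Integrated class contrast <dA> between averaged wavelet spectra.

    2-D trapezoidal quadrature of (<A_L> - <A_R>) over ``f_band`` x
    ``t_window`` (defaults: the full grid).  With ``normalize`` the value
    is divided by the same quadrature of the grand mean (<A_L> + <A_R>)/2,
    giving a dimensionless comparison coefficient.
    """
    if a_l.energy.shape != a_r.energy.shape or not (
        np.allclose(a_l.freq_axis, a_r.freq_axis)
        and np.allclose(a_l.time_axis, a_r.time_axis)
    ):
        raise ValueError("the two spectra must share the same grid")
    f_band = f_band or (float(a_l.freq_axis[0]), float(a_l.freq_axis[-1]))
    t_window = t_window or (float(a_l.time_axis[0]), float(a_l.time_axis[-1]))
    diff = _grid_quadrature(
        a_l.energy - a_r.energy, a_l.freq_axis, a_l.time_axis, f_band, t_window
    )
    if not normalize:
        return diff
    denom = _grid_quadrature(
        (a_l.energy + a_r.energy) / 2.0, a_l.freq_axis, a_l.time_axis, f_band, t_window
    )
    return diff / denom


def band_mean(
    tfmap: TimeFreqMap,
    f_band: tuple[float, float],
    t_window: tuple[float, float],
) -> float:
    """Mean energy over a frequency band x time window (grid mean)."""
    fi = (tfmap.freq_axis >= f_band[0] - 1e-12) & (tfmap.freq_axis <= f_band[1] + 1e-12)
    ti = (tfmap.time_axis >= t_window[0] - 1e-12) & (tfmap.time_axis <= t_window[1] + 1e-12)
    if not fi.any() or not ti.any():
        raise ValueError("band/window outside the grid")
    return float(tfmap.energy[np.ix_(fi, ti)].mean())


def write_timefreq_map(tfmap: TimeFreqMap, path) -> None:
    """Delimited matrix with axis header rows: first row the time axis,
    first column the frequency axis."""
    df = pd.DataFrame(
        tfmap.energy,
        index=pd.Index(tfmap.freq_axis, name="freq_hz"),
        columns=np.round(tfmap.time_axis, 9),
    )
    df.to_csv(path, sep="\t")
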