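"""Seeded synthetic multi-subject EEG sessions for the Necker-cube paradigm.

The generator emulates the statistical structure the downstream analysis
assumes: per-subject background EEG (1/f-like noise plus an
occipital-dominant alpha rhythm), stimulus-locked alpha desynchronization,
a class-dependent biphasic evoked component whose two lobes differ in
scalp topography, and linearly mixed blink/saccade EOG artifacts with
frontal-weighted gains.  Trial timing follows the two experimental
designs: 0.8-1.3 s presentations, inter-stimulus intervals of 2-3 s
(button response) or 5-7 s (voice response), and a wireframe-contrast
parameter g drawn from the seven values used in the study.

Every output is a pure function of (seed, parameters): all draws come
from one session-level seeded stream with a documented draw order (see
:func:`generate_session`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .montage import (
    ALPHA_GAINS,
    CHANNELS_1020,
    EOG_GAINS_DEFAULT,
    EVOKED_EARLY_GAINS,
    EVOKED_LATE_GAINS,
    N_CHANNELS,
    channel_index,
)

#: The seven wireframe-contrast values presented in the study.
G_VALUES: tuple[float, ...] = (0.15, 0.3, 0.4, 0.5, 0.6, 0.7, 0.85)

#: Presentation duration range tau, seconds.
TAU_RANGE: tuple[float, float] = (0.8, 1.3)

#: Inter-stimulus interval ranges, seconds, per experimental design.
ISI_RANGES: dict[str, tuple[float, float]] = {
    "button": (2.0, 3.0),   # gamma in the key-press design
    "voice": (5.0, 7.0),    # eta in the voice-response design
}

#: Quiet lead-in/lead-out appended around the trial sequence, seconds.
LEAD_SECONDS = 2.0

#: Hard cap on session duration, seconds.
MAX_SESSION_SECONDS = 3600.0

# Timing of the two lobes of the class-dependent evoked component,
# seconds after stimulus onset.
EARLY_WINDOW: tuple[float, float] = (0.2, 0.4)
LATE_WINDOW: tuple[float, float] = (0.6, 0.8)


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject generator parameters.

    Amplitudes are in microvolts.  ``alpha_amp`` is the peak amplitude of
    the background alpha oscillation at O1/O2; ``noise_amp`` is the RMS of
    the 1/f^slope background noise per channel; ``class_effect_amp`` is
    the peak amplitude *a* of each lobe of the class-dependent evoked
    component at O1/O2.
    """

    subject_id: int
    alpha_freq: float = 10.0          # Hz, individual alpha peak
    alpha_amp: float = 20.0           # uV at O1/O2
    noise_amp: float = 10.0           # uV RMS per channel
    noise_slope: float = 1.0          # spectral exponent of 1/f^slope noise
    class_effect_amp: float = 15.0    # uV, lobe peak at O1/O2
    desync_factor: float = 0.6        # alpha gain during presentations
    blink_rate: float = 12.0          # events/min on the vertical EOG
    saccade_rate: float = 8.0         # events/min on the horizontal EOG
    class_alpha_surplus: float = 0.0  # extra alpha gain during L presentations
    eog_mix_gains: np.ndarray = field(
        default_factory=lambda: EOG_GAINS_DEFAULT.copy()
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 8.0 <= self.alpha_freq <= 12.0:
            raise ValueError(f"alpha_freq must be in [8, 12] Hz, got {self.alpha_freq}")
        if not 0.0 <= self.desync_factor <= 1.0:
            raise ValueError(f"desync_factor must be in [0, 1], got {self.desync_factor}")
        for name in (
            "alpha_amp", "noise_amp", "class_effect_amp",
            "blink_rate", "saccade_rate", "class_alpha_surplus",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        gains = np.asarray(self.eog_mix_gains, dtype=float)
        if gains.shape != (N_CHANNELS,):
            raise ValueError(f"eog_mix_gains must have shape ({N_CHANNELS},)")
        if not gains[channel_index("Fp1")] > gains[channel_index("O1")]:
            raise ValueError("eog_mix_gains must be frontal-dominant (Fp1 > O1)")
        object.__setattr__(self, "eog_mix_gains", gains)


@dataclass
class Recording:
    """A multichannel scalp recording with its two EOG references.

    ``signal`` is channels x samples in microvolts, in the order of
    :data:`neckernet.montage.CHANNELS_1020`.
    """

    signal: np.ndarray          # (P, S) uV
    fs: float                   # Hz
    channel_labels: tuple[str, ...]
    eog_v: np.ndarray           # (S,) uV, vertical EOG reference
    eog_h: np.ndarray           # (S,) uV, horizontal EOG reference
    subject_id: int = 0

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.eog_v = np.asarray(self.eog_v, dtype=float)
        self.eog_h = np.asarray(self.eog_h, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D channels x samples array")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        s = self.signal.shape[1]
        if self.eog_v.shape != (s,) or self.eog_h.shape != (s,):
            raise ValueError("EOG references must match the signal sample count")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError("channel_labels length must match signal rows")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def copy(self) -> "Recording":
        return Recording(
            signal=self.signal.copy(),
            fs=self.fs,
            channel_labels=tuple(self.channel_labels),
            eog_v=self.eog_v.copy(),
            eog_h=self.eog_h.copy(),
            subject_id=self.subject_id,
        )


#: EventLog column order (tab-delimited on disk).
EVENT_COLUMNS = ("onset_sample", "g", "label", "presentation_samples")


def empty_event_log() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "onset_sample": pd.Series(dtype=int),
            "g": pd.Series(dtype=float),
            "label": pd.Series(dtype=str),
            "presentation_samples": pd.Series(dtype=int),
        }
    )


def validate_event_log(events: pd.DataFrame, n_samples: int | None = None) -> None:
    """Check the EventLog invariants (ordering, labels, bounds)."""
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise ValueError(f"event log missing columns: {sorted(missing)}")
    onsets = events["onset_sample"].to_numpy()
    if len(onsets) > 1 and not np.all(np.diff(onsets) > 0):
        raise ValueError("event onsets must be strictly increasing")
    bad = set(events["label"].unique()) - {"L", "R"}
    if bad:
        raise ValueError(f"labels must be 'L' or 'R', found {sorted(bad)}")
    if n_samples is not None and len(onsets) and onsets[-1] >= n_samples:
        raise ValueError("event onset beyond end of recording")


def generate_subject_profile(
    seed: int, subject_id: int, overrides: dict | None = None
) -> SubjectProfile:
    """Draw a deterministic :class:`SubjectProfile` for one subject.

    The individual alpha peak is drawn uniformly in 8-12 Hz and the
    desynchronization factor in 0.4-0.8; everything else takes the class
    defaults unless overridden.  Identical ``(seed, subject_id)`` always
    yields the identical profile; ``overrides`` are validated against the
    profile invariants.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(subject_id)]))
    drawn = {
        "alpha_freq": float(rng.uniform(8.0, 12.0)),
        "desync_factor": float(rng.uniform(0.4, 0.8)),
        "rng_seed": int(rng.integers(0, 2**31 - 1)),
    }
    if overrides:
        unknown = set(overrides) - {f.name for f in dataclasses.fields(SubjectProfile)}
        if unknown:
            raise ValueError(f"unknown profile overrides: {sorted(unknown)}")
        drawn.update(overrides)
    return SubjectProfile(subject_id=subject_id, **drawn)


def _shaped_noise(rng: np.random.Generator, n: int, slope: float, fs: float) -> np.ndarray:
    """Unit-RMS Gaussian noise with a 1/f^slope amplitude spectrum."""
    white = rng.standard_normal(n)
    if slope == 0:
        out = white
    else:
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, d=1.0 / fs)
        shaping = np.zeros_like(freqs)
        shaping[1:] = freqs[1:] ** (-slope / 2.0)
        out = np.fft.irfft(spec * shaping, n=n)
    rms = np.sqrt(np.mean(out**2))
    return out / rms if rms > 0 else out


def _narrowband_alpha(
    rng: np.random.Generator, n: int, fs: float, f0: float, amp: float
) -> np.ndarray:
    """Waxing-waning alpha rhythm: white noise band-passed around f0.

    Scaled so the oscillation's RMS equals ``amp / sqrt(2)``, i.e. ``amp``
    plays the role of a sinusoid amplitude.
    """
    white = rng.standard_normal(n)
    lo, hi = max(f0 - 1.0, 0.5), min(f0 + 1.0, fs / 2 - 1.0)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    band = sps.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(band**2))
    if rms > 0:
        band = band * (amp / np.sqrt(2.0) / rms)
    return band


def _raised_cosine_lobe(fs: float, start: float, end: float, n: int) -> np.ndarray:
    """Unit-peak raised-cosine (Hann) lobe on [start, end) s, length n."""
    out = np.zeros(n)
    i0, i1 = int(round(start * fs)), int(round(end * fs))
    i1 = min(i1, n)
    if i1 > i0:
        width = i1 - i0
        t = np.arange(width)
        out[i0:i1] = 0.5 * (1.0 - np.cos(2.0 * np.pi * (t + 0.5) / width))
    return out


def class_component_templates(fs: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    """The two unit-peak lobes of the evoked component, length ``n`` samples.

    Returns ``(early, late)``: raised-cosine lobes on 0.2-0.4 s and
    0.6-0.8 s after onset.  For an L-labelled trial the injected component
    on channel p is ``a * (early * g_early[p] - late * g_late[p])``; for R
    it is negated.
    """
    early = _raised_cosine_lobe(fs, *EARLY_WINDOW, n)
    late = _raised_cosine_lobe(fs, *LATE_WINDOW, n)
    return early, late


def ground_truth_difference_mean(
    profile: SubjectProfile,
    window: tuple[float, float],
    fs: float,
    channel: str = "O1",
) -> float:
    """Exact window mean of the injected L-minus-R difference trace.

    The class-averaged difference at channel p equals twice the injected
    L component: ``2a * (early * g_early[p] - late * g_late[p])``.  This
    is the generator's ground truth against which recovered ERP
    difference-window means can be compared.
    """
    n = int(round(fs * 1.0))
    early, late = class_component_templates(fs, n)
    p = channel_index(channel)
    template = 2.0 * profile.class_effect_amp * (
        early * EVOKED_EARLY_GAINS[p] - late * EVOKED_LATE_GAINS[p]
    )
    i0, i1 = int(round(window[0] * fs)), int(round(window[1] * fs))
    return float(np.mean(template[i0:i1]))


def generate_session(
    profile: SubjectProfile,
    n_trials: int,
    fs: float = 250.0,
    design: str = "button",
) -> tuple[Recording, pd.DataFrame]:
    """Simulate one recording session for a subject.

    Draw order from the session stream (seeded by ``profile.rng_seed``):

    1. per-trial presentation durations tau_i ~ U(0.8, 1.3) s;
    2. per-trial inter-stimulus intervals (U(2, 3) s button, U(5, 7) s voice);
    3. per-trial contrasts g_i uniform over the seven study values;
    4. per-trial labels, P(L) = 1 - g (low contrast of the left-corner
       wireframe biases toward the left-oriented percept);
    5. per-channel 1/f^slope background noise;
    6. the shared narrowband alpha waveform.

    The alpha waveform is attenuated by ``desync_factor`` during each
    presentation window, weighted across channels by the occipital-dominant
    alpha topography.  The class-dependent biphasic component is added per
    trial with sign +1 for L and -1 for R.  EOG channels are returned as
    zeros; use :func:`inject_eog` to add ocular artifacts.
    """
    if n_trials < 0:
        raise ValueError("n_trials must be non-negative")
    if fs < 100:
        raise ValueError("sampling rate must be at least 100 Hz")
    if design not in ISI_RANGES:
        raise ValueError(f"design must be one of {sorted(ISI_RANGES)}")

    rng = np.random.default_rng(np.random.SeedSequence([profile.rng_seed, 0]))

    tau = rng.uniform(*TAU_RANGE, size=n_trials)
    isi = rng.uniform(*ISI_RANGES[design], size=n_trials)
    g = rng.choice(G_VALUES, size=n_trials)
    labels = np.where(rng.random(n_trials) < (1.0 - g), "L", "R")

    duration = 2 * LEAD_SECONDS + float(np.sum(tau) + np.sum(isi))
    if duration > MAX_SESSION_SECONDS:
        raise ValueError(
            f"session of {duration:.0f} s exceeds the {MAX_SESSION_SECONDS:.0f} s maximum"
        )
    n_samples = int(round(duration * fs))

    onsets = np.zeros(n_trials, dtype=int)
    t_cursor = LEAD_SECONDS
    pres_samples = np.zeros(n_trials, dtype=int)
    for i in range(n_trials):
        onsets[i] = int(round(t_cursor * fs))
        pres_samples[i] = int(round(tau[i] * fs))
        t_cursor += tau[i] + isi[i]

    signal_uv = np.empty((N_CHANNELS, n_samples))
    for p in range(N_CHANNELS):
        signal_uv[p] = profile.noise_amp * _shaped_noise(
            rng, n_samples, profile.noise_slope, fs
        )

    alpha = _narrowband_alpha(rng, n_samples, fs, profile.alpha_freq, profile.alpha_amp)
    desync_mask = np.ones(n_samples)
    for i in range(n_trials):
        factor = profile.desync_factor
        if labels[i] == "L":
            # optional class-dependent alpha modulation (off by default)
            factor = factor * (1.0 + profile.class_alpha_surplus)
        desync_mask[onsets[i] : onsets[i] + pres_samples[i]] = factor
    alpha_masked = alpha * desync_mask
    signal_uv += ALPHA_GAINS[:, None] * alpha_masked[None, :]

    trial_len = int(round(fs * 1.0))
    early, late = class_component_templates(fs, trial_len)
    comp = (
        EVOKED_EARLY_GAINS[:, None] * early[None, :]
        - EVOKED_LATE_GAINS[:, None] * late[None, :]
    ) * profile.class_effect_amp
    for i in range(n_trials):
        sign = 1.0 if labels[i] == "L" else -1.0
        stop = min(onsets[i] + trial_len, n_samples)
        signal_uv[:, onsets[i] : stop] += sign * comp[:, : stop - onsets[i]]

    recording = Recording(
        signal=signal_uv,
        fs=fs,
        channel_labels=CHANNELS_1020,
        eog_v=np.zeros(n_samples),
        eog_h=np.zeros(n_samples),
        subject_id=profile.subject_id,
    )
    events = pd.DataFrame(
        {
            "onset_sample": onsets,
            "g": g,
            "label": labels,
            "presentation_samples": pres_samples,
        }
    )
    validate_event_log(events, n_samples)
    return recording, events


def _eog_events(
    rng: np.random.Generator,
    n_samples: int,
    fs: float,
    rate_per_min: float,
    waveform: np.ndarray,
    amp_mean: float,
    amp_sd: float,
    signed: bool,
) -> np.ndarray:
    """Superpose a stereotyped waveform at Poisson event times."""
    out = np.zeros(n_samples)
    n_events = rng.poisson(rate_per_min / 60.0 * n_samples / fs)
    starts = np.sort(rng.integers(0, max(n_samples - len(waveform), 1), size=n_events))
    for s in starts:
        amp = rng.normal(amp_mean, amp_sd)
        if signed and rng.random() < 0.5:
            amp = -amp
        stop = min(s + len(waveform), n_samples)
        out[s:stop] += amp * waveform[: stop - s]
    return out


def inject_eog(recording: Recording, profile: SubjectProfile) -> Recording:
    """Add blink/saccade ocular artifacts to a recording (pure, seeded).

    Blinks are ~300 ms raised-cosine bumps (mean 120 uV) on the vertical
    EOG; saccades are ~250 ms smoothed square pulses of random sign (mean
    60 uV) on the horizontal EOG, at the profile's Poisson rates.  Both
    references are added to every scalp channel scaled by the profile's
    frontal-dominant mixing gains — purely additive linear mixing, so
    downstream orthogonalization can remove the contamination exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([profile.rng_seed, 1]))
    out = recording.copy()
    n, fs = out.n_samples, out.fs

    blink_len = int(round(0.3 * fs))
    blink_wave = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(blink_len) / blink_len))
    eog_v = _eog_events(rng, n, fs, profile.blink_rate, blink_wave, 120.0, 20.0, signed=False)

    sacc_len = int(round(0.25 * fs))
    ramp = max(int(round(0.04 * fs)), 1)
    sacc_wave = np.ones(sacc_len)
    sacc_wave[:ramp] = np.linspace(0.0, 1.0, ramp)
    sacc_wave[-ramp:] = np.linspace(1.0, 0.0, ramp)
    eog_h = _eog_events(rng, n, fs, profile.saccade_rate, sacc_wave, 60.0, 15.0, signed=True)

    out.eog_v = out.eog_v + eog_v
    out.eog_h = out.eog_h + eog_h
    out.signal = out.signal + profile.eog_mix_gains[:, None] * (eog_v + eog_h)[None, :]
    return out


def generate_cohort(
    seed: int,
    n_subjects: int,
    n_trials: int,
    fs: float = 250.0,
    design: str = "button",
    overrides: dict | None = None,
    with_eog: bool = True,
) -> list[tuple[SubjectProfile, Recording, pd.DataFrame]]:
    """Generate a multi-subject cohort of sessions with one master seed."""
    cohort = []
    for sid in range(1, n_subjects + 1):
        profile = generate_subject_profile(seed, sid, overrides)
        rec, events = generate_session(profile, n_trials, fs=fs, design=design)
        if with_eog:
            rec = inject_eog(rec, profile)
        cohort.append((profile, rec, events))
    return cohort


def write_event_log(events: pd.DataFrame, path) -> None:
    """Write an EventLog as tab-delimited text."""
    events.loc[:, list(EVENT_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_event_log(path) -> pd.DataFrame:
    """Read a tab-delimited EventLog written by :func:`write_event_log`."""
    events = pd.read_csv(path, sep="\t", dtype={"label": str})
    validate_event_log(events)
    return events
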