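"""Event-related potentials: class-conditional trial averages, the
L-minus-R difference trace, and window summaries of its components."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import Trial


@dataclass
class ERPTrace:
    """Per-channel class-averaged trace x_bar_p(t)."""

    mean_trace: np.ndarray       # (P, N), trial-scaled units
    n_trials: int
    label: str                   # 'L' or 'R'
    channel_labels: tuple[str, ...]
    fs: float

    def __post_init__(self) -> None:
        self.mean_trace = np.asarray(self.mean_trace, dtype=float)
        if not np.all(np.isfinite(self.mean_trace)):
            raise ValueError("ERP trace must be finite")
        if self.n_trials < 1:
            raise ValueError("an ERP trace requires at least one trial")


def average_trials(
    trials: list[Trial], label: str, channel_labels: tuple[str, ...] | None = None
) -> ERPTrace:
    """Arithmetic per-channel mean over the trials of one percept class."""
    selected = [tr for tr in trials if tr.label == label]
    if not selected:
        raise ValueError(f"no trials with label {label!r}")
    shapes = {tr.data.shape for tr in selected}
    if len(shapes) != 1:
        raise ValueError("trials must share channel count and length")
    mean = np.mean([tr.data for tr in selected], axis=0)
    if channel_labels is None:
        from .montage import CHANNELS_1020

        channel_labels = CHANNELS_1020[: mean.shape[0]]
    return ERPTrace(
        mean_trace=mean,
        n_trials=len(selected),
        label=label,
        channel_labels=tuple(channel_labels),
        fs=selected[0].fs,
    )


def difference_trace(erp_l: ERPTrace, erp_r: ERPTrace) -> np.ndarray:
    """Delta_p(t) = x_bar_p^L(t) - x_bar_p^R(t), per channel."""
    if erp_l.mean_trace.shape != erp_r.mean_trace.shape:
        raise ValueError("class averages must have the same shape")
    if erp_l.channel_labels != erp_r.channel_labels:
        raise ValueError("class averages must share the channel set")
    return erp_l.mean_trace - erp_r.mean_trace


def component_windows(
    delta: np.ndarray,
    windows: list[tuple[float, float]],
    fs: float,
    channel_labels: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Mean of the difference trace over each [start, end) s window.

    Windows use the half-open sample convention ``[round(start*fs),
    round(end*fs))``.  Returns channels x windows, columns labelled
    '<start>-<end>s'.
    """
    delta = np.asarray(delta, dtype=float)
    n = delta.shape[1]
    duration = n / fs
    out = {}
    for start, end in windows:
        if start < 0 or end > duration + 1e-9 or end <= start:
            raise ValueError(f"window ({start}, {end}) outside [0, {duration:.3f}] s")
        i0, i1 = int(round(start * fs)), int(round(end * fs))
        out[f"{start:g}-{end:g}s"] = delta[:, i0:i1].mean(axis=1)
    if channel_labels is None:
        from .montage import CHANNELS_1020

        channel_labels = CHANNELS_1020[: delta.shape[0]]
    return pd.DataFrame(out, index=pd.Index(channel_labels, name="channel"))
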