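"""Channel conventions for the 19-electrode 10-20 montage.

All spatial weighting used by the synthetic generator lives here: the scalp
channel order, the occipital-dominant topography of the background alpha
rhythm, the topographies of the two lobes of the class-dependent evoked
component, and the frontal-weighted gains with which ocular (EOG) activity
leaks into the scalp channels.
"""

from __future__ import annotations

import numpy as np

#: Scalp channels in recording order (classic 19-channel 10-20 set).
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

N_CHANNELS = len(CHANNELS_1020)

#: Default occipital channel subset for wavelet averaging.
OCCIPITAL_DEFAULT: tuple[str, ...] = ("O1", "O2")

#: Extended posterior set (occipital + parietal + central midline).
OCCIPITAL_EXTENDED: tuple[str, ...] = ("O1", "O2", "P3", "P4", "Cz", "Pz")


def channel_index(label: str) -> int:
    """Index of a 10-20 label in the recording order."""
    try:
        return CHANNELS_1020.index(label)
    except ValueError as exc:
        raise KeyError(f"unknown 10-20 channel label: {label!r}") from exc


def _gain_vector(mapping: dict[str, float], default: float) -> np.ndarray:
    return np.array([mapping.get(ch, default) for ch in CHANNELS_1020])


# Background alpha rhythm: strongest over occipital cortex, fading frontally.
ALPHA_GAINS = _gain_vector(
    {
        "O1": 1.0, "O2": 1.0,
        "T5": 0.6, "T6": 0.6, "P3": 0.6, "P4": 0.6, "Pz": 0.6,
        "C3": 0.35, "Cz": 0.35, "C4": 0.35, "T3": 0.35, "T4": 0.35,
    },
    default=0.2,
)

# Early lobe (0.2-0.4 s) of the class-dependent evoked component:
# occipital-dominant with weak frontal spread.
EVOKED_EARLY_GAINS = _gain_vector(
    {
        "O1": 1.0, "O2": 1.0,
        "P3": 0.5, "P4": 0.5, "Pz": 0.5, "Cz": 0.5,
        "Fz": 0.4,
    },
    default=0.2,
)

# Late lobe (0.6-0.8 s): strongest at the fronto-central midline with the
# occipital sites still clearly involved -- the two lobes deliberately
# differ in topography, which is what makes the percept classes
# distinguishable to a classifier applied sample-by-sample (a pure sign
# flip with identical topography would be invisible to any order-invariant
# trial statistic).
EVOKED_LATE_GAINS = _gain_vector(
    {
        "Fz": 1.0, "Cz": 0.8,
        "F3": 0.5, "F4": 0.5,
        "O1": 0.6, "O2": 0.6,
        "P3": 0.3, "P4": 0.3, "Pz": 0.3,
    },
    default=0.2,
)

# Ocular artifact leakage into scalp channels: strongest at the frontal
# poles, negligible occipitally.
EOG_GAINS_DEFAULT = _gain_vector(
    {
        "Fp1": 0.40, "Fp2": 0.40,
        "F7": 0.25, "F8": 0.25,
        "F3": 0.20, "Fz": 0.20, "F4": 0.20,
        "T3": 0.10, "T4": 0.10,
        "C3": 0.08, "Cz": 0.08, "C4": 0.08,
        "T5": 0.05, "P3": 0.05, "Pz": 0.05, "P4": 0.05, "T6": 0.05,
    },
    default=0.02,
)
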