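"""EDF round-trip for synthetic recordings.

Recordings are written as plain EDF (16-bit, 1-s data records) with the 19
scalp channels followed by the two EOG references as extra channels, and
read back through :func:`mne.io.read_raw_edf`.  Amplitudes survive the
round trip up to the 16-bit quantization of each channel's physical range.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np

from .synthgen import Recording

EOG_LABELS = ("EOGv", "EOGh")

_HDR_DATE = datetime.datetime(2000, 1, 1, 0, 0, 0)  # fixed: outputs are synthetic


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {text!r} (max {width})")
    return b.ljust(width)


def write_edf(recording: Recording, path) -> Path:
    """Write a :class:`Recording` to a plain EDF file.

    Each channel is digitized to int16 over its own physical min/max
    (symmetric about zero).  The record duration is 1 s; the signal is
    zero-padded to a whole number of records.
    """
    path = Path(path)
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record per channel

    data = np.vstack([recording.signal, recording.eog_v, recording.eog_h])
    labels = list(recording.channel_labels) + list(EOG_LABELS)
    ns, n_samples = data.shape
    n_records = int(np.ceil(n_samples / spr))
    padded = np.zeros((ns, n_records * spr))
    padded[:, :n_samples] = data

    phys_max = np.maximum(np.abs(padded).max(axis=1), 1e-3)
    dig_max, dig_min = 32767, -32768
    scale = dig_max / phys_max

    header = b"".join(
        [
            _field("0", 8),
            _field(f"subject_{recording.subject_id} synthetic", 80),
            _field("neckernet synthetic session", 80),
            _field(_HDR_DATE.strftime("%d.%m.%y"), 8),
            _field(_HDR_DATE.strftime("%H.%M.%S"), 8),
            _field(str(256 * (ns + 1)), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field("1", 8),
            _field(str(ns), 4),
        ]
    )
    sig_hdr = b"".join(
        [
            b"".join(_field(lbl, 16) for lbl in labels),
            b"".join(_field("synthetic", 80) for _ in labels),
            b"".join(_field("uV", 8) for _ in labels),
            b"".join(_field(f"{-phys_max[i]:.6g}"[:8], 8) for i in range(ns)),
            b"".join(_field(f"{phys_max[i]:.6g}"[:8], 8) for i in range(ns)),
            b"".join(_field(str(dig_min), 8) for _ in labels),
            b"".join(_field(str(dig_max), 8) for _ in labels),
            b"".join(_field("HP:1Hz LP:100Hz N:50Hz", 80) for _ in labels),
            b"".join(_field(str(spr), 8) for _ in labels),
            b"".join(_field("", 32) for _ in labels),
        ]
    )

    digital = np.clip(
        np.rint(padded * scale[:, None]), dig_min, dig_max
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_hdr)
        for r in range(n_records):
            sl = slice(r * spr, (r + 1) * spr)
            for i in range(ns):
                fh.write(digital[i, sl].tobytes())
    return path


def read_edf(path, subject_id: int = 0) -> Recording:
    """Read an EDF file back into a :class:`Recording` via MNE.

    The two trailing ``EOGv``/``EOGh`` channels are split back out as the
    EOG references.  Values are returned in microvolts.
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # MNE loads EDF in volts
    names = list(raw.ch_names)
    eog_idx = {lbl: names.index(lbl) for lbl in EOG_LABELS if lbl in names}
    if len(eog_idx) != 2:
        raise ValueError("EDF file lacks the EOGv/EOGh reference channels")
    scalp_idx = [i for i in range(len(names)) if i not in eog_idx.values()]
    return Recording(
        signal=data_uv[scalp_idx],
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(names[i] for i in scalp_idx),
        eog_v=data_uv[eog_idx["EOGv"]],
        eog_h=data_uv[eog_idx["EOGh"]],
        subject_id=subject_id,
    )
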