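"""Minimal European Data Format (EDF) writer/reader.

Implements the plain EDF container (256-byte fixed header, 256 bytes per
signal header, 16-bit little-endian samples, one data record per second),
which is sufficient for round-tripping simulated cohorts and typical
clinical exports. Annotations are intentionally not parsed; eyes-closed
intervals travel in a sidecar CSV (see :mod:`eegfc.simulate`).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import List

import numpy as np

from .montage import validate_labels
from .recording import GROUP_UNKNOWN, GROUPS, Recording

_DIG_MIN = -32768
_DIG_MAX = 32767


class EDFError(ValueError):
    pass


def _ascii_field(value: str, width: int) -> bytes:
    raw = value.encode("ascii", errors="replace")[:width]
    return raw.ljust(width)


def write_edf(path: str | Path, recording: Recording) -> Path:
    """Write one recording as an EDF file (one data record per second).

    The subject id is stored in the patient-identification field and the
    group label in the recording-identification field. Signals are scaled
    per channel to the full 16-bit digital range; physical dimension is uV.
    """
    path = Path(path)
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise EDFError(f"EDF export requires an integer sampling rate, got {fs}")
    fs = int(round(fs))
    n_ch = recording.n_channels
    n_rec = recording.n_samples // fs
    if n_rec * fs != recording.n_samples:
        warnings.warn(
            f"{recording.subject_id}: trailing {recording.n_samples - n_rec * fs} "
            "samples do not fill a 1-s data record and are dropped on export"
        )
    if n_rec < 1:
        raise EDFError("recording shorter than one data record (1 s)")
    data = recording.data[:, : n_rec * fs]

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    flat = phys_max - phys_min < 1e-12
    phys_min = np.where(flat, phys_min - 1.0, phys_min)
    phys_max = np.where(flat, phys_max + 1.0, phys_max)
    gain = (_DIG_MAX - _DIG_MIN) / (phys_max - phys_min)
    digital = np.round((data - phys_min[:, None]) * gain[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    header = bytearray()
    header += _ascii_field("0", 8)
    header += _ascii_field(recording.subject_id, 80)
    header += _ascii_field(f"group={recording.group_label}", 80)
    header += _ascii_field("01.01.20", 8)
    header += _ascii_field("00.00.00", 8)
    header += _ascii_field(str(256 * (1 + n_ch)), 8)
    header += _ascii_field("", 44)
    header += _ascii_field(str(n_rec), 8)
    header += _ascii_field("1", 8)
    header += _ascii_field(str(n_ch), 4)

    def sig_fields(values: List[str], width: int) -> bytes:
        return b"".join(_ascii_field(v, width) for v in values)

    header += sig_fields(list(recording.channel_labels), 16)
    header += sig_fields([""] * n_ch, 80)
    header += sig_fields(["uV"] * n_ch, 8)
    header += sig_fields([f"{v:.8g}"[:8] for v in phys_min], 8)
    header += sig_fields([f"{v:.8g}"[:8] for v in phys_max], 8)
    header += sig_fields([str(_DIG_MIN)] * n_ch, 8)
    header += sig_fields([str(_DIG_MAX)] * n_ch, 8)
    header += sig_fields([""] * n_ch, 80)
    header += sig_fields([str(fs)] * n_ch, 8)
    header += sig_fields([""] * n_ch, 32)

    # records: interleave by second, each signal contiguous within a record
    body = digital.reshape(n_ch, n_rec, fs).transpose(1, 0, 2).tobytes()
    path.write_bytes(bytes(header) + body)
    return path


def read_edf(path: str | Path, normalize_channel_labels: bool = True) -> Recording:
    """Read a plain EDF file back into a :class:`Recording`.

    Eyes-closed intervals default to the full duration; callers holding a
    sidecar annotation table should overwrite them afterwards.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise EDFError(f"{path}: truncated EDF header")

    def field(offset: int, width: int) -> str:
        return raw[offset : offset + width].decode("ascii", errors="replace").strip()

    subject_id = field(8, 80) or path.stem
    rec_field = field(88, 80)
    group_label = GROUP_UNKNOWN
    if rec_field.startswith("group="):
        candidate = rec_field[len("group="):]
        if candidate in GROUPS:
            group_label = candidate
    n_rec = int(field(236, 8))
    rec_dur = float(field(244, 8))
    n_ch = int(field(252, 4))

    off = 256
    labels = [field(off + 16 * i, 16) for i in range(n_ch)]
    off += n_ch * (16 + 80 + 8)  # skip transducer + physical dimension
    phys_min = np.array([float(field(off + 8 * i, 8)) for i in range(n_ch)])
    off += n_ch * 8
    phys_max = np.array([float(field(off + 8 * i, 8)) for i in range(n_ch)])
    off += n_ch * 8
    dig_min = np.array([float(field(off + 8 * i, 8)) for i in range(n_ch)])
    off += n_ch * 8
    dig_max = np.array([float(field(off + 8 * i, 8)) for i in range(n_ch)])
    off += n_ch * 8 + n_ch * 80
    spr = [int(field(off + 8 * i, 8)) for i in range(n_ch)]
    if len(set(spr)) != 1:
        raise EDFError(f"{path}: heterogeneous samples-per-record {set(spr)} unsupported")
    spr0 = spr[0]

    header_bytes = 256 * (1 + n_ch)
    body = np.frombuffer(raw, dtype="<i2", offset=header_bytes,
                         count=n_rec * n_ch * spr0)
    digital = body.reshape(n_rec, n_ch, spr0).transpose(1, 0, 2).reshape(n_ch, -1)
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    data = (digital - dig_min[:, None]) * gain[:, None] + phys_min[:, None]

    fs = spr0 / rec_dur
    if normalize_channel_labels:
        labels = validate_labels(labels)
    duration = n_rec * rec_dur
    return Recording(
        subject_id=subject_id,
        group_label=group_label,
        channel_labels=labels,
        fs=fs,
        data=data,
        eyes_closed_intervals=[(0.0, duration)],
    )
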