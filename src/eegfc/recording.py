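"""Continuous multichannel recording container."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Sequence, Tuple

import numpy as np

GROUP_A = "ASD-like"
GROUP_B = "TD-like"
GROUP_UNKNOWN = "unknown"
GROUPS = (GROUP_A, GROUP_B, GROUP_UNKNOWN)


@dataclass
class Recording:
    """One subject's continuous multichannel EEG-like signal.

    Attributes
    ----------
    subject_id : str
        Unique subject identifier.
    group_label : str
        One of ``"ASD-like"``, ``"TD-like"``, ``"unknown"``.
    channel_labels : list of str
        Montage labels, one per row of ``data``.
    fs : float
        Sampling rate in Hz.
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    eyes_closed_intervals : list of (start_s, end_s)
        Annotated eyes-closed stretches, in seconds from recording start.
    """

    subject_id: str
    group_label: str
    channel_labels: List[str]
    fs: float
    data: np.ndarray
    eyes_closed_intervals: List[Tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.group_label not in GROUPS:
            raise ValueError(f"group_label must be one of {GROUPS}")
        dur = self.duration_s
        for start, end in self.eyes_closed_intervals:
            if not (0 <= start < end <= dur + 1e-9):
                raise ValueError(
                    f"eyes-closed interval ({start}, {end}) outside [0, {dur:.3f}]"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray, channel_labels: Sequence[str] | None = None) -> "Recording":
        """Copy of this recording with replaced signal (and optionally labels)."""
        labels = list(channel_labels) if channel_labels is not None else list(self.channel_labels)
        return replace(self, data=np.asarray(data, dtype=float), channel_labels=labels)

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_labels.index(label)]
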