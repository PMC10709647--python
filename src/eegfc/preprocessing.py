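"""Broadband/band-specific FIR filtering, Fz re-referencing and 2-s epoching.

Processing order for a full run is: broadband filter -> re-reference to Fz
-> eyes-closed extraction -> (band filters for connectivity) -> epoching.
All filters are linear-phase Hamming-window FIR designs applied
forward-backward (zero phase) so no group delay leaks into downstream
instantaneous-phase estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import signal

from .montage import MontageError
from .recording import Recording

BROADBAND: Tuple[float, float] = (1.0, 45.0)
DEFAULT_EPOCH_S = 2.0


class FilterDesignError(ValueError):
    pass


class EpochingError(ValueError):
    pass


@dataclass(frozen=True)
class FilterSpec:
    """A designed linear-phase band-pass FIR filter (Hamming window)."""

    f_low: float
    f_high: float
    fs: float
    order: int  # taps - 1, even (type I linear phase)
    taps: np.ndarray
    zero_phase: bool = True
    window: str = "hamming"

    @property
    def n_taps(self) -> int:
        return self.order + 1

    def frequency_response(self, freqs: np.ndarray) -> np.ndarray:
        """Complex response of the one-pass design at the given frequencies."""
        _, h = signal.freqz(self.taps, worN=np.asarray(freqs, dtype=float), fs=self.fs)
        return h


def _heuristic_order(f_low: float, fs: float) -> int:
    # transition bandwidth: 25% of the lower passband edge, floored at 2 Hz;
    # Hamming-window length rule n ~= 3.3 / (tbw / fs), rounded up to even
    tbw = max(0.25 * f_low, 2.0)
    order = int(math.ceil(3.3 * fs / tbw))
    if order % 2:
        order += 1
    return order


def design_bandpass(f_low: float, f_high: float, fs: float,
                    order: int | None = None) -> FilterSpec:
    """Design a Hamming-window band-pass FIR filter.

    When ``order`` is omitted it is derived from a transition bandwidth of
    25% of the lower passband edge (floored at 2 Hz). Explicit orders
    (e.g. 24 for theta/alpha/low-beta phase filters, 50 for high beta)
    override the heuristic. The design is normalized to unity gain at the
    passband center.
    """
    if not (0 < f_low < f_high):
        raise FilterDesignError(f"need 0 < f_low < f_high, got ({f_low}, {f_high})")
    if f_high >= fs / 2:
        raise FilterDesignError(
            f"f_high={f_high} Hz must be below the Nyquist frequency {fs / 2} Hz")
    if order is None:
        order = _heuristic_order(f_low, fs)
    if order < 2 or order % 2:
        raise FilterDesignError(f"order must be even and >= 2, got {order}")
    taps = signal.firwin(order + 1, [f_low, f_high], window="hamming",
                         pass_zero=False, fs=fs)
    # null residual DC leakage when the design already suppresses DC
    # (long filters); short paper-order filters pass DC structurally and
    # must not be redesigned
    if abs(taps.sum()) < 0.01:
        taps = taps - taps.mean()
    return FilterSpec(f_low=f_low, f_high=f_high, fs=fs, order=order, taps=taps)


def filter_array(data: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Apply the filter along the last axis (zero-phase by default)."""
    n = data.shape[-1]
    if n < 3 * spec.n_taps:
        raise FilterDesignError(
            f"signal of {n} samples is shorter than 3 x filter length "
            f"({3 * spec.n_taps}); edge handling would dominate")
    if spec.zero_phase:
        return signal.filtfilt(spec.taps, [1.0], data, axis=-1)
    return signal.lfilter(spec.taps, [1.0], data, axis=-1)


def apply_filter(recording: Recording, spec: FilterSpec) -> Recording:
    """Zero-phase per-channel filtering; length and metadata preserved."""
    if abs(recording.fs - spec.fs) > 1e-9:
        raise FilterDesignError(
            f"recording fs {recording.fs} does not match design fs {spec.fs}")
    return recording.with_data(filter_array(recording.data, spec))


def rereference_to_fz(recording: Recording) -> Recording:
    """Subtract the Fz channel from every other channel and drop Fz."""
    if "Fz" not in recording.channel_labels:
        raise MontageError(
            "cannot re-reference: 'Fz' not among channels "
            f"({', '.join(recording.channel_labels)})")
    idx = recording.channel_labels.index("Fz")
    ref = recording.data[idx]
    keep = [i for i in range(recording.n_channels) if i != idx]
    data = recording.data[keep] - ref
    labels = [recording.channel_labels[i] for i in keep]
    return recording.with_data(data, labels)


@dataclass
class EpochSet:
    """Stack of fixed-length epochs cut from one recording.

    ``epochs`` has shape (n_epochs, n_channels, n_samples_per_epoch).
    """

    subject_id: str
    group_label: str
    channel_labels: List[str]
    fs: float
    epochs: np.ndarray

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (epochs x channels x samples)")
        if self.epochs.shape[1] != len(self.channel_labels):
            raise ValueError("channel count mismatch")
        if self.epochs.shape[0] < 1:
            raise EpochingError("EpochSet requires at least one epoch")
        if np.isnan(self.epochs).any():
            raise ValueError("epochs contain NaNs")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def epoch_len(self) -> int:
        return self.epochs.shape[2]


def interval_slices(intervals: Sequence[Tuple[float, float]], fs: float,
                    n_samples: int) -> List[slice]:
    """Sample slices covering each annotated interval."""
    out = []
    for start, end in intervals:
        a = int(round(start * fs))
        b = min(int(round(end * fs)), n_samples)
        if b > a:
            out.append(slice(a, b))
    return out


def extract_epochs(recording: Recording, epoch_s: float = DEFAULT_EPOCH_S) -> EpochSet:
    """Tile non-overlapping epochs within each eyes-closed interval.

    Trailing partial segments are discarded so every epoch has exactly
    ``round(epoch_s * fs)`` samples.
    """
    if epoch_s <= 0:
        raise EpochingError("epoch_s must be positive")
    length = int(round(epoch_s * recording.fs))
    chunks = []
    for sl in interval_slices(recording.eyes_closed_intervals, recording.fs,
                              recording.n_samples):
        seg = recording.data[:, sl]
        n_ep = seg.shape[1] // length
        for k in range(n_ep):
            chunks.append(seg[:, k * length:(k + 1) * length])
    if not chunks:
        raise EpochingError(
            f"no eyes-closed interval of at least {epoch_s} s "
            f"in {recording.subject_id}")
    return EpochSet(
        subject_id=recording.subject_id,
        group_label=recording.group_label,
        channel_labels=list(recording.channel_labels),
        fs=recording.fs,
        epochs=np.stack(chunks),
    )


def preprocess(recording: Recording,
               broadband: Tuple[float, float] = BROADBAND) -> Recording:
    """Broadband filter then re-reference to Fz (18 channels out of 19)."""
    spec = design_bandpass(broadband[0], broadband[1], recording.fs)
    return rereference_to_fz(apply_filter(recording, spec))
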