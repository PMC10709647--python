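"""Welch band-power features with per-segment 0-1 rescaling across electrodes.

For each 2-s epoch and each band, band power is averaged-PSD over the band,
min-max rescaled across the channels of that epoch, then averaged over
epochs into an (n_channels x 4) feature matrix per subject — 72 features
for the 18-channel post-reference montage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal

from .bands import CANONICAL_BANDS, BandDefinition
from .preprocessing import EpochSet

#: Welch settings inside one 2-s epoch: 1-s Hamming windows, 50% overlap
#: -> 1 Hz grid resolution, 3 averaged windows.
WELCH_WINDOW_S = 1.0
WELCH_OVERLAP = 0.5


class SpectralError(ValueError):
    pass


def welch_psd(epoch: np.ndarray, fs: float,
              window_s: float = WELCH_WINDOW_S,
              overlap: float = WELCH_OVERLAP) -> Tuple[np.ndarray, np.ndarray]:
    """Per-channel Welch PSD (Hamming window) of one epoch.

    Returns ``(freqs, psd)`` with ``psd`` of shape (n_channels, n_freqs).
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    nperseg = int(round(window_s * fs))
    if epoch.shape[-1] < nperseg:
        raise SpectralError(
            f"epoch of {epoch.shape[-1]} samples shorter than one Welch "
            f"window ({nperseg} samples)")
    freqs, psd = signal.welch(
        epoch, fs=fs, window="hamming", nperseg=nperseg,
        noverlap=int(round(nperseg * overlap)), detrend=False, axis=-1)
    return freqs, psd


def band_power(freqs: np.ndarray, psd: np.ndarray, band: BandDefinition) -> np.ndarray:
    """Mean PSD over grid frequencies inside the band (edges inclusive)."""
    mask = (freqs >= band.f_low) & (freqs <= band.f_high)
    if not mask.any():
        raise SpectralError(
            f"band {band.name} ({band.f_low}-{band.f_high} Hz) does not "
            "intersect the PSD frequency grid")
    return np.asarray(psd)[..., mask].mean(axis=-1)


def normalize_segment(values: np.ndarray) -> np.ndarray:
    """Min-max rescale one epoch's per-channel band powers to [0, 1].

    All-equal input maps to all 0.5 (symmetric degenerate convention).
    """
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        raise SpectralError("non-finite band powers cannot be rescaled")
    lo, hi = values.min(), values.max()
    if hi - lo < 1e-300:
        return np.full_like(values, 0.5)
    return (values - lo) / (hi - lo)


@dataclass
class SpectralFeatures:
    """Per-subject normalized band-power topography (channels x bands)."""

    subject_id: str
    group_label: str
    channel_labels: List[str]
    band_names: Tuple[str, ...]
    matrix: np.ndarray  # (n_channels, n_bands), entries in [0, 1]
    n_epochs_used: int

    @property
    def feature_names(self) -> List[str]:
        return [f"{ch}_{band}" for ch in self.channel_labels
                for band in self.band_names]

    def flatten(self) -> np.ndarray:
        return self.matrix.reshape(-1)


def subject_spectral_features(epochs: EpochSet,
                              bands: Sequence[BandDefinition] = CANONICAL_BANDS
                              ) -> SpectralFeatures:
    """Epoch-averaged, per-epoch-normalized band powers for one subject."""
    if epochs.n_epochs < 1:
        raise SpectralError("need at least one epoch")
    n_ch = len(epochs.channel_labels)
    acc = np.zeros((n_ch, len(bands)))
    for ep in epochs.epochs:
        freqs, psd = welch_psd(ep, epochs.fs)
        for b_idx, band in enumerate(bands):
            acc[:, b_idx] += normalize_segment(band_power(freqs, psd, band))
    matrix = acc / epochs.n_epochs
    return SpectralFeatures(
        subject_id=epochs.subject_id,
        group_label=epochs.group_label,
        channel_labels=list(epochs.channel_labels),
        band_names=tuple(b.name for b in bands),
        matrix=matrix,
        n_epochs_used=epochs.n_epochs,
    )


def spectral_feature_table(features: Sequence[SpectralFeatures]) -> pd.DataFrame:
    """Subjects x features table with a ``group`` column."""
    rows = []
    for f in features:
        row = dict(zip(f.feature_names, f.flatten()))
        row["group"] = f.group_label
        rows.append(pd.Series(row, name=f.subject_id))
    return pd.DataFrame(rows)
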