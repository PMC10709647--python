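"""Phase-coupling features: PLV and corrected imaginary PLV (ciPLV).

For each band the continuous eyes-closed signal is band-filtered
(zero-phase FIR, order 24 for theta/alpha/low-beta and 50 for high beta),
converted to instantaneous phase through the analytic signal, cut into 2-s
epochs, and both coupling measures are evaluated per channel pair and
averaged over epochs. With 18 post-reference channels this yields 153 pair
features per band and 612 per measure.

Given the mean phasor m = (1/T) sum_t exp(-i (phi_i(t) - phi_j(t))):

    PLV   = |m|
    ciPLV = |Im(m)| / sqrt(1 - Re(m)^2)

ciPLV is reported as a magnitude so both measures live in [0, 1]; it is
insensitive to zero-lag (volume-conduction) coupling, for which Im(m) = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .bands import (CANONICAL_BANDS, CONNECTIVITY_FILTER_ORDERS,
                    BandDefinition)
from .montage import pair_labels
from .preprocessing import (DEFAULT_EPOCH_S, EpochSet, design_bandpass,
                            filter_array, interval_slices)
from .recording import Recording

MEASURES = ("plv", "ciplv")
_DENOM_EPS = 1e-9


class ConnectivityError(ValueError):
    pass


def instantaneous_phase(band_filtered: np.ndarray) -> np.ndarray:
    """Instantaneous phase (rad, in (-pi, pi]) via the analytic signal.

    Input must already be band-limited; rows are channels, the last axis
    is time.
    """
    arr = np.atleast_2d(np.asarray(band_filtered, dtype=float))
    power = (arr ** 2).sum(axis=-1)
    if (power == 0).any():
        raise ConnectivityError(
            "instantaneous phase undefined for an all-zero channel")
    return np.angle(hilbert(arr, axis=-1)).reshape(np.shape(band_filtered))


def _mean_phasor(phases_i: np.ndarray, phases_j: np.ndarray) -> complex:
    phases_i = np.asarray(phases_i, dtype=float)
    phases_j = np.asarray(phases_j, dtype=float)
    if phases_i.shape != phases_j.shape:
        raise ConnectivityError(
            f"phase sequences differ in shape: {phases_i.shape} vs {phases_j.shape}")
    if phases_i.size < 2:
        raise ConnectivityError("need at least T = 2 phase samples")
    return complex(np.exp(-1j * (phases_i - phases_j)).mean())


def plv(phases_i: np.ndarray, phases_j: np.ndarray) -> float:
    """Phase-locking value: modulus of the mean phase-difference phasor."""
    return abs(_mean_phasor(phases_i, phases_j))


def ciplv(phases_i: np.ndarray, phases_j: np.ndarray) -> float:
    """Corrected imaginary PLV (magnitude convention).

    Near-perfect zero-lag locking drives the denominator sqrt(1 - Re^2)
    to 0 with a vanishing numerator; that degenerate case returns 0 with
    a warning.
    """
    m = _mean_phasor(phases_i, phases_j)
    denom_sq = 1.0 - m.real ** 2
    if denom_sq < _DENOM_EPS:
        warnings.warn(
            "ciPLV denominator ~ 0 (near-perfect zero-lag locking); returning 0")
        return 0.0
    return abs(m.imag) / np.sqrt(denom_sq)


def _epoch_pair_matrices(phase_epoch: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """(PLV, ciPLV) matrices (n_ch x n_ch) for one phase epoch, vectorized."""
    z = np.exp(1j * np.asarray(phase_epoch))
    m = (np.conj(z) @ z.T) / phase_epoch.shape[-1]  # m[i, j] = mean e^{-i(phi_i-phi_j)}
    plv_mat = np.abs(m)
    denom_sq = 1.0 - m.real ** 2
    safe = denom_sq >= _DENOM_EPS
    ciplv_mat = np.zeros_like(plv_mat)
    ciplv_mat[safe] = np.abs(m.imag[safe]) / np.sqrt(denom_sq[safe])
    return plv_mat, ciplv_mat


@dataclass
class ConnectivityFeatures:
    """Epoch-averaged pair coupling values for one subject and one measure."""

    subject_id: str
    group_label: str
    measure: str  # "plv" | "ciplv"
    channel_labels: List[str]
    band_names: Tuple[str, ...]
    values: np.ndarray  # (n_bands, n_pairs)
    n_epochs_used: int

    @property
    def pairs(self) -> List[Tuple[str, str]]:
        return pair_labels(self.channel_labels)

    @property
    def n_pairs(self) -> int:
        return self.values.shape[1]

    @property
    def feature_names(self) -> List[str]:
        return [f"{a}-{b}_{band}_{self.measure}"
                for band in self.band_names for a, b in self.pairs]

    def flatten(self) -> np.ndarray:
        return self.values.reshape(-1)

    def matrix(self, band: str) -> np.ndarray:
        """Symmetric (n_ch x n_ch) coupling matrix for one band."""
        n = len(self.channel_labels)
        out = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        out[iu] = self.values[self.band_names.index(band)]
        return out + out.T


def band_phase_epochs(recording: Recording,
                      bands: Sequence[BandDefinition] = CANONICAL_BANDS,
                      epoch_s: float = DEFAULT_EPOCH_S,
                      filter_orders: Dict[str, int] | None = None
                      ) -> Dict[str, EpochSet]:
    """Band-filter, Hilbert-transform and epoch a (preprocessed) recording.

    The analytic signal is computed on each continuous eyes-closed stretch
    before epoching so 2-s boundaries carry no Gibbs edge bias; the returned
    EpochSets hold instantaneous phases, not voltages.
    """
    orders = dict(CONNECTIVITY_FILTER_ORDERS)
    if filter_orders:
        orders.update(filter_orders)
    length = int(round(epoch_s * recording.fs))
    slices = interval_slices(recording.eyes_closed_intervals, recording.fs,
                             recording.n_samples)
    out: Dict[str, EpochSet] = {}
    for band in bands:
        spec = design_bandpass(band.f_low, band.f_high, recording.fs,
                               order=orders.get(band.name))
        chunks = []
        for sl in slices:
            seg = filter_array(recording.data[:, sl], spec)
            phase = instantaneous_phase(seg)
            n_ep = phase.shape[-1] // length
            for k in range(n_ep):
                chunks.append(phase[:, k * length:(k + 1) * length])
        if not chunks:
            raise ConnectivityError(
                f"no eyes-closed interval long enough for a {epoch_s} s epoch")
        out[band.name] = EpochSet(
            subject_id=recording.subject_id,
            group_label=recording.group_label,
            channel_labels=list(recording.channel_labels),
            fs=recording.fs,
            epochs=np.stack(chunks),
        )
    return out


def subject_connectivity(phase_epochs: Dict[str, EpochSet],
                         measure: str) -> ConnectivityFeatures:
    """Epoch-averaged coupling features over all unique channel pairs."""
    if measure not in MEASURES:
        raise ConnectivityError(f"measure must be one of {MEASURES}")
    band_names = tuple(phase_epochs)
    first = next(iter(phase_epochs.values()))
    n_ch = len(first.channel_labels)
    iu = np.triu_indices(n_ch, k=1)
    values = np.zeros((len(band_names), len(iu[0])))
    for b_idx, name in enumerate(band_names):
        eset = phase_epochs[name]
        if eset.n_epochs < 1:
            raise ConnectivityError(f"zero epochs in band {name}")
        acc = np.zeros(len(iu[0]))
        for ep in eset.epochs:
            plv_mat, ciplv_mat = _epoch_pair_matrices(ep)
            acc += (plv_mat if measure == "plv" else ciplv_mat)[iu]
        values[b_idx] = acc / eset.n_epochs
    return ConnectivityFeatures(
        subject_id=first.subject_id,
        group_label=first.group_label,
        measure=measure,
        channel_labels=list(first.channel_labels),
        band_names=band_names,
        values=values,
        n_epochs_used=first.n_epochs,
    )


def connectivity_feature_table(features: Sequence[ConnectivityFeatures]
                               ) -> pd.DataFrame:
    """Subjects x features table with a ``group`` column."""
    rows = []
    for f in features:
        row = dict(zip(f.feature_names, f.flatten()))
        row["group"] = f.group_label
        rows.append(pd.Series(row, name=f.subject_id))
    return pd.DataFrame(rows)
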