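"""Canonical analysis frequency bands."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with inclusive edges in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0 < self.f_low < self.f_high):
            raise ValueError(f"invalid band edges ({self.f_low}, {self.f_high})")

    @property
    def center(self) -> float:
        return 0.5 * (self.f_low + self.f_high)


#: The four analysis bands: theta 4-7, alpha 8-12, low beta 13-20, high beta 21-30 Hz.
CANONICAL_BANDS: Tuple[BandDefinition, ...] = (
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta1", 13.0, 20.0),
    BandDefinition("beta2", 21.0, 30.0),
)

BAND_NAMES: Tuple[str, ...] = tuple(b.name for b in CANONICAL_BANDS)
BAND_BY_NAME: Dict[str, BandDefinition] = {b.name: b for b in CANONICAL_BANDS}

#: FIR orders used for the band-limiting filters feeding the phase estimates.
CONNECTIVITY_FILTER_ORDERS: Dict[str, int] = {
    "theta": 24,
    "alpha": 24,
    "beta1": 24,
    "beta2": 50,
}
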