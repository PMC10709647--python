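"""Standard 10-20 scalp montage: labels, normalization, pair enumeration."""

from __future__ import annotations

from typing import Iterable, List, Sequence, Tuple

#: The 19 electrodes of the classic 10-20 clinical montage, in conventional
#: anterior-to-posterior, left-to-right order.
TEN_TWENTY_19: Tuple[str, ...] = (
    "Fp1", "Fp2",
    "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: Frontal / fronto-central electrodes (used by the group-difference preset).
FRONTAL: Tuple[str, ...] = ("Fp1", "Fp2", "F3", "F4", "F7", "F8", "Cz")

# Modern equivalents of the older temporal/posterior-temporal names.
_ALIASES = {
    "T7": "T3",
    "T8": "T4",
    "P7": "T5",
    "P8": "T6",
}

_CANONICAL = {label.lower(): label for label in TEN_TWENTY_19}
_CANONICAL.update({alias.lower(): target for alias, target in _ALIASES.items()})


class MontageError(ValueError):
    """Raised when an electrode label cannot be resolved against the montage."""


def normalize_label(label: str) -> str:
    """Map a raw channel label to its canonical 10-20 name.

    Matching is case- and whitespace-insensitive and resolves modern
    aliases (T7->T3, T8->T4, P7->T5, P8->T6). Common clinical prefixes
    such as ``EEG `` and reference suffixes (``-REF``, ``-A1``) are
    stripped.
    """
    cleaned = label.strip()
    for prefix in ("EEG ", "eeg "):
        if cleaned.startswith(prefix):
            cleaned = cleaned[len(prefix):]
    cleaned = cleaned.split("-")[0].strip()
    key = cleaned.lower()
    if key not in _CANONICAL:
        raise MontageError(
            f"unknown electrode label {label!r}; known labels: "
            f"{', '.join(TEN_TWENTY_19)}"
        )
    return _CANONICAL[key]


def validate_labels(labels: Iterable[str]) -> List[str]:
    """Normalize a sequence of labels and check uniqueness."""
    out = [normalize_label(lbl) for lbl in labels]
    if len(set(out)) != len(out):
        raise MontageError(f"duplicate electrode labels after normalization: {out}")
    return out


def pair_labels(channel_labels: Sequence[str]) -> List[Tuple[str, str]]:
    """All unordered distinct channel pairs (i < j) in fixed channel order.

    For the 18 post-reference channels this enumerates the 153 unique pairs
    that index one band of the connectivity feature vector.
    """
    n = len(channel_labels)
    return [
        (channel_labels[i], channel_labels[j])
        for i in range(n)
        for j in range(i + 1, n)
    ]
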