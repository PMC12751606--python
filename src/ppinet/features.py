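"""The 60-value propensity descriptor of a protein.

For each of the 10 propensity scales the descriptor carries four raw sums
of per-residue scale values — over the whole sequence and over its start,
middle and end thirds (40 values) — followed by the counts of the 20
standard amino acids in alphabetical order (20 values).  Region sums are
plain sums, not length-normalized, so the whole-sequence value is exactly
the sum of the three region values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ppinet.io import NONSTANDARD_AMINO_ACIDS, STANDARD_AMINO_ACIDS, PropensityTable

logger = logging.getLogger(__name__)

#: Version tag of the feature layout; serialized models record it and
#: prediction refuses a mismatch.
FEATURE_LAYOUT_VERSION = "propensity-60/v1"

N_FEATURES = 60

REGION_NAMES = ("whole", "start", "middle", "end")


@dataclass(frozen=True)
class FeatureVector:
    """Propensity descriptor; ``values`` follows the frozen layout:
    scale-major (whole, start, middle, end) sums then residue counts.

    With the standard 10-scale table the length is exactly 60 (40 region
    sums + 20 counts); smaller tables yield 4·n_scales + 20 values.
    """

    values: np.ndarray
    layout_version: str = FEATURE_LAYOUT_VERSION

    def __post_init__(self) -> None:
        n = self.values.shape[0] if self.values.ndim == 1 else -1
        if n < 24 or (n - 20) % 4 != 0:
            raise ValueError(
                f"feature vector length must be 4*n_scales + 20, got shape {self.values.shape}"
            )

    @property
    def n_scales(self) -> int:
        return (len(self.values) - 20) // 4

    @property
    def region_sums(self) -> np.ndarray:
        """The propensity region sums, shape (n_scales, 4)."""
        return self.values[: 4 * self.n_scales].reshape(-1, 4)

    @property
    def counts(self) -> np.ndarray:
        """The 20 standard amino-acid counts, alphabetical order."""
        return self.values[-20:]


def feature_names(table: PropensityTable) -> list[str]:
    """Column names matching the frozen layout, e.g. ``BASIC_whole``."""
    names = [f"{scale}_{region}" for scale in table.scales for region in REGION_NAMES]
    names += [f"count_{aa}" for aa in STANDARD_AMINO_ACIDS]
    return names


def segment_regions(sequence: str) -> tuple[str, str, str]:
    """Split a sequence into start/middle/end thirds.

    Start and end take ``floor(n/3)`` residues each; the middle receives
    the remainder, so the concatenation reproduces the input.
    """
    if not sequence:
        raise ValueError("cannot segment an empty sequence")
    third = len(sequence) // 3
    return sequence[:third], sequence[third : len(sequence) - third], sequence[len(sequence) - third :]


def featurize(sequence: str, table: PropensityTable) -> FeatureVector:
    """Compute the 60-value descriptor of one sequence.

    Non-standard residue letters (B, J, O, U, X, Z) contribute zero to
    every scale sum and are excluded from the 20 counts (a warning is
    logged).  Any other letter missing from the table is an error.
    """
    if not sequence:
        raise ValueError("cannot featurize an empty sequence")
    sequence = sequence.upper()
    standard = set(STANDARD_AMINO_ACIDS)
    unknown = sorted({c for c in sequence if c not in standard and c not in NONSTANDARD_AMINO_ACIDS})
    if unknown:
        raise ValueError(f"residues {unknown} are neither standard nor recognized ambiguity codes")
    nonstd = {c for c in sequence if c in NONSTANDARD_AMINO_ACIDS}
    if nonstd:
        logger.warning(
            "non-standard residues %s contribute zero to scale sums and are not counted",
            sorted(nonstd),
        )

    start, middle, end = segment_regions(sequence)
    values = np.empty(4 * len(table.scales) + 20, dtype=float)
    i = 0
    for scale in table.scales:
        region_sums = [
            sum(table.values[(scale, aa)] for aa in region if aa in standard)
            for region in (sequence, start, middle, end)
        ]
        values[i : i + 4] = region_sums
        i += 4
    for j, aa in enumerate(STANDARD_AMINO_ACIDS):
        values[i + j] = sequence.count(aa)
    return FeatureVector(values=values)


def featurize_many(records, table: PropensityTable) -> np.ndarray:
    """Feature matrix for a list of protein records, shape (n, 60)."""
    return np.vstack([featurize(rec.sequence, table).values for rec in records])
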