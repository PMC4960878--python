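"""Intra-class pairwise sequence-identity statistics.

Each class of a protein family is aligned separately; the alignment is
trimmed of sparsely occupied columns (trailing ends of fragment sequences),
every pair of sequences is compared, and the distribution of pairwise
identity percentages is summarised (median / mean / min).

Identity is, by default, ``100 * matches / co-occupied columns`` where a
co-occupied column is one in which both sequences carry a residue; an
alignment-length denominator is available for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import Alignment, GAP

DEFAULT_MIN_OCCUPANCY = 0.2


class EmptyAlignmentError(ValueError):
    pass


@dataclass
class IdentityMatrix:
    labels: list[str]
    values: np.ndarray          # symmetric, percent; NaN where undefined
    defined: np.ndarray         # boolean mask (off-diagonal pairs with >=1 co-occupied column)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def pair_values(self) -> np.ndarray:
        """Defined off-diagonal identities (upper triangle, one per pair)."""
        n = len(self.labels)
        iu = np.triu_indices(n, k=1)
        vals = self.values[iu]
        ok = self.defined[iu]
        return vals[ok]


@dataclass
class IdentitySummary:
    class_label: str
    median: float
    mean: float
    min: float
    n_pairs: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def trim_alignment(alignment: Alignment, min_occupancy: float = DEFAULT_MIN_OCCUPANCY) -> Alignment:
    """Drop columns whose non-gap fraction is below ``min_occupancy``."""
    if not 0.0 <= min_occupancy <= 1.0:
        raise ValueError("min_occupancy must be in [0, 1]")
    mat = alignment.matrix()
    occupancy = (mat != GAP.encode()).mean(axis=0)
    keep = np.nonzero(occupancy >= min_occupancy)[0]
    if keep.size == 0:
        raise EmptyAlignmentError("trimming removed every column")
    if keep.size == alignment.n_columns:
        return alignment
    return alignment.take_columns([int(c) for c in keep])


def pairwise_identity_matrix(alignment: Alignment,
                             denominator: str = "co-occupied") -> IdentityMatrix:
    """Symmetric matrix of pairwise identity percentages.

    ``denominator`` is "co-occupied" (columns where both sequences have a
    residue; pairs with none are undefined) or "alignment" (all columns).
    """
    if len(alignment) < 2:
        raise ValueError("need at least 2 sequences")
    if denominator not in ("co-occupied", "alignment"):
        raise ValueError(f"unknown denominator {denominator!r}")
    mat = alignment.matrix()
    residue = mat != GAP.encode()
    n = len(alignment)
    values = np.full((n, n), np.nan)
    defined = np.zeros((n, n), dtype=bool)
    np.fill_diagonal(values, 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            both = residue[i] & residue[j]
            denom = int(both.sum()) if denominator == "co-occupied" else alignment.n_columns
            if denom == 0:
                continue
            matches = int((mat[i][both] == mat[j][both]).sum())
            values[i, j] = values[j, i] = 100.0 * matches / denom
            defined[i, j] = defined[j, i] = True
    return IdentityMatrix(alignment.ids, values, defined)


def identity_summary(matrix: IdentityMatrix, class_label: str = "") -> IdentitySummary:
    """Median / mean / min over the defined off-diagonal identities."""
    vals = matrix.pair_values()
    if vals.size == 0:
        raise ValueError("no defined off-diagonal pairs")
    return IdentitySummary(
        class_label=class_label,
        median=float(np.median(vals)),
        mean=float(np.mean(vals)),
        min=float(np.min(vals)),
        n_pairs=int(vals.size),
    )


def class_identity_table(alignments: dict[str, Alignment],
                         min_occupancy: float = DEFAULT_MIN_OCCUPANCY) -> pd.DataFrame:
    """Per-class summary table (one trimmed alignment per class)."""
    rows = []
    for label, aln in alignments.items():
        trimmed = trim_alignment(aln, min_occupancy)
        summary = identity_summary(pairwise_identity_matrix(trimmed), label)
        rows.append(summary.__dict__)
    return pd.DataFrame(rows)
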