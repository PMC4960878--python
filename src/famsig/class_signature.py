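"""Class-unique conserved-residue scoring for a labelled protein-family MSA.

The analysis partitions an aligned family into the studied class and the
pooled remainder ("rest"), drops the columns where the studied class has no
residues, builds a per-column conservation-rate profile (PSSM) for each
partition, and scores every retained column with

    s(pos) = max(PSSM_class(pos))^3 / PSSM_rest(pos)_aa          if the class's
                                                                 top residue is
                                                                 seen in rest
    s(pos) = max(PSSM_class(pos))^3 / ((1 / seqs_rest) / 2)      otherwise,

where ``aa`` is the residue achieving the class maximum and ``seqs_rest`` is
the number of sequences outside the studied class.  The second branch assigns
an absent residue half the rate of a single rest sequence, so a residue that
is fully conserved in the class and never seen elsewhere scores
``2 * seqs_rest``.  High scores therefore flag positions that are strongly
conserved within the class yet rare or absent outside it — candidate
class-signature residues.

Conservation rates use the count of standard residues in the partition at the
column as denominator; gaps and non-standard codes (X, B, Z) are missing data.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .io_formats import Alignment, STANDARD_AA, STANDARD_AA_SET

_AA_BYTES = np.frombuffer(STANDARD_AA.encode(), dtype="S1")


class UnknownClassError(KeyError):
    pass


class EmptyProfileError(ValueError):
    pass


@dataclass
class ClassPssm:
    """Per-column residue conservation rates for one sequence partition.

    ``columns[i]`` maps residue -> rate for retained column ``i``;
    ``column_origin[i]`` is the original alignment column it came from.
    """

    columns: list[dict[str, float]]
    n_sequences: int
    column_origin: list[int]

    def __len__(self) -> int:
        return len(self.columns)


@dataclass
class SignaturePositionScore:
    column: int                 # original alignment column (0-based)
    residue: str                # residue achieving the class maximum
    class_max_rate: float
    rest_rate: float
    score: float
    zero_case: bool


@dataclass
class SignatureReport:
    class_label: str
    reference_id: str
    seqs_class: int
    seqs_rest: int
    entries: list[dict] = field(default_factory=list)   # ranked, top_n rows
    track: list[SignaturePositionScore] = field(default_factory=list)  # all columns

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries)

    def track_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column": [s.column for s in self.track],
                "residue": [s.residue for s in self.track],
                "class_max_rate": [s.class_max_rate for s in self.track],
                "rest_rate": [s.rest_rate for s in self.track],
                "score": [s.score for s in self.track],
                "zero_case": [s.zero_case for s in self.track],
            }
        )


def _partition_indices(alignment: Alignment, class_label: str) -> tuple[list[int], list[int]]:
    alignment.require_class_labels()
    in_class = [i for i, r in enumerate(alignment.records) if r.class_label == class_label]
    rest = [i for i, r in enumerate(alignment.records) if r.class_label != class_label]
    if not in_class:
        raise UnknownClassError(f"class {class_label!r} not present in alignment")
    if not rest:
        raise EmptyProfileError(f"no sequences outside class {class_label!r}")
    return in_class, rest


def _rate_columns(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Counts (20 x n_cols) of standard residues and non-missing totals."""
    counts = np.stack([(matrix == aa).sum(axis=0) for aa in _AA_BYTES])
    return counts, counts.sum(axis=0)


def build_class_pssms(alignment: Alignment, class_label: str) -> tuple[ClassPssm, ClassPssm]:
    """Build (class, rest) conservation profiles after class-based column filtering.

    Columns where the studied class contributes no standard residue are
    removed from both profiles; ``column_origin`` records the surviving
    columns' original indices (identical in both outputs).
    """
    idx_class, idx_rest = _partition_indices(alignment, class_label)
    mat = alignment.matrix()
    counts_c, totals_c = _rate_columns(mat[idx_class])
    counts_r, totals_r = _rate_columns(mat[idx_rest])
    keep = np.nonzero(totals_c > 0)[0]
    if keep.size == 0:
        raise EmptyProfileError(
            f"every column empty for class {class_label!r} after filtering"
        )

    def cols_for(counts: np.ndarray, totals: np.ndarray) -> list[dict[str, float]]:
        out = []
        for j in keep:
            total = totals[j]
            if total == 0:
                out.append({})
                continue
            col = {
                STANDARD_AA[a]: counts[a, j] / total
                for a in range(20)
                if counts[a, j] > 0
            }
            out.append(col)
        return out

    origin = [int(j) for j in keep]
    pssm_class = ClassPssm(cols_for(counts_c, totals_c), len(idx_class), origin)
    pssm_rest = ClassPssm(cols_for(counts_r, totals_r), len(idx_rest), list(origin))
    return pssm_class, pssm_rest


def score_position(class_col: dict[str, float], rest_col: dict[str, float],
                   seqs_rest: int) -> SignaturePositionScore:
    """Score one column; ties for the class maximum favour the highest score,
    then the alphabetically first residue."""
    if not class_col:
        raise EmptyProfileError("empty class column reached the scorer")
    if seqs_rest < 1:
        raise ValueError("seqs_rest must be >= 1")
    m = max(class_col.values())
    tied = sorted(aa for aa, rate in class_col.items() if rate == m)
    best: Optional[SignaturePositionScore] = None
    for aa in tied:
        q = rest_col.get(aa, 0.0)
        if q > 0:
            s = m**3 / q
            cand = SignaturePositionScore(-1, aa, m, q, s, False)
        else:
            s = m**3 / ((1.0 / seqs_rest) / 2.0)
            cand = SignaturePositionScore(-1, aa, m, 0.0, s, True)
        if best is None or cand.score > best.score:
            best = cand
    return best


def residue_prevalence(alignment: Alignment, column: int, residue: str,
                       partition: str, class_label: Optional[str] = None) -> float:
    """Fraction of the partition's non-missing residues at ``column`` equal to
    ``residue``.  ``partition`` is a class label, or "rest" (everything not in
    ``class_label``).  Returns 0 when the partition has no residues there."""
    if not 0 <= column < alignment.n_columns:
        raise IndexError(f"column {column} out of range")
    if partition == "rest":
        if class_label is None:
            raise ValueError("partition 'rest' requires class_label")
        rows = [r for r in alignment.records if r.class_label != class_label]
    else:
        rows = [r for r in alignment.records if r.class_label == partition]
    chars = [r.seq[column] for r in rows]
    non_missing = [c for c in chars if c in STANDARD_AA_SET]
    if not non_missing:
        return 0.0
    return non_missing.count(residue) / len(non_missing)


def reference_numbering(alignment: Alignment, reference_id: str) -> dict[int, int]:
    """Map alignment column -> 1-based residue number of the reference sequence
    (first residue = 1); gap columns of the reference are absent from the map."""
    ref = alignment.record(reference_id)
    mapping: dict[int, int] = {}
    n = 0
    for col, ch in enumerate(ref.seq):
        if ch != "-":
            n += 1
            mapping[col] = n
    return mapping


def scan_signature_positions(alignment: Alignment, class_label: str,
                             reference_id: str, top_n: int = 10) -> SignatureReport:
    """Score every retained column and report the ``top_n`` class-signature
    candidates with reference numbering and per-class prevalences."""
    ref_rec = alignment.record(reference_id)
    if ref_rec.class_label != class_label:
        raise ValueError(
            f"reference {reference_id!r} is not a member of class {class_label!r}"
        )
    pssm_class, pssm_rest = build_class_pssms(alignment, class_label)
    ref_map = reference_numbering(alignment, reference_id)
    other_labels = sorted(alignment.class_labels - {class_label})

    track: list[SignaturePositionScore] = []
    for i, (ccol, rcol) in enumerate(zip(pssm_class.columns, pssm_rest.columns)):
        s = score_position(ccol, rcol, pssm_rest.n_sequences)
        s.column = pssm_class.column_origin[i]
        track.append(s)

    ranked = sorted(track, key=lambda s: (-s.score, s.column))[:top_n]
    mat = alignment.matrix()
    label_arr = np.array([r.class_label for r in alignment.records])
    entries = []
    for rank, s in enumerate(ranked, start=1):
        row: dict = {
            "rank": rank,
            "column": s.column,
            "reference_position": ref_map.get(s.column),
            "reference_residue": (
                f"{s.residue}{ref_map[s.column]}" if s.column in ref_map else None
            ),
            "residue": s.residue,
            "score": s.score,
            "zero_case": s.zero_case,
            "class_prevalence": residue_prevalence(alignment, s.column, s.residue, class_label),
            "rest_prevalence": residue_prevalence(
                alignment, s.column, s.residue, "rest", class_label
            ),
        }
        # modal residue of each other class at the column (reporting only)
        col_chars = mat[:, s.column].astype("U1")
        for lab in other_labels:
            chars = [c for c in col_chars[label_arr == lab] if c in STANDARD_AA_SET]
            if chars:
                modal, count = Counter(chars).most_common(1)[0]
                row[f"modal_{lab}"] = modal
                row[f"modal_{lab}_prevalence"] = count / len(chars)
            else:
                row[f"modal_{lab}"] = None
                row[f"modal_{lab}_prevalence"] = 0.0
        entries.append(row)

    return SignatureReport(
        class_label=class_label,
        reference_id=reference_id,
        seqs_class=pssm_class.n_sequences,
        seqs_rest=pssm_rest.n_sequences,
        entries=entries,
        track=track,
    )
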