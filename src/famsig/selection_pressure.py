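"""dN/dS estimation for in-frame codon alignments by the Nei-Gojobori (1986)
counting method.

The estimator counts, per codon, the fractions of single-nucleotide changes
that are synonymous (S sites) or nonsynonymous (N sites), counts observed
synonymous/nonsynonymous differences between codon pairs by averaging over
all minimal substitution pathways, applies the Jukes-Cantor multiple-hit
correction d = -(3/4) ln(1 - 4p/3) to the proportions pS = Sd/S and
pN = Nd/N, and reports the ratio dN/dS.  A ratio below 1 indicates purifying
selection (an evolutionary pressure against amino-acid change).

Conventions (NG86 implementations differ here): single-nucleotide changes
that create a stop codon are excluded both from the possible-change set when
counting sites (with per-position renormalization, so S + N = 3 for every
sense codon) and from substitution pathways; all remaining pathways are
weighted equally.  Codons containing gaps or ambiguity in either member of a
pair are skipped for that pair only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from math import log
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .io_formats import FormatError
from Bio import SeqIO

NUCLEOTIDES = "ACGT"


class SaturationError(ValueError):
    """Proportion of differences too large for the Jukes-Cantor correction."""


def _code(table_id: int = 1) -> tuple[dict[str, str], frozenset[str]]:
    table = unambiguous_dna_by_id[table_id]
    return dict(table.forward_table), frozenset(table.stop_codons)


@dataclass
class CodonAlignment:
    """Equal-length, in-frame nucleotide sequences over {A,C,G,T,-,N}."""

    records: dict[str, str]
    table_id: int = 1

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.records.values()}
        if len(lengths) != 1:
            raise FormatError("codon alignment sequences have unequal lengths")
        (length,) = lengths
        if length % 3 != 0:
            raise FormatError(f"alignment length {length} not divisible by 3")
        self.records = {k: v.upper() for k, v in self.records.items()}

    @property
    def n_codons(self) -> int:
        return len(next(iter(self.records.values()))) // 3

    def codons(self, seq_id: str) -> list[str]:
        s = self.records[seq_id]
        return [s[i:i + 3] for i in range(0, len(s), 3)]


@dataclass
class SiteCounts:
    syn_sites: float
    nonsyn_sites: float


@dataclass
class DnDsEstimate:
    dN: Optional[float]
    dS: Optional[float]
    ratio: Optional[float]          # None when dS == 0 (undefined)
    n_codons_used: int
    scope: str = "pair"             # "pair", "pooled" or "mean-of-pairs"
    method: str = "counting (NG86-style)"
    Sd: float = 0.0
    Nd: float = 0.0
    S: float = 0.0
    N: float = 0.0
    extras: dict = field(default_factory=dict)

    @property
    def purifying(self) -> Optional[bool]:
        """The decision rule: ratio < 1 flags an evolutionary pressure."""
        return None if self.ratio is None else self.ratio < 1.0


# ---------------------------------------------------------------------------
# per-codon site counts
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def ng86_site_counts(codon: str, table_id: int = 1) -> SiteCounts:
    """Synonymous/nonsynonymous site counts for one sense codon.

    Each position contributes the fraction of its non-stop single-nucleotide
    changes that are synonymous to ``syn_sites`` and the complement to
    ``nonsyn_sites``; S + N = 3 exactly for every sense codon.
    """
    forward, stops = _code(table_id)
    codon = codon.upper()
    if codon not in forward:
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = forward[codon]
    syn = 0.0
    for pos in range(3):
        n_syn = n_valid = 0
        for base in NUCLEOTIDES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt in stops:
                continue
            n_valid += 1
            if forward[alt] == aa:
                n_syn += 1
        if n_valid:
            syn += n_syn / n_valid
        # a position whose every change creates a stop contributes no sites
        # to either class only in theory; for the standard code it never occurs
    return SiteCounts(syn_sites=syn, nonsyn_sites=3.0 - syn)


# ---------------------------------------------------------------------------
# per-codon-pair observed differences (pathway averaging)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _pair_differences(c1: str, c2: str, table_id: int = 1) -> tuple[float, float]:
    """(Sd, Nd) between two sense codons, averaged over all minimal
    substitution pathways that avoid stop codons.  Returns (nan, nan) when no
    stop-free pathway exists."""
    forward, stops = _code(table_id)
    if c1 not in forward or c2 not in forward:
        raise ValueError(f"not sense codons: {c1!r}, {c2!r}")
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    totals = []
    for order in itertools.permutations(diff_pos):
        current = c1
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1:]
            if nxt in stops:
                ok = False
                break
            if forward[current] == forward[nxt]:
                sd += 1
            else:
                nd += 1
            current = nxt
        if ok:
            totals.append((sd, nd))
    if not totals:
        return float("nan"), float("nan")
    sd = sum(t[0] for t in totals) / len(totals)
    nd = sum(t[1] for t in totals) / len(totals)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """Multiple-hit correction; valid for p < 3/4."""
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.3f} >= 3/4; distance saturated")
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


def _is_sense(codon: str, forward: dict[str, str]) -> bool:
    return codon in forward


def _pair_counts(codons_a: list[str], codons_b: list[str],
                 table_id: int = 1) -> tuple[float, float, float, float, int]:
    """Accumulate (S, N, Sd, Nd, n_codons_used) over one sequence pair."""
    forward, _ = _code(table_id)
    S = N = Sd = Nd = 0.0
    used = 0
    for ca, cb in zip(codons_a, codons_b):
        if not (_is_sense(ca, forward) and _is_sense(cb, forward)):
            continue
        sd, nd = _pair_differences(ca, cb, table_id)
        if sd != sd:            # NaN: no stop-free pathway
            continue
        sc_a = ng86_site_counts(ca, table_id)
        sc_b = ng86_site_counts(cb, table_id)
        S += (sc_a.syn_sites + sc_b.syn_sites) / 2.0
        N += (sc_a.nonsyn_sites + sc_b.nonsyn_sites) / 2.0
        Sd += sd
        Nd += nd
        used += 1
    return S, N, Sd, Nd, used


def _estimate_from_counts(S: float, N: float, Sd: float, Nd: float,
                          used: int, scope: str) -> DnDsEstimate:
    if used == 0 or S <= 0 or N <= 0:
        raise ValueError("no usable codons for dN/dS estimation")
    # a saturated synonymous proportion still bounds the ratio (dS -> inf,
    # ratio -> 0); saturation on the nonsynonymous side is unrecoverable
    try:
        dS = jukes_cantor(Sd / S) if Sd > 0 else 0.0
    except SaturationError:
        dS = float("inf")
    dN = jukes_cantor(Nd / N) if Nd > 0 else 0.0
    ratio = dN / dS if dS > 0 else None
    return DnDsEstimate(dN=dN, dS=dS, ratio=ratio, n_codons_used=used,
                        scope=scope, Sd=Sd, Nd=Nd, S=S, N=N)


def ng86_pair(a: str, b: str, table_id: int = 1) -> DnDsEstimate:
    """dN/dS between two equal-length in-frame codon sequences."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    if len(a) % 3 != 0:
        raise ValueError("sequence length not divisible by 3")
    codons_a = [a[i:i + 3].upper() for i in range(0, len(a), 3)]
    codons_b = [b[i:i + 3].upper() for i in range(0, len(b), 3)]
    S, N, Sd, Nd, used = _pair_counts(codons_a, codons_b, table_id)
    return _estimate_from_counts(S, N, Sd, Nd, used, "pair")


def alignment_dnds(aln: CodonAlignment) -> DnDsEstimate:
    """Alignment-wide dN/dS.

    The primary estimate pools Sd, Nd, S, N over all sequence pairs before
    the Jukes-Cantor correction; the mean of defined pairwise ratios is kept
    alongside in ``extras`` together with the full pairwise table.
    """
    ids = list(aln.records)
    if len(ids) < 2:
        raise ValueError("need at least 2 sequences")
    codon_lists = {i: aln.codons(i) for i in ids}
    S = N = Sd = Nd = 0.0
    used = 0
    pairwise_rows = []
    ratios = []
    for ia, ib in itertools.combinations(ids, 2):
        s, n, sd, nd, u = _pair_counts(codon_lists[ia], codon_lists[ib], aln.table_id)
        if u == 0:
            continue
        S += s; N += n; Sd += sd; Nd += nd; used += u
        try:
            est = _estimate_from_counts(s, n, sd, nd, u, "pair")
        except SaturationError:
            est = None
        row = {"id_a": ia, "id_b": ib, "Sd": sd, "Nd": nd, "S": s, "N": n}
        if est is not None:
            row.update({"dN": est.dN, "dS": est.dS, "ratio": est.ratio})
            if est.ratio is not None:
                ratios.append(est.ratio)
        pairwise_rows.append(row)
    if not pairwise_rows:
        raise ValueError("no sequence pair with usable codons")
    pooled = _estimate_from_counts(S, N, Sd, Nd, used, "pooled")
    pooled.extras["mean_of_pair_ratios"] = float(np.mean(ratios)) if ratios else None
    pooled.extras["n_pairs"] = len(pairwise_rows)
    pooled.extras["pairwise"] = pd.DataFrame(pairwise_rows)
    return pooled


def read_codon_alignment(path: str | Path, table_id: int = 1) -> CodonAlignment:
    """Read an aligned in-frame FASTA of coding nucleotide sequences."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return CodonAlignment(records, table_id=table_id)


def dnds_table(aln: CodonAlignment) -> pd.DataFrame:
    """Pairwise table plus a pooled summary row, ready for TSV export."""
    pooled = alignment_dnds(aln)
    table: pd.DataFrame = pooled.extras["pairwise"].copy()
    summary = {
        "id_a": "(pooled)", "id_b": "",
        "Sd": pooled.Sd, "Nd": pooled.Nd, "S": pooled.S, "N": pooled.N,
        "dN": pooled.dN, "dS": pooled.dS, "ratio": pooled.ratio,
    }
    return pd.concat([table, pd.DataFrame([summary])], ignore_index=True)
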