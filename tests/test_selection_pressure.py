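"""Nei-Gojobori counting estimator against brute-force enumeration oracles."""

import itertools

import numpy as np
import pytest

from famsig.selection_pressure import (
    CodonAlignment,
    SaturationError,
    alignment_dnds,
    jukes_cantor,
    ng86_pair,
    ng86_site_counts,
    read_codon_alignment,
    _code,
)
from famsig.io_formats import FormatError
from famsig.synthetic_data import CodonSimSpec, simulate_codon_alignment

FORWARD, STOPS = _code(1)
SENSE = sorted(FORWARD)


def oracle_site_counts(codon: str) -> tuple[float, float]:
    """Independent enumeration over the 9 single-nucleotide neighbours."""
    syn = 0.0
    for pos in range(3):
        outcomes = []
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt in STOPS:
                continue
            outcomes.append(FORWARD[alt] == FORWARD[codon])
        if outcomes:
            syn += sum(outcomes) / len(outcomes)
    return syn, 3.0 - syn


def oracle_pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """Independent recursive pathway enumeration avoiding stop codons."""
    def walk(current: str, remaining: tuple[int, ...]):
        if not remaining:
            yield (0, 0)
            return
        for pick in remaining:
            nxt = current[:pick] + c2[pick] + current[pick + 1:]
            if nxt in STOPS:
                continue
            step = (1, 0) if FORWARD[current] == FORWARD[nxt] else (0, 1)
            rest = tuple(p for p in remaining if p != pick)
            for sd, nd in walk(nxt, rest):
                yield (step[0] + sd, step[1] + nd)

    diff = tuple(i for i in range(3) if c1[i] != c2[i])
    paths = list(walk(c1, diff))
    if not paths:
        return float("nan"), float("nan")
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


class TestSiteCounts:
    def test_all_sense_codons_match_oracle_exactly(self):
        for codon in SENSE:
            sc = ng86_site_counts(codon)
            syn, nonsyn = oracle_site_counts(codon)
            assert sc.syn_sites == syn, codon
            assert sc.nonsyn_sites == nonsyn, codon
            assert sc.syn_sites + sc.nonsyn_sites == 3.0, codon

    @pytest.mark.parametrize("codon,syn", [
        ("TTT", 1 / 3),     # only TTC synonymous
        ("ATG", 0.0),       # Met has no synonymous neighbour
        ("TGG", 0.0),       # Trp: TGA excluded as stop
    ])
    def test_known_codons(self, codon, syn):
        sc = ng86_site_counts(codon)
        assert sc.syn_sites == pytest.approx(syn)
        assert sc.nonsyn_sites == pytest.approx(3 - syn)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng86_site_counts("TAA")


class TestPairEstimates:
    def test_identical_sequences(self):
        est = ng86_pair("TTTATG", "TTTATG")
        assert est.dN == 0.0 and est.dS == 0.0
        assert est.ratio is None and est.purifying is None

    def test_single_synonymous_difference(self):
        est = ng86_pair("TTT", "TTC")
        assert est.Sd == 1.0 and est.Nd == 0.0
        assert est.dN == 0.0 and est.dS > 0
        assert est.ratio == 0.0 and est.purifying is True

    def test_two_difference_codon_matches_pathway_oracle(self):
        est = ng86_pair("TTT", "GTC")
        sd, nd = oracle_pathway_differences("TTT", "GTC")
        assert est.Sd == pytest.approx(sd)
        assert est.Nd == pytest.approx(nd)

    def test_pathway_averaging_all_codon_pairs(self):
        from famsig.selection_pressure import _pair_differences
        for c1 in SENSE:
            for c2 in SENSE:
                sd, nd = _pair_differences(c1, c2)
                osd, ond = oracle_pathway_differences(c1, c2)
                if osd != osd:          # no stop-free pathway
                    assert sd != sd, (c1, c2)
                    continue
                assert sd == pytest.approx(osd), (c1, c2)
                assert nd == pytest.approx(ond), (c1, c2)

    def test_symmetry(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            codons = [SENSE[i] for i in rng.integers(len(SENSE), size=40)]
            a = "".join(codons)
            mutated = list(codons)
            for pos in rng.choice(40, size=8, replace=False):
                mutated[pos] = SENSE[rng.integers(len(SENSE))]
            b = "".join(mutated)
            e1, e2 = ng86_pair(a, b), ng86_pair(b, a)
            assert e1.dN == pytest.approx(e2.dN)
            assert e1.dS == pytest.approx(e2.dS)

    def test_gapped_codons_skipped_pairwise(self):
        est = ng86_pair("TTT---ATG", "TTTAAAATG")
        assert est.n_codons_used == 2

    def test_site_counts_sum_over_sequence(self):
        rng = np.random.default_rng(2)
        codons = [SENSE[i] for i in rng.integers(len(SENSE), size=50)]
        total = sum(ng86_site_counts(c).syn_sites + ng86_site_counts(c).nonsyn_sites
                    for c in codons)
        assert total == pytest.approx(3 * len(codons))

    def test_jukes_cantor_saturation(self):
        with pytest.raises(SaturationError):
            jukes_cantor(0.8)


class TestAlignmentEstimates:
    def test_identical_sequences_pooled_undefined(self):
        aln = CodonAlignment({"a": "TTTATG", "b": "TTTATG"})
        est = alignment_dnds(aln)
        assert est.ratio is None

    def test_validation(self):
        with pytest.raises(FormatError):
            CodonAlignment({"a": "TTTA", "b": "TTTA"})
        with pytest.raises(FormatError):
            CodonAlignment({"a": "TTT", "b": "TTTTTT"})

    def test_read_codon_alignment(self, tmp_path):
        p = tmp_path / "c.fasta"
        p.write_text(">a\nTTTATG\n>b\nTTCATG\n")
        aln = read_codon_alignment(p)
        assert aln.n_codons == 2
        est = alignment_dnds(aln)
        assert est.ratio == 0.0

    def test_purifying_below_neutral_discrimination(self):
        """Mean pooled estimate under omega=0.3 sits clearly below omega=1."""
        lows, highs = [], []
        for seed in range(5):
            low, _ = simulate_codon_alignment(
                CodonSimSpec(n_sequences=4, n_codons=150, omega=0.3, seed=seed)
            )
            high, _ = simulate_codon_alignment(
                CodonSimSpec(n_sequences=4, n_codons=150, omega=1.0, seed=seed)
            )
            lows.append(alignment_dnds(low).ratio)
            highs.append(alignment_dnds(high).ratio)
        assert max(lows) < min(highs)
        assert np.mean(lows) < 0.5 < np.mean(highs)
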