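"""Class-signature scoring: PSSM construction, s(pos), prevalence, ranking."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from famsig.class_signature import (
    EmptyProfileError,
    UnknownClassError,
    build_class_pssms,
    reference_numbering,
    residue_prevalence,
    scan_signature_positions,
    score_position,
)
from famsig.io_formats import Alignment, SequenceRecord, STANDARD_AA_SET


def _aln(seqs_by_class: dict[str, list[str]]) -> Alignment:
    records = []
    for label, seqs in seqs_by_class.items():
        for k, s in enumerate(seqs):
            records.append(SequenceRecord(f"{label}{k}", s, label))
    return Alignment(records)


class TestBuildClassPssms:
    def test_direct_counting(self):
        aln = _aln({"A": ["ACD", "ACD"], "B": ["ACE", "GCE"]})
        pc, pr = build_class_pssms(aln, "A")
        assert pc.columns[2] == {"D": 1.0}
        assert pr.columns[2] == {"E": 1.0}
        assert pr.columns[0] == {"A": 0.5, "G": 0.5}
        assert pc.n_sequences == 2 and pr.n_sequences == 2

    def test_all_gap_class_column_removed_from_both(self):
        aln = _aln({"A": ["A-D", "A-D"], "B": ["ACE", "ACE"]})
        pc, pr = build_class_pssms(aln, "A")
        assert len(pc) == len(pr) == 2
        assert pc.column_origin == [0, 2] and pr.column_origin == [0, 2]

    def test_x_only_column_removed(self):
        aln = _aln({"A": ["AX"], "B": ["AC"]})
        pc, _ = build_class_pssms(aln, "A")
        assert pc.column_origin == [0]

    def test_unknown_class(self):
        aln = _aln({"A": ["AC"], "B": ["AC"]})
        with pytest.raises(UnknownClassError):
            build_class_pssms(aln, "Z")

    def test_rates_sum_to_one(self, planted_family):
        aln, _ = planted_family
        pc, pr = build_class_pssms(aln, "V")
        for pssm in (pc, pr):
            for col in pssm.columns:
                if col:
                    assert abs(sum(col.values()) - 1.0) < 1e-12


class TestScorePosition:
    @pytest.mark.parametrize(
        "class_col,rest_col,seqs_rest,expected,zero",
        [
            ({"K": 1.0}, {"K": 0.5}, 10, 2.0, False),
            ({"K": 1.0}, {}, 100, 200.0, True),
            ({"K": 0.6, "R": 0.4}, {"K": 0.2}, 10, 1.08, False),
            ({"Q": 0.9, "S": 0.1}, {"Q": 0.9}, 10, 0.81, False),  # m^3/m = m^2
        ],
    )
    def test_closed_forms(self, class_col, rest_col, seqs_rest, expected, zero):
        s = score_position(class_col, rest_col, seqs_rest)
        assert s.score == pytest.approx(expected, abs=1e-12)
        assert s.zero_case is zero

    def test_tie_breaking_prefers_most_distinctive(self):
        # L and V tie in class; V rarer in rest, so V scores higher and wins
        s = score_position({"L": 0.5, "V": 0.5}, {"L": 0.5, "V": 0.1}, 10)
        assert s.residue == "V"
        # exact tie in rest too: alphabetical
        s = score_position({"L": 0.5, "V": 0.5}, {"L": 0.2, "V": 0.2}, 10)
        assert s.residue == "L"

    def test_empty_column_is_error(self):
        with pytest.raises(EmptyProfileError):
            score_position({}, {}, 10)

    @given(
        m1=st.floats(0.05, 1.0), m2=st.floats(0.05, 1.0),
        q1=st.floats(0.01, 1.0), q2=st.floats(0.01, 1.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_conservation_and_rarity(self, m1, m2, q1, q2):
        lo_m, hi_m = sorted([m1, m2])
        lo_q, hi_q = sorted([q1, q2])
        if lo_m != hi_m:
            assert (score_position({"K": lo_m}, {"K": lo_q}, 10).score
                    < score_position({"K": hi_m}, {"K": lo_q}, 10).score)
        if lo_q != hi_q:
            assert (score_position({"K": hi_m}, {"K": hi_q}, 10).score
                    < score_position({"K": hi_m}, {"K": lo_q}, 10).score)

    @pytest.mark.parametrize("n_rest", [10, 100, 558])
    @pytest.mark.parametrize("m", [round(0.1 * k, 1) for k in range(1, 11)])
    def test_half_sequence_boundary_jump(self, m, n_rest):
        at_floor = score_position({"K": m}, {"K": 1.0 / n_rest}, n_rest).score
        absent = score_position({"K": m}, {}, n_rest).score
        assert at_floor == pytest.approx(n_rest * m**3, rel=1e-12)
        assert absent == pytest.approx(2.0 * n_rest * m**3, rel=1e-12)
        assert absent == pytest.approx(2.0 * at_floor, rel=1e-12)


class TestResiduePrevalence:
    def test_values(self):
        aln = _aln({"A": ["K", "K", "K", "K"], "B": ["K", "R", "R", "R"]})
        assert residue_prevalence(aln, 0, "K", "A") == 1.0
        assert residue_prevalence(aln, 0, "K", "B") == 0.25
        assert residue_prevalence(aln, 0, "K", "rest", class_label="A") == 0.25

    def test_gap_excluded_from_denominator(self):
        aln = _aln({"A": ["K", "K", "-", "-"], "B": ["R"]})
        assert residue_prevalence(aln, 0, "K", "A") == 1.0

    def test_empty_partition_returns_zero(self):
        aln = _aln({"A": ["-"], "B": ["R"]})
        assert residue_prevalence(aln, 0, "K", "A") == 0.0


def brute_force_scores(aln: Alignment, label: str) -> dict[int, tuple[float, str]]:
    """Independent per-column recount of the signature score (oracle)."""
    class_rows = [r.seq for r in aln.records if r.class_label == label]
    rest_rows = [r.seq for r in aln.records if r.class_label != label]
    out = {}
    for col in range(aln.n_columns):
        cvals = [s[col] for s in class_rows if s[col] in STANDARD_AA_SET]
        if not cvals:
            continue
        rvals = [s[col] for s in rest_rows if s[col] in STANDARD_AA_SET]
        counts = Counter(cvals)
        m = max(counts.values()) / len(cvals)
        best = None
        for aa in sorted(counts):
            if counts[aa] / len(cvals) != m:
                continue
            q = rvals.count(aa) / len(rvals) if rvals else 0.0
            s = m**3 / q if q > 0 else 2.0 * len(rest_rows) * m**3
            if best is None or s > best[0]:
                best = (s, aa)
        out[col] = best
    return out


class TestScan:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        alphabet = "ACDEFG-X"
        for _ in range(10):
            n_seq = int(rng.integers(4, 11))
            n_col = int(rng.integers(3, 11))
            records = []
            for i in range(n_seq):
                seq = "".join(alphabet[k] for k in rng.integers(len(alphabet), size=n_col))
                records.append(SequenceRecord(f"s{i}", seq, "A" if i < n_seq // 2 else "B"))
            aln = Alignment(records)
            oracle = brute_force_scores(aln, "A")
            if not oracle:
                continue
            ref_id = records[0].id
            report = scan_signature_positions(aln, "A", ref_id, top_n=n_col)
            got = {s.column: (s.score, s.residue) for s in report.track}
            assert set(got) == set(oracle)
            for col, (score, aa) in oracle.items():
                assert got[col][0] == pytest.approx(score, rel=1e-12)
                assert got[col][1] == aa

    def test_identical_partitions_scores_bounded_by_one(self):
        seqs = ["MKLV", "MKLA", "MRLV"]
        aln = Alignment(
            [SequenceRecord(f"a{i}", s, "A") for i, s in enumerate(seqs)]
            + [SequenceRecord(f"b{i}", s, "B") for i, s in enumerate(seqs)]
        )
        report = scan_signature_positions(aln, "A", "a0", top_n=4)
        for s in report.track:
            assert s.score <= 1.0 + 1e-12
            assert s.score == pytest.approx(s.class_max_rate**2, rel=1e-12)

    def test_reference_numbering_skips_leading_gap(self):
        aln = Alignment([
            SequenceRecord("ref", "-MK", "A"),
            SequenceRecord("x", "AMK", "A"),
            SequenceRecord("y", "AQK", "B"),
        ])
        numbering = reference_numbering(aln, "ref")
        assert numbering == {1: 1, 2: 2}
        report = scan_signature_positions(aln, "A", "ref", top_n=3)
        by_col = {e["column"]: e for e in report.entries}
        assert by_col[1]["reference_position"] == 1

    def test_reference_must_be_in_class(self, planted_family):
        aln, _ = planted_family
        outsider = next(r.id for r in aln.records if r.class_label == "I")
        with pytest.raises(ValueError, match="not a member"):
            scan_signature_positions(aln, "V", outsider)

    def test_planted_columns_recovered(self, planted_family):
        aln, truth = planted_family
        ref = next(r.id for r in aln.records
                   if r.class_label == "V" and "-" not in r.seq)
        report = scan_signature_positions(aln, "V", ref, top_n=10)
        assert {e["column"] for e in report.entries} == set(truth["column"])
        scores = [e["score"] for e in report.entries]
        assert scores == sorted(scores, reverse=True)
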