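"""Kabsch-Sander assignment, chain mapping, dimer filtering, census metrics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from famsig.geometry import build_chain
from famsig.io_formats import Alignment, BackboneStructure, SequenceRecord
from famsig.structure_screen import (
    ChainMapping,
    ClashError,
    ScreenConfig,
    SsAssignment,
    UnmappableChainError,
    assign_secondary_structure,
    dimer_filter,
    hbond_energy,
    interface_strand_metrics,
    map_structure_to_alignment,
    reconstruct_amide_hydrogens,
    screen_structures,
    window_columns,
)
from famsig.synthetic_data import build_strand_pair


class TestHbondEnergy:
    def test_vanishes_at_large_separation(self):
        a = build_chain([(-57.0, -47.0)] * 2)
        b = build_chain([(-57.0, -47.0)] * 2)
        far = [r for r in b]
        for r in far:
            r.atoms = {k: v + np.array([500.0, 0, 0]) for k, v in r.atoms.items()}
        h = reconstruct_amide_hydrogens(far)[1]
        e = hbond_energy(a[0], far[1], h)
        assert abs(e) < 0.05

    def test_ideal_helix_turn_is_bonded(self):
        res = build_chain([(-57.0, -47.0)] * 8)
        h = reconstruct_amide_hydrogens(res)
        assert hbond_energy(res[1], res[5], h[5]) < -0.5

    def test_clash_raises(self):
        res = build_chain([(-57.0, -47.0)] * 3)
        clone = build_chain([(-57.0, -47.0)] * 3)
        clone[1].atoms["N"] = res[0].atoms["O"] + 1e-3
        h = reconstruct_amide_hydrogens(clone)
        with pytest.raises(ClashError):
            hbond_energy(res[0], clone[1], clone[1].atoms["N"] + 1e-4)

    def test_rigid_motion_invariance(self):
        res = build_chain([(-57.0, -47.0)] * 8)
        h = reconstruct_amide_hydrogens(res)
        e0 = hbond_energy(res[1], res[5], h[5])
        rot = Rotation.from_rotvec([0.3, -1.1, 2.0]).as_matrix()
        shift = np.array([11.0, -3.0, 7.0])
        moved = build_chain([(-57.0, -47.0)] * 8)
        for r in moved:
            r.atoms = {k: rot @ v + shift for k, v in r.atoms.items()}
        hm = reconstruct_amide_hydrogens(moved)
        e1 = hbond_energy(moved[1], moved[5], hm[5])
        assert abs(e0 - e1) < 1e-9


class TestAssignment:
    @pytest.mark.parametrize("length", range(6, 21))
    def test_ideal_helix_interiors(self, length):
        st = BackboneStructure({"A": build_chain([(-57.0, -47.0)] * length)})
        ss = assign_secondary_structure(st)["A"]
        assert set(ss[1:-1]) == {"H"}
        assert ss[0] == "-" and ss[-1] == "-"

    def test_isolated_strand_has_no_e(self):
        st = BackboneStructure({"A": build_chain([(-120.0, 120.0)] * 12)})
        assert "E" not in assign_secondary_structure(st)["A"]

    @pytest.mark.parametrize("length", [2, 3, 4, 5])
    def test_planted_sheet_run_lengths(self, length):
        ss = assign_secondary_structure(build_strand_pair(length))
        for chain in ("A", "B"):
            runs = [len(x) for x in ss[chain].replace("B", "-").split("-") if x]
            assert runs == [length]

    def test_proline_never_donates(self):
        res = build_chain([(-57.0, -47.0)] * 8, sequence="AAAAAPAA")
        h = reconstruct_amide_hydrogens(res)
        assert h[5] is None

    def test_short_chain_warns(self):
        st = BackboneStructure({"A": build_chain([(-57.0, -47.0)] * 2)})
        with pytest.warns(UserWarning, match="fewer than 3"):
            ss = assign_secondary_structure(st)
        assert ss["A"] == "--"


def _family(n=3, length=60, seed=4):
    rng = np.random.default_rng(seed)
    aa = "ACDEFGHIKLMNQRSTVWY"
    records = []
    for i in range(n):
        seq = "".join(aa[k] for k in rng.integers(len(aa), size=length))
        records.append(SequenceRecord(f"fam{i}", seq, "V"))
    return Alignment(records)


class TestMapping:
    def test_identity_mapping(self):
        fam = _family()
        target = fam.records[0]
        m = map_structure_to_alignment(target.seq, fam)
        assert m.best_match_id == target.id
        assert m.identity == 1.0
        assert all(m.col_of_res[i] == i for i in range(len(target.seq)))

    def test_internal_deletion_stays_collinear(self):
        fam = _family()
        chain = fam.records[0].seq
        deleted = chain[:20] + chain[25:]       # family member loses 5 residues
        m = map_structure_to_alignment(deleted, fam)
        cols = [m.col_of_res[i] for i in sorted(m.col_of_res)]
        assert cols == sorted(cols)
        assert m.col_of_res[19] == 19
        assert m.col_of_res[20] == 25

    def test_random_sequence_unmappable(self):
        fam = _family()
        rng = np.random.default_rng(1)
        junk = "".join("ACDEFGHIKLMNPQRSTVWY"[k] for k in rng.integers(20, size=60))
        with pytest.raises(UnmappableChainError):
            map_structure_to_alignment(junk, fam, min_identity=0.6)

    def test_short_chain_rejected(self):
        with pytest.raises(UnmappableChainError, match="too short"):
            map_structure_to_alignment("MKLV", _family())


class TestDimerFilterAndMetrics:
    def _mapping(self, chain_id, n=20):
        return ChainMapping(chain_id, "fam0", 1.0, {i: i for i in range(n)})

    def test_single_chain_is_non_dimeric(self):
        ca = {"A": np.zeros((20, 3))}
        keep, reason, _ = dimer_filter(ca, {"A": self._mapping("A")}, set(range(20)))
        assert not keep and reason == "non-dimeric"

    def test_distant_chains_fail_orientation(self):
        base = np.arange(20)[:, None] * np.array([3.8, 0, 0])
        ca = {"A": base, "B": base + np.array([0, 100.0, 0])}
        mappings = {c: self._mapping(c) for c in "AB"}
        keep, reason, _ = dimer_filter(ca, mappings, set(range(20)))
        assert not keep and reason == "orientation"

    def test_contacting_chains_kept(self):
        base = np.arange(20)[:, None] * np.array([3.8, 0, 0])
        ca = {"A": base, "B": base + np.array([0, 5.0, 0])}
        mappings = {c: self._mapping(c) for c in "AB"}
        keep, reason, pair = dimer_filter(ca, mappings, set(range(20)))
        assert keep and reason == "kept" and pair == ("A", "B")

    @pytest.mark.parametrize("ss,expect_len,expect_helix", [
        ("---EEE----HHHH--", 3, True),
        ("--EEEEE-----------", 5, False),
        ("------------------", 0, False),
    ])
    def test_window_metrics(self, ss, expect_len, expect_helix):
        n = len(ss)
        mappings = {c: ChainMapping(c, "fam0", 1.0, {i: i for i in range(n)})
                    for c in "AB"}
        assignment = SsAssignment({"A": ss, "B": ss})
        m = interface_strand_metrics(assignment, mappings, set(range(n)),
                                     ("A", "B"), window=(1, n))
        assert m.strand_length["A"] == expect_len
        assert m.helix_present["A"] is expect_helix

    def test_strand_outside_window_not_counted(self):
        ss = "EEEE------"
        mappings = {c: ChainMapping(c, "fam0", 1.0, {i: i for i in range(10)})
                    for c in "AB"}
        m = interface_strand_metrics(SsAssignment({"A": ss, "B": ss}), mappings,
                                     {6, 7, 8, 9}, ("A", "B"))
        assert m.strand_length["A"] == 0


class TestWindowColumns:
    def test_reference_window_respects_gaps(self):
        aln = Alignment([
            SequenceRecord("ref", "-MK-LV", "V"),
            SequenceRecord("x", "AMKQLV", "V"),
        ])
        cols = window_columns(aln, "ref", (2, 3))
        assert cols == {2, 4}       # K is residue 2, L residue 3


class TestScreenBatch:
    def test_census_bookkeeping(self, census_batch):
        summary = screen_structures(
            census_batch["pdb"], census_batch["alignment"],
            ScreenConfig(reference_id=census_batch["reference_id"]),
        )
        assert len(summary.kept) + len(summary.discarded) == len(census_batch["pdb"])
        assert sum(summary.strand_histogram.values()) == len(summary.kept)

    def test_unreadable_file_skipped(self, tmp_path, census_batch):
        bad = tmp_path / "junk.pdb"
        bad.write_text("ATOM garbage\n")
        summary = screen_structures(
            [bad] + list(census_batch["pdb"][:1]), census_batch["alignment"],
            ScreenConfig(reference_id=census_batch["reference_id"]),
        )
        assert any("unreadable" in reason for _, reason in summary.discarded)
        assert len(summary.kept) == 1
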