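"""Shared fixtures: synthetic families and a reusable structure batch.

Everything is generated programmatically with fixed seeds; the heavier
geometry batch is session-scoped because several test modules screen it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from famsig.io_formats import (
    DsspRecord,
    read_pdb_backbone,
    write_dssp_file,
    write_pdb_backbone,
)
from famsig.structure_screen import assign_secondary_structure
from famsig.synthetic_data import (
    FamilySimSpec,
    build_interface_dimer,
    default_planted_sites,
    interface_chain_length,
    simulate_class_family,
)


@pytest.fixture(scope="session")
def small_family():
    """6 classes x 4 sequences, no fragments; ungapped members."""
    aln, truth = simulate_class_family(
        FamilySimSpec(n_per_class=4, fragment_rate=0.0, seed=11)
    )
    return aln, truth


@pytest.fixture(scope="session")
def planted_family():
    """Signature-bearing family at the default study conditions."""
    rng = np.random.default_rng(5)
    prevalences = [1.0, 0.8, 0.9, 1.0, 0.86, 0.8, 1.0, 0.94, 0.9, 0.82]
    planted = default_planted_sites(380, "V", 10, rng, prevalences)
    aln, truth = simulate_class_family(FamilySimSpec(planted=planted, seed=5))
    return aln, truth


def _reference_record(alignment, label="V"):
    return next(r for r in alignment.records if r.class_label == label)


@pytest.fixture(scope="session")
def census_batch(tmp_path_factory, small_family):
    """12 structure files: 7 planted 3-residue-strand dimers, 3 planted
    5-residue-strand dimers, 1 monomer, 1 separated chain pair — written both
    as PDB files and as classic DSSP files."""
    aln, _ = small_family
    ref = _reference_record(aln)
    refseq = ref.ungapped
    p0 = 280
    out = tmp_path_factory.mktemp("census")
    pdb_paths: list[Path] = []
    for name, length in [(f"d3_{i}", 3) for i in range(7)] + [(f"d5_{i}", 5) for i in range(3)]:
        st = build_interface_dimer(
            length, refseq[p0:p0 + interface_chain_length(length)], structure_id=name
        )
        path = out / f"{name}.pdb"
        write_pdb_backbone(st, path)
        pdb_paths.append(path)
    seq3 = refseq[p0:p0 + interface_chain_length(3)]
    mono = build_interface_dimer(3, seq3, structure_id="mono", monomer=True)
    write_pdb_backbone(mono, out / "mono.pdb")
    pdb_paths.append(out / "mono.pdb")
    sep = build_interface_dimer(3, seq3, structure_id="sep", separation=100.0)
    write_pdb_backbone(sep, out / "sep.pdb")
    pdb_paths.append(out / "sep.pdb")

    dssp_paths: list[Path] = []
    for path in pdb_paths:
        st = read_pdb_backbone(path)
        ss = assign_secondary_structure(st)
        records = []
        for cid in st.chains:
            for res, code in zip(st.complete_residues(cid), ss[cid]):
                records.append(DsspRecord(cid, res.number, res.one_letter, code,
                                          res.atoms["CA"]))
        dssp = path.with_suffix(".dssp")
        write_dssp_file(records, dssp)
        dssp_paths.append(dssp)
    return {"alignment": aln, "reference_id": ref.id,
            "pdb": pdb_paths, "dssp": dssp_paths}
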