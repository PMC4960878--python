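"""Backbone geometry primitives: dihedrals and internal-to-Cartesian placement.

Used by the synthetic-structure builder (NeRF-style chain construction from
ideal bond lengths/angles and requested phi/psi) and by the Ramachandran-style
round-trip checks.
"""

from __future__ import annotations

import numpy as np

from .io_formats import BackboneResidue, BackboneStructure, ONE_TO_THREE

# ideal backbone internal coordinates (Angstrom, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

#: canonical (phi, psi) for named motifs
MOTIF_DIHEDRALS = {
    "helix": (-57.0, -47.0),
    "strand": (-139.0, 135.0),
    "coil": (-75.0, 150.0),
}


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b1 / np.linalg.norm(b1))
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d bonded to c with angle(d,c,b) and dihedral(d,c,b,a) given.

    Standard natural-extension (NeRF) construction.
    """
    angle = np.radians(angle_deg)
    torsion = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(angle), np.sin(angle) * np.cos(torsion), np.sin(angle) * np.sin(torsion)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_chain(dihedrals: list[tuple[float, float]],
                sequence: str | None = None,
                chain_id: str = "A",
                start_number: int = 1) -> list[BackboneResidue]:
    """Build a backbone chain from per-residue (phi, psi) targets.

    The first residue's phi is ignored (undefined); the last residue's psi is
    still used to orient its carbonyl oxygen.  Peptide bonds are planar-trans
    (omega 180 deg).
    """
    n_res = len(dihedrals)
    if n_res == 0:
        raise ValueError("empty chain spec")
    if sequence is None:
        sequence = "A" * n_res
    if len(sequence) != n_res:
        raise ValueError("sequence length does not match dihedral list")

    coords: list[dict[str, np.ndarray]] = []
    # first residue laid out in the z=0 plane
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        phi_i = dihedrals[i][0]
        psi_prev = dihedrals[i - 1][1]
        prev = coords[i - 1]
        n_i = place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca_i = place_atom(prev["CA"], prev["C"], n_i, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_i = place_atom(prev["C"], n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi_i)
        coords.append({"N": n_i, "CA": ca_i, "C": c_i})
    # carbonyl oxygens, anti to the following amide nitrogen
    for i in range(n_res):
        psi_i = dihedrals[i][1]
        c = coords[i]
        c["O"] = place_atom(c["N"], c["CA"], c["C"], BOND_C_O, ANGLE_CA_C_O, psi_i + 180.0)

    residues = []
    for i, atom_map in enumerate(coords):
        residues.append(
            BackboneResidue(
                name=ONE_TO_THREE.get(sequence[i], "ALA"),
                number=start_number + i,
                atoms=atom_map,
            )
        )
    return residues


def chain_dihedrals(residues: list[BackboneResidue]) -> list[tuple[float | None, float | None]]:
    """Recompute (phi, psi) from coordinates; None where undefined."""
    out: list[tuple[float | None, float | None]] = []
    for i, res in enumerate(residues):
        phi = psi = None
        if i > 0:
            phi = dihedral(residues[i - 1].atoms["C"], res.atoms["N"],
                           res.atoms["CA"], res.atoms["C"])
        if i < len(residues) - 1:
            psi = dihedral(res.atoms["N"], res.atoms["CA"],
                           res.atoms["C"], residues[i + 1].atoms["N"])
        out.append((phi, psi))
    return out


def transform_residues(residues: list[BackboneResidue], rotation: np.ndarray,
                       translation: np.ndarray) -> list[BackboneResidue]:
    """Apply a rigid transform, returning new residues."""
    out = []
    for res in residues:
        atoms = {k: rotation @ v + translation for k, v in res.atoms.items()}
        out.append(BackboneResidue(res.name, res.number, res.icode, atoms))
    return out


def structure_from_chains(chains: dict[str, list[BackboneResidue]],
                          id: str = "synthetic") -> BackboneStructure:
    return BackboneStructure(chains, id=id)
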