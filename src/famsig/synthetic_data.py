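"""Synthetic inputs with exact ground truth for every pipeline stage.

Three generators:

* :func:`simulate_class_family` — a class-structured protein-family MSA with
  planted class-signature columns at requested prevalences.  Classes diverge
  from a common root; substitutions are drawn from a small per-column residue
  repertoire (mimicking per-site chemical constraints), so that a residue
  outside a column's repertoire — the planted signature — is genuinely
  class-unique, as in real families.
* :func:`simulate_codon_alignment` — star-tree codon evolution under a chosen
  dN/dS (omega): single-nucleotide proposals accepted with probability 1 if
  synonymous and omega if nonsynonymous; changes to stop codons are rejected.
* :func:`build_ideal_backbone` — backbone chains from ideal internal
  coordinates and per-residue phi/psi, including two-chain placement that
  brings strand segments into antiparallel H-bond register with a planted
  interface beta-strand length.

All generators are pure functions of their spec (which carries the seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from . import geometry
from .geometry import MOTIF_DIHEDRALS, build_chain, transform_residues
from .io_formats import (
    Alignment,
    BackboneResidue,
    BackboneStructure,
    STANDARD_AA,
    SequenceRecord,
)
from .selection_pressure import CodonAlignment, _code

ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


# ---------------------------------------------------------------------------
# protein family simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSite:
    column: int
    class_label: str
    residue: str
    class_prevalence: float = 1.0
    rest_prevalence: float = 0.0


@dataclass
class FamilySimSpec:
    n_classes: int = 6
    n_per_class: int = 50
    length: int = 380
    inter_class_divergence: float = 0.4     # ~60% inter-class identity
    intra_class_divergence: float = 0.15    # ~85% intra-class identity
    planted: Sequence[PlantedSite] = field(default_factory=tuple)
    fragment_rate: float = 0.05             # chance a member is an end-trimmed fragment
    max_fragment_trim: float = 0.25         # at most this fraction of columns trimmed
    column_alphabet_size: int = 4           # per-column residue repertoire
    off_alphabet_rate: float = 0.1          # noise substitutions outside the repertoire
    seed: int = 0

    def validate(self) -> None:
        if self.n_classes < 2 or self.n_classes > len(ROMAN):
            raise ValueError("n_classes must be in [2, 10]")
        cols = [p.column for p in self.planted]
        if len(cols) != len(set(cols)):
            raise ValueError("planted columns must be distinct")
        for p in self.planted:
            if not (0 <= p.column < self.length):
                raise ValueError(f"planted column {p.column} out of range")
            if not (0.0 <= p.class_prevalence <= 1.0 and 0.0 <= p.rest_prevalence <= 1.0):
                raise ValueError("prevalences must be in [0, 1]")
            if p.residue not in STANDARD_AA:
                raise ValueError(f"planted residue {p.residue!r} not a standard amino acid")


class PlantingError(ValueError):
    pass


def _substitute(rng: np.random.Generator, current: str, repertoire: str,
                off_rate: float) -> str:
    """Draw a replacement residue: from the column repertoire (minus the
    current residue) with probability 1 - off_rate, else any other residue."""
    options = [a for a in repertoire if a != current]
    if options and rng.random() >= off_rate:
        return options[rng.integers(len(options))]
    others = [a for a in STANDARD_AA if a != current]
    return others[rng.integers(len(others))]


def simulate_class_family(spec: FamilySimSpec) -> tuple[Alignment, pd.DataFrame]:
    """Generate the family alignment plus a ground-truth table of planted sites.

    Planted sites overwrite member residues so the realized class and rest
    prevalences (over non-gap members) hit the requested values exactly after
    rounding to the nearest count; the planted residue is removed from the
    column's repertoire and scrubbed from every non-selected sequence.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    aa = np.array(list(STANDARD_AA))
    planted_by_col = {p.column: p for p in spec.planted}

    root = aa[rng.integers(20, size=spec.length)]
    # the root never carries a planted residue at its planted column, so the
    # signature is genuinely outside the column's background repertoire
    for col, site in planted_by_col.items():
        if root[col] == site.residue:
            pool = [a for a in STANDARD_AA if a != site.residue]
            root[col] = pool[rng.integers(len(pool))]
    repertoire: list[str] = []
    for col in range(spec.length):
        forbidden = {planted_by_col[col].residue} if col in planted_by_col else set()
        pool = [a for a in STANDARD_AA if a != root[col] and a not in forbidden]
        extra = rng.choice(pool, size=max(spec.column_alphabet_size - 1, 0), replace=False)
        repertoire.append(str(root[col]) + "".join(extra))

    labels = ROMAN[: spec.n_classes]
    consensus: dict[str, np.ndarray] = {}
    for label in labels:
        cons = root.copy()
        flips = rng.random(spec.length) < spec.inter_class_divergence
        for col in np.nonzero(flips)[0]:
            # consensus divergence stays inside the column repertoire: a class
            # consensus explores the site's permitted chemistry, while
            # off-repertoire variants arise only in individual sequences
            cons[col] = _substitute(rng, cons[col], repertoire[col], 0.0)
        # class consensus must not coincide with a planted residue of any class
        for col, site in planted_by_col.items():
            if cons[col] == site.residue:
                cons[col] = root[col]
        consensus[label] = cons

    records: list[SequenceRecord] = []
    seq_class: list[str] = []
    rows: list[np.ndarray] = []
    for label in labels:
        for k in range(spec.n_per_class):
            member = consensus[label].copy()
            flips = rng.random(spec.length) < spec.intra_class_divergence
            for col in np.nonzero(flips)[0]:
                member[col] = _substitute(rng, member[col], repertoire[col],
                                          spec.off_alphabet_rate)
            if rng.random() < spec.fragment_rate:
                trim = int(rng.integers(1, max(int(spec.length * spec.max_fragment_trim), 2)))
                if rng.random() < 0.5:
                    member[:trim] = "-"
                else:
                    member[spec.length - trim:] = "-"
            rows.append(member)
            seq_class.append(label)
            records.append(SequenceRecord(f"{label}_{k:03d}", "", label))

    mat = np.array(rows)
    class_arr = np.array(seq_class)

    truth_rows = []
    for site in spec.planted:
        col = site.column
        res = site.residue
        in_class = class_arr == site.class_label
        if not in_class.any():
            raise PlantingError(f"column {col}: class {site.class_label!r} absent")
        scrub_with = consensus[site.class_label][col]
        if scrub_with == res:
            scrub_with = root[col]

        def plant(mask: np.ndarray, prevalence: float, fallback: str) -> float:
            rows_idx = np.nonzero(mask & (mat[:, col] != "-"))[0]
            n_nm = rows_idx.size
            if n_nm == 0:
                raise PlantingError(f"column {col}: no non-gap members to plant into")
            target = int(round(prevalence * n_nm))
            if target == 0 and prevalence > 0:
                raise PlantingError(
                    f"column {col}: prevalence {prevalence} unreachable with {n_nm} members"
                )
            chosen = rng.choice(rows_idx, size=target, replace=False)
            mat[chosen, col] = res
            others = np.setdiff1d(rows_idx, chosen)
            hit = others[mat[others, col] == res]
            mat[hit, col] = fallback
            return target / n_nm

        realized_class = plant(in_class, site.class_prevalence, scrub_with)
        realized_rest = plant(~in_class, site.rest_prevalence, root[col])
        truth_rows.append({
            "column": col,
            "class_label": site.class_label,
            "residue": res,
            "class_prevalence": realized_class,
            "rest_prevalence": realized_rest,
        })

    for rec, row in zip(records, mat):
        rec.seq = "".join(row)
    truth = pd.DataFrame(
        truth_rows,
        columns=["column", "class_label", "residue", "class_prevalence", "rest_prevalence"],
    )
    return Alignment(records), truth


def default_planted_sites(length: int, class_label: str, n_sites: int,
                          rng: np.random.Generator,
                          prevalences: Optional[Sequence[float]] = None) -> list[PlantedSite]:
    """Convenience: distinct random columns with signature residues for one class."""
    cols = rng.choice(length, size=n_sites, replace=False)
    if prevalences is None:
        prevalences = [1.0] * n_sites
    sites = []
    for col, prev in zip(cols, prevalences):
        res = STANDARD_AA[rng.integers(20)]
        sites.append(PlantedSite(int(col), class_label, res, float(prev), 0.0))
    return sites


# ---------------------------------------------------------------------------
# codon alignment simulation
# ---------------------------------------------------------------------------

@dataclass
class CodonSimSpec:
    n_sequences: int = 10
    n_codons: int = 500
    omega: float = 0.3                      # target dN/dS
    branch_length: float = 0.5              # expected substitutions per codon per lineage
    kappa: float = 1.0                      # transition/transversion rate ratio
    seed: int = 0

    def validate(self) -> None:
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if self.branch_length < 0:
            raise ValueError("branch_length must be non-negative")


def simulate_codon_alignment(spec: CodonSimSpec) -> tuple[CodonAlignment, float]:
    """Star-tree codon evolution from a random stop-free root.

    Substitutions are generated by acceptance-rejection on uniform (or
    kappa-weighted) single-nucleotide proposals: synonymous changes accepted
    with probability min(1, 1/omega), nonsynonymous with min(1, omega);
    proposals creating stop codons are always rejected.  Each lineage receives
    a Poisson(branch_length * n_codons) number of accepted substitutions.
    Returns the alignment and the generating omega.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    forward, stops = _code(1)
    sense = sorted(forward)
    root = [sense[i] for i in rng.integers(len(sense), size=spec.n_codons)]

    p_syn = min(1.0, 1.0 / spec.omega)
    p_non = min(1.0, spec.omega)
    transition = {"A": "G", "G": "A", "C": "T", "T": "C"}

    def propose_base(current: str) -> str:
        others = [b for b in "ACGT" if b != current]
        if spec.kappa == 1.0:
            return others[rng.integers(3)]
        weights = np.array([spec.kappa if b == transition[current] else 1.0 for b in others])
        weights = weights / weights.sum()
        return others[rng.choice(3, p=weights)]

    records: dict[str, str] = {}
    for s in range(spec.n_sequences):
        codons = list(root)
        n_sub = rng.poisson(spec.branch_length * spec.n_codons)
        accepted = 0
        attempts = 0
        max_attempts = 1000 * (n_sub + 1)
        while accepted < n_sub and attempts < max_attempts:
            attempts += 1
            ci = int(rng.integers(spec.n_codons))
            pos = int(rng.integers(3))
            codon = codons[ci]
            base = propose_base(codon[pos])
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt in stops:
                continue
            p_accept = p_syn if forward[alt] == forward[codon] else p_non
            if rng.random() < p_accept:
                codons[ci] = alt
                accepted += 1
        records[f"seq_{s:03d}"] = "".join(codons)
    return CodonAlignment(records), spec.omega


# ---------------------------------------------------------------------------
# ideal-geometry structures
# ---------------------------------------------------------------------------

@dataclass
class ChainGeometrySpec:
    """Per-chain layout: a list of (motif, length) segments, or explicit
    per-residue (phi, psi) targets."""
    segments: Sequence[tuple[str, int]] = field(default_factory=tuple)
    dihedrals: Optional[Sequence[tuple[float, float]]] = None
    sequence: Optional[str] = None
    chain_id: str = "A"

    def resolved_dihedrals(self) -> list[tuple[float, float]]:
        if self.dihedrals is not None:
            return list(self.dihedrals)
        out: list[tuple[float, float]] = []
        for motif, length in self.segments:
            if motif not in MOTIF_DIHEDRALS:
                raise ValueError(f"unknown motif {motif!r}")
            out.extend([MOTIF_DIHEDRALS[motif]] * length)
        if not out:
            raise ValueError("chain spec resolves to zero residues")
        return out


@dataclass
class GeometrySpec:
    chains: Sequence[ChainGeometrySpec]
    pairing: Optional[Sequence[tuple[int, int]]] = None  # antiparallel register pairs
    separation: float = 0.0      # extra translation applied to chain 2 after placement
    structure_id: str = "synthetic"
    seed: int = 0


class PlacementError(ValueError):
    pass


def _narrow_pair_bonds(pairing: Sequence[tuple[int, int]]):
    """Planted H-bonds for an antiparallel register: every *other* pair,
    starting from the second, donates and accepts across the interface."""
    narrow = [p for k, p in enumerate(sorted(pairing)) if k % 2 == 1]
    bonds = []
    for i, j in narrow:
        bonds.append(("A", i, "B", j))   # CO of A_i accepts from NH of B_j
        bonds.append(("B", j, "A", i))
    return bonds


def place_antiparallel(chain_a: list[BackboneResidue], chain_b: list[BackboneResidue],
                       pairing: Sequence[tuple[int, int]]) -> list[BackboneResidue]:
    """Rigidly place ``chain_b`` so that the given (res_a, res_b) pairs form an
    antiparallel H-bond register with chain_a (N...O 2.9 A, H...O 1.9 A).

    The transform is found by least squares from several deterministic
    starting orientations; raises :class:`PlacementError` if no clash-free
    register is achievable.
    """
    from .structure_screen import reconstruct_amide_hydrogens

    bonds = _narrow_pair_bonds(pairing)
    h_a = reconstruct_amide_hydrogens(chain_a)
    h_b_local = reconstruct_amide_hydrogens(chain_b)

    atoms_b = np.array([v for r in chain_b for v in r.atoms.values()])
    atoms_a = np.array([v for r in chain_a for v in r.atoms.values()])

    def transformed(params: np.ndarray):
        rot = Rotation.from_rotvec(params[:3]).as_matrix()
        t = params[3:]
        return rot, t

    def residuals(params: np.ndarray) -> np.ndarray:
        rot, t = transformed(params)
        res = []
        for acc_chain, i, don_chain, j in bonds:
            if acc_chain == "A":
                o = chain_a[i].atoms["O"]
                nb = rot @ chain_b[j].atoms["N"] + t
                hb = None if h_b_local[j] is None else rot @ h_b_local[j] + t
            else:
                o = rot @ chain_b[i].atoms["O"] + t
                nb = chain_a[j].atoms["N"]
                hb = h_a[j]
            res.append(np.linalg.norm(o - nb) - 2.9)
            if hb is not None:
                res.append(np.linalg.norm(o - hb) - 1.9)
        # soft clash penalty, aggregated so the residual size stays fixed
        moved = (rot @ atoms_b.T).T + t
        d = np.linalg.norm(atoms_a[:, None, :] - moved[None, :, :], axis=-1)
        overlap = np.clip(2.6 - d, 0.0, None)
        res.append(3.0 * float(np.sqrt((overlap ** 2).sum())))
        return np.asarray(res)

    # initial transform: superpose B's donor/acceptor atoms onto ideal
    # positions along A's C=O and N-H directions (Kabsch fit), then refine
    local_pts, target_pts = [], []
    for acc_chain, i, don_chain, j in bonds:
        if acc_chain == "A":
            o, c = chain_a[i].atoms["O"], chain_a[i].atoms["C"]
            u = o - c
            u = u / np.linalg.norm(u)
            local_pts.append(chain_b[j].atoms["N"])
            target_pts.append(o + 1.0 * u + 0.0)
            target_pts[-1] = o + 2.9 * u
            if h_b_local[j] is not None:
                local_pts.append(h_b_local[j])
                target_pts.append(o + 1.9 * u)
        else:
            nn, hh = chain_a[j].atoms["N"], h_a[j]
            u = (hh - nn) if hh is not None else np.array([0.0, 1.0, 0.0])
            u = u / np.linalg.norm(u)
            local_pts.append(chain_b[i].atoms["O"])
            target_pts.append(nn + 2.9 * u)
    local = np.asarray(local_pts)
    target = np.asarray(target_pts)
    cl, ct = local.mean(axis=0), target.mean(axis=0)
    rot0, _ = Rotation.align_vectors(target - ct, local - cl)
    t0 = ct - rot0.as_matrix() @ cl
    x0 = np.concatenate([rot0.as_rotvec(), t0])

    best = least_squares(residuals, x0, method="lm", max_nfev=500)
    if best.cost > 1e-4:
        for axis in np.eye(3):
            for sign in (1.0, -1.0):
                alt = np.concatenate([np.pi * sign * axis, t0])
                sol = least_squares(residuals, alt, method="lm", max_nfev=1000)
                if sol.cost < best.cost:
                    best = sol
                if best.cost < 1e-6:
                    break
            if best.cost < 1e-6:
                break
    rot, t = transformed(best.x)
    placed = transform_residues(chain_b, rot, t)
    # verify: planted bond distances within 0.2 A and no hard clashes
    check = residuals(best.x)
    n_bond_res = sum(2 if (b[2] == "B" and h_b_local[b[3]] is not None)
                     or (b[2] == "A" and h_a[b[3]] is not None) else 1
                     for b in bonds)
    if np.any(np.abs(check[:n_bond_res]) > 0.2):
        raise PlacementError("could not reach the requested H-bond register")
    moved = np.array([v for r in placed for v in r.atoms.values()])
    d = np.linalg.norm(atoms_a[:, None, :] - moved[None, :, :], axis=-1)
    if d.min() < 1.7:
        raise PlacementError(f"inter-chain clash at {d.min():.2f} A")
    return placed


def build_ideal_backbone(spec: GeometrySpec) -> BackboneStructure:
    """Build a structure from ideal internal coordinates per chain spec.

    When ``pairing`` is given, the second chain is rigidly placed into
    antiparallel H-bond register with the first; ``separation`` then
    translates the second chain away (for planted non-dimer controls).
    """
    if not spec.chains:
        raise ValueError("no chains in spec")
    chains: dict[str, list[BackboneResidue]] = {}
    built = []
    for i, cs in enumerate(spec.chains):
        dihedrals = cs.resolved_dihedrals()
        seq = cs.sequence
        residues = build_chain(dihedrals, sequence=seq, chain_id=cs.chain_id)
        built.append((cs.chain_id, residues))
    if spec.pairing is not None:
        if len(built) != 2:
            raise ValueError("pairing requires exactly two chains")
        (id_a, chain_a), (id_b, chain_b) = built
        chain_b = place_antiparallel(chain_a, chain_b, spec.pairing)
        built = [(id_a, chain_a), (id_b, chain_b)]
    if spec.separation and len(built) == 2:
        (id_a, chain_a), (id_b, chain_b) = built
        shift = np.array([spec.separation, 0.0, 0.0])
        chain_b = transform_residues(chain_b, np.eye(3), shift)
        built = [(id_a, chain_a), (id_b, chain_b)]
    for chain_id, residues in built:
        if chain_id in chains:
            raise ValueError(f"duplicate chain id {chain_id!r}")
        chains[chain_id] = residues
    return BackboneStructure(chains, id=spec.structure_id)


# -- convenience layouts for the structure screen ---------------------------

#: chain layout used by the census generators: a coil prefix, the interface
#: strand, a short linker, the interface helix, and a coil suffix.
PREFIX_LEN = 8
LINKER_LEN = 4
HELIX_LEN = 10
SUFFIX_LEN = 8
STRAND_START = PREFIX_LEN            # chain index of the first strand residue

_COIL_WOBBLE = [(-75.0, 150.0), (-95.0, 125.0), (-65.0, 160.0), (-85.0, 140.0)]
_LINKER = [(-80.0, -20.0), (-120.0, 60.0), (-70.0, 140.0), (-100.0, 130.0)]


def interface_chain_dihedrals(strand_len: int) -> list[tuple[float, float]]:
    """Dihedral layout for one census chain with an L-residue paired strand
    (the buildable strand segment is L+2 residues; the flanks stay unpaired)."""
    out: list[tuple[float, float]] = []
    for k in range(PREFIX_LEN):
        out.append(_COIL_WOBBLE[k % len(_COIL_WOBBLE)])
    # strand flanks: the entering phi and the leaving psi are bent away from
    # ideal strand values so the ladder cannot extend past the planted run
    # into the prefix/linker (their neighbours' carbonyl/amide planes rotate
    # out of H-bond register)
    out.append((-60.0, MOTIF_DIHEDRALS["strand"][1]))
    out.extend([MOTIF_DIHEDRALS["strand"]] * strand_len)
    out.append((MOTIF_DIHEDRALS["strand"][0], -30.0))
    out.extend(_LINKER[:LINKER_LEN])
    out.extend([MOTIF_DIHEDRALS["helix"]] * HELIX_LEN)
    for k in range(SUFFIX_LEN):
        out.append(_COIL_WOBBLE[(k + 2) % len(_COIL_WOBBLE)])
    return out


def interface_chain_length(strand_len: int) -> int:
    return PREFIX_LEN + strand_len + 2 + LINKER_LEN + HELIX_LEN + SUFFIX_LEN


def build_interface_dimer(strand_len: int, sequence: str,
                          structure_id: str = "dimer",
                          monomer: bool = False,
                          separation: float = 0.0) -> BackboneStructure:
    """A census structure: two identical chains whose interface strands pair
    antiparallel with a planted E-run of exactly ``strand_len`` (odd lengths),
    each followed by a short helix.  ``sequence`` must cover the chain length;
    prolines are replaced (they cannot donate the planted H-bonds)."""
    n = interface_chain_length(strand_len)
    if len(sequence) < n:
        raise ValueError(f"sequence too short: need {n}, got {len(sequence)}")
    seq = sequence[:n].replace("P", "A")
    dihedrals = interface_chain_dihedrals(strand_len)
    cs_a = ChainGeometrySpec(dihedrals=dihedrals, sequence=seq, chain_id="A")
    if monomer:
        return build_ideal_backbone(GeometrySpec([cs_a], structure_id=structure_id))
    cs_b = ChainGeometrySpec(dihedrals=dihedrals, sequence=seq, chain_id="B")
    s0 = STRAND_START
    n_strand = strand_len + 2
    pairing = [(s0 + k, s0 + (n_strand - 1 - k)) for k in range(n_strand)]
    return build_ideal_backbone(
        GeometrySpec([cs_a, cs_b], pairing=pairing, separation=separation,
                     structure_id=structure_id)
    )


def build_strand_pair(strand_len: int, structure_id: str = "sheet") -> BackboneStructure:
    """Two bare strand chains (length ``strand_len`` + 2) in antiparallel
    register, planting an E-run of exactly ``strand_len`` per chain for any
    length >= 2 (chain termini terminate the ladder)."""
    n = strand_len + 2
    cs_a = ChainGeometrySpec(segments=[("strand", n)], chain_id="A")
    cs_b = ChainGeometrySpec(segments=[("strand", n)], chain_id="B")
    pairing = [(k, n - 1 - k) for k in range(n)]
    return build_ideal_backbone(
        GeometrySpec([cs_a, cs_b], pairing=pairing, structure_id=structure_id)
    )
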