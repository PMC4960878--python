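"""Structural census of a dimer-interface region.

Given backbone coordinates (or precomputed DSSP files) and a labelled family
alignment, the screen

1. assigns secondary structure with a minimal Kabsch-Sander procedure
   (backbone H-bond energy, 4-turn helices, beta bridges and ladders),
   reduced to the alphabet {H, E, B, -};
2. maps each chain sequence onto the family alignment by pairwise alignment
   against every family member (best identity wins);
3. discards structures that are not dimers or whose subunits are not in
   contact across the interface window ("incorrect subunit orientation");
4. measures, per chain, the length of the longest beta-strand run touching
   the interface window and whether an alpha-helix (H-run of >= 4) is present
   there;
5. aggregates a census histogram of interface strand lengths over the batch.

The interface window is given in reference-sequence numbering (for the
alcohol dehydrogenase family that motivated the screen, the subunit
interaction region spans roughly positions 282-320).
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .class_signature import reference_numbering
from .io_formats import (
    Alignment,
    BackboneResidue,
    BackboneStructure,
    DsspRecord,
    FormatError,
    read_dssp_file,
    read_pdb_backbone,
    sniff_structure_format,
)

logger = logging.getLogger(__name__)

#: Kabsch-Sander electrostatic H-bond model constants
HB_COUPLING = 27.888            # q1*q2*332 kcal/mol*A
HB_E_MIN = -9.9                 # clamp
HB_CUTOFF = -0.5                # bond declared below this energy
CLASH_DISTANCE = 0.5

DEFAULT_WINDOW = (282, 320)
DEFAULT_MIN_CONTACTS = 5
DEFAULT_MIN_IDENTITY = 0.3
CONTACT_CUTOFF = 8.0            # CA-CA, Angstrom


class ClashError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Kabsch-Sander assignment
# ---------------------------------------------------------------------------

def hbond_energy(acceptor: BackboneResidue, donor: BackboneResidue,
                 donor_h: np.ndarray) -> float:
    """Kabsch-Sander electrostatic energy (kcal/mol) of the backbone H-bond
    donated by ``donor``'s amide to ``acceptor``'s carbonyl.

    E = 27.888 * (1/r(ON) + 1/r(CH) - 1/r(OH) - 1/r(CN)), clamped at -9.9.
    """
    o = acceptor.atoms["O"]
    c = acceptor.atoms["C"]
    n = donor.atoms["N"]
    h = donor_h
    d_on = np.linalg.norm(o - n)
    d_ch = np.linalg.norm(c - h)
    d_oh = np.linalg.norm(o - h)
    d_cn = np.linalg.norm(c - n)
    if min(d_on, d_ch, d_oh, d_cn) < CLASH_DISTANCE:
        raise ClashError("donor/acceptor atoms closer than 0.5 A")
    energy = HB_COUPLING * (1.0 / d_on + 1.0 / d_ch - 1.0 / d_oh - 1.0 / d_cn)
    return max(energy, HB_E_MIN)


def reconstruct_amide_hydrogens(residues: Sequence[BackboneResidue]) -> list[Optional[np.ndarray]]:
    """Amide H per residue: 1.0 A from N, anti-parallel to the preceding
    carbonyl C=O (the DSSP convention).  None for the first residue and for
    prolines (no donor); an H already present in the file is used as-is."""
    out: list[Optional[np.ndarray]] = []
    for i, res in enumerate(residues):
        if res.name == "PRO":
            out.append(None)
            continue
        if "H" in res.atoms:
            out.append(res.atoms["H"])
            continue
        if i == 0:
            out.append(None)
            continue
        prev = residues[i - 1]
        direction = prev.atoms["C"] - prev.atoms["O"]
        norm = np.linalg.norm(direction)
        if norm == 0:
            out.append(None)
            continue
        out.append(res.atoms["N"] + direction / norm)
    return out


@dataclass
class SsAssignment:
    """Reduced secondary-structure strings per chain, over complete residues."""
    chains: dict[str, str]

    def __getitem__(self, chain_id: str) -> str:
        return self.chains[chain_id]


def assign_secondary_structure(structure: BackboneStructure) -> SsAssignment:
    """Assign {H, E, B, -} per complete residue of every chain.

    Helices: runs of >= 2 consecutive i -> i+4 backbone H-bonds (4-turns) mark
    residues i..i+3 as H.  Strands: Kabsch-Sander parallel/antiparallel bridge
    patterns; ladders (>= 2 consecutive bridges) become E, isolated bridges B.
    The remaining DSSP states (3/5-turns, bends) collapse to '-'.  Helix takes
    priority over strand where both patterns match.
    """
    # flat residue list with chain bookkeeping
    flat: list[BackboneResidue] = []
    chain_of: list[str] = []
    pos_in_chain: list[int] = []
    chain_slices: dict[str, tuple[int, int]] = {}
    for chain_id in structure.chains:
        residues = structure.complete_residues(chain_id)
        if len(residues) < 3:
            warnings.warn(f"chain {chain_id}: fewer than 3 complete residues, skipped")
            chain_slices[chain_id] = (len(flat), len(flat) + len(residues))
            flat.extend(residues)
            chain_of.extend([chain_id] * len(residues))
            pos_in_chain.extend(range(len(residues)))
            continue
        chain_slices[chain_id] = (len(flat), len(flat) + len(residues))
        flat.extend(residues)
        chain_of.extend([chain_id] * len(residues))
        pos_in_chain.extend(range(len(residues)))

    n = len(flat)
    hydrogens: list[Optional[np.ndarray]] = []
    for chain_id in structure.chains:
        lo, hi = chain_slices[chain_id]
        hydrogens.extend(reconstruct_amide_hydrogens(flat[lo:hi]))

    ca = np.array([r.atoms["CA"] for r in flat]) if n else np.empty((0, 3))
    # candidate pairs by CA distance (KS uses 9 A)
    if n:
        d2 = np.sum((ca[:, None, :] - ca[None, :, :]) ** 2, axis=-1)
        near = d2 < 81.0
    else:
        near = np.zeros((0, 0), dtype=bool)

    def same_chain(i: int, j: int) -> bool:
        return chain_of[i] == chain_of[j]

    # hbond[i][j] True when CO of i accepts from NH of j
    hbond = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            if i == j or not near[i, j]:
                continue
            if same_chain(i, j) and abs(pos_in_chain[i] - pos_in_chain[j]) < 2:
                continue
            if hydrogens[j] is None:
                continue
            try:
                e = hbond_energy(flat[i], flat[j], hydrogens[j])
            except ClashError:
                continue
            if e < HB_CUTOFF:
                hbond[i, j] = True

    ss = ["-"] * n

    def neighbor(i: int, step: int) -> Optional[int]:
        j = i + step
        if 0 <= j < n and same_chain(i, j) and pos_in_chain[j] == pos_in_chain[i] + step:
            return j
        return None

    # --- beta bridges ---
    def hb(i: Optional[int], j: Optional[int]) -> bool:
        return i is not None and j is not None and hbond[i, j]

    bridges: dict[tuple[int, int], str] = {}
    for i in range(n):
        for j in range(i + 1, n):
            if same_chain(i, j) and abs(pos_in_chain[i] - pos_in_chain[j]) < 3:
                continue
            if not near[i, j]:
                continue
            im1, ip1 = neighbor(i, -1), neighbor(i, 1)
            jm1, jp1 = neighbor(j, -1), neighbor(j, 1)
            parallel = (hb(im1, j) and hb(j, ip1)) or (hb(jm1, i) and hb(i, jp1))
            antiparallel = (hb(i, j) and hb(j, i)) or (hb(im1, jp1) and hb(jm1, ip1))
            if parallel:
                bridges[(i, j)] = "P"
            elif antiparallel:
                bridges[(i, j)] = "A"

    # ladders: bridges (i,j)&(i+1,j+1) (parallel sense) or (i,j)&(i+1,j-1)
    # (antiparallel sense) extend each other
    in_ladder: set[int] = set()
    bridge_set = set(bridges)
    for (i, j), kind in bridges.items():
        ext = ((i + 1, j + 1) in bridge_set) or ((i - 1, j - 1) in bridge_set) \
            if kind == "P" else \
            ((i + 1, j - 1) in bridge_set or (j - 1, i + 1) in bridge_set
             or (i - 1, j + 1) in bridge_set or (j + 1, i - 1) in bridge_set)
        if ext:
            in_ladder.update((i, j))
    for (i, j) in bridges:
        for k in (i, j):
            if ss[k] == "-":
                ss[k] = "E" if k in in_ladder else "B"

    # --- 4-turn helices (priority over strand) ---
    turn4 = np.zeros(n, dtype=bool)
    for i in range(n):
        j = i + 4
        if j < n and same_chain(i, j) and pos_in_chain[j] == pos_in_chain[i] + 4:
            if hbond[i, j]:
                turn4[i] = True
    for i in range(1, n):
        if turn4[i - 1] and turn4[i]:
            for k in range(i, min(i + 4, n)):
                ss[k] = "H"

    chains = {}
    for chain_id in structure.chains:
        lo, hi = chain_slices[chain_id]
        chains[chain_id] = "".join(ss[lo:hi])
    return SsAssignment(chains)


# ---------------------------------------------------------------------------
# mapping chains onto the family alignment
# ---------------------------------------------------------------------------

@dataclass
class ChainMapping:
    chain_id: str
    best_match_id: str
    identity: float                     # matches / aligned residue pairs
    col_of_res: dict[int, int]          # complete-residue index -> alignment column


class UnmappableChainError(ValueError):
    pass


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    # free end gaps: chains are usually fragments of the family sequences
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:      # older biopython naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    aligner.mode = "global"
    return aligner


def map_structure_to_alignment(chain_sequence: str, alignment: Alignment,
                               min_identity: float = DEFAULT_MIN_IDENTITY,
                               chain_id: str = "") -> ChainMapping:
    """Map a chain sequence onto alignment columns via its best-matching
    family member (global alignment, affine gaps, BLOSUM62, free end gaps).

    Raises :class:`UnmappableChainError` when the best identity over aligned
    pairs falls below ``min_identity``.
    """
    if len(chain_sequence) < 30:
        raise UnmappableChainError(
            f"chain sequence too short to map ({len(chain_sequence)} < 30)"
        )
    aligner = _make_aligner()
    clean = "".join(c if c in "ACDEFGHIKLMNPQRSTVWYBZX" else "X" for c in chain_sequence)
    best = None
    for rec in alignment.records:
        target = rec.ungapped
        aln = aligner.align(target, clean)[0]
        pairs = []
        matches = 0
        for (t0, t1), (q0, q1) in zip(*aln.aligned):
            for k in range(t1 - t0):
                pairs.append((t0 + k, q0 + k))
                if target[t0 + k] == clean[q0 + k]:
                    matches += 1
        if not pairs:
            continue
        identity = matches / len(pairs)
        if best is None or identity > best[0]:
            best = (identity, rec, pairs)
    if best is None or best[0] < min_identity:
        got = 0.0 if best is None else best[0]
        raise UnmappableChainError(
            f"best family identity {got:.2f} below threshold {min_identity:.2f}"
        )
    identity, rec, pairs = best
    # compose through the family member's alignment columns
    cols_of_seq_pos = [c for c, ch in enumerate(rec.seq) if ch != "-"]
    col_of_res = {q: cols_of_seq_pos[t] for t, q in pairs}
    return ChainMapping(chain_id=chain_id, best_match_id=rec.id,
                        identity=identity, col_of_res=col_of_res)


def window_columns(alignment: Alignment, reference_id: str,
                   window: tuple[int, int] = DEFAULT_WINDOW) -> set[int]:
    """Alignment columns whose reference residue number lies in ``window``
    (inclusive, 1-based reference numbering)."""
    ref_map = reference_numbering(alignment, reference_id)
    lo, hi = window
    return {col for col, num in ref_map.items() if lo <= num <= hi}


# ---------------------------------------------------------------------------
# dimer filter and metrics
# ---------------------------------------------------------------------------

@dataclass
class StrandMetrics:
    structure_id: str
    chain_pair: tuple[str, str]
    strand_length: dict[str, int]       # per chain
    helix_present: dict[str, bool]      # per chain
    window: tuple[int, int]


@dataclass
class ScreenSummary:
    strand_histogram: Counter
    helix_counts: Counter               # True/False counts per structure
    kept: list[str]
    discarded: list[tuple[str, str]]    # (structure id, reason)
    details: pd.DataFrame = field(default_factory=pd.DataFrame)


def dimer_filter(ca_by_chain: dict[str, np.ndarray],
                 mappings: dict[str, ChainMapping],
                 window_cols: set[int],
                 min_contacts: int = DEFAULT_MIN_CONTACTS) -> tuple[bool, str, Optional[tuple[str, str]]]:
    """Keep a structure iff >= 2 chains mapped and some chain pair has at
    least ``min_contacts`` inter-chain CA-CA contacts (<= 8 A) between
    residues mapping inside the interface window.

    Returns (keep, reason, best_chain_pair); reasons are "kept",
    "non-dimeric" and "orientation".
    """
    mapped = [c for c in ca_by_chain if c in mappings]
    if len(mapped) < 2:
        return False, "non-dimeric", None
    best_pair, best_contacts = None, -1
    for a_i in range(len(mapped)):
        for b_i in range(a_i + 1, len(mapped)):
            a, b = mapped[a_i], mapped[b_i]
            idx_a = [i for i, col in mappings[a].col_of_res.items() if col in window_cols]
            idx_b = [i for i, col in mappings[b].col_of_res.items() if col in window_cols]
            if not idx_a or not idx_b:
                continue
            ca_a = ca_by_chain[a][idx_a]
            ca_b = ca_by_chain[b][idx_b]
            d = np.linalg.norm(ca_a[:, None, :] - ca_b[None, :, :], axis=-1)
            contacts = int((d <= CONTACT_CUTOFF).sum())
            if contacts > best_contacts:
                best_contacts, best_pair = contacts, (a, b)
    if best_pair is None or best_contacts < min_contacts:
        return False, "orientation", best_pair
    return True, "kept", best_pair


def _runs(ss: str, code: str) -> list[tuple[int, int]]:
    """Maximal runs of ``code`` as (start, end-exclusive)."""
    runs = []
    start = None
    for i, c in enumerate(ss + "\x00"):
        if c == code and start is None:
            start = i
        elif c != code and start is not None:
            runs.append((start, i))
            start = None
    return runs


def interface_strand_metrics(ss: SsAssignment, mappings: dict[str, ChainMapping],
                             window_cols: set[int],
                             chain_pair: tuple[str, str],
                             structure_id: str = "",
                             window: tuple[int, int] = DEFAULT_WINDOW) -> StrandMetrics:
    """Per chain: length of the longest E-run with >= 1 residue mapped inside
    the window (0 when none), and presence of an H-run of >= 4 residues
    touching the window."""
    strand_length: dict[str, int] = {}
    helix_present: dict[str, bool] = {}
    for chain in chain_pair:
        mapping = mappings[chain]
        in_window = {i for i, col in mapping.col_of_res.items() if col in window_cols}
        if not in_window:
            logger.warning("%s chain %s: window maps to no residues", structure_id, chain)
            strand_length[chain] = 0
            helix_present[chain] = False
            continue
        chain_ss = ss[chain]
        best = 0
        for start, end in _runs(chain_ss, "E"):
            if any(i in in_window for i in range(start, end)):
                best = max(best, end - start)
        strand_length[chain] = best
        helix = False
        for start, end in _runs(chain_ss, "H"):
            if end - start >= 4 and any(i in in_window for i in range(start, end)):
                helix = True
                break
        helix_present[chain] = helix
    return StrandMetrics(structure_id, chain_pair, strand_length, helix_present, window)


# ---------------------------------------------------------------------------
# batch screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenConfig:
    reference_id: str
    window: tuple[int, int] = DEFAULT_WINDOW
    min_identity: float = DEFAULT_MIN_IDENTITY
    min_contacts: int = DEFAULT_MIN_CONTACTS


def _structure_inputs(path: Path) -> tuple[str, dict[str, str], dict[str, np.ndarray], Optional[SsAssignment]]:
    """Load one input file; returns (id, chain sequences, CA coords, SS or None).

    PDB files get their secondary structure assigned from coordinates; DSSP
    files carry the assignment (collapsed to {H,E,B,-}) and CA coordinates.
    """
    kind = sniff_structure_format(path)
    if kind == "pdb":
        st = read_pdb_backbone(path)
        ss = assign_secondary_structure(st)
        seqs = {c: st.chain_sequence(c) for c in st.chains}
        cas = {c: np.array([r.atoms["CA"] for r in st.complete_residues(c)])
               for c in st.chains}
        return st.id, seqs, cas, ss
    records = read_dssp_file(path)
    chains: dict[str, list[DsspRecord]] = {}
    for rec in records:
        chains.setdefault(rec.chain_id, []).append(rec)
    seqs = {c: "".join(r.amino_acid for r in rs) for c, rs in chains.items()}
    collapse = {"H": "H", "E": "E", "B": "B"}
    ss = SsAssignment({c: "".join(collapse.get(r.ss, "-") for r in rs)
                       for c, rs in chains.items()})
    cas = {}
    for c, rs in chains.items():
        if any(r.ca is None for r in rs):
            raise FormatError(f"{path}: DSSP file lacks CA coordinates")
        cas[c] = np.array([r.ca for r in rs])
    return Path(path).stem, seqs, cas, ss


def screen_structures(paths: Sequence[str | Path], alignment: Alignment,
                      config: ScreenConfig) -> ScreenSummary:
    """Run the census over a batch of PDB and/or DSSP files."""
    if not paths:
        raise ValueError("no input files")
    win_cols = window_columns(alignment, config.reference_id, config.window)
    hist: Counter = Counter()
    helix_counts: Counter = Counter()
    kept: list[str] = []
    discarded: list[tuple[str, str]] = []
    detail_rows = []
    for path in paths:
        path = Path(path)
        try:
            sid, seqs, cas, ss = _structure_inputs(path)
        except (FormatError, OSError) as exc:
            logger.warning("skipping %s: %s", path, exc)
            discarded.append((path.stem, f"unreadable: {exc}"))
            continue
        mappings: dict[str, ChainMapping] = {}
        for chain, seq in seqs.items():
            try:
                mappings[chain] = map_structure_to_alignment(
                    seq, alignment, config.min_identity, chain_id=chain
                )
            except UnmappableChainError as exc:
                logger.info("%s chain %s unmappable: %s", sid, chain, exc)
        keep, reason, pair = dimer_filter(cas, mappings, win_cols, config.min_contacts)
        if not keep:
            discarded.append((sid, reason))
            continue
        metrics = interface_strand_metrics(ss, mappings, win_cols, pair,
                                           structure_id=sid, window=config.window)
        # per-structure aggregation: the maximum-length chain
        structure_len = max(metrics.strand_length.values())
        structure_helix = any(metrics.helix_present.values())
        hist[structure_len] += 1
        helix_counts[structure_helix] += 1
        kept.append(sid)
        for chain in pair:
            detail_rows.append({
                "structure": sid,
                "chain": chain,
                "mapped_to": mappings[chain].best_match_id,
                "identity": mappings[chain].identity,
                "strand_length": metrics.strand_length[chain],
                "helix_present": metrics.helix_present[chain],
            })
    return ScreenSummary(
        strand_histogram=hist,
        helix_counts=helix_counts,
        kept=kept,
        discarded=discarded,
        details=pd.DataFrame(detail_rows),
    )
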