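"""Readers and writers for the plain-text formats every pipeline stage consumes.

Three families of input are handled here:

* aligned FASTA plus an optional two-column TSV mapping sequence id to class
  label (class labels may alternatively be pulled out of the FASTA header with
  a regular expression);
* backbone coordinates (N, CA, C, O) from PDB files, parsed with gemmi and
  reduced to a light-weight :class:`BackboneStructure`;
* classic-format DSSP output files, including the CA coordinate columns that
  the structure screen needs for its dimer contact filter.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

#: the twenty standard amino acids; everything else (gaps, X, B, Z, ...) is
#: treated as missing data wherever per-column rates are computed.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
STANDARD_AA_SET = frozenset(STANDARD_AA)

GAP = "-"

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

DSSP_CODES = frozenset("HBEGITS ")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """One (possibly aligned) protein sequence with an optional class label."""

    id: str
    seq: str
    class_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        self.seq = self.seq.upper()

    @property
    def ungapped(self) -> str:
        return self.seq.replace(GAP, "")


class Alignment:
    """An ordered collection of equal-length sequence records.

    The class keeps a cached byte matrix (``n_records x n_columns``) because
    the signature scan and the identity statistics are both column-wise
    counting problems that vectorize well over it.
    """

    def __init__(self, records: Sequence[SequenceRecord]):
        records = list(records)
        if not records:
            raise FormatError("alignment with no records")
        n_columns = len(records[0].seq)
        if n_columns == 0:
            raise FormatError("alignment with zero columns")
        seen: set[str] = set()
        for rec in records:
            if rec.id in seen:
                raise FormatError(f"duplicate sequence id: {rec.id!r}")
            seen.add(rec.id)
            if len(rec.seq) != n_columns:
                raise FormatError(
                    f"length mismatch: record {rec.id!r} has {len(rec.seq)} "
                    f"columns, expected {n_columns}"
                )
        self.records = records
        self.n_columns = n_columns
        self._matrix: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def class_labels(self) -> set[str]:
        return {r.class_label for r in self.records if r.class_label is not None}

    def record(self, seq_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == seq_id:
                return rec
        raise KeyError(f"no record with id {seq_id!r}")

    def matrix(self) -> np.ndarray:
        """Byte matrix of shape (n_records, n_columns), dtype ``|S1``."""
        if self._matrix is None:
            self._matrix = np.array(
                [np.frombuffer(r.seq.encode("ascii"), dtype="S1") for r in self.records]
            )
        return self._matrix

    def subset(self, indices: Iterable[int]) -> "Alignment":
        return Alignment([self.records[i] for i in indices])

    def take_columns(self, columns: Sequence[int]) -> "Alignment":
        cols = list(columns)
        out = []
        for rec in self.records:
            out.append(
                SequenceRecord(rec.id, "".join(rec.seq[c] for c in cols), rec.class_label)
            )
        return Alignment(out)

    def require_class_labels(self) -> None:
        missing = [r.id for r in self.records if r.class_label is None]
        if missing:
            raise FormatError(
                f"class labels required but missing for: {', '.join(missing[:5])}"
                + ("..." if len(missing) > 5 else "")
            )


def read_class_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (id, label) TSV; '#' lines are comments."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: expected two columns, got {line!r}")
        mapping[parts[0]] = parts[1]
    return mapping


def read_fasta_alignment(
    path: str | Path,
    class_map: Optional[str | Path | dict] = None,
    label_regex: Optional[str] = None,
    require_labels: bool = False,
) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Class labels come from ``class_map`` (a TSV path or an id->label dict) or,
    failing that, from ``label_regex`` applied to the full FASTA description
    (first capture group is the label).  On conflict the TSV map wins.
    """
    mapping: dict[str, str] = {}
    if class_map is not None:
        mapping = class_map if isinstance(class_map, dict) else read_class_map(class_map)
    pattern = re.compile(label_regex) if label_regex else None

    records: list[SequenceRecord] = []
    for bio in SeqIO.parse(str(path), "fasta"):
        label = mapping.get(bio.id)
        if label is None and pattern is not None:
            m = pattern.search(bio.description)
            if m:
                label = m.group(1)
        records.append(SequenceRecord(bio.id, str(bio.seq), label))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    aln = Alignment(records)
    if class_map is not None or require_labels:
        uncovered = [r.id for r in records if r.class_label is None]
        if uncovered:
            raise FormatError(
                f"class map does not cover: {', '.join(uncovered[:5])}"
                + ("..." if len(uncovered) > 5 else "")
            )
    return aln


def write_fasta(alignment: Alignment | Sequence[SequenceRecord], path: str | Path) -> None:
    records = alignment.records if isinstance(alignment, Alignment) else list(alignment)
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta-2line")


def write_class_map(alignment: Alignment, path: str | Path) -> None:
    lines = [f"{r.id}\t{r.class_label}" for r in alignment.records if r.class_label]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# backbone structures
# ---------------------------------------------------------------------------

@dataclass
class BackboneResidue:
    """One residue's backbone atoms (coordinates in Angstrom)."""

    name: str                       # 3-letter residue name
    number: int                     # author residue number
    icode: str = ""                 # insertion code, "" if none
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    BACKBONE = ("N", "CA", "C", "O")

    @property
    def complete(self) -> bool:
        return all(a in self.atoms for a in self.BACKBONE)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")


class BackboneStructure:
    """Chains of backbone residues, ordered by (residue number, insertion code)."""

    def __init__(self, chains: dict[str, list[BackboneResidue]], id: str = ""):
        self.id = id
        self.chains = chains

    def complete_residues(self, chain_id: str) -> list[BackboneResidue]:
        """Residues usable for secondary-structure assignment."""
        return [r for r in self.chains[chain_id] if r.complete]

    def chain_sequence(self, chain_id: str) -> str:
        return "".join(r.one_letter for r in self.complete_residues(chain_id))


def read_pdb_backbone(path: str | Path) -> BackboneStructure:
    """Parse backbone N/CA/C/O coordinates from a PDB file (MODEL 1 only).

    Alternate locations are resolved per atom to the highest occupancy, ties
    broken alphabetically by altloc id.  Residues missing any of the four
    backbone atoms are retained but flagged incomplete (``complete`` False).
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"no ATOM records (no model) in {path}")
    model = st[0]
    chains: dict[str, list[BackboneResidue]] = {}
    n_atoms = 0
    for chain in model:
        residues: list[BackboneResidue] = []
        for res in chain:
            icode = res.seqid.icode.strip()
            out = BackboneResidue(name=res.name, number=res.seqid.num, icode=icode)
            best: dict[str, tuple[float, str, np.ndarray]] = {}
            for atom in res:
                if atom.name not in BackboneResidue.BACKBONE and atom.name != "H":
                    continue
                n_atoms += 1
                key = (-(atom.occ), atom.altloc or "")
                prev = best.get(atom.name)
                if prev is None or key < prev[0:2]:
                    pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                    best[atom.name] = (key[0], key[1], pos)
            out.atoms = {name: v[2] for name, v in best.items()}
            if out.atoms:
                residues.append(out)
        if residues:
            residues.sort(key=lambda r: (r.number, r.icode))
            chains[chain.name] = residues
    if not chains or n_atoms == 0:
        raise FormatError(f"no backbone ATOM records in {path}")
    return BackboneStructure(chains, id=path.stem)


def write_pdb_backbone(structure: BackboneStructure, path: str | Path) -> None:
    """Write backbone atoms as a minimal single-model PDB file."""
    lines: list[str] = []
    serial = 1
    for chain_id, residues in structure.chains.items():
        for res in residues:
            for name in ("N", "CA", "C", "O", "H"):
                if name not in res.atoms:
                    continue
                x, y, z = res.atoms[name]
                element = name[0]
                lines.append(
                    f"ATOM  {serial:5d} {name:^4s}{res.name:>4s} {chain_id}"
                    f"{res.number:4d}{res.icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {element:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}      {residues[-1].name:>3s} {chain_id}"
                     f"{residues[-1].number:4d}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# DSSP files
# ---------------------------------------------------------------------------

@dataclass
class DsspRecord:
    chain_id: str
    number: int
    amino_acid: str
    ss: str                         # one of DSSP_CODES, blank mapped to '-'
    ca: Optional[np.ndarray] = None


_DSSP_HEADER = re.compile(r"^\s*#\s+RESIDUE\s+AA\s+STRUCTURE")


def read_dssp_file(path: str | Path) -> list[DsspRecord]:
    """Parse a classic-format DSSP output file.

    Chain-break rows ('!') are skipped.  The blank secondary-structure code is
    mapped to '-' (coil).  CA coordinates are read when the X-CA/Y-CA/Z-CA
    columns are present.
    """
    lines = Path(path).read_text().splitlines()
    start = None
    for i, line in enumerate(lines):
        if _DSSP_HEADER.match(line):
            start = i + 1
            break
    if start is None:
        raise FormatError(f"{path}: DSSP data header ('#  RESIDUE AA STRUCTURE') not found")
    records: list[DsspRecord] = []
    for line in lines[start:]:
        if len(line) < 17:
            continue
        aa = line[13]
        if aa == "!":                     # chain break
            continue
        try:
            number = int(line[5:11].split()[0])
        except (ValueError, IndexError):
            continue
        chain_id = line[11].strip() or "A"
        ss = line[16]
        if ss == " ":
            ss = "-"
        elif ss not in DSSP_CODES:
            raise FormatError(f"{path}: unexpected secondary-structure code {ss!r}")
        ca = None
        if len(line) >= 118:
            try:
                ca = np.array([float(line[115:122]), float(line[122:129]),
                               float(line[129:136])])
            except ValueError:
                ca = None
        records.append(DsspRecord(chain_id, number, aa.upper(), ss, ca))
    if not records:
        warnings.warn(f"{path}: DSSP file has an empty data section")
    return records


def write_dssp_file(records: Sequence[DsspRecord], path: str | Path,
                    title: str = "famsig synthetic assignment") -> None:
    """Write records in classic DSSP layout (enough columns for re-parsing).

    Only the columns the screen consumes (residue number, chain, amino acid,
    summary structure code, CA coordinates) carry information; accessibility
    and energy columns are zero-filled.
    """
    lines = [
        "==== Secondary Structure Definition, synthetic file ====",
        f"REFERENCE  {title}",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    "
        "N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA",
    ]
    idx = 1
    prev_chain = None
    for rec in records:
        if prev_chain is not None and rec.chain_id != prev_chain:
            lines.append(f"{idx:5d}        !              0   0    0"
                         + " " * 78)
            idx += 1
        prev_chain = rec.chain_id
        ss = " " if rec.ss == "-" else rec.ss
        ca = rec.ca if rec.ca is not None else np.zeros(3)
        body = (f"{idx:5d}{rec.number:6d}{rec.chain_id} {rec.amino_acid}"
                f"  {ss}" + " " * 14 + "0   0    0")
        pad = 115 - len(body)
        body += " " * max(pad, 1)
        body = body[:115]
        body += f"{ca[0]:7.1f}{ca[1]:7.1f}{ca[2]:7.1f}"
        lines.append(body)
        idx += 1
    Path(path).write_text("\n".join(lines) + "\n")


def sniff_structure_format(path: str | Path) -> str:
    """Return 'dssp' or 'pdb' by inspecting file content."""
    head = Path(path).read_text()[:4000]
    if "Secondary Structure Definition" in head or _DSSP_HEADER.search(head):
        return "dssp"
    return "pdb"
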