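"""Shared domain types and readers/writers for the formats the pipeline touches.

Sequences travel as :class:`ProteinRecord`, structures as :class:`ParsedStructure`
(author residue numbering, single conformer), alignments as
:class:`PairwiseAlignment` / :class:`MSA`.  All tabular outputs are tab-delimited
UTF-8 with LF line endings.  The gap character everywhere is ``'-'``; internal
column indices are 0-based while user-facing reports are 1-based.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.Data.PDBData import protein_letters_3to1

logger = logging.getLogger("asclust")

#: the 20 standard one-letter residue codes
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
#: unknown-residue symbol
UNKNOWN = "X"
#: gap character used in every alignment and site string
GAP = "-"
#: full symbol set of site strings and the distance matrix
SITE_ALPHABET = AA_ALPHABET + GAP  # X handled by rule in scoring

_VALID_CHARS = frozenset(AA_ALPHABET + UNKNOWN)


@dataclass(frozen=True)
class ProteinRecord:
    """One family member: unique id plus an ungapped protein sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("ProteinRecord id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"sequence of {self.id!r} is empty")
        bad = set(self.sequence) - _VALID_CHARS
        if bad:
            raise ValueError(
                f"sequence of {self.id!r} contains invalid characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class Atom:
    name: str
    x: float
    y: float
    z: float
    element: str

    @property
    def coord(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass(frozen=True)
class Residue:
    chain: str
    number: int
    icode: str
    name: str  # 3-letter code as found in the file
    atoms: tuple[Atom, ...]

    @property
    def key(self) -> tuple[str, int, str]:
        """Author-numbering identity key ``(chain, residue_number, insertion_code)``."""
        return (self.chain, self.number, self.icode)

    @property
    def one_letter(self) -> str:
        return protein_letters_3to1.get(self.name, UNKNOWN)


@dataclass
class ParsedStructure:
    """A single-conformer view of a PDB file in author numbering.

    ``residues`` holds polymer (ATOM) residues in file order; ``het_groups``
    holds non-polymer HETATM components with water excluded.
    """

    id: str
    chains: list[str]
    residues: list[Residue]
    het_groups: list[Residue]

    def residue_map(self) -> dict[tuple[str, int, str], Residue]:
        return {r.key: r for r in self.residues}

    def chain_sequence(self, chain: str) -> str:
        """One-letter polymer sequence of one chain, non-standard residues as X."""
        return "".join(r.one_letter for r in self.residues if r.chain == chain)


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two gapped rows of equal length; reference first, target second."""

    ref_id: str
    target_id: str
    ref_row: str
    target_row: str

    def __post_init__(self) -> None:
        if len(self.ref_row) != len(self.target_row):
            raise ValueError(
                f"alignment rows for {self.ref_id!r}/{self.target_id!r} "
                f"have unequal lengths ({len(self.ref_row)} vs {len(self.target_row)})"
            )

    @property
    def ref_sequence(self) -> str:
        return self.ref_row.replace(GAP, "")

    @property
    def target_sequence(self) -> str:
        return self.target_row.replace(GAP, "")


@dataclass
class MSA:
    """A multiple sequence alignment: (id, gapped row) pairs, rows equal length."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("MSA has no records")
        lengths = {len(row) for _, row in self.records}
        if len(lengths) != 1:
            raise ValueError(f"MSA rows have unequal lengths: {sorted(lengths)}")
        ids = [rid for rid, _ in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate MSA ids: {dup}")

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def row(self, rid: str) -> str:
        for r, row in self.records:
            if r == rid:
                return row
        raise KeyError(f"id {rid!r} not in MSA")


@dataclass(frozen=True)
class Discard:
    """A member removed from the analysis, with the reason."""

    member_id: str
    reason: str


# ---------------------------------------------------------------------------
# FASTA


def _clean_sequence(rid: str, raw: str) -> str:
    seq = raw.upper()
    replaced = sorted(set(seq) - _VALID_CHARS)
    if replaced:
        logger.warning(
            "sequence %s: replacing non-standard characters %s with %s",
            rid, "".join(replaced), UNKNOWN,
        )
        seq = "".join(c if c in _VALID_CHARS else UNKNOWN for c in seq)
    return seq


def read_fasta(path: str | os.PathLike) -> list[ProteinRecord]:
    """Read ungapped protein sequences; characters outside the 20+X alphabet
    are replaced by X with a logged warning."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, _clean_sequence(rec.id, str(rec.seq))))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_msa(path: str | os.PathLike) -> MSA:
    """Read an aligned FASTA into an MSA (gaps kept, sequences uppercased)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        row = str(rec.seq).upper()
        row = "".join(
            c if (c in _VALID_CHARS or c == GAP) else UNKNOWN for c in row
        )
        records.append((rec.id, row))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return MSA(records)


def write_msa(msa: MSA, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rid, row in msa.records:
            fh.write(f">{rid}\n{row}\n")


def read_pairwise_alignment_fasta(path: str | os.PathLike) -> PairwiseAlignment:
    """Read an aligned-FASTA pair (reference first, target second), e.g. the
    sequence output of a structural superposition tool.

    Columns that are gap in both rows are removed.
    """
    recs = list(SeqIO.parse(str(path), "fasta"))
    if len(recs) != 2:
        raise ValueError(
            f"{path}: expected exactly 2 aligned records, found {len(recs)}"
        )
    ref, tgt = recs
    ref_row, tgt_row = str(ref.seq).upper(), str(tgt.seq).upper()
    if len(ref_row) != len(tgt_row):
        raise ValueError(
            f"{path}: aligned rows have unequal lengths "
            f"({len(ref_row)} vs {len(tgt_row)})"
        )
    kept = [
        (a, b) for a, b in zip(ref_row, tgt_row) if not (a == GAP and b == GAP)
    ]
    ref_row = "".join(a for a, _ in kept)
    tgt_row = "".join(b for _, b in kept)
    return PairwiseAlignment(ref.id, tgt.id, ref_row, tgt_row)


def write_pairwise_alignment_fasta(
    aln: PairwiseAlignment, path: str | os.PathLike
) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f">{aln.ref_id}\n{aln.ref_row}\n>{aln.target_id}\n{aln.target_row}\n")


# ---------------------------------------------------------------------------
# PDB


def read_pdb(path: str | os.PathLike, structure_id: str | None = None) -> ParsedStructure:
    """Parse a PDB file into a single-conformer :class:`ParsedStructure`.

    Only the first model is read.  For alternate locations, the blank or 'A'
    conformer is kept.  HETATM components are collected in ``het_groups`` with
    water (HOH) excluded.
    """
    sid = structure_id or os.path.splitext(os.path.basename(str(path)))[0]
    parser = PDBParser(QUIET=True)
    bio = parser.get_structure(sid, str(path))
    try:
        model = next(bio.get_models())
    except StopIteration:
        raise ValueError(f"{path}: no polymer ATOM records found") from None

    residues: list[Residue] = []
    het_groups: list[Residue] = []
    chains: list[str] = []
    for chain in model:
        if chain.id not in chains:
            chains.append(chain.id)
        for res in chain:
            hetflag, resseq, icode = res.id
            atoms: list[Atom] = []
            for atom in res.get_unpacked_list():
                if atom.get_altloc() not in (" ", "A"):
                    continue
                x, y, z = (float(v) for v in atom.coord)
                atoms.append(Atom(atom.get_name(), x, y, z, atom.element or ""))
            if not atoms:
                continue
            parsed = Residue(
                chain.id, int(resseq), icode.strip(), res.get_resname().strip(),
                tuple(atoms),
            )
            if hetflag == " ":
                residues.append(parsed)
            elif hetflag == "W" or parsed.name == "HOH":
                continue
            else:
                het_groups.append(parsed)
    if not residues:
        raise ValueError(f"{path}: no polymer ATOM records found")
    return ParsedStructure(sid, chains, residues, het_groups)


def write_pdb(structure: ParsedStructure, path: str | os.PathLike) -> None:
    """Write a structure back out as fixed-width ATOM/HETATM records."""
    serial = 0
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for record, residues in (("ATOM", structure.residues),
                                 ("HETATM", structure.het_groups)):
            for res in residues:
                for atom in res.atoms:
                    serial += 1
                    name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                    fh.write(
                        f"{record:<6s}{serial:>5d} {name:<4s} {res.name:>3s} "
                        f"{res.chain:1s}{res.number:>4d}{res.icode or ' ':1s}   "
                        f"{atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}"
                        f"{1.00:6.2f}{0.00:6.2f}          "
                        f"{atom.element:>2s}\n"
                    )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Tabular outputs

GROUPS_HEADER = ("member_id", "site", "cluster", "reference_id")


def write_groups_tsv(rows: Sequence[tuple[str, str, int, str]],
                     path: str | os.PathLike) -> None:
    """Write the per-member groups table: id, active-site string, cluster label
    (0 = unclustered), reference id."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(GROUPS_HEADER) + "\n")
        for member_id, site, label, ref_id in rows:
            fh.write(f"{member_id}\t{site}\t{label}\t{ref_id}\n")


def read_groups_tsv(path: str | os.PathLike) -> list[tuple[str, str, int, str]]:
    rows: list[tuple[str, str, int, str]] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != GROUPS_HEADER:
            raise ValueError(f"{path}: unexpected groups header {header}")
        for line in fh:
            if not line.strip():
                continue
            member_id, site, label, ref_id = line.rstrip("\n").split("\t")
            rows.append((member_id, site, int(label), ref_id))
    return rows


def write_cluster_fastas(
    rows: Sequence[tuple[str, str, int, str]],
    sequences: dict[str, str],
    out_dir: str | os.PathLike,
) -> list[str]:
    """Write one FASTA of full member sequences per cluster label.

    Unclustered members (label 0) go to ``unclustered.fasta``.  Returns the
    paths written.
    """
    os.makedirs(out_dir, exist_ok=True)
    by_label: dict[int, list[str]] = {}
    for member_id, _, label, _ in rows:
        by_label.setdefault(label, []).append(member_id)
    paths = []
    for label in sorted(by_label):
        name = "unclustered.fasta" if label == 0 else f"cluster_{label}.fasta"
        path = os.path.join(str(out_dir), name)
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for member_id in by_label[label]:
                if member_id in sequences:
                    fh.write(f">{member_id}\n{sequences[member_id]}\n")
        paths.append(path)
    return paths


def write_discard_log(discards: Sequence[Discard], path: str | os.PathLike) -> None:
    """One line per discarded member: id TAB reason."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for d in discards:
            fh.write(f"{d.member_id}\t{d.reason}\n")
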