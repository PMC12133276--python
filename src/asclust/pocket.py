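"""Reference active-site pocket definition.

Three sources are supported: a P2RANK predictions CSV (machine-learned
ligandability scores, parsed here, never recomputed), geometric ligand
proximity in a holo structure, or an explicit user residue list.  A pocket is
an ordered set of author-numbered residue positions on one reference
structure; ordering is always (chain, residue_number, insertion_code)
ascending so that downstream site strings are comparable across runs.
"""

from __future__ import annotations

import csv
import logging
import os
import re
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .io_core import ParsedStructure, Residue

logger = logging.getLogger("asclust")

#: default heavy-atom ligand-contact cutoff, Angstrom (first-shell contacts)
DEFAULT_CONTACT_CUTOFF = 4.5

_TOKEN_RE = re.compile(r"^(?P<chain>[A-Za-z0-9])_(?P<num>-?\d+)(?P<icode>[A-Za-z]?)$")


@dataclass(frozen=True)
class PocketCandidate:
    """One predicted pocket: a name, a ligandability score and its residues."""

    name: str
    score: float
    residues: tuple[tuple[str, int, str], ...]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"pocket {self.name!r} has no residues")
        if not np.isfinite(self.score) or self.score < 0:
            raise ValueError(f"pocket {self.name!r} has invalid score {self.score}")


@dataclass(frozen=True)
class PocketDefinition:
    """The reference pocket: ordered unique positions with residue names."""

    reference_id: str
    positions: tuple[tuple[str, int, str, str], ...]  # chain, number, icode, aa
    source: str  # p2rank | ligand_proximity | user

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError("pocket has no positions")
        keys = [(c, n, i) for c, n, i, _ in self.positions]
        if len(keys) != len(set(keys)):
            raise ValueError("pocket positions are not unique")
        if keys != sorted(keys):
            raise ValueError("pocket positions are not in ascending order")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def keys(self) -> list[tuple[str, int, str]]:
        return [(c, n, i) for c, n, i, _ in self.positions]


def _ordered_positions(
    keys: set[tuple[str, int, str]], structure: ParsedStructure
) -> tuple[tuple[str, int, str, str], ...]:
    rmap = structure.residue_map()
    out = []
    for key in sorted(keys):
        if key not in rmap:
            chain, num, icode = key
            raise ValueError(
                f"residue {chain}_{num}{icode} not found in structure {structure.id}"
            )
        out.append((*key, rmap[key].one_letter))
    return tuple(out)


def parse_residue_token(token: str) -> tuple[str, int, str]:
    """Parse a ``chain_number[icode]`` token, e.g. ``A_52`` or ``A_52B``."""
    m = _TOKEN_RE.match(token.strip())
    if not m:
        raise ValueError(f"cannot parse residue token {token!r} (expected CHAIN_NUM)")
    return (m.group("chain"), int(m.group("num")), m.group("icode"))


# ---------------------------------------------------------------------------
# P2RANK predictions


def parse_p2rank_predictions(
    csv_path: str | os.PathLike, structure: ParsedStructure
) -> list[PocketCandidate]:
    """Parse a P2RANK per-pocket predictions CSV against a reference structure.

    Expects a header row with (case-insensitively, spaces stripped) a ``name``
    column, a ``score`` column and a ``residue_ids`` column of space-separated
    ``chain_number`` tokens.  Candidates are returned sorted by score
    descending; ties keep file order.
    """
    with open(csv_path, encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{csv_path}: empty predictions file")
        cols = {h.strip().lower(): k for k, h in enumerate(header)}
        for needed in ("name", "score", "residue_ids"):
            if needed not in cols:
                raise ValueError(f"{csv_path}: missing column {needed!r}")
        rmap = structure.residue_map()
        candidates: list[PocketCandidate] = []
        for row in reader:
            if not row or not "".join(row).strip():
                continue
            name = row[cols["name"]].strip()
            score = float(row[cols["score"]].strip())
            tokens = row[cols["residue_ids"]].split()
            keys = []
            for tok in tokens:
                key = parse_residue_token(tok)
                if key not in rmap:
                    chain, num, icode = key
                    raise ValueError(
                        f"{csv_path}: pocket {name!r} references residue "
                        f"{chain}_{num}{icode} absent from structure {structure.id}"
                    )
                keys.append(key)
            candidates.append(PocketCandidate(name, score, tuple(keys)))
    if not candidates:
        raise ValueError(f"{csv_path}: no pocket rows found")
    # stable sort preserves file order among equal scores
    candidates.sort(key=lambda c: -c.score)
    return candidates


def select_pocket(
    candidates: list[PocketCandidate], rank: int | None = None
) -> PocketCandidate:
    """Select the highest-score candidate, or the rank-th best (1-based)."""
    if not candidates:
        raise ValueError("no pocket candidates to select from")
    ordered = sorted(candidates, key=lambda c: -c.score)
    if rank is None:
        return ordered[0]
    if not 1 <= rank <= len(ordered):
        raise ValueError(
            f"pocket rank {rank} out of range 1..{len(ordered)}"
        )
    return ordered[rank - 1]


def candidate_to_definition(
    candidate: PocketCandidate, structure: ParsedStructure, source: str = "p2rank"
) -> PocketDefinition:
    return PocketDefinition(
        structure.id, _ordered_positions(set(candidate.residues), structure), source
    )


# ---------------------------------------------------------------------------
# Ligand proximity


def _heavy_coords(res: Residue) -> np.ndarray:
    pts = [a.coord for a in res.atoms if not a.is_hydrogen]
    return np.asarray(pts, dtype=float).reshape(-1, 3)


def detect_pocket_by_ligand(
    structure: ParsedStructure,
    ligand_name: str | None = None,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> PocketDefinition:
    """Define the pocket as every polymer residue with a heavy atom within
    ``cutoff`` angstrom of any heavy ligand atom.

    Requires a holo structure.  If ``ligand_name`` is not given, the HET
    component with the most atoms is used.
    """
    if not structure.het_groups:
        raise ValueError(
            f"structure {structure.id} has no ligand (HET) component; "
            "supply the pocket residues explicitly"
        )
    if ligand_name is not None:
        ligands = [h for h in structure.het_groups if h.name == ligand_name]
        if not ligands:
            raise ValueError(
                f"ligand {ligand_name!r} not found in structure {structure.id}"
            )
        ligand = ligands[0]
    else:
        ligand = max(structure.het_groups, key=lambda h: len(h.atoms))
    lig_xyz = _heavy_coords(ligand)
    if lig_xyz.size == 0:
        raise ValueError(f"ligand {ligand.name!r} has no heavy atoms")

    keys: set[tuple[str, int, str]] = set()
    for res in structure.residues:
        xyz = _heavy_coords(res)
        if xyz.size == 0:
            continue
        if cdist(xyz, lig_xyz).min() <= cutoff:
            keys.add(res.key)
    if not keys:
        raise ValueError(
            f"no residue within {cutoff} A of ligand {ligand.name!r} in "
            f"{structure.id}; supply the pocket residues explicitly"
        )
    logger.info(
        "ligand-proximity pocket on %s: %d residues within %.1f A of %s",
        structure.id, len(keys), cutoff, ligand.name,
    )
    return PocketDefinition(
        structure.id, _ordered_positions(keys, structure), "ligand_proximity"
    )


# ---------------------------------------------------------------------------
# User-supplied list


def pocket_from_user_list(
    reference_id: str, entries: list[str], structure: ParsedStructure
) -> PocketDefinition:
    """Build a pocket from user ``chain_number[icode]`` tokens; duplicates are
    collapsed and positions ordered."""
    if not entries:
        raise ValueError("empty pocket residue list")
    keys = {parse_residue_token(tok) for tok in entries}
    return PocketDefinition(reference_id, _ordered_positions(keys, structure), "user")


# ---------------------------------------------------------------------------
# Pocket TSV round-trip

POCKET_HEADER = ("reference_id", "chain", "residue_number", "insertion_code",
                 "residue_name")


def write_pocket_tsv(pocket: PocketDefinition, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(POCKET_HEADER) + "\n")
        for chain, num, icode, aa in pocket.positions:
            fh.write(f"{pocket.reference_id}\t{chain}\t{num}\t{icode}\t{aa}\n")


def read_pocket_tsv(path: str | os.PathLike) -> PocketDefinition:
    positions = []
    reference_id = None
    with open(path, encoding="utf-8") as fh:
        header = tuple(fh.readline().rstrip("\n").split("\t"))
        if header != POCKET_HEADER:
            raise ValueError(f"{path}: unexpected pocket header {header}")
        for line in fh:
            if not line.strip():
                continue
            ref_id, chain, num, icode, aa = line.rstrip("\n").split("\t")
            reference_id = reference_id or ref_id
            positions.append((chain, int(num), icode, aa))
    if not positions:
        raise ValueError(f"{path}: pocket file has no positions")
    return PocketDefinition(reference_id, tuple(positions), "user")
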