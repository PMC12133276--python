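"""Mapping reference pocket positions onto family members.

The 3D route reads one pairwise alignment per target (the sequence view of a
structural superposition); the 2D route reads the pocket off MSA columns.
Both produce one fixed-length active-site string per member — position k of
the string is the target residue aligned to the k-th pocket position, '-'
where the target is gapped there.

Two filters guard the mapping: the sequence-identity gate (default >= 30%
identity to the chosen reference) and the gap-discard rule (sites with more
than half their positions gapped are dropped and logged).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .io_core import (
    GAP,
    MSA,
    Discard,
    PairwiseAlignment,
)
from .pocket import PocketDefinition

logger = logging.getLogger("asclust")

#: minimum percent identity to the reference for a member to be mapped
DEFAULT_IDENTITY_THRESHOLD = 30.0
#: maximum tolerated fraction of gap positions in a site string
DEFAULT_MAX_GAP_FRACTION = 0.5


@dataclass(frozen=True)
class ActiveSiteSequence:
    """A member's active site: one character per pocket position."""

    member_id: str
    site: str
    reference_id: str
    mode: str  # "3d" | "2d"


@dataclass(frozen=True)
class IdentityReport:
    member_id: str
    reference_id: str
    percent_identity: float


def percent_identity(alignment: PairwiseAlignment) -> float:
    """Percent identity over columns where both rows are non-gap.

    Terminal and internal gap columns never enter the denominator, so the
    value is insensitive to how aligners pad sequence ends.  Returns 0.0 when
    no column has both rows non-gap.
    """
    both = matches = 0
    for a, b in zip(alignment.ref_row, alignment.target_row):
        if a != GAP and b != GAP:
            both += 1
            if a == b:
                matches += 1
    return 100.0 * matches / both if both else 0.0


def select_reference(
    target_alignments: list[PairwiseAlignment],
) -> tuple[PairwiseAlignment, IdentityReport]:
    """Among alignments of one target to several references, pick the
    reference with the best percent identity (ties: first in input order)."""
    if not target_alignments:
        raise ValueError("no alignments to select a reference from")
    target_ids = {a.target_id for a in target_alignments}
    if len(target_ids) != 1:
        raise ValueError(f"alignments mix several targets: {sorted(target_ids)}")
    best = max(target_alignments, key=lambda a: percent_identity(a))
    report = IdentityReport(best.target_id, best.ref_id, percent_identity(best))
    return best, report


def apply_identity_gate(
    reports: list[IdentityReport], threshold: float = DEFAULT_IDENTITY_THRESHOLD
) -> tuple[list[IdentityReport], list[Discard]]:
    """Keep members with identity >= threshold; the bound is inclusive."""
    if not 0.0 <= threshold <= 100.0:
        raise ValueError(f"identity threshold {threshold} outside [0, 100]")
    kept, discarded = [], []
    for rep in reports:
        if rep.percent_identity >= threshold:
            kept.append(rep)
        else:
            logger.warning(
                "discarding %s: identity %.1f%% to %s below threshold %.1f%%",
                rep.member_id, rep.percent_identity, rep.reference_id, threshold,
            )
            discarded.append(Discard(rep.member_id, f"identity<{threshold:g}"))
    return kept, discarded


# ---------------------------------------------------------------------------
# Pocket position -> sequence index -> alignment column


def pocket_sequence_indices(pocket: PocketDefinition, ref_sequence: str,
                            structure=None) -> list[int]:
    """0-based indices of the pocket positions within the reference polymer
    sequence.

    When ``structure`` is given, each author-numbered pocket position is
    located by counting polymer residues of its chain in file order; the
    concatenated chain sequences must equal ``ref_sequence``.  Without a
    structure, residue numbers are interpreted as 1-based sequence positions
    on a single implicit chain.
    """
    if structure is not None:
        offset = 0
        index_by_key: dict[tuple[str, int, str], int] = {}
        for chain in structure.chains:
            chain_res = [r for r in structure.residues if r.chain == chain]
            for k, res in enumerate(chain_res):
                index_by_key[res.key] = offset + k
            offset += len(chain_res)
        indices = []
        for key in pocket.keys:
            if key not in index_by_key:
                chain, num, icode = key
                raise ValueError(
                    f"pocket residue {chain}_{num}{icode} not in structure "
                    f"{structure.id}"
                )
            indices.append(index_by_key[key])
    else:
        indices = [num - 1 for _, num, _, _ in pocket.positions]
    for idx in indices:
        if not 0 <= idx < len(ref_sequence):
            raise ValueError(
                f"pocket position index {idx + 1} beyond reference sequence "
                f"length {len(ref_sequence)}"
            )
    return indices


def _columns_of_ref_indices(ref_row: str, indices: list[int]) -> list[int]:
    """Alignment column of each 0-based reference-sequence index."""
    col_of_index = []
    for col, c in enumerate(ref_row):
        if c != GAP:
            col_of_index.append(col)
    cols = []
    for idx in indices:
        if idx >= len(col_of_index):
            raise ValueError(
                f"pocket index {idx + 1} beyond reference row "
                f"({len(col_of_index)} residues)"
            )
        cols.append(col_of_index[idx])
    return cols


def map_pocket_through_alignment(
    alignment: PairwiseAlignment,
    pocket: PocketDefinition,
    ref_sequence: str,
    structure=None,
) -> ActiveSiteSequence:
    """Read the target's residues at the alignment columns of the reference
    pocket positions (3D mode)."""
    if alignment.ref_sequence != ref_sequence:
        raise ValueError(
            f"degapped reference row of alignment {alignment.ref_id!r}/"
            f"{alignment.target_id!r} does not match the reference sequence"
        )
    indices = pocket_sequence_indices(pocket, ref_sequence, structure)
    cols = _columns_of_ref_indices(alignment.ref_row, indices)
    site = "".join(alignment.target_row[c] for c in cols)
    return ActiveSiteSequence(alignment.target_id, site, alignment.ref_id, "3d")


def extract_sites_from_msa(
    msa: MSA,
    reference_id: str,
    pocket: PocketDefinition,
    ref_sequence: str,
    structure=None,
) -> list[ActiveSiteSequence]:
    """Read every non-reference MSA row at the pocket columns (2D mode).

    The reference row must be present and degap to ``ref_sequence``.
    """
    if reference_id not in msa.ids:
        raise ValueError(f"reference id {reference_id!r} absent from MSA")
    ref_row = msa.row(reference_id)
    if ref_row.replace(GAP, "") != ref_sequence:
        raise ValueError(
            f"degapped MSA row of {reference_id!r} does not match the "
            "reference sequence"
        )
    indices = pocket_sequence_indices(pocket, ref_sequence, structure)
    cols = _columns_of_ref_indices(ref_row, indices)
    sites = []
    for rid, row in msa.records:
        if rid == reference_id:
            continue
        site = "".join(row[c] for c in cols)
        sites.append(ActiveSiteSequence(rid, site, reference_id, "2d"))
    return sites


def apply_gap_discard(
    sites: list[ActiveSiteSequence],
    max_gap_fraction: float = DEFAULT_MAX_GAP_FRACTION,
) -> tuple[list[ActiveSiteSequence], list[Discard]]:
    """Drop sites whose gap fraction strictly exceeds ``max_gap_fraction``."""
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError(f"max_gap_fraction {max_gap_fraction} outside [0, 1]")
    kept, discarded = [], []
    for s in sites:
        frac = s.site.count(GAP) / len(s.site) if s.site else 0.0
        if frac > max_gap_fraction:
            logger.warning(
                "discarding %s: gap fraction %.2f exceeds %.2f",
                s.member_id, frac, max_gap_fraction,
            )
            discarded.append(Discard(s.member_id, f"gap_fraction>{max_gap_fraction:g}"))
        else:
            kept.append(s)
    return kept, discarded


# ---------------------------------------------------------------------------
# Fallback global aligner (used only when no alignment files are supplied)


def global_align(
    seq_a: str,
    seq_b: str,
    substitution_table: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    ids: tuple[str, str] = ("ref", "target"),
) -> PairwiseAlignment:
    """Optimal global alignment under affine gaps (a gap of length L costs
    gap_open + (L-1)*gap_extend, subtracted from the substitution score).

    Reference is ``seq_a``; end gaps are penalized.  The trace-back is
    deterministic (the aligner's canonical first alignment).
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(substitution_table)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(seq_a, seq_b)[0]
    ref_row, tgt_row = str(aln[0]), str(aln[1])
    return PairwiseAlignment(ids[0], ids[1], ref_row, tgt_row)


def global_align_score(
    seq_a: str,
    seq_b: str,
    substitution_table: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Optimal global alignment score under the same model as :func:`global_align`."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(substitution_table)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return float(aligner.score(seq_a, seq_b))


# ---------------------------------------------------------------------------
# Sites TSV (re-entry point for re-clustering)

SITES_HEADER = ("member_id", "site", "reference_id", "mode")


def write_sites_tsv(sites: list[ActiveSiteSequence], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(SITES_HEADER) + "\n")
        for s in sites:
            fh.write(f"{s.member_id}\t{s.site}\t{s.reference_id}\t{s.mode}\n")


def read_sites_tsv(path: str | os.PathLike) -> list[ActiveSiteSequence]:
    sites = []
    with open(path, encoding="utf-8") as fh:
        header = tuple(fh.readline().rstrip("\n").split("\t"))
        if header != SITES_HEADER:
            raise ValueError(f"{path}: unexpected sites header {header}")
        for line in fh:
            if not line.strip():
                continue
            member_id, site, ref_id, mode = line.rstrip("\n").split("\t")
            sites.append(ActiveSiteSequence(member_id, site, ref_id, mode))
    if not sites:
        raise ValueError(f"{path}: no sites found")
    return sites
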