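"""Self-contained synthetic fixtures: enzyme families with planted
isofunctional groups, mutually consistent alignments, and toy holo
structures.

The generator emulates the situation the pipeline is built for: a family
whose members fall into groups distinguished by the chemistry of a handful
of active-site positions.  Each group carries a signature of site residues;
discriminative positions place different groups in different physicochemical
classes, while within-group noise substitutes residues only inside their
class, so a chemistry-aware distance sees group mates as near.  Full
sequences embed the (noised) signature at fixed scaffold offsets, and the
MSA and pairwise alignments are constructed column-consistent by design —
no insertions — which makes the 2D and 3D extraction routes provably
comparable on these fixtures.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np

from .io_core import (
    AA_ALPHABET,
    GAP,
    MSA,
    ParsedStructure,
    PairwiseAlignment,
    ProteinRecord,
    Residue,
    Atom,
    write_fasta,
    write_msa,
    write_pairwise_alignment_fasta,
)
from .pocket import PocketDefinition
from .scoring import RESIDUE_CLASSES
from .site_extraction import ActiveSiteSequence

REFERENCE_ID = "REF"

_CLASS_LIST = [sorted(c) for c in RESIDUE_CLASSES]


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one synthetic family.

    ``p_noise`` is the per-site-position probability of a same-class
    substitution; ``p_gap`` the per-site-position probability of a deletion.
    ``seed`` is mandatory — every draw is reproducible.
    """

    seed: int
    n_groups: int = 5
    members_per_group: int = 40
    site_length: int = 12
    full_sequence_length: int = 120
    p_noise: float = 0.05
    p_gap: float = 0.02
    min_cross_class_positions: int = 3
    signatures: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.site_length > self.full_sequence_length:
            raise ValueError("site_length exceeds full_sequence_length")
        if not (0 <= self.p_noise < 1 and 0 <= self.p_gap < 1):
            raise ValueError("rates must lie in [0, 1)")
        if self.signatures is None and self.n_groups > len(RESIDUE_CLASSES):
            raise ValueError(
                f"auto signatures support at most {len(RESIDUE_CLASSES)} groups; "
                "supply signatures explicitly"
            )


@dataclass
class FamilyFixture:
    """Everything one run needs, mutually consistent by construction."""

    spec: FamilySpec
    reference: ProteinRecord
    records: list[ProteinRecord]
    true_labels: dict[str, int]          # member id -> planted group (1-based)
    true_sites: dict[str, str]           # member id -> noised site string
    msa: MSA                             # includes the reference row
    pairwise: list[PairwiseAlignment]    # reference vs each member
    pocket: PocketDefinition             # 1-based sequence positions, chain A
    site_offsets: tuple[int, ...]        # 0-based positions of the site in the scaffold


def _make_signatures(spec: FamilySpec, rng: np.random.Generator,
                     disc_positions: np.ndarray) -> list[str]:
    """One signature per group; at every discriminative position the groups
    sit in pairwise-different physicochemical classes."""
    if spec.signatures is not None:
        if len(spec.signatures) != spec.n_groups:
            raise ValueError("signature count does not match n_groups")
        if any(len(s) != spec.site_length for s in spec.signatures):
            raise ValueError("signature length does not match site_length")
        return list(spec.signatures)
    base = [rng.choice(list(AA_ALPHABET)) for _ in range(spec.site_length)]
    sigs = []
    n_cls = len(_CLASS_LIST)
    for g in range(spec.n_groups):
        sig = list(base)
        for j, pos in enumerate(disc_positions):
            cls = _CLASS_LIST[(g + j) % n_cls]
            sig[pos] = cls[int(rng.integers(len(cls)))]
        sigs.append("".join(sig))
    return sigs


def _same_class_substitute(aa: str, rng: np.random.Generator) -> str:
    for cls in _CLASS_LIST:
        if aa in cls:
            others = [c for c in cls if c != aa]
            if others:
                return others[int(rng.integers(len(others)))]
            return aa
    return aa


def generate_family(spec: FamilySpec) -> FamilyFixture:
    """Generate a family with planted groups and consistent alignments.

    The reference member carries group 1's clean signature; members embed
    their group's signature with same-class noise (rate ``p_noise``) and
    deletions (rate ``p_gap``) restricted to site positions.  With both
    rates zero every extracted site equals its group signature exactly.
    """
    rng = np.random.default_rng(spec.seed)
    L, N = spec.site_length, spec.full_sequence_length

    # evenly spread the site positions through the scaffold
    site_offsets = np.unique(
        np.round(np.linspace(0, N - 1, L)).astype(int)
    )
    if len(site_offsets) != L:
        raise ValueError("full_sequence_length too short to place the site")

    disc = rng.choice(L, size=min(spec.min_cross_class_positions, L),
                      replace=False)
    signatures = _make_signatures(spec, rng, np.sort(disc))

    scaffold = list(rng.choice(list(AA_ALPHABET), size=N))
    is_site = np.zeros(N, dtype=bool)
    is_site[site_offsets] = True

    def full_row(site: str) -> str:
        row = list(scaffold)
        for k, pos in enumerate(site_offsets):
            row[pos] = site[k]
        return "".join(row)

    ref_site = signatures[0]
    ref_row = full_row(ref_site)
    reference = ProteinRecord(REFERENCE_ID, ref_row)

    records: list[ProteinRecord] = []
    true_labels: dict[str, int] = {}
    true_sites: dict[str, str] = {}
    msa_records = [(REFERENCE_ID, ref_row)]
    pairwise: list[PairwiseAlignment] = []

    for g in range(spec.n_groups):
        for m in range(spec.members_per_group):
            member_id = f"G{g + 1}_M{m + 1:03d}"
            site = list(signatures[g])
            for k in range(L):
                if rng.random() < spec.p_noise:
                    site[k] = _same_class_substitute(site[k], rng)
            for k in range(L):
                if rng.random() < spec.p_gap:
                    site[k] = GAP
            site = "".join(site)
            row = full_row(site)
            seq = row.replace(GAP, "")
            records.append(ProteinRecord(member_id, seq))
            true_labels[member_id] = g + 1
            true_sites[member_id] = site
            msa_records.append((member_id, row))
            pairwise.append(
                PairwiseAlignment(REFERENCE_ID, member_id, ref_row, row)
            )

    positions = tuple(
        ("A", int(pos) + 1, "", ref_row[pos]) for pos in site_offsets
    )
    pocket = PocketDefinition(REFERENCE_ID, positions, "user")

    return FamilyFixture(
        spec=spec,
        reference=reference,
        records=records,
        true_labels=true_labels,
        true_sites=true_sites,
        msa=MSA(msa_records),
        pairwise=pairwise,
        pocket=pocket,
        site_offsets=tuple(int(p) for p in site_offsets),
    )


def true_site_sequences(fixture: FamilyFixture,
                        mode: str = "2d") -> list[ActiveSiteSequence]:
    """The planted site strings as ready-made :class:`ActiveSiteSequence`."""
    return [
        ActiveSiteSequence(rid, fixture.true_sites[rid], REFERENCE_ID, mode)
        for rid in (r.id for r in fixture.records)
    ]


def write_fixture(fixture: FamilyFixture, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write the fixture as standard files consumable by the CLI.

    Returns a name -> path map: sequences FASTA, MSA FASTA, one aligned-FASTA
    pair per member under ``alignments/``, and the pocket TSV.
    """
    from .pocket import write_pocket_tsv

    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    aln_dir = os.path.join(out_dir, "alignments")
    os.makedirs(aln_dir, exist_ok=True)
    paths = {
        "sequences": os.path.join(out_dir, "family.fasta"),
        "reference": os.path.join(out_dir, "reference.fasta"),
        "msa": os.path.join(out_dir, "family_msa.fasta"),
        "pocket": os.path.join(out_dir, "pocket.tsv"),
        "alignments": aln_dir,
        "labels": os.path.join(out_dir, "true_labels.tsv"),
    }
    write_fasta(fixture.records, paths["sequences"])
    write_fasta([fixture.reference], paths["reference"])
    write_msa(fixture.msa, paths["msa"])
    write_pocket_tsv(fixture.pocket, paths["pocket"])
    for aln in fixture.pairwise:
        write_pairwise_alignment_fasta(
            aln, os.path.join(aln_dir, f"{aln.target_id}.fasta")
        )
    with open(paths["labels"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("member_id\tgroup\n")
        for rid, g in fixture.true_labels.items():
            fh.write(f"{rid}\t{g}\n")
    return paths


# ---------------------------------------------------------------------------
# Toy structures

HELIX_RISE = 1.5      # Angstrom per residue
HELIX_TWIST = 100.0   # degrees per residue
HELIX_RADIUS = 2.3    # Angstrom

_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}


def generate_toy_structure(
    sequence: str,
    site_residue_indices: list[int],
    ligand_offset: float = 0.0,
    structure_id: str = "toy",
) -> ParsedStructure:
    """Place a sequence on an ideal helix with CA and CB atoms per residue
    and drop one ligand atom at the centroid of the designated site residues'
    CA positions, displaced along x by ``ligand_offset`` angstrom.

    The designated residues are therefore the ones a ligand-proximity pocket
    search should recover at offset 0.
    """
    for idx in site_residue_indices:
        if not 0 <= idx < len(sequence):
            raise ValueError(f"site residue index {idx} outside sequence")
    residues = []
    ca_coords = []
    for i, aa in enumerate(sequence):
        theta = math.radians(HELIX_TWIST * i)
        z = HELIX_RISE * i
        ca = (HELIX_RADIUS * math.cos(theta), HELIX_RADIUS * math.sin(theta), z)
        cb = ((HELIX_RADIUS + 1.5) * math.cos(theta),
              (HELIX_RADIUS + 1.5) * math.sin(theta), z)
        ca_coords.append(ca)
        residues.append(
            Residue("A", i + 1, "", _ONE_TO_THREE.get(aa, "UNK"), (
                Atom("CA", *ca, "C"),
                Atom("CB", *cb, "C"),
            ))
        )
    site_ca = np.array([ca_coords[i] for i in site_residue_indices])
    cx, cy, cz = site_ca.mean(axis=0)
    ligand = Residue("A", len(sequence) + 1, "", "LIG",
                     (Atom("C1", cx + ligand_offset, cy, cz, "C"),))
    return ParsedStructure(structure_id, ["A"], residues, [ligand])
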