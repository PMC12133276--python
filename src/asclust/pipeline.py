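"""End-to-end runs: extraction -> scoring -> clustering -> reports.

Every run writes the same output inventory into its output directory:

* ``groups.tsv`` — member id, site string, cluster label (0 = unclustered),
  reference id; every input member appears exactly once across this file and
  the discard log (member conservation).
* ``sites.tsv`` — the extracted site strings (re-entry point for re-clustering).
* ``clusters/`` — one FASTA of full sequences per cluster.
* ``cluster_summary.tsv`` + per-cluster PFM TSVs (and optional PNG logos).
* ``discarded.tsv`` — id and reason for every removed member.
* ``run_metadata.yaml`` — version, resolved parameters (including auto-chosen
  eps/min_samples) and input checksums.
"""

from __future__ import annotations

import hashlib
import logging
import os
from dataclasses import dataclass

import yaml

from . import __version__
from .clustering import (
    ClusteringParams,
    ClusteringResult,
    auto_params,
    dbscan,
)
from .io_core import (
    MSA,
    Discard,
    PairwiseAlignment,
    ParsedStructure,
    read_pairwise_alignment_fasta,
    write_cluster_fastas,
    write_discard_log,
    write_groups_tsv,
)
from .pocket import PocketDefinition
from .scoring import AADistanceMatrix, ScoreMatrix, build_score_matrix
from .site_extraction import (
    DEFAULT_IDENTITY_THRESHOLD,
    DEFAULT_MAX_GAP_FRACTION,
    ActiveSiteSequence,
    apply_gap_discard,
    apply_identity_gate,
    extract_sites_from_msa,
    map_pocket_through_alignment,
    percent_identity,
    IdentityReport,
    select_reference,
    write_sites_tsv,
)
from .summaries import write_cluster_report

logger = logging.getLogger("asclust")


@dataclass
class RunResult:
    out_dir: str
    result: ClusteringResult
    score: ScoreMatrix
    sites: list[ActiveSiteSequence]
    discards: list[Discard]


def _checksum(path: str) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_metadata(out_dir: str, mode: str, params: ClusteringParams,
                    inputs: dict[str, str], extra: dict) -> None:
    meta = {
        "tool": "asclust",
        "version": __version__,
        "mode": mode,
        "clustering": {
            "eps": float(params.eps),
            "min_samples": int(params.min_samples),
            "auto": bool(params.auto),
        },
        "inputs": {
            name: {"path": path, "md5": _checksum(path)}
            for name, path in inputs.items()
            if path and os.path.isfile(path)
        },
        **extra,
    }
    with open(os.path.join(out_dir, "run_metadata.yaml"), "w",
              encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def cluster_and_report(
    sites: list[ActiveSiteSequence],
    discards: list[Discard],
    out_dir: str,
    mode: str,
    sequences: dict[str, str] | None = None,
    matrix: AADistanceMatrix | None = None,
    params: ClusteringParams | None = None,
    render_logos: bool = False,
    inputs: dict[str, str] | None = None,
    thresholds: dict | None = None,
) -> RunResult:
    """Score, cluster and write the full output inventory for a set of sites."""
    if len(sites) < 2:
        raise ValueError(
            f"only {len(sites)} site(s) survived extraction; need at least 2"
        )
    os.makedirs(out_dir, exist_ok=True)
    score = build_score_matrix(sites, matrix)
    resolved = params or auto_params(score)
    result = dbscan(score, resolved)

    label_of = dict(zip(result.member_ids, result.labels))
    rows = [
        (s.member_id, s.site, label_of[s.member_id], s.reference_id)
        for s in sites
    ]
    write_groups_tsv(rows, os.path.join(out_dir, "groups.tsv"))
    write_sites_tsv(sites, os.path.join(out_dir, "sites.tsv"))
    write_discard_log(discards, os.path.join(out_dir, "discarded.tsv"))
    if sequences:
        write_cluster_fastas(rows, sequences, os.path.join(out_dir, "clusters"))
    write_cluster_report(result, sites, score, out_dir, render_logos=render_logos)
    _write_metadata(
        out_dir, mode, resolved, inputs or {},
        {
            "counts": {
                "clustered": int(sum(1 for l in result.labels if l != 0)),
                "unclustered": int(sum(1 for l in result.labels if l == 0)),
                "discarded": len(discards),
            },
            "thresholds": thresholds or {},
        },
    )
    return RunResult(out_dir, result, score, sites, discards)


# ---------------------------------------------------------------------------
# 3D route: pairwise alignments against one or more references


def read_alignment_dir(aln_dir: str) -> list[PairwiseAlignment]:
    files = sorted(
        f for f in os.listdir(aln_dir)
        if f.endswith((".fasta", ".fa", ".afa", ".aln"))
    )
    if not files:
        raise ValueError(f"no alignment FASTA files in {aln_dir}")
    return [read_pairwise_alignment_fasta(os.path.join(aln_dir, f)) for f in files]


def extract_sites_3d(
    alignments: list[PairwiseAlignment],
    pockets: dict[str, PocketDefinition],
    ref_sequences: dict[str, str],
    structures: dict[str, ParsedStructure] | None = None,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    max_gap_fraction: float = DEFAULT_MAX_GAP_FRACTION,
) -> tuple[list[ActiveSiteSequence], list[Discard]]:
    """Map each target through its best-identity reference alignment.

    ``pockets`` and ``ref_sequences`` are keyed by reference id; when several
    references are supplied their pockets must have equal length so the site
    strings stay comparable.
    """
    lengths = {len(p) for p in pockets.values()}
    if len(lengths) != 1:
        raise ValueError(
            f"pockets of different references have unequal sizes {sorted(lengths)}"
        )
    for ref_id in pockets:
        if ref_id not in ref_sequences:
            raise ValueError(f"no reference sequence for pocket of {ref_id!r}")

    by_target: dict[str, list[PairwiseAlignment]] = {}
    for aln in alignments:
        if aln.ref_id not in pockets:
            raise ValueError(
                f"alignment references {aln.ref_id!r} but no pocket is "
                f"defined for it (have: {sorted(pockets)})"
            )
        by_target.setdefault(aln.target_id, []).append(aln)

    structures = structures or {}
    sites: list[ActiveSiteSequence] = []
    reports: list[IdentityReport] = []
    best_aln: dict[str, PairwiseAlignment] = {}
    for target_id, alns in by_target.items():
        best, report = select_reference(alns)
        reports.append(report)
        best_aln[target_id] = best

    kept, discards = apply_identity_gate(reports, identity_threshold)
    for rep in kept:
        aln = best_aln[rep.member_id]
        sites.append(
            map_pocket_through_alignment(
                aln, pockets[aln.ref_id], ref_sequences[aln.ref_id],
                structures.get(aln.ref_id),
            )
        )
    sites, gap_discards = apply_gap_discard(sites, max_gap_fraction)
    return sites, discards + gap_discards


# ---------------------------------------------------------------------------
# 2D route: MSA columns


def extract_sites_2d(
    msa: MSA,
    pocket: PocketDefinition,
    reference_id: str,
    ref_sequence: str | None = None,
    structure: ParsedStructure | None = None,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    max_gap_fraction: float = DEFAULT_MAX_GAP_FRACTION,
) -> tuple[list[ActiveSiteSequence], list[Discard]]:
    """Read every MSA row at the pocket columns, after gating each member on
    its identity to the reference over the MSA-induced pairwise alignment."""
    if reference_id not in msa.ids:
        raise ValueError(f"reference id {reference_id!r} absent from MSA")
    ref_row = msa.row(reference_id)
    if ref_sequence is None:
        ref_sequence = ref_row.replace("-", "")

    reports = [
        IdentityReport(
            rid, reference_id,
            percent_identity(PairwiseAlignment(reference_id, rid, ref_row, row)),
        )
        for rid, row in msa.records if rid != reference_id
    ]
    kept, discards = apply_identity_gate(reports, identity_threshold)
    kept_ids = {r.member_id for r in kept}

    sites = extract_sites_from_msa(msa, reference_id, pocket, ref_sequence,
                                   structure)
    sites = [s for s in sites if s.member_id in kept_ids]
    sites, gap_discards = apply_gap_discard(sites, max_gap_fraction)
    return sites, discards + gap_discards
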