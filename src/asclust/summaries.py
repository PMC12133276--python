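"""Cluster summaries: position frequency matrices, information content,
consensus reports and the 2D-vs-3D active-site comparison.

A cluster's site strings are condensed into a position frequency matrix
(PFM) over the 20 residues, the gap and the unknown symbol; logo stack
heights follow the standard information-content convention
``IC(k) = log2(20) - H(k)`` with the entropy taken over non-gap symbols and
the column's IC scaled by its non-gap fraction.  Rendering to PNG is
optional — the matrices are the contract.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import GAP
from .clustering import NOISE, ClusteringResult
from .scoring import ScoreMatrix
from .site_extraction import ActiveSiteSequence

#: PFM column order: 20 residues, gap, unknown
PFM_SYMBOLS = tuple("ACDEFGHIKLMNPQRSTVWY") + (GAP, "X")


@dataclass(frozen=True)
class SiteAgreementReport:
    """Agreement between the 2D- and 3D-derived site strings of a family."""

    per_member: dict[str, float]        # identity fraction per shared member
    mean_agreement: float
    per_position_mismatches: tuple[int, ...]
    only_2d: tuple[str, ...]
    only_3d: tuple[str, ...]


def frequency_matrix(cluster_sites: list[ActiveSiteSequence]) -> pd.DataFrame:
    """Column-wise relative symbol frequencies of a cluster's sites.

    Rows are 1-based positions, columns the symbols of :data:`PFM_SYMBOLS`;
    every row sums to 1.
    """
    if not cluster_sites:
        raise ValueError("cannot build a frequency matrix from an empty cluster")
    lengths = {len(s.site) for s in cluster_sites}
    if len(lengths) != 1:
        raise ValueError(f"sites have unequal lengths: {sorted(lengths)}")
    L = lengths.pop()
    counts = np.zeros((L, len(PFM_SYMBOLS)))
    col = {s: j for j, s in enumerate(PFM_SYMBOLS)}
    for s in cluster_sites:
        for k, c in enumerate(s.site):
            counts[k, col[c]] += 1
    freqs = counts / len(cluster_sites)
    return pd.DataFrame(freqs, index=pd.RangeIndex(1, L + 1, name="position"),
                        columns=list(PFM_SYMBOLS))


def information_content(pfm: pd.DataFrame, alphabet_size: int = 20) -> np.ndarray:
    """Per-position information content in bits.

    ``IC(k) = (1 - f_gap) * (log2(alphabet_size) - H(k))`` where H is the
    Shannon entropy of the column's non-gap symbol distribution renormalized
    to sum to 1.  A fully gapped column has IC 0.
    """
    max_bits = np.log2(alphabet_size)
    ic = np.zeros(len(pfm))
    gap_freq = pfm[GAP].to_numpy()
    residue_cols = [c for c in pfm.columns if c != GAP]
    res = pfm[residue_cols].to_numpy()
    for k in range(len(pfm)):
        non_gap = 1.0 - gap_freq[k]
        if non_gap <= 0.0:
            continue
        p = res[k] / non_gap
        p = p[p > 0]
        entropy = float(-(p * np.log2(p)).sum())
        ic[k] = non_gap * (max_bits - entropy)
    return ic


def consensus(pfm: pd.DataFrame) -> str:
    """Argmax symbol per position; ties broken by the lexicographically
    smallest symbol (columns scanned in sorted symbol order)."""
    order = sorted(pfm.columns)
    sub = pfm[order].to_numpy()
    return "".join(order[int(np.argmax(row))] for row in sub)


def compare_2d_3d(
    sites_2d: list[ActiveSiteSequence], sites_3d: list[ActiveSiteSequence]
) -> SiteAgreementReport:
    """Per-member and family-level agreement between the MSA-derived (2D) and
    structure-derived (3D) site strings, restricted to shared member ids."""
    map_2d = {s.member_id: s.site for s in sites_2d}
    map_3d = {s.member_id: s.site for s in sites_3d}
    shared = [m for m in map_2d if m in map_3d]
    if not shared:
        raise ValueError("no member ids shared between the 2D and 3D site sets")
    lengths = {len(map_2d[m]) for m in shared} | {len(map_3d[m]) for m in shared}
    if len(lengths) != 1:
        raise ValueError(f"2D and 3D sites have unequal lengths: {sorted(lengths)}")
    L = lengths.pop()
    per_member = {}
    mismatches = np.zeros(L, dtype=int)
    for m in shared:
        a, b = map_2d[m], map_3d[m]
        same = sum(x == y for x, y in zip(a, b))
        per_member[m] = same / L
        for k, (x, y) in enumerate(zip(a, b)):
            if x != y:
                mismatches[k] += 1
    return SiteAgreementReport(
        per_member=per_member,
        mean_agreement=float(np.mean(list(per_member.values()))),
        per_position_mismatches=tuple(int(c) for c in mismatches),
        only_2d=tuple(sorted(set(map_2d) - set(map_3d))),
        only_3d=tuple(sorted(set(map_3d) - set(map_2d))),
    )


def write_agreement_tsv(report: SiteAgreementReport, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("member_id\tagreement\n")
        for m in sorted(report.per_member):
            fh.write(f"{m}\t{report.per_member[m]:.6f}\n")
        fh.write(f"#mean\t{report.mean_agreement:.6f}\n")
        fh.write("#position_mismatches\t"
                 + " ".join(str(c) for c in report.per_position_mismatches) + "\n")


# ---------------------------------------------------------------------------
# Cluster report


def write_cluster_report(
    result: ClusteringResult,
    sites: list[ActiveSiteSequence],
    score: ScoreMatrix,
    out_dir: str | os.PathLike,
    render_logos: bool = False,
) -> dict[int, pd.DataFrame]:
    """Write the per-cluster summary TSV and one PFM TSV per cluster.

    Summary columns: cluster, size, consensus site, mean within-cluster
    distance.  Noise members are listed in an ``unclustered`` section.
    Returns the PFM per cluster label.
    """
    os.makedirs(out_dir, exist_ok=True)
    site_by_id = {s.member_id: s for s in sites}
    pfms: dict[int, pd.DataFrame] = {}
    summary_path = os.path.join(str(out_dir), "cluster_summary.tsv")
    with open(summary_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("cluster\tsize\tconsensus\tmean_within_distance\n")
        for label in sorted(result.cluster_sizes):
            members = result.members_of(label)
            cluster_sites = [site_by_id[m] for m in members]
            pfm = frequency_matrix(cluster_sites)
            pfms[label] = pfm
            sub = score.submatrix(members).values
            n = len(members)
            mean_dist = float(sub[np.triu_indices(n, k=1)].mean()) if n > 1 else 0.0
            fh.write(f"{label}\t{n}\t{consensus(pfm)}\t{mean_dist:.6f}\n")
            pfm_path = os.path.join(str(out_dir), f"cluster_{label}_pfm.tsv")
            pfm.to_csv(pfm_path, sep="\t", lineterminator="\n",
                       float_format="%.6f")
            if render_logos:
                render_logo(pfm, os.path.join(str(out_dir),
                                              f"cluster_{label}_logo.png"))
        noise_members = result.members_of(NOISE)
        if noise_members:
            fh.write("#unclustered\t" + " ".join(noise_members) + "\n")
    return pfms


def render_logo(pfm: pd.DataFrame, path: str | os.PathLike) -> None:
    """Minimal stacked-letter logo: letters scaled by frequency * column IC."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ic = information_content(pfm)
    L = len(pfm)
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * L), 2.5))
    for k in range(L):
        heights = [(sym, pfm.iloc[k][sym] * ic[k]) for sym in PFM_SYMBOLS
                   if sym != GAP and pfm.iloc[k][sym] > 0]
        heights.sort(key=lambda t: t[1])
        y = 0.0
        for sym, h in heights:
            if h <= 0:
                continue
            ax.text(k + 1, y + h / 2, sym, ha="center", va="center",
                    fontsize=6 + 14 * min(h / np.log2(20), 1.0), family="monospace")
            y += h
    ax.set_xlim(0.5, L + 0.5)
    ax.set_ylim(0, np.log2(20))
    ax.set_xlabel("pocket position")
    ax.set_ylabel("bits")
    ax.set_xticks(range(1, L + 1))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def mean_within_cluster_distance(
    result: ClusteringResult, score: ScoreMatrix
) -> dict[int, float]:
    out = {}
    for label in sorted(result.cluster_sizes):
        members = result.members_of(label)
        sub = score.submatrix(members).values
        n = len(members)
        out[label] = float(sub[np.triu_indices(n, k=1)].mean()) if n > 1 else 0.0
    return out
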