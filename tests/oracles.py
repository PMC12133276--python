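"""Independent brute-force oracles used by the tests.

Each oracle re-derives the expected answer from first principles, without
touching the implementation path it checks: DBSCAN by explicit core
enumeration plus connected components, ligand-contact pockets by all-pairs
atom distances, and global alignment by exhaustive enumeration of the
alignment space.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


def brute_force_dbscan(D: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """DBSCAN labels from explicit core enumeration + connected components.

    Returns raw labels: -1 for noise, clusters as non-negative integers.
    Clusters are numbered by their smallest core-point index (formation
    order); a border point reachable from several clusters goes to the one
    formed first.
    """
    n = len(D)
    within = D <= eps
    core = within.sum(axis=1) >= min_samples
    labels = np.full(n, -1, dtype=int)
    core_idx = np.nonzero(core)[0]
    if len(core_idx) == 0:
        return labels

    adj = csr_matrix(within[np.ix_(core_idx, core_idx)])
    _, comp = connected_components(adj, directed=False)

    # number components by their smallest contained core index
    order = {}
    for c in comp[np.argsort(core_idx)]:
        if c not in order:
            order[c] = len(order)
    first_core_index = {}
    for pos, c in enumerate(comp):
        lab = order[c]
        if lab not in first_core_index:
            first_core_index[lab] = core_idx[pos]
        first_core_index[lab] = min(first_core_index[lab], core_idx[pos])
    for pos, c in enumerate(comp):
        labels[core_idx[pos]] = order[c]

    for i in range(n):
        if core[i] or labels[i] != -1:
            continue
        candidates = {
            labels[j] for j in core_idx if within[i, j]
        }
        if candidates:
            labels[i] = min(candidates, key=lambda lab: first_core_index[lab])
    return labels


def brute_force_contact_residues(
    residue_atoms: dict, ligand_atoms: list, cutoff: float
) -> set:
    """Residue keys with any heavy atom within cutoff of any heavy ligand atom,
    by explicit all-pairs distances."""
    hits = set()
    for key, atoms in residue_atoms.items():
        for (x1, y1, z1) in atoms:
            for (x2, y2, z2) in ligand_atoms:
                d = math.dist((x1, y1, z1), (x2, y2, z2))
                if d <= cutoff:
                    hits.add(key)
    return hits


def enumerate_global_alignment_score(
    seq_a: str,
    seq_b: str,
    sub: dict,
    gap_open: float,
    gap_extend: float,
) -> float:
    """Optimal global affine-gap score by exhaustive enumeration of every
    alignment (monotone lattice path); a gap run of length L costs
    gap_open + (L-1)*gap_extend.  End gaps are penalized."""
    best = -math.inf
    n, m = len(seq_a), len(seq_b)

    def score_path(moves: tuple[str, ...]) -> float:
        total = 0.0
        i = j = 0
        run = None
        for mv in moves:
            if mv == "M":
                total += sub[(seq_a[i], seq_b[j])]
                i += 1
                j += 1
                run = None
            else:
                if mv == run:
                    total -= gap_extend
                else:
                    total -= gap_open
                run = mv
                if mv == "I":  # gap in seq_a, consumes seq_b
                    j += 1
                else:          # gap in seq_b, consumes seq_a
                    i += 1
        return total

    def paths(i: int, j: int):
        if i == n and j == m:
            yield ()
            return
        if i < n and j < m:
            for rest in paths(i + 1, j + 1):
                yield ("M",) + rest
        if j < m:
            for rest in paths(i, j + 1):
                yield ("I",) + rest
        if i < n:
            for rest in paths(i + 1, j):
                yield ("D",) + rest

    for moves in paths(0, 0):
        best = max(best, score_path(moves))
    return best
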