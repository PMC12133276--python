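"""Amino-acid distance matrix and all-vs-all site score matrix.

Active-site strings are compared position-wise with a residue distance matrix
that encodes physicochemical equivalence: substitutions within a chemical
class are near (0.3), substitutions across classes are far (1.0), identity is
0 and a residue aligned to a gap is maximally distant.  The distance between
two sites is the arithmetic mean of the per-position entries, so the
all-vs-all score matrix lies in [0, 1] by construction, with 0 on the
diagonal.

The default matrix is a documented class-based construction; a custom matrix
(e.g. one fitted to a particular family) can be dropped in from a labeled TSV
through :func:`load_distance_matrix`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import AA_ALPHABET, GAP, UNKNOWN
from .site_extraction import ActiveSiteSequence

#: physicochemical residue classes of the default matrix
RESIDUE_CLASSES: tuple[frozenset[str], ...] = (
    frozenset("AVLIM"),   # aliphatic / small hydrophobic
    frozenset("FWY"),     # aromatic
    frozenset("STNQC"),   # polar uncharged
    frozenset("KRH"),     # basic
    frozenset("DE"),      # acidic
    frozenset("GP"),      # conformationally special
)

WITHIN_CLASS_DISTANCE = 0.3
BETWEEN_CLASS_DISTANCE = 1.0
GAP_DISTANCE = 1.0
UNKNOWN_DISTANCE = 0.5

#: symbols carried by every distance matrix: 20 residues, gap, unknown
MATRIX_ALPHABET = AA_ALPHABET + GAP + UNKNOWN


@dataclass(frozen=True)
class AADistanceMatrix:
    """Symmetric residue-level distance table over the 21-symbol alphabet
    (20 residues + gap), plus the unknown symbol X."""

    alphabet: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        n = len(self.alphabet)
        v = self.values
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match alphabet size {n}")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(v < 0.0) or np.any(v > 1.0):
            raise ValueError("distance matrix entries outside [0, 1]")

    def index(self, symbol: str) -> int:
        i = self.alphabet.find(symbol)
        if i < 0:
            raise KeyError(f"symbol {symbol!r} not in matrix alphabet")
        return i

    def distance(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])


def _class_of(aa: str) -> int:
    for k, cls in enumerate(RESIDUE_CLASSES):
        if aa in cls:
            return k
    raise ValueError(f"residue {aa!r} not covered by the class partition")


def default_distance_matrix() -> AADistanceMatrix:
    """The class-based default: 0 identity, 0.3 within a physicochemical
    class, 1.0 across classes; gap vs any residue 1.0; X is 0.5 from
    everything except itself."""
    symbols = MATRIX_ALPHABET
    n = len(symbols)
    v = np.zeros((n, n))
    for i, a in enumerate(symbols):
        for j, b in enumerate(symbols):
            if a == b:
                continue
            if UNKNOWN in (a, b):
                v[i, j] = UNKNOWN_DISTANCE
            elif GAP in (a, b):
                v[i, j] = GAP_DISTANCE
            elif _class_of(a) == _class_of(b):
                v[i, j] = WITHIN_CLASS_DISTANCE
            else:
                v[i, j] = BETWEEN_CLASS_DISTANCE
    return AADistanceMatrix(symbols, v)


def write_distance_matrix(m: AADistanceMatrix, path: str | os.PathLike) -> None:
    df = pd.DataFrame(m.values, index=list(m.alphabet), columns=list(m.alphabet))
    df.to_csv(path, sep="\t", lineterminator="\n")


def load_distance_matrix(path: str | os.PathLike) -> AADistanceMatrix:
    """Load a labeled square TSV and validate every matrix invariant.

    The file must cover the 20 residues and the gap symbol; an X row/column is
    optional and filled with the default unknown-distance rule when absent.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row labels differ from column labels")
    required = set(AA_ALPHABET + GAP)
    missing = required - set(df.index)
    if missing:
        raise ValueError(f"{path}: missing symbols {sorted(missing)}")
    if UNKNOWN not in df.index:
        default = default_distance_matrix()
        for s in df.index:
            df.loc[s, UNKNOWN] = default.distance(s, UNKNOWN) if UNKNOWN != s else 0.0
        df.loc[UNKNOWN] = [default.distance(UNKNOWN, s) for s in df.columns]
    order = [s for s in MATRIX_ALPHABET if s in df.index]
    extra = [s for s in df.index if s not in order]
    if extra:
        raise ValueError(f"{path}: unexpected symbols {extra}")
    df = df.loc[order, order]
    values = df.to_numpy(dtype=float)
    if not np.allclose(values, values.T):
        bad = np.argwhere(~np.isclose(values, values.T))[0]
        a, b = order[bad[0]], order[bad[1]]
        raise ValueError(f"{path}: asymmetric entries d({a},{b}) != d({b},{a})")
    if np.any(np.diag(values) != 0.0):
        sym = order[int(np.nonzero(np.diag(values))[0][0])]
        raise ValueError(f"{path}: nonzero diagonal at symbol {sym!r}")
    if np.any((values < 0) | (values > 1)):
        raise ValueError(f"{path}: entries outside [0, 1]")
    return AADistanceMatrix("".join(order), values)


# ---------------------------------------------------------------------------
# Site comparison


def site_distance(s1: str, s2: str, m: AADistanceMatrix) -> float:
    """Mean per-position residue distance between two equal-length sites."""
    if len(s1) != len(s2):
        raise ValueError(f"site lengths differ ({len(s1)} vs {len(s2)})")
    if not s1:
        raise ValueError("empty site strings")
    total = 0.0
    for a, b in zip(s1, s2):
        total += m.values[m.index(a), m.index(b)]
    return total / len(s1)


@dataclass(frozen=True)
class ScoreMatrix:
    """All-vs-all site distances: symmetric, zero diagonal, entries in [0,1]."""

    member_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        n = len(self.member_ids)
        if self.values.shape != (n, n):
            raise ValueError("score matrix shape does not match member count")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("score matrix is not symmetric")
        if np.any(np.diag(self.values) != 0.0):
            raise ValueError("score matrix diagonal is not zero")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("score matrix entries outside [0, 1]")

    def __len__(self) -> int:
        return len(self.member_ids)

    def submatrix(self, member_ids: list[str]) -> "ScoreMatrix":
        pos = {m: i for i, m in enumerate(self.member_ids)}
        idx = np.array([pos[m] for m in member_ids], dtype=int)
        return ScoreMatrix(tuple(member_ids), self.values[np.ix_(idx, idx)])


def build_score_matrix(
    sites: list[ActiveSiteSequence], m: AADistanceMatrix | None = None
) -> ScoreMatrix:
    """All-vs-all mean-per-position distances between site strings.

    Entries are means of [0,1] matrix values, so the result is in [0,1] with
    no further rescaling.
    """
    if len(sites) < 2:
        raise ValueError("need at least 2 sites to build a score matrix")
    lengths = {len(s.site) for s in sites}
    if len(lengths) != 1:
        raise ValueError(f"sites have unequal lengths: {sorted(lengths)}")
    m = m or default_distance_matrix()
    L = lengths.pop()
    codes = np.array(
        [[m.index(c) for c in s.site] for s in sites], dtype=np.intp
    )
    n = len(sites)
    total = np.zeros((n, n))
    for k in range(L):
        col = codes[:, k]
        total += m.values[np.ix_(col, col)]
    values = total / L
    values = (values + values.T) / 2.0  # exact symmetry against float noise
    np.fill_diagonal(values, 0.0)
    return ScoreMatrix(tuple(s.member_id for s in sites), values)


def write_score_matrix(score: ScoreMatrix, path: str | os.PathLike) -> None:
    df = pd.DataFrame(score.values, index=list(score.member_ids),
                      columns=list(score.member_ids))
    df.to_csv(path, sep="\t", lineterminator="\n")
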