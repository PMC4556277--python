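"""David's scores, I&SI rank ordering and hierarchy steepness.

Dyadic dominance is summarised either by the raw win proportion

    P_ij = s_ij / n_ij            (0 when the dyad never interacted)

or by its chance-corrected version

    D_ij = P_ij - (P_ij - 1/2) / (n_ij + 1)

which shrinks sparse dyads toward 1/2 (empty dyads sit exactly at 1/2).

David's score weights wins by the strength of the opponents:

    w_i  = sum_j p_ij          w2_i = sum_j p_ij * w_j
    l_i  = sum_j p_ji          l2_i = sum_j p_ji * l_j
    DS_i = w_i + w2_i - l_i - l2_i

and NormDS_i = (DS_i + n(n-1)/2) / n maps the scores into [0, n-1].

Steepness is the absolute slope of the ordinary-least-squares fit of
NormDS against the ordinal rank 1..n; its significance comes from a
randomization test in which each dyad keeps its interaction total and the
wins are re-drawn Binomial(n_ij, 1/2).

The I&SI method orders individuals to minimise first the number of
inconsistencies I (dyads in which a lower-ranked individual dominates a
higher-ranked one) and then their summed strength SI (the rank distances
of the inconsistent dyads), lexicographically.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .sociomatrix import Sociomatrix, SociomatrixError

__all__ = [
    "DyadicProportions",
    "ScoreTable",
    "OrderResult",
    "SteepnessResult",
    "dyadic_proportions",
    "david_scores",
    "isi_order",
    "steepness",
    "steepness_test",
]


@dataclass(frozen=True)
class DyadicProportions:
    labels: tuple[str, ...]
    p: np.ndarray       # square, floats in [0, 1], zero diagonal
    n_ij: np.ndarray    # symmetric interaction totals
    variant: str        # "pij" | "dij"


@dataclass(frozen=True)
class ScoreTable:
    labels: tuple[str, ...]
    w: np.ndarray
    w2: np.ndarray
    l: np.ndarray
    l2: np.ndarray
    ds: np.ndarray
    normds: np.ndarray
    ordinal_rank: np.ndarray  # 1 = highest NormDS; ties broken by label order
    variant: str

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "w": self.w, "w2": self.w2, "l": self.l, "l2": self.l2,
                "DS": self.ds, "NormDS": self.normds,
                "rank": self.ordinal_rank,
            },
            index=list(self.labels),
        )

    def by_rank(self) -> tuple[str, ...]:
        """Labels from rank 1 (highest NormDS) down."""
        return tuple(str(x) for x in np.asarray(self.labels)[np.argsort(self.ordinal_rank)])


@dataclass(frozen=True)
class OrderResult:
    order: tuple[str, ...]  # position 0 = top rank
    inconsistencies: int    # I
    strength: int           # SI
    optimal_certified: bool


@dataclass(frozen=True)
class SteepnessResult:
    steepness: float
    intercept: float
    variant: str
    null_mean: Optional[float] = None
    p_right: Optional[float] = None
    n_randomizations: int = 0
    seed: Optional[int] = None


def dyadic_proportions(m: Sociomatrix, variant: str = "pij") -> DyadicProportions:
    """Compute P_ij or D_ij matrices from a count sociomatrix."""
    variant = variant.lower()
    if variant not in ("pij", "dij"):
        raise ValueError(f"variant must be 'pij' or 'dij', got {variant!r}")
    c = m.counts.astype(float)
    tot = c + c.T
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, c / np.where(tot > 0, tot, 1), 0.0)
    if variant == "dij":
        d = p - (p - 0.5) / (tot + 1)
        d = np.where(tot > 0, d, 0.5)  # empty dyads at chance
        p = d
    np.fill_diagonal(p, 0.0)
    return DyadicProportions(m.labels, p, tot, variant)


def _batch_david(p: np.ndarray) -> np.ndarray:
    """NormDS for a batch of proportion matrices, shape (..., n, n)."""
    n = p.shape[-1]
    w = p.sum(axis=-1)
    l = p.sum(axis=-2)
    w2 = np.einsum("...ij,...j->...i", p, w)
    l2 = np.einsum("...ji,...j->...i", p, l)
    ds = w + w2 - l - l2
    return (ds + n * (n - 1) / 2.0) / n


def david_scores(dp: DyadicProportions) -> ScoreTable:
    """Per-individual David's scores and normalized David's scores."""
    p = dp.p
    n = p.shape[0]
    w = p.sum(axis=1)
    l = p.sum(axis=0)
    w2 = p @ w
    l2 = p.T @ l
    ds = w + w2 - l - l2
    normds = (ds + n * (n - 1) / 2.0) / n
    # Ordinal ranks by decreasing NormDS; ties broken by label (matrix)
    # order so that equal scores still receive distinct ranks.
    order = np.lexsort((np.arange(n), -normds))
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(1, n + 1)
    return ScoreTable(dp.labels, w, w2, l, l2, ds, normds, rank, dp.variant)


# ---------------------------------------------------------------------------
# I&SI ordering
# ---------------------------------------------------------------------------

def _dominance_relation(counts: np.ndarray) -> np.ndarray:
    """dom[i, j] True iff i dominates j (strictly more wins).

    Tied and unknown dyads carry no direction and contribute no
    inconsistency under any order.
    """
    return counts > counts.T


def _i_si(dom: np.ndarray, order: np.ndarray) -> tuple[int, int]:
    """I and SI for ``order`` (position 0 = top rank)."""
    sub = dom[np.ix_(order, order)]
    lower_beats_higher = np.tril(sub, k=-1)
    pos = np.nonzero(lower_beats_higher)
    i_count = len(pos[0])
    si = int(np.sum(pos[0] - pos[1]))
    return i_count, si


def _swap_descent(dom: np.ndarray, order: np.ndarray) -> tuple[np.ndarray, int, int]:
    """Local search minimising (I, SI) lexicographically.

    The neighbourhood contains every pairwise swap and every single-element
    relocation (insertion); passes repeat until no move improves.
    """
    order = order.copy()
    best = _i_si(dom, order)
    n = len(order)
    improved = True
    while improved:
        improved = False
        for a in range(n - 1):
            for b in range(a + 1, n):
                order[a], order[b] = order[b], order[a]
                cand = _i_si(dom, order)
                if cand < best:
                    best = cand
                    improved = True
                else:
                    order[a], order[b] = order[b], order[a]
        for a in range(n):
            for b in range(n):
                if a == b:
                    continue
                moved = np.delete(order, a)
                moved = np.insert(moved, b, order[a])
                cand = _i_si(dom, moved)
                if cand < best:
                    order = moved
                    best = cand
                    improved = True
    return order, best[0], best[1]


def isi_order(
    m: Sociomatrix,
    max_exhaustive_n: int = 8,
    n_restarts: int = 20,
    seed: Optional[int] = None,
) -> OrderResult:
    """Rank order most consistent with a linear hierarchy (I&SI method).

    For groups of at most ``max_exhaustive_n`` the optimum is certified by
    exhaustive search over all permutations; larger groups use an
    iterative-swap heuristic started from the decreasing-NormDS order with
    seeded random restarts.
    """
    if m.n < 2:
        raise SociomatrixError("I&SI ordering requires at least 2 individuals")
    dom = _dominance_relation(m.counts)
    labels = np.asarray(m.labels)

    if m.n <= max_exhaustive_n:
        best_order = None
        best = (np.inf, np.inf)
        for perm in itertools.permutations(range(m.n)):
            cand = _i_si(dom, np.asarray(perm))
            if cand < best:
                best = cand
                best_order = perm
                if best == (0, 0):
                    break
        return OrderResult(tuple(str(x) for x in labels[list(best_order)]),
                           int(best[0]), int(best[1]), True)

    rng = np.random.default_rng(seed)
    start = np.argsort(david_scores(dyadic_proportions(m, "pij")).ordinal_rank)
    best_order, bi, bsi = _swap_descent(dom, np.asarray(start))
    for _ in range(n_restarts):
        cand_order, ci, csi = _swap_descent(dom, rng.permutation(m.n))
        if (ci, csi) < (bi, bsi):
            best_order, bi, bsi = cand_order, ci, csi
    return OrderResult(tuple(str(x) for x in labels[best_order]), bi, bsi, False)


# ---------------------------------------------------------------------------
# Steepness
# ---------------------------------------------------------------------------

def _slope_intercept(normds: np.ndarray) -> tuple[float, float]:
    """OLS fit of NormDS (sorted decreasing) against ranks 1..n."""
    n = len(normds)
    y = np.sort(normds)[::-1]
    x = np.arange(1, n + 1, dtype=float)
    xc = x - x.mean()
    slope = float(np.dot(xc, y) / np.dot(xc, xc))
    intercept = float(y.mean() - slope * x.mean())
    return slope, intercept


def steepness(st: ScoreTable) -> SteepnessResult:
    """Absolute OLS slope of NormDS against ordinal rank."""
    if st.n < 3:
        raise SociomatrixError("steepness requires at least 3 individuals")
    slope, intercept = _slope_intercept(st.normds)
    return SteepnessResult(abs(slope), intercept, st.variant)


def steepness_test(
    m: Sociomatrix,
    variant: str = "pij",
    n_rand: int = 20000,
    seed: Optional[int] = None,
) -> SteepnessResult:
    """Randomization test of hierarchy steepness.

    Every replicate keeps each dyad's interaction total n_ij and draws the
    win split Binomial(n_ij, 1/2); the proportions, NormDS and steepness
    are recomputed.  p_right = (1 + #{null >= observed}) / (n_rand + 1).
    """
    if seed is None:
        raise ValueError("seed is mandatory for the randomization test")
    obs = steepness(david_scores(dyadic_proportions(m, variant)))
    rng = np.random.default_rng(seed)

    n = m.n
    tot = (m.counts + m.counts.T).astype(np.int64)
    iu, ju = np.triu_indices(n, k=1)
    t = tot[iu, ju]

    wins = rng.binomial(t[None, :], 0.5, size=(n_rand, len(t)))
    c = np.zeros((n_rand, n, n), dtype=float)
    c[:, iu, ju] = wins
    c[:, ju, iu] = t[None, :] - wins
    batch_tot = tot[None, :, :].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(batch_tot > 0, c / np.where(batch_tot > 0, batch_tot, 1), 0.0)
    if variant.lower() == "dij":
        p = np.where(batch_tot > 0, p - (p - 0.5) / (batch_tot + 1), 0.5)
    diag = np.arange(n)
    p[:, diag, diag] = 0.0

    normds = _batch_david(p)
    y = np.sort(normds, axis=1)[:, ::-1]
    x = np.arange(1, n + 1, dtype=float)
    xc = x - x.mean()
    slopes = (y @ xc) / np.dot(xc, xc)
    null = np.abs(slopes)
    k_ge = int(np.sum(null >= obs.steepness - 1e-12))
    return SteepnessResult(
        steepness=obs.steepness, intercept=obs.intercept, variant=variant.lower(),
        null_mean=float(null.mean()), p_right=(1 + k_ge) / (n_rand + 1),
        n_randomizations=n_rand, seed=seed,
    )
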