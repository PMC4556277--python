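"""Covariation of status indicators.

Per-individual NormDS profiles of the selected behavioural variables are
compared with Pearson correlation, clustered with average linkage on the
distance d = 1 - r (heights linearly rescaled to [0, 25]), and individual
rank is related to covariates (age, weight) with a one-tailed Spearman
rank correlation (exact permutation null for small groups).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import rankdata, t as t_dist

from .linearity import LinearityResult, RelationshipSummary
from .ranking import ScoreTable

__all__ = [
    "Dendrogram",
    "select_variables",
    "profile_matrix",
    "profile_correlations",
    "average_linkage_cluster",
    "spearman_rank_correlation",
]


def select_variables(
    linearity: Mapping[str, LinearityResult],
    relationships: Mapping[str, RelationshipSummary],
    alpha: float = 0.05,
    max_unknown_fraction: float = 0.25,
    alpha_inclusive: bool = True,
) -> list[str]:
    """Variables with significant linearity and sufficient coverage.

    Keeps a variable when its linearity p-value is at most ``alpha``
    (strictly below when ``alpha_inclusive`` is False) and its unknown-dyad
    fraction is strictly below ``max_unknown_fraction``.
    """
    keep = []
    for name, lin in linearity.items():
        if lin.p_right is None:
            raise ValueError(f"variable {name!r} has no linearity p-value")
        sig = lin.p_right <= alpha if alpha_inclusive else lin.p_right < alpha
        if sig and relationships[name].unknown_fraction < max_unknown_fraction:
            keep.append(name)
    return keep


def profile_matrix(scores: Mapping[str, ScoreTable]) -> pd.DataFrame:
    """NormDS profile matrix: variables as rows, individuals as columns."""
    names = list(scores)
    labels = scores[names[0]].labels
    for name in names:
        if scores[name].labels != labels:
            raise ValueError(f"score table {name!r} has mismatched individuals")
    return pd.DataFrame(
        {name: scores[name].normds for name in names}, index=list(labels)
    ).T


def profile_correlations(pm: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between every pair of variable profiles."""
    if pm.shape[0] < 2 or pm.shape[1] < 3:
        raise ValueError("need at least 2 variables and 3 individuals")
    r = np.corrcoef(pm.to_numpy())
    return pd.DataFrame(r, index=pm.index, columns=pm.index)


@dataclass(frozen=True)
class Dendrogram:
    """Average-linkage merge tree with heights rescaled to [0, max_height]."""

    labels: tuple[str, ...]
    merges: np.ndarray  # scipy linkage matrix, heights rescaled
    max_height: float = 25.0

    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def cut(self, k: int) -> dict[str, int]:
        """Flat clusters from cutting the tree into ``k`` groups."""
        from scipy.cluster.hierarchy import fcluster

        flat = fcluster(self.merges, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))

    def to_newick(self) -> str:
        """Newick string with branch lengths from the rescaled heights."""
        tree = to_tree(self.merges)

        def render(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        root = (
            f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"
            if not tree.is_leaf()
            else f"{self.labels[tree.id]};"
        )
        return root

    def to_merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.merges, columns=["cluster_a", "cluster_b", "height", "size"]
        )


def average_linkage_cluster(
    corr: pd.DataFrame,
    max_height: float = 25.0,
    absolute: bool = False,
) -> Dendrogram:
    """Agglomerative average-linkage clustering of a correlation matrix.

    Similarity r is converted to the distance d = 1 - r, so perfectly
    anti-correlated profiles are maximally distant (``absolute=True``
    uses d = 1 - |r| instead).  The merge height of two clusters is the
    mean pairwise distance between their members; final heights are
    linearly rescaled so the last merge sits at ``max_height``, which
    preserves merge order and height ratios.
    """
    r = corr.to_numpy(dtype=float)
    if r.shape[0] != r.shape[1] or not np.allclose(r, r.T, atol=1e-8):
        raise ValueError("correlation matrix must be square and symmetric")
    d = 1.0 - (np.abs(r) if absolute else r)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    z = linkage(squareform(d, checks=False), method="average")
    top = z[-1, 2]
    if top > 0:
        z = z.copy()
        z[:, 2] *= max_height / top
    return Dendrogram(tuple(str(x) for x in corr.index), z, max_height)


# ---------------------------------------------------------------------------
# Spearman rank correlation with exact permutation p for small groups
# ---------------------------------------------------------------------------

def _all_permutations(n: int) -> np.ndarray:
    """All n! permutations of range(n) as an (n!, n) array."""
    perms = np.zeros((1, 1), dtype=np.int8)
    for m in range(2, n + 1):
        old = perms
        k = old.shape[0]
        new = np.empty((k * m, m), dtype=np.int8)
        for pos in range(m):
            block = new[pos * k:(pos + 1) * k]
            block[:, pos] = m - 1
            cols = [c for c in range(m) if c != pos]
            block[:, cols] = old
        perms = new
    return perms


def spearman_rank_correlation(
    scores: "ScoreTable | Sequence[float]",
    covariate: Sequence[float],
    exact_max_n: int = 10,
) -> tuple[float, float]:
    """One-tailed Spearman correlation of dominance with a covariate.

    ``scores`` may be a ScoreTable (its NormDS values are used) or any
    per-individual numeric vector.  Ties receive average ranks.  Higher
    dominance paired with a larger covariate gives positive r_S; the
    p-value is right-tailed (Pr(r >= observed) under random pairing),
    computed by exact enumeration of all pairings for groups of at most
    ``exact_max_n`` and by the t approximation otherwise.
    """
    values = np.asarray(
        scores.normds if isinstance(scores, ScoreTable) else scores, dtype=float
    )
    cov = np.asarray(covariate, dtype=float)
    if values.shape != cov.shape:
        raise ValueError("covariate must have one value per individual")
    n = len(values)
    if n < 3:
        raise ValueError("need at least 3 individuals")
    a = rankdata(values)
    b = rankdata(cov)
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.sqrt(np.dot(ac, ac) * np.dot(bc, bc))
    if denom == 0:
        return np.nan, np.nan
    r_obs = float(np.dot(ac, bc) / denom)

    if n <= exact_max_n:
        perms = _all_permutations(n)
        # r for a permuted pairing is monotone in the dot product a . b[perm].
        dots = bc[perms.astype(np.intp)] @ ac
        r_null = dots / denom
        p = float(np.mean(r_null >= r_obs - 1e-12))
    else:
        t_stat = r_obs * np.sqrt((n - 2) / max(1e-12, 1.0 - r_obs**2))
        p = float(t_dist.sf(t_stat, df=n - 2))
    return r_obs, p
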