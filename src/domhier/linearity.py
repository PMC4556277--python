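"""Linearity, directional consistency and coverage of a dominance matrix.

Implements Landau's linearity index h, the improved index h' correcting
for unknown and tied relationships, the directional consistency index
(DCI), the unknown/1-way/2-way/tied dyad classification, and a
randomization test of linearity.

Notation: for each unordered dyad {i, j}, H_ij is the larger and L_ij the
smaller of the two directed counts.  A dyad is *unknown* if both counts
are zero, *tied* if both are equal and nonzero.  For linearity each dyad
contributes a dominance score s_ij = 1 (i beats j), 0 (j beats i) or 0.5
(unknown or tied); V_i = sum_j s_ij and

    h  = 12 / (n^3 - n) * sum_i (V_i - (n - 1)/2)^2
    h' = h + 6 u / (n^3 - n)

where u counts the unknown-or-tied dyads.  h' equals the expected value
of h when every such dyad is resolved at random (probability 1/2 each
way), which is the Monte-Carlo oracle used in the test suite.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .sociomatrix import Sociomatrix, SociomatrixError

__all__ = [
    "RelationshipSummary",
    "DCIResult",
    "LinearityResult",
    "classify_relationships",
    "dci",
    "landau_h",
    "improved_h",
    "linearity_test",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RelationshipSummary:
    """Dyad classification counts for one behavioural variable."""

    n_dyads: int
    unknown: int
    one_way: int
    two_way: int
    tied: int

    def __post_init__(self) -> None:
        assert self.unknown + self.one_way + self.two_way == self.n_dyads
        assert self.tied <= self.two_way

    def pct(self, count: int) -> float:
        """Percentage of all dyads, rounded to one decimal."""
        return round(100.0 * count / self.n_dyads, 1)

    @property
    def unknown_fraction(self) -> float:
        return self.unknown / self.n_dyads

    @property
    def coverage(self) -> float:
        """Proportion of dyads with at least one interaction."""
        return 1.0 - self.unknown_fraction


@dataclass(frozen=True)
class DCIResult:
    dci: Optional[float]  # None when no dyad interacted at all
    numerator: int
    denominator: int


@dataclass(frozen=True)
class LinearityResult:
    h: float
    h_prime: float
    u: int  # unknown-or-tied dyads
    n_individuals: int
    p_right: Optional[float] = None
    n_randomizations: int = 0
    seed: Optional[int] = None


def classify_relationships(m: Sociomatrix) -> RelationshipSummary:
    """Classify every unordered dyad as unknown / one-way / two-way (/tied)."""
    if m.n < 2:
        raise SociomatrixError("need at least 2 individuals")
    c = m.counts
    iu, ju = np.triu_indices(m.n, k=1)
    a, b = c[iu, ju], c[ju, iu]
    unknown = int(np.sum((a == 0) & (b == 0)))
    two_way = int(np.sum((a > 0) & (b > 0)))
    one_way = m.n_dyads - unknown - two_way
    tied = int(np.sum((a > 0) & (a == b)))
    return RelationshipSummary(m.n_dyads, unknown, one_way, two_way, tied)


def dci(m: Sociomatrix) -> DCIResult:
    """Directional consistency index: sum(H - L) / sum(H + L) over dyads.

    0 means every exchanged dyad is perfectly symmetric, 1 means every
    exchange is one-way.  Unknown dyads contribute nothing to either sum;
    an all-zero matrix has no defined DCI (returned as None).
    """
    c = m.counts
    iu, ju = np.triu_indices(m.n, k=1)
    a, b = c[iu, ju], c[ju, iu]
    hi, lo = np.maximum(a, b), np.minimum(a, b)
    num, den = int(np.sum(hi - lo)), int(np.sum(hi + lo))
    if den == 0:
        warnings.warn("all-zero matrix: DCI undefined", stacklevel=2)
        return DCIResult(None, num, den)
    return DCIResult(num / den, num, den)


def _dominance_scores(counts: np.ndarray) -> np.ndarray:
    """s_ij matrix: 1 if i beats j, 0 if j beats i, 0.5 if unknown/tied."""
    s = np.full(counts.shape, 0.5)
    s[counts > counts.T] = 1.0
    s[counts < counts.T] = 0.0
    np.fill_diagonal(s, 0.0)
    return s


def _h_from_scores(s: np.ndarray) -> float:
    n = s.shape[0]
    v = s.sum(axis=1)
    return float(12.0 / (n**3 - n) * np.sum((v - (n - 1) / 2.0) ** 2))


def landau_h(m: Sociomatrix) -> float:
    """Landau's h on the 0.5-filled dominance matrix (unknowns/ties = 0.5)."""
    if m.n < 3:
        raise SociomatrixError("Landau's h requires at least 3 individuals")
    return _h_from_scores(_dominance_scores(m.counts))


def _unknown_or_tied(counts: np.ndarray) -> int:
    iu, ju = np.triu_indices(counts.shape[0], k=1)
    a, b = counts[iu, ju], counts[ju, iu]
    return int(np.sum(a == b))  # both zero (unknown) or equal nonzero (tied)


def improved_h(m: Sociomatrix) -> LinearityResult:
    """Improved linearity index h' = h + 6u/(n^3 - n)."""
    if m.n < 3:
        raise SociomatrixError("h' requires at least 3 individuals")
    h = landau_h(m)
    u = _unknown_or_tied(m.counts)
    h_prime = h + 6.0 * u / (m.n**3 - m.n)
    return LinearityResult(h=h, h_prime=h_prime, u=u, n_individuals=m.n)


def linearity_test(
    m: Sociomatrix,
    n_rand: int = 10000,
    seed: Optional[int] = None,
    rerandomize_all_dyads: bool = False,
) -> LinearityResult:
    """Right-tailed randomization test of h'.

    Under the null every *known* dyad's direction is an independent fair
    coin while the unknown dyads stay unknown (tied dyads are resolved to
    a direction in the replicates, so their u contribution vanishes).
    With ``rerandomize_all_dyads=True`` every dyad, unknown ones included,
    is given a random direction — the unconditional null.

    p_right = (1 + #{replicates with h' >= observed h'}) / (n_rand + 1).
    """
    if m.n < 3:
        raise SociomatrixError("linearity test requires at least 3 individuals")
    if seed is None:
        raise ValueError("seed is mandatory for the randomization test")
    if n_rand < 100:
        warnings.warn(f"n_rand={n_rand} is very small; p will be coarse",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    obs = improved_h(m)

    n = m.n
    iu, ju = np.triu_indices(n, k=1)
    known = (m.counts[iu, ju] + m.counts[ju, iu]) > 0
    if rerandomize_all_dyads:
        rand_mask = np.ones_like(known)
    else:
        rand_mask = known
    n_random_dyads = int(rand_mask.sum())
    u_rep = int((~rand_mask).sum())  # dyads that stay at 0.5 in replicates

    # Replicate dominance scores for the randomized dyads: Bernoulli(1/2).
    draws = rng.random((n_rand, n_random_dyads)) < 0.5
    # V_i per replicate: fixed 0.5 contribution for preserved dyads.
    v = np.full((n_rand, n), 0.0)
    ri = iu[rand_mask]
    rj = ju[rand_mask]
    # i gets 1 when the draw favours i, j gets 1 otherwise.
    for k in range(n_random_dyads):
        v[:, ri[k]] += draws[:, k]
        v[:, rj[k]] += ~draws[:, k]
    fi = iu[~rand_mask]
    fj = ju[~rand_mask]
    for k in range(len(fi)):
        v[:, fi[k]] += 0.5
        v[:, fj[k]] += 0.5

    h_rep = 12.0 / (n**3 - n) * np.sum((v - (n - 1) / 2.0) ** 2, axis=1)
    hp_rep = h_rep + 6.0 * u_rep / (n**3 - n)
    k_ge = int(np.sum(hp_rep >= obs.h_prime - 1e-12))
    p = (1 + k_ge) / (n_rand + 1)
    return LinearityResult(
        h=obs.h, h_prime=obs.h_prime, u=obs.u, n_individuals=n,
        p_right=p, n_randomizations=n_rand, seed=seed,
    )
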