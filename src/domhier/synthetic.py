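"""Synthetic dominance data with controlled hierarchy structure.

The generator emulates the statistical structure of a small, newly formed
dog group observed over a fixed window: a latent linear hierarchy, dyad
interaction totals with zero-inflation (dyads that never interact and so
stay "unknown"), and outcome directions biased toward the latent order
through a logistic win probability,

    p_win(i over j) = 1 / (1 + exp(-beta * (rank_j - rank_i)))

with rank 1 the top individual.  beta = 0 gives the null (fair coins per
interaction); large beta approaches a fully unidirectional matrix.  The
defaults reproduce the regime of the observed core group: 10 individuals,
about 13.5 interactions per active dyad (≈550 events in total), 8.9% of
dyads silent, and directionality strong enough that linearity and
directional consistency both exceed 0.9.

``generate_interaction_log`` inverts the event coder: given a target
lowering-of-posture matrix it writes interaction records that the coder
classifies back into exactly that matrix, plus distractor records that
yield no events.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ethogram import InteractionRecord, detect_lop
from .sociomatrix import Sociomatrix

__all__ = [
    "GeneratorConfig",
    "LatentGroup",
    "CORE_GROUP_COVARIATES",
    "generate_matrix",
    "generate_interaction_log",
]

# Age (months) and weight (kg) of the ten core-group dogs, used verbatim
# as the covariate fixture.  Codes are the published individual labels.
CORE_GROUP_COVARIATES: pd.DataFrame = pd.DataFrame(
    {
        "age_months": [24.0, 12.5, 6.7, 6.7, 6.7, 6.7, 5.7, 5.0, 4.8, 3.4],
        "weight_kg": [6.3, 25.3, 11.0, 11.9, 10.2, 9.9, 10.6, 16.4, 16.1, 14.5],
    },
    index=["I", "P", "V", "Z", "S", "K", "W", "T", "U", "B"],
)

_AGE_RANGE = (2.0, 78.0)       # observed range across the full group
_WEIGHT_RANGE = (6.2, 44.9)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic sociomatrix generator.

    n : group size (>= 3)
    lam : mean interactions per non-silent dyad (Poisson, clamped below
        by ``min_interactions``)
    zero_inflation : probability a dyad is silent, i.e. unknown
    beta : slope of the logistic win probability in latent rank difference
    min_interactions : lower clamp on per-dyad totals (default 1)
    """

    n: int = 10
    lam: float = 13.5
    zero_inflation: float = 0.089
    beta: float = 5.0
    seed: Optional[int] = None
    min_interactions: int = 1
    labels: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("n must be at least 3")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if not 0 <= self.zero_inflation < 1:
            raise ValueError("zero_inflation must lie in [0, 1)")
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")
        if self.labels is not None and len(self.labels) != self.n:
            raise ValueError("labels must have length n")


@dataclass(frozen=True)
class LatentGroup:
    labels: tuple[str, ...]
    ranks: tuple[int, ...]  # 1 = top of the latent hierarchy
    covariates: pd.DataFrame  # age_months, weight_kg per individual

    def by_rank(self) -> tuple[str, ...]:
        return tuple(str(x) for x in np.asarray(self.labels)[np.argsort(self.ranks)])


def _default_labels(n: int) -> tuple[str, ...]:
    if n <= 10:
        return tuple(CORE_GROUP_COVARIATES.index[:n])
    return tuple(f"D{k:02d}" for k in range(1, n + 1))


def _covariates(labels: Sequence[str], rng: np.random.Generator) -> pd.DataFrame:
    rows = {}
    for lbl in labels:
        if lbl in CORE_GROUP_COVARIATES.index:
            rows[lbl] = CORE_GROUP_COVARIATES.loc[lbl]
        else:
            rows[lbl] = pd.Series(
                {
                    "age_months": round(rng.uniform(*_AGE_RANGE), 1),
                    "weight_kg": round(rng.uniform(*_WEIGHT_RANGE), 1),
                }
            )
    return pd.DataFrame(rows).T[["age_months", "weight_kg"]]


def generate_matrix(cfg: GeneratorConfig) -> tuple[Sociomatrix, LatentGroup]:
    """Draw one sociomatrix from the latent-hierarchy model.

    Per dyad: silent with probability ``zero_inflation``; otherwise the
    interaction total is Poisson(lambda) clamped to at least
    ``min_interactions`` and the wins of the higher-ranked member are
    Binomial(total, p_win).  Reproducible for equal seeds.
    """
    rng = np.random.default_rng(cfg.seed)
    labels = cfg.labels or _default_labels(cfg.n)
    ranks = np.arange(1, cfg.n + 1)  # label order = latent order
    counts = np.zeros((cfg.n, cfg.n), dtype=np.int64)
    for i in range(cfg.n):
        for j in range(i + 1, cfg.n):
            if rng.random() < cfg.zero_inflation:
                continue
            total = max(int(rng.poisson(cfg.lam)), cfg.min_interactions)
            p_win = 1.0 / (1.0 + np.exp(-cfg.beta * (ranks[j] - ranks[i])))
            wins = rng.binomial(total, p_win)
            counts[i, j] = wins
            counts[j, i] = total - wins
    group = LatentGroup(tuple(labels), tuple(int(r) for r in ranks),
                        _covariates(labels, rng))
    matrix = Sociomatrix(tuple(labels), counts, "synthetic-dominance")
    return matrix, group


# ---------------------------------------------------------------------------
# Interaction-log synthesis
# ---------------------------------------------------------------------------

def _lop_record(ts: int, submitter: str, receiver: str, context: str,
                rng: np.random.Generator) -> InteractionRecord:
    """A record that the event coder classifies as exactly one LoP event."""
    start = rng.choice(["neutral", "half-high", "high"])
    end = rng.choice(["half-low", "low", "low-on-back"])
    if context == "spontaneous":
        return InteractionRecord(
            timestamp=ts, actor_id=submitter, recipient_id=receiver,
            posture_start_actor=start, posture_end_actor=end,
            posture_start_recipient="neutral", posture_end_recipient="neutral",
        )
    if context == "agonistic":
        return InteractionRecord(
            timestamp=ts, actor_id=submitter, recipient_id=receiver,
            posture_start_actor=start, posture_end_actor=end,
            posture_start_recipient="high", posture_end_recipient="high",
            behaviours_recipient=frozenset({rng.choice(["growl", "stare", "snap"])}),
        )
    if context == "competitive":
        return InteractionRecord(
            timestamp=ts, actor_id=submitter, recipient_id=receiver,
            posture_start_actor=start, posture_end_actor=end,
            posture_start_recipient="neutral", posture_end_recipient="neutral",
            resource_context=True, resource_controller_posture="neutral",
        )
    raise ValueError(f"unknown context {context!r}")


def _distractor_record(ts: int, a: str, b: str,
                       rng: np.random.Generator) -> InteractionRecord:
    """A record carrying no lowering-of-posture event."""
    kind = rng.integers(3)
    if kind == 0:  # plain approach, both neutral throughout
        return InteractionRecord(
            timestamp=ts, actor_id=a, recipient_id=b,
            behaviours_actor=frozenset({"approach"}),
        )
    if kind == 1:  # posture rises — the opposite of a LoP
        return InteractionRecord(
            timestamp=ts, actor_id=a, recipient_id=b,
            posture_start_actor="neutral", posture_end_actor="high",
            behaviours_actor=frozenset({"tail wag"}),
        )
    # friendly exchange, no posture change, no aggression
    return InteractionRecord(
        timestamp=ts, actor_id=a, recipient_id=b,
        posture_start_actor="half-high", posture_end_actor="half-high",
        behaviours_actor=frozenset({"tail wag"}),
        behaviours_recipient=frozenset({"approach"}),
    )


def generate_interaction_log(
    target_lop: Sociomatrix,
    context_mix: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
    seed: Optional[int] = None,
    distractor_fraction: float = 0.1,
) -> list[InteractionRecord]:
    """Interaction records whose LoP coding reproduces ``target_lop`` exactly.

    For every cell (i, j) the log contains counts[i, j] records each coded
    as one LoP event i -> j, with contexts drawn multinomially from
    ``context_mix`` (spontaneous, agonistic, competitive); seeded
    distractor records that code to no event are interleaved.
    """
    mix = np.asarray(context_mix, dtype=float)
    if mix.shape != (3,) or (mix < 0).any() or not np.isclose(mix.sum(), 1.0):
        raise ValueError("context_mix must be 3 nonnegative proportions summing to 1")
    rng = np.random.default_rng(seed)
    contexts = np.array(["spontaneous", "agonistic", "competitive"])
    labels = target_lop.labels

    records: list[InteractionRecord] = []
    ts = 0
    for i in range(target_lop.n):
        for j in range(target_lop.n):
            for _ in range(int(target_lop.counts[i, j])):
                ctx = str(rng.choice(contexts, p=mix))
                rec = _lop_record(ts, labels[i], labels[j], ctx, rng)
                records.append(rec)
                ts += 1
    n_distract = int(round(distractor_fraction * len(records)))
    for _ in range(n_distract):
        a, b = rng.choice(target_lop.n, size=2, replace=False)
        rec = _distractor_record(ts, labels[a], labels[b], rng)
        assert not detect_lop(rec), "distractor produced a LoP event"
        records.append(rec)
        ts += 1
    # Shuffle event order, then renumber timestamps so they are ascending.
    order = rng.permutation(len(records))
    shuffled = [records[k] for k in order]
    from dataclasses import replace as _replace

    return [_replace(rec, timestamp=k) for k, rec in enumerate(shuffled)]
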