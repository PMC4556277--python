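"""Square actor-by-recipient count matrices (sociomatrices).

A sociomatrix holds directed interaction counts: ``counts[i, j]`` is the
number of times individual ``labels[i]`` directed the variable at
``labels[j]``.  The diagonal is structurally zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .ethogram import BEHAVIOURS, InteractionRecord, POSTURES, detect_lop

__all__ = [
    "Sociomatrix",
    "SociomatrixError",
    "accumulate_matrix",
    "combine_matrices",
    "transpose_submission",
]

logger = logging.getLogger(__name__)


class SociomatrixError(ValueError):
    """Raised on malformed sociomatrix input (non-square, negative, ...)."""


@dataclass(frozen=True)
class Sociomatrix:
    labels: tuple[str, ...]
    counts: np.ndarray
    variable_name: str = ""
    window: str = ""
    transposed: bool = False

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise SociomatrixError(f"counts must be square, got shape {counts.shape}")
        if len(labels) != counts.shape[0]:
            raise SociomatrixError(
                f"{len(labels)} labels for a {counts.shape[0]}x{counts.shape[1]} matrix"
            )
        if len(set(labels)) != len(labels):
            raise SociomatrixError("labels must be unique")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded, atol=1e-9):
                raise SociomatrixError("counts must be integers")
            counts = rounded.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise SociomatrixError("counts must be nonnegative")
        if np.diag(counts).any():
            raise SociomatrixError("diagonal must be zero")
        counts = counts.copy()
        counts.flags.writeable = False
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "counts", counts)

    # -- basic queries -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def n_dyads(self) -> int:
        return self.n * (self.n - 1) // 2

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    # -- derived matrices ----------------------------------------------
    def transpose(self) -> "Sociomatrix":
        """Mirror around the diagonal (submission -> dominance direction)."""
        name = self.variable_name + " (transposed)" if self.variable_name else ""
        return Sociomatrix(
            self.labels, self.counts.T.copy(), name, self.window,
            transposed=not self.transposed,
        )

    def permute(self, order: Sequence[str]) -> "Sociomatrix":
        """Reorder rows and columns simultaneously to ``order``."""
        if sorted(order) != sorted(self.labels):
            raise SociomatrixError("order must be a permutation of the labels")
        idx = [self.index_of(lbl) for lbl in order]
        return replace(self, labels=tuple(order),
                       counts=self.counts[np.ix_(idx, idx)])

    def __add__(self, other: "Sociomatrix") -> "Sociomatrix":
        return combine_matrices(self, other)

    # -- pandas bridge ---------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels),
                            columns=list(self.labels))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, variable_name: str = "",
                       window: str = "") -> "Sociomatrix":
        if list(df.index) != list(df.columns):
            raise SociomatrixError("row and column labels must match")
        return cls(tuple(str(x) for x in df.index), df.to_numpy(),
                   variable_name, window)


def combine_matrices(a: Sociomatrix, b: Sociomatrix) -> Sociomatrix:
    """Elementwise sum of two sociomatrices over the same group and window."""
    if a.labels != b.labels:
        raise SociomatrixError("matrices must share identical labels")
    if a.window != b.window:
        raise SociomatrixError("matrices must share the same window")
    name = "+".join(x for x in (a.variable_name, b.variable_name) if x)
    return Sociomatrix(a.labels, a.counts + b.counts, name, a.window)


def transpose_submission(m: Sociomatrix) -> Sociomatrix:
    """Transpose a submission-variable matrix so rows mean dominance."""
    return m.transpose()


def _qualifying_events(record: InteractionRecord, variable: str):
    """Yield (source, target) pairs for one record under one variable.

    * ``"lop"`` — lowering-of-posture events (submitter -> receiver);
    * a posture label — each participant that displays the posture at the
      start or end of the interaction (one event per participant);
    * a behaviour label — each participant whose behaviour set contains it.
    """
    def canon(label):
        return "back" if label == "on-back" else label

    if variable == "lop":
        for ev in detect_lop(record):
            yield ev.submitter_id, ev.receiver_id
    elif canon(variable) in POSTURES:
        variable = canon(variable)
        start_a = canon(record.posture_start_actor)
        end_a = canon(record.posture_end_actor or record.posture_start_actor)
        start_r = canon(record.posture_start_recipient)
        end_r = canon(record.posture_end_recipient or record.posture_start_recipient)
        if variable in (start_a, end_a):
            yield record.actor_id, record.recipient_id
        if variable in (start_r, end_r):
            yield record.recipient_id, record.actor_id
    elif variable in BEHAVIOURS:
        if variable in record.behaviours_actor:
            yield record.actor_id, record.recipient_id
        if variable in record.behaviours_recipient:
            yield record.recipient_id, record.actor_id
    else:
        raise SociomatrixError(
            f"unknown variable {variable!r}: expected 'lop', a posture or a behaviour"
        )


def accumulate_matrix(
    records: Iterable[InteractionRecord],
    variable: str,
    roster: Sequence[str],
    window: Optional[tuple[int, int]] = None,
) -> Sociomatrix:
    """Accumulate a per-variable sociomatrix from an interaction log.

    Parameters
    ----------
    records : iterable of InteractionRecord
    variable : "lop", a posture label, or a behaviour label
    roster : the individuals to keep; records involving others are dropped
    window : optional half-open ``[start, end)`` timestamp interval

    Every behavioural variable is treated as a point event: ``counts[i, j]``
    is the number of qualifying events by ``i`` directed at ``j``.
    """
    roster = list(roster)
    if not roster:
        raise SociomatrixError("roster must not be empty")
    if len(set(roster)) != len(roster):
        raise SociomatrixError("roster labels must be unique")
    idx = {lbl: k for k, lbl in enumerate(roster)}
    counts = np.zeros((len(roster), len(roster)), dtype=np.int64)
    any_in_window = False
    for record in records:
        if window is not None and not (window[0] <= record.timestamp < window[1]):
            continue
        any_in_window = True
        if record.actor_id not in idx or record.recipient_id not in idx:
            continue
        for src, dst in _qualifying_events(record, variable):
            counts[idx[src], idx[dst]] += 1
    if not any_in_window:
        logger.warning(
            "window %s excludes all records for variable %r; matrix is all-zero",
            window, variable,
        )
    win = f"{window[0]}-{window[1]}" if window is not None else ""
    return Sociomatrix(tuple(roster), counts, variable, win)
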