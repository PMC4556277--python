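"""CSV and config file I/O.

Sociomatrix CSV: first row and first column carry the individual labels,
cells are integer counts, the diagonal is written as 0.

Interaction-log CSV columns: time, actor, recipient, actor_posture_start,
actor_posture_end, recipient_posture_start, recipient_posture_end,
actor_behaviours (semicolon-joined), recipient_behaviours,
resource_context (0/1), resource_controller_posture, sampling.
"""

from __future__ import annotations

import os
from typing import Iterable, Union

import pandas as pd
import yaml

from .ethogram import InteractionRecord
from .sociomatrix import Sociomatrix, SociomatrixError

__all__ = [
    "read_sociomatrix",
    "write_sociomatrix",
    "read_interaction_log",
    "write_interaction_log",
    "load_config",
]

PathLike = Union[str, os.PathLike]

LOG_COLUMNS = [
    "time", "actor", "recipient",
    "actor_posture_start", "actor_posture_end",
    "recipient_posture_start", "recipient_posture_end",
    "actor_behaviours", "recipient_behaviours",
    "resource_context", "resource_controller_posture", "sampling",
]


def read_sociomatrix(path: PathLike, variable_name: str = "") -> Sociomatrix:
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise SociomatrixError(
            f"{path}: matrix is {df.shape[0]}x{df.shape[1]}, expected square; "
            f"first offending row label: {df.index[min(df.shape)] if df.shape[0] > df.shape[1] else df.columns[min(df.shape)]!r}"
        )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise SociomatrixError(f"{path}: row labels do not match column labels")
    name = variable_name or os.path.splitext(os.path.basename(path))[0]
    return Sociomatrix.from_dataframe(df, variable_name=name)


def write_sociomatrix(m: Sociomatrix, path: PathLike) -> None:
    m.to_dataframe().to_csv(path)


def _split_behaviours(cell) -> frozenset[str]:
    if pd.isna(cell) or cell == "":
        return frozenset()
    return frozenset(b.strip() for b in str(cell).split(";") if b.strip())


def read_interaction_log(path: PathLike) -> list[InteractionRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise SociomatrixError(f"{path}: missing log columns {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(
            InteractionRecord(
                timestamp=int(row["time"]),
                actor_id=row["actor"],
                recipient_id=row["recipient"],
                posture_start_actor=row["actor_posture_start"] or "neutral",
                posture_end_actor=row["actor_posture_end"] or None,
                posture_start_recipient=row["recipient_posture_start"] or "neutral",
                posture_end_recipient=row["recipient_posture_end"] or None,
                behaviours_actor=_split_behaviours(row["actor_behaviours"]),
                behaviours_recipient=_split_behaviours(row["recipient_behaviours"]),
                resource_context=row["resource_context"] in ("1", "true", "True"),
                resource_controller_posture=(
                    row["resource_controller_posture"] or None
                ),
                sampling=row["sampling"] or "focal",
            )
        )
    return records


def write_interaction_log(records: Iterable[InteractionRecord],
                          path: PathLike) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "time": r.timestamp,
                "actor": r.actor_id,
                "recipient": r.recipient_id,
                "actor_posture_start": r.posture_start_actor,
                "actor_posture_end": r.posture_end_actor or "",
                "recipient_posture_start": r.posture_start_recipient,
                "recipient_posture_end": r.posture_end_recipient or "",
                "actor_behaviours": ";".join(sorted(r.behaviours_actor)),
                "recipient_behaviours": ";".join(sorted(r.behaviours_recipient)),
                "resource_context": int(r.resource_context),
                "resource_controller_posture": r.resource_controller_posture or "",
                "sampling": r.sampling,
            }
        )
    pd.DataFrame(rows, columns=LOG_COLUMNS).to_csv(path, index=False)


def load_config(path: PathLike) -> dict:
    """Load a flat key-value (YAML) analysis config."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
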