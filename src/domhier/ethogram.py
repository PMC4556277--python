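"""Ethogram coding for dyadic dog-dog interactions.

The postural ethogram distinguishes 7 postures ordered by height (high,
half-high, neutral, half-low, low) plus two lying variants (back at neutral
height, low-on-back at low height).  The behavioural ethogram lists 24
elements, of which 12 are flagged aggressive and 10 are flagged as
fear/submission/avoidance signals.

A *Lowering of Posture* (LoP) event is a within-interaction change of
postural display into one of the lowered postures (half-low, low,
low-on-back, or on-back), scored in one of three contexts:

* spontaneous — the dog lowers while its partner shows no aggression;
* agonistic — the dog lowers in reaction to the partner's aggressive
  behaviour, or, if already low, starts signalling fear/submission;
* competitive — the dog lowers during a contest over an object, bone or
  feeding place.

When several context clauses match a single record, agonistic takes
precedence over competitive, which takes precedence over spontaneous:
"spontaneous" is defined by the absence of partner aggression, and the
competitive context requires the explicit resource flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, NamedTuple, Optional

__all__ = [
    "Posture",
    "POSTURES",
    "LOP_TARGET_POSTURES",
    "BEHAVIOURS",
    "AGGRESSIVE_BEHAVIOURS",
    "FEAR_SUBMISSION_BEHAVIOURS",
    "InteractionRecord",
    "LoPEvent",
    "EthogramError",
    "normalize_behaviour",
    "detect_lop",
]


class EthogramError(ValueError):
    """Raised when a record refers to an unknown posture or behaviour label."""


class Posture(NamedTuple):
    label: str
    height_level: int  # 5 = high ... 1 = low; lying variants keep the height
    lying: bool


POSTURES: dict[str, Posture] = {
    "high": Posture("high", 5, False),
    "half-high": Posture("half-high", 4, False),
    "neutral": Posture("neutral", 3, False),
    "back": Posture("back", 3, True),
    "half-low": Posture("half-low", 2, False),
    "low": Posture("low", 1, False),
    "low-on-back": Posture("low-on-back", 1, True),
}

# "on-back" appears as a synonym of the lying-at-neutral posture in the
# results tables; both names resolve to the same entity.
_POSTURE_ALIASES = {"on-back": "back"}

# Postures that qualify as the target of a lowering-of-posture display.
# "back" is included explicitly even though its height equals neutral:
# lowering into a lying position counts (flagged for audit, see LoPEvent).
LOP_TARGET_POSTURES: FrozenSet[str] = frozenset(
    {"half-low", "low", "low-on-back", "back"}
)

AGGRESSIVE_BEHAVIOURS: FrozenSet[str] = frozenset(
    {
        "stare",
        "pilo-erection",
        "growl",
        "show teeth",
        "snap",
        "lunge",
        "bite",
        "muzzle bite",
        "fight",
        "stand over",
        "chase",
        "bark",
    }
)

FEAR_SUBMISSION_BEHAVIOURS: FrozenSet[str] = frozenset(
    {
        "tongue flick",
        "freeze",
        "look away",
        "body tail wag",
        "mouth lick",
        "pass under head",
        "high pitch vocalisations",
        "flee",
        "retreat",
        "shrink back",
    }
)

# The 24-element behavioural ethogram.  "chase" and "high pitch
# vocalisations" are not among the 24 but occur in the context rule lists;
# they are accepted as valid labels carrying the appropriate flag.
BEHAVIOURS: FrozenSet[str] = frozenset(
    {
        "mouth lick",
        "body tail wag",
        "pass under head",
        "stare",
        "pilo-erection",
        "growl",
        "show teeth",
        "snap",
        "lunge",
        "bite",
        "fight",
        "shrink back",
        "retreat",
        "flee",
        "stand over",
        "muzzle bite",
        "tongue flick",
        "look away",
        "freeze",
        "approach",
        "take away object",
        "bark",
        "tail wag",
        "paw on",
    }
)

_EXTRA_BEHAVIOURS: FrozenSet[str] = frozenset({"chase", "high pitch vocalisations"})
_BEHAVIOUR_ALIASES = {"lick mouth": "mouth lick"}

_VALID_BEHAVIOURS = BEHAVIOURS | _EXTRA_BEHAVIOURS


def normalize_behaviour(label: str) -> str:
    """Resolve aliases and validate a behaviour label."""
    label = _BEHAVIOUR_ALIASES.get(label, label)
    if label not in _VALID_BEHAVIOURS:
        raise EthogramError(f"unknown behaviour label: {label!r}")
    return label


def _resolve_posture(label: Optional[str]) -> Optional[Posture]:
    if label is None or label == "":
        return None
    label = _POSTURE_ALIASES.get(label, label)
    if label not in POSTURES:
        raise EthogramError(f"unknown posture label: {label!r}")
    return POSTURES[label]


@dataclass(frozen=True)
class InteractionRecord:
    """One coded dyadic interaction.

    Missing end postures inherit the start posture (no change); behaviour
    sets default to empty.  Timestamps are opaque ordinals.
    """

    timestamp: int
    actor_id: str
    recipient_id: str
    posture_start_actor: str = "neutral"
    posture_end_actor: Optional[str] = None
    posture_start_recipient: str = "neutral"
    posture_end_recipient: Optional[str] = None
    behaviours_actor: FrozenSet[str] = field(default_factory=frozenset)
    behaviours_recipient: FrozenSet[str] = field(default_factory=frozenset)
    resource_context: bool = False
    resource_controller_posture: Optional[str] = None
    sampling: str = "focal"

    def __post_init__(self) -> None:
        if self.actor_id == self.recipient_id:
            raise EthogramError(
                f"actor and recipient must differ (both {self.actor_id!r})"
            )
        object.__setattr__(
            self, "behaviours_actor",
            frozenset(normalize_behaviour(b) for b in self.behaviours_actor),
        )
        object.__setattr__(
            self, "behaviours_recipient",
            frozenset(normalize_behaviour(b) for b in self.behaviours_recipient),
        )
        # Validate posture labels eagerly so malformed records fail on entry.
        for lbl in (
            self.posture_start_actor,
            self.posture_end_actor,
            self.posture_start_recipient,
            self.posture_end_recipient,
            self.resource_controller_posture,
        ):
            _resolve_posture(lbl)


@dataclass(frozen=True)
class LoPEvent:
    """A lowering-of-posture display by ``submitter_id`` toward ``receiver_id``."""

    submitter_id: str
    receiver_id: str
    context: str  # spontaneous | agonistic | competitive
    source_record: InteractionRecord
    lying_transition: bool = False  # neutral->back special case, for audit


def _participant_view(record: InteractionRecord, role: str):
    if role == "actor":
        return (
            record.actor_id,
            record.recipient_id,
            _resolve_posture(record.posture_start_actor),
            _resolve_posture(record.posture_end_actor),
            record.behaviours_actor,
            record.behaviours_recipient,
        )
    return (
        record.recipient_id,
        record.actor_id,
        _resolve_posture(record.posture_start_recipient),
        _resolve_posture(record.posture_end_recipient),
        record.behaviours_recipient,
        record.behaviours_actor,
    )


def _lowers_into_target(start: Posture, end: Optional[Posture]) -> tuple[bool, bool]:
    """Did the dog lower its display into a LoP target posture?

    Returns (lowered, lying_transition).  The lying transition covers the
    level-equal neutral->back case, which counts as a lowering because the
    target list names on-back explicitly.
    """
    if end is None:
        return False, False
    if end.label not in LOP_TARGET_POSTURES:
        return False, False
    if end.height_level < start.height_level:
        return True, end.lying and not start.lying
    if end.lying and not start.lying and end.height_level <= start.height_level:
        return True, True
    return False, False


def detect_lop(record: InteractionRecord) -> list[LoPEvent]:
    """Classify lowering-of-posture events in one interaction record.

    Each participant is evaluated symmetrically; at most one event is
    emitted per participant.  Context precedence: agonistic > competitive >
    spontaneous.
    """
    events: list[LoPEvent] = []
    for role in ("actor", "recipient"):
        me, other, start, end, my_beh, other_beh = _participant_view(record, role)
        if end is None:
            end = start  # no change recorded
        lowered, lying = _lowers_into_target(start, end)
        other_aggressive = bool(other_beh & AGGRESSIVE_BEHAVIOURS)
        already_low = start.label in LOP_TARGET_POSTURES
        signals_fear = bool(my_beh & FEAR_SUBMISSION_BEHAVIOURS)

        context: Optional[str] = None
        if other_aggressive and (lowered or (already_low and signals_fear)):
            context = "agonistic"
        elif record.resource_context and lowered:
            # Both competitive clauses (lowering toward the contestant;
            # lowering while the controller holds neutral-or-higher) require
            # the dog itself to lower, so the resource flag plus a lowering
            # suffices; the controller posture is retained for audit only.
            context = "competitive"
        elif lowered and not other_aggressive:
            context = "spontaneous"

        if context is not None:
            events.append(
                LoPEvent(
                    submitter_id=me,
                    receiver_id=other,
                    context=context,
                    source_record=record,
                    lying_transition=lying,
                )
            )
    return events


def iter_lop_events(records: Iterable[InteractionRecord]) -> Iterable[LoPEvent]:
    for record in records:
        yield from detect_lop(record)
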