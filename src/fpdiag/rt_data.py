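"""Trial-level response-time data: domain types, CSV interchange, temporal thirds.

The universal input to every stage of the pipeline is a long-format table of
trials, one row per trial, with a participant identifier, a condition label,
block and trial positions, the response time in milliseconds, and a flag
marking whether the participant responded before the deadline.  Trials on
which the deadline lapsed ("too slow") are retained but excluded from every
RT pool downstream.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

#: Default CSV column names; a schema mapping may rename any of them.
DEFAULT_SCHEMA: dict[str, str] = {
    "participant": "participant",
    "condition": "condition",
    "block": "block",
    "trial": "trial",
    "rt_ms": "rt_ms",
    "responded": "responded",
}

_TRUTHY = {"true", "1", "t", "yes"}
_FALSY = {"false", "0", "f", "no"}


class TemporalPart(enum.Enum):
    """Thirds of a participant's session, by rank of global trial index."""

    BEGINNING = "beginning"
    MIDDLE = "middle"
    END = "end"


@dataclass(frozen=True)
class Trial:
    """One trial of a two-condition RT experiment.

    ``rt_ms`` is meaningful only when ``responded`` is true; non-responded
    trials carry ``rt_ms = nan`` and never enter an RT pool.
    """

    participant_id: str
    condition: str
    block_index: int
    trial_index: int
    rt_ms: float
    responded: bool = True

    def __post_init__(self) -> None:
        if self.responded:
            if not np.isfinite(self.rt_ms) or self.rt_ms <= 0:
                raise ValidationError(
                    f"responded trial {self.trial_index} of participant "
                    f"{self.participant_id!r} has non-positive rt_ms={self.rt_ms}"
                )
        if self.block_index < 1 or self.trial_index < 1:
            raise ValidationError("block_index and trial_index must be >= 1")


@dataclass
class TrialTable:
    """A collection of trials plus the response deadline.

    Invariants checked at construction: unique trial_index per participant,
    and every responded RT within (0, deadline_ms].
    """

    trials: list[Trial]
    deadline_ms: float = 6500.0

    def __post_init__(self) -> None:
        if self.deadline_ms <= 0:
            raise ValidationError("deadline_ms must be positive")
        seen: dict[str, set[int]] = {}
        for t in self.trials:
            idx = seen.setdefault(t.participant_id, set())
            if t.trial_index in idx:
                raise ValidationError(
                    f"duplicate trial_index {t.trial_index} for participant {t.participant_id!r}"
                )
            idx.add(t.trial_index)
            if t.responded and t.rt_ms > self.deadline_ms:
                raise ValidationError(
                    f"rt_ms={t.rt_ms} exceeds deadline {self.deadline_ms} "
                    f"(participant {t.participant_id!r}, trial {t.trial_index})"
                )

    @property
    def participants(self) -> list[str]:
        """Participant identifiers in first-appearance order."""
        out: list[str] = []
        seen: set[str] = set()
        for t in self.trials:
            if t.participant_id not in seen:
                seen.add(t.participant_id)
                out.append(t.participant_id)
        return out

    @property
    def conditions(self) -> list[str]:
        out: list[str] = []
        seen: set[str] = set()
        for t in self.trials:
            if t.condition not in seen:
                seen.add(t.condition)
                out.append(t.condition)
        return out

    def responded_trials(self, participant: str, condition: str | None = None) -> list[Trial]:
        """Responded trials of one participant, optionally restricted to a condition."""
        return [
            t
            for t in self.trials
            if t.participant_id == participant
            and t.responded
            and (condition is None or t.condition == condition)
        ]

    def rts(self, participant: str, condition: str | None = None) -> np.ndarray:
        """RTs (ms) of a participant's responded trials, in trial order."""
        ts = sorted(self.responded_trials(participant, condition), key=lambda t: t.trial_index)
        return np.array([t.rt_ms for t in ts], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame with the default column names."""
        return pd.DataFrame(
            {
                "participant": [t.participant_id for t in self.trials],
                "condition": [t.condition for t in self.trials],
                "block": [t.block_index for t in self.trials],
                "trial": [t.trial_index for t in self.trials],
                "rt_ms": [t.rt_ms if t.responded else np.nan for t in self.trials],
                "responded": [t.responded for t in self.trials],
            }
        )


def _parse_responded(value: object, row: int) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValidationError(f"row {row}: cannot interpret responded={value!r} as a boolean")


def read_trials(
    path,
    schema: Mapping[str, str] | None = None,
    deadline_ms: float = 6500.0,
) -> TrialTable:
    """Read a long-format trial CSV into a validated :class:`TrialTable`.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Optional mapping from canonical field names (``participant``,
        ``condition``, ``block``, ``trial``, ``rt_ms``, ``responded``) to the
        column names actually used in the file.  Missing entries fall back to
        the canonical names.  The ``responded`` column itself may be absent
        from the file, in which case all trials are treated as responded.
    deadline_ms
        Response deadline; responded RTs must not exceed it.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path, float_precision="round_trip")
    for key in ("participant", "condition", "block", "trial", "rt_ms"):
        if colmap[key] not in df.columns:
            raise SchemaError(f"missing required column {colmap[key]!r} (field {key!r})")
    has_resp = colmap["responded"] in df.columns

    trials: list[Trial] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        responded = _parse_responded(rec[colmap["responded"]], i) if has_resp else True
        rt_raw = rec[colmap["rt_ms"]]
        if responded:
            try:
                rt = float(rt_raw)
            except (TypeError, ValueError):
                raise SchemaError(f"row {i}: rt_ms value {rt_raw!r} is not a number") from None
            if not np.isfinite(rt) or rt <= 0:
                raise ValidationError(f"row {i}: responded trial has non-positive rt_ms={rt_raw!r}")
        else:
            rt = np.nan
        trials.append(
            Trial(
                participant_id=str(rec[colmap["participant"]]),
                condition=str(rec[colmap["condition"]]),
                block_index=int(rec[colmap["block"]]),
                trial_index=int(rec[colmap["trial"]]),
                rt_ms=rt,
                responded=responded,
            )
        )
    return TrialTable(trials=trials, deadline_ms=deadline_ms)


def write_trials(table: TrialTable, path, schema: Mapping[str, str] | None = None) -> None:
    """Write a :class:`TrialTable` as CSV (inverse of :func:`read_trials`)."""
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    df = table.to_frame().rename(columns=colmap)
    df[colmap["responded"]] = df[colmap["responded"]].map(lambda b: "true" if b else "false")
    # shortest round-trip representation so write → read is bit-exact
    df[colmap["rt_ms"]] = df[colmap["rt_ms"]].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    df.to_csv(path, index=False)


def split_into_parts(table: TrialTable, participant: str) -> dict[TemporalPart, list[Trial]]:
    """Partition a participant's responded trials into temporal thirds.

    Thirds are contiguous in ``trial_index`` rank over responded trials only;
    when the count is not divisible by three, the earliest part(s) receive the
    remainder, so sizes never differ by more than one.
    """
    if participant not in table.participants:
        raise KeyError(f"unknown participant {participant!r}")
    ts = sorted(table.responded_trials(participant), key=lambda t: t.trial_index)
    n = len(ts)
    if n < 3:
        raise ValidationError(
            f"participant {participant!r} has only {n} responded trials; need >= 3 to form thirds"
        )
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    parts: dict[TemporalPart, list[Trial]] = {}
    start = 0
    for part, size in zip(TemporalPart, sizes):
        parts[part] = ts[start : start + size]
        start += size
    return parts
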