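"""Season data model: players, events, workload records, injuries.

The central object is the Footballer Workload Footprint (FWF): for one
player, a variables x events matrix whose entry (i, j) is the value of
external-workload variable v_i recorded at season event e_j.  Events are
anything that produces load — training sessions and matches — indexed
0..#E-1 in chronological order; calendar dates are carried as metadata
only, since every downstream operator works on event counts.

Microcycle structure is encoded as a match-day offset per event: 0 on a
match day (MD), -1 on the last training before the match (MD-1), and so
on.  MD-1 is the prediction time point of the whole framework: injury
labels observed on match day are shifted back onto the MD-1 event so a
model can be asked "will this player get injured tomorrow?".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date as _date

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CalendarEvent",
    "SeasonCalendar",
    "PlayerRoster",
    "WorkloadRecord",
    "InjuryReport",
    "InjuryVector",
    "FWFMatrix",
    "SchemaError",
    "ValidationError",
    "load_workload_table",
    "load_injury_report",
    "records_to_frame",
    "build_fwf",
    "build_injury_vector",
    "shift_match_labels_to_md1",
    "participation_mask",
]


class SchemaError(ValueError):
    """Input table is missing a required column."""


class ValidationError(ValueError):
    """Input values violate a data-model invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalendarEvent:
    """One season event: a training session or a match."""

    event_index: int
    date: _date | None
    event_type: str  # "training" | "match"
    md_offset: int | None = None  # 0 = match day, -1 = MD-1, ...

    def __post_init__(self) -> None:
        if self.event_type not in ("training", "match"):
            raise ValidationError(
                f"event_type must be 'training' or 'match', got {self.event_type!r}"
            )
        if self.md_offset is not None and self.md_offset > 0:
            raise ValidationError(f"md_offset must be <= 0, got {self.md_offset}")


@dataclass
class SeasonCalendar:
    """Ordered, gap-free sequence of season events."""

    events: list[CalendarEvent]

    def __post_init__(self) -> None:
        idx = [e.event_index for e in self.events]
        if idx != list(range(len(idx))):
            raise ValidationError(
                "event indices must be 0-based, strictly increasing and gap-free"
            )
        dates = [e.date for e in self.events if e.date is not None]
        if any(b < a for a, b in zip(dates, dates[1:])):
            raise ValidationError("event dates must be non-decreasing")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def event_indices(self) -> list[int]:
        return [e.event_index for e in self.events]

    @property
    def match_indices(self) -> list[int]:
        return [e.event_index for e in self.events if e.event_type == "match"]

    def md1_for_match(self, match_index: int) -> int | None:
        """Event index of the MD-1 session immediately preceding a match.

        Returns None when the match has no tagged MD-1 predecessor (e.g.
        season opener, or congested fixture without a training day).
        """
        j = match_index - 1
        if j >= 0 and self.events[j].md_offset == -1:
            return j
        return None


@dataclass
class PlayerRoster:
    """Anonymized player identifiers f_k."""

    players: list[str]

    def __post_init__(self) -> None:
        if len(set(self.players)) != len(self.players):
            raise ValidationError("player identifiers must be unique")

    def __contains__(self, player: str) -> bool:
        return player in self.players

    def __len__(self) -> int:
        return len(self.players)

    def __iter__(self):
        return iter(self.players)


@dataclass(frozen=True)
class WorkloadRecord:
    """One observed value x_{v_i}(e_j) for one player."""

    player: str
    event_index: int
    variable: str
    value: float


@dataclass
class InjuryReport:
    """Injury occurrences keyed by (player, event)."""

    entries: list[tuple[str, int, str]]  # (player, event_index, injury_class)

    def labels_for(self, player: str) -> set[int]:
        return {j for (p, j, _c) in self.entries if p == player}


@dataclass
class InjuryVector:
    """Binary outcome sequence for one player, aligned to the calendar."""

    player: str
    labels: np.ndarray  # int {0,1}, length #E

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("injury labels must be binary")


@dataclass
class FWFMatrix:
    """Footballer Workload Footprint: variables x events matrix for one player.

    Under ``zero_fill`` every calendar event appears as a column and events
    the player did not take part in hold 0; under ``omit_event`` those
    columns are dropped, so ``event_indices`` records which events remain.
    """

    player: str
    variables: list[str]
    event_indices: list[int]
    values: np.ndarray  # shape (#V, #E)
    missing_policy: str = "zero_fill"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.variables), len(self.event_indices)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.variables)} variables x {len(self.event_indices)} events"
            )
        if not np.isfinite(self.values).all():
            raise ValidationError("FWF matrix values must be finite")
        if self.missing_policy not in ("zero_fill", "omit_event"):
            raise ValidationError(f"unknown missing_policy {self.missing_policy!r}")

    def series(self, variable: str) -> np.ndarray:
        """Per-event load series of one variable (a row of the footprint)."""
        try:
            i = self.variables.index(variable)
        except ValueError:
            raise KeyError(f"variable {variable!r} not in footprint") from None
        return self.values[i]

    def to_frame(self) -> pd.DataFrame:
        """Wide view: rows = variables, columns = event indices."""
        return pd.DataFrame(
            self.values, index=self.variables, columns=self.event_indices
        )


# ---------------------------------------------------------------------------
# loading / validation
# ---------------------------------------------------------------------------

_WORKLOAD_COLUMNS = ("player_id", "event_index", "event_type", "variable", "value")

DEFAULT_SCHEMA = {
    "player_id": "player_id",
    "event_index": "event_index",
    "date": "date",
    "event_type": "event_type",
    "md_offset": "md_offset",
    "variable": "variable",
    "value": "value",
}


def _validate_records_frame(df: pd.DataFrame) -> pd.DataFrame:
    neg = df.index[df["value"] < 0]
    if len(neg):
        raise ValidationError(
            f"negative workload value at row {neg[0]} "
            f"(player={df.loc[neg[0], 'player_id']!r}, "
            f"event={df.loc[neg[0], 'event_index']}, "
            f"variable={df.loc[neg[0], 'variable']!r})"
        )
    dup = df.duplicated(subset=["player_id", "event_index", "variable"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            "duplicate (player, event, variable) record: "
            f"({row['player_id']!r}, {row['event_index']}, {row['variable']!r})"
        )
    if not np.isfinite(df["value"]).all():
        raise ValidationError("workload values must be finite")
    return df


def load_workload_table(
    path,
    schema: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, SeasonCalendar, PlayerRoster]:
    """Load a long-format workload CSV.

    Expected columns (renameable via ``schema``, a mapping from canonical
    name to the file's column name): ``player_id, event_index, date,
    event_type, md_offset, variable, value``.  ``date`` and ``md_offset``
    are optional.

    Returns the validated records as a DataFrame (one row per
    player/event/variable observation) together with the reconstructed
    :class:`SeasonCalendar` and :class:`PlayerRoster`.
    """
    mapping = dict(DEFAULT_SCHEMA)
    if schema:
        mapping.update(schema)
    raw = pd.read_csv(path)
    rename = {v: k for k, v in mapping.items() if v in raw.columns}
    df = raw.rename(columns=rename)
    missing = [c for c in _WORKLOAD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"workload table is missing columns: {missing}")
    df = df.astype({"event_index": int, "value": float})
    df["player_id"] = df["player_id"].astype(str)
    _validate_records_frame(df)

    has_date = "date" in df.columns
    has_md = "md_offset" in df.columns
    events = []
    cal_cols = ["event_index", "event_type"] + (["date"] if has_date else []) + (
        ["md_offset"] if has_md else []
    )
    cal = df[cal_cols].drop_duplicates("event_index").sort_values("event_index")
    for _, row in cal.iterrows():
        events.append(
            CalendarEvent(
                event_index=int(row["event_index"]),
                date=pd.Timestamp(row["date"]).date() if has_date else None,
                event_type=str(row["event_type"]),
                md_offset=int(row["md_offset"]) if has_md and pd.notna(row["md_offset"]) else None,
            )
        )
    calendar = SeasonCalendar(events)
    roster = PlayerRoster(sorted(df["player_id"].unique().tolist()))
    records = df[["player_id", "event_index", "variable", "value"]].reset_index(drop=True)
    return records, calendar, roster


def load_injury_report(path, calendar: SeasonCalendar | None = None,
                       roster: PlayerRoster | None = None) -> InjuryReport:
    """Load an injury-report CSV (``player_id,event_index,injury_class``)."""
    df = pd.read_csv(path)
    missing = [c for c in ("player_id", "event_index") if c not in df.columns]
    if missing:
        raise SchemaError(f"injury report is missing columns: {missing}")
    if "injury_class" not in df.columns:
        df["injury_class"] = "unspecified"
    entries = [
        (str(p), int(j), str(c))
        for p, j, c in df[["player_id", "event_index", "injury_class"]].itertuples(index=False)
    ]
    report = InjuryReport(entries)
    if calendar is not None:
        valid = set(calendar.event_indices)
        for p, j, _c in entries:
            if j not in valid:
                raise ValidationError(f"injury entry references unknown event {j}")
    if roster is not None:
        for p, j, _c in entries:
            if p not in roster:
                raise ValidationError(f"injury entry references unknown player {p!r}")
    return report


def records_to_frame(records) -> pd.DataFrame:
    """Normalize records to the canonical DataFrame form.

    Accepts either the DataFrame produced by :func:`load_workload_table`
    or an iterable of :class:`WorkloadRecord`.
    """
    if isinstance(records, pd.DataFrame):
        return records
    rows = [(r.player, r.event_index, r.variable, r.value) for r in records]
    df = pd.DataFrame(rows, columns=["player_id", "event_index", "variable", "value"])
    return _validate_records_frame(df)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def participation_mask(records, calendar: SeasonCalendar, player: str) -> np.ndarray:
    """Boolean per-event participation: a player takes part in e_j iff at
    least one workload record exists for (player, e_j)."""
    df = records_to_frame(records)
    present = set(df.loc[df["player_id"] == player, "event_index"].unique())
    return np.array([j in present for j in calendar.event_indices])


def build_fwf(
    records,
    calendar: SeasonCalendar,
    player: str,
    variables: list[str] | None = None,
    missing_policy: str = "zero_fill",
) -> FWFMatrix:
    """Assemble the FWF matrix of one player from long-format records.

    ``zero_fill`` keeps every calendar event as a column, writing 0 where
    the player has no record (did not participate); ``omit_event`` drops
    non-participated events entirely, so column count varies by player.
    """
    df = records_to_frame(records)
    mine = df[df["player_id"] == player]
    if mine.empty:
        raise KeyError(f"player {player!r} has no workload records")
    if variables is None:
        variables = sorted(mine["variable"].unique().tolist())
    else:
        unknown = set(variables) - set(df["variable"].unique())
        if unknown:
            raise KeyError(f"unknown variables: {sorted(unknown)}")
    if not variables:
        raise ValidationError("variable set must be non-empty")

    wide = (
        mine[mine["variable"].isin(variables)]
        .pivot(index="variable", columns="event_index", values="value")
        .reindex(index=variables, columns=calendar.event_indices)
    )
    if missing_policy == "zero_fill":
        wide = wide.fillna(0.0)
        event_indices = calendar.event_indices
    elif missing_policy == "omit_event":
        mask = participation_mask(df, calendar, player)
        event_indices = [j for j, m in zip(calendar.event_indices, mask) if m]
        wide = wide[event_indices].fillna(0.0)
    else:
        raise ValidationError(f"unknown missing_policy {missing_policy!r}")
    return FWFMatrix(
        player=player,
        variables=list(variables),
        event_indices=list(event_indices),
        values=wide.to_numpy(dtype=float),
        missing_policy=missing_policy,
    )


def build_injury_vector(
    report: InjuryReport, calendar: SeasonCalendar, player: str
) -> InjuryVector:
    """Binary per-event outcome: labels[j] = 1 iff the player was injured
    at event e_j according to the report."""
    injured = report.labels_for(player)
    labels = np.array([1 if j in injured else 0 for j in calendar.event_indices])
    return InjuryVector(player=player, labels=labels)


def shift_match_labels_to_md1(
    vector: InjuryVector, calendar: SeasonCalendar
) -> InjuryVector:
    """Move match-day injury labels onto the preceding MD-1 event.

    The prediction question is asked the day before the match, so an
    injury realized on match day is treated as the outcome of the MD-1
    sample.  A match-day label with no tagged MD-1 predecessor is dropped
    with a warning (it cannot be associated with any pre-match sample).
    """
    labels = vector.labels.copy()
    for j in calendar.match_indices:
        if labels[j] == 1:
            md1 = calendar.md1_for_match(j)
            labels[j] = 0
            if md1 is None:
                logger.warning(
                    "injury at match event %d for player %s has no MD-1 "
                    "predecessor; label dropped",
                    j,
                    vector.player,
                )
            else:
                labels[md1] = 1
    return InjuryVector(player=vector.player, labels=labels)
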