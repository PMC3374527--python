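"""Response data model: participant profiles, reported activities, category
midpoint maps, and the study's response-level validity filters."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ParticipantProfile",
    "ResponseItem",
    "QuestionnaireResponse",
    "CategoryMap",
    "CategoryMapError",
    "ValidityFlag",
    "INCOMPLETE_LEISURE",
    "OVERFULL_DAY",
    "resolve_daily_hours",
    "validate_response",
    "apply_study_exclusions",
    "responses_to_table",
    "responses_from_table",
    "profiles_to_table",
    "profiles_from_table",
]

#: occupation pseudo-row marker used in the delimited response table
OCCUPATION_ROW = "occupation"

ValidityFlag = str
INCOMPLETE_LEISURE: ValidityFlag = "INCOMPLETE_LEISURE"
OVERFULL_DAY: ValidityFlag = "OVERFULL_DAY"


class CategoryMapError(KeyError):
    """Unknown frequency/duration label, or an invalid midpoint table."""


@dataclass(frozen=True)
class ParticipantProfile:
    participant_id: str
    sex: str
    age_years: int
    weight_kg: float
    height_cm: float | None = None
    education_years: str | None = None
    smoking: str | None = None
    snuff: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.age_years < 18:
            raise ValueError(f"adult questionnaire: age must be >= 18, got {self.age_years}")
        if not self.weight_kg > 0:
            raise ValueError(f"weight_kg must be positive, got {self.weight_kg}")


@dataclass(frozen=True)
class ResponseItem:
    """One reported activity with categorical frequency/duration answers.

    ``mean_daily_hours`` is derived by :func:`resolve_daily_hours`; it is
    ``None`` until resolved against a :class:`CategoryMap`.
    """

    activity_id: str
    frequency_category: str
    duration_category: str
    mean_daily_hours: float | None = None

    def __post_init__(self) -> None:
        if self.mean_daily_hours is not None and not (
            0 <= self.mean_daily_hours <= 24
        ):
            raise ValueError(
                f"mean_daily_hours must lie in [0, 24], got {self.mean_daily_hours}"
            )


@dataclass(frozen=True)
class QuestionnaireResponse:
    participant_id: str
    administration: str  # "I" or "II"
    occupation_effort_rank: int
    occupation_hours: float  # the one free-entry answer, h/d
    items: tuple[ResponseItem, ...] = ()
    overall_grade: int | None = None  # user-friendliness rating 1..5, optional

    def __post_init__(self) -> None:
        if self.administration not in ("I", "II"):
            raise ValueError(f"administration must be 'I' or 'II', got {self.administration!r}")
        if not 1 <= self.occupation_effort_rank <= 5:
            raise ValueError(
                f"occupation_effort_rank must be 1..5, got {self.occupation_effort_rank}"
            )
        if self.occupation_hours < 0:
            raise ValueError(f"occupation_hours must be >= 0, got {self.occupation_hours}")
        seen: set[str] = set()
        for item in self.items:
            if item.activity_id in seen:
                raise ValueError(
                    f"activity {item.activity_id!r} reported more than once"
                )
            seen.add(item.activity_id)

    def total_reported_hours(self) -> float:
        """Occupation hours plus all resolved item hours."""
        extra = sum(i.mean_daily_hours or 0.0 for i in self.items)
        return self.occupation_hours + extra


@dataclass(frozen=True)
class CategoryMap:
    """Midpoint tables: frequency label -> occasions/week and duration
    label -> hours per occasion.  Midpoints must be positive and unique per
    table so answers can be rendered back from resolved hours."""

    frequency: Mapping[str, float]
    duration: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, table in (("frequency", self.frequency), ("duration", self.duration)):
            if not table:
                raise CategoryMapError(f"{name} table is empty")
            vals = list(table.values())
            if any(v <= 0 for v in vals):
                raise CategoryMapError(f"{name} midpoints must be > 0")
            if len(set(vals)) != len(vals):
                raise CategoryMapError(f"{name} midpoints must be unique (invertible)")

    def frequency_midpoint(self, label: str) -> float:
        try:
            return self.frequency[label]
        except KeyError:
            raise CategoryMapError(f"unknown frequency label {label!r}") from None

    def duration_midpoint(self, label: str) -> float:
        try:
            return self.duration[label]
        except KeyError:
            raise CategoryMapError(f"unknown duration label {label!r}") from None

    def nearest_duration(self, hours: float) -> str:
        """Label whose midpoint is closest to ``hours`` (used by simulators)."""
        return min(self.duration, key=lambda lab: abs(self.duration[lab] - hours))


def resolve_daily_hours(item: ResponseItem, category_map: CategoryMap) -> float:
    """Mean daily hours = (occasions/week midpoint x hours/occasion midpoint) / 7."""
    freq = category_map.frequency_midpoint(item.frequency_category)
    dur = category_map.duration_midpoint(item.duration_category)
    return freq * dur / 7.0


def resolve_items(
    resp: QuestionnaireResponse, category_map: CategoryMap
) -> QuestionnaireResponse:
    """Return a copy of ``resp`` with every item's mean_daily_hours filled in."""
    items = tuple(
        replace(i, mean_daily_hours=resolve_daily_hours(i, category_map))
        for i in resp.items
    )
    return replace(resp, items=items)


def validate_response(
    resp: QuestionnaireResponse,
    catalog,
    category_map: CategoryMap | None = None,
) -> list[ValidityFlag]:
    """Response-level validity flags (not exceptions).

    INCOMPLETE_LEISURE — summed leisure-domain hours < 1 h/d;
    OVERFULL_DAY — total reported hours (occupation + items) > 24.
    """
    if category_map is not None:
        resp = resolve_items(resp, category_map)
    flags: list[ValidityFlag] = []
    leisure_hours = sum(
        (i.mean_daily_hours or 0.0)
        for i in resp.items
        if catalog.domain_of(i.activity_id) == "leisure"
    )
    if leisure_hours < 1.0:
        flags.append(INCOMPLETE_LEISURE)
    if resp.total_reported_hours() > 24.0:
        flags.append(OVERFULL_DAY)
    return flags


def apply_study_exclusions(roster: Sequence) -> list:
    """Retain roster records with all exclusion flags false, order preserved.

    Records may be mappings or objects exposing boolean attributes/keys
    ``illness``, ``incomplete_first_questionnaire`` and ``unreliable_dlw``.
    """
    def flagged(rec) -> bool:
        def get(name):
            if isinstance(rec, Mapping):
                return bool(rec.get(name, False))
            return bool(getattr(rec, name, False))

        return (
            get("illness")
            or get("incomplete_first_questionnaire")
            or get("unreliable_dlw")
        )

    return [rec for rec in roster if not flagged(rec)]


# ---------------------------------------------------------------------------
# Delimited-table IO.  One row per ResponseItem plus one occupation pseudo-row
# per response (activity_id == "occupation"; frequency_category carries the
# effort rank, duration_category the free-entry hours).

_RESPONSE_COLUMNS = [
    "participant_id",
    "administration",
    "activity_id",
    "frequency_category",
    "duration_category",
]


def responses_to_table(responses: Iterable[QuestionnaireResponse]) -> pd.DataFrame:
    rows = []
    for resp in responses:
        rows.append(
            {
                "participant_id": resp.participant_id,
                "administration": resp.administration,
                "activity_id": OCCUPATION_ROW,
                "frequency_category": str(resp.occupation_effort_rank),
                "duration_category": repr(float(resp.occupation_hours)),
            }
        )
        for item in resp.items:
            rows.append(
                {
                    "participant_id": resp.participant_id,
                    "administration": resp.administration,
                    "activity_id": item.activity_id,
                    "frequency_category": item.frequency_category,
                    "duration_category": item.duration_category,
                }
            )
    return pd.DataFrame(rows, columns=_RESPONSE_COLUMNS)


def responses_from_table(table: pd.DataFrame) -> list[QuestionnaireResponse]:
    missing = set(_RESPONSE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"response table missing columns {sorted(missing)}")
    out: list[QuestionnaireResponse] = []
    for (pid, admin), group in table.groupby(
        ["participant_id", "administration"], sort=False
    ):
        occ = group[group["activity_id"] == OCCUPATION_ROW]
        if len(occ) != 1:
            raise ValueError(
                f"response ({pid}, {admin}) must have exactly one occupation row, "
                f"found {len(occ)}"
            )
        items = tuple(
            ResponseItem(
                activity_id=row.activity_id,
                frequency_category=row.frequency_category,
                duration_category=row.duration_category,
            )
            for row in group[group["activity_id"] != OCCUPATION_ROW].itertuples()
        )
        out.append(
            QuestionnaireResponse(
                participant_id=str(pid),
                administration=str(admin),
                occupation_effort_rank=int(occ["frequency_category"].iloc[0]),
                occupation_hours=float(occ["duration_category"].iloc[0]),
                items=items,
            )
        )
    return out


def profiles_to_table(profiles: Iterable[ParticipantProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": p.participant_id,
                "sex": p.sex,
                "age_years": p.age_years,
                "weight_kg": p.weight_kg,
                "height_cm": p.height_cm,
            }
            for p in profiles
        ]
    )


def profiles_from_table(table: pd.DataFrame) -> list[ParticipantProfile]:
    return [
        ParticipantProfile(
            participant_id=str(row.participant_id),
            sex=str(row.sex),
            age_years=int(row.age_years),
            weight_kg=float(row.weight_kg),
            height_cm=float(row.height_cm) if pd.notna(row.height_cm) else None,
        )
        for row in table.itertuples()
    ]
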