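"""Energy-expenditure scoring.

Each reported activity contributes ``MET x weight (kg) x duration (h/d) x
4.184`` kJ/day (1 MET taken as 1 kcal.kg-1.h-1).  The crude total sums those
contributions; the 24-hour adjustment adds eight hours of sleep and a signed
filler block at MET 2.0 covering whatever time remains to (or exceeds) 24 h.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import pandas as pd

from .activity_catalog import DOMAINS, Catalog, lookup_met, occupation_met
from .config import ScoringConfig
from .questionnaire import (
    OVERFULL_DAY,
    CategoryMap,
    ParticipantProfile,
    QuestionnaireResponse,
    resolve_items,
    validate_response,
)

__all__ = ["EnergyProfile", "activity_ee", "score_response", "adjust_to_24h",
           "met_hours", "profiles_to_table"]

KCAL_TO_KJ = 4.184


def activity_ee(met: float, weight_kg: float, daily_hours: float) -> float:
    """kJ/day contributed by one activity."""
    if met <= 0:
        raise ValueError(f"met must be > 0, got {met}")
    if weight_kg <= 0:
        raise ValueError(f"weight_kg must be > 0, got {weight_kg}")
    if daily_hours < 0:
        raise ValueError(f"daily_hours must be >= 0, got {daily_hours}")
    return met * weight_kg * daily_hours * KCAL_TO_KJ


def _signed_ee(met: float, weight_kg: float, hours: float) -> float:
    # filler time may be negative (over-reported day); energy is signed
    return met * weight_kg * hours * KCAL_TO_KJ


@dataclass(frozen=True)
class EnergyProfile:
    """Scored energy expenditure for one participant-administration."""

    participant_id: str
    administration: str
    per_activity_kj: Mapping[str, float]
    per_domain_kj: Mapping[str, float]
    crude_total_kj: float
    crude_hours: float
    sleep_hours: float = 8.0
    sleep_met: float = 0.9
    filler_met: float = 2.0
    filler_hours: float | None = None
    adjusted_total_kj: float | None = None


def score_response(
    resp: QuestionnaireResponse,
    profile: ParticipantProfile,
    catalog: Catalog,
    category_map: CategoryMap,
    scoring: ScoringConfig | None = None,
) -> EnergyProfile:
    """Score one response into per-activity/per-domain/crude energy.

    The response must not over-fill the day (OVERFULL_DAY); an unknown
    activity raises a lookup error from the catalog.
    """
    scoring = scoring or ScoringConfig()
    resolved = resolve_items(resp, category_map)
    flags = validate_response(resolved, catalog)
    if OVERFULL_DAY in flags:
        raise ValueError(
            f"response ({resp.participant_id}, {resp.administration}) reports "
            f"{resolved.total_reported_hours():.2f} h > 24 h"
        )
    weight = profile.weight_kg

    per_activity: dict[str, float] = {}
    per_domain: dict[str, float] = {d: 0.0 for d in DOMAINS}

    occ_met = occupation_met(catalog, resp.occupation_effort_rank)
    occ_ee = activity_ee(occ_met, weight, resp.occupation_hours)
    per_activity["occupation"] = occ_ee
    per_domain["occupation"] = occ_ee

    for item in resolved.items:
        met = lookup_met(catalog, item.activity_id)
        ee = activity_ee(met, weight, item.mean_daily_hours)
        per_activity[item.activity_id] = ee
        per_domain[catalog.domain_of(item.activity_id)] += ee

    crude_total = sum(per_activity.values())
    return EnergyProfile(
        participant_id=resp.participant_id,
        administration=resp.administration,
        per_activity_kj=per_activity,
        per_domain_kj=per_domain,
        crude_total_kj=crude_total,
        crude_hours=resolved.total_reported_hours(),
        sleep_hours=scoring.sleep_hours,
        sleep_met=scoring.sleep_met,
        filler_met=scoring.filler_met,
    )


def adjust_to_24h(profile: EnergyProfile, weight_kg: float) -> EnergyProfile:
    """Fill the day to 24 h: sleep at ``sleep_met`` plus a signed MET-2.0
    filler; negative filler subtracts energy (over-reported day)."""
    if profile.crude_hours < 0:
        raise ValueError("crude_hours must be >= 0")
    filler_hours = 24.0 - profile.sleep_hours - profile.crude_hours
    adjusted = (
        profile.crude_total_kj
        + activity_ee(profile.sleep_met, weight_kg, profile.sleep_hours)
        + _signed_ee(profile.filler_met, weight_kg, filler_hours)
    )
    return replace(profile, filler_hours=filler_hours, adjusted_total_kj=adjusted)


def met_hours(profile: EnergyProfile, weight_kg: float) -> float:
    """Crude MET-hours per day (weight-free activity summary)."""
    return profile.crude_total_kj / (KCAL_TO_KJ * weight_kg)


def profiles_to_table(profiles: Iterable[EnergyProfile]) -> pd.DataFrame:
    """One row per participant-administration with per-domain columns."""
    rows = []
    for p in profiles:
        row = {
            "participant_id": p.participant_id,
            "administration": p.administration,
        }
        for d in DOMAINS:
            row[f"{d}_kj"] = p.per_domain_kj.get(d, 0.0)
        row.update(
            crude_total_kj=p.crude_total_kj,
            crude_hours=p.crude_hours,
            filler_hours=p.filler_hours,
            adjusted_total_kj=p.adjusted_total_kj,
        )
        rows.append(row)
    return pd.DataFrame(rows)
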