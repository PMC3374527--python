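"""Synthetic validation cohort with known ground truth.

Responses are built by *inverse scoring*: each participant gets a target
adjusted 24-h energy expenditure (true TEE + reporting bias + correlated
log-scale reporting noise), categorical answers are laid down across the
transportation/leisure/sport domains in roughly the configured domain
proportions, and the free-entry occupation hours are then solved exactly so
that scoring the response reproduces the target.  Urine enrichment series
are built by inverting the isotope-kinetics pipeline from the same true TEE.

A single cohort seed governs everything through per-stage, per-participant
seed sequences, so administrations I and II can be generated independently
yet share correlated reporting errors.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .activity_catalog import Catalog, default_catalog, lookup_met
from .config import CohortSpec, DlwConstants, ScoringConfig
from .dlw_kinetics import UrineSampleSeries, assign_dose
from .questionnaire import (
    CategoryMap,
    ParticipantProfile,
    QuestionnaireResponse,
    ResponseItem,
    resolve_daily_hours,
)

__all__ = [
    "AllocationError",
    "generate_cohort",
    "generate_responses",
    "simulate_enrichment",
    "expected_icc",
    "expected_spearman",
]

log = logging.getLogger(__name__)

# stage tags for seed-sequence spawning
_STAGE_COHORT = 0
_STAGE_NOISE = 1
_STAGE_ITEMS = {"I": 2, "II": 3}
_STAGE_ENRICH = 4

#: share of the true-TEE variance explained by body weight
_WEIGHT_TEE_CORR = 0.6
#: leisure activity at the filler MET, guaranteeing >= 1 h of leisure
_NEUTRAL_LEISURE = "musical_instrument_active_games"
_NEUTRAL_HOURS = 1.0
_OCC_MAX_HOURS = 14.0

_AGE_BANDS = {
    "20-29": (20, 29),
    "30-39": (30, 39),
    "40-49": (40, 49),
    "50-59": (50, 59),
    "60-65": (60, 65),
}


class AllocationError(ValueError):
    """Target energy expenditure unreachable within a 24-hour day."""


def _rng(spec: CohortSpec, stage: int, participant: int | None = None):
    entropy = [spec.seed, stage]
    if participant is not None:
        entropy.append(participant)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def generate_cohort(spec: CohortSpec) -> tuple[list[ParticipantProfile], np.ndarray]:
    """Draw demographics and per-participant true TEE; deterministic per seed."""
    rng = _rng(spec, _STAGE_COHORT)
    n = spec.n
    sex = np.where(rng.random(n) < spec.female_fraction, "female", "male")
    bands = list(spec.age_band_weights)
    weights = np.array([spec.age_band_weights[b] for b in bands], dtype=float)
    band_idx = rng.choice(len(bands), size=n, p=weights / weights.sum())
    ages = np.array(
        [rng.integers(*_AGE_BANDS[bands[i]], endpoint=True) for i in band_idx]
    )
    height = np.where(
        sex == "female", rng.normal(166.0, 6.0, n), rng.normal(178.0, 7.0, n)
    )
    bmi = np.clip(rng.normal(spec.bmi_mean, spec.bmi_sd, n), 16.0, None)
    weight = bmi * (height / 100.0) ** 2

    # true TEE correlated with weight, calibrated to the configured mean/SD
    z_w = (weight - weight.mean()) / max(weight.std(), 1e-9)
    z_i = rng.normal(0.0, 1.0, n)
    z = _WEIGHT_TEE_CORR * z_w + math.sqrt(1.0 - _WEIGHT_TEE_CORR**2) * z_i
    true_tee = np.clip(
        spec.true_tee_mean_kj + spec.true_tee_sd_kj * z, 4000.0, None
    )

    profiles = [
        ParticipantProfile(
            participant_id=f"P{i + 1:04d}",
            sex=str(sex[i]),
            age_years=int(ages[i]),
            weight_kg=float(weight[i]),
            height_cm=float(height[i]),
        )
        for i in range(n)
    ]
    return profiles, true_tee


def _reporting_error(spec: CohortSpec, participant: int, administration: str) -> float:
    """Mean-one multiplicative log-normal reporting error; administrations
    share a component with correlation ``retest_reliability``."""
    rng = _rng(spec, _STAGE_NOISE, participant)
    z1, z2 = rng.normal(size=2)
    rho = spec.retest_reliability
    z = z1 if administration == "I" else rho * z1 + math.sqrt(1.0 - rho**2) * z2
    sigma = spec.questionnaire_noise_sd
    return math.exp(sigma * z - 0.5 * sigma**2)


def _freq_label(category_map: CategoryMap) -> tuple[str, float]:
    # the densest available frequency (daily if present)
    label = max(category_map.frequency, key=lambda k: category_map.frequency[k])
    return label, category_map.frequency[label]


def _make_item(
    activity_id: str,
    target_daily_hours: float,
    category_map: CategoryMap,
) -> ResponseItem | None:
    freq_label, freq_mid = _freq_label(category_map)
    if target_daily_hours < 0.15:
        return None
    dur_label = category_map.nearest_duration(7.0 * target_daily_hours / freq_mid)
    item = ResponseItem(
        activity_id=activity_id,
        frequency_category=freq_label,
        duration_category=dur_label,
    )
    hours = resolve_daily_hours(item, category_map)
    if hours < 1e-9:
        return None
    return item


_ALLOC_ACTIVITIES = {
    "transportation": ("walking_transportation", "bicycling_transportation"),
    "leisure": ("household_chores", "walking_leisure", "dancing"),
    "sport": (
        "aerobics",
        "weight_lifting",
        "jogging_running",
        "spinning",
        "swimming",
        "soccer_basketball_volleyball_floorball",
    ),
}
_DOMAIN_HOUR_CAPS = {"transportation": 3.0, "leisure": 10.0, "sport": 8.0}


def _build_response(
    participant_id: str,
    administration: str,
    target_adjusted_kj: float,
    weight_kg: float,
    rng: np.random.Generator,
    catalog: Catalog,
    category_map: CategoryMap,
    scoring: ScoringConfig,
    spec: CohortSpec,
) -> tuple[QuestionnaireResponse, bool]:
    """Inverse-score one response; returns (response, clamped?)."""
    c = weight_kg * scoring.kcal_to_kj
    awake = 24.0 - scoring.sleep_hours
    base = scoring.sleep_met * scoring.sleep_hours * c + scoring.filler_met * c * awake

    # reachable band given the hour caps below; targets outside are clamped
    lo = base - 15.5 * c
    hi = base + 52.0 * c
    clamped = not (lo <= target_adjusted_kj <= hi)
    target = float(np.clip(target_adjusted_kj, lo, hi))
    if clamped and not spec.clamp_to_feasible:
        raise AllocationError(
            f"{participant_id}/{administration}: target {target_adjusted_kj:.0f} kJ "
            f"outside reachable band [{lo:.0f}, {hi:.0f}]"
        )

    excess = target - base  # energy to create via (MET - filler_met) weighted hours

    items: list[ResponseItem] = []
    neutral = _make_item(_NEUTRAL_LEISURE, _NEUTRAL_HOURS, category_map)
    if neutral is not None:
        items.append(neutral)

    shares = dict(spec.domain_shares)
    total_share = sum(shares.values())

    if excess > 0:
        for domain in ("transportation", "leisure", "sport"):
            target_d = excess * shares.get(domain, 0.0) / total_share
            activity_id = str(rng.choice(_ALLOC_ACTIVITIES[domain]))
            met = lookup_met(catalog, activity_id)
            if met <= scoring.filler_met:
                continue
            hours = target_d / ((met - scoring.filler_met) * c)
            hours = min(hours, _DOMAIN_HOUR_CAPS[domain])
            item = _make_item(activity_id, hours, category_map)
            if item is not None:
                items.append(item)
    else:
        # under-reporting day: low-MET screen time absorbs what a rank-1
        # occupation block cannot
        occ_capacity = (scoring.filler_met - catalog.occupation_scale[1]) * c * 12.0
        deficit = -excess
        if deficit > occ_capacity:
            tv_met = lookup_met(catalog, "watching_tv")
            tv_hours = (deficit - 0.5 * occ_capacity) / (
                (scoring.filler_met - tv_met) * c
            )
            tv_hours = min(tv_hours, 9.0)
            item = _make_item("watching_tv", tv_hours, category_map)
            if item is not None:
                items.append(item)

    # exact residual after the categorical items
    resolved_hours = {
        i.activity_id: resolve_daily_hours(i, category_map) for i in items
    }
    items_excess = sum(
        (lookup_met(catalog, aid) - scoring.filler_met) * h * c
        for aid, h in resolved_hours.items()
    )
    h_items = sum(resolved_hours.values())
    residual = excess - items_excess
    h_budget = min(_OCC_MAX_HOURS, 24.0 - h_items)

    # occupation hours are free-entry: solve them exactly
    rank, occ_hours = None, None
    if residual >= 0:
        for cand in (3, 4, 5):
            met = catalog.occupation_scale[cand]
            hours = residual / ((met - scoring.filler_met) * c)
            if hours <= h_budget:
                rank, occ_hours = cand, hours
                break
        if rank is None:
            rank, occ_hours, clamped = 5, h_budget, True
    else:
        met = catalog.occupation_scale[1]
        hours = residual / ((met - scoring.filler_met) * c)  # negative / negative
        if hours <= h_budget:
            rank, occ_hours = 1, hours
        else:
            rank, occ_hours, clamped = 1, h_budget, True

    resp = QuestionnaireResponse(
        participant_id=participant_id,
        administration=administration,
        occupation_effort_rank=rank,
        occupation_hours=float(occ_hours),
        items=tuple(items),
    )
    return resp, clamped


def generate_responses(
    profiles: list[ParticipantProfile],
    true_tee: np.ndarray,
    spec: CohortSpec,
    administration: str,
    catalog: Catalog | None = None,
    category_map: CategoryMap | None = None,
    scoring: ScoringConfig | None = None,
) -> list[QuestionnaireResponse]:
    """Emit one administration's responses.

    Administration II reuses each participant's reporting-error stream with
    correlation ``retest_reliability``; item selection is re-drawn per
    administration.
    """
    if administration not in ("I", "II"):
        raise ValueError(f"administration must be 'I' or 'II', got {administration!r}")
    catalog = catalog or default_catalog()
    if category_map is None:
        from .config import default_config

        category_map = default_config().categories
    scoring = scoring or ScoringConfig()

    responses = []
    n_clamped = 0
    for i, profile in enumerate(profiles):
        err = _reporting_error(spec, i, administration)
        target = (float(true_tee[i]) + spec.questionnaire_bias_kj) * err
        rng = _rng(spec, _STAGE_ITEMS[administration], i)
        resp, clamped = _build_response(
            profile.participant_id,
            administration,
            target,
            profile.weight_kg,
            rng,
            catalog,
            category_map,
            scoring,
            spec,
        )
        n_clamped += clamped
        responses.append(resp)
    if n_clamped:
        log.info(
            "administration %s: %d/%d targets clamped to the reachable band",
            administration,
            n_clamped,
            len(profiles),
        )
    return responses


#: total-body-water fraction of body mass used when inverting the kinetics
_WATER_FRACTION = {"female": 0.55, "male": 0.62}
_MOL_WATER_PER_KG = 1000.0 / 18.015
_DILUTION_SPACE_RATIO = 1.034  # n_h / n_o


def simulate_enrichment(
    profiles: list[ParticipantProfile],
    true_tee: np.ndarray,
    spec: CohortSpec,
    constants: DlwConstants | None = None,
) -> list[UrineSampleSeries]:
    """Invert the kinetics pipeline: from each participant's true TEE derive
    (k_h, k_o, dilution spaces) and emit an 11-point series (baseline day 0
    plus post-dose days 1-10) with multiplicative enrichment noise."""
    constants = constants or DlwConstants()
    out = []
    for i, profile in enumerate(profiles):
        rng = _rng(spec, _STAGE_ENRICH, i)
        w = profile.weight_kg
        dose = assign_dose(w)
        n_o = _WATER_FRACTION[profile.sex] * w * _MOL_WATER_PER_KG
        n_h = _DILUTION_SPACE_RATIO * n_o

        r_co2 = float(true_tee[i]) / constants.kj_per_mol_co2()
        flux = r_co2 / constants.flux_to_rco2
        water_turnover = 55.0 + 1.7 * w  # mol/day, ~3 L/day for a 70 kg adult
        k_h = water_turnover / n_h
        k_o = (flux + constants.frac_h * k_h * n_h) / (constants.frac_o * n_o)
        if k_o <= k_h:
            raise ValueError(
                f"{profile.participant_id}: derived k_o <= k_h; "
                "true TEE too low for the assumed water turnover"
            )

        a_h = dose * constants.dose_2h_atoms_per_g / (2.0 * n_h)
        a_o = dose * constants.dose_18o_atoms_per_g / n_o
        samples = [(0.0, 0.0, 0.0)]  # pre-dose baseline
        sigma = spec.enrichment_noise_sd
        for day in range(1, 11):
            noise_h = math.exp(sigma * rng.normal()) if sigma > 0 else 1.0
            noise_o = math.exp(sigma * rng.normal()) if sigma > 0 else 1.0
            samples.append(
                (
                    float(day),
                    a_h * math.exp(-k_h * day) * noise_h,
                    a_o * math.exp(-k_o * day) * noise_o,
                )
            )
        out.append(
            UrineSampleSeries(
                participant_id=profile.participant_id,
                samples=tuple(samples),
                dose_g=dose,
                weight_kg=w,
            )
        )
    return out


def expected_icc(spec: CohortSpec) -> float:
    """Analytic test-retest ICC implied by the generator's noise model
    (log-normal reporting error shared with correlation rho)."""
    m = spec.true_tee_mean_kj + spec.questionnaire_bias_kj
    v = spec.true_tee_sd_kj**2
    s2 = spec.questionnaire_noise_sd**2
    var_x = (m**2 + v) * math.exp(s2) - m**2
    cov = (m**2 + v) * math.exp(spec.retest_reliability * s2) - m**2
    return cov / var_x


def expected_spearman(spec: CohortSpec) -> float:
    """Approximate questionnaire-vs-reference Spearman correlation implied by
    the generator (normal-scores approximation on the log scale, ignoring the
    small reference-method noise)."""
    sigma_t = spec.true_tee_sd_kj / (spec.true_tee_mean_kj + spec.questionnaire_bias_kj)
    r = sigma_t / math.sqrt(sigma_t**2 + spec.questionnaire_noise_sd**2)
    return (6.0 / math.pi) * math.asin(r / 2.0)
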