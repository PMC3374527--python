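"""Study configuration: one structured file holds the category midpoints,
scoring constants, isotope-kinetics constants, agreement options and the
synthetic-cohort generator spec."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from importlib import resources
from typing import Any, Mapping

import yaml

from .questionnaire import CategoryMap

__all__ = [
    "ScoringConfig",
    "DlwConstants",
    "AgreementConfig",
    "CohortSpec",
    "StudyConfig",
    "load_config",
    "default_config",
]


@dataclass(frozen=True)
class ScoringConfig:
    sleep_hours: float = 8.0
    sleep_met: float = 0.9
    filler_met: float = 2.0
    kcal_to_kj: float = 4.184


@dataclass(frozen=True)
class DlwConstants:
    """Two-pool slope-intercept constants.

    These are a documented implementation choice, not asserted by the
    validation study itself; override any of them through the config file.
    """

    rq: float = 0.85
    fit_windows: tuple[tuple[float, float], ...] = ((1.0, 3.0), (8.0, 10.0))
    method: str = "multipoint"  # or "twopoint"
    frac_o: float = 1.007
    frac_h: float = 1.041
    co2_divisor: float = 2.078
    frac_loss: float = 0.0246
    frac_loss_scale: float = 1.05
    weir_o2: float = 3.941
    weir_co2: float = 1.106
    litres_per_mol: float = 22.4
    dose_2h_atoms_per_g: float = 0.004209
    dose_18o_atoms_per_g: float = 0.005156

    @property
    def flux_to_rco2(self) -> float:
        """mol CO2 per mol of fractionation-corrected isotope flux."""
        return 1.0 / self.co2_divisor - self.frac_loss * self.frac_loss_scale

    def kj_per_mol_co2(self, rq: float | None = None) -> float:
        rq = self.rq if rq is None else rq
        kcal_per_litre = self.weir_o2 / rq + self.weir_co2
        return 4.184 * self.litres_per_mol * kcal_per_litre


@dataclass(frozen=True)
class AgreementConfig:
    icc_model: str = "oneway"
    loa_sd_factor: float = 2.0


@dataclass(frozen=True)
class CohortSpec:
    """Generator parameters for the synthetic validation cohort."""

    n: int = 37
    seed: int = 0
    female_fraction: float = 0.81
    age_band_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "20-29": 22,
            "30-39": 5,
            "40-49": 5,
            "50-59": 4,
            "60-65": 1,
        }
    )
    bmi_mean: float = 23.0
    bmi_sd: float = 3.8
    true_tee_mean_kj: float = 11229.0
    true_tee_sd_kj: float = 2256.0
    questionnaire_bias_kj: float = 440.0
    questionnaire_noise_sd: float = 0.33
    retest_reliability: float = 0.75
    enrichment_noise_sd: float = 0.005
    domain_shares: Mapping[str, float] = field(
        default_factory=lambda: {
            "occupation": 2971,
            "transportation": 434,
            "leisure": 2243,
            "sport": 1360,
        }
    )
    clamp_to_feasible: bool = True

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError(f"cohort size must be >= 3, got {self.n}")
        for name in ("true_tee_sd_kj", "questionnaire_noise_sd", "bmi_sd",
                     "enrichment_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.female_fraction <= 1:
            raise ValueError("female_fraction must lie in [0, 1]")
        if not -1 <= self.retest_reliability <= 1:
            raise ValueError("retest_reliability must lie in [-1, 1]")


@dataclass(frozen=True)
class StudyConfig:
    categories: CategoryMap
    scoring: ScoringConfig = ScoringConfig()
    dlw: DlwConstants = DlwConstants()
    agreement: AgreementConfig = AgreementConfig()
    cohort: CohortSpec = CohortSpec()


def _build(cls, raw: Mapping[str, Any]):
    known = {f.name for f in fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(raw)
    if "fit_windows" in kwargs:
        kwargs["fit_windows"] = tuple(tuple(map(float, w)) for w in kwargs["fit_windows"])
    return cls(**kwargs)


def load_config(source: str | None = None) -> StudyConfig:
    """Load a YAML study config; with ``source=None`` use the built-in default.

    ``source`` may be YAML text or an open file object.  Sections missing
    from the document fall back to the package defaults.
    """
    default_text = (
        resources.files("activeq").joinpath("data/default_config.yaml").read_text()
    )
    doc = yaml.safe_load(default_text)
    if source is not None:
        text = source.read() if hasattr(source, "read") else source
        user = yaml.safe_load(text) or {}
        for section, value in user.items():
            if isinstance(value, Mapping) and isinstance(doc.get(section), dict):
                doc[section].update(value)
            else:
                doc[section] = value
    cats = doc.get("categories", {})
    category_map = CategoryMap(
        frequency=dict(cats.get("frequency", {})),
        duration=dict(cats.get("duration", {})),
    )
    return StudyConfig(
        categories=category_map,
        scoring=_build(ScoringConfig, doc.get("scoring", {})),
        dlw=_build(DlwConstants, doc.get("dlw", {})),
        agreement=_build(AgreementConfig, doc.get("agreement", {})),
        cohort=_build(CohortSpec, doc.get("cohort", {})),
    )


def default_config() -> StudyConfig:
    return load_config(None)


def with_cohort(config: StudyConfig, **overrides) -> StudyConfig:
    """Convenience: a copy of ``config`` with cohort-spec fields overridden."""
    return replace(config, cohort=replace(config.cohort, **overrides))
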