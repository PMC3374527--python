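"""Reference total energy expenditure from doubly-labeled-water kinetics.

Log-linear fits of the post-dose urine enrichment decay give the elimination
rates and the t=0 intercepts for each isotope; the intercepts and the dose
size give the dilution spaces; a two-pool slope-intercept equation converts
the fractionation-corrected isotope flux into CO2 production, and a Weir-type
relation (with an assumed respiratory quotient) converts that into kJ/day.

All equation constants live in :class:`activeq.config.DlwConstants` and are a
documented implementation choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import DlwConstants

__all__ = [
    "UrineSampleSeries",
    "IsotopeKinetics",
    "DlwResult",
    "DlwError",
    "assign_dose",
    "fit_elimination",
    "compute_rco2",
    "tee_from_rco2",
    "tee_pipeline",
    "series_to_table",
    "series_from_table",
]


class DlwError(ValueError):
    """Unusable isotope data or unphysiological kinetics."""


@dataclass(frozen=True)
class UrineSampleSeries:
    """Post-dose enrichment time series for one participant.

    Enrichments are above-baseline excess atom fractions (2H relative to H
    atoms, 18O relative to O atoms) in body water.  ``samples`` rows are
    (time_days, delta2h, delta18o) with strictly increasing times starting
    at the first post-dose day.
    """

    participant_id: str
    samples: tuple[tuple[float, float, float], ...]
    dose_g: float
    weight_kg: float

    def __post_init__(self) -> None:
        times = [s[0] for s in self.samples]
        if any(t < 0 for t in times):
            raise DlwError("sample times must be >= 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise DlwError("sample times must be strictly increasing")
        if self.dose_g <= 0:
            raise DlwError("dose_g must be positive")

    def times(self) -> np.ndarray:
        return np.array([s[0] for s in self.samples], dtype=float)

    def enrichment(self, isotope: str) -> np.ndarray:
        idx = {"2H": 1, "18O": 2}[isotope]
        return np.array([s[idx] for s in self.samples], dtype=float)


@dataclass(frozen=True)
class IsotopeKinetics:
    """Per-isotope elimination rates, t=0 intercepts, and dilution spaces."""

    k_h: float  # 2H elimination rate, /day
    k_o: float  # 18O elimination rate, /day
    intercept_h: float  # enrichment at t=0 (back-extrapolated)
    intercept_o: float
    n_h: float  # 2H dilution space, mol water
    n_o: float  # 18O dilution space, mol water


@dataclass(frozen=True)
class DlwResult:
    participant_id: str
    kinetics: IsotopeKinetics
    r_co2: float  # mol/day
    rq: float
    tee_kj_day: float


def assign_dose(weight_kg: float) -> float:
    """Standard bulk-dose size in grams: 108 below 75 kg, 141 at or above."""
    if weight_kg <= 0:
        raise ValueError(f"weight_kg must be positive, got {weight_kg}")
    return 108.0 if weight_kg < 75.0 else 141.0


def _in_windows(times: np.ndarray, windows: Iterable[tuple[float, float]]) -> np.ndarray:
    mask = np.zeros(len(times), dtype=bool)
    for lo, hi in windows:
        mask |= (times >= lo) & (times <= hi)
    return mask


def _fit_one(
    times: np.ndarray,
    enrichment: np.ndarray,
    windows: Sequence[tuple[float, float]],
    method: str,
    isotope: str,
) -> tuple[float, float]:
    mask = _in_windows(times, windows)
    t = times[mask]
    e = enrichment[mask]
    if len(t) < 2:
        raise DlwError(
            f"{isotope}: need >= 2 samples inside the fit windows, got {len(t)}"
        )
    bad = np.nonzero(e <= 0)[0]
    if bad.size:
        raise DlwError(
            f"{isotope}: non-positive enrichment at day(s) "
            f"{', '.join(f'{t[i]:g}' for i in bad)}"
        )
    log_e = np.log(e)
    if method == "multipoint":
        slope, intercept = np.polyfit(t, log_e, 1)
    elif method == "twopoint":
        # mean log-enrichment of the first and last window
        lo_mask = _in_windows(t, windows[:1])
        hi_mask = _in_windows(t, windows[-1:])
        if not lo_mask.any() or not hi_mask.any():
            raise DlwError(f"{isotope}: two-point fit needs samples in both windows")
        t0, y0 = t[lo_mask].mean(), log_e[lo_mask].mean()
        t1, y1 = t[hi_mask].mean(), log_e[hi_mask].mean()
        if t1 == t0:
            raise DlwError(f"{isotope}: degenerate two-point fit (single window)")
        slope = (y1 - y0) / (t1 - t0)
        intercept = y0 - slope * t0
    else:
        raise ValueError(f"unknown fit method {method!r}")
    k = -slope
    if k <= 0:
        raise DlwError(f"{isotope}: non-positive elimination rate ({k:g}/day)")
    return k, float(np.exp(intercept))


def fit_elimination(
    series: UrineSampleSeries,
    constants: DlwConstants | None = None,
    windows: Sequence[tuple[float, float]] | None = None,
) -> IsotopeKinetics:
    """OLS fit of log(enrichment) vs time inside the sampling windows.

    Slope gives -k; the back-extrapolated t=0 intercept together with the
    tracer content of the dose gives the dilution space for each isotope
    (2H enrichment is per H atom, two per water molecule).
    """
    constants = constants or DlwConstants()
    windows = tuple(windows) if windows is not None else constants.fit_windows
    times = series.times()
    k_h, a_h = _fit_one(times, series.enrichment("2H"), windows, constants.method, "2H")
    k_o, a_o = _fit_one(times, series.enrichment("18O"), windows, constants.method, "18O")
    d_h = series.dose_g * constants.dose_2h_atoms_per_g
    d_o = series.dose_g * constants.dose_18o_atoms_per_g
    n_h = d_h / (2.0 * a_h)
    n_o = d_o / a_o
    return IsotopeKinetics(
        k_h=k_h, k_o=k_o, intercept_h=a_h, intercept_o=a_o, n_h=n_h, n_o=n_o
    )


def compute_rco2(kin: IsotopeKinetics, constants: DlwConstants | None = None) -> float:
    """Two-pool slope-intercept CO2 production, mol/day."""
    constants = constants or DlwConstants()
    for name in ("k_h", "k_o", "n_h", "n_o"):
        if getattr(kin, name) <= 0:
            raise DlwError(f"kinetics field {name} must be positive")
    flux = constants.frac_o * kin.k_o * kin.n_o - constants.frac_h * kin.k_h * kin.n_h
    r_co2 = flux * constants.flux_to_rco2
    if r_co2 <= 0:
        raise DlwError(
            "corrected isotope flux is non-positive (k_o N_o too close to k_h N_h); "
            "data are unphysiological"
        )
    return r_co2


def tee_from_rco2(
    r_co2: float, rq: float = 0.85, constants: DlwConstants | None = None
) -> float:
    """Energy expenditure (kJ/day) from CO2 production via the Weir relation
    with VO2 = VCO2 / RQ."""
    constants = constants or DlwConstants()
    if r_co2 < 0:
        raise ValueError(f"r_co2 must be >= 0, got {r_co2}")
    if not 0.7 <= rq <= 1.0:
        raise ValueError(f"rq outside physiological bounds [0.7, 1.0]: {rq}")
    return r_co2 * constants.kj_per_mol_co2(rq)


def tee_pipeline(
    series: UrineSampleSeries, constants: DlwConstants | None = None
) -> DlwResult:
    """fit -> CO2 production -> TEE for one participant."""
    constants = constants or DlwConstants()
    kin = fit_elimination(series, constants)
    r_co2 = compute_rco2(kin, constants)
    tee = tee_from_rco2(r_co2, constants.rq, constants)
    return DlwResult(
        participant_id=series.participant_id,
        kinetics=kin,
        r_co2=r_co2,
        rq=constants.rq,
        tee_kj_day=tee,
    )


def series_to_table(series: Iterable[UrineSampleSeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        for t, d2h, d18o in s.samples:
            rows.append(
                {
                    "participant_id": s.participant_id,
                    "day": t,
                    "delta2h": d2h,
                    "delta18o": d18o,
                    "dose_g": s.dose_g,
                    "weight_kg": s.weight_kg,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["participant_id", "day", "delta2h", "delta18o", "dose_g", "weight_kg"],
    )


def series_from_table(table: pd.DataFrame) -> list[UrineSampleSeries]:
    out = []
    for pid, group in table.groupby("participant_id", sort=False):
        group = group.sort_values("day")
        out.append(
            UrineSampleSeries(
                participant_id=str(pid),
                samples=tuple(
                    (float(r.day), float(r.delta2h), float(r.delta18o))
                    for r in group.itertuples()
                ),
                dose_g=float(group["dose_g"].iloc[0]),
                weight_kg=float(group["weight_kg"].iloc[0]),
            )
        )
    return out
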