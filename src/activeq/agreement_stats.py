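"""Validity and reproducibility statistics, implemented from first
principles: Spearman rank correlation with midranks, Bland-Altman agreement
with limits at +/- 2 SD of the differences, and the one-way random-effects
ANOVA intraclass correlation with an F-distribution confidence interval.

Only distribution quantile/tail functions are delegated to scipy; the
estimators themselves are computed here so they can be cross-checked against
brute-force oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np
from scipy import stats as _dists

__all__ = [
    "PairedMeasurements",
    "AgreementReport",
    "DegenerateDataError",
    "spearman",
    "bland_altman",
    "icc_anova",
    "agreement_report",
]


class DegenerateDataError(ValueError):
    """Constant input where a correlation/ICC is undefined."""


@dataclass(frozen=True)
class PairedMeasurements:
    """Two measurements per participant (methods A/B or administrations I/II)."""

    ids: tuple[str, ...]
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if len(a) != len(b) or len(self.ids) != len(a):
            raise ValueError("ids, a and b must have equal lengths")
        if np.isnan(a).any() or np.isnan(b).any():
            raise ValueError("missing values must be dropped upstream")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    def __len__(self) -> int:
        return len(self.a)

    @classmethod
    def from_dicts(cls, a: dict, b: dict) -> tuple["PairedMeasurements", int]:
        """Pair two id-keyed maps; returns (pairs, number of ids dropped)."""
        common = [k for k in a if k in b]
        dropped = len(set(a) | set(b)) - len(common)
        return (
            cls(
                ids=tuple(str(k) for k in common),
                a=np.array([a[k] for k in common], dtype=float),
                b=np.array([b[k] for k in common], dtype=float),
            ),
            dropped,
        )


@dataclass(frozen=True)
class AgreementReport:
    spearman_r: float
    spearman_p: float
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    icc: float
    icc_ci_low: float
    icc_ci_high: float


def _midranks(x: np.ndarray) -> np.ndarray:
    """Average ranks, 1-based, ties receive their midrank."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    sorted_x = x[order]
    while i < len(x):
        j = i
        while j + 1 < len(x) and sorted_x[j + 1] == sorted_x[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        raise DegenerateDataError("correlation undefined for a constant vector")
    return float((xc * yc).sum() / denom)


def spearman(
    pairs: PairedMeasurements, p_method: str = "t"
) -> tuple[float, float]:
    """Spearman rank correlation with midranks for ties.

    ``p_method='t'`` uses the two-sided large-sample t approximation;
    ``'exact'`` enumerates all n! rank permutations (n <= 10 only).
    """
    n = len(pairs)
    if n < 3:
        raise ValueError(f"need n >= 3 pairs, got {n}")
    ra = _midranks(pairs.a)
    rb = _midranks(pairs.b)
    r = _pearson(ra, rb)
    if p_method == "t":
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
            p = float(2.0 * _dists.t.sf(abs(t), df=n - 2))
    elif p_method == "exact":
        if n > 10:
            raise ValueError("exact permutation p-value limited to n <= 10")
        count = 0
        total = 0
        for perm in permutations(range(n)):
            total += 1
            if abs(_pearson(ra, rb[list(perm)])) >= abs(r) - 1e-12:
                count += 1
        p = count / total
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return r, p


def bland_altman(
    pairs: PairedMeasurements, sd_factor: float = 2.0
) -> tuple[float, float, float, float, np.ndarray]:
    """Agreement between two methods: mean difference, SD of the differences,
    limits of agreement at mean +/- ``sd_factor`` SD (factor 2 by default),
    and the plot-ready (mean, difference) points."""
    n = len(pairs)
    if n < 2:
        raise ValueError(f"need n >= 2 pairs, got {n}")
    diff = pairs.a - pairs.b
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    loa_low = mean_diff - sd_factor * sd_diff
    loa_high = mean_diff + sd_factor * sd_diff
    points = np.column_stack([(pairs.a + pairs.b) / 2.0, diff])
    return mean_diff, sd_diff, loa_low, loa_high, points


def _oneway_mean_squares(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """(MSB, MSW) for the one-way model with k=2 measurements per subject."""
    data = np.column_stack([a, b])
    n, k = data.shape
    subject_means = data.mean(axis=1)
    grand = data.mean()
    msb = k * ((subject_means - grand) ** 2).sum() / (n - 1)
    msw = ((data - subject_means[:, None]) ** 2).sum() / (n * (k - 1))
    return float(msb), float(msw)


def icc_anova(
    pairs: PairedMeasurements,
    model: str = "oneway",
    alpha: float = 0.05,
) -> tuple[float, float, float]:
    """ANOVA estimator of the intraclass correlation for k=2 repeats.

    One-way random effects (default): ICC = (MSB - MSW) / (MSB + (k-1) MSW),
    with the exact F-bound confidence interval of the one-way model.  The
    two-way random-effects variant (absolute agreement, single measurement)
    is available with ``model='twoway'``; its interval uses the same F-bound
    construction on MSR/MSE and is approximate.
    """
    n = len(pairs)
    if n < 3:
        raise ValueError(f"need n >= 3 subjects, got {n}")
    k = 2
    a, b = pairs.a, pairs.b
    if np.ptp(np.concatenate([a, b])) == 0:
        raise DegenerateDataError("ICC undefined: zero total variance")
    if model == "oneway":
        msb, msw = _oneway_mean_squares(a, b)
        if msb == 0 and msw == 0:
            raise DegenerateDataError("ICC undefined: zero total variance")
        icc = (msb - msw) / (msb + (k - 1) * msw)
        df1, df2 = n - 1, n * (k - 1)
        if msw == 0:
            return float(icc), 1.0, 1.0
        f_obs = msb / msw
        f_l = f_obs / _dists.f.ppf(1 - alpha / 2, df1, df2)
        f_u = f_obs * _dists.f.ppf(1 - alpha / 2, df2, df1)
        ci_low = (f_l - 1) / (f_l + k - 1)
        ci_high = (f_u - 1) / (f_u + k - 1)
    elif model == "twoway":
        data = np.column_stack([a, b])
        grand = data.mean()
        row_means = data.mean(axis=1)
        col_means = data.mean(axis=0)
        ssr = k * ((row_means - grand) ** 2).sum()
        ssc = n * ((col_means - grand) ** 2).sum()
        sst = ((data - grand) ** 2).sum()
        sse = sst - ssr - ssc
        msr = ssr / (n - 1)
        msc = ssc / (k - 1)
        mse = sse / ((n - 1) * (k - 1))
        icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        if mse == 0:
            return float(icc), 1.0, 1.0
        df1, df2 = n - 1, (n - 1) * (k - 1)
        f_obs = msr / mse
        f_l = f_obs / _dists.f.ppf(1 - alpha / 2, df1, df2)
        f_u = f_obs * _dists.f.ppf(1 - alpha / 2, df2, df1)
        ci_low = (f_l - 1) / (f_l + k - 1)
        ci_high = (f_u - 1) / (f_u + k - 1)
    else:
        raise ValueError(f"unknown ICC model {model!r}")
    return float(icc), float(ci_low), float(ci_high)


def agreement_report(
    pairs: PairedMeasurements,
    icc_model: str = "oneway",
    loa_sd_factor: float = 2.0,
) -> AgreementReport:
    """All three statistics for one paired-measurement set."""
    r, p = spearman(pairs)
    mean_diff, sd_diff, loa_low, loa_high, _ = bland_altman(pairs, loa_sd_factor)
    icc, ci_low, ci_high = icc_anova(pairs, model=icc_model)
    return AgreementReport(
        spearman_r=r,
        spearman_p=p,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=loa_low,
        loa_high=loa_high,
        icc=icc,
        icc_ci_low=ci_low,
        icc_ci_high=ci_high,
    )
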