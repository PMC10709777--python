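"""Direct age standardization and percentile-gap disparity statistics.

County rates are made comparable across places and years by direct
standardization to a fixed reference age distribution — here the national
distribution of live births by maternal age group in the reference year
(2007 by default, the first study year).  Cross-county disparity in a year
is summarized by the distribution of standardized county rates: minimum,
10th percentile, median, IQR, 90th percentile, maximum, the 90th−10th
percentile gap, the 90th/10th ratio, and the max−min gap.  Confidence
intervals for the gap and ratio come from a county-resampling percentile
bootstrap (the distribution functionals have no simple closed-form SE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import CountPanel

__all__ = [
    "ReferenceWeights",
    "reference_weights",
    "age_standardize",
    "DisparitySummary",
    "disparity_summary",
    "bootstrap_gap_ci",
]


@dataclass
class ReferenceWeights:
    """Reference age distribution: non-negative weights summing to one."""

    age_groups: list
    weights: np.ndarray
    ref_year: int | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.age_groups) != self.weights.shape[0]:
            raise ValueError("one weight per age group")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        s = self.weights.sum()
        if not np.isclose(s, 1.0):
            raise ValueError(f"weights sum to {s}, expected 1")


def reference_weights(panel: CountPanel, ref_year: int) -> ReferenceWeights:
    """National age distribution of live births in ``ref_year``:
    w_k = sum_i n_ik,ref / sum_i sum_k n_ik,ref."""
    if ref_year not in panel.years:
        raise ValueError(f"reference year {ref_year} not in panel")
    t = panel.years.index(ref_year)
    totals = panel.births[:, :, t].sum(axis=0).astype(float)
    total = totals.sum()
    if total == 0:
        raise ValueError(f"no births recorded in reference year {ref_year}")
    return ReferenceWeights(list(panel.age_groups), totals / total, ref_year)


def age_standardize(rates, weights: ReferenceWeights) -> float:
    """Directly standardized rate: sum_k w_k * rate_k (a convex combination,
    so the result always lies within [min rate, max rate])."""
    rates = np.asarray(rates, dtype=float)
    w = weights.weights if isinstance(weights, ReferenceWeights) else np.asarray(weights)
    if rates.shape[-1] != w.shape[0]:
        raise ValueError("one rate per age group required")
    if np.any(np.isnan(rates)):
        raise ValueError("missing age-group rate")
    return rates @ w


@dataclass
class DisparitySummary:
    """Distribution of standardized county rates in one year."""

    year: int
    n_counties: int
    minimum: float
    p10: float
    p25: float
    median: float
    p75: float
    p90: float
    maximum: float
    gap_90_10: float
    ratio_90_10: float
    gap_max_min: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _quantile(x: np.ndarray, q) -> np.ndarray:
    # linear interpolation of order statistics (the common continuous rule)
    return np.quantile(x, q, method="linear")


def disparity_summary(county_rates, year: int, min_counties: int = 10) -> DisparitySummary:
    """Percentile summary and gap statistics of county rates in one year.

    Percentiles use linear interpolation over order statistics; with fewer
    than ``min_counties`` counties the percentiles are meaningless and a
    ValueError is raised.
    """
    x = np.asarray(county_rates, dtype=float)
    x = x[~np.isnan(x)]
    if x.shape[0] < min_counties:
        raise ValueError(
            f"{x.shape[0]} counties is too few for percentile summaries "
            f"(need >= {min_counties})"
        )
    p10, p25, p50, p75, p90 = _quantile(x, [0.10, 0.25, 0.50, 0.75, 0.90])
    return DisparitySummary(
        year=year,
        n_counties=int(x.shape[0]),
        minimum=float(x.min()),
        p10=float(p10),
        p25=float(p25),
        median=float(p50),
        p75=float(p75),
        p90=float(p90),
        maximum=float(x.max()),
        gap_90_10=float(p90 - p10),
        ratio_90_10=float(p90 / p10),
        gap_max_min=float(x.max() - x.min()),
    )


def bootstrap_gap_ci(county_rates, B: int = 1000, seed: int | None = None,
                     level: float = 0.95) -> dict:
    """County-resampling percentile bootstrap CI for the 90th−10th gap and
    ratio.  Deterministic given ``seed``.

    Returns {"gap": (lo, hi), "ratio": (lo, hi)}.
    """
    if B < 200:
        raise ValueError("B must be at least 200 for stable percentile CIs")
    x = np.asarray(county_rates, dtype=float)
    x = x[~np.isnan(x)]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.shape[0], size=(B, x.shape[0]))
    samples = x[idx]
    p10 = np.quantile(samples, 0.10, axis=1, method="linear")
    p90 = np.quantile(samples, 0.90, axis=1, method="linear")
    gaps = p90 - p10
    ratios = p90 / p10
    a = (1 - level) / 2
    return {
        "gap": tuple(np.quantile(gaps, [a, 1 - a], method="linear")),
        "ratio": tuple(np.quantile(ratios, [a, 1 - a], method="linear")),
    }
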