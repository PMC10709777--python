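"""Log-linear trends in county rates and crude geographic aggregation.

Each county's temporal trend is summarized by ordinary least squares of
ln(rate) on the year index t = 0 ... T-1:

    ln(lambda_t) = beta0 + beta1 * t

The total percent change over the study period is 100 * (e^((T-1)*beta1) - 1)
(for the 13-year 2007-2019 span, (T-1) = 12).  Its 95% CI is the monotone
transformation of the t-based CI for (T-1)*beta1 (delta method on the OLS
standard error); a county is classified as a significant increase/decrease
when that CI excludes zero.

National, state and region (combined-statistical-area-like) rates are
produced by aggregating crude, unsuppressed county counts — sums of Y and n
preserving the age x year structure — after which standardization and trend
fitting reuse the same operations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.proportion import proportion_confint

from .panel import CountPanel

__all__ = ["TrendFit", "fit_loglinear_trend", "classify_counties", "aggregate_crude"]


@dataclass
class TrendFit:
    """Per-unit log-linear trend: coefficients, percent change and flags."""

    unit_id: str | None
    age_stratum: str | None
    beta0: float
    beta1: float
    se_beta1: float
    n_years: int
    pct_change: float
    ci_lo: float
    ci_hi: float
    significant_increase: bool
    significant_decrease: bool


def fit_loglinear_trend(rates, unit_id: str | None = None,
                        age_stratum: str | None = None) -> TrendFit:
    """OLS of ln(rate) on the year index; percent change over the span.

    ``rates`` is the ordered series of annual rates (> 0, at least 3
    years).  The percent-change CI transforms the t-distribution CI of
    (T-1)*beta1 through 100(e^x - 1); significance flags record whether it
    excludes 0 (they are mutually exclusive by construction).
    """
    r = np.asarray(rates, dtype=float)
    T = r.shape[0]
    if T < 3:
        raise ValueError("need at least 3 years to fit a trend")
    if np.any(~np.isfinite(r)) or np.any(r <= 0):
        raise ValueError("rates must be positive to take logarithms")
    t = np.arange(T, dtype=float)
    y = np.log(r)
    tbar = t.mean()
    sxx = np.sum((t - tbar) ** 2)
    beta1 = float(np.sum((t - tbar) * (y - y.mean())) / sxx)
    beta0 = float(y.mean() - beta1 * tbar)
    resid = y - (beta0 + beta1 * t)
    dof = T - 2
    s2 = float(np.sum(resid**2) / dof)
    se = float(np.sqrt(s2 / sxx))
    span = T - 1
    est = span * beta1
    tcrit = scipy.stats.t.ppf(0.975, dof)
    lo, hi = est - tcrit * span * se, est + tcrit * span * se
    pct = 100.0 * np.expm1(est)
    ci_lo, ci_hi = 100.0 * np.expm1(lo), 100.0 * np.expm1(hi)
    return TrendFit(
        unit_id=unit_id,
        age_stratum=age_stratum,
        beta0=beta0,
        beta1=beta1,
        se_beta1=se,
        n_years=T,
        pct_change=float(pct),
        ci_lo=float(ci_lo),
        ci_hi=float(ci_hi),
        significant_increase=bool(ci_lo > 0),
        significant_decrease=bool(ci_hi < 0),
    )


def classify_counties(fits) -> pd.DataFrame:
    """Shares of units with significant increases / decreases / no change,
    with Wilson 95% binomial CIs, broken down by age stratum (the ``None``
    stratum rows cover unstratified fits)."""
    fits = list(fits)
    if not fits:
        raise ValueError("no trend fits supplied")
    df = pd.DataFrame(
        {
            "age_stratum": [f.age_stratum or "all" for f in fits],
            "increase": [f.significant_increase for f in fits],
            "decrease": [f.significant_decrease for f in fits],
        }
    )
    rows = []
    for stratum, grp in df.groupby("age_stratum", sort=False):
        n = len(grp)
        for cls in ("increase", "decrease", "flat"):
            if cls == "flat":
                k = int((~grp["increase"] & ~grp["decrease"]).sum())
            else:
                k = int(grp[cls].sum())
            lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
            rows.append(
                {
                    "age_stratum": stratum,
                    "class": cls,
                    "n_units": n,
                    "count": k,
                    "share": k / n,
                    "ci_lo": lo,
                    "ci_hi": hi,
                }
            )
    return pd.DataFrame(rows)


def aggregate_crude(panel: CountPanel, membership: pd.Series | dict) -> CountPanel:
    """Aggregate crude county counts to larger units (nation, states,
    regions), preserving the age x year structure.

    ``membership`` maps every county id to a unit id.  Counties mapped to
    an empty/missing unit raise; build rest-of-state units upstream (see
    ``membership_units``).  Totals are conserved exactly:
    sums over units equal sums over counties.
    """
    if isinstance(membership, dict):
        membership = pd.Series(membership)
    membership = membership.astype(str)
    missing = [c for c in panel.county_ids if c not in membership.index]
    if missing:
        raise ValueError(f"membership missing counties: {missing[:5]} ...")
    assign = membership.loc[list(panel.county_ids)]
    if assign.isna().any() or (assign == "").any():
        raise ValueError("counties with empty unit assignment")
    units = sorted(assign.unique())
    uidx = {u: j for j, u in enumerate(units)}
    shape = (len(units), len(panel.age_groups), len(panel.years))
    births = np.zeros(shape, dtype=np.int64)
    preterm = np.zeros_like(births)
    early = np.zeros_like(births)
    for i, cid in enumerate(panel.county_ids):
        j = uidx[assign.iloc[i]]
        births[j] += panel.births[i]
        preterm[j] += panel.preterm[i]
        early[j] += panel.early_preterm[i]
    return CountPanel(units, list(panel.age_groups), list(panel.years),
                      births, preterm, early)


def membership_units(membership_df: pd.DataFrame, level: str = "region") -> pd.Series:
    """Resolve a county_id,state_id,region_id table into a county -> unit
    map at a given level.

    level = "national": every county in one unit; "state": by state_id;
    "region": region_id where present, otherwise a rest-of-state unit
    ``rest_of_<state>`` (counties outside any combined area are aggregated
    within their state).  A county appearing twice is an error.
    """
    df = membership_df.copy()
    if df["county_id"].duplicated().any():
        raise ValueError("county mapped to two units")
    df = df.set_index("county_id")
    if level == "national":
        return pd.Series("national", index=df.index)
    if level == "state":
        return df["state_id"].astype(str)
    if level == "region":
        region = df["region_id"].fillna("").astype(str)
        rest = "rest_of_" + df["state_id"].astype(str)
        return region.where(region != "", rest)
    raise ValueError(f"unknown level {level!r}")
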