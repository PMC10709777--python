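"""Association of county social vulnerability with smoothed birth-outcome rates.

The CDC Social Vulnerability Index (SVI) summarizes county disadvantage as
an overall percentile plus four themes (1: socioeconomic status, 2:
household composition and disability, 3: minority status and language, 4:
housing and transportation).  The SVI is released for specific years; each
analysis year is assigned a release (time-varying SVI): 2010 for 2007-2011,
2014 for 2012-2015, 2016 for 2016-2017, 2018 for 2018-2019.

Associations are quantified three ways:
  * negative binomial regression of outcome counts on SVI quartile (or
    continuous SVI) with a log-offset for total births — rate ratios e^beta
    with Wald 95% CIs, one model per year (optionally per age stratum);
  * ordinary least-squares variance explained (R^2) of standardized rates
    by each SVI theme, univariate and sequential;
  * SVI profiles of the counties in the bottom and top deciles of the
    standardized rate distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SviTable",
    "default_release_map",
    "assign_svi_quartiles",
    "NbFit",
    "fit_nb_rate_model",
    "ols_variance_explained",
    "profile_extreme_counties",
]

logger = logging.getLogger(__name__)

SVI_COLUMNS = ["svi_overall", "theme1", "theme2", "theme3", "theme4"]

#: analysis year -> release year, per the time-varying SVI convention
CANONICAL_RELEASE_MAP = {
    **{y: 2010 for y in range(2007, 2012)},
    **{y: 2014 for y in range(2012, 2016)},
    **{y: 2016 for y in (2016, 2017)},
    **{y: 2018 for y in (2018, 2019)},
}


def default_release_map(analysis_years, release_years) -> dict:
    """Analysis-year -> release-year map.  Uses the canonical 2010/2014/
    2016/2018 assignment where those releases are available and the year is
    covered; otherwise falls back to the nearest release (ties to the
    earlier release)."""
    release_years = sorted(release_years)
    out = {}
    for y in analysis_years:
        y = int(y)
        if y in CANONICAL_RELEASE_MAP and CANONICAL_RELEASE_MAP[y] in release_years:
            out[y] = CANONICAL_RELEASE_MAP[y]
        else:
            out[y] = min(release_years, key=lambda r: (abs(r - y), r))
    return out


@dataclass
class SviTable:
    """County SVI percentiles per release year, plus the release map."""

    table: pd.DataFrame
    release_map: dict

    def __post_init__(self):
        need = ["county_id", "release_year"] + SVI_COLUMNS
        missing = [c for c in need if c not in self.table.columns]
        if missing:
            raise ValueError(f"SVI table missing columns: {missing}")
        vals = self.table[SVI_COLUMNS].to_numpy()
        if np.any(vals <= 0) or np.any(vals > 1):
            raise ValueError("SVI percentiles must lie in (0, 1]")

    @classmethod
    def from_csv(cls, path, analysis_years) -> "SviTable":
        df = pd.read_csv(path, dtype={"county_id": str})
        rmap = default_release_map(analysis_years, df["release_year"].unique())
        return cls(df, rmap)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def for_year(self, year: int) -> pd.DataFrame:
        """SVI rows of the release mapped to an analysis year, indexed by
        county."""
        if year not in self.release_map:
            raise KeyError(f"analysis year {year} not covered by release map")
        ry = self.release_map[year]
        sub = self.table[self.table["release_year"] == ry]
        if sub.empty:
            raise KeyError(f"release year {ry} absent from SVI table")
        return sub.set_index("county_id")


def assign_svi_quartiles(svi: SviTable, year: int) -> pd.Series:
    """Quartile (1-4) of the overall SVI among included counties for one
    analysis year.  Cutpoints are the empirical quartiles; counties exactly
    at a cutpoint go to the lower quartile.  If all counties share one SVI
    value every county lands in quartile 1 (with a warning)."""
    sub = svi.for_year(year)
    x = sub["svi_overall"].to_numpy(dtype=float)
    if np.all(x == x[0]):
        warnings.warn("all counties share a single SVI value; assigning quartile 1")
        return pd.Series(1, index=sub.index, name="svi_quartile")
    q1, q2, q3 = np.quantile(x, [0.25, 0.50, 0.75], method="linear")
    quart = 1 + (x > q1).astype(int) + (x > q2).astype(int) + (x > q3).astype(int)
    return pd.Series(quart, index=sub.index, name="svi_quartile")


@dataclass
class NbFit:
    """Negative binomial rate-ratio fit for one year (and age stratum)."""

    year: int | None
    age_stratum: str | None
    params: pd.Series
    bse: pd.Series
    dispersion: float
    rate_ratios: pd.DataFrame  # contrast, rr, lo, hi
    converged: bool
    n_obs: int

    @property
    def beta0(self) -> float:
        return float(self.params.iloc[0])

    @property
    def beta1(self) -> float:
        """Slope (continuous SVI) or the last quartile contrast coefficient."""
        return float(self.params.iloc[-1])

    @property
    def rate_ratio(self) -> float:
        return float(np.exp(self.beta1))


def fit_nb_rate_model(Y, n, design, year: int | None = None,
                      age_stratum: str | None = None,
                      quartiles: bool = True) -> NbFit:
    """Maximum-likelihood negative binomial (NB2) regression of outcome
    counts on SVI with a log-offset for births.

    Parameters
    ----------
    Y, n : county-level outcome counts and live births (offsets; all > 0).
    design : per-county SVI quartile labels (1-4, with ``quartiles=True``)
        or continuous SVI values.
    quartiles : fit quartile indicator contrasts (2 vs 1, 3 vs 1, 4 vs 1)
        rather than a single continuous slope.

    Returns an NbFit with Wald 95% CIs on the rate ratios e^beta.  The
    dispersion parameter is estimated by ML (statsmodels NegativeBinomial).
    """
    Y = np.asarray(Y, dtype=float)
    n = np.asarray(n, dtype=float)
    design = np.asarray(design)
    if Y.shape[0] < 20:
        raise ValueError("need at least 20 counties for a stable NB fit")
    if np.any(n <= 0):
        raise ValueError("offsets (births) must be positive")
    if quartiles:
        levels = np.unique(design)
        if levels.shape[0] < 2:
            raise ValueError("zero-variance design: a single SVI quartile")
        X = np.column_stack([(design == q).astype(float) for q in levels[1:]])
        names = ["const"] + [f"q{int(q)}_vs_q{int(levels[0])}" for q in levels[1:]]
    else:
        if np.ptp(design.astype(float)) == 0:
            raise ValueError("zero-variance design: constant SVI")
        X = design.astype(float)[:, None]
        names = ["const", "svi"]
    X = sm.add_constant(X, has_constant="add")

    model = sm.NegativeBinomial(Y, X, exposure=n, loglike_method="nb2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=200)
        except Exception:
            res = model.fit(method="nm", disp=0, maxiter=2000)
    converged = bool(res.mle_retvals.get("converged", False))
    if not converged:
        logger.warning("NB fit did not report convergence (year=%s, stratum=%s): "
                       "|grad|=%s", year, age_stratum,
                       res.mle_retvals.get("gopt", "n/a"))

    params = pd.Series(res.params[:-1], index=names)
    bse = pd.Series(res.bse[:-1], index=names)
    z = 1.959963984540054
    rows = []
    for name in names[1:]:
        b, se = params[name], bse[name]
        rows.append({"contrast": name, "rr": np.exp(b),
                     "lo": np.exp(b - z * se), "hi": np.exp(b + z * se)})
    return NbFit(
        year=year,
        age_stratum=age_stratum,
        params=params,
        bse=bse,
        dispersion=float(res.params[-1]),
        rate_ratios=pd.DataFrame(rows),
        converged=converged,
        n_obs=Y.shape[0],
    )


def ols_variance_explained(rates, themes: pd.DataFrame) -> pd.DataFrame:
    """OLS variance-explained table: one univariate model per SVI theme,
    then sequential models adding themes in order, ending at the fully
    adjusted model.

    ``rates`` is a per-county vector aligned with the rows of ``themes``
    (columns theme1..theme4).  Returns a table with model label, R^2, and
    the fitted coefficients.  Collinear columns are dropped with a flag.
    """
    y = np.asarray(rates, dtype=float)
    if y.shape[0] < 20:
        raise ValueError("need at least 20 counties")
    cols = [c for c in themes.columns if c.startswith("theme")]
    rows = []

    def _fit(use):
        X = themes[use].to_numpy(dtype=float)
        keep = list(use)
        if len(use) > 1:
            rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), X]))
            while rank < len(keep) + 1 and len(keep) > 1:
                dropped = keep.pop()
                logger.warning("dropping collinear SVI column %s", dropped)
                X = themes[keep].to_numpy(dtype=float)
                rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), X]))
        res = sm.OLS(y, sm.add_constant(X)).fit()
        coefs = {c: b for c, b in zip(keep, res.params[1:])}
        return res.rsquared, coefs

    for c in cols:
        r2, coefs = _fit([c])
        rows.append({"model": f"univariate:{c}", "r_squared": r2, **coefs})
    for j in range(2, len(cols) + 1):
        use = cols[:j]
        r2, coefs = _fit(use)
        label = "full" if j == len(cols) else f"sequential:{'+'.join(use)}"
        rows.append({"model": label, "r_squared": r2, **coefs})
    return pd.DataFrame(rows)


def profile_extreme_counties(rates: pd.Series, svi: SviTable, year: int) -> pd.DataFrame:
    """SVI profile of counties in the tails of the rate distribution.

    Counties at or below the 10th / at or above the 90th percentile of the
    (reliability-filtered) standardized rate are grouped; within each group
    the median percentile of the overall SVI and of each theme is reported
    (the synthetic SVI carries percentiles, not raw theme values).
    """
    rates = rates.dropna()
    sub = svi.for_year(year)
    common = rates.index.intersection(sub.index)
    rates = rates.loc[common]
    sub = sub.loc[common]
    lo_cut, hi_cut = np.quantile(rates.to_numpy(), [0.10, 0.90], method="linear")
    low = rates.index[rates <= lo_cut]
    high = rates.index[rates >= hi_cut]
    if len(low) == 0 or len(high) == 0:
        raise ValueError("empty extreme group; too few counties")
    rows = []
    for label, members in (("<=p10", low), (">=p90", high)):
        rec = {"group": label, "n_counties": len(members)}
        for c in SVI_COLUMNS:
            rec[f"median_{c}"] = float(sub.loc[members, c].median())
        rows.append(rec)
    return pd.DataFrame(rows)
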