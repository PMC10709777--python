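"""SVI tables, quartile assignment, NB rate ratios, OLS variance explained."""

import numpy as np
import pandas as pd
import pytest

import countysae as cs
from countysae.svi import SviTable, default_release_map


def _svi_table(values, release_year=2014, themes=None):
    n = len(values)
    df = pd.DataFrame(
        {
            "county_id": [f"{i:05d}" for i in range(n)],
            "release_year": release_year,
            "svi_overall": values,
        }
    )
    for j in range(1, 5):
        df[f"theme{j}"] = themes[j - 1] if themes else values
    return SviTable(df, default_release_map(range(2007, 2020), [release_year]))


def test_release_map_matches_time_varying_convention():
    rmap = default_release_map(range(2007, 2020), [2010, 2014, 2016, 2018])
    assert rmap[2007] == rmap[2011] == 2010
    assert rmap[2012] == rmap[2013] == rmap[2015] == 2014
    assert rmap[2016] == rmap[2017] == 2016
    assert rmap[2018] == rmap[2019] == 2018


def test_release_map_fallback_nearest():
    rmap = default_release_map([2000, 2003], [2001, 2005])
    assert rmap[2000] == 2001
    assert rmap[2003] == 2001  # tie 2001/2005 -> earlier


def test_quartiles_balanced_split():
    svi = _svi_table(np.linspace(0.1, 1.0, 8))
    q = cs.assign_svi_quartiles(svi, 2013)  # 2013 -> 2014 release
    assert sorted(q) == [1, 1, 2, 2, 3, 3, 4, 4]


def test_quartiles_all_tied_warns():
    svi = _svi_table(np.full(8, 0.5))
    with pytest.warns(UserWarning, match="quartile 1"):
        q = cs.assign_svi_quartiles(svi, 2013)
    assert set(q) == {1}


def test_quartiles_unmapped_year():
    svi = _svi_table(np.linspace(0.1, 1.0, 8))
    with pytest.raises(KeyError):
        cs.assign_svi_quartiles(svi, 1990)


def test_svi_percentile_bounds_enforced():
    with pytest.raises(ValueError, match="0, 1"):
        _svi_table(np.linspace(0.0, 1.0, 8))  # 0 is out of (0, 1]


def test_nb_no_signal_when_design_flat():
    """Identical counts and offsets: the SVI slope is zero at the optimum."""
    n = np.full(40, 1000.0)
    Y = np.full(40, 120.0)
    svi = np.linspace(0.025, 1, 40)
    fit = cs.fit_nb_rate_model(Y, n, svi, quartiles=False)
    assert fit.params["svi"] == pytest.approx(0.0, abs=1e-4)
    assert fit.rate_ratio == pytest.approx(1.0, abs=1e-4)
    assert fit.rate_ratio == pytest.approx(np.exp(fit.beta1), rel=1e-12)


def test_nb_matches_poisson_on_equidispersed_counts(rng):
    """As dispersion -> 0 the NB fit agrees with the Poisson fit."""
    import statsmodels.api as sm

    n = rng.integers(500, 5000, size=300).astype(float)
    svi = rng.random(300)
    mu = n * 0.12 * np.exp(0.3 * svi)
    Y = rng.poisson(mu).astype(float)
    nb = cs.fit_nb_rate_model(Y, n, svi, quartiles=False)
    X = sm.add_constant(svi)
    pois = sm.Poisson(Y, X, exposure=n).fit(disp=0)
    assert nb.params["svi"] == pytest.approx(pois.params[1], abs=1e-3)
    assert nb.dispersion < 0.01


def test_nb_quartile_gradient_recovery(rng):
    """Planted quartile gradient (1.08, 1.18, 1.34 vs quartile 1) is
    recovered by the quartile-contrast NB model."""
    N = 800
    n = rng.integers(500, 4000, size=N).astype(float)
    quart = np.repeat([1, 2, 3, 4], N // 4)
    beta = np.log([1.0, 1.08, 1.18, 1.34])[quart - 1]
    mu = n * 0.126 * np.exp(beta)
    lam = rng.gamma(shape=1 / 0.02, scale=0.02 * mu)  # NB2, alpha = 0.02
    Y = rng.poisson(lam).astype(float)
    fit = cs.fit_nb_rate_model(Y, n, quart, year=2007)
    rr = fit.rate_ratios.set_index("contrast")["rr"]
    assert rr["q4_vs_q1"] == pytest.approx(1.34, abs=0.06)
    assert rr["q2_vs_q1"] < rr["q3_vs_q1"] < rr["q4_vs_q1"]


def test_nb_preconditions():
    with pytest.raises(ValueError, match="20 counties"):
        cs.fit_nb_rate_model([1] * 5, [10] * 5, [1, 2, 3, 4, 1])
    with pytest.raises(ValueError, match="positive"):
        cs.fit_nb_rate_model([1] * 25, [0] * 25, [1, 2] * 12 + [1])
    with pytest.raises(ValueError, match="zero-variance"):
        cs.fit_nb_rate_model([1] * 25, [10] * 25, [2] * 25)


def test_ols_r2_exact_linear_function():
    themes = pd.DataFrame(
        np.random.default_rng(0).random((50, 4)),
        columns=["theme1", "theme2", "theme3", "theme4"],
    )
    y = 3.0 + 5.0 * themes["theme1"].to_numpy()
    out = cs.ols_variance_explained(y, themes)
    assert out.loc[out.model == "univariate:theme1", "r_squared"].iloc[0] == pytest.approx(1.0)


def test_ols_r2_null_case(rng):
    themes = pd.DataFrame(rng.random((400, 4)),
                          columns=["theme1", "theme2", "theme3", "theme4"])
    y = rng.normal(12, 2, size=400)
    out = cs.ols_variance_explained(y, themes)
    assert (out.loc[out.model.str.startswith("univariate"), "r_squared"] < 0.05).all()


def test_ols_r2_nesting_property(rng):
    themes = pd.DataFrame(rng.random((100, 4)),
                          columns=["theme1", "theme2", "theme3", "theme4"])
    y = 10 + themes["theme1"] * 2 + rng.normal(0, 1, 100)
    out = cs.ols_variance_explained(y.to_numpy(), themes)
    seq = out[~out.model.str.startswith("univariate")]["r_squared"].to_numpy()
    uni1 = out.loc[out.model == "univariate:theme1", "r_squared"].iloc[0]
    assert np.all(np.diff(np.concatenate([[uni1], seq])) >= -1e-12)
    assert ((out["r_squared"] >= 0) & (out["r_squared"] <= 1)).all()


def test_extreme_profile_monotone_and_sizes():
    n = 200
    rng_ = np.random.default_rng(5)
    rates = pd.Series(np.sort(rng_.uniform(8, 18, n)),
                      index=[f"{i:05d}" for i in range(n)])
    svi = _svi_table(np.linspace(1 / n, 1.0, n))  # SVI monotone in rate
    prof = cs.profile_extreme_counties(rates, svi, 2013)
    lo = prof[prof.group == "<=p10"].iloc[0]
    hi = prof[prof.group == ">=p90"].iloc[0]
    assert lo["median_svi_overall"] < hi["median_svi_overall"]
    assert lo["n_counties"] == pytest.approx(0.1 * n, abs=2)
    assert hi["n_counties"] == pytest.approx(0.1 * n, abs=2)


def test_extreme_profile_exchangeable_svi(rng):
    n = 300
    rates = pd.Series(rng.uniform(8, 18, n), index=[f"{i:05d}" for i in range(n)])
    perm = rng.permutation(n)
    svi = _svi_table((np.arange(1, n + 1) / n)[perm])  # independent of rates
    prof = cs.profile_extreme_counties(rates, svi, 2013)
    assert prof["median_svi_overall"].between(0.3, 0.7).all()


def test_generator_theme1_variance_explained_calibration():
    """The default SVI coupling targets theme-1 univariate R^2 of about
    0.27 against reference-year standardized rates (averaged over seeds to
    control the Monte-Carlo spread of a single 400-county draw)."""
    vals = []
    for seed in (1, 2, 3, 4):
        cfg = cs.SyntheticConfig(
            n_rows=20, n_cols=20, births_range=(200, 800), seed=seed)
        panel, truth = cs.generate_panel(cfg)
        svi = cs.generate_svi(cfg, truth, [2010])
        w = cs.reference_weights(panel, panel.years[0])
        crude = np.nan_to_num(panel.crude_rates())
        std = np.einsum("nk,k->n", crude[:, :, 0], w.weights)
        sub = svi.for_year(panel.years[0]).loc[panel.county_ids]
        out = cs.ols_variance_explained(
            std, sub[["theme1", "theme2", "theme3", "theme4"]])
        vals.append(out.loc[out.model == "univariate:theme1", "r_squared"].iloc[0])
    assert np.mean(vals) == pytest.approx(0.27, abs=0.05)
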