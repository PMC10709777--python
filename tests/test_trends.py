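"""Log-linear trend fits, percent-change classification, crude aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import countysae as cs
from countysae.trends import membership_units


def test_constant_series_gives_exact_zero_change():
    fit = cs.fit_loglinear_trend(np.full(13, 11.7))
    assert fit.beta1 == 0.0
    assert fit.pct_change == 0.0
    assert not fit.significant_increase and not fit.significant_decrease


def test_noiseless_exponential_closed_form():
    t = np.arange(13)
    fit = cs.fit_loglinear_trend(10.0 * np.exp(0.01 * t))
    assert fit.beta1 == pytest.approx(0.01, rel=1e-10)
    assert fit.pct_change == pytest.approx(100 * np.expm1(0.12), rel=1e-10)
    assert fit.se_beta1 == pytest.approx(0.0, abs=1e-12)


def test_preconditions():
    with pytest.raises(ValueError, match="3 years"):
        cs.fit_loglinear_trend([10.0, 11.0])
    with pytest.raises(ValueError, match="positive"):
        cs.fit_loglinear_trend([10.0, 0.0, 11.0])


@given(scale=st.floats(0.1, 10), seed=st.integers(0, 50))
def test_scale_equivariance(scale, seed):
    """Multiplying all rates by c shifts beta0 only; slope and percent
    change are unchanged."""
    r = np.random.default_rng(seed).uniform(8, 16, size=13)
    a = cs.fit_loglinear_trend(r)
    b = cs.fit_loglinear_trend(scale * r)
    assert b.beta1 == pytest.approx(a.beta1, rel=1e-9, abs=1e-12)
    assert b.pct_change == pytest.approx(a.pct_change, rel=1e-9, abs=1e-9)
    assert b.beta0 == pytest.approx(a.beta0 + np.log(scale), rel=1e-9)


def test_flag_iff_ci_excludes_zero():
    """A decline of about -5% whose CI spans zero is classified as no
    significant change; flags are mutually exclusive."""
    rng = np.random.default_rng(42)
    t = np.arange(13)
    found_nonsig_decline = False
    for _ in range(20):
        r = 12.6 * np.exp(np.log(0.95) / 12 * t + rng.normal(0, 0.04, 13))
        fit = cs.fit_loglinear_trend(r)
        assert not (fit.significant_increase and fit.significant_decrease)
        assert fit.significant_increase == (fit.ci_lo > 0)
        assert fit.significant_decrease == (fit.ci_hi < 0)
        if fit.pct_change < 0 and fit.ci_lo < 0 < fit.ci_hi:
            found_nonsig_decline = True
    assert found_nonsig_decline


def test_classify_single_significant_county():
    fit = cs.fit_loglinear_trend(10.0 * np.exp(0.05 * np.arange(13)))
    out = cs.classify_counties([fit])
    inc = out[(out["class"] == "increase")].iloc[0]
    assert inc["share"] == 1.0 and inc["n_units"] == 1


def test_classify_empty_errors():
    with pytest.raises(ValueError):
        cs.classify_counties([])


def test_aggregation_conserves_totals(small_panel):
    panel, _ = small_panel
    mapping = pd.Series("national", index=pd.Index(panel.county_ids))
    agg = cs.aggregate_crude(panel, mapping)
    assert agg.births.sum() == panel.births.sum()
    assert np.array_equal(agg.births[0], panel.births.sum(axis=0))
    assert np.array_equal(agg.preterm[0], panel.preterm.sum(axis=0))


def test_split_and_reaggregate_is_identity(small_panel):
    panel, _ = small_panel
    half = len(panel.county_ids) // 2
    mapping = pd.Series(
        ["left"] * half + ["right"] * (len(panel.county_ids) - half),
        index=pd.Index(panel.county_ids),
    )
    parts = cs.aggregate_crude(panel, mapping)
    merged = cs.aggregate_crude(parts, pd.Series("all", index=pd.Index(parts.county_ids)))
    assert np.array_equal(merged.births[0], panel.births.sum(axis=0))
    assert np.array_equal(merged.early_preterm[0], panel.early_preterm.sum(axis=0))


def test_membership_levels_and_rest_of_state():
    df = pd.DataFrame(
        {
            "county_id": ["A", "B", "C"],
            "state_id": ["S1", "S1", "S2"],
            "region_id": ["R1", "", ""],
        }
    )
    m = membership_units(df, "region")
    assert m["A"] == "R1"
    assert m["B"] == "rest_of_S1"
    assert m["C"] == "rest_of_S2"
    assert set(membership_units(df, "state")) == {"S1", "S2"}
    dup = pd.concat([df, df.iloc[[0]]])
    with pytest.raises(ValueError, match="two units"):
        membership_units(dup, "state")


def test_duplicate_unit_assignment_rejected(small_panel):
    panel, _ = small_panel
    mapping = pd.Series("x", index=pd.Index(panel.county_ids[:-1]))
    with pytest.raises(ValueError, match="missing"):
        cs.aggregate_crude(panel, mapping)


def test_flat_generator_slopes_center_on_zero():
    """With trend_sd = 0 the per-county fitted log-linear slopes on crude
    standardized rates center on zero."""
    cfg = cs.SyntheticConfig(n_rows=8, n_cols=8, trend_sd=0.0,
                             births_range=(500, 1500), seed=21)
    panel, _ = cs.generate_panel(cfg)
    w = cs.reference_weights(panel, panel.years[0])
    crude = np.nan_to_num(panel.crude_rates())
    std = np.einsum("nkt,k->nt", crude, w.weights)
    slopes = [cs.fit_loglinear_trend(std[i]).beta1 for i in range(std.shape[0])]
    assert np.mean(slopes) == pytest.approx(0.0, abs=0.002)
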