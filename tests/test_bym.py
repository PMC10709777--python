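"""BYM space-time-age estimator: collapse cases, shrinkage, reliability."""

import numpy as np
import pandas as pd
import pytest

import countysae as cs
from countysae.spatial import structure_from_edges


def _single_cell_panel(Y=12, n=100):
    return cs.CountPanel(["00001"], ["25-29"], [2007],
                         births=[[[n]]], preterm=[[[Y]]], early_preterm=[[[0]]])


def test_single_cell_collapses_to_poisson_rate():
    """One county, one age, one year: the model reduces to estimating a
    single Poisson rate, so the posterior median sits near Y/n = 12%."""
    panel = _single_cell_panel()
    structure = structure_from_edges([], ["00001"])
    model = cs.PretermBYMModel(panel, structure)
    res = model.fit(iterations=4000, burn_in=2000, thin=2, seed=3,
                    fixed_precisions={"v": 1e8, "phi": 1e8})
    assert res.point[0, 0, 0] == pytest.approx(12.0, abs=1.5)
    assert res.lo[0, 0, 0] < res.point[0, 0, 0] < res.hi[0, 0, 0]


def test_zero_count_county_shrinks_toward_neighbors():
    """A county observing 0/30 surrounded by neighbors at crude rate 15
    gets pulled strictly between 0 and the neighborhood rate."""
    ids = [f"{i:05d}" for i in range(9)]
    structure = structure_from_edges(cs.lattice_edges(3, 3, ids), ids)
    births = np.full((9, 1, 1), 200)
    preterm = np.full((9, 1, 1), 30)  # crude 15 per 100
    births[4] = 30
    preterm[4] = 0
    panel = cs.CountPanel(ids, ["25-29"], [2007], births, preterm,
                          np.zeros_like(preterm))
    res = cs.PretermBYMModel(panel, structure).fit(
        iterations=3000, burn_in=1500, thin=3, seed=5)
    center = res.point[4, 0, 0]
    assert 0.5 < center < 15.0
    assert center > 100 * 0 / 30  # strictly above the crude zero


def test_posterior_rates_bounded(small_fit):
    assert np.all(small_fit.point > 0)
    assert np.all(small_fit.point < 100)
    assert np.all(small_fit.lo <= small_fit.point)
    assert np.all(small_fit.point <= small_fit.hi)


def test_smoothing_beats_crude_on_small_counts():
    """The reason small-area estimation exists: smoothed cell rates have
    lower RMSE against truth than crude rates when counts are small."""
    cfg = cs.SyntheticConfig(n_rows=6, n_cols=6, years=tuple(range(2007, 2012)),
                             births_range=(30, 200), seed=13)
    panel, truth = cs.generate_panel(cfg)
    res = cs.PretermBYMModel(panel, truth.structure).fit(
        iterations=1500, burn_in=750, thin=3, seed=2)
    crude = panel.crude_rates()
    ok = ~np.isnan(crude)
    rmse_crude = np.sqrt(np.mean((crude[ok] - truth.true_rate[ok]) ** 2))
    rmse_smooth = np.sqrt(np.mean((res.point - truth.true_rate) ** 2))
    assert rmse_smooth < rmse_crude


def test_seed_reproducibility_and_mc_agreement(small_panel):
    panel, truth = small_panel
    model = cs.PretermBYMModel(panel, truth.structure)
    a = model.fit(iterations=1000, burn_in=500, thin=5, seed=11)
    b = model.fit(iterations=1000, burn_in=500, thin=5, seed=11)
    assert np.array_equal(a.lam_draws, b.lam_draws)  # bit-identical
    c = model.fit(iterations=1000, burn_in=500, thin=5, seed=12)
    # different seeds agree within Monte-Carlo error (3 MCSE, pooled)
    mcse = a.lam_draws.std(axis=0) / np.sqrt(a.n_saved)
    diff = np.abs(a.point - c.point)
    frac_within = np.mean(diff <= 3 * np.sqrt(2) * np.maximum(mcse, 0.05))
    assert frac_within > 0.95


def test_large_fixed_precisions_approach_pooled_age_rates(small_panel):
    """Smoothing limit: with all random-effect precisions pinned huge the
    fit collapses to the age-specific pooled national rates."""
    panel, truth = small_panel
    res = cs.PretermBYMModel(panel, truth.structure).fit(
        iterations=2000, burn_in=1000, thin=2, seed=4,
        fixed_precisions={"u": 1e8, "v": 1e8, "delta": 1e8, "phi": 1e8})
    pooled = 100 * panel.preterm.sum(axis=(0, 2)) / panel.births.sum(axis=(0, 2))
    est = np.median(res.point, axis=(0, 2))  # constant over counties/years
    assert np.allclose(est, pooled, rtol=0.05)
    assert res.point.std(axis=0).max() < 0.2  # no county variation left


def test_all_zero_birth_county_dropped_with_warning(caplog):
    ids = ["00001", "00002", "00003"]
    structure = structure_from_edges([("00001", "00002"), ("00002", "00003")], ids)
    births = np.array([[[100]], [[0]], [[100]]])
    preterm = np.array([[[10]], [[0]], [[12]]])
    panel = cs.CountPanel(ids, ["25-29"], [2007], births, preterm,
                          np.zeros_like(preterm))
    with caplog.at_level("WARNING"):
        model = cs.PretermBYMModel(panel, structure)
    assert model.panel.county_ids == ["00001", "00003"]
    assert "zero births" in caplog.text


def test_reliability_rule_hand_cases():
    """The mapping rule applied literally: width < point AND >= 100
    births in every year."""
    panel = cs.CountPanel(
        ["A", "B", "C"], ["25-29"], [2007, 2008],
        births=[[[150, 150]], [[150, 150]], [[150, 99]]],
        preterm=[[[15, 15]], [[15, 15]], [[15, 15]]],
        early_preterm=np.zeros((3, 1, 2), dtype=int),
    )
    std = pd.DataFrame(
        [
            # A: width 6.0 >= point 5.0 in 2008 -> unreliable
            {"county_id": "A", "year": 2007, "post_median": 12.0, "ci_lo": 10.0, "ci_hi": 14.0},
            {"county_id": "A", "year": 2008, "post_median": 5.0, "ci_lo": 2.0, "ci_hi": 8.0},
            # B: narrow CIs, births 150 every year -> reliable
            {"county_id": "B", "year": 2007, "post_median": 12.0, "ci_lo": 10.0, "ci_hi": 14.0},
            {"county_id": "B", "year": 2008, "post_median": 12.0, "ci_lo": 10.0, "ci_hi": 14.0},
            # C: narrow CIs but 99 births in 2008 -> unreliable
            {"county_id": "C", "year": 2007, "post_median": 12.0, "ci_lo": 11.0, "ci_hi": 13.0},
            {"county_id": "C", "year": 2008, "post_median": 12.0, "ci_lo": 11.0, "ci_hi": 13.0},
        ]
    )
    flags = cs.reliability_flags(std, panel, min_births=100)
    assert flags.to_dict() == {"A": False, "B": True, "C": False}


def test_summary_text(small_fit):
    text = small_fit.summary()
    assert "acceptance rates" in text
    assert "15-19" in text
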