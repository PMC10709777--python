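"""End-to-end pipeline: generate/load -> fit -> standardize -> associate ->
trends -> aggregate, driven by one YAML config with reproducible seeds.

Every stage reads its inputs from, and writes its outputs to, the run
directory as plain delimited text, so each stage can be re-run in
isolation.  A manifest records stage order, input/output content hashes,
wall times, the config hash and the seed — the audit trail for runs whose
filters (reliability, minimum births) change denominators.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bym import MCMCSettings, PretermBYMModel, reliability_flags
from .panel import CountPanel, read_panel, validate_panel
from .spatial import load_adjacency
from .standardize import bootstrap_gap_ci, disparity_summary, reference_weights
from .svi import (SviTable, assign_svi_quartiles, fit_nb_rate_model,
                  ols_variance_explained, profile_extreme_counties)
from .synthetic import (SyntheticConfig, generate_membership, generate_panel,
                        generate_svi, write_adjacency)
from .trends import (aggregate_crude, classify_counties, fit_loglinear_trend,
                     membership_units)

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

STAGES = ["simulate", "fit", "standardize", "associate", "trends", "aggregate"]


@dataclass
class PipelineConfig:
    """Validated run configuration (see docs for an annotated example)."""

    output_dir: str
    seed: int = 0
    outcome: str = "preterm"
    reference_year: int | None = None
    synthetic: dict | None = None
    inputs: dict | None = None
    mcmc: dict = field(default_factory=dict)
    bootstrap_B: int = 1000
    filters: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError(
                "config must carry exactly one of 'synthetic' or 'inputs'"
            )
        if self.outcome not in ("preterm", "early_preterm"):
            raise ValueError(f"outcome must be preterm or early_preterm, "
                             f"got {self.outcome!r}")
        if self.inputs is not None:
            for key in ("panel", "adjacency", "svi"):
                if key not in self.inputs:
                    raise ValueError(f"inputs missing required path: {key!r}")
        for k, v in self.filters.items():
            if k.startswith("min_") and v < 0:
                raise ValueError(f"filter {k} must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def mcmc_settings(self) -> MCMCSettings:
        kw = dict(self.mcmc)
        kw.setdefault("seed", self.seed)
        return MCMCSettings(**kw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class _Run:
    """Holds paths and the growing manifest for one pipeline run."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.output_dir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "stages": [],
        }

    def path(self, name: str) -> Path:
        return self.outdir / name

    def record(self, stage: str, inputs: list, outputs: list, t0: float):
        self.manifest["stages"].append(
            {
                "stage": stage,
                "inputs": {p.name: _sha256(p) for p in inputs if p.exists()},
                "outputs": {p.name: _sha256(p) for p in outputs},
                "wall_time_s": round(time.time() - t0, 3),
            }
        )

    def write_manifest(self):
        with open(self.path("manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=2)


# ---------------------------------------------------------------------------
# stages (each re-runnable from the previous stage's files)
# ---------------------------------------------------------------------------

def stage_simulate(run: _Run):
    """Generate (or copy in) panel, adjacency, SVI and membership files."""
    cfg = run.config
    t0 = time.time()
    panel_p, adj_p = run.path("panel.csv"), run.path("adjacency.csv")
    svi_p, mem_p = run.path("svi.csv"), run.path("membership.csv")
    if cfg.synthetic is not None:
        syn = SyntheticConfig(**{**cfg.synthetic, "seed": cfg.seed})
        panel, truth = generate_panel(syn)
        svi = generate_svi(syn, truth, [2010, 2014, 2016, 2018])
        panel.to_csv(panel_p)
        write_adjacency(truth.structure, adj_p)
        svi.to_csv(svi_p)
        generate_membership(syn).to_csv(mem_p, index=False)
    else:
        import shutil

        shutil.copy(cfg.inputs["panel"], panel_p)
        shutil.copy(cfg.inputs["adjacency"], adj_p)
        shutil.copy(cfg.inputs["svi"], svi_p)
        if "membership" in cfg.inputs:
            shutil.copy(cfg.inputs["membership"], mem_p)
    violations = validate_panel(panel_p)
    if violations:
        raise ValueError(f"stage simulate: panel validation failed: {violations[:3]}")
    run.record("simulate", [], [panel_p, adj_p, svi_p, mem_p], t0)


def stage_fit(run: _Run):
    """Fit the BYM space-time-age model; write posterior cell summaries."""
    cfg = run.config
    t0 = time.time()
    panel = read_panel(run.path("panel.csv"))
    n_before = len(panel.county_ids)
    min_age = int(cfg.filters.get("min_births_per_age", 0))
    if min_age:
        ok = (panel.births.min(axis=2) > min_age).all(axis=1)
        panel = panel.subset_counties(
            [c for c, keep in zip(panel.county_ids, ok) if keep]
        )
        logger.info("age-specific births filter: %d -> %d counties",
                    n_before, len(panel.county_ids))
    structure = load_adjacency(run.path("adjacency.csv"), panel.county_ids)
    model = PretermBYMModel(panel, structure, outcome=cfg.outcome)
    results = model.fit(settings=cfg.mcmc_settings())
    out = run.path("summaries.csv")
    results.to_dataframe().to_csv(out, index=False)
    (run.outdir / "fit_summary.txt").write_text(results.summary() + "\n")
    run._results = results  # in-memory handoff; files remain authoritative
    run.record("fit", [run.path("panel.csv"), run.path("adjacency.csv")],
               [out, run.path("fit_summary.txt")], t0)
    return results


def stage_standardize(run: _Run, results=None):
    """Age-standardize smoothed rates; disparity table with bootstrap CIs."""
    cfg = run.config
    t0 = time.time()
    panel = read_panel(run.path("panel.csv"))
    results = results or getattr(run, "_results", None)
    if results is None:
        raise RuntimeError("standardize requires the fit stage's results")
    rpanel = results.panel
    ref_year = cfg.reference_year or rpanel.years[0]
    w = reference_weights(rpanel, ref_year)
    std = results.age_standardized(w)
    flags = reliability_flags(std, rpanel,
                              min_births=int(cfg.filters.get("min_births", 100)))
    std = std.merge(flags.rename("reliable"), left_on="county_id", right_index=True)
    std_p = run.path("standardized.csv")
    std.to_csv(std_p, index=False)

    rows = []
    reliable = std[std["reliable"]]
    for yr in rpanel.years:
        rates = reliable.loc[reliable["year"] == yr, "post_median"].to_numpy()
        if rates.shape[0] < 10:
            logger.warning("year %s: only %d reliable counties; skipping "
                           "disparity summary", yr, rates.shape[0])
            continue
        summ = disparity_summary(rates, yr).as_dict()
        ci = bootstrap_gap_ci(rates, B=cfg.bootstrap_B, seed=cfg.seed + yr)
        summ.update(gap_ci_lo=ci["gap"][0], gap_ci_hi=ci["gap"][1],
                    ratio_ci_lo=ci["ratio"][0], ratio_ci_hi=ci["ratio"][1])
        rows.append(summ)
    disp_p = run.path("disparity.csv")
    pd.DataFrame(rows).to_csv(disp_p, index=False)
    run._standardized = std
    run.record("standardize", [run.path("summaries.csv")], [std_p, disp_p], t0)
    return std


def stage_associate(run: _Run):
    """SVI association: NB quartile rate ratios, OLS R^2, extreme profiles."""
    cfg = run.config
    t0 = time.time()
    panel = read_panel(run.path("panel.csv"))
    std = getattr(run, "_standardized", None)
    if std is None:
        raise RuntimeError("associate requires the standardize stage")
    svi = SviTable.from_csv(run.path("svi.csv"), panel.years)

    rr_rows = []
    Y_nt = panel.outcome_counts(cfg.outcome).sum(axis=1)  # (N, T)
    n_nt = panel.births.sum(axis=1)
    for yr in panel.years:
        t = panel.years.index(yr)
        quart = assign_svi_quartiles(svi, yr).reindex(panel.county_ids)
        keep = quart.notna() & (n_nt[:, t] > 0)
        if keep.sum() < 20:
            continue
        fit = fit_nb_rate_model(Y_nt[keep.to_numpy(), t],
                                n_nt[keep.to_numpy(), t],
                                quart[keep].to_numpy(), year=yr)
        for _, r in fit.rate_ratios.iterrows():
            rr_rows.append({"year": yr, "stratum": "all",
                            "contrast": r["contrast"], "rr": r["rr"],
                            "lo": r["lo"], "hi": r["hi"]})
    rr_p = run.path("rate_ratios.csv")
    pd.DataFrame(rr_rows).to_csv(rr_p, index=False)

    last = panel.years[-1]
    rates = (std[(std["year"] == last) & std["reliable"]]
             .set_index("county_id")["post_median"])
    themes = svi.for_year(last).loc[rates.index]
    r2_p = run.path("r_squared.csv")
    ols_variance_explained(rates.to_numpy(),
                           themes[["theme1", "theme2", "theme3", "theme4"]]
                           ).to_csv(r2_p, index=False)
    prof_p = run.path("extreme_profile.csv")
    profile_extreme_counties(rates, svi, last).to_csv(prof_p, index=False)
    run.record("associate", [run.path("svi.csv"), run.path("standardized.csv")],
               [rr_p, r2_p, prof_p], t0)


def stage_trends(run: _Run):
    """Per-county log-linear trends on smoothed standardized rates."""
    t0 = time.time()
    std = getattr(run, "_standardized", None)
    if std is None:
        raise RuntimeError("trends requires the standardize stage")
    reliable = std[std["reliable"]]
    fits, rows = [], []
    for cid, grp in reliable.sort_values("year").groupby("county_id"):
        fit = fit_loglinear_trend(grp["post_median"].to_numpy(), unit_id=cid)
        fits.append(fit)
        cls = ("increase" if fit.significant_increase
               else "decrease" if fit.significant_decrease else "flat")
        rows.append({"county_id": cid, "pct_change": fit.pct_change,
                     "ci_lo": fit.ci_lo, "ci_hi": fit.ci_hi, "class": cls})
    cls_p = run.path("county_trends.csv")
    pd.DataFrame(rows).to_csv(cls_p, index=False)
    share_p = run.path("trend_shares.csv")
    classify_counties(fits).to_csv(share_p, index=False)
    run.record("trends", [run.path("standardized.csv")], [cls_p, share_p], t0)


def stage_aggregate(run: _Run):
    """Crude aggregation to nation/state/region; standardized rates and
    trends per aggregate unit."""
    cfg = run.config
    t0 = time.time()
    panel = read_panel(run.path("panel.csv"))
    mem_p = run.path("membership.csv")
    rows = []
    ref_year = cfg.reference_year or panel.years[0]
    w = reference_weights(panel, ref_year)
    levels = ["national"]
    if mem_p.exists():
        mem_df = pd.read_csv(mem_p, dtype=str).fillna("")
        levels += ["state", "region"]
    for level in levels:
        if level == "national":
            mapping = pd.Series("national", index=pd.Index(panel.county_ids))
        else:
            mapping = membership_units(mem_df, level)
        agg = aggregate_crude(panel, mapping)
        y = agg.outcome_counts(cfg.outcome).astype(float)
        n = np.maximum(agg.births.astype(float), 1)
        rates_kt = 100.0 * y / n  # (U, K, T) crude age-specific rates
        std_ut = np.einsum("ukt,k->ut", rates_kt, w.weights)
        for j, unit in enumerate(agg.county_ids):
            series = std_ut[j]
            rec = {"level": level, "unit_id": unit}
            for t, yr in enumerate(agg.years):
                rec[f"rate_{yr}"] = series[t]
            if np.all(series > 0) and len(series) >= 3:
                fit = fit_loglinear_trend(series, unit_id=unit)
                rec.update(pct_change=fit.pct_change, ci_lo=fit.ci_lo,
                           ci_hi=fit.ci_hi)
            rows.append(rec)
    agg_p = run.path("aggregates.csv")
    pd.DataFrame(rows).to_csv(agg_p, index=False)
    run.record("aggregate", [run.path("panel.csv"), mem_p], [agg_p], t0)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages in order; returns the run directory.

    Outputs: panel/adjacency/svi/membership inputs, posterior summaries,
    standardized rates with reliability flags, disparity table, SVI
    rate-ratio and R^2 tables, county trend classification, aggregate
    rates/trends, and manifest.json with per-stage hashes and wall times.
    """
    run = _Run(config)
    stage_simulate(run)
    results = stage_fit(run)
    stage_standardize(run, results)
    stage_associate(run)
    stage_trends(run)
    stage_aggregate(run)
    run.write_manifest()
    return run.outdir
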