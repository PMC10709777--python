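"""Bayesian space-time-age smoothing of county birth-outcome rates.

The model is a Besag-York-Mollié (BYM) convolution extended across age
groups and years.  For county i, age group k and year t with outcome count
Y_ikt out of n_ikt live births:

    Y_ikt ~ Poisson(n_ikt * lambda_ikt / 100)
    log(lambda_ikt / 100) = alpha_k + u_i + v_i + delta_ik + phi_it

with
    alpha_k    age-group intercepts (flat prior),
    u_i        spatially structured effects, intrinsic CAR on the county
               adjacency graph,
    v_i        unstructured iid Normal(0, 1/tau_v) heterogeneity,
    delta_ik   county-age interactions, ICAR in space within each age
               column, exchangeable across ages (one shared precision),
    phi_it     county-specific first-order random walks in time.

Precisions carry Gamma(0.5, 0.0005) hyperpriors (shape, rate) — a
conventional weakly informative disease-mapping choice — and are updated by
conjugate Gibbs steps.  The log-linear effects are updated by adaptive
random-walk Metropolis targeting 0.44 acceptance; single-site updates are
vectorized over proper-coloring classes of the adjacency graph (sites in
one class are conditionally independent, so simultaneous accept/reject is a
valid parallel single-site sampler).  Sum-to-zero identifiability
constraints are enforced by recentering each block every sweep, with the
removed means folded into alpha (for u, delta) or v (for phi county means)
so the linear predictor is unchanged.

Rates are reported per 100 live births as posterior medians with 95%
credible intervals, following the reliability convention that a county is
mapped only when the credible-interval width is below the point estimate
and it recorded at least 100 births in every study year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import CountPanel
from .spatial import AdjacencyStructure, icar_quadratic_form

__all__ = ["MCMCSettings", "PretermBYMModel", "BYMResults", "fit_bym_st", "reliability_flags"]

logger = logging.getLogger(__name__)


@dataclass
class MCMCSettings:
    """Sampler settings. Defaults are desk-scale; all configurable."""

    iterations: int = 5000
    burn_in: int = 2500
    thin: int = 5
    seed: int | None = None
    prior_shape: float = 0.5
    prior_rate: float = 0.0005
    target_accept: float = 0.44
    adapt_rate: float = 0.05

    def __post_init__(self):
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


class PretermBYMModel:
    """Space-time-age BYM model bound to a count panel and adjacency graph.

    Parameters
    ----------
    panel : CountPanel
        Rectangular county x age x year counts.
    structure : AdjacencyStructure
        County neighbor graph over the same county set (order may differ).
    outcome : {"preterm", "early_preterm"}
        Which outcome column supplies Y_ikt.

    Counties with zero births in every cell carry no information and an
    undefined offset; they are dropped before fitting with a warning.
    """

    def __init__(self, panel: CountPanel, structure: AdjacencyStructure,
                 outcome: str = "preterm"):
        if set(panel.county_ids) != set(structure.county_ids):
            raise ValueError("panel and adjacency cover different county sets")
        if list(panel.county_ids) != list(structure.county_ids):
            order = [structure.county_ids.index(c) for c in panel.county_ids]
            # realign the graph to the panel's county order
            remap = {o: i for i, o in enumerate(order)}
            structure = AdjacencyStructure(
                county_ids=list(panel.county_ids),
                neighbor_lists=[
                    sorted(remap[j] for j in structure.neighbor_lists[o])
                    for o in order
                ],
            )
        dead = panel.births.sum(axis=(1, 2)) == 0
        if dead.any():
            keep = [c for c, d in zip(panel.county_ids, dead) if not d]
            logger.warning(
                "dropping %d counties with zero births in all cells: %s",
                int(dead.sum()),
                [c for c, d in zip(panel.county_ids, dead) if d],
            )
            panel = panel.subset_counties(keep)
            idx = np.flatnonzero(~dead)
            remap = {o: i for i, o in enumerate(idx)}
            structure = AdjacencyStructure(
                county_ids=keep,
                neighbor_lists=[
                    sorted(remap[j] for j in structure.neighbor_lists[o]
                           if j in remap)
                    for o in idx
                ],
            )
        self.panel = panel
        self.structure = structure
        self.outcome = outcome
        self.Y = panel.outcome_counts(outcome).astype(float)
        self.n = panel.births.astype(float)
        self.mask = self.n > 0

    # ------------------------------------------------------------------
    def fit(self, iterations: int = 5000, burn_in: int = 2500, thin: int = 5,
            seed: int | None = None, fixed_precisions: dict | None = None,
            settings: MCMCSettings | None = None) -> "BYMResults":
        """Run the Metropolis-within-Gibbs sampler and summarize rates.

        ``fixed_precisions`` may pin any of the blocks ``{"u","v","delta",
        "phi"}`` to a given precision (skipping its Gibbs update) — useful
        for smoothing-limit checks.  Deterministic given ``seed``.
        """
        if settings is None:
            settings = MCMCSettings(iterations=iterations, burn_in=burn_in,
                                    thin=thin, seed=seed)
        st = settings
        rng = np.random.default_rng(st.seed)
        fixed = dict(fixed_precisions or {})

        Y, n, mask = self.Y, self.n, self.mask
        N, K, T = Y.shape
        struct = self.structure
        W = struct.adjacency_matrix()
        deg = struct.n_neighbors.astype(float)
        colors = struct.coloring()
        n_comp_nonisolated = int(
            sum(1 for c in range(struct.n_components)
                if (struct.component_labels == c).sum() > 1)
        )
        icar_rank = N - struct.n_components  # rank of D - W
        isolated = deg == 0
        comp = struct.component_labels

        # state
        with np.errstate(divide="ignore"):
            alpha = np.log((Y.sum(axis=(0, 2)) + 0.5) / np.maximum(n.sum(axis=(0, 2)), 1.0))
        u = np.zeros(N)
        v = np.zeros(N)
        delta = np.zeros((N, K))
        phi = np.zeros((N, T))
        tau = {"u": 10.0, "v": 10.0, "delta": 10.0, "phi": 10.0}
        tau.update(fixed)

        # adaptive proposal scales (log-scale Robbins-Monro toward 0.44)
        s_alpha = np.full(K, 0.05)
        s_u = np.full(N, 0.1)
        s_v = np.full(N, 0.1)
        s_delta = np.full((N, K), 0.1)
        s_phi = np.full((N, T), 0.1)

        # per-group outcome totals (constant across iterations)
        Yk = Y.sum(axis=(0, 2)); Yi = Y.sum(axis=(1, 2))
        Yik = Y.sum(axis=2); Yit = Y.sum(axis=1)

        a0, b0 = st.prior_shape, st.prior_rate
        target, arate = st.target_accept, st.adapt_rate

        n_saved = (st.iterations - st.burn_in + st.thin - 1) // st.thin
        lam_draws = np.empty((n_saved, N, K, T), dtype=np.float32)
        tau_draws = {k_: np.empty(n_saved) for k_ in tau}
        alpha_draws = np.empty((n_saved, K))
        acc_count = {"alpha": 0.0, "u": 0.0, "v": 0.0, "delta": 0.0, "phi": 0.0}
        prop_count = {k_: 0.0 for k_ in acc_count}
        save_idx = 0

        def eta_full():
            return (alpha[None, :, None] + (u + v)[:, None, None]
                    + delta[:, :, None] + phi[:, None, :])

        for it in range(st.iterations):
            adapting = it < st.burn_in
            eta = eta_full()
            mu = np.where(mask, n * np.exp(eta), 0.0)

            # ---- alpha_k: flat prior, one cell-set per k (disjoint) -----
            d = s_alpha * rng.standard_normal(K)
            Mk = mu.sum(axis=(0, 2))
            dll = d * Yk - np.expm1(d) * Mk
            acc = np.log(rng.random(K)) < dll
            if acc.any():
                alpha[acc] += d[acc]
                mu[:, acc, :] *= np.exp(d[acc])[None, :, None]
            acc_count["alpha"] += acc.sum(); prop_count["alpha"] += K
            if adapting:
                s_alpha *= np.exp(arate * (acc - target))

            # ---- u_i: ICAR prior, per color class ----------------------
            for cls in colors:
                cls_a = cls[~isolated[cls]]
                if cls_a.size == 0:
                    continue
                d = s_u[cls_a] * rng.standard_normal(cls_a.size)
                Mi = mu.sum(axis=(1, 2))[cls_a]
                nbr = W @ u
                dprior = -0.5 * tau["u"] * (
                    deg[cls_a] * (2 * u[cls_a] * d + d * d) - 2 * d * nbr[cls_a]
                )
                dll = d * Yi[cls_a] - np.expm1(d) * Mi + dprior
                acc = np.log(rng.random(cls_a.size)) < dll
                ai = cls_a[acc]
                u[ai] += d[acc]
                mu[ai] *= np.exp(d[acc])[:, None, None]
                acc_count["u"] += acc.sum(); prop_count["u"] += cls_a.size
                if adapting:
                    s_u[cls_a] *= np.exp(arate * (acc - target))

            # ---- v_i: iid normal prior, all sites at once --------------
            d = s_v * rng.standard_normal(N)
            Mi = mu.sum(axis=(1, 2))
            dprior = -0.5 * tau["v"] * (2 * v * d + d * d)
            dll = d * Yi - np.expm1(d) * Mi + dprior
            acc = np.log(rng.random(N)) < dll
            v[acc] += d[acc]
            mu[acc] *= np.exp(d[acc])[:, None, None]
            acc_count["v"] += acc.sum(); prop_count["v"] += N
            if adapting:
                s_v *= np.exp(arate * (acc - target))

            # ---- delta_ik: ICAR per age column, per color class --------
            for cls in colors:
                cls_a = cls[~isolated[cls]]
                if cls_a.size == 0:
                    continue
                d = s_delta[cls_a] * rng.standard_normal((cls_a.size, K))
                Mik = mu.sum(axis=2)[cls_a]
                nbr = W @ delta  # (N, K)
                dprior = -0.5 * tau["delta"] * (
                    deg[cls_a, None] * (2 * delta[cls_a] * d + d * d)
                    - 2 * d * nbr[cls_a]
                )
                dll = d * Yik[cls_a] - np.expm1(d) * Mik + dprior
                acc = np.log(rng.random((cls_a.size, K))) < dll
                step = np.where(acc, d, 0.0)
                delta[cls_a] += step
                mu[cls_a] *= np.exp(step)[:, :, None]
                acc_count["delta"] += acc.sum(); prop_count["delta"] += acc.size
                if adapting:
                    s_delta[cls_a] *= np.exp(arate * (acc - target))

            # ---- phi_it: RW1 per county, by parity of t ----------------
            if T > 1:
                deg_t = np.full(T, 2.0); deg_t[0] = deg_t[-1] = 1.0
                for par in (0, 1):
                    ts = np.arange(par, T, 2)
                    d = s_phi[:, ts] * rng.standard_normal((N, ts.size))
                    Mit = mu.sum(axis=1)[:, ts]
                    nbr = np.zeros((N, ts.size))
                    left = ts - 1
                    ok = left >= 0
                    nbr[:, ok] += phi[:, left[ok]]
                    right = ts + 1
                    ok = right <= T - 1
                    nbr[:, ok] += phi[:, right[ok]]
                    dprior = -0.5 * tau["phi"] * (
                        deg_t[ts][None, :] * (2 * phi[:, ts] * d + d * d)
                        - 2 * d * nbr
                    )
                    dll = d * Yit[:, ts] - np.expm1(d) * Mit + dprior
                    acc = np.log(rng.random((N, ts.size))) < dll
                    step = np.where(acc, d, 0.0)
                    phi[:, ts] += step
                    # mu update: step varies by (i, t)
                    full_step = np.zeros((N, T)); full_step[:, ts] = step
                    mu *= np.exp(full_step)[:, None, :]
                    acc_count["phi"] += acc.sum(); prop_count["phi"] += acc.size
                    if adapting:
                        s_phi[:, ts] *= np.exp(arate * (acc - target))

            # ---- recenter (identifiability), predictor-preserving ------
            for c in range(struct.n_components):
                m_ = comp == c
                mc = u[m_].mean()
                u[m_] -= mc
                v[m_] += mc
            dm = delta.mean(axis=0)
            delta -= dm[None, :]
            alpha += dm
            if struct.n_components > 1:
                # residual per-component centering (approximate for islands)
                for c in range(struct.n_components):
                    m_ = comp == c
                    delta[m_] -= delta[m_].mean(axis=0, keepdims=True)
            pm = phi.mean(axis=1)
            phi -= pm[:, None]
            v += pm

            # ---- precisions: conjugate Gamma Gibbs ---------------------
            if "u" not in fixed:
                q = icar_quadratic_form(u, struct)
                tau["u"] = rng.gamma(a0 + 0.5 * icar_rank, 1.0 / (b0 + 0.5 * q))
            if "v" not in fixed:
                tau["v"] = rng.gamma(a0 + 0.5 * N, 1.0 / (b0 + 0.5 * np.sum(v * v)))
            if "delta" not in fixed:
                q = sum(icar_quadratic_form(delta[:, k_], struct) for k_ in range(K))
                tau["delta"] = rng.gamma(a0 + 0.5 * K * icar_rank, 1.0 / (b0 + 0.5 * q))
            if "phi" not in fixed and T > 1:
                q = np.sum(np.diff(phi, axis=1) ** 2)
                tau["phi"] = rng.gamma(a0 + 0.5 * N * (T - 1), 1.0 / (b0 + 0.5 * q))

            # ---- save ---------------------------------------------------
            if it >= st.burn_in and (it - st.burn_in) % st.thin == 0:
                lam_draws[save_idx] = (100.0 * np.exp(eta_full())).astype(np.float32)
                for k_ in tau:
                    tau_draws[k_][save_idx] = tau[k_]
                alpha_draws[save_idx] = alpha
                save_idx += 1

        accept = {k_: acc_count[k_] / max(prop_count[k_], 1.0) for k_ in acc_count}
        return BYMResults(
            model=self,
            lam_draws=lam_draws[:save_idx],
            tau_draws={k_: v_[:save_idx] for k_, v_ in tau_draws.items()},
            alpha_draws=alpha_draws[:save_idx],
            accept_rates=accept,
            settings=st,
        )


@dataclass
class BYMResults:
    """Posterior summaries and retained MCMC draws of the cell rates."""

    model: PretermBYMModel
    lam_draws: np.ndarray  # (S, N, K, T) rates per 100 live births
    tau_draws: dict
    alpha_draws: np.ndarray
    accept_rates: dict
    settings: MCMCSettings
    point: np.ndarray = field(init=False)
    lo: np.ndarray = field(init=False)
    hi: np.ndarray = field(init=False)

    def __post_init__(self):
        q = np.percentile(self.lam_draws, [2.5, 50.0, 97.5], axis=0)
        self.lo, self.point, self.hi = q[0], q[1], q[2]

    @property
    def n_saved(self) -> int:
        return self.lam_draws.shape[0]

    @property
    def panel(self) -> CountPanel:
        return self.model.panel

    # -- standardization over ages --------------------------------------
    def age_standardized_draws(self, weights) -> np.ndarray:
        """(S, N, T) draws of directly age-standardized county-year rates."""
        w = np.asarray(getattr(weights, "weights", weights), dtype=float)
        if w.shape[0] != self.lam_draws.shape[2]:
            raise ValueError("one weight per age group required")
        return np.einsum("snkt,k->snt", self.lam_draws, w)

    def age_standardized(self, weights) -> pd.DataFrame:
        """Posterior median and 95% CrI of standardized county-year rates."""
        draws = self.age_standardized_draws(weights)
        q = np.percentile(draws, [2.5, 50.0, 97.5], axis=0)
        p = self.panel
        recs = []
        for i, cid in enumerate(p.county_ids):
            for t, yr in enumerate(p.years):
                recs.append({"county_id": cid, "year": yr,
                             "post_median": q[1, i, t],
                             "ci_lo": q[0, i, t], "ci_hi": q[2, i, t]})
        return pd.DataFrame(recs)

    def reliability(self, weights, min_births: int = 100) -> pd.Series:
        """Per-county reliability flags on the standardized rates."""
        std = self.age_standardized(weights)
        return reliability_flags(std, self.panel, min_births=min_births)

    # -- export ----------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        """Long summary table: county, age group, year, median and 95% CrI."""
        p = self.panel
        idx = pd.MultiIndex.from_product(
            [p.county_ids, p.age_groups, p.years],
            names=["county_id", "age_group", "year"],
        )
        return pd.DataFrame(
            {
                "outcome": self.model.outcome,
                "post_median": self.point.reshape(-1),
                "ci_lo": self.lo.reshape(-1),
                "ci_hi": self.hi.reshape(-1),
            },
            index=idx,
        ).reset_index()

    def summary(self) -> str:
        lines = [
            "BYM space-time-age model — posterior summary",
            f"  outcome: {self.model.outcome}",
            f"  counties x ages x years: {self.point.shape}",
            f"  saved draws: {self.n_saved} "
            f"(of {self.settings.iterations}, burn-in {self.settings.burn_in}, "
            f"thin {self.settings.thin})",
            "  acceptance rates: "
            + ", ".join(f"{k}={r:.2f}" for k, r in self.accept_rates.items()),
            "  age-group intercepts (posterior median of exp(alpha_k)*100, per 100):",
        ]
        med = np.median(100 * np.exp(self.alpha_draws), axis=0)
        for ag, m in zip(self.panel.age_groups, med):
            lines.append(f"    {ag}: {m:6.2f}")
        lines.append("  precision posterior medians: "
                     + ", ".join(f"tau_{k}={np.median(v):.3g}"
                                 for k, v in self.tau_draws.items()))
        return "\n".join(lines)


def fit_bym_st(panel: CountPanel, structure: AdjacencyStructure,
               mcmc: MCMCSettings | None = None,
               outcome: str = "preterm") -> BYMResults:
    """Functional wrapper: build the model and fit with the given settings."""
    model = PretermBYMModel(panel, structure, outcome=outcome)
    return model.fit(settings=mcmc or MCMCSettings())


def reliability_flags(standardized: pd.DataFrame, panel: CountPanel,
                      min_births: int = 100) -> pd.Series:
    """County reliability per the mapping rule: for every study year, the
    95% credible-interval width must be below the point estimate AND total
    births (across age groups) must be at least ``min_births``.

    ``standardized`` must carry county_id, year, post_median, ci_lo, ci_hi.
    Returns a boolean Series indexed by county_id.
    """
    births_ny = panel.total_births_by_county_year()
    enough = pd.Series(
        (births_ny >= min_births).all(axis=1), index=panel.county_ids
    )
    width_ok = (
        standardized.assign(ok=lambda d: (d.ci_hi - d.ci_lo) < d.post_median)
        .groupby("county_id")["ok"].all()
    )
    flags = width_ok.reindex(panel.county_ids, fill_value=False) & enough
    flags.name = "reliable"
    return flags
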