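"""Fitting the minimal clone-fate model to clone tables.

Three layers:

* linear growth fits of μ(t) = ⟨ln n⟩ and σ²(t) = var(ln n) against cycle
  number (both grow linearly under the minimal model);
* a per-mouse effective-cycle regression that uses the coscaling of μ and σ²
  to regress out mouse-to-mouse timescale variability, anchored so that the
  mean effective cycle number at each nominal day equals day divided by the
  oestrous-cycle length (default 5.5 days, the midpoint of 4–7);
* simulated method of moments for (unit_size, p_activate, loss_prob): a
  coarse grid then Nelder–Mead, matching the surviving-fraction curve and
  the μ/σ² growth slopes between data and model simulations run with common
  random numbers. The expansion factor is assumed, not fitted — it is
  confounded with p_activate through the per-cycle drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import InsufficientDataError
from .io import CloneTable
from .minimal import MinimalModelParams, simulate
from .scaling import MomentSummary, log_moments

__all__ = [
    "GrowthFit",
    "FittedParams",
    "RecoveryReport",
    "fit_linear_growth",
    "infer_effective_cycles",
    "estimate_unit_size",
    "fit_model_params",
    "recovery_experiment",
]

ADMISSIBLE = {
    "unit_size": (1.0, 40.0),
    "p_activate": (0.005, 0.6),
    "loss_prob": (0.05, 0.95),
}


@dataclass
class GrowthFit:
    slope_mu: float
    slope_sigma2: float
    intercept_mu: float
    intercept_sigma2: float
    r2_mu: float
    r2_sigma2: float
    n_groups: int
    per_mouse_effective_cycles: Optional[dict[str, float]] = None


@dataclass
class FittedParams:
    unit_size_est: float
    p_activate_est: float
    loss_prob_est: float
    expansion_factor_assumed: float
    mutant_drift_delta: Optional[float] = None
    uncertainty: Optional[dict[str, tuple[float, float]]] = None
    objective: float = float("nan")


@dataclass
class RecoveryReport:
    true_params: dict[str, float]
    estimates: list[dict[str, float]]
    bias: dict[str, float]
    rmse: dict[str, float]
    n_replicates: int
    seed: int


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(slope, intercept, R²); R² = 1 for an exact fit / degenerate spread."""
    res = stats.linregress(x, y)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return float(res.slope), float(res.intercept), 1.0
    pred = res.slope * x + res.intercept
    r2 = 1.0 - float(((y - pred) ** 2).sum()) / ss_tot
    return float(res.slope), float(res.intercept), r2


def fit_linear_growth(
    summaries: Sequence[MomentSummary], x: Sequence[float]
) -> GrowthFit:
    """OLS of μ and σ² against cycle number (one summary per cycle value)."""
    x = np.asarray(x, dtype=float)
    if len(summaries) != x.size:
        raise ValueError("one x value per summary required")
    if np.unique(x).size < 3:
        raise InsufficientDataError("need >= 3 distinct cycle values")
    mu = np.array([s.mu for s in summaries])
    s2 = np.array([s.sigma2 for s in summaries])
    b_mu, a_mu, r2_mu = _ols(x, mu)
    b_s2, a_s2, r2_s2 = _ols(x, s2)
    return GrowthFit(
        slope_mu=b_mu,
        slope_sigma2=b_s2,
        intercept_mu=a_mu,
        intercept_sigma2=a_s2,
        r2_mu=r2_mu,
        r2_sigma2=r2_s2,
        n_groups=len(summaries),
    )


def infer_effective_cycles(
    per_mouse_summaries: Sequence[MomentSummary],
    anchor_days_per_cycle: float = 5.5,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> GrowthFit:
    """Joint fit of shared μ/σ² growth lines and per-mouse effective cycles.

    Alternating least squares: given effective cycles t_m, both lines are
    fitted by OLS; given the lines, each t_m minimises that mouse's summed
    squared residual of μ and σ² (closed form), clipped at 0. The overall
    timescale is fixed by rescaling so that the mean t_m of the mice at each
    nominal day equals day / anchor_days_per_cycle. Input: one summary per
    mouse carrying ``mouse_id`` and ``time_days`` group keys.
    """
    mice = [str(s.key("mouse_id")) for s in per_mouse_summaries]
    days = np.array([float(s.key("time_days")) for s in per_mouse_summaries])
    if len(mice) != len(set(mice)):
        raise ValueError("one summary per mouse required")
    if len(mice) < 3:
        raise InsufficientDataError("need >= 3 mice")
    mu = np.array([s.mu for s in per_mouse_summaries])
    s2 = np.array([s.sigma2 for s in per_mouse_summaries])
    t = days / anchor_days_per_cycle
    day_groups = {d: np.nonzero(days == d)[0] for d in np.unique(days)}

    def renormalise(t_vec: np.ndarray) -> np.ndarray:
        out = t_vec.copy()
        for d, idx in day_groups.items():
            target = d / anchor_days_per_cycle
            mean_t = out[idx].mean()
            out[idx] = target if mean_t <= 0 else out[idx] * (target / mean_t)
        return out

    if len(day_groups) < 2:
        # a single nominal timepoint carries no timescale information beyond
        # the anchor; effective cycles are day/anchor for every mouse
        b_mu, a_mu, r2m = 0.0, float(mu.mean()), 1.0 if np.ptp(mu) == 0 else 0.0
        b_s2, a_s2, r2s = 0.0, float(s2.mean()), 1.0 if np.ptp(s2) == 0 else 0.0
        return GrowthFit(
            slope_mu=b_mu, slope_sigma2=b_s2, intercept_mu=a_mu,
            intercept_sigma2=a_s2, r2_mu=r2m, r2_sigma2=r2s,
            n_groups=len(mice),
            per_mouse_effective_cycles={m: float(v) for m, v in zip(mice, t)},
        )

    prev_obj = np.inf
    for _ in range(max_iter):
        b_mu, a_mu, _ = _ols(t, mu)
        b_s2, a_s2, _ = _ols(t, s2)
        denom = b_mu**2 + b_s2**2
        if denom <= 0:
            break
        t = (b_mu * (mu - a_mu) + b_s2 * (s2 - a_s2)) / denom
        t = renormalise(np.maximum(t, 0.0))
        obj = float(((mu - a_mu - b_mu * t) ** 2 + (s2 - a_s2 - b_s2 * t) ** 2).sum())
        if prev_obj - obj <= tol * max(prev_obj, 1e-12):
            prev_obj = obj
            break
        prev_obj = obj
    else:
        raise RuntimeError(
            f"effective-cycle regression did not converge (residual {prev_obj:.3g})"
        )
    _, _, r2m = _ols(t, mu)
    _, _, r2s = _ols(t, s2)
    return GrowthFit(
        slope_mu=float(b_mu),
        slope_sigma2=float(b_s2),
        intercept_mu=float(a_mu),
        intercept_sigma2=float(a_s2),
        r2_mu=max(min(r2m, 1.0), 0.0),
        r2_sigma2=max(min(r2s, 1.0), 0.0),
        n_groups=len(mice),
        per_mouse_effective_cycles={m: float(v) for m, v in zip(mice, t)},
    )


def estimate_unit_size(surviving_fraction_plateau: float) -> float:
    """Unit size from the long-term surviving-clone fraction: u = 1/fraction.

    A plateau of 20% of recombined cells with long-term renewal capacity
    corresponds to 5-cell units; 10% to 10-cell units.
    """
    if not 0 < surviving_fraction_plateau <= 1:
        raise ValueError("surviving fraction must be in (0, 1]")
    return 1.0 / surviving_fraction_plateau


# ---------------------------------------------------------------------------
# Simulated method of moments
# ---------------------------------------------------------------------------


def _table_targets(
    days: np.ndarray, counts: np.ndarray, mus: np.ndarray, s2s: np.ndarray,
    cycles: np.ndarray,
) -> np.ndarray:
    """Target vector: log surviving-fraction ratios + μ/σ² growth slopes."""
    ratios = counts[1:] / counts[0]
    if cycles.size >= 2:
        slope_mu = _ols(cycles, mus)[0]
        slope_s2 = _ols(cycles, s2s)[0]
    else:  # pragma: no cover - guarded by caller
        slope_mu = slope_s2 = 0.0
    return np.concatenate([np.log(np.maximum(ratios, 1e-6)), [slope_mu, slope_s2]])


def _summarise_table(table: CloneTable, anchor: float):
    days = np.array(sorted({r.time_days for r in table.records}), dtype=float)
    if days.size < 2:
        raise InsufficientDataError("need >= 2 timepoints")
    if len(table) < 200:
        raise InsufficientDataError("need >= 200 clones")
    counts, mus, s2s = [], [], []
    for d in days:
        sizes = [r.size_cells for r in table.records if r.time_days == d]
        counts.append(len(sizes))
        m, v = log_moments(sizes)
        mus.append(m)
        s2s.append(v)
    cycles = days / anchor
    return days, np.array(counts, float), np.array(mus), np.array(s2s), cycles


def _simulate_targets(
    theta: np.ndarray,
    cycles: np.ndarray,
    assumed_f: float,
    descendant_persistence: float,
    n_sim: int,
    seed: int,
) -> Optional[np.ndarray]:
    u, pa, q = theta
    params = MinimalModelParams(
        unit_size=1,  # rooting handled analytically below via 1/u weighting
        p_activate=pa,
        expansion_factor=assumed_f,
        loss_prob=q,
        descendant_persistence=descendant_persistence,
        homeostasis=False,
        mouse_scale_sd=0.0,
    )
    max_cycle = int(round(cycles.max()))
    cyc_idx = np.round(cycles).astype(int)
    traj = simulate(params, n_sim, max_cycle, seed)
    counts, mus, s2s = [], [], []
    for t in cyc_idx:
        sizes = traj.sizes[:, t]
        alive = sizes > 0
        # expected surviving count mixes MaSC-rooted (simulated) and
        # descendant-rooted (pure geometric decay) clones with weights 1/u
        n_masc = alive.mean()
        n_desc = descendant_persistence**t
        counts.append(n_masc / u + n_desc * (1 - 1 / u))
        if alive.sum() < 5:
            return None
        # log-size moments: survivors are MaSC-rooted (size from simulation)
        # or descendant-rooted (size 1, ln = 0), weighted by survival mass
        ln = np.log(sizes[alive].astype(float))
        w_masc = (n_masc / u) / (n_masc / u + n_desc * (1 - 1 / u))
        mu_m, s2_m = float(ln.mean()), float(ln.var())
        mu_mix = w_masc * mu_m
        s2_mix = w_masc * (s2_m + mu_m**2) - mu_mix**2
        mus.append(mu_mix)
        s2s.append(s2_mix)
    counts = np.array(counts)
    return _table_targets(cyc_idx.astype(float), counts, np.array(mus), np.array(s2s), cycles)


def fit_model_params(
    table: CloneTable,
    assumed_f: float = 2.0,
    anchor_days_per_cycle: float = 5.5,
    n_sim: int = 5000,
    seed: int = 0,
    descendant_persistence: float = 0.8,
    n_boot: int = 100,
    weighting: str = "bootstrap",
) -> FittedParams:
    """Simulated method of moments for (unit_size, p_activate, loss_prob).

    Matches the surviving-fraction curve (log count ratios relative to the
    earliest timepoint) and the growth slopes of μ and σ² against nominal
    cycle number between the data and model simulations (``n_sim`` clones,
    common random numbers so the objective is deterministic per seed).
    Coarse grid search, then Nelder–Mead refinement, boxed to the admissible
    ranges. Targets are weighted by their inverse two-level bootstrap
    variance (clones within mouse, then mice); ``weighting="none"`` uses
    plain unweighted least squares. ``n_boot`` bootstrap refits give
    percentile intervals for the estimates; set 0 to skip the (slower)
    interval step — the objective weights are computed either way. When both genotypes are present the model is
    fitted to WT clones and ``mutant_drift_delta`` reports the mutant excess
    in the μ growth slope.
    """
    genotypes = sorted({r.genotype for r in table.records})
    mutant_drift_delta = None
    fit_table = table
    if len(genotypes) > 1:
        wt = table.subset(genotype="WT")
        mut = CloneTable(
            [r for r in table.records if r.genotype != "WT"], table.provenance
        )
        d_wt = _summarise_table(wt, anchor_days_per_cycle)
        d_mut = _summarise_table(mut, anchor_days_per_cycle)
        slope_wt = _ols(d_wt[4], d_wt[2])[0]
        slope_mut = _ols(d_mut[4], d_mut[2])[0]
        mutant_drift_delta = float(slope_mut - slope_wt)
        fit_table = wt

    days, counts, mus, s2s, cycles = _summarise_table(fit_table, anchor_days_per_cycle)
    target = _table_targets(days, counts, mus, s2s, cycles)
    if weighting == "bootstrap":
        weights = _bootstrap_weights(fit_table, anchor_days_per_cycle, seed, 100)
    elif weighting == "none":
        weights = np.ones(target.size)
    else:
        raise ValueError("weighting must be 'bootstrap' or 'none'")

    def objective(theta: np.ndarray) -> float:
        u, pa, q = theta
        lo_ok = (
            ADMISSIBLE["unit_size"][0] <= u <= ADMISSIBLE["unit_size"][1]
            and ADMISSIBLE["p_activate"][0] <= pa <= ADMISSIBLE["p_activate"][1]
            and ADMISSIBLE["loss_prob"][0] <= q <= ADMISSIBLE["loss_prob"][1]
        )
        if not lo_ok:
            return 1e6
        sim = _simulate_targets(
            theta, cycles, assumed_f, descendant_persistence, n_sim, seed + 10_000
        )
        if sim is None:
            return 1e6
        return float((weights * (sim - target) ** 2).sum())

    best_theta, best_obj = None, np.inf
    for u0 in (2.0, 4.0, 6.0, 8.0, 12.0):
        for pa0 in (0.05, 0.1, 0.2, 0.35):
            for q0 in (0.3, 0.5, 0.7):
                val = objective(np.array([u0, pa0, q0]))
                if val < best_obj:
                    best_obj, best_theta = val, np.array([u0, pa0, q0])
    res = optimize.minimize(
        objective,
        best_theta,
        method="Nelder-Mead",
        options={"maxiter": 200, "xatol": 1e-3, "fatol": 1e-8},
    )
    theta = res.x if res.fun <= best_obj else best_theta
    obj = min(float(res.fun), best_obj)

    uncertainty = None
    if n_boot > 0:
        uncertainty = _bootstrap_intervals(
            fit_table, theta, assumed_f, anchor_days_per_cycle,
            descendant_persistence, n_sim, seed, n_boot, weights,
        )
    return FittedParams(
        unit_size_est=float(theta[0]),
        p_activate_est=float(theta[1]),
        loss_prob_est=float(theta[2]),
        expansion_factor_assumed=assumed_f,
        mutant_drift_delta=mutant_drift_delta,
        uncertainty=uncertainty,
        objective=obj,
    )


def _resample_table(table: CloneTable, rng: np.random.Generator) -> CloneTable:
    """Two-level bootstrap: resample mice, then clones within each mouse."""
    by_mouse: dict[str, list] = {}
    for r in table.records:
        by_mouse.setdefault(r.mouse_id, []).append(r)
    mice = sorted(by_mouse)
    picked = rng.choice(len(mice), size=len(mice), replace=True)
    records = []
    for bi, mi in enumerate(picked):
        recs = by_mouse[mice[mi]]
        idx = rng.integers(len(recs), size=len(recs))
        for j in idx:
            rec = recs[j]
            # relabel so resampled copies of one mouse stay distinct strata
            records.append(
                type(rec)(
                    mouse_id=f"boot{bi:02d}",
                    gland_id=rec.gland_id,
                    genotype=rec.genotype,
                    lineage=rec.lineage,
                    time_days=rec.time_days,
                    size_cells=rec.size_cells,
                    location=rec.location,
                    branch_level=rec.branch_level,
                    transformed=rec.transformed,
                    color=rec.color,
                )
            )
    return CloneTable(records=records, provenance=table.provenance + "; bootstrap")


def _bootstrap_weights(
    table: CloneTable, anchor: float, seed: int, n_boot: int
) -> np.ndarray:
    """Inverse bootstrap-variance weights for the target vector."""
    days, counts, mus, s2s, cycles = _summarise_table(table, anchor)
    base = _table_targets(days, counts, mus, s2s, cycles)
    rng = np.random.default_rng(seed + 777)
    boots = []
    for _ in range(min(n_boot, 100)):
        bt = _resample_table(table, rng)
        try:
            d, c, m, v, cy = _summarise_table(bt, anchor)
        except InsufficientDataError:
            continue
        if d.size != days.size:
            continue
        boots.append(_table_targets(d, c, m, v, cy))
    if len(boots) < 10:
        return np.ones(base.size)
    var = np.asarray(boots).var(axis=0)
    return 1.0 / np.maximum(var, 1e-8)


def _bootstrap_intervals(
    table, theta, assumed_f, anchor, dp, n_sim, seed, n_boot, weights
) -> dict[str, tuple[float, float]]:
    rng = np.random.default_rng(seed + 999)
    estimates = []
    for _ in range(n_boot):
        bt = _resample_table(table, rng)
        try:
            days, counts, mus, s2s, cycles = _summarise_table(bt, anchor)
        except InsufficientDataError:
            continue
        target = _table_targets(days, counts, mus, s2s, cycles)

        def obj(th):
            if not all(
                lo <= v <= hi
                for v, (lo, hi) in zip(th, ADMISSIBLE.values())
            ):
                return 1e6
            sim = _simulate_targets(th, cycles, assumed_f, dp, max(n_sim // 2, 1000), seed + 10_000)
            if sim is None:
                return 1e6
            return float((weights[: target.size] * (sim - target) ** 2).sum())

        res = optimize.minimize(
            obj, theta, method="Nelder-Mead", options={"maxiter": 60, "xatol": 5e-3}
        )
        estimates.append(res.x)
    if not estimates:
        return {}
    est = np.asarray(estimates)
    names = ("unit_size", "p_activate", "loss_prob")
    return {
        n: (float(np.percentile(est[:, i], 2.5)), float(np.percentile(est[:, i], 97.5)))
        for i, n in enumerate(names)
    }


def recovery_experiment(
    true_params: MinimalModelParams,
    design,
    n_replicates: int,
    seed: int,
    n_sim: int = 5000,
) -> RecoveryReport:
    """Generate-and-refit harness: bias and RMSE of the fitted parameters."""
    from .synth import generate_clone_table  # local import avoids a cycle

    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    truth = {
        "unit_size": float(true_params.unit_size),
        "p_activate": float(true_params.p_activate),
        "loss_prob": float(true_params.loss_prob),
    }
    estimates = []
    for rep in range(n_replicates):
        rep_seed = int(np.random.SeedSequence(entropy=(seed, rep)).generate_state(1)[0] % 2**31)
        table = generate_clone_table(design, true_params, seed=rep_seed)
        fitted = fit_model_params(
            table,
            assumed_f=true_params.expansion_factor,
            anchor_days_per_cycle=design.days_per_cycle,
            n_sim=n_sim,
            seed=rep_seed,
            descendant_persistence=true_params.descendant_persistence,
            n_boot=0,
        )
        estimates.append(
            {
                "unit_size": fitted.unit_size_est,
                "p_activate": fitted.p_activate_est,
                "loss_prob": fitted.loss_prob_est,
            }
        )
    bias, rmse = {}, {}
    for name, true_val in truth.items():
        vals = np.array([e[name] for e in estimates])
        bias[name] = float((vals - true_val).mean())
        rmse[name] = float(np.sqrt(((vals - true_val) ** 2).mean()))
    return RecoveryReport(
        true_params=truth,
        estimates=estimates,
        bias=bias,
        rmse=rmse,
        n_replicates=n_replicates,
        seed=seed,
    )
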