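"""Bayesian unification of asynchronous embryo time series.

Two-phase model.

Phase 1 (*staging*): each experimental series ``s`` has four parameters —
initial mean developmental age ``t0``, growth rate ``g`` relative to the
standard clock, initial stage-distribution variance ``sigma0_sq``, and
the rate ``variance_rate`` at which that variance grows.  A sample taken
at experiment time ``t`` is a mixture over standard stages with weights
given by the discretized Gaussian age distribution (see
:mod:`wormcycle.stages`).  The observation model for inference gene g in
sample j is lognormal around the composition-weighted mixture:

    log x_gj ~ N( log( sum_k w_jk(params) E_gk ), sigma_g^2 ).

Staging parameters, the per-gene stage profiles ``E`` (on the log
scale, under a weak smoothness prior) and per-gene noise variances are
sampled jointly: vectorized per-stage random-walk updates for ``log E``
across all genes at once, conjugate inverse-gamma Gibbs steps for
``sigma_g^2``, and adaptive scalar Metropolis–Hastings for the staging
parameters.  Only the staging posterior is retained from this phase.

Because compositions are invariant to a common stretch of the clock
(all ``g`` and ``t0`` scaled together, profiles re-indexed), the
absolute scale is anchored by the lognormal(0, 0.25) prior on each
growth rate; relative rates are data-identified.

Phase 2 (*deconvolution*): with compositions fixed at their posterior
point estimate, each gene's per-stage expression ``E_k`` is sampled on
the log scale (nonnegativity by construction) under a lognormal
observation model ``log x_j ~ N(log(sum_k w_jk E_k), sigma_g^2)`` with a
weak smoothness prior across stages and a conjugate inverse-gamma update
for the per-gene noise variance.  Posterior means and central credible
intervals per stage form the unified series; stages receiving almost no
composition weight anywhere are flagged unidentified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stages import composition_matrix

__all__ = [
    "McmcConfig",
    "SeriesStagingModel",
    "StagingFit",
    "UnifiedSeries",
    "select_inference_genes",
    "fit_staging",
    "deconvolve",
    "calibrate_time",
    "call_regulated",
]


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings (defaults sized for production runs; scale down for tests)."""

    chains: int = 4
    burn_in: int = 5000
    iterations: int = 20000
    thin: int = 5
    seed: int = 0
    credible: float = 0.95
    target_accept: float = 0.3
    rhat_threshold: float = 1.1


@dataclass
class SeriesStagingModel:
    """Posterior summary for one series' staging parameters."""

    series_id: str
    t0: float
    growth_rate: float
    sigma0_sq: float
    variance_rate: float
    samples: pd.DataFrame  # kept posterior draws, one column per parameter
    rhat: dict[str, float]
    converged: bool


@dataclass
class StagingFit:
    models: dict[str, SeriesStagingModel]
    compositions: dict[str, pd.DataFrame]  # sample x stage weights at posterior median
    acceptance: dict[str, float]
    warm_start: dict | None = None


@dataclass
class UnifiedSeries:
    """Per-gene per-stage posterior expression with credible bounds."""

    mean: pd.DataFrame
    lower: pd.DataFrame
    upper: pd.DataFrame
    credible: float
    unidentified_stages: list[str]
    ess: pd.DataFrame | None = None


def select_inference_genes(matrices: dict[str, pd.DataFrame] | pd.DataFrame, n: int) -> pd.Index:
    """Top-``n`` genes by mean dcpm across all samples of all series.

    Deterministic: ties broken by gene_id (ascending).
    """
    if isinstance(matrices, dict):
        combined = pd.concat(matrices.values(), axis=1)
    else:
        combined = matrices
    if n > combined.shape[0]:
        raise ValueError(f"n={n} exceeds number of genes {combined.shape[0]}")
    means = combined.mean(axis=1)
    df = pd.DataFrame({"mean": means.to_numpy(), "gene_id": means.index})
    df = df.sort_values(["mean", "gene_id"], ascending=[False, True])
    return pd.Index(df["gene_id"].head(n), name="gene_id")


# ---------------------------------------------------------------------------
# phase 1: staging
# ---------------------------------------------------------------------------

def _composition_rows(theta_row: np.ndarray, times: np.ndarray, stage_times: np.ndarray):
    t0, log_g, log_s0sq, log_vr = theta_row
    means = t0 + np.exp(log_g) * times
    variances = np.exp(log_s0sq) + np.exp(log_vr) * times
    return composition_matrix(means, variances, stage_times)


def _staging_log_prior(theta: np.ndarray, stage_times: np.ndarray) -> float:
    """Weakly informative priors anchoring the clock's scale and origin.

    Growth is lognormal(0, 0.25) — without it a common stretch of all
    clocks is a near-symmetry.  t0 is normal around half a stage step
    after the grid start (the standard clock's origin is defined by
    where the series begin, so populations start near it); without this
    a common translation of all clocks drifts freely.  Variances are
    half-normal with log-parameterization Jacobians.
    """
    span_lo = stage_times[0] - 2 * (stage_times[1] - stage_times[0])
    span_hi = stage_times[-1]
    step = stage_times[1] - stage_times[0]
    t0_center = stage_times[0] + 0.5 * step
    lp = 0.0
    for t0, log_g, log_s0sq, log_vr in theta:
        if not (span_lo <= t0 <= span_hi):
            return -np.inf
        lp += -0.5 * ((t0 - t0_center) / 20.0) ** 2            # t0 ~ N(start + step/2, 20 min)
        lp += -0.5 * (log_g / 0.25) ** 2                       # growth ~ lognormal(0, 0.25)
        s0sq, vr = np.exp(log_s0sq), np.exp(log_vr)
        lp += -0.5 * (s0sq / 400.0) ** 2 + log_s0sq            # half-normal(400) + Jacobian
        lp += -0.5 * (vr / 2.0) ** 2 + log_vr                  # half-normal(2) + Jacobian
    return lp


def _split_rhat(chains: np.ndarray) -> float:
    """Gelman-Rubin split-R^ for one parameter; chains shape (n_chains, n_draws)."""
    half = chains.shape[1] // 2
    if half < 2:
        return np.nan
    parts = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = parts.shape
    means = parts.mean(axis=1)
    b = n * np.var(means, ddof=1)
    w = np.mean(np.var(parts, axis=1, ddof=1))
    if w <= 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


_PARAM_NAMES = ("t0", "growth_rate", "sigma0_sq", "variance_rate")


def fit_staging(
    series: dict[str, pd.DataFrame],
    stage_times: np.ndarray,
    sample_times: dict[str, np.ndarray] | None = None,
    genes: pd.Index | None = None,
    config: McmcConfig = McmcConfig(),
    smoothness_sd: float = 2.0,
) -> StagingFit:
    """Infer per-series staging parameters and sample stage compositions.

    Parameters
    ----------
    series
        Mapping series_id -> gene x sample dcpm matrix.  Sample times in
        minutes are taken from ``sample_times`` or from each frame's
        ``attrs['sample_times']``.
    stage_times
        The standard stage grid (minutes).
    genes
        Inference gene subset (default: all genes present in every series).
    """
    sids = list(series)
    if sample_times is None:
        sample_times = {
            sid: np.array([series[sid].attrs["sample_times"][c] for c in series[sid].columns])
            for sid in sids
        }
    for sid in sids:
        if len(sample_times[sid]) < 2:
            raise ValueError(f"series {sid} needs at least 2 samples")
    if genes is None:
        genes = series[sids[0]].index
        for sid in sids[1:]:
            genes = genes.intersection(series[sid].index)
    X = np.concatenate([series[sid].loc[genes].to_numpy() for sid in sids], axis=1)
    floor = 1e-8  # keep the full dynamic range: sharp decay tails identify widths
    logX = np.log(np.maximum(X, floor))
    G = X.shape[0]

    stage_times = np.asarray(stage_times, dtype=float)
    S = stage_times.size
    n_series = len(sids)
    n_par = 4 * n_series
    offsets = [0] + list(np.cumsum([len(sample_times[sid]) for sid in sids]).tolist())
    times_list = [np.asarray(sample_times[sid], dtype=float) for sid in sids]

    def build_W_series(theta, i):
        return _composition_rows(theta[i], times_list[i], stage_times)

    span = stage_times[-1] - stage_times[0]
    init = np.zeros(n_par)
    for i in range(n_series):
        # start narrow: conditional on sharp profiles the width likelihood
        # is well-behaved, while an over-smooth start self-reinforces
        init[4 * i : 4 * i + 4] = (stage_times[0], 0.0, np.log(25.0), np.log(0.05))
    step0 = np.tile([0.06 * span / 10, 0.03, 0.4, 0.4], n_series)
    a0, b0 = 2.0, 0.08          # weak inverse-gamma prior on per-gene noise variance
    d2_scale = 1.0 / (2.0 * smoothness_sd**2)
    N = offsets[-1]

    def profile_prior(th):
        d2 = th[:, 2:] - 2 * th[:, 1:-1] + th[:, :-2]
        return -d2_scale * np.sum(d2**2, axis=1)

    # ---- coordinate-ascent warm start: alternate greedy profile fitting
    # with 1-D conditional optimization of each staging parameter.  The
    # posterior couples profiles and compositions strongly; chains
    # started from this joint mode mix well where cold chains stall.
    # Run from a narrow and a wide composition start and keep the better
    # mode (collapsed posterior, noise variances integrated out).
    from scipy.optimize import minimize_scalar

    def _map_start(s0_init: float, vr_init: float):
        rng = np.random.default_rng([config.seed, 524287])
        vec = init.copy()
        for i in range(n_series):
            vec[4 * i + 2] = np.log(s0_init)
            vec[4 * i + 3] = np.log(vr_init)
        theta = vec.reshape(n_series, 4)
        W = np.concatenate([build_W_series(theta, i) for i in range(n_series)], axis=0)
        wsum = np.maximum(W.sum(axis=0), 1e-12)
        Theta = np.log(np.maximum((X @ W) / wsum, floor))
        E = np.exp(Theta)
        M = E @ W.T
        sigma2 = np.full(G, 0.1)
        bounds = {
            0: (stage_times[0] - 2 * (stage_times[1] - stage_times[0]), stage_times[-1]),
            1: (-0.7, 0.7),
            2: (np.log(1.0), np.log(2500.0)),
            3: (np.log(1e-4), np.log(10.0)),
        }
        prev_obj = np.inf
        for rnd in range(20):
            # greedy stage sweeps on profiles, annealed proposal scale
            prof_scale = 0.3 if rnd < 6 else (0.1 if rnd < 12 else 0.05)
            for _ in range(15):
                for k in range(S):
                    prop_k = Theta[:, k] + rng.normal(0, prof_scale, size=G)
                    dE = np.exp(prop_k) - E[:, k]
                    M_p = M + dE[:, None] * W[None, :, k]
                    res = logX - np.log(np.maximum(M_p, floor))
                    ll_p = -0.5 * np.sum(res**2, axis=1) / sigma2
                    th_p = Theta.copy()
                    th_p[:, k] = prop_k
                    cur = (-0.5 * np.sum((logX - np.log(np.maximum(M, floor))) ** 2, axis=1)
                           / sigma2 + profile_prior(Theta))
                    better = (ll_p + profile_prior(th_p)) > cur
                    if np.any(better):
                        Theta[better, k] = prop_k[better]
                        E[better, k] = np.exp(prop_k[better])
                        M[better] = M_p[better]
            rss = np.sum((logX - np.log(np.maximum(M, floor))) ** 2, axis=1)
            sigma2 = (b0 + 0.5 * rss) / (a0 + 0.5 * N)
            # conditional 1-D optimization of each staging parameter
            for p in range(n_par):
                i, j = divmod(p, 4)
                sl = slice(offsets[i], offsets[i + 1])

                def negpost(val, p=p, i=i, sl=sl):
                    v2 = vec.copy()
                    v2[p] = val
                    th2 = v2.reshape(n_series, 4)
                    lp = _staging_log_prior(th2, stage_times)
                    if not np.isfinite(lp):
                        return 1e30
                    Wi = build_W_series(th2, i)
                    Mi = E @ Wi.T
                    r = logX[:, sl] - np.log(np.maximum(Mi, floor))
                    return float(np.sum(0.5 * np.sum(r**2, axis=1) / sigma2) - lp)

                # coarse grid first: conditional surfaces can be nearly
                # discontinuous when compositions approach point masses
                lo, hi = bounds[j]
                grid = np.linspace(lo, hi, 33)
                vals = [negpost(v) for v in grid]
                ix = int(np.argmin(vals))
                cell = grid[1] - grid[0]
                res = minimize_scalar(
                    negpost,
                    bounds=(max(lo, grid[ix] - cell), min(hi, grid[ix] + cell)),
                    method="bounded", options={"xatol": 1e-4},
                )
                if res.fun < negpost(vec[p]):
                    vec[p] = float(res.x)
                    theta = vec.reshape(n_series, 4)
                    W[sl] = build_W_series(theta, i)
                    M[:, sl] = E @ W[sl].T
            obj = float(np.sum(rss / sigma2))
            if prev_obj - obj < 1e-3 * abs(prev_obj) and rnd >= 10:
                break
            prev_obj = obj
        rss = np.sum((logX - np.log(np.maximum(M, floor))) ** 2, axis=1)
        collapsed = (
            float(np.sum((a0 + 0.5 * N) * np.log(b0 + 0.5 * rss)))
            - float(np.sum(profile_prior(Theta)))
            - _staging_log_prior(vec.reshape(n_series, 4), stage_times)
        )
        return vec, Theta, collapsed

    starts = [_map_start(25.0, 0.05), _map_start(225.0, 0.5)]
    map_vec, map_Theta, map_obj = min(starts, key=lambda s: s[2])
    warm_diag = {"start_objs": [s[2] for s in starts],
                 "start_vecs": [s[0].copy() for s in starts]}

    # ---- refinement: the ascent can lock profiles to slightly wrong bin
    # assignments (a conditional trap of ~1-2% in growth).  Rescan each
    # series' clock jointly over (t0, growth) with near-point-mass
    # compositions — there the profile estimate is just the per-bin
    # average, so candidates are cheap to score exactly.  Candidates only
    # replace the incumbent when their collapsed objective is better, so
    # genuinely mixed (noisy, wide) data keep the ascent solution.
    def _collapsed_with_fresh_profiles(vec_cand, rng, sweeps=12):
        theta_c = vec_cand.reshape(n_series, 4)
        lp = _staging_log_prior(theta_c, stage_times)
        if not np.isfinite(lp):
            return np.inf, None
        W = np.concatenate([build_W_series(theta_c, i) for i in range(n_series)], axis=0)
        wsum = np.maximum(W.sum(axis=0), 1e-12)
        Theta = np.log(np.maximum((X @ W) / wsum, floor))
        E = np.exp(Theta)
        M = E @ W.T
        rss = np.sum((logX - np.log(np.maximum(M, floor))) ** 2, axis=1)
        sigma2 = (b0 + 0.5 * rss) / (a0 + 0.5 * N)
        for sweep in range(sweeps):
            scale = 0.3 if sweep < 6 else 0.1
            for k in range(S):
                prop_k = Theta[:, k] + rng.normal(0, scale, size=G)
                dE = np.exp(prop_k) - E[:, k]
                M_p = M + dE[:, None] * W[None, :, k]
                res = logX - np.log(np.maximum(M_p, floor))
                ll_p = -0.5 * np.sum(res**2, axis=1) / sigma2
                th_p = Theta.copy()
                th_p[:, k] = prop_k
                cur = (-0.5 * np.sum((logX - np.log(np.maximum(M, floor))) ** 2, axis=1)
                       / sigma2 + profile_prior(Theta))
                better = (ll_p + profile_prior(th_p)) > cur
                if np.any(better):
                    Theta[better, k] = prop_k[better]
                    E[better, k] = np.exp(prop_k[better])
                    M[better] = M_p[better]
            rss = np.sum((logX - np.log(np.maximum(M, floor))) ** 2, axis=1)
            sigma2 = (b0 + 0.5 * rss) / (a0 + 0.5 * N)
        obj = (float(np.sum((a0 + 0.5 * N) * np.log(b0 + 0.5 * rss)))
               - float(np.sum(profile_prior(Theta))) - lp)
        return obj, Theta

    rng_ref = np.random.default_rng([config.seed, 999983])
    grid_step = stage_times[1] - stage_times[0]
    for i in range(n_series):
        best_cand = None
        for t0_c in np.linspace(map_vec[4 * i] - grid_step, map_vec[4 * i] + grid_step, 31):
            for g_fac in np.linspace(-0.06, 0.06, 25):
                cand = map_vec.copy()
                cand[4 * i] = t0_c
                cand[4 * i + 1] += g_fac
                cand[4 * i + 2] = np.log(0.01)   # near-point mass: sd 0.1 min
                cand[4 * i + 3] = np.log(1e-6)
                obj_c, _ = _collapsed_with_fresh_profiles(cand, rng_ref, sweeps=0)
                if best_cand is None or obj_c < best_cand[0]:
                    best_cand = (obj_c, cand)
        if best_cand is not None and best_cand[0] < map_obj:
            obj_c, Theta_c = _collapsed_with_fresh_profiles(best_cand[1], rng_ref, sweeps=12)
            if obj_c < map_obj:
                map_vec, map_Theta, map_obj = best_cand[1], Theta_c, obj_c

    keep_every = max(config.thin, 1)
    all_draws = []
    accept_counts = np.zeros(n_par)
    propose_counts = np.zeros(n_par)
    for chain in range(config.chains):
        rng = np.random.default_rng([config.seed, 7919, chain])
        vec = map_vec + rng.normal(0, 0.005, size=n_par) * (1 + np.abs(map_vec))
        theta = vec.reshape(n_series, 4)
        W = np.concatenate([build_W_series(theta, i) for i in range(n_series)], axis=0)
        Theta = map_Theta.copy()
        E = np.exp(Theta)
        M = E @ W.T
        rss0 = np.sum((logX - np.log(np.maximum(M, floor))) ** 2, axis=1)
        sigma2 = (b0 + 0.5 * rss0) / (a0 + 0.5 * N)
        cur_lp_params = _staging_log_prior(theta, stage_times)
        cur_res = logX - np.log(np.maximum(M, floor))
        cur_ll_g = -0.5 * np.sum(cur_res**2, axis=1) / sigma2
        cur_prof = profile_prior(Theta)

        step = step0.copy()
        prof_step = np.full((G, S), 0.3)
        acc_batch = np.zeros(n_par)
        prof_acc = np.zeros((G, S))
        draws = []
        total = config.burn_in + config.iterations
        for it in range(total):
            # --- vectorized per-stage update of all gene profiles
            for k in range(S):
                prop_k = Theta[:, k] + rng.normal(0, prof_step[:, k], size=G)
                dE = np.exp(prop_k) - E[:, k]
                M_p = M + dE[:, None] * W[None, :, k]
                res = logX - np.log(np.maximum(M_p, floor))
                ll_p = -0.5 * np.sum(res**2, axis=1) / sigma2
                th_p = Theta.copy()
                th_p[:, k] = prop_k
                prof_p = profile_prior(th_p)
                accept = np.log(rng.random(G)) < (ll_p + prof_p) - (cur_ll_g + cur_prof)
                if np.any(accept):
                    Theta[accept, k] = prop_k[accept]
                    E[accept, k] = np.exp(prop_k[accept])
                    M[accept] = M_p[accept]
                    cur_ll_g[accept] = ll_p[accept]
                    cur_prof[accept] = prof_p[accept]
                    prof_acc[accept, k] += 1
            # --- Gibbs update of per-gene noise variances
            rss = np.sum((logX - np.log(np.maximum(M, floor))) ** 2, axis=1)
            sigma2 = 1.0 / rng.gamma(a0 + 0.5 * N, 1.0 / (b0 + 0.5 * rss))
            cur_ll_g = -0.5 * rss / sigma2
            # --- staging parameter updates (scalar MH, one series block at a time)
            for p in rng.permutation(n_par):
                i, j = divmod(p, 4)
                prop = vec.copy()
                prop[p] += rng.normal(0, step[p])
                th_p = prop.reshape(n_series, 4)
                lp_p = _staging_log_prior(th_p, stage_times)
                if it >= config.burn_in:
                    propose_counts[p] += 1
                if not np.isfinite(lp_p):
                    continue
                Wi = build_W_series(th_p, i)
                sl = slice(offsets[i], offsets[i + 1])
                M_i = E @ Wi.T
                res_i = logX[:, sl] - np.log(np.maximum(M_i, floor))
                d_ll = float(
                    np.sum(
                        (-0.5 * np.sum(res_i**2, axis=1)
                         + 0.5 * np.sum((logX[:, sl] - np.log(np.maximum(M[:, sl], floor))) ** 2,
                                        axis=1))
                        / sigma2
                    )
                )
                if np.log(rng.random()) < d_ll + lp_p - cur_lp_params:
                    vec, theta, cur_lp_params = prop, th_p, lp_p
                    W[sl] = Wi
                    M[:, sl] = M_i
                    cur_ll_g = -0.5 * np.sum((logX - np.log(np.maximum(M, floor))) ** 2, axis=1) / sigma2
                    acc_batch[p] += 1
                    if it >= config.burn_in:
                        accept_counts[p] += 1
            # --- adaptation during burn-in
            if it < config.burn_in and (it + 1) % 50 == 0:
                step *= np.exp(np.clip(acc_batch / 50.0 - config.target_accept, -0.5, 0.5))
                prof_step *= np.exp(np.clip(prof_acc / 50.0 - 0.35, -0.5, 0.5))
                acc_batch[:] = 0
                prof_acc[:] = 0
            if it >= config.burn_in and (it - config.burn_in) % keep_every == 0:
                draws.append(vec.copy())
        all_draws.append(np.array(draws))

    draws = np.stack(all_draws)  # chains x kept x n_par
    flat = draws.reshape(-1, n_par)
    med = np.median(flat, axis=0)

    models: dict[str, SeriesStagingModel] = {}
    compositions: dict[str, pd.DataFrame] = {}
    stage_cols = [f"stage{k:02d}" for k in range(S)]
    for i, sid in enumerate(sids):
        cols = {}
        raw = draws[:, :, 4 * i : 4 * i + 4]
        cols["t0"] = raw[:, :, 0]
        cols["growth_rate"] = np.exp(raw[:, :, 1])
        cols["sigma0_sq"] = np.exp(raw[:, :, 2])
        cols["variance_rate"] = np.exp(raw[:, :, 3])
        rhat = {k: _split_rhat(v) for k, v in cols.items()}
        samples = pd.DataFrame({k: v.reshape(-1) for k, v in cols.items()})
        medians = samples.median()
        W_i = _composition_rows(
            np.array([medians["t0"], np.log(medians["growth_rate"]),
                      np.log(medians["sigma0_sq"]), np.log(medians["variance_rate"])]),
            np.asarray(sample_times[sid], dtype=float),
            stage_times,
        )
        compositions[sid] = pd.DataFrame(
            W_i, index=pd.Index(series[sid].columns, name="sample_id"), columns=stage_cols
        )
        models[sid] = SeriesStagingModel(
            series_id=sid,
            t0=float(medians["t0"]),
            growth_rate=float(medians["growth_rate"]),
            sigma0_sq=float(medians["sigma0_sq"]),
            variance_rate=float(medians["variance_rate"]),
            samples=samples,
            rhat=rhat,
            converged=all(
                (np.isnan(v) or v < config.rhat_threshold) for v in rhat.values()
            ),
        )
    accept = {
        "overall": float(accept_counts.sum() / max(propose_counts.sum(), 1)),
    }
    warm_diag["chosen_vec"] = map_vec
    return StagingFit(models=models, compositions=compositions, acceptance=accept,
                      warm_start=warm_diag)


# ---------------------------------------------------------------------------
# phase 2: deconvolution
# ---------------------------------------------------------------------------

def deconvolve(
    series: dict[str, pd.DataFrame],
    compositions: dict[str, pd.DataFrame],
    config: McmcConfig = McmcConfig(),
    weight_floor: float = 0.01,
    smoothness_sd: float = 0.5,
) -> UnifiedSeries:
    """Deconvolve mixed-stage samples into one per-stage expression series.

    Observation model per gene g and sample j:
    ``log x_gj ~ N(log(sum_k w_jk E_gk), sigma_g^2)`` with ``E = exp(theta)``
    sampled by vectorized per-stage random-walk MH across all genes at
    once, a weak Gaussian prior on second differences of ``theta``
    (scale ``smoothness_sd``), and conjugate inverse-gamma resampling of
    each gene's noise variance.

    Stages whose total composition weight across all samples is below
    ``weight_floor`` are reported in ``unidentified_stages``.
    """
    sids = list(series)
    genes = series[sids[0]].index
    X = np.concatenate([series[sid].loc[genes].to_numpy() for sid in sids], axis=1)
    W = np.concatenate([compositions[sid].to_numpy() for sid in sids], axis=0)
    stage_cols = list(compositions[sids[0]].columns)
    G, N = X.shape
    S = W.shape[1]
    floor = 1e-3  # dcpm detection floor: bounds the log dynamic range for stable fits
    logX = np.log(np.maximum(X, floor))

    unidentified = [stage_cols[k] for k in range(S) if W[:, k].sum() < weight_floor]

    rng = np.random.default_rng([config.seed, 104729])
    # init: per-gene weighted back-projection of observed values
    wsum = np.maximum(W.sum(axis=0), 1e-12)
    E0 = np.maximum((X @ W) / wsum, floor)
    theta = np.log(E0)
    a0, b0 = 1.0, 1e-4
    rss0 = np.sum((logX - np.log(np.maximum(E0 @ W.T, floor))) ** 2, axis=1)
    sigma2 = (b0 + 0.5 * rss0) / (a0 + 0.5 * X.shape[1])

    E = np.exp(theta)
    M = E @ W.T  # G x N mixtures
    step = np.full((G, S), 0.3)
    # Student-t smoothness on second differences of log E: behaves like a
    # Gaussian of scale ``smoothness_sd`` for small curvature but its
    # penalty saturates at genuine corners (e.g. expression collapsing to
    # the detection floor), which a quadratic penalty would flatten even
    # against a decisive likelihood.
    t_df = 4.0

    def prior_vec(th):
        d2 = th[:, 2:] - 2 * th[:, 1:-1] + th[:, :-2]
        return -0.5 * (t_df + 1.0) * np.sum(
            np.log1p(d2**2 / (t_df * smoothness_sd**2)), axis=1
        )

    cur_res = logX - np.log(np.maximum(M, floor))
    cur_ll = -0.5 * np.sum(cur_res**2, axis=1) / sigma2
    cur_lp = prior_vec(theta)

    total = config.burn_in + config.iterations
    keep_every = max(config.thin, 1)
    sums = np.zeros((G, S))
    sums2 = np.zeros((G, S))
    kept_draws = []
    n_kept = 0
    acc = np.zeros((G, S))
    for it in range(total):
        for k in range(S):
            prop_k = theta[:, k] + rng.normal(0, step[:, k], size=G)
            dE = np.exp(prop_k) - E[:, k]
            M_p = M + dE[:, None] * W[None, :, k]
            res = logX - np.log(np.maximum(M_p, floor))
            ll_p = -0.5 * np.sum(res**2, axis=1) / sigma2
            th_p = theta.copy()
            th_p[:, k] = prop_k
            lp_p = prior_vec(th_p)
            accept = np.log(rng.random(G)) < (ll_p + lp_p) - (cur_ll + cur_lp)
            if np.any(accept):
                theta[accept, k] = prop_k[accept]
                E[accept, k] = np.exp(prop_k[accept])
                M[accept] = M_p[accept]
                cur_ll[accept] = ll_p[accept]
                cur_lp[accept] = lp_p[accept]
                acc[accept, k] += 1
        # Gibbs update of per-gene noise variance
        rss = np.sum((logX - np.log(np.maximum(M, floor))) ** 2, axis=1)
        sigma2 = 1.0 / rng.gamma(a0 + 0.5 * N, 1.0 / (b0 + 0.5 * rss))
        cur_ll = -0.5 * rss / sigma2
        if it < config.burn_in and (it + 1) % 50 == 0:
            step *= np.exp(np.clip(acc / 50.0 - 0.35, -0.5, 0.5))
            acc[:] = 0
        if it >= config.burn_in and (it - config.burn_in) % keep_every == 0:
            sums += E
            sums2 += E**2
            kept_draws.append(E.copy())
            n_kept += 1

    draws = np.array(kept_draws)  # n_kept x G x S
    mean = sums / n_kept
    alpha = (1.0 - config.credible) / 2.0
    lower = np.quantile(draws, alpha, axis=0)
    upper = np.quantile(draws, 1.0 - alpha, axis=0)
    idx = pd.Index(genes, name="gene_id")
    return UnifiedSeries(
        mean=pd.DataFrame(mean, index=idx, columns=stage_cols),
        lower=pd.DataFrame(lower, index=idx, columns=stage_cols),
        upper=pd.DataFrame(upper, index=idx, columns=stage_cols),
        credible=config.credible,
        unidentified_stages=unidentified,
    )


# ---------------------------------------------------------------------------
# calibration and regulation calls
# ---------------------------------------------------------------------------

def calibrate_time(pseudotimes: np.ndarray, anchor_minutes: np.ndarray) -> tuple[float, float]:
    """Least-squares affine map pseudotime -> minutes: returns (slope, intercept)."""
    pseudotimes = np.asarray(pseudotimes, dtype=float)
    anchor_minutes = np.asarray(anchor_minutes, dtype=float)
    if pseudotimes.size < 2:
        raise ValueError("need at least 2 anchors for an affine fit")
    slope, intercept = np.polyfit(pseudotimes, anchor_minutes, 1)
    return float(slope), float(intercept)


def call_regulated(
    unified: UnifiedSeries, min_fold: float = 1.5
) -> pd.DataFrame:
    """Up/down regulation calls between adjacent stages from credible intervals.

    A gene is called *up* at transition k->k+1 when the lower credible
    bound at stage k+1 exceeds the upper bound at stage k (and the
    posterior-mean fold change is at least ``min_fold``); *down* is
    symmetric.  Overlapping intervals give no call.
    """
    cols = list(unified.mean.columns)
    records = []
    lo, hi, mean = unified.lower, unified.upper, unified.mean
    eps = 1e-12
    for k in range(len(cols) - 1):
        a, b = cols[k], cols[k + 1]
        fold_up = mean[b] / np.maximum(mean[a], eps)
        fold_dn = mean[a] / np.maximum(mean[b], eps)
        up = (lo[b] > hi[a]) & (fold_up >= min_fold)
        down = (hi[b] < lo[a]) & (fold_dn >= min_fold)
        for gid in unified.mean.index[up]:
            records.append({"transition": f"{a}->{b}", "gene_id": gid, "direction": "up"})
        for gid in unified.mean.index[down]:
            records.append({"transition": f"{a}->{b}", "gene_id": gid, "direction": "down"})
    return pd.DataFrame(records, columns=["transition", "gene_id", "direction"])
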