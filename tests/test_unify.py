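"""Staging, deconvolution, time calibration and regulation calls."""

import numpy as np
import pandas as pd
import pytest

from wormcycle.stages import stage_grid
from wormcycle.synthetic_data import SeriesSpec, SimulationConfig, simulate_series
from wormcycle.unify import (
    McmcConfig,
    calibrate_time,
    call_regulated,
    deconvolve,
    fit_staging,
    select_inference_genes,
    UnifiedSeries,
)

FAST = McmcConfig(chains=1, burn_in=300, iterations=800, thin=2, seed=3)


class TestSelectInferenceGenes:
    def test_identity_when_n_equals_total(self, small_sim):
        _, series, _ = small_sim
        sel = select_inference_genes(series, series["series0"].shape[0])
        assert set(sel) == set(series["series0"].index)

    def test_single_top_gene(self):
        m = pd.DataFrame({"a": [1.0, 5.0, 2.0]},
                         index=pd.Index(["g0", "g1", "g2"], name="gene_id"))
        assert list(select_inference_genes(m, 1)) == ["g1"]

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.uniform(0, 10, size=(50, 4)),
                         index=pd.Index([f"g{i:02d}" for i in range(50)], name="gene_id"))
        sel = select_inference_genes(m, 20)
        oracle = sorted(m.index, key=lambda g: (-m.loc[g].mean(), g))[:20]
        assert list(sel) == oracle

    def test_rejects_oversized_n(self):
        m = pd.DataFrame({"a": [1.0]}, index=pd.Index(["g"], name="gene_id"))
        with pytest.raises(ValueError):
            select_inference_genes(m, 2)


class TestFitStaging:
    def test_noiseless_single_series_growth_recovered(self):
        """Identifiable noiseless limit: growth posterior median within 1% of 1.

        More samples than stage bins, so any clock distortion forces two
        unequal samples into one bin and is rejected by the exact fit.
        t0 offsets the population so no embryo age sits exactly on a
        stage-bin edge (a measure-zero degeneracy of the noiseless case).
        """
        spec = SeriesSpec(t0=7.3, growth_rate=1.0, sigma0=0.0, variance_rate=0.0,
                          sample_times=tuple(np.linspace(0, 570, 25)))
        cfg = SimulationConfig(n_genes=50, n_stages=20, series_specs=(spec,),
                               lognormal_sd=0.0, seed=21)
        series, _ = simulate_series(cfg)
        fit = fit_staging(series, stage_grid(20), config=FAST)
        assert abs(fit.models["series0"].growth_rate - 1.0) < 0.01

    def test_composition_rows_are_probability_vectors(self, small_sim):
        _, series, _ = small_sim
        genes = select_inference_genes(series, 60)
        fit = fit_staging(series, stage_grid(20), genes=genes, config=FAST)
        for comp in fit.compositions.values():
            w = comp.to_numpy()
            assert np.all(w >= 0)
            np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-9)

    def test_too_few_samples_rejected(self):
        df = pd.DataFrame({"s0": [1.0]}, index=pd.Index(["g"], name="gene_id"))
        df.attrs["sample_times"] = {"s0": 0.0}
        with pytest.raises(ValueError):
            fit_staging({"x": df}, stage_grid(5))


class TestDeconvolve:
    def test_identity_composition_limit(self, noiseless_identity_sim):
        """No mixing, no noise: posterior means reproduce inputs within 1%."""
        _, series, truth = noiseless_identity_sim
        uni = deconvolve(series, truth.per_sample_composition,
                         config=McmcConfig(chains=1, burn_in=500, iterations=1000,
                                           thin=2, seed=5))
        E = truth.stage_expression.to_numpy()
        m = uni.mean.to_numpy()
        mask = E > 0.01
        rel = np.abs(m - E)[mask] / E[mask]
        assert rel.max() < 0.01

    def test_two_stage_linear_solve_oracle(self):
        """2 stages x 2 samples with known weights: matches exact solve."""
        W = np.array([[0.8, 0.2], [0.3, 0.7]])
        E_true = np.array([[4.0, 1.0], [0.5, 6.0], [2.0, 2.0]])
        X = E_true @ W.T
        genes = pd.Index([f"g{i}" for i in range(3)], name="gene_id")
        series = {"s": pd.DataFrame(X, index=genes, columns=["a", "b"])}
        comps = {"s": pd.DataFrame(W, index=pd.Index(["a", "b"], name="sample_id"),
                                   columns=["stage00", "stage01"])}
        uni = deconvolve(series, comps,
                         config=McmcConfig(chains=1, burn_in=1000, iterations=3000,
                                           thin=2, seed=8))
        sd = (uni.upper.to_numpy() - uni.lower.to_numpy()) / 4  # ~95% interval
        err = np.abs(uni.mean.to_numpy() - E_true)
        assert np.all(err <= 2 * sd + 0.02 * E_true)

    def test_gene_permutation_equivariance(self, noiseless_identity_sim):
        _, series, truth = noiseless_identity_sim
        cfg = McmcConfig(chains=1, burn_in=100, iterations=200, thin=1, seed=9)
        (sid, df), = series.items()
        perm = df.index[::-1]
        uni1 = deconvolve({sid: df}, truth.per_sample_composition, config=cfg)
        uni2 = deconvolve({sid: df.loc[perm]}, truth.per_sample_composition, config=cfg)
        # same genes recovered regardless of order (sampler streams are per-run,
        # so compare values loosely)
        np.testing.assert_allclose(
            uni1.mean.loc[perm].to_numpy(), uni2.mean.to_numpy(), rtol=0.2, atol=0.05
        )

    def test_unidentified_stage_flagged(self):
        genes = pd.Index(["g0"], name="gene_id")
        X = pd.DataFrame([[1.0, 2.0]], index=genes, columns=["a", "b"])
        W = pd.DataFrame([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]],
                         index=pd.Index(["a", "b"], name="sample_id"),
                         columns=["stage00", "stage01", "stage02"])
        uni = deconvolve({"s": X}, {"s": W},
                         config=McmcConfig(chains=1, burn_in=50, iterations=100, thin=1, seed=1))
        assert uni.unidentified_stages == ["stage02"]

    def test_noise_ladder_rmse_decreases(self, grid20):
        """Deconvolution is consistent: less noise, lower recovery error."""
        rmses = []
        for sd in (0.4, 0.1, 0.0):
            cfg = SimulationConfig(n_genes=40, n_stages=20, lognormal_sd=sd, seed=33)
            series, truth = simulate_series(cfg)
            uni = deconvolve(series, truth.per_sample_composition,
                             config=McmcConfig(chains=1, burn_in=300, iterations=700,
                                               thin=2, seed=2))
            E = truth.stage_expression.to_numpy()
            m = uni.mean.to_numpy()
            sel = E.max(axis=1) > 1
            denom = np.maximum(E[sel], 0.1)
            rmses.append(np.sqrt(np.mean(((m[sel] - E[sel]) / denom) ** 2)))
        assert rmses[0] > rmses[1] > rmses[2]


class TestCalibrateTime:
    def test_identity_map(self):
        t = np.array([0.0, 100.0, 300.0])
        slope, intercept = calibrate_time(t, t)
        assert slope == pytest.approx(1.0, abs=1e-9)
        assert intercept == pytest.approx(0.0, abs=1e-9)

    def test_inverse_affine(self):
        minutes = np.array([0.0, 50.0, 120.0, 200.0])
        pseudo = 2 * minutes + 10
        slope, intercept = calibrate_time(pseudo, minutes)
        assert slope == pytest.approx(0.5, abs=1e-12)
        assert intercept == pytest.approx(-5.0, abs=1e-9)

    def test_noisy_anchors_match_normal_equations(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 600, 20)
        y = 1.3 * x - 7 + rng.normal(0, 5, 20)
        slope, intercept = calibrate_time(x, y)
        A = np.vstack([x, np.ones_like(x)]).T
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert slope == pytest.approx(beta[0], rel=1e-9)
        assert intercept == pytest.approx(beta[1], rel=1e-6)

    def test_single_anchor_rejected(self):
        with pytest.raises(ValueError):
            calibrate_time(np.array([1.0]), np.array([2.0]))


class TestCallRegulated:
    @staticmethod
    def _unified(mean, lo, hi):
        idx = pd.Index([f"g{i}" for i in range(mean.shape[0])], name="gene_id")
        cols = [f"stage{k:02d}" for k in range(mean.shape[1])]
        mk = lambda a: pd.DataFrame(a, index=idx, columns=cols)
        return UnifiedSeries(mean=mk(mean), lower=mk(lo), upper=mk(hi),
                             credible=0.95, unidentified_stages=[])

    def test_clear_increase_called_up(self):
        uni = self._unified(np.array([[1.0, 3.0]]), np.array([[0.8, 2.5]]),
                            np.array([[1.2, 3.5]]))
        calls = call_regulated(uni)
        assert list(calls.direction) == ["up"]

    def test_overlapping_intervals_no_call(self):
        uni = self._unified(np.array([[1.0, 1.4]]), np.array([[0.5, 0.9]]),
                            np.array([[1.5, 1.9]]))
        assert len(call_regulated(uni)) == 0

    def test_fold_filter_suppresses_small_changes(self):
        uni = self._unified(np.array([[1.0, 1.2]]), np.array([[0.98, 1.15]]),
                            np.array([[1.02, 1.25]]))
        assert len(call_regulated(uni, min_fold=1.5)) == 0
        assert len(call_regulated(uni, min_fold=1.0)) == 1

    def test_step_genes_detected_flat_genes_quiet(self):
        """2x steps vs flat genes at matched noise: sensitivity and specificity."""
        rng = np.random.default_rng(12)
        n_step, n_flat, S = 30, 30, 10
        grid = stage_grid(S)
        E = np.ones((n_step + n_flat, S))
        step_at = S // 2
        E[:n_step, step_at:] = 2.0
        E *= np.exp(rng.normal(0, 0.1, size=(E.shape[0], 1)))
        genes = pd.Index([f"g{i:03d}" for i in range(E.shape[0])], name="gene_id")
        W = np.eye(S)
        comps = {}
        series = {}
        for r in range(3):  # three replicate identity series
            X = E @ W.T * np.exp(rng.normal(0, 0.1, size=E.shape))
            sids = [f"r{r}_s{j}" for j in range(S)]
            series[f"r{r}"] = pd.DataFrame(X, index=genes, columns=sids)
            comps[f"r{r}"] = pd.DataFrame(W, index=pd.Index(sids, name="sample_id"),
                                          columns=[f"stage{k:02d}" for k in range(S)])
        uni = deconvolve(series, comps,
                         config=McmcConfig(chains=1, burn_in=400, iterations=1200,
                                           thin=2, seed=4))
        calls = call_regulated(uni, min_fold=1.5)
        trans = f"stage{step_at-1:02d}->stage{step_at:02d}"
        up = set(calls.loc[(calls.transition == trans) & (calls.direction == "up"), "gene_id"])
        sens = len(up & set(genes[:n_step])) / n_step
        flat_calls = calls[calls.gene_id.isin(genes[n_step:])]
        fpr = len(flat_calls) / (n_flat * (S - 1))
        assert sens >= 0.8
        assert fpr <= 0.05
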