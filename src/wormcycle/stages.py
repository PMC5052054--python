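"""Standard developmental stage grid and embryo-age stage compositions.

A bulk embryo sample is a population of embryos whose developmental ages
are spread around a drifting mean.  We model the age distribution as a
Gaussian (truncated at the first stage boundary) with

    mean(t)     = t0 + growth_rate * t
    variance(t) = sigma0_sq + variance_rate * t

for a sample collected ``t`` minutes into the experiment, and discretize
it onto a uniform grid of standard stages by integrating the density over
each stage bin.  The resulting weight vector (the *stage composition*)
always sums to one: the first and last bins are extended to -inf/+inf, so
truncation mass is absorbed at the boundaries.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

__all__ = ["stage_grid", "stage_composition", "composition_matrix"]


def stage_grid(n_stages: int, step_minutes: float = 30.0, start: float = 0.0) -> np.ndarray:
    """Uniform stage grid in minutes: ``start, start+step, ...`` (length ``n_stages``)."""
    if n_stages < 2:
        raise ValueError(f"need at least 2 stages, got {n_stages}")
    return start + step_minutes * np.arange(n_stages, dtype=float)


def _bin_edges(stage_times: np.ndarray) -> np.ndarray:
    """Interior bin edges (midpoints between adjacent stage times)."""
    stage_times = np.asarray(stage_times, dtype=float)
    if stage_times.ndim != 1 or stage_times.size < 2:
        raise ValueError("stage grid must be 1-D with at least 2 stages")
    if np.any(np.diff(stage_times) <= 0):
        raise ValueError("stage grid must be strictly increasing")
    return 0.5 * (stage_times[:-1] + stage_times[1:])


def stage_composition(mean: float, var: float, stage_times: np.ndarray) -> np.ndarray:
    """Discretized (truncated-)Gaussian age distribution over stage bins.

    Parameters
    ----------
    mean, var
        Mean and variance (minutes, minutes^2) of the embryo-age
        distribution.  ``var == 0`` yields a point mass on the bin
        containing ``mean``.
    stage_times
        Strictly increasing stage grid in minutes.

    Returns
    -------
    Weight vector of length ``len(stage_times)`` summing to 1.
    """
    out = composition_matrix(np.array([mean]), np.array([var]), stage_times)
    return out[0]


def composition_matrix(
    means: np.ndarray, variances: np.ndarray, stage_times: np.ndarray
) -> np.ndarray:
    """Stage-composition rows for many samples at once.

    Rows are the discretized Gaussian weights for each (mean, variance)
    pair; every row sums to 1 exactly (up to float rounding, renormalized).
    """
    means = np.atleast_1d(np.asarray(means, dtype=float))
    variances = np.atleast_1d(np.asarray(variances, dtype=float))
    if means.shape != variances.shape:
        raise ValueError("means and variances must have the same shape")
    if np.any(variances < 0):
        raise ValueError("variances must be nonnegative")
    stage_times = np.asarray(stage_times, dtype=float)
    edges = _bin_edges(stage_times)
    n, s = means.size, stage_times.size
    out = np.zeros((n, s))

    degenerate = variances <= 0.0
    if np.any(degenerate):
        idx = np.searchsorted(edges, means[degenerate], side="right")
        out[np.flatnonzero(degenerate), idx] = 1.0
    if np.any(~degenerate):
        rows = np.flatnonzero(~degenerate)
        sd = np.sqrt(variances[rows])[:, None]
        mu = means[rows][:, None]
        cdf = norm.cdf((edges[None, :] - mu) / sd)
        full = np.concatenate(
            [np.zeros((rows.size, 1)), cdf, np.ones((rows.size, 1))], axis=1
        )
        w = np.diff(full, axis=1)
        out[rows] = w / w.sum(axis=1, keepdims=True)
    return out
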