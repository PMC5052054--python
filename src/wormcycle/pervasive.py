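"""Pervasive (intergenic) transcription: blocks and windowed correlations.

Two analyses:

* *Block finding* — maximal contiguous runs of intergenic bases whose
  coverage is at or above a dcpm threshold (default 0.01), kept when
  strictly longer than 200 bases; in multi-sample mode only bases above
  threshold in at least ``min_shared`` samples count.

* *Window correlation* — chromosomes are tiled with non-overlapping
  80-kb windows; per window and annotation class (intergenic, coding,
  noncoding) a dcpm value is computed, and the intergenic vector is
  compared with the coding (or noncoding) vector by Spearman
  correlation.  Significance comes from permuting the intergenic vector
  1000 times: Z = (rho_obs - mean(rho_perm)) / sd(rho_perm), plus an
  empirical two-sided p-value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "find_blocks",
    "class_array",
    "window_vectors",
    "permutation_correlation",
]

BLOCK_THRESHOLD = 0.01  # dcpm, inclusive
BLOCK_MIN_LEN = 200     # bases, strict ">"
WINDOW_SIZE = 80_000
CLASS_NAMES = ("intergenic", "coding", "noncoding")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean array as half-open intervals."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def find_blocks(
    coverage: np.ndarray | list[np.ndarray],
    threshold: float = BLOCK_THRESHOLD,
    min_len: int = BLOCK_MIN_LEN,
    min_shared: int = 1,
    intergenic_mask: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """Above-threshold transcription blocks on one chromosome.

    ``coverage`` is either a single dense dcpm array or a list of
    per-sample arrays; in the latter case a base qualifies when its
    value is >= ``threshold`` (inclusive) in at least ``min_shared``
    samples.  Blocks must be strictly longer than ``min_len`` bases and
    are maximal.  ``intergenic_mask`` restricts the search to intergenic
    bases (other bases never qualify).
    """
    if isinstance(coverage, np.ndarray) and coverage.ndim == 1:
        tracks = [coverage]
    else:
        tracks = list(coverage)
    above = np.zeros(tracks[0].size, dtype=np.int32)
    for arr in tracks:
        above += (arr >= threshold).astype(np.int32)
    mask = above >= max(min_shared, 1)
    if intergenic_mask is not None:
        mask &= intergenic_mask.astype(bool)
    return [(s, e) for s, e in _runs(mask) if (e - s) > min_len]


def class_array(genes: pd.DataFrame, chrom: str, size: int) -> np.ndarray:
    """Per-base annotation class codes for one chromosome.

    0 = intergenic, 1 = coding, 2 = noncoding.  Precedence when features
    overlap: coding > noncoding > intergenic.  ``genes`` needs columns
    chrom, start, end, kind (kind != 'noncoding' counts as coding).
    """
    arr = np.zeros(size, dtype=np.int8)
    # precedence rank: coding (1) > noncoding (2) > intergenic (0)
    rank = np.array([0, 2, 1], dtype=np.int8)
    sub = genes[genes.chrom == chrom]
    for row in sub.itertuples(index=False):
        code = 2 if row.kind == "noncoding" else 1
        lo, hi = max(int(row.start), 0), min(int(row.end), size)
        seg = arr[lo:hi]
        arr[lo:hi] = np.where(rank[code] > rank[seg], code, seg)
    return arr


def window_vectors(
    coverage: np.ndarray,
    classes: np.ndarray,
    total_mapped_reads: float,
    window: int = WINDOW_SIZE,
    keep_short_frac: float = 0.5,
) -> pd.DataFrame:
    """Per-window dcpm for each annotation class on one chromosome.

    Windows tile the chromosome from coordinate 0; the ragged final
    window is kept only when it covers at least ``keep_short_frac`` of a
    full window.  A window's class entry is the mean depth over that
    class's bases divided by (total mapped reads / 1e6); windows with no
    bases of a class get NaN.
    """
    if coverage.shape != classes.shape:
        raise ValueError("coverage and classes must be equal-length")
    n = coverage.size
    scale = total_mapped_reads / 1e6
    rows = []
    start = 0
    while start < n:
        end = min(start + window, n)
        if (end - start) < keep_short_frac * window:
            break
        cls = classes[start:end]
        cov = coverage[start:end]
        rec = {"start": start, "end": end}
        for code, name in enumerate(CLASS_NAMES):
            sel = cls == code
            rec[name] = float(cov[sel].mean() / scale) if sel.any() else np.nan
        rows.append(rec)
        start += window
    return pd.DataFrame(rows)


def _spearman(xr: np.ndarray, yr: np.ndarray) -> float:
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    return float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))


def permutation_correlation(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    min_windows: int = 10,
) -> dict:
    """Spearman rho of (x, y) with a permutation Z-score and empirical p.

    Missing windows are dropped pairwise.  The x vector is permuted
    ``n_perm`` times; Z = (rho_obs - mean(rho_perm)) / sd(rho_perm) and
    p = (1 + #{|rho_perm| >= |rho_obs|}) / (n_perm + 1).  Ties receive
    average ranks, so the statistic is invariant to monotone transforms.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < min_windows:
        raise ValueError(f"need >= {min_windows} paired windows, got {x.size}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: correlation undefined")
    xr = rankdata(x)
    yr = rankdata(y)
    rho_obs = _spearman(xr, yr)
    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    yc = yr - yr.mean()
    y_norm = np.sqrt(yc @ yc)
    for i in range(n_perm):
        xp = rng.permutation(xr)
        xc = xp - xp.mean()
        perm[i] = xc @ yc / (np.sqrt(xc @ xc) * y_norm)
    z = (rho_obs - perm.mean()) / perm.std(ddof=0)
    p = (1 + int(np.sum(np.abs(perm) >= abs(rho_obs)))) / (n_perm + 1)
    return {"rho": rho_obs, "z": float(z), "p": float(p), "n_windows": int(x.size)}
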