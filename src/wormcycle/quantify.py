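"""Expression quantification in dcpm and per-gene profile analytics.

dcpm (depth of coverage per base per million mapped reads) for a gene is
the mean per-base read depth over the union of its exon bases, divided
by total mapped reads in millions:

    dcpm = (sum of depth over exon-union bases / union length)
           / (total_mapped_reads / 1e6)

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "union_intervals",
    "compute_dcpm",
    "dcpm_matrix",
    "expressed_genes",
    "normalize_and_group_by_max",
]

EXPRESSION_THRESHOLD = 0.07  # dcpm; strict ">" comparison


def union_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge possibly-overlapping half-open intervals into a disjoint union."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"zero/negative-length interval ({s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def compute_dcpm(
    coverage: np.ndarray,
    intervals: list[tuple[int, int]],
    total_mapped_reads: float,
) -> float:
    """dcpm of one gene from a dense per-base depth array on its chromosome.

    ``intervals`` are the gene's exons (0-based half-open); overlapping
    exons are unioned before averaging.
    """
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    union = union_intervals(intervals)
    n = coverage.shape[0]
    total = 0.0
    length = 0
    for s, e in union:
        if s < 0 or e > n:
            raise ValueError(f"interval ({s}, {e}) off chromosome of length {n}")
        total += float(coverage[s:e].sum())
        length += e - s
    return (total / length) / (total_mapped_reads / 1e6)


def dcpm_matrix(
    coverage_by_sample: dict[str, dict[str, np.ndarray]],
    gene_intervals: dict[str, tuple[str, list[tuple[int, int]]]],
    total_mapped_reads: dict[str, float] | float,
) -> pd.DataFrame:
    """dcpm for every gene x sample.

    ``coverage_by_sample`` maps sample -> chrom -> dense depth array;
    ``gene_intervals`` maps gene -> (chrom, exon interval list).
    """
    samples = list(coverage_by_sample)
    if not isinstance(total_mapped_reads, dict):
        total_mapped_reads = {s: float(total_mapped_reads) for s in samples}
    genes = list(gene_intervals)
    out = np.zeros((len(genes), len(samples)))
    for j, sample in enumerate(samples):
        cov = coverage_by_sample[sample]
        for i, gid in enumerate(genes):
            chrom, ivs = gene_intervals[gid]
            out[i, j] = compute_dcpm(cov[chrom], ivs, total_mapped_reads[sample])
    return pd.DataFrame(out, index=pd.Index(genes, name="gene_id"), columns=samples)


def expressed_genes(
    matrix: pd.DataFrame, threshold: float = EXPRESSION_THRESHOLD
) -> tuple[pd.DataFrame, pd.Index]:
    """Per-sample above-threshold mask and the union gene set.

    A gene counts as expressed in a sample if its dcpm is strictly
    greater than ``threshold`` (default 0.07); the union set contains
    genes expressed in at least one sample.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    mask = matrix > threshold
    return mask, matrix.index[mask.any(axis=1)]


def normalize_and_group_by_max(
    matrix: pd.DataFrame, threshold: float = EXPRESSION_THRESHOLD
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene 0-100% normalized profiles and stage-of-maximum assignment.

    Each retained gene's profile is scaled to ``100 * value / max``;
    the gene is assigned to the stage (column) where it attains its
    maximum, ties broken by the earliest stage.  Genes never exceeding
    the expression threshold, or with an all-zero profile, are dropped
    (the latter with a warning).
    """
    _, keep = expressed_genes(matrix, threshold)
    sub = matrix.loc[keep]
    maxima = sub.max(axis=1)
    zero = maxima <= 0
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} gene(s) with zero maximal expression")
        sub, maxima = sub.loc[~zero], maxima.loc[~zero]
    profile = 100.0 * sub.div(maxima, axis=0)
    # earliest-stage tie break == first argmax in column order
    assignment = pd.Series(
        sub.columns[np.argmax(sub.to_numpy(), axis=1)], index=sub.index, name="max_stage"
    )
    return profile, assignment
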