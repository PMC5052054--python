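"""Read assignment among near-identical histone gene copies.

Core replicative histones occur in many nearly identical copies, so
most reads align equally well to several family members.  The strategy:
find the *discriminating bases* at which copies differ; a read covering
such a base is assigned to the copies it matches exactly, and a read
consistent with k copies contributes 1/k to each (kept as exact
rationals so read mass is conserved bit-for-bit).  Reads matching no
copy at a covered discriminating site are excluded as mismatches and
counted separately.

Downstream summaries: the histone fraction of all aligned reads per
sample (split into uniquely assigned and ambiguous mass) and a
maternal/zygotic/other classification of per-cluster expression
patterns over the unified time series.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

__all__ = [
    "GeneFamily",
    "find_discriminating_bases",
    "assign_reads",
    "histone_read_fraction",
    "classify_expression_pattern",
]


@dataclass
class GeneFamily:
    """Aligned, length-matched gene copies (no-indel model)."""

    members: dict[str, str]
    discriminating_positions: list[int]
    equivalence_classes: list[list[str]]

    @property
    def length(self) -> int:
        return len(next(iter(self.members.values())))


def find_discriminating_bases(members: dict[str, str], read_length: int = 50) -> GeneFamily:
    """Positions where copies differ, and classes of indistinguishable copies.

    Members must be pre-aligned and equal length (histone paralogs are
    length-conserved; families with indels are rejected).  Two members
    fall in the same equivalence class iff no read-length window can
    tell them apart — with equal-length, gap-free sequences that means
    they are identical over the whole gene.
    """
    if not members:
        raise ValueError("empty family")
    names = list(members)
    length = len(members[names[0]])
    if any(len(members[m]) != length for m in names):
        raise ValueError("family members differ in length (indels unsupported)")
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    mat = np.array([list(members[m]) for m in names])
    disc = [j for j in range(length) if len(set(mat[:, j])) > 1]
    classes: dict[str, list[str]] = {}
    for m in names:
        classes.setdefault(members[m], []).append(m)
    return GeneFamily(
        members=dict(members),
        discriminating_positions=disc,
        equivalence_classes=list(classes.values()),
    )


def assign_reads(reads: pd.DataFrame, family: GeneFamily) -> tuple[pd.DataFrame, dict]:
    """Distribute reads among family members by exact sequence match.

    ``reads`` needs columns read_id, position (0-based offset of the
    read within the aligned family coordinates) and sequence.  A read is
    compatible with a member if it matches the member's subsequence
    exactly; it contributes 1/k to each of its k compatible members
    (k = 1 means uniquely assigned).  Reads compatible with no member
    are excluded and tallied as mismatches.  Counts are exact rationals;
    total assigned mass + mismatches equals the input read count.

    Returns (per-member table with unique/ambiguous/total columns,
    summary dict).
    """
    names = list(family.members)
    unique_counts = {m: Fraction(0) for m in names}
    ambiguous_counts = {m: Fraction(0) for m in names}
    n_mismatch = 0
    length = family.length
    for row in reads.itertuples(index=False):
        pos = int(row.position)
        seq = row.sequence
        if pos < 0 or pos + len(seq) > length:
            n_mismatch += 1
            continue
        compatible = [m for m in names if family.members[m][pos : pos + len(seq)] == seq]
        k = len(compatible)
        if k == 0:
            n_mismatch += 1
        elif k == 1:
            unique_counts[compatible[0]] += 1
        else:
            share = Fraction(1, k)
            for m in compatible:
                ambiguous_counts[m] += share
    table = pd.DataFrame(
        {
            "member": names,
            "unique": [float(unique_counts[m]) for m in names],
            "ambiguous": [float(ambiguous_counts[m]) for m in names],
        }
    )
    table["total"] = table["unique"] + table["ambiguous"]
    assigned = sum(unique_counts.values()) + sum(ambiguous_counts.values())
    summary = {
        "n_reads": len(reads),
        "assigned_mass": assigned,  # exact Fraction
        "n_mismatch": n_mismatch,
        "mass_conserved": assigned + n_mismatch == len(reads),
    }
    return table, summary


def histone_read_fraction(
    assigned: pd.DataFrame | dict[str, pd.DataFrame],
    total_aligned: dict[str, float] | float,
) -> pd.DataFrame:
    """Histone-derived fraction of all aligned reads, per sample.

    ``assigned`` maps sample -> per-member assignment table (or a single
    table); fractions are reported separately for uniquely assigned and
    ambiguous (equally split) read mass, plus their sum.
    """
    if isinstance(assigned, pd.DataFrame):
        assigned = {"sample": assigned}
    if not isinstance(total_aligned, dict):
        total_aligned = {s: float(total_aligned) for s in assigned}
    rows = []
    for sample, table in assigned.items():
        tot = total_aligned[sample]
        if tot <= 0:
            raise ValueError(f"total aligned reads must be positive for {sample}")
        u = table["unique"].sum() / tot
        a = table["ambiguous"].sum() / tot
        rows.append({"sample": sample, "unique_fraction": u, "ambiguous_fraction": a,
                     "fraction": u + a})
    return pd.DataFrame(rows)


def classify_expression_pattern(
    expression: np.ndarray,
    times: np.ndarray,
    maternal_start_frac: float = 0.5,
    zygotic_start_frac: float = 0.1,
    peak_window: tuple[float, float] = (150.0, 350.0),
) -> str:
    """Maternal / zygotic / other call for one cluster's unified series.

    *maternal*: expression at the first time point is already at least
    ``maternal_start_frac`` of the peak (messages deposited in the
    oocyte).  *zygotic*: the first time point is below
    ``zygotic_start_frac`` of the peak and the peak falls inside
    ``peak_window`` (minutes) — low initial levels rising rapidly to a
    mid-embryogenesis maximum.  Everything else (including all-zero
    series) is *other*.
    """
    y = np.asarray(expression, dtype=float)
    t = np.asarray(times, dtype=float)
    peak = y.max()
    if peak <= 0:
        import warnings

        warnings.warn("all-zero cluster expression; classifying as 'other'")
        return "other"
    t_peak = t[int(np.argmax(y))]
    if y[0] >= maternal_start_frac * peak:
        return "maternal"
    if y[0] < zygotic_start_frac * peak and peak_window[0] <= t_peak <= peak_window[1]:
        return "zygotic"
    return "other"
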