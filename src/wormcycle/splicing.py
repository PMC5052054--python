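"""Splice-junction filtering, alternative-pair analysis and usage runs.

Junction tables carry one row per intron (0-based half-open interval)
with per-sample spanning-read counts, an overlapping gene id (empty for
intergenic junctions) and an annotation status (``known``/``novel``).

Filtering follows the study's two-stage rule: a junction must be
observed (>= ``min_reads`` spanning reads) in more than one sample, and
— within a gene — its aggregate level must reach at least 1% of the mean
aggregate level of the gene's *other* junctions.  Alternative-splice
pairs are formed at each shared donor/acceptor site between the top
junction by total reads (the major form) and every other junction (the
minor forms); the minor fraction rho = minor / (minor + major) per
sample is the differential-usage statistic.  A *run* is a maximal
consecutive-sample stretch in which rho stays above 0.85 (minor form
predominating) or below 0.15, allowing at most two exception samples;
the top two runs per direction are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "sample_columns",
    "filter_junctions",
    "pair_alternatives",
    "classify_novelty",
    "Run",
    "differential_usage_runs",
    "build_models_from_junctions",
    "longest_orf_aa",
]

_META = ["junction_id", "chrom", "start", "end", "strand", "gene_id", "status"]


def sample_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in _META]


def filter_junctions(
    table: pd.DataFrame,
    min_samples: int = 2,
    rel_frac: float = 0.01,
    min_reads: int = 2,
) -> pd.DataFrame:
    """Apply the multi-sample and within-gene relative-level filters.

    A junction is *observed* in a sample when it has >= ``min_reads``
    spanning reads there.  Kept junctions are observed in at least
    ``min_samples`` samples and, when assigned to a gene with other
    junctions, have aggregate reads >= ``rel_frac`` times the mean
    aggregate of those other junctions (inclusive).  Single-junction
    genes pass the relative rule vacuously; intergenic junctions face
    only the sample rule.
    """
    scols = sample_columns(table)
    counts = table[scols].to_numpy()
    detected = (counts >= min_reads).sum(axis=1) >= min_samples
    totals = counts.sum(axis=1).astype(float)
    rel_ok = np.ones(len(table), dtype=bool)
    gene_ids = table["gene_id"].fillna("").to_numpy()
    for gene, idx in pd.Series(range(len(table))).groupby(pd.Series(gene_ids)):
        if gene == "" or len(idx) < 2:
            continue
        pos = idx.to_numpy()
        tot = totals[pos]
        others_mean = (tot.sum() - tot) / (len(pos) - 1)
        rel_ok[pos] = tot >= rel_frac * others_mean
    return table.loc[detected & rel_ok].reset_index(drop=True)


def pair_alternatives(table: pd.DataFrame) -> pd.DataFrame:
    """Alternative-splice pairs at shared donor/acceptor sites.

    For each site — a (chrom, strand, coordinate, side) key shared by
    two or more junctions — the junction with the most total reads is
    the major form (ties: shorter intron, then coordinate), and every
    other junction is emitted as one (minor, major) pair.
    """
    scols = sample_columns(table)
    totals = table[scols].sum(axis=1)
    lengths = table["end"] - table["start"]
    rows = []
    for side, coord in (("donor", "start"), ("acceptor", "end")):
        grouped = table.groupby(["chrom", "strand", coord])
        for (chrom, strand, pos), idx in grouped.groups.items():
            if len(idx) < 2:
                continue
            sub = table.loc[idx]
            order = sorted(
                idx,
                key=lambda i: (-totals[i], lengths[i], table.at[i, "start"], table.at[i, "end"]),
            )
            major = order[0]
            for minor in order[1:]:
                rows.append(
                    {
                        "site_id": f"{chrom}:{pos}:{strand}:{side}",
                        "chrom": chrom,
                        "strand": strand,
                        "side": side,
                        "major_id": table.at[major, "junction_id"],
                        "minor_id": table.at[minor, "junction_id"],
                        "major_idx": major,
                        "minor_idx": minor,
                        "major_total": float(totals[major]),
                        "minor_total": float(totals[minor]),
                    }
                )
    pairs = pd.DataFrame(
        rows,
        columns=["site_id", "chrom", "strand", "side", "major_id", "minor_id",
                 "major_idx", "minor_idx", "major_total", "minor_total"],
    )
    if len(pairs):
        pairs["ratio"] = pairs.minor_total / pairs.major_total.replace(0, np.nan)
    else:
        pairs["ratio"] = pd.Series(dtype=float)
    return pairs


def classify_novelty(
    pairs: pd.DataFrame, known_junctions: set[str]
) -> pd.DataFrame:
    """Annotate pairs by WormBase-style novelty category and rarity.

    Categories: both_known, minor_novel, both_novel, major_novel.  A
    pair's minor form is *rare* when it has <= 100 total reads AND is
    <= 5% of the major form (escaping either bound — strictly more than
    100 reads, or strictly more than 5% — makes it non-rare).
    """
    out = pairs.copy()
    major_known = out["major_id"].isin(known_junctions)
    minor_known = out["minor_id"].isin(known_junctions)
    cat = np.select(
        [major_known & minor_known, major_known & ~minor_known, ~major_known & ~minor_known],
        ["both_known", "minor_novel", "both_novel"],
        default="major_novel",
    )
    out["category"] = cat
    ratio = out["minor_total"] / out["major_total"].replace(0, np.nan)
    out["rare"] = (out["minor_total"] <= 100) & ~(ratio > 0.05)
    return out


@dataclass(frozen=True)
class Run:
    start: int            # first sample index (inclusive)
    end: int              # last sample index (inclusive)
    direction: str        # "high" or "low"
    exceptions: int
    mean_excess: float    # mean |rho - threshold| over passing samples

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _candidate_runs(passes: np.ndarray, excess: np.ndarray, direction: str,
                    max_exceptions: int) -> list[Run]:
    n = passes.size
    cands = []
    for i in range(n):
        if not passes[i]:
            continue
        exc = 0
        for j in range(i, n):
            if not passes[j]:
                exc += 1
                if exc > max_exceptions:
                    break
                continue
            cands.append(
                Run(i, j, direction, exc, float(excess[i : j + 1][passes[i : j + 1]].mean()))
            )
    # keep only maximal candidates (not contained in a longer candidate)
    maximal = []
    for r in cands:
        if not any(
            (o.start <= r.start and o.end >= r.end and (o.start, o.end) != (r.start, r.end))
            for o in cands
        ):
            maximal.append(r)
    return maximal


def differential_usage_runs(
    minor_counts: np.ndarray,
    major_counts: np.ndarray,
    hi: float = 0.85,
    lo: float = 0.15,
    max_exceptions: int = 2,
    min_minor_reads: int = 10,
    min_minor_frac: float = 0.01,
    top: int = 2,
) -> dict:
    """Top runs of unusually high/low minor-form usage for one pair.

    Eligibility: the minor form must total >= ``min_minor_reads``
    spanning reads and reach >= ``min_minor_frac`` of the major form.
    rho is undefined where minor + major = 0; such samples count as
    exceptions, never as threshold passes.  A run must begin and end on
    passing samples, contain at most ``max_exceptions`` exceptions, and
    be maximal (not contained in another qualifying run).  Runs are
    ranked by length, then by mean excess beyond the threshold.
    """
    minor = np.asarray(minor_counts, dtype=float)
    major = np.asarray(major_counts, dtype=float)
    if minor.sum() < min_minor_reads:
        return {"eligible": False, "reason": "min_minor_reads", "high": [], "low": []}
    if major.sum() > 0 and minor.sum() < min_minor_frac * major.sum():
        return {"eligible": False, "reason": "min_minor_frac", "high": [], "low": []}
    denom = minor + major
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, minor / denom, np.nan)
    defined = ~np.isnan(rho)
    result = {"eligible": True, "rho": rho}
    for direction, passes, excess in (
        ("high", defined & (rho > hi), rho - hi),
        ("low", defined & (rho < lo), lo - rho),
    ):
        runs = _candidate_runs(passes, excess, direction, max_exceptions)
        runs.sort(key=lambda r: (-r.length, -r.mean_excess, r.start))
        result[direction] = runs[:top]
    return result


# ---------------------------------------------------------------------------
# junction-seeded gene models and ORF screening
# ---------------------------------------------------------------------------

def longest_orf_aa(seq: str, both_strands: bool = False) -> int:
    """Longest ATG-initiated open reading frame (aa, excluding the stop).

    Scans the three forward frames (six if ``both_strands``); an ORF may
    run off the end of the fragment without a stop codon.
    """
    best = 0
    seqs = [seq.upper()]
    if both_strands:
        seqs.append(str(Seq(seq).reverse_complement()).upper())
    for s in seqs:
        for frame in range(3):
            aa = str(Seq(s[frame : frame + 3 * ((len(s) - frame) // 3)]).translate())
            for chunk in aa.split("*"):
                m = chunk.find("M")
                if m >= 0:
                    best = max(best, len(chunk) - m)
    return best


def _grow_exon(cov: np.ndarray, anchor: int, direction: int, threshold: float,
               max_extend: int) -> tuple[int, int] | None:
    """Extend an exon from ``anchor`` (exclusive boundary) while coverage holds."""
    n = cov.size
    length = 0
    pos = anchor
    if direction > 0:
        while pos < n and length < max_extend and cov[pos] >= threshold:
            pos += 1
            length += 1
        return (anchor, pos) if length else None
    while pos > 0 and length < max_extend and cov[pos - 1] >= threshold:
        pos -= 1
        length += 1
    return (pos, anchor) if length else None


def build_models_from_junctions(
    junctions: pd.DataFrame,
    coverage: dict[str, np.ndarray],
    genome: dict[str, str],
    block_threshold: float = 0.01,
    max_extend: int = 2000,
    min_orf_aa: int = 80,
) -> tuple[pd.DataFrame, list[str]]:
    """Grow transcript fragments around orphan junctions and screen ORFs.

    Exons are grown outward from each junction's flanks while per-base
    coverage stays at or above ``block_threshold``; junctions whose
    grown exons overlap are chained into one fragment.  Each fragment's
    spliced sequence (exon union minus introns) is screened for its
    longest ORF; fragments exceeding ``min_orf_aa`` amino acids are
    flagged as coding candidates, the rest as putative ncRNAs.  The
    strand is read off the intron's splice-site dinucleotides (GT..AG)
    when recognizable; otherwise both strands are screened.

    Returns (models table, unflanked junction ids).
    """
    frags: list[dict] = []
    unflanked: list[str] = []
    for row in junctions.itertuples(index=False):
        cov = coverage[row.chrom]
        left = _grow_exon(cov, int(row.start), -1, block_threshold, max_extend)
        right = _grow_exon(cov, int(row.end), +1, block_threshold, max_extend)
        if left is None and right is None:
            unflanked.append(row.junction_id)
            continue
        exons = [e for e in (left, right) if e is not None]
        frags.append(
            {"chrom": row.chrom, "junction_id": row.junction_id,
             "intron": (int(row.start), int(row.end)), "exons": exons}
        )

    # chain fragments whose exons overlap on the same chromosome
    models = []
    by_chrom: dict[str, list[dict]] = {}
    for f in frags:
        by_chrom.setdefault(f["chrom"], []).append(f)
    fid = 0
    for chrom, items in by_chrom.items():
        items.sort(key=lambda f: min(s for s, _ in f["exons"]))
        groups: list[list[dict]] = []
        for f in items:
            placed = False
            for g in groups:
                if any(
                    s1 < e2 and s2 < e1
                    for (s1, e1) in f["exons"]
                    for prev in g
                    for (s2, e2) in prev["exons"]
                ):
                    g.append(f)
                    placed = True
                    break
            if not placed:
                groups.append([f])
        for g in groups:
            introns = sorted(f["intron"] for f in g)
            exon_union = _merge([iv for f in g for iv in f["exons"]])
            spliced = _spliced_sequence(genome[chrom], exon_union, introns)
            strand = _infer_strand(genome[chrom], introns)
            orf = longest_orf_aa(spliced, both_strands=strand is None)
            models.append(
                {
                    "model_id": f"mod{fid:04d}",
                    "chrom": chrom,
                    "strand": strand or ".",
                    "n_junctions": len(g),
                    "exons": ";".join(f"{s}-{e}" for s, e in exon_union),
                    "spliced_length": len(spliced),
                    "orf_aa": orf,
                    "classification": "coding_candidate" if orf > min_orf_aa else "putative_ncRNA",
                }
            )
            fid += 1
    return pd.DataFrame(models), unflanked


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted(intervals)
    out: list[list[int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _spliced_sequence(chrom_seq: str, exons: list[tuple[int, int]],
                      introns: list[tuple[int, int]]) -> str:
    pieces = []
    for s, e in exons:
        mask_pieces = [(s, e)]
        for i_s, i_e in introns:
            mask_pieces = [
                piece
                for (ps, pe) in mask_pieces
                for piece in (((ps, min(pe, i_s)),) if ps < min(pe, i_s) else ())
                + (((max(ps, i_e), pe),) if max(ps, i_e) < pe else ())
            ]
        for ps, pe in mask_pieces:
            pieces.append(chrom_seq[ps:pe])
    return "".join(pieces)


def _infer_strand(chrom_seq: str, introns: list[tuple[int, int]]) -> str | None:
    votes = {"+": 0, "-": 0}
    for s, e in introns:
        d, a = chrom_seq[s : s + 2].upper(), chrom_seq[e - 2 : e].upper()
        if d == "GT" and a == "AG":
            votes["+"] += 1
        elif d == "CT" and a == "AC":
            votes["-"] += 1
    if votes["+"] > votes["-"]:
        return "+"
    if votes["-"] > votes["+"]:
        return "-"
    return None
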