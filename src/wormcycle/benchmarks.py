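"""End-to-end recovery benchmarks on simulated data with known truth.

Each function regenerates its inputs from a seed, runs the relevant
pipeline stage, and reports recovery metrics.  The problem sizes are
the package's standard validation conditions: three replicate embryo
series (growth rates 0.9 / 1.0 / 1.15) of 200 genes over twenty 30-min
stages for the staging/deconvolution model, 500 genes for change-point
detection, 500 window-vector pairs for permutation-test calibration,
and a ~900-operon genome for SL-ratio binning.

The oracle checks reimplement each operation naively (per-base loops,
exhaustive interval enumeration, per-read match sets) and compare the
fast implementations against them on randomized instances.
"""

from __future__ import annotations

import hashlib
from fractions import Fraction

import numpy as np
import pandas as pd

from . import histones, operons, pervasive, quantify, splicing
from .changepoint import RjmcmcConfig, fit_changepoints
from .stages import stage_grid
from .synthetic_data import (
    GenomeConfig,
    SeriesSpec,
    SimulationConfig,
    simulate_changepoint_series,
    simulate_family_reads,
    simulate_genome,
    simulate_junctions,
    simulate_series,
)
from .unify import McmcConfig, deconvolve, fit_staging, select_inference_genes

TRUE_GROWTH = {"series0": 0.9, "series1": 1.0, "series2": 1.15}


def _staging_mcmc(seed: int) -> McmcConfig:
    return McmcConfig(chains=2, burn_in=400, iterations=1200, thin=2, seed=seed)


def _deconv_mcmc(seed: int) -> McmcConfig:
    return McmcConfig(chains=1, burn_in=600, iterations=1500, thin=3, seed=seed)


def staging_benchmark(seed: int, n_genes: int = 200, n_stages: int = 20) -> dict:
    """Criterion: growth-rate recovery and composition accuracy.

    Returns growth-rate relative errors (%), the worst per-sample
    total-variation distance between fitted and true compositions, and
    the fitted objects for reuse downstream.
    """
    cfg = SimulationConfig(n_genes=n_genes, n_stages=n_stages, seed=seed, lognormal_sd=0.2)
    series, truth = simulate_series(cfg)
    genes = select_inference_genes(series, int(n_genes * 0.75))
    fit = fit_staging(series, stage_grid(n_stages), genes=genes,
                      config=_staging_mcmc(seed + 1))
    growth_err_pct = {}
    tv_max = {}
    for sid, model in fit.models.items():
        g_true = TRUE_GROWTH[sid]
        growth_err_pct[sid] = 100.0 * abs(model.growth_rate - g_true) / g_true
        tv = 0.5 * np.abs(
            fit.compositions[sid].to_numpy()
            - truth.per_sample_composition[sid].to_numpy()
        ).sum(axis=1)
        tv_max[sid] = float(tv.max())
    return {
        "growth_err_pct": growth_err_pct,
        "max_growth_err_pct": max(growth_err_pct.values()),
        "tv_max": tv_max,
        "max_tv": max(tv_max.values()),
        "series": series,
        "truth": truth,
        "fit": fit,
    }


def deconvolution_benchmark(seed: int, staging: dict | None = None) -> dict:
    """Criterion: unified posterior means track truth (Pearson r, well-expressed genes)."""
    if staging is None:
        staging = staging_benchmark(seed)
    uni = deconvolve(staging["series"], staging["fit"].compositions,
                     config=_deconv_mcmc(seed + 2))
    E = staging["truth"].stage_expression.to_numpy()
    m = uni.mean.to_numpy()
    sel = E.max(axis=1) > 1.0
    r = float(np.corrcoef(E[sel].ravel(), m[sel].ravel())[0, 1])
    return {"pearson_r": r, "n_genes": int(sel.sum()), "unified": uni}


def identity_limit_benchmark(seed: int, n_genes: int = 40, n_stages: int = 20) -> dict:
    """Criterion: no-mixing no-noise limit reproduces inputs within 1%."""
    spec = SeriesSpec(t0=0.0, growth_rate=1.0, sigma0=0.0, variance_rate=0.0,
                      sample_times=tuple(30.0 * np.arange(n_stages)))
    cfg = SimulationConfig(n_genes=n_genes, n_stages=n_stages, series_specs=(spec,),
                           lognormal_sd=0.0, seed=seed)
    series, truth = simulate_series(cfg)
    uni = deconvolve(series, truth.per_sample_composition,
                     config=McmcConfig(chains=1, burn_in=1000, iterations=2500,
                                       thin=2, seed=seed + 3))
    E = truth.stage_expression.to_numpy()
    m = uni.mean.to_numpy()
    mask = E > 0.01
    rel = np.abs(m - E)[mask] / E[mask]
    return {"max_rel_err": float(rel.max()), "n_values": int(mask.sum())}


def changepoint_benchmark(seed: int, n_genes: int = 500, noise_sd: float = 0.15) -> dict:
    """Criterion: K recovery >= 80%, knots within one grid step >= 90%, K=0 FPR <= 10%."""
    t = 30.0 * np.arange(20)
    df, truth = simulate_changepoint_series(n_genes, t, noise_sd=noise_sd, seed=seed)
    cfg = RjmcmcConfig(log_scale=False, seed=seed + 1, iterations=3000, burn_in=800)
    k_ok = knot_ok = knot_tot = fp = n0 = 0
    for gid in df.index:
        fit = fit_changepoints(df.loc[gid].to_numpy(), t, cfg)
        tk, tkn, _ = truth[gid]
        k_ok += fit.map_k == tk
        if tk == 0:
            n0 += 1
            fp += fit.map_k > 0
        for kn in fit.map_knots:
            knot_tot += 1
            knot_ok += any(abs(kn - x) <= 30.0 for x in tkn)
    return {
        "k_accuracy": k_ok / n_genes,
        "knot_within_one_step": knot_ok / max(knot_tot, 1),
        "k0_false_positive_rate": fp / max(n0, 1),
        "n_genes": n_genes,
        "n_k0": n0,
    }


# ---------------------------------------------------------------------------
# oracle-equivalence suites (naive reference implementations)
# ---------------------------------------------------------------------------

def dcpm_oracle_check(seed: int, n_cases: int = 50) -> dict:
    """Fast dcpm vs per-base loop over explicit exon-union base sets."""
    rng = np.random.default_rng(seed)
    cov = rng.uniform(0, 40, size=2000)
    worst = 0.0
    for _ in range(n_cases):
        exons = []
        pos = int(rng.integers(0, 500))
        for _ in range(int(rng.integers(1, 4))):
            length = int(rng.integers(10, 150))
            exons.append((pos, min(pos + length, 2000)))
            pos += length + int(rng.integers(-30, 100))
            pos = min(max(pos, 0), 1800)
        total = float(rng.uniform(1e5, 1e7))
        fast = quantify.compute_dcpm(cov, exons, total)
        bases = sorted({b for s, e in exons for b in range(s, e)})
        naive = (sum(float(cov[b]) for b in bases) / len(bases)) / (total / 1e6)
        worst = max(worst, abs(fast - naive))
    return {"max_abs_err": worst, "n_cases": n_cases}


def _random_junction_table(rng, n_junctions=40, n_samples=6, n_genes=8):
    rows = []
    samples = [f"s{j}" for j in range(n_samples)]
    for i in range(n_junctions):
        start = int(rng.integers(0, 500)) * 10
        end = start + int(rng.integers(5, 40)) * 10
        gene = f"g{rng.integers(0, n_genes)}" if rng.random() < 0.8 else ""
        counts = rng.poisson(rng.uniform(0, 30), size=n_samples)
        rows.append(["chrT", start, end, rng.choice(["+", "-"]), gene,
                     rng.choice(["known", "novel"]), *counts])
    t = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id",
                                    "status", *samples])
    t.insert(0, "junction_id", [f"j{i}" for i in range(len(t))])
    return t


def junction_oracle_check(seed: int, n_tables: int = 30) -> dict:
    """Filter and alt-pairing vs brute-force set logic on random tables."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_tables):
        t = _random_junction_table(rng)
        scols = splicing.sample_columns(t)
        got = set(splicing.filter_junctions(t).junction_id)
        want = set()
        for i, row in t.iterrows():
            det = sum(1 for c in scols if row[c] >= 2) >= 2
            rel = True
            if row["gene_id"]:
                others = t[(t.gene_id == row.gene_id) & (t.index != i)]
                if len(others):
                    rel = row[scols].sum() >= 0.01 * others[scols].sum(axis=1).mean()
            if det and rel:
                want.add(row["junction_id"])
        filter_ok = got == want
        pairs = splicing.pair_alternatives(t)
        got_pairs = {(r.side, r.major_id, r.minor_id) for r in pairs.itertuples()}
        want_pairs = set()
        totals = t[scols].sum(axis=1)
        for side, coord in (("donor", "start"), ("acceptor", "end")):
            sites: dict = {}
            for i, row in t.iterrows():
                sites.setdefault((row.chrom, row.strand, row[coord]), []).append(i)
            for idx in sites.values():
                if len(idx) < 2:
                    continue
                idx = sorted(idx, key=lambda i: (-totals[i], t.at[i, "end"] - t.at[i, "start"],
                                                 t.at[i, "start"], t.at[i, "end"]))
                for minor in idx[1:]:
                    want_pairs.add((side, t.at[idx[0], "junction_id"],
                                    t.at[minor, "junction_id"]))
        agree += filter_ok and (got_pairs == want_pairs)
    return {"agreement": agree / n_tables, "n_tables": n_tables}


def run_finder_oracle_check(seed: int, n_series: int = 1000, max_len: int = 30) -> dict:
    """Differential-usage run finder vs exhaustive interval enumeration."""
    rng = np.random.default_rng(seed)
    agree = total = 0
    for _ in range(n_series):
        n = int(rng.integers(3, max_len + 1))
        minor = rng.integers(0, 60, n)
        major = rng.integers(0, 60, n)
        if minor.sum() < 10:
            minor[0] += 10
        res = splicing.differential_usage_runs(minor, major)
        if not res["eligible"]:
            continue
        total += 1
        rho = [m / (m + M) if (m + M) > 0 else None for m, M in zip(minor, major)]
        ok = True
        for d, thr, cmp in (("high", 0.85, lambda v: v > 0.85),
                            ("low", 0.15, lambda v: v < 0.15)):
            passes = [r is not None and cmp(r) for r in rho]
            cands = []
            for i in range(n):
                for j in range(i, n):
                    if passes[i] and passes[j]:
                        exc = sum(1 for x in range(i, j + 1) if not passes[x])
                        if exc <= 2:
                            cands.append((i, j, exc))
            maximal = [c for c in cands
                       if not any(o[0] <= c[0] and o[1] >= c[1] and o[:2] != c[:2]
                                  for o in cands)]

            def excess(c):
                vals = [abs(rho[x] - thr) for x in range(c[0], c[1] + 1) if passes[x]]
                return float(np.mean(vals))

            maximal.sort(key=lambda c: (-(c[1] - c[0] + 1), -excess(c), c[0]))
            want = [(c[0], c[1]) for c in maximal[:2]]
            got = [(r.start, r.end) for r in res[d]]
            ok = ok and got == want
        agree += ok
    return {"agreement": agree / max(total, 1), "n_eligible": total}


def histone_oracle_check(seed: int, n_reads: int = 1000) -> dict:
    """Read assignment vs per-read match-set oracle; exact mass conservation."""
    rng = np.random.default_rng(seed)
    base = "".join(rng.choice(list("ACGT"), size=240))
    members = {}
    for i, p in enumerate((60, 120, 180)):
        seq = list(base)
        seq[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[p]]
        members[f"his{i}"] = "".join(seq)
    fam = histones.find_discriminating_bases(members)
    reads = simulate_family_reads(members, {m: 1 / 3 for m in members}, n_reads,
                                  read_length=40, seed=seed + 1)
    table, summary = histones.assign_reads(reads, fam)
    mass = {m: Fraction(0) for m in members}
    mism = 0
    for r in reads.itertuples():
        compat = [m for m, s in members.items()
                  if s[r.position : r.position + 40] == r.sequence]
        if not compat:
            mism += 1
        else:
            for m in compat:
                mass[m] += Fraction(1, len(compat))
    got = table.set_index("member").total
    max_err = max(abs(got[m] - float(mass[m])) for m in members)
    conserved = summary["assigned_mass"] + summary["n_mismatch"] == n_reads
    return {"max_abs_err": float(max_err), "mass_conserved": bool(conserved),
            "n_reads": n_reads}


def permutation_calibration(seed: int, n_runs: int = 500, n_windows: int = 60,
                            n_perm: int = 500) -> dict:
    """Criterion: |Z| > 1.96 on independent vectors in ~5% of runs; rho(x,x)=1."""
    rng = np.random.default_rng(seed)
    hits = 0
    for i in range(n_runs):
        x = rng.lognormal(0, 1, n_windows)
        y = rng.lognormal(0, 1, n_windows)
        res = pervasive.permutation_correlation(x, y, n_perm=n_perm, seed=seed + i)
        hits += abs(res["z"]) > 1.96
    x = np.arange(20, dtype=float)
    rho_identity = pervasive.permutation_correlation(x, x, n_perm=100, seed=seed)["rho"]
    return {"reject_rate": hits / n_runs, "n_runs": n_runs,
            "rho_identity": rho_identity}


def operon_binning_benchmark(seed: int, n_operons: int = 920) -> dict:
    """Criterion: >= 840 eligible second genes, 8 equal bins (+/-1),
    internal promoters enriched in the low-SL2 bins."""
    g = simulate_genome(GenomeConfig(n_operons=n_operons, n_singletons=80,
                                     n_noncoding=40, seed=seed))
    truth = g["operon_truth"]
    ratios = operons.sl2_ratio(g["sl1"], g["sl2"])
    bins = operons.rank_and_bin(ratios, g["expression"], truth.gene2.tolist(), n_bins=8)
    sizes = bins.bin.value_counts()
    merged = bins.merge(truth, left_on="gene_id", right_on="gene2")
    frac = merged.groupby("bin").internal_promoter.mean()
    low = float(frac.iloc[:2].mean())
    high = float(frac.iloc[-2:].mean())
    return {
        "n_eligible": int(len(bins)),
        "bin_size_spread": int(sizes.max() - sizes.min()),
        "internal_frac_low_bins": low,
        "internal_frac_high_bins": high,
        "enrichment": low / max(high, 1e-9),
    }


# ---------------------------------------------------------------------------
# end-to-end smoke
# ---------------------------------------------------------------------------

def _digest(frames: list[pd.DataFrame]) -> str:
    h = hashlib.sha256()
    for df in frames:
        h.update(df.round(10).to_csv().encode())
    return h.hexdigest()


def pipeline_smoke(seed: int, n_genes: int = 60, n_stages: int = 12) -> dict:
    """Run every stage once from a single config + seed; return output digests.

    simulate -> quantify -> unify -> changepoints -> junctions -> operons
    -> pervasive -> histones, all at small problem sizes.  Calling this
    twice with the same seed must give identical digests.
    """
    from .io import coverage_arrays

    cfg = SimulationConfig(n_genes=n_genes, n_stages=n_stages, seed=seed,
                           lognormal_sd=0.2)
    series, truth = simulate_series(cfg)

    # quantify: expression thresholds + max-stage grouping on one series
    profiles, assignment = quantify.normalize_and_group_by_max(series["series0"])

    # unify (small sampler)
    genes = select_inference_genes(series, n_genes // 2)
    fit = fit_staging(series, stage_grid(n_stages), genes=genes,
                      config=McmcConfig(chains=1, burn_in=150, iterations=400,
                                        thin=2, seed=seed + 1))
    uni = deconvolve(series, fit.compositions,
                     config=McmcConfig(chains=1, burn_in=150, iterations=400,
                                       thin=2, seed=seed + 2))

    # changepoints on the first few unified genes
    t = stage_grid(n_stages)
    cp_rows = []
    for gid in uni.mean.index[:10]:
        f = fit_changepoints(uni.mean.loc[gid].to_numpy(), t,
                             RjmcmcConfig(seed=seed + 3, iterations=1500, burn_in=400))
        cp_rows.append({"gene_id": gid, "map_k": f.map_k, "peak_time": f.peak_time})
    cp = pd.DataFrame(cp_rows)

    # junctions
    table, _ = simulate_junctions(n_pairs=20, n_constitutive=10, n_samples=12,
                                  seed=seed + 4)
    filtered = splicing.filter_junctions(table)
    pairs = splicing.pair_alternatives(filtered)

    # genome-derived stages
    g = simulate_genome(GenomeConfig(n_operons=40, n_singletons=20, n_noncoding=10,
                                     n_samples=6, seed=seed + 5))
    ratios = operons.sl2_ratio(g["sl1"], g["sl2"])
    bins = operons.rank_and_bin(ratios, g["expression"],
                                g["operon_truth"].gene2.tolist(), n_bins=4)

    chrom = "chr1"
    cov = coverage_arrays(g["coverage"]["s00"], g["chrom_sizes"])[chrom]
    cls = pervasive.class_array(g["genes"], chrom, g["chrom_sizes"][chrom])
    wv = pervasive.window_vectors(cov, cls, 1e6, window=20000)
    blocks = pervasive.find_blocks(cov, intergenic_mask=cls == 0)

    fam = histones.find_discriminating_bases(g["histone_families"]["hcl0"])
    reads = simulate_family_reads(fam.members, {m: 1 / len(fam.members)
                                                for m in fam.members}, 500,
                                  seed=seed + 6)
    assigned, _ = histones.assign_reads(reads, fam)
    frac = histones.histone_read_fraction(assigned, 2000.0)

    digest = _digest([
        series["series0"], profiles, assignment.to_frame(), fit.compositions["series0"],
        uni.mean, cp, filtered, pairs, bins, wv,
        pd.DataFrame(blocks, columns=["start", "end"]), assigned, frac,
    ])
    return {"digest": digest, "histone_fraction": float(frac.iloc[0].fraction),
            "n_blocks": len(blocks)}
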