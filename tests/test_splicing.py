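"""Junction filtering, alternative pairing, usage runs and junction-seeded models.

Each operation is checked against an independently coded brute-force
oracle on randomized inputs, plus the documented boundary cases.
"""

import numpy as np
import pandas as pd
import pytest

from wormcycle.splicing import (
    Run,
    build_models_from_junctions,
    classify_novelty,
    differential_usage_runs,
    filter_junctions,
    longest_orf_aa,
    pair_alternatives,
    sample_columns,
)

from conftest import random_junction_table


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation)
# ---------------------------------------------------------------------------

def oracle_filter(table, min_samples=2, rel_frac=0.01, min_reads=2):
    scols = sample_columns(table)
    keep = []
    for i, row in table.iterrows():
        detected = sum(1 for c in scols if row[c] >= min_reads) >= min_samples
        rel = True
        if row["gene_id"]:
            others = table[(table.gene_id == row.gene_id) & (table.index != i)]
            if len(others):
                mean_others = others[scols].sum(axis=1).mean()
                rel = row[scols].sum() >= rel_frac * mean_others
        keep.append(detected and rel)
    return table.loc[keep].reset_index(drop=True)


def oracle_pairs(table):
    scols = sample_columns(table)
    pairs = set()
    for side, coord in (("donor", "start"), ("acceptor", "end")):
        sites = {}
        for i, row in table.iterrows():
            sites.setdefault((row.chrom, row.strand, row[coord], side), []).append(i)
        for key, idx in sites.items():
            if len(idx) < 2:
                continue
            def rank(i):
                r = table.loc[i]
                return (-r[scols].sum(), r.end - r.start, r.start, r.end)
            idx = sorted(idx, key=rank)
            for minor in idx[1:]:
                pairs.add((key[3], table.loc[idx[0], "junction_id"],
                           table.loc[minor, "junction_id"]))
    return pairs


def oracle_runs(minor, major, hi, lo, max_exc, top=2):
    """Exhaustive interval enumeration under the documented run definition."""
    n = len(minor)
    rho = [m / (m + M) if (m + M) > 0 else None for m, M in zip(minor, major)]

    def passes(i, d):
        if rho[i] is None:
            return False
        return rho[i] > hi if d == "high" else rho[i] < lo

    out = {}
    for d, thr in (("high", hi), ("low", lo)):
        cands = []
        for i in range(n):
            for j in range(i, n):
                if not (passes(i, d) and passes(j, d)):
                    continue
                exc = sum(1 for t in range(i, j + 1) if not passes(t, d))
                if exc <= max_exc:
                    cands.append((i, j, exc))
        maximal = [c for c in cands
                   if not any(o[0] <= c[0] and o[1] >= c[1] and o[:2] != c[:2]
                              for o in cands)]
        def excess(c):
            vals = [abs(rho[t] - thr) for t in range(c[0], c[1] + 1) if passes(t, d)]
            return float(np.mean(vals))
        maximal.sort(key=lambda c: (-(c[1] - c[0] + 1), -excess(c), c[0]))
        out[d] = [(c[0], c[1]) for c in maximal[:top]]
    return out


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

class TestFilterJunctions:
    def test_single_sample_junction_removed(self):
        t = pd.DataFrame({"junction_id": ["j"], "chrom": ["c"], "start": [0],
                          "end": [100], "strand": ["+"], "gene_id": ["g"],
                          "status": ["known"], "s0": [50], "s1": [0], "s2": [1]})
        assert len(filter_junctions(t)) == 0

    def test_exactly_one_percent_kept(self):
        t = pd.DataFrame({
            "junction_id": ["a", "b"], "chrom": ["c"] * 2, "start": [0, 10],
            "end": [100, 110], "strand": ["+"] * 2, "gene_id": ["g"] * 2,
            "status": ["known"] * 2,
            "s0": [500, 2], "s1": [300, 2], "s2": [200, 6],
        })
        # junction b: total 10 == 1% of a's 1000, detected in 3 samples
        assert set(filter_junctions(t).junction_id) == {"a", "b"}

    def test_single_junction_gene_passes_vacuously(self):
        t = pd.DataFrame({"junction_id": ["j"], "chrom": ["c"], "start": [0],
                          "end": [100], "strand": ["+"], "gene_id": ["g"],
                          "status": ["known"], "s0": [3], "s1": [3]})
        assert len(filter_junctions(t)) == 1

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            t = random_junction_table(rng)
            got = filter_junctions(t)
            want = oracle_filter(t)
            assert list(got.junction_id) == list(want.junction_id)

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(12)
        t = random_junction_table(rng, n_junctions=60)
        base = set(filter_junctions(t, rel_frac=0.01).junction_id)
        stricter = set(filter_junctions(t, rel_frac=0.1).junction_id)
        more_samples = set(filter_junctions(t, min_samples=4).junction_id)
        assert stricter <= base
        assert more_samples <= base


class TestPairAlternatives:
    def test_major_by_total_reads(self):
        t = pd.DataFrame({
            "junction_id": ["A", "B"], "chrom": ["c"] * 2, "start": [100, 100],
            "end": [300, 500], "strand": ["+"] * 2, "gene_id": ["g"] * 2,
            "status": ["known"] * 2, "s0": [100, 10],
        })
        p = pair_alternatives(t)
        assert len(p) == 1
        assert p.iloc[0].major_id == "A" and p.iloc[0].minor_id == "B"

    def test_tie_broken_by_shorter_intron(self):
        t = pd.DataFrame({
            "junction_id": ["long", "short"], "chrom": ["c"] * 2, "start": [100, 100],
            "end": [900, 300], "strand": ["+"] * 2, "gene_id": ["g"] * 2,
            "status": ["known"] * 2, "s0": [50, 50],
        })
        p = pair_alternatives(t)
        assert p.iloc[0].major_id == "short"

    def test_matches_site_grouping_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(15):
            t = random_junction_table(rng, n_junctions=30)
            got = {(r.side, r.major_id, r.minor_id)
                   for r in pair_alternatives(t).itertuples()}
            assert got == oracle_pairs(t)

    def test_no_duplicate_pairs(self, junction_data):
        table, _ = junction_data
        p = pair_alternatives(table)
        keys = list(zip(p.site_id, p.minor_id))
        assert len(keys) == len(set(keys))


class TestClassifyNovelty:
    def test_categories(self):
        pairs = pd.DataFrame({
            "major_id": ["a", "a", "x", "x"],
            "minor_id": ["b", "y", "b", "z"],
            "major_total": [1000.0] * 4,
            "minor_total": [500.0] * 4,
        })
        out = classify_novelty(pairs, known_junctions={"a", "b"})
        assert list(out.category) == ["both_known", "minor_novel", "major_novel",
                                      "both_novel"]

    def test_rare_boundary_is_strict(self):
        pairs = pd.DataFrame({
            "major_id": ["a"] * 3, "minor_id": ["b", "c", "d"],
            "major_total": [2000.0] * 3,
            "minor_total": [100.0, 101.0, 100.0],
        })
        pairs.loc[2, "major_total"] = 1999.0  # 100/1999 > 5%
        out = classify_novelty(pairs, known_junctions=set())
        # exactly 100 reads and exactly 5%: rare; >100 reads or >5%: not rare
        assert bool(out.loc[0, "rare"]) is True
        assert bool(out.loc[1, "rare"]) is False
        assert bool(out.loc[2, "rare"]) is False

    def test_membership_matches_set_oracle(self):
        rng = np.random.default_rng(14)
        ids = [f"j{i}" for i in range(40)]
        known = set(rng.choice(ids, size=15, replace=False))
        pairs = pd.DataFrame({
            "major_id": rng.choice(ids, 30), "minor_id": rng.choice(ids, 30),
            "major_total": rng.uniform(10, 1000, 30),
            "minor_total": rng.uniform(1, 500, 30),
        })
        out = classify_novelty(pairs, known)
        for r in out.itertuples():
            exp = {(True, True): "both_known", (True, False): "minor_novel",
                   (False, True): "major_novel", (False, False): "both_novel"}[
                (r.major_id in known, r.minor_id in known)]
            assert r.category == exp


class TestDifferentialUsageRuns:
    def test_all_high_single_run(self):
        res = differential_usage_runs(np.array([90, 90, 90]), np.array([10, 10, 10]))
        assert res["eligible"]
        (run,) = res["high"]
        assert (run.start, run.end, run.exceptions) == (0, 2, 0)

    def test_no_runs_at_intermediate_ratio(self):
        res = differential_usage_runs(np.full(10, 50), np.full(10, 50))
        assert res["high"] == [] and res["low"] == []

    def test_undefined_samples_are_exceptions(self):
        minor = np.array([90, 0, 90, 90])
        major = np.array([5, 0, 5, 5])
        res = differential_usage_runs(minor, major)
        (run,) = res["high"][:1]
        assert run.start == 0 and run.end == 3 and run.exceptions == 1

    def test_ineligible_pair_skipped_with_reason(self):
        res = differential_usage_runs(np.array([1, 1]), np.array([500, 500]))
        assert not res["eligible"] and res["reason"] == "min_minor_reads"

    def test_matches_bruteforce_on_random_series(self):
        rng = np.random.default_rng(15)
        for _ in range(300):
            n = int(rng.integers(3, 30))
            minor = rng.integers(0, 60, n)
            major = rng.integers(0, 60, n)
            if minor.sum() < 10:
                minor[0] += 10
            res = differential_usage_runs(minor, major)
            if not res["eligible"]:
                continue
            want = oracle_runs(minor, major, 0.85, 0.15, 2)
            for d in ("high", "low"):
                got = [(r.start, r.end) for r in res[d]]
                assert got == want[d], (minor.tolist(), major.tolist(), d)

    def test_reported_runs_satisfy_their_rule_post_hoc(self):
        rng = np.random.default_rng(16)
        for _ in range(50):
            n = int(rng.integers(5, 25))
            minor = rng.integers(0, 80, n)
            major = rng.integers(0, 80, n)
            res = differential_usage_runs(minor, major)
            if not res["eligible"]:
                continue
            rho = res["rho"]
            for d, check in (("high", lambda v: v > 0.85), ("low", lambda v: v < 0.15)):
                for run in res[d]:
                    seg = rho[run.start : run.end + 1]
                    exc = sum(1 for v in seg if not (np.isfinite(v) and check(v)))
                    assert exc <= 2
                    assert np.isfinite(seg[0]) and check(seg[0])
                    assert np.isfinite(seg[-1]) and check(seg[-1])


class TestBuildModels:
    def test_unflanked_junction_counted(self):
        junctions = pd.DataFrame({
            "junction_id": ["j0"], "chrom": ["c"], "start": [100], "end": [200],
            "strand": ["."], "gene_id": [""], "status": ["novel"], "s0": [5],
        })
        cov = {"c": np.zeros(400)}
        models, unflanked = build_models_from_junctions(junctions, cov, {"c": "A" * 400})
        assert unflanked == ["j0"] and len(models) == 0

    def test_two_exon_fragment_with_100aa_orf(self):
        orf = "ATG" + "GCT" * 100 + "TAA"
        exon1, exon2 = orf[:150], orf[150:]
        intron = "GT" + "A" * 96 + "AG"
        seq = "C" * 50 + exon1 + intron + exon2 + "C" * 50
        cov = {"c": np.zeros(len(seq))}
        e1s, e1e = 50, 50 + len(exon1)
        i_s, i_e = e1e, e1e + len(intron)
        e2s, e2e = i_e, i_e + len(exon2)
        cov["c"][e1s:e1e] = 1.0
        cov["c"][e2s:e2e] = 1.0
        junctions = pd.DataFrame({
            "junction_id": ["j0"], "chrom": ["c"], "start": [i_s], "end": [i_e],
            "strand": ["+"], "gene_id": [""], "status": ["novel"], "s0": [20],
        })
        models, unflanked = build_models_from_junctions(junctions, cov, {"c": seq})
        assert unflanked == []
        assert len(models) == 1
        row = models.iloc[0]
        assert row.orf_aa == pytest.approx(101, abs=1)  # oracle: direct translation
        assert row.classification == "coding_candidate"
        assert row.strand == "+"

    def test_short_fragment_with_stops_is_ncrna(self):
        # 90 nt littered with stop codons in every frame
        core = "TAATAGTGA" * 10
        seq = "C" * 30 + core + "C" * 30
        cov = {"c": np.zeros(len(seq))}
        cov["c"][30 : 30 + 90] = 1.0
        junctions = pd.DataFrame({
            "junction_id": ["j0"], "chrom": ["c"], "start": [60], "end": [70],
            "strand": ["."], "gene_id": [""], "status": ["novel"], "s0": [5],
        })
        models, _ = build_models_from_junctions(junctions, cov, {"c": seq})
        assert len(models) == 1
        assert models.iloc[0].orf_aa < 80
        assert models.iloc[0].classification == "putative_ncRNA"


def test_longest_orf_counts_aa_from_start_codon():
    assert longest_orf_aa("ATG" + "GCA" * 10 + "TAG") == 11
    assert longest_orf_aa("CCCCCC") == 0
    # reverse strand ORF found only when both strands scanned
    from Bio.Seq import Seq

    fwd = "ATG" + "GGA" * 20 + "TAG"
    rc = str(Seq(fwd).reverse_complement())  # revcomp contains no forward ATG
    assert longest_orf_aa(rc, both_strands=False) == 0
    assert longest_orf_aa(rc, both_strands=True) == 21
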