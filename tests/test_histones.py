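"""Histone family read assignment and expression-pattern summaries."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from wormcycle.histones import (
    assign_reads,
    classify_expression_pattern,
    find_discriminating_bases,
    histone_read_fraction,
)
from wormcycle.synthetic_data import simulate_family_reads


def private_snv_family(n_members=3, length=300, seed=0):
    """Each copy carries one private variant base (so it is identifiable)."""
    rng = np.random.default_rng(seed)
    base = "".join(rng.choice(list("ACGT"), size=length))
    members = {}
    # private bases sit away from the ends (equal read coverage per copy)
    # and more than a read length apart (no read spans two private bases,
    # so unique assignments come only from a copy's own variant)
    positions = np.linspace(60, length - 60, n_members).astype(int)
    for i in range(n_members):
        seq = list(base)
        p = int(positions[i])
        seq[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[p]]
        members[f"his{i}"] = "".join(seq)
    return members


class TestFindDiscriminatingBases:
    def test_identical_sequences_one_class(self):
        fam = find_discriminating_bases({"a": "ACGT" * 10, "b": "ACGT" * 10})
        assert fam.discriminating_positions == []
        assert len(fam.equivalence_classes) == 1

    def test_single_difference_found(self):
        fam = find_discriminating_bases({"a": "AAAA", "b": "AACA"})
        assert fam.discriminating_positions == [2]
        assert len(fam.equivalence_classes) == 2

    def test_matches_pairwise_comparison_oracle(self):
        rng = np.random.default_rng(1)
        length = 80
        members = {f"m{i}": "".join(rng.choice(list("ACGT"), length)) for i in range(5)}
        fam = find_discriminating_bases(members)
        oracle = [
            j for j in range(length)
            if len({members[m][j] for m in members}) > 1
        ]
        assert fam.discriminating_positions == oracle

    def test_indel_family_rejected(self):
        with pytest.raises(ValueError):
            find_discriminating_bases({"a": "ACGT", "b": "ACG"})

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            find_discriminating_bases({})


class TestAssignReads:
    def test_identical_copies_split_equally(self):
        fam = find_discriminating_bases({"a": "ACGT" * 20, "b": "ACGT" * 20})
        reads = pd.DataFrame({
            "read_id": [f"r{i}" for i in range(10)],
            "position": [0] * 10,
            "sequence": ["ACGT" * 5] * 10,
        })
        table, summary = assign_reads(reads, fam)
        assert table.set_index("member").loc["a", "total"] == 5.0
        assert table.set_index("member").loc["b", "total"] == 5.0
        assert summary["mass_conserved"]

    def test_discriminating_base_assigns_uniquely(self):
        fam = find_discriminating_bases({"a": "AAAAAAAA", "g": "AAAAGAAA"})
        reads = pd.DataFrame({"read_id": ["r0"], "position": [2],
                              "sequence": ["AAGA"]})
        table, _ = assign_reads(reads, fam)
        t = table.set_index("member")
        assert t.loc["g", "unique"] == 1.0 and t.loc["a", "total"] == 0.0

    def test_mismatched_read_excluded_but_counted(self):
        fam = find_discriminating_bases({"a": "AAAA", "c": "AACA"})
        reads = pd.DataFrame({"read_id": ["r0"], "position": [0],
                              "sequence": ["AGGA"]})
        table, summary = assign_reads(reads, fam)
        assert summary["n_mismatch"] == 1
        assert table.total.sum() == 0.0
        assert summary["mass_conserved"]

    def test_matches_per_read_match_set_oracle(self):
        members = private_snv_family(4, 200, seed=2)
        fam = find_discriminating_bases(members)
        reads = simulate_family_reads(
            members, {m: 0.25 for m in members}, 1000, read_length=40, seed=3
        )
        table, summary = assign_reads(reads, fam)
        # oracle: exact-match sets per read, Fraction mass
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
        for m in members:
            assert got[m] == pytest.approx(float(mass[m]), abs=1e-12)
        assert summary["n_mismatch"] == mism
        assert float(sum(mass.values())) + mism == len(reads)

    def test_member_permutation_equivariance(self):
        members = private_snv_family(3, 150, seed=4)
        fam1 = find_discriminating_bases(members)
        fam2 = find_discriminating_bases(dict(reversed(members.items())))
        reads = simulate_family_reads(members, {m: 1 / 3 for m in members}, 300, seed=5)
        t1 = assign_reads(reads, fam1)[0].set_index("member").total
        t2 = assign_reads(reads, fam2)[0].set_index("member").total
        for m in members:
            assert t1[m] == t2[m]

    def test_known_proportions_recovered_from_unique_reads(self):
        """Copy proportions 0.7/0.2/0.1 recovered within 3 SE from uniquely
        assignable reads (reads covering a copy's private base)."""
        members = private_snv_family(3, 300, seed=6)
        fam = find_discriminating_bases(members)
        props = {"his0": 0.7, "his1": 0.2, "his2": 0.1}
        reads = simulate_family_reads(members, props, 10_000, read_length=50, seed=7)
        table, _ = assign_reads(reads, fam)
        t = table.set_index("member")
        unique_total = t.unique.sum()
        for m, p in props.items():
            est = t.loc[m, "unique"] / unique_total
            se = np.sqrt(p * (1 - p) / unique_total)
            assert abs(est - p) <= 3 * se


class TestHistoneReadFraction:
    def test_all_reads_histone(self):
        t = pd.DataFrame({"member": ["a"], "unique": [800.0], "ambiguous": [200.0],
                          "total": [1000.0]})
        out = histone_read_fraction(t, 1000.0)
        assert out.iloc[0].fraction == 1.0

    def test_no_histone_reads(self):
        t = pd.DataFrame({"member": ["a"], "unique": [0.0], "ambiguous": [0.0],
                          "total": [0.0]})
        assert histone_read_fraction(t, 5000.0).iloc[0].fraction == 0.0

    def test_constructed_35_percent_sample(self):
        members = private_snv_family(2, 200, seed=8)
        fam = find_discriminating_bases(members)
        n_his, n_total = 3500, 10_000
        reads = simulate_family_reads(members, {m: 0.5 for m in members}, n_his, seed=9)
        table, _ = assign_reads(reads, fam)
        out = histone_read_fraction(table, float(n_total))
        assert out.iloc[0].fraction == pytest.approx(0.35, abs=0.001)
        assert out.iloc[0].unique_fraction + out.iloc[0].ambiguous_fraction \
            == pytest.approx(out.iloc[0].fraction)


class TestClassifyExpressionPattern:
    times = 30.0 * np.arange(20)

    def test_decaying_profile_is_maternal(self):
        y = np.exp(-self.times / 200.0)
        assert classify_expression_pattern(y, self.times) == "maternal"

    def test_mid_peak_from_zero_is_zygotic(self):
        y = np.exp(-((self.times - 250.0) ** 2) / (2 * 60.0**2))
        y[0] = 0.0
        assert classify_expression_pattern(y, self.times) == "zygotic"

    def test_all_zero_is_other_with_warning(self):
        with pytest.warns(UserWarning):
            assert classify_expression_pattern(np.zeros(20), self.times) == "other"

    def test_late_peak_is_other(self):
        y = np.exp(-((self.times - 500.0) ** 2) / (2 * 60.0**2))
        y[0] = 0.0
        assert classify_expression_pattern(y, self.times) == "other"

    def test_simulated_cluster_patterns_agree(self):
        """Maternal (deposited, decaying) and zygotic (peak 200-300 min)
        cluster curves classify correctly >= 90% at default thresholds."""
        rng = np.random.default_rng(19)
        times = self.times
        n_ok = n = 0
        for _ in range(40):
            amp = float(np.exp(rng.normal(2, 0.5)))
            y = amp * np.exp(-times / rng.uniform(120, 300))
            y *= np.exp(rng.normal(0, 0.1, times.size))
            n += 1
            n_ok += classify_expression_pattern(y, times) == "maternal"
        for _ in range(40):
            amp = float(np.exp(rng.normal(2, 0.5)))
            peak = rng.uniform(200, 300)
            y = amp * np.exp(-((times - peak) ** 2) / (2 * 70.0**2))
            y *= np.exp(rng.normal(0, 0.1, times.size))
            n += 1
            n_ok += classify_expression_pattern(y, times) == "zygotic"
        assert n_ok / n >= 0.9
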