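import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from thermotrace.calling import (
    CallingThresholds,
    bonferroni,
    call_thermospores,
    detection_by_group,
    detection_sets_from_abundance,
    fisher_exact_two_sided,
    fold_change,
    relative_abundance,
    summarize_abundance_table,
    summarize_counts,
    venn_partition,
)
from thermotrace.tables_io import load_reported_abundance_fixture
from thermotrace.types import OtuCountTable, Pretreatment, SampleRecord, ValidationError


def fisher_oracle(a, b, c, d, rtol=1e-7):
    """Exact enumeration with integer binomial coefficients (independent
    of the log-gamma implementation under test)."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    denom = math.comb(n, row1)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    pmfs = {
        k: math.comb(col1, k) * math.comb(n - col1, row1 - k) / denom
        for k in range(lo, hi + 1)
    }
    obs = pmfs[a]
    kept = [p for p in pmfs.values() if p <= obs * (1 + rtol)]
    if len(kept) == len(pmfs):
        return 1.0
    return min(1.0, sum(kept))


class TestFisherExact:
    def test_identical_proportions_give_one(self):
        assert fisher_exact_two_sided(1, 9, 1, 9) == 1.0

    def test_perfect_separation_small(self):
        # all 252 tables with margins (5,5)/(5,5); only the two extremes
        # are as extreme as observed: p = 2/252
        assert fisher_exact_two_sided(5, 0, 0, 5) == pytest.approx(2 / 252, rel=1e-9)

    def test_enrichment_at_depth_is_extreme(self):
        p = fisher_exact_two_sided(2, 44998, 900, 44100)
        assert 0 < p < 1e-6

    def test_negative_cell_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_two_sided(-1, 2, 3, 4)

    def test_agrees_with_enumeration_oracle_exhaustive_small(self):
        for n in range(0, 16):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        got = fisher_exact_two_sided(a, b, c, d)
                        want = fisher_oracle(a, b, c, d)
                        assert got == pytest.approx(want, rel=1e-9), (a, b, c, d)

    def test_agrees_with_oracles_on_random_tables(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 101, size=4)
            if a + b + c + d == 0:
                continue
            got = fisher_exact_two_sided(a, b, c, d)
            assert got == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-9)
            # third, fully independent route
            assert got == pytest.approx(
                scipy_fisher([[a, b], [c, d]]).pvalue, rel=1e-6
            )


class TestBonferroni:
    def test_scales_and_caps(self):
        adj = bonferroni([0.0005, 0.5], 100)
        assert adj[0] == pytest.approx(0.05)
        assert adj[1] == 1.0

    def test_order_preserved_and_never_below_raw(self):
        p = [0.3, 0.001, 0.02]
        adj = bonferroni(p, 10)
        assert np.all(adj >= np.asarray(p))
        assert list(np.argsort(adj)) == list(np.argsort(p))

    def test_family_size_validation(self):
        with pytest.raises(ValidationError):
            bonferroni([0.5], 0)
        with pytest.raises(ValidationError):
            bonferroni([0.5, 0.5], 1)


class TestFoldChange:
    def test_simple_ratio(self):
        assert fold_change(0.001, 0.02, 45000) == pytest.approx(20.0)

    def test_zero_day0_uses_half_read_pseudocount(self):
        assert fold_change(0.0, 0.005, 45000) == pytest.approx(450.0)

    def test_absent_both_days_is_zero(self):
        assert fold_change(0.0, 0.0, 45000) == 0.0

    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValidationError):
            fold_change(1.5, 0.5, 100)


class TestRelativeAbundance:
    def test_columns_normalize(self, small_study):
        table, _, _ = small_study
        rel = relative_abundance(table)
        sums = rel.fractions.sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_simple_column(self):
        df = pd.DataFrame({"s1": {"a": 10, "b": 30}})
        rel = relative_abundance(OtuCountTable(df))
        assert rel.fractions["s1"].tolist() == [0.25, 0.75]


class TestCallThermospores:
    def test_canonical_germination_case_is_called(self, toy_pair_table):
        table, meta = toy_pair_table
        calls = {c.otu_id: c for c in call_thermospores(table, meta)}
        call = calls["OTU_A"]
        t = call.per_microcosm["PLUS4_R1"]
        assert call.is_thermospore
        assert t.fold_change == pytest.approx(450.0, rel=1e-9)
        assert t.day7_fraction == pytest.approx(0.02)
        assert t.p_adjusted < 1e-100
        assert not calls["OTU_B"].is_thermospore
        assert not calls["OTU_C"].is_thermospore

    def test_below_abundance_floor_not_called(self):
        # 40-fold increase but only 0.4% at day 7
        df = pd.DataFrame(
            {"d0": {"x": 1, "bg": 9999}, "d7": {"x": 40, "bg": 9960}}
        )
        meta = [
            SampleRecord("d0", Pretreatment.PLUS4, "R1", 0),
            SampleRecord("d7", Pretreatment.PLUS4, "R1", 7),
        ]
        calls = {c.otu_id: c for c in call_thermospores(OtuCountTable(df), meta)}
        assert not calls["x"].is_thermospore
        assert calls["x"].per_microcosm["PLUS4_R1"].passes_fold

    def test_below_fold_threshold_not_called(self):
        # 0.1% -> 0.9%: nine-fold, under the 10x criterion
        df = pd.DataFrame(
            {"d0": {"x": 45, "bg": 44955}, "d7": {"x": 405, "bg": 44595}}
        )
        meta = [
            SampleRecord("d0", Pretreatment.PLUS4, "R1", 0),
            SampleRecord("d7", Pretreatment.PLUS4, "R1", 7),
        ]
        calls = {c.otu_id: c for c in call_thermospores(OtuCountTable(df), meta)}
        call = calls["x"]
        assert not call.is_thermospore
        t = call.per_microcosm["PLUS4_R1"]
        assert t.passes_abundance and t.passes_significance and not t.passes_fold

    def test_adjusted_p_at_least_raw(self, small_study):
        table, meta, _ = small_study
        for call in call_thermospores(table, meta):
            for t in call.per_microcosm.values():
                assert t.p_adjusted >= t.p_raw

    def test_calling_is_monotone_in_thresholds(self, small_study):
        table, meta, _ = small_study
        base = CallingThresholds()
        loose = call_thermospores(table, meta, base)
        called = {c.otu_id for c in loose if c.is_thermospore}
        for stricter in (
            CallingThresholds(abundance_floor=0.02),
            CallingThresholds(fold_change_min=50),
            CallingThresholds(alpha=1e-6),
        ):
            strict = call_thermospores(table, meta, stricter)
            assert {c.otu_id for c in strict if c.is_thermospore} <= called


class TestVennPartition:
    def test_disjoint_singletons(self):
        v = venn_partition({"A": {1}, "B": {2}, "C": {3}})
        assert v.total == 3
        assert v.only("A") == v.only("B") == v.only("C") == 1
        assert v.all_three == 0

    def test_regions_sum_to_union_and_order_invariant(self):
        rng = np.random.default_rng(7)
        sets = {
            "A": set(rng.integers(0, 30, 12).tolist()),
            "B": set(rng.integers(0, 30, 12).tolist()),
            "C": set(rng.integers(0, 30, 12).tolist()),
        }
        v = venn_partition(sets)
        assert sum(v.regions.values()) == v.total == len(sets["A"] | sets["B"] | sets["C"])
        shuffled = venn_partition({k: sets[k] for k in ("C", "A", "B")})
        assert shuffled.regions == v.regions

    def test_wrong_group_count_rejected(self):
        with pytest.raises(ValidationError):
            venn_partition({"A": set(), "B": set()})

    def test_fixture_partition_matches_study(self):
        groups = detection_sets_from_abundance(load_reported_abundance_fixture())
        v = venn_partition(groups)
        assert v.total == 22
        assert v.all_three == 12
        assert v.only(Pretreatment.PLUS4) == 1
        assert v.only(Pretreatment.MINUS80) == 2
        assert v.exclusive_to(Pretreatment.MINUS20, Pretreatment.MINUS80) == 6

    def test_fixture_group_sizes(self):
        groups = detection_sets_from_abundance(load_reported_abundance_fixture())
        # 16 OTUs seen at +4C; 18 survive -80C (all but Thermospores 5/7/16/22)
        assert len(groups[Pretreatment.PLUS4]) == 16
        assert len(groups[Pretreatment.MINUS80]) == 18
        missing80 = {f"Thermospore_{i}" for i in (5, 7, 16, 22)}
        assert set(load_reported_abundance_fixture().otu_ids) - groups[Pretreatment.MINUS80] == missing80


class TestSummaries:
    def test_fixture_counts_reproduce_reported_row(self):
        df = summarize_abundance_table(load_reported_abundance_fixture())
        counts = df["n_thermospore_otus"]
        assert counts.tolist() == [15, 11, 14, 16, 9, 10, 8, 12, 11]
        assert counts.min() == 8 and counts.max() == 16

    def test_fixture_totals_near_reported(self):
        df = summarize_abundance_table(load_reported_abundance_fixture())
        reported = [42.6, 43.0, 37.4, 61.1, 39.4, 42.4, 47.4, 36.1, 44.2]
        got = (df["total_thermospore_fraction"] * 100).tolist()
        # sums of one-decimal rounded cells: agreement within rounding slack
        assert np.allclose(got, reported, atol=0.5)

    def test_summarize_counts_from_calls(self, toy_pair_table):
        table, meta = toy_pair_table
        calls = call_thermospores(table, meta)
        df = summarize_counts(calls, meta)
        assert df.loc["PLUS4_R1", "n_thermospore_otus"] == 1
        assert df.loc["PLUS4_R1", "total_thermospore_fraction"] == pytest.approx(0.02)

    def test_detection_by_group_places_single_detection(self, toy_pair_table):
        table, meta = toy_pair_table
        groups = detection_by_group(call_thermospores(table, meta))
        assert groups[Pretreatment.PLUS4] == {"OTU_A"}
        assert groups[Pretreatment.MINUS20] == set()
        assert groups[Pretreatment.MINUS80] == set()
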