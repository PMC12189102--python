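import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from conftest import make_table
from svscape import variant_qc
from svscape.variant_qc import (
    apply_hard_filters,
    classify_size,
    filter_cohort,
    genotype_stats,
    proximity_dedup,
)


class TestClassifySize:
    @pytest.mark.parametrize("length,expected", [
        (1, "Small"), (10, "Small"), (11, "Medium"), (50, "Medium"),
        (51, "Large"), (87101, "Large")])
    def test_boundaries(self, length, expected):
        assert classify_size(length) == expected

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            classify_size(0)

    @given(st.integers(min_value=1, max_value=10**6))
    @settings(derandomize=True, max_examples=200)
    def test_partitions_positive_lengths(self, length):
        """Every length maps to exactly one of the three classes."""
        assert classify_size(length) in ("Small", "Medium", "Large")


def indel_table(records):
    """records: (pos, qual) or (pos, qual, vtype)."""
    rows = []
    for i, rec in enumerate(records):
        pos, qual = rec[0], rec[1]
        vtype = rec[2] if len(rec) > 2 else "DEL"
        rows.append((f"v{i}", "chr1", pos, pos, pos + 2, vtype, 2, qual))
    return make_table(rows)


class TestProximityDedup:
    def test_three_indel_chain_keeps_only_highest(self):
        """{100/Q50, 105/Q60, 112/Q40}: the Q60 survivor eliminates both."""
        t = proximity_dedup(indel_table([(100, 50), (105, 60), (112, 40)]))
        assert list(t.df["pos"]) == [105]

    def test_distant_indels_both_survive(self):
        t = proximity_dedup(indel_table([(100, 5), (120, 99)]))
        assert len(t) == 2

    def test_empty_table(self):
        t = proximity_dedup(indel_table([]))
        assert len(t) == 0

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        recs = [(int(p), float(q)) for p, q in
                zip(rng.integers(0, 200, 20), rng.uniform(10, 90, 20))]
        once = proximity_dedup(indel_table(recs))
        twice = proximity_dedup(once)
        assert once.df.equals(twice.df)

    def test_matches_exhaustive_subset_oracle(self):
        """Greedy survivors equal the exhaustively enumerated priority-first
        conflict-free subset on 200 random toys of up to 8 indels."""
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(1, 9))
            recs = [(int(rng.integers(0, 60)), float(round(rng.uniform(10, 90), 1)),
                     "DEL" if rng.random() < 0.5 else "INS")
                    for _ in range(n)]
            survivors = proximity_dedup(indel_table(recs))
            expected = oracles.dedup_exhaustive(recs)
            got = {int(v[1:]) for v in survivors.df["id"]}
            assert got == expected, recs

    def test_survivors_never_within_distance(self):
        rng = np.random.default_rng(5)
        recs = [(int(p), float(q)) for p, q in
                zip(rng.integers(0, 500, 60), rng.uniform(10, 90, 60))]
        t = proximity_dedup(indel_table(recs))
        pos = np.sort(t.df["pos"].to_numpy())
        assert (np.diff(pos) > 10).all()


def one_variant(vtype, qual, info):
    t = make_table([("v0", "chr1", 100, 100, 101, vtype, 1 if vtype == "SNP" else 5,
                     qual)])
    t.info = [info]
    return t


class TestHardFilters:
    def test_snp_low_qd_removed(self):
        t, tally = apply_hard_filters(one_variant("SNP", 50.0, {"QD": 1.9}))
        assert len(t) == 0
        assert tally == {"QD_min": 1}

    def test_indel_fs_boundary_retained(self):
        """FS = 200.0 exactly: the rule is FS > 200.0, strict."""
        t, tally = apply_hard_filters(one_variant("DEL", 50.0, {"FS": 200.0}))
        assert len(t) == 1 and tally == {}

    def test_indel_fs_above_boundary_removed(self):
        t, _ = apply_hard_filters(one_variant("DEL", 50.0, {"FS": 200.01}))
        assert len(t) == 0

    def test_missing_info_rules_are_skipped(self):
        t, tally = apply_hard_filters(one_variant("SNP", 31.0, {}))
        assert len(t) == 1 and tally == {}

    def test_qual_rule_applies_without_info(self):
        t, tally = apply_hard_filters(one_variant("SNP", 29.9, {}))
        assert len(t) == 0 and tally == {"QUAL_min": 1}


class TestGenotypeStats:
    def test_maf_exactly_001_boundary(self):
        """50 diploids, one het: maf = 1/100 = 0.01, failing 'greater than 0.01'."""
        dos = np.zeros((1, 50), dtype=np.int16)
        dos[0, 0] = 1
        t = make_table([("v0", "chr1", 100, 100, 160, "DEL", 60, 50.0)],
                       samples=[f"s{i}" for i in range(50)], dosages=dos)
        stats = genotype_stats(t)
        assert stats["maf"][0] == pytest.approx(0.01)
        kept, _ = filter_cohort(t)
        assert len(kept) == 0

    def test_missing_rate_boundary(self):
        dos = np.full((1, 10), 1, dtype=np.int16)
        dos[0, :3] = -1
        t = make_table([("v0", "chr1", 100, 100, 160, "DEL", 60, 50.0)],
                       samples=[f"s{i}" for i in range(10)], dosages=dos)
        stats = genotype_stats(t)
        assert stats["missing_rate"][0] == pytest.approx(0.3)
        kept, _ = filter_cohort(t)  # 0.3 fails the strict 'below 30%' rule
        assert len(kept) == 0

    def test_all_hom_alt_maf_zero(self):
        dos = np.full((1, 10), 2, dtype=np.int16)
        t = make_table([("v0", "chr1", 100, 100, 101, "SNP", 1, 50.0)],
                       samples=[f"s{i}" for i in range(10)], dosages=dos)
        assert genotype_stats(t)["maf"][0] == 0

    def test_all_missing_flagged_undefined(self):
        dos = np.full((1, 4), -1, dtype=np.int16)
        t = make_table([("v0", "chr1", 100, 100, 101, "SNP", 1, 50.0)],
                       samples=list("abcd"), dosages=dos)
        assert bool(genotype_stats(t)["undefined"][0])

    def test_per_population_frequencies(self):
        dos = np.array([[2, 2, 0, 0]], dtype=np.int16)
        t = make_table([("v0", "chr1", 100, 100, 101, "SNP", 1, 50.0)],
                       samples=list("abcd"), dosages=dos)
        stats = genotype_stats(t, pop_map={"a": "P1", "b": "P1", "c": "P2", "d": "P2"})
        assert stats["af_P1"][0] == 1.0 and stats["af_P2"][0] == 0.0


class TestFilterCohort:
    def test_sv_passing_both_rules_retained(self):
        dos = np.zeros((1, 100), dtype=np.int16)
        dos[0, :5] = 1       # maf 0.025
        dos[0, 95:] = -1     # missing 0.05
        t = make_table([("v0", "chr1", 100, 100, 160, "DEL", 60, 50.0)],
                       samples=[f"s{i}" for i in range(100)], dosages=dos)
        kept, stats = filter_cohort(t)
        assert len(kept) == 1 and bool(stats["retained"][0])

    def test_indel_missing_boundary_removed(self):
        """Missing rate exactly 0.1 fails the strict '< 0.1' indel rule."""
        dos = np.full((1, 10), 1, dtype=np.int16)
        dos[0, 0] = -1
        t = make_table([("v0", "chr1", 100, 100, 105, "DEL", 5, 50.0)],
                       samples=[f"s{i}" for i in range(10)], dosages=dos)
        kept, _ = filter_cohort(t)
        assert len(kept) == 0

    def test_monotone_removal(self, default_cohort):
        """Cohort filtering only removes records, never alters survivors."""
        table = default_cohort.table
        kept, stats = filter_cohort(table)
        assert len(kept) <= len(table)
        assert set(kept.df["id"]) <= set(table.df["id"])


class TestQcRecoversPlantedFailures(object):
    def test_planted_hard_filter_failures_are_removed(self, default_cohort):
        c = default_cohort
        table, report = variant_qc.qc_pipeline(c.table, pop_map=c.pop_map)
        truth = c.truth.variants
        planted = set(truth.index[truth["planted_fail_rule"] != ""])
        assert planted, "generator should plant hard-filter failures"
        assert planted.isdisjoint(set(table.df["id"]))
        planted_qc = set(truth.index[truth["planted_high_missing"]
                                     | truth["planted_low_maf"]])
        assert planted_qc and planted_qc.isdisjoint(set(table.df["id"]))
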