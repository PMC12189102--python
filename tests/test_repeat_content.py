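import numpy as np
import pytest

import oracles
from svscape.repeat_content import (
    annotate_repeats,
    calls_frame,
    classify_driver,
    parse_unit_length,
    simple_repeat_spectrum,
    te_fraction,
    te_length_profile,
)


def rep_arrays(intervals):
    """intervals: (start, end, cls, name)."""
    return (np.array([i[0] for i in intervals]),
            np.array([i[1] for i in intervals]),
            np.array([i[2] for i in intervals], dtype=object),
            np.array([i[3] for i in intervals], dtype=object))


class TestTeFraction:
    def test_strict_80_percent_boundary(self):
        """Coverage of exactly 80 bases on a 100 bp span is NOT TE-driven;
        81 bases is."""
        frac80, _ = te_fraction(0, 100, 100, *rep_arrays([(0, 80, "LINE/L1", "L1")]))
        frac81, _ = te_fraction(0, 100, 100, *rep_arrays([(0, 81, "LINE/L1", "L1")]))
        assert frac80 == pytest.approx(0.80) and not frac80 > 0.8
        assert frac81 == pytest.approx(0.81) and frac81 > 0.8

    def test_union_semantics_on_overlapping_hits(self):
        frac, contrib = te_fraction(
            0, 100, 100, *rep_arrays([(0, 60, "LINE/L1", "L1"),
                                      (40, 90, "LINE/L1", "L1")]))
        assert frac == pytest.approx(0.9)
        assert sum(b for *_, b in contrib) == 110  # raw contributions overlap

    def test_union_never_exceeds_summed_lengths(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            n = int(rng.integers(1, 6))
            ivals = []
            for _ in range(n):
                s = int(rng.integers(0, 90))
                e = s + int(rng.integers(1, 40))
                ivals.append((s, min(e, 100), "LINE/L1", "L1"))
            frac, contrib = te_fraction(0, 100, 100, *rep_arrays(ivals))
            assert frac * 100 <= sum(b for *_, b in contrib) + 1e-9

    def test_matches_per_base_oracle(self):
        """Union coverage equals brute-force per-base counting on 500 toys."""
        rng = np.random.default_rng(31)
        for _ in range(500):
            length = int(rng.integers(10, 200))
            start = int(rng.integers(0, 50))
            end = start + length
            n = int(rng.integers(0, 5))
            ivals = []
            for _ in range(n):
                s = int(rng.integers(0, end + 20))
                e = s + int(rng.integers(1, 120))
                ivals.append((s, e, "LINE/L1", "L1"))
            if ivals:
                frac, _ = te_fraction(start, end, length, *rep_arrays(ivals))
            else:
                frac = te_fraction(start, end, length, np.array([]), np.array([]),
                                   np.array([]), np.array([]))[0]
            expected = oracles.covered_fraction(start, end,
                                                [(s, e) for s, e, *_ in ivals])
            assert frac == pytest.approx(expected, abs=1e-12)

    def test_zero_length_errors(self):
        with pytest.raises(ValueError):
            te_fraction(0, 0, 0, np.array([]), np.array([]), np.array([]),
                        np.array([]))


class TestClassifyDriver:
    def test_longest_contributor_wins(self):
        cls, name = classify_driver([("LINE/L1", "L1", 70),
                                     ("SINE/Core-RTE", "BOV-A2", 20)])
        assert (cls, name) == ("LINE/L1", "L1")

    def test_tie_breaks_lexicographically(self):
        cls, _ = classify_driver([("SINE/Core-RTE", "BOV-A2", 50),
                                  ("LINE/L1", "L1", 50)])
        assert cls == "LINE/L1"

    def test_empty_contributors(self):
        assert classify_driver([]) == ("none", "")


class TestUnitLength:
    @pytest.mark.parametrize("name,expected", [
        ("(TG)n", 2), ("(ATCGA)n", 5), ("(A)n", 1), ("GC_rich", None),
        ("BOV-A2", None)])
    def test_parse(self, name, expected):
        assert parse_unit_length(name) == expected


def cohort_calls(cohort):
    return annotate_repeats(cohort.table, cohort.ref_repeats, cohort.alt_repeats)


class TestAnnotateRepeats:
    def test_small_variants_never_classified(self, default_cohort):
        calls, tally = cohort_calls(default_cohort)
        df = calls_frame(calls, default_cohort.table)
        assert tally["small_excluded"] > 0
        assert (df["size_class"] != "Small").all()
        assert not df[df["size_class"] == "Small"]["is_te_driven"].any()

    def test_planted_te_status_recovered(self, default_cohort):
        c = default_cohort
        calls, _ = cohort_calls(c)
        df = calls_frame(calls, c.table).set_index("id")
        truth = c.truth.variants
        joined = df.join(truth, rsuffix="_t")
        assert (joined["is_te_driven"] == joined["is_te_driven_t"]).all()
        assert (joined["is_simple_repeat"] == joined["is_simple_repeat_t"]).all()
        drv = joined[joined["is_te_driven"]]
        assert (drv["driver_class"] == drv["driver_class_t"]).all()
        assert np.allclose(joined["te_fraction"], joined["te_fraction_t"])

    def test_ins_without_alt_annotation_skipped(self, default_cohort):
        c = default_cohort
        calls, tally = annotate_repeats(c.table, c.ref_repeats, None)
        df = calls_frame(calls, c.table)
        assert tally["ins_unannotated"] > 0
        assert (df["vtype"] == "DEL").all()

    def test_te_and_simple_mutually_exclusive(self, default_cohort):
        calls, _ = cohort_calls(default_cohort)
        for c in calls:
            assert not (c.is_te_driven and c.is_simple_repeat)


class TestSpectraAndProfiles:
    def test_unit_length_spectrum_matches_planted_mix(self, default_cohort):
        """Planted geometric-ish unit mix recovered within binomial error."""
        c = default_cohort
        calls, _ = cohort_calls(c)
        spectrum, unparsed = simple_repeat_spectrum(calls, c.table)
        assert unparsed == 0
        got = spectrum.groupby("unit_length")["count"].sum()
        truth = c.truth.variants
        planted = truth[truth["is_simple_repeat"]]["unit_length"].value_counts()
        for u in planted.index:
            assert got.get(u, 0) == planted[u]

    def test_sine_core_rte_peak_within_expected_band(self, default_cohort):
        """Planted SINE/Core-RTE lengths ~N(138, 9): modal bin in [120, 150]."""
        c = default_cohort
        calls, _ = cohort_calls(c)
        profile = te_length_profile(calls, c.table, bin_width=10)
        sine = profile[profile["driver_class"] == "SINE/Core-RTE"]
        assert len(sine)
        modal = sine.loc[sine["count"].idxmax()]
        assert 120 <= modal["length_bin_start"] <= 150

    def test_empty_class_absent_from_profile(self, default_cohort):
        calls, _ = cohort_calls(default_cohort)
        profile = te_length_profile(calls, default_cohort.table)
        assert "none" not in set(profile["driver_class"])


class TestIsTeDrivenMonotone:
    def test_monotone_in_fraction(self):
        """Increasing repeat coverage can only turn is_te_driven on, not off."""
        fracs = []
        for cov in range(60, 101, 5):
            f, _ = te_fraction(0, 100, 100,
                               *rep_arrays([(0, cov, "LINE/L1", "L1")]))
            fracs.append(f > 0.8)
        assert fracs == sorted(fracs)
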