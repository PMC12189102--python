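import numpy as np
import pandas as pd
import pytest

import oracles
from svscape.popgen_fst import (
    hudson_fst_freq,
    hudson_fst_overall,
    top_selection_regions,
    wc_components,
    wc_fst_overall,
    wc_fst_site,
    windowed_fst,
    genes_in_regions,
    shared_genes,
)


def random_genotypes(rng, n_min=2, n_max=12):
    n1 = int(rng.integers(n_min, n_max))
    n2 = int(rng.integers(n_min, n_max))
    g1 = rng.integers(0, 3, n1).tolist()
    g2 = rng.integers(0, 3, n2).tolist()
    return g1, g2


class TestWeirCockerham:
    def test_complete_fixation_gives_one(self):
        d1 = np.full((1, 10), 2, dtype=np.int16)
        d2 = np.zeros((1, 10), dtype=np.int16)
        res = wc_fst_site(d1, d2)
        assert res["fst"][0] == pytest.approx(1.0)

    def test_identical_populations_nonpositive(self):
        g = np.array([[2, 1, 0, 1]], dtype=np.int16)
        res = wc_fst_site(g, g.copy())
        assert res["fst"][0] <= 0

    def test_monomorphic_site_undefined(self):
        d = np.zeros((1, 6), dtype=np.int16)
        res = wc_fst_site(d, d.copy())
        assert bool(res["undefined"][0])

    def test_symmetric_under_population_swap(self):
        rng = np.random.default_rng(2)
        d1 = rng.integers(0, 3, (50, 8)).astype(np.int16)
        d2 = rng.integers(0, 3, (50, 6)).astype(np.int16)
        a = wc_fst_site(d1, d2)["fst"]
        b = wc_fst_site(d2, d1)["fst"]
        assert np.allclose(a, b, equal_nan=True)

    def test_matches_direct_formula_oracle(self):
        """a, b, c agree with an independent WC84 transcription to 1e-12
        on 1000 random genotype tables."""
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(1000):
            g1, g2 = random_genotypes(rng)
            a, b, c = wc_components(np.array([g1], dtype=np.int16),
                                    np.array([g2], dtype=np.int16))
            ea, eb, ec = oracles.wc84_components(g1, g2)
            assert a[0] == pytest.approx(ea, abs=1e-12)
            assert b[0] == pytest.approx(eb, abs=1e-12)
            assert c[0] == pytest.approx(ec, abs=1e-12)
            checked += 1
        assert checked == 1000

    def test_missing_genotypes_excluded(self):
        d1 = np.array([[2, 2, 2, -1]], dtype=np.int16)
        d2 = np.array([[0, 0, 0, -1]], dtype=np.int16)
        res = wc_fst_site(d1, d2)
        full = wc_fst_site(d1[:, :3], d2[:, :3])
        assert res["fst"][0] == pytest.approx(full["fst"][0])


class TestHudson:
    def test_fixed_opposite_alleles(self):
        assert hudson_fst_freq(1.0, 40, 0.0, 40) == pytest.approx(1.0)

    def test_equal_frequencies_limit_to_zero(self):
        val = hudson_fst_freq(0.5, 10**7, 0.5, 10**7)
        assert abs(val) < 1e-6

    def test_both_fixed_same_allele_undefined(self):
        assert np.isnan(hudson_fst_freq(0.0, 40, 0.0, 40))

    def test_rejects_out_of_range_frequency(self):
        with pytest.raises(ValueError):
            hudson_fst_freq(1.2, 40, 0.5, 40)

    def test_matches_oracle_on_random_draws(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            p1, p2 = rng.uniform(0.01, 0.99, 2)
            n1 = int(rng.integers(4, 200))
            n2 = int(rng.integers(4, 200))
            got = hudson_fst_freq(p1, n1, p2, n2)
            assert got == pytest.approx(oracles.hudson_fst(p1, n1, p2, n2),
                                        abs=1e-12)

    def test_example_value(self):
        assert hudson_fst_freq(0.8, 40, 0.2, 40) == pytest.approx(
            oracles.hudson_fst(0.8, 40, 0.2, 40), abs=1e-12)


def sites_frame(positions, a, b, c, chrom="c1"):
    a, b, c = map(np.asarray, (a, b, c))
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = a / (a + b + c)
    return pd.DataFrame({
        "id": [f"v{i}" for i in range(len(positions))], "chrom": chrom,
        "pos": positions, "start": positions, "a": a, "b": b, "c": c,
        "fst": fst, "undefined": np.isnan(fst)})


class TestWindowedFst:
    def test_single_site_window_equals_site(self):
        sites = sites_frame([1000], [0.2], [0.3], [0.5])
        wins = windowed_fst(sites)
        assert np.allclose(wins["fst_weighted"], 0.2)

    def test_all_zero_a_gives_zero(self):
        sites = sites_frame([100, 2000, 30_000], [0, 0, 0], [1, 1, 1], [1, 1, 1])
        wins = windowed_fst(sites)
        assert (wins["fst_weighted"] == 0).all()

    def test_matches_bruteforce_window_loop(self):
        """Window stats equal an explicit per-window recomputation on a
        100-site toy chromosome."""
        rng = np.random.default_rng(4)
        pos = np.sort(rng.integers(0, 300_000, 100))
        a = rng.uniform(-0.05, 0.3, 100)
        b = rng.uniform(0, 0.4, 100)
        c = rng.uniform(0, 0.6, 100)
        sites = sites_frame(pos, a, b, c)
        wins = windowed_fst(sites, window=50_000, step=20_000)
        for row in wins.itertuples(index=False):
            sel = (pos >= row.start) & (pos < row.end)
            assert row.n_sites == sel.sum()
            assert row.fst_weighted == pytest.approx(
                a[sel].sum() / (a[sel] + b[sel] + c[sel]).sum())
            assert row.fst_mean == pytest.approx(
                np.mean(a[sel] / (a[sel] + b[sel] + c[sel])))

    def test_pooled_additivity(self):
        """Ratio-of-sums of a window equals Fst of the pooled components."""
        rng = np.random.default_rng(6)
        a = rng.uniform(0, 0.2, 10)
        b = rng.uniform(0, 0.4, 10)
        c = rng.uniform(0.1, 0.6, 10)
        sites = sites_frame(np.arange(10) * 100, a, b, c)
        wins = windowed_fst(sites, window=50_000, step=50_000)
        assert wins["fst_weighted"][0] == pytest.approx(
            a.sum() / (a + b + c).sum())


class TestTopSelectionRegions:
    def test_top_one_percent_count(self):
        df = pd.DataFrame({"chrom": "c1", "start": range(500),
                           "end": range(1, 501),
                           "fst": np.linspace(0, 1, 500)})
        top = top_selection_regions(df, "fst")
        assert len(top) == 5

    def test_ties_included(self):
        df = pd.DataFrame({"chrom": "c1", "start": range(300),
                           "end": range(1, 301),
                           "fst": [0.9] * 10 + [0.1] * 290})
        top = top_selection_regions(df, "fst")
        assert len(top) == 10  # k=3 but 10 bins tie at 0.9

    def test_planted_selection_locus_detected(self):
        """Locus with F=0.5 on background F=0.02 lands in the top 1%."""
        rng = np.random.default_rng(21)
        L, n = 1000, 50
        F = np.full(L, 0.02)
        F[123] = 0.5
        p = rng.uniform(0.05, 0.95, L)
        pk = rng.beta(p * (1 - F) / F, (1 - p) * (1 - F) / F, (2, L)).T
        d1 = rng.binomial(2, pk[:, 0][:, None], (L, n))
        d2 = rng.binomial(2, pk[:, 1][:, None], (L, n))
        f1, f2 = d1.mean(axis=1) / 2, d2.mean(axis=1) / 2
        sites = pd.DataFrame({"chrom": "c1", "start": np.arange(L) * 1000,
                              "end": np.arange(L) * 1000 + 100,
                              "fst": hudson_fst_freq(f1, 2 * n, f2, 2 * n)})
        top = top_selection_regions(sites, "fst")
        assert 123 in set(top.index) or 123 in set(
            sites.index[sites["fst"] >= top["fst"].min()])


class TestAggregateEstimators:
    def test_balding_nichols_parameter_recovery_smoke(self):
        """Quick single-F recovery; the full sweep runs in the acceptance suite."""
        rng = np.random.default_rng(13)
        F, L, n = 0.05, 2000, 50
        p = rng.uniform(0.05, 0.95, L)
        p1 = rng.beta(p * (1 - F) / F, (1 - p) * (1 - F) / F)
        p2 = rng.beta(p * (1 - F) / F, (1 - p) * (1 - F) / F)
        d1 = rng.binomial(2, p1[:, None], (L, n)).astype(np.int16)
        d2 = rng.binomial(2, p2[:, None], (L, n)).astype(np.int16)
        assert wc_fst_overall(d1, d2) == pytest.approx(F, abs=0.01)
        f1, f2 = d1.mean(axis=1) / 2, d2.mean(axis=1) / 2
        assert hudson_fst_overall(f1, 2 * n, f2, 2 * n) == pytest.approx(F, abs=0.01)


class TestGeneOverlap:
    def test_genes_and_shared_genes(self):
        genes = pd.DataFrame({
            "gene_id": ["gA", "gB", "gC"], "chrom": ["c1", "c1", "c2"],
            "start": [100, 5000, 100], "end": [200, 6000, 300]})
        regions = pd.DataFrame({"chrom": ["c1"], "start": [150], "end": [5500]})
        assert genes_in_regions(regions, genes) == ["gA", "gB"]
        shared = shared_genes({("P1", "P2"): ["gA", "gB"], ("P1", "P3"): ["gB"]})
        assert shared["gene_id"].tolist() == ["gB"]
        assert shared["n_pairs"].tolist() == [2]
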