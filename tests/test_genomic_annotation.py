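import numpy as np
import pandas as pd

import oracles
from svscape.genomic_annotation import (
    REGIONS,
    build_region_index,
    classify_region,
    classify_variants,
    region_summary,
)
from svscape.io_formats import GeneModelSet


def toy_to_models(toy):
    """Convert the oracle's toy description into a GeneModelSet."""
    genes, txs = [], []
    exons, utr5, utr3 = {}, {}, {}
    for i, g in enumerate(toy["coding"]):
        gid, tid = f"g{i}", f"t{i}"
        genes.append((gid, "c1", g["span"][0], g["span"][1], "+", "protein_coding"))
        txs.append((tid, gid, "c1", "+", "mRNA"))
        exons[tid] = sorted(g["exons"])
        utr5[tid] = list(g["utr5"])
        utr3[tid] = list(g["utr3"])
    for j, (s, e) in enumerate(toy["noncoding"]):
        gid, tid = f"ng{j}", f"nt{j}"
        genes.append((gid, "c1", s, e, "+", "lncRNA"))
        txs.append((tid, gid, "c1", "+", "lnc_RNA"))
        exons[tid] = [(s, e)]
    return GeneModelSet(
        pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end",
                                     "strand", "biotype"]),
        pd.DataFrame(txs, columns=["tx_id", "gene_id", "chrom", "strand",
                                   "tx_type"]),
        exons, utr5, utr3)


def random_toy(rng):
    """A toy gene neighbourhood on a 10 kb chromosome."""
    toy = {"coding": [], "noncoding": []}
    if rng.random() < 0.8:
        start = int(rng.integers(1500, 3000))
        n_ex = int(rng.integers(2, 4))
        exons = []
        cur = start
        for _ in range(n_ex):
            e = cur + int(rng.integers(60, 200))
            exons.append((cur, e))
            cur = e + int(rng.integers(40, 300))
        end = exons[-1][1]
        u5 = int(rng.integers(10, 40))
        u3 = int(rng.integers(10, 40))
        toy["coding"].append({
            "span": (start, end), "exons": exons,
            "utr5": [(exons[0][0], exons[0][0] + u5)],
            "utr3": [(exons[-1][1] - u3, exons[-1][1])]})
    if rng.random() < 0.5:
        s = int(rng.integers(6000, 8000))
        toy["noncoding"].append((s, s + int(rng.integers(300, 1200))))
    return toy


class TestClassifyRegionOracle:
    def test_agrees_with_per_base_precedence_vote(self):
        """200 random toy gene models x random spans: classification equals
        a brute-force per-base feature vote with the same precedence."""
        rng = np.random.default_rng(99)
        for _ in range(200):
            toy = random_toy(rng)
            index = build_region_index(toy_to_models(toy))
            for _ in range(12):
                start = int(rng.integers(0, 9_900))
                length = int(rng.integers(0, 80))
                end = min(start + length, 10_000)
                got = classify_region("c1", start, end, index).region
                expected = oracles.span_region(start, end, toy)
                assert got == expected, (toy, start, end)

    def test_exon_over_intron_precedence_across_genes(self):
        """A span touching gene A's exon and gene B's intron is exonic."""
        toy = {"coding": [
            {"span": (1000, 2000), "exons": [(1000, 1400), (1800, 2000)],
             "utr5": [], "utr3": []},
            {"span": (1300, 2500), "exons": [(1300, 1350), (2400, 2500)],
             "utr5": [], "utr3": []}],
            "noncoding": []}
        index = build_region_index(toy_to_models(toy))
        # 1360..1380 is exonic in gene 0, intronic in gene 1
        call = classify_region("c1", 1360, 1380, index)
        assert call.region == "exonic_splicing"
        assert set(call.gene_ids) == {"g0", "g1"}

    def test_upstream_flank_rule(self):
        toy = {"coding": [{"span": (5000, 6000), "exons": [(5000, 6000)],
                           "utr5": [], "utr3": []}], "noncoding": []}
        index = build_region_index(toy_to_models(toy))
        assert classify_region("c1", 4500, 4501, index).region == \
            "upstream_downstream"
        assert classify_region("c1", 3500, 3501, index).region == "intergenic"

    def test_splice_window_is_exonic_splicing(self):
        toy = {"coding": [{"span": (1000, 2000),
                           "exons": [(1000, 1200), (1800, 2000)],
                           "utr5": [], "utr3": []}], "noncoding": []}
        index = build_region_index(toy_to_models(toy))
        assert classify_region("c1", 1200, 1201, index).region == "exonic_splicing"
        assert classify_region("c1", 1202, 1203, index).region == "intronic"


class TestRegionSummary:
    def test_rows_sum_to_100(self, default_cohort):
        c = default_cohort
        calls = classify_variants(c.table, c.models)
        summary = region_summary(calls[calls["vtype"] != "SNP"])
        totals = summary[list(REGIONS)].sum(axis=1)
        assert np.allclose(totals, 100.0, atol=0.01)

    def test_empty_input_empty_table(self):
        empty = pd.DataFrame(columns=["id", "vtype", "size_class", "region"])
        assert len(region_summary(empty)) == 0

    def test_all_intergenic_without_genes(self):
        from svscape.synthetic_data import SimConfig, simulate_cohort

        cfg = SimConfig(seed=3, n_genes=0, n_snps=150, n_indels=150, n_svs=40,
                        n_qtl=10, n_re=10, n_background_repeats=5)
        c = simulate_cohort(cfg)
        calls = classify_variants(c.table, c.models)
        assert (calls["region"] == "intergenic").all()


class TestPlantedRegionRecovery:
    def test_pipeline_calls_match_generator_truth(self, default_cohort):
        """Every variant's classified region equals the planted truth."""
        c = default_cohort
        calls = classify_variants(c.table, c.models).set_index("id")
        truth = c.truth.variants
        merged = calls.join(truth["region"], rsuffix="_truth")
        assert (merged["region"] == merged["region_truth"]).all()

    def test_planted_mix_recovered_within_sampling_error(self, small_cfg_kwargs):
        """Point variants drawn from a target region mix reproduce it."""
        from svscape.synthetic_data import SimConfig, simulate_cohort

        cfg = SimConfig(seed=41, hotspot_multiplier=1.0, n_snps=4000,
                        n_indels=0, n_svs=0, n_genes=10, n_qtl=20, n_re=10,
                        n_background_repeats=10)
        c = simulate_cohort(cfg)
        calls = classify_variants(c.table, c.models)
        got = calls["region"].value_counts(normalize=True)
        n = len(calls)
        for region, target in cfg.region_mix.items():
            se = np.sqrt(target * (1 - target) / n)
            # pool exhaustion can only push mass toward intergenic
            if region == "intergenic":
                assert got.get(region, 0) >= target - 4 * se
            else:
                assert got.get(region, 0) <= target + 4 * se + 0.01
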