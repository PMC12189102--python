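"""Desk-scale synthetic multi-breed cohorts with planted ground truth.

The generator emulates the statistical structure every pipeline stage
assumes, not sequence-level realism:

* Population structure follows the Balding-Nichols model: each locus has
  an ancestral frequency p ~ Uniform(0.05, 0.95) and per-population
  frequencies p_k ~ Beta(p(1-F)/F, (1-p)(1-F)/F), so the expected Fst
  between populations is approximately F.  Per-locus F overrides plant
  selection signals.
* Variant lengths mix the Small/Medium/Large classes; SV-scale lengths
  come from a transposable-element library whose SINE/Core-RTE component
  (BOV-A2-like) peaks near 140 bp.
* Positions are drawn from region-class pools (so a target region mix is
  planted exactly), with a fraction of indels/SVs relocated into
  designated hotspot bins to plant a breakpoint-rate multiplier.
* Repeat annotations are emitted in genuine RepeatMasker ``.out`` column
  layout (reference coordinates for deletions, ALT-sequence coordinates
  keyed by variant id for insertions) with planted coverage fractions on
  either side of the 80% rule.
* LD tags are planted by copying (high) or partially resampling (medium)
  an e/sQTL SNP's dosage vector into a variant.

Every emitted variant is covered by the returned :class:`SyntheticTruth`;
identical seeds give byte-identical output files.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import genomic_annotation
from .io_formats import (
    MISSING,
    GeneModelSet,
    GenomeLayout,
    IntervalTrack,
    VariantTable,
    write_bed,
    write_genome_tsv,
    write_vcf,
)

QTL_CATEGORIES = ("Exterior", "Health", "Meat and Carcass", "Milk",
                  "Production", "Reproduction")

DEFAULT_TISSUES = ("Blood", "Liver", "Muscle", "Mammary", "Uterus",
                   "Rumen", "Adipose", "Hypothalamus")

# (class, name, sampler kind, params, weight); lengths in bp, all > 50
DEFAULT_TE_LIBRARY = (
    ("LINE/L1", "L1_BT", "lognormal", (6.5, 0.7), 0.40),
    ("LINE/RTE-BovB", "BovB", "lognormal", (6.2, 0.6), 0.12),
    ("SINE/Core-RTE", "BOV-A2", "normal", (138.0, 9.0), 0.28),
    ("SINE/tRNA-Core", "SINE2_BT", "normal", (200.0, 25.0), 0.10),
    ("LTR/ERVK", "ERV2-1_BT", "lognormal", (6.0, 0.5), 0.10),
)

# unit-length mix for simple repeats: 2 bp units dominate, decreasing 3..10
DEFAULT_UNIT_MIX = (0.10, 0.40, 0.16, 0.10, 0.07, 0.06, 0.04, 0.03, 0.02, 0.02)

DEFAULT_REGION_MIX = {
    "intergenic": 0.70, "intronic": 0.19, "exonic_splicing": 0.02,
    "UTR5": 0.005, "UTR3": 0.005, "upstream_downstream": 0.04, "ncRNA": 0.04,
}


@dataclass
class SimConfig:
    """Generator parameters; defaults emulate the five-breed study design."""

    seed: int = 0
    pop_names: tuple[str, ...] = ("Dabieshan", "Wuling", "Yiling", "Yunba", "Zaobei")
    n_per_pop: int = 20
    chrom_names: tuple[str, ...] = ("1", "2")
    chrom_length: int = 5_000_000
    n_snps: int = 4000
    n_indels: int = 3000
    n_svs: int = 800
    F: float = 0.02                      # background differentiation
    n_selection_loci: int = 0
    selection_F: float = 0.5
    hotspot_frac: float = 0.01
    hotspot_multiplier: float = 20.0
    n_genes: int = 40
    region_mix: dict = field(default_factory=lambda: dict(DEFAULT_REGION_MIX))
    te_library: tuple = DEFAULT_TE_LIBRARY
    te_driven_frac_large: float = 0.44   # fraction of Large INS/DEL that are TE-driven
    te_driven_frac_medium: float = 0.06
    simple_repeat_frac: float = 0.025    # of Medium+Large
    simple_repeat_unit_mix: tuple = DEFAULT_UNIT_MIX
    n_background_repeats: int = 200
    n_qtl: int = 300
    n_re: int = 200
    eqtl_frac: float = 0.15              # of SNPs flagged as e/sQTL
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    missing_rate: float = 0.02
    high_missing_frac: float = 0.02      # SVs planted to fail the 30% cap
    low_maf_frac: float = 0.02           # SVs planted to fail MAF > 0.01
    hard_filter_fail_frac: float = 0.02  # SNPs/indels planted to fail one rule
    tag_high_frac: float = 0.25          # indels/SVs copied from an e/sQTL SNP
    tag_medium_frac: float = 0.15
    small_frac: float = 0.8              # of indels; rest Medium

    def __post_init__(self) -> None:
        if not 0 < self.F < 1:
            raise ValueError("F must be in (0, 1)")
        if self.hotspot_multiplier < 1:
            raise ValueError("hotspot multiplier must be >= 1")
        total = sum(self.region_mix.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("region_mix proportions must sum to 1")
        if abs(sum(self.simple_repeat_unit_mix) - 1.0) > 1e-6:
            raise ValueError("simple_repeat_unit_mix must sum to 1")

    @property
    def layout(self) -> GenomeLayout:
        return GenomeLayout(tuple(self.chrom_names),
                            {c: self.chrom_length for c in self.chrom_names})

    @property
    def n_samples(self) -> int:
        return len(self.pop_names) * self.n_per_pop


@dataclass
class SyntheticTruth:
    """Planted ground truth keyed by variant id."""

    variants: pd.DataFrame
    hotspot_bins: list[tuple[str, int]]
    pop_freqs: pd.DataFrame      # per variant x population allele frequency
    config: SimConfig


@dataclass
class SyntheticCohort:
    """In-memory outputs of one simulation, plus file paths when written."""

    table: VariantTable
    layout: GenomeLayout
    pop_map: dict[str, str]
    models: GeneModelSet
    qtl: IntervalTrack
    regulatory: IntervalTrack
    eqtl_snps: IntervalTrack
    ref_repeats: IntervalTrack
    alt_repeats: IntervalTrack
    truth: SyntheticTruth
    paths: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# placement bookkeeping
# ---------------------------------------------------------------------------

class _Occupancy:
    """Per-chromosome disjoint occupied spans + minimum start spacing."""

    def __init__(self, min_gap: int = 12) -> None:
        self.spans: dict[str, tuple[list[int], list[int]]] = {}
        self.starts: dict[str, list[int]] = {}
        self.min_gap = min_gap

    def fits(self, chrom: str, s: int, e: int) -> bool:
        e = max(e, s + 1)
        ss, ee = self.spans.setdefault(chrom, ([], []))
        i = bisect.bisect_right(ss, s)
        if i > 0 and ee[i - 1] > s:
            return False
        if i < len(ss) and ss[i] < e:
            return False
        starts = self.starts.setdefault(chrom, [])
        j = bisect.bisect_left(starts, s)
        for k in (j - 1, j):
            if 0 <= k < len(starts) and abs(starts[k] - s) <= self.min_gap:
                return False
        return True

    def add(self, chrom: str, s: int, e: int) -> None:
        e = max(e, s + 1)
        ss, ee = self.spans.setdefault(chrom, ([], []))
        i = bisect.bisect_right(ss, s)
        ss.insert(i, s)
        ee.insert(i, e)
        bisect.insort(self.starts.setdefault(chrom, []), s)


def _pool_arrays(index: "genomic_annotation.RegionIndex", layout: GenomeLayout
                 ) -> dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Per-region sampling pools: each region's track minus higher precedence.

    A point drawn from pool L is guaranteed to classify as L.  The
    intergenic pool is the complement of every other track.
    """
    from ._intervals import merge, subtract

    regions = genomic_annotation.REGIONS
    pools: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {r: {} for r in regions}
    for chrom in layout.chrom_names:
        higher_s = np.array([], dtype=np.int64)
        higher_e = np.array([], dtype=np.int64)
        for label in regions[:-1]:
            track = index.tracks[label].get(chrom)
            ts, te = track if track is not None else (np.array([], dtype=np.int64),) * 2
            ps, pe = subtract(ts, te, higher_s, higher_e)
            if len(ps):
                pools[label][chrom] = (ps, pe)
            higher_s, higher_e = merge(np.concatenate([higher_s, ts]),
                                       np.concatenate([higher_e, te]))
        clen = layout.chrom_lengths[chrom]
        # start at 1 so every variant has a padding base before it in VCF terms
        gs, ge = subtract(np.array([1]), np.array([clen]), higher_s, higher_e)
        pools["intergenic"][chrom] = (gs, ge)
    return pools


def _sample_from_pool(rng, pool: dict[str, tuple[np.ndarray, np.ndarray]],
                      span_len: int, occ: _Occupancy, tries: int = 60
                      ) -> tuple[str, int] | None:
    """A (chrom, start) whose span of span_len bp fits inside one pool interval."""
    chroms = sorted(pool)
    if not chroms:
        return None
    need = max(span_len, 1)
    weights = []
    flat = []
    for chrom in chroms:
        s, e = pool[chrom]
        ok = (e - s) >= need
        for i in np.flatnonzero(ok):
            flat.append((chrom, int(s[i]), int(e[i])))
            weights.append(int(e[i] - s[i]) - need + 1)
    if not flat:
        return None
    w = np.array(weights, dtype=float)
    w /= w.sum()
    for _ in range(tries):
        j = rng.choice(len(flat), p=w)
        chrom, s, e = flat[j]
        start = int(rng.integers(s, e - need + 1))
        if occ.fits(chrom, start, start + span_len):
            return chrom, start
    return None


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def _build_genes(cfg: SimConfig, rng) -> GeneModelSet:
    genes, txs = [], []
    exons: dict[str, list[tuple[int, int]]] = {}
    utr5: dict[str, list[tuple[int, int]]] = {}
    utr3: dict[str, list[tuple[int, int]]] = {}
    per_chrom = max(cfg.n_genes // max(len(cfg.chrom_names), 1), 0)
    gid = 0
    for chrom in cfg.chrom_names:
        pos = 5000
        for _ in range(per_chrom):
            pos += int(rng.integers(20_000, 120_000))
            coding = rng.random() < 0.85
            gene_id = f"GENE{gid:04d}"
            tx_id = f"TX{gid:04d}"
            if coding:
                n_ex = int(rng.integers(3, 7))
                ex_lens = rng.integers(150, 400, size=n_ex)
                in_lens = rng.integers(500, 3000, size=n_ex - 1)
                cur = pos
                ex = []
                for i in range(n_ex):
                    ex.append((cur, cur + int(ex_lens[i])))
                    cur = ex[-1][1]
                    if i < n_ex - 1:
                        cur += int(in_lens[i])
                end = ex[-1][1]
                if end > cfg.chrom_length - 5000:
                    break
                strand = "+" if rng.random() < 0.5 else "-"
                u5 = int(rng.integers(50, 120))
                u3 = int(rng.integers(50, 120))
                first, last = ex[0], ex[-1]
                if strand == "+":
                    utr5[tx_id] = [(first[0], first[0] + u5)]
                    utr3[tx_id] = [(last[1] - u3, last[1])]
                else:
                    utr5[tx_id] = [(last[1] - u3, last[1])]
                    utr3[tx_id] = [(first[0], first[0] + u5)]
                genes.append((gene_id, chrom, pos, end, strand, "protein_coding"))
                txs.append((tx_id, gene_id, chrom, strand, "mRNA"))
                exons[tx_id] = ex
            else:
                glen = int(rng.integers(1000, 5000))
                end = pos + glen
                if end > cfg.chrom_length - 5000:
                    break
                genes.append((gene_id, chrom, pos, end, "+", "lncRNA"))
                txs.append((tx_id, gene_id, chrom, "+", "lnc_RNA"))
                exons[tx_id] = [(pos, end)]
            pos = genes[-1][3]
            gid += 1
    return GeneModelSet(
        pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end",
                                     "strand", "biotype"]),
        pd.DataFrame(txs, columns=["tx_id", "gene_id", "chrom", "strand", "tx_type"]),
        exons, utr5, utr3)


def write_gff3(models: GeneModelSet, path) -> None:
    """Write gene models as GFF3 (1-based inclusive coordinates)."""
    tx_by_gene: dict[str, list] = {}
    for t in models.transcripts.itertuples(index=False):
        tx_by_gene.setdefault(t.gene_id, []).append(t)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models.genes.itertuples(index=False):
            ftype = "gene" if g.biotype == "protein_coding" else "ncRNA_gene"
            fh.write(f"{g.chrom}\tsvscape\t{ftype}\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id};biotype={g.biotype}\n")
            for t in tx_by_gene.get(g.gene_id, []):
                fh.write(f"{g.chrom}\tsvscape\t{t.tx_type}\t{g.start + 1}\t{g.end}\t.\t"
                         f"{g.strand}\t.\tID={t.tx_id};Parent={g.gene_id}\n")
                for i, (s, e) in enumerate(models.exons.get(t.tx_id, [])):
                    fh.write(f"{g.chrom}\tsvscape\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                             f"ID={t.tx_id}.exon{i};Parent={t.tx_id}\n")
                for kind, store in (("five_prime_UTR", models.utr5),
                                    ("three_prime_UTR", models.utr3)):
                    for i, (s, e) in enumerate(store.get(t.tx_id, [])):
                        fh.write(f"{g.chrom}\tsvscape\t{kind}\t{s + 1}\t{e}\t.\t"
                                 f"{g.strand}\t.\tID={t.tx_id}.{kind}{i};Parent={t.tx_id}\n")


RM_HEADER = (
    "   SW   perc perc perc  query       position in query              matching"
    "  repeat            position in repeat\n"
    "score   div. del. ins.  sequence    begin  end          (left)     repeat"
    "    class/family    begin  end    (left)   ID\n"
    "\n")


def write_repeatmasker_out(rows: list[tuple], path) -> None:
    """rows: (chrom/query, start0, end_excl, class_family, name).

    Written in genuine RepeatMasker .out column layout (1-based inclusive
    query coordinates) so the production parser is exercised.
    """
    with open(path, "w") as fh:
        fh.write(RM_HEADER)
        for i, (query, s, e, cls, name) in enumerate(rows, 1):
            ln = e - s
            fh.write(f"{250 + ln:>5} 10.0  0.5  0.5  {query}  {s + 1}  {e}  (0)  +"
                     f"  {name}  {cls}  1  {ln}  (0)  {i}\n")


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def _draw_te_length(rng, kind: str, params) -> int:
    if kind == "normal":
        val = rng.normal(*params)
    else:
        val = rng.lognormal(*params)
    return int(np.clip(round(val), 55, 8000))


def _random_unit(rng, length: int) -> str:
    unit = "".join(rng.choice(list("ACGT"), size=length))
    return f"({unit})n"


def divergent_pop_freqs(rng, p: float, F: float, n_pops: int,
                        min_divergence: float | None = None,
                        max_tries: int = 200) -> np.ndarray:
    """Balding-Nichols per-population frequencies for a planted sweep.

    An unconditioned Beta draw at high F leaves every population on the
    same side of the ancestral frequency about half the time — no sweep to
    detect.  A planted selection locus therefore rejection-samples until
    some population pair's frequency divergence
    ``(p_i - p_j)^2 / (p_i(1-p_j) + p_j(1-p_i))`` reaches
    ``min_divergence`` (default: F itself, the expected value of that
    ratio under the model).
    """
    if min_divergence is None:
        min_divergence = F
    a = p * (1 - F) / F
    b = (1 - p) * (1 - F) / F
    pk = rng.beta(a, b, n_pops)
    for _ in range(max_tries):
        best = 0.0
        for i in range(n_pops):
            for j in range(i + 1, n_pops):
                den = pk[i] * (1 - pk[j]) + pk[j] * (1 - pk[i])
                if den > 0:
                    best = max(best, (pk[i] - pk[j]) ** 2 / den)
        if best >= min_divergence:
            return pk
        pk = rng.beta(a, b, n_pops)
    return pk


def simulate_cohort(cfg: SimConfig, out_dir=None) -> SyntheticCohort:
    """Generate a full synthetic cohort, optionally writing all input files."""
    rng = np.random.default_rng(cfg.seed)
    layout = cfg.layout
    models = _build_genes(cfg, rng)
    index = genomic_annotation.build_region_index(models)
    pools = _pool_arrays(index, layout)
    occ = _Occupancy(min_gap=12)

    region_labels = list(cfg.region_mix)
    region_p = np.array([cfg.region_mix[r] for r in region_labels], dtype=float)
    region_p /= region_p.sum()

    bin_size = 100_000
    bins_per_chrom = {c: -(-layout.chrom_lengths[c] // bin_size)
                      for c in layout.chrom_names}
    all_bins = [(c, b) for c in layout.chrom_names for b in range(bins_per_chrom[c])]
    n_hot = int(np.floor(cfg.hotspot_frac * len(all_bins)))
    if cfg.hotspot_multiplier > 1 and cfg.hotspot_frac > 0:
        n_hot = max(n_hot, 1)
    hot_idx = sorted(rng.choice(len(all_bins), size=n_hot, replace=False)) if n_hot else []
    hotspot_bins = [all_bins[i] for i in hot_idx]
    hot_set = set(hotspot_bins)
    area = layout.total_length
    hot_area = n_hot * bin_size
    m = cfg.hotspot_multiplier
    q_hot = ((m - 1) * hot_area / (area + (m - 1) * hot_area)
             if n_hot and m > 1 else 0.0)

    def sample_hot_position(span_len: int) -> tuple[str, int] | None:
        for _ in range(60):
            chrom, b = hotspot_bins[int(rng.integers(0, len(hotspot_bins)))]
            lo = b * bin_size
            hi = min((b + 1) * bin_size, layout.chrom_lengths[chrom])
            start = int(rng.integers(max(lo, 1), hi))
            if start + span_len <= layout.chrom_lengths[chrom] and \
                    occ.fits(chrom, start, start + span_len):
                return chrom, start
        return None

    def sample_position(span_len: int, allow_hot: bool) -> tuple[str, int, str]:
        """(chrom, start, truth_region); start >= 1 so a VCF pad base exists."""
        if allow_hot and q_hot and rng.random() < q_hot:
            got = sample_hot_position(span_len)
            if got is not None:
                chrom, start = got
                call = genomic_annotation.classify_region(
                    chrom, start, start + span_len, index)
                return chrom, start, call.region
        label = region_labels[int(rng.choice(len(region_labels), p=region_p))]
        got = _sample_from_pool(rng, pools.get(label, {}), span_len, occ)
        if got is None:
            label = "intergenic"
            got = _sample_from_pool(rng, pools["intergenic"], span_len, occ)
        if got is None:
            raise RuntimeError("cannot place variant; genome too crowded")
        chrom, start = got
        if span_len > 0:
            call = genomic_annotation.classify_region(chrom, start, start + span_len,
                                                      index)
            label = call.region
        return chrom, start, label

    # ----- draw variant skeletons ---------------------------------------
    records = []   # dicts, one per variant
    for i in range(cfg.n_snps):
        chrom, start, region = sample_position(1, allow_hot=False)
        occ.add(chrom, start, start + 1)
        records.append(dict(id=f"SNP{i:06d}", vtype="SNP", length=1,
                            chrom=chrom, start=start, end=start + 1, region=region))
    for i in range(cfg.n_indels):
        if rng.random() < cfg.small_frac:
            length = int(np.clip(rng.geometric(0.45), 1, 10))
        else:
            length = int(rng.integers(11, 51))
        vtype = "DEL" if rng.random() < 0.6 else "INS"
        span = length if vtype == "DEL" else 0
        chrom, start, region = sample_position(span, allow_hot=True)
        occ.add(chrom, start, start + span)
        records.append(dict(id=f"IND{i:06d}", vtype=vtype, length=length,
                            chrom=chrom, start=start, end=start + span, region=region))
    te_lib = cfg.te_library
    te_w = np.array([t[4] for t in te_lib], dtype=float)
    te_w /= te_w.sum()
    for i in range(cfg.n_svs):
        lib = te_lib[int(rng.choice(len(te_lib), p=te_w))]
        length = _draw_te_length(rng, lib[2], lib[3])
        vtype = "DEL" if rng.random() < 0.6 else "INS"
        span = length if vtype == "DEL" else 0
        chrom, start, region = sample_position(span, allow_hot=True)
        occ.add(chrom, start, start + span)
        records.append(dict(id=f"SV{i:06d}", vtype=vtype, length=length,
                            chrom=chrom, start=start, end=start + span, region=region,
                            te_lib=lib))

    df = pd.DataFrame(records)
    df["size_class"] = np.where(df["vtype"] == "SNP", "",
                                np.where(df["length"] <= 10, "Small",
                                         np.where(df["length"] <= 50, "Medium",
                                                  "Large")))
    hot_member = [
        (row.chrom, row.start // bin_size) in hot_set for row in df.itertuples()]
    df["hotspot_member"] = hot_member

    # ----- repeat annotation planting -----------------------------------
    ref_rep_rows: list[tuple] = []
    alt_rep_rows: list[tuple] = []
    te_fraction = np.zeros(len(df))
    driver_class = np.array([""] * len(df), dtype=object)
    driver_name = np.array([""] * len(df), dtype=object)
    is_te = np.zeros(len(df), dtype=bool)
    is_simple = np.zeros(len(df), dtype=bool)
    unit_length = np.full(len(df), -1)
    unit_mix = np.array(cfg.simple_repeat_unit_mix, dtype=float)
    unit_mix /= unit_mix.sum()

    for i, row in enumerate(df.itertuples()):
        if row.vtype == "SNP" or row.size_class == "Small":
            continue
        L = int(row.length)
        u = rng.random()
        te_frac_target = (cfg.te_driven_frac_large if row.size_class == "Large"
                          else cfg.te_driven_frac_medium)
        planted = None
        if u < cfg.simple_repeat_frac:
            ul = 1 + int(rng.choice(10, p=unit_mix))
            name = _random_unit(rng, ul)
            planted = ("Simple_repeat", name)
            is_simple[i] = True
            unit_length[i] = ul
        elif u < cfg.simple_repeat_frac + te_frac_target:
            if hasattr(row, "te_lib") and isinstance(getattr(row, "te_lib"), tuple):
                cls, name = row.te_lib[0], row.te_lib[1]
            else:
                lib = te_lib[int(rng.choice(len(te_lib), p=te_w))]
                cls, name = lib[0], lib[1]
            planted = (cls, name)
            is_te[i] = True
        if planted is not None:
            cov = int(np.ceil(0.801 * L)) + int(rng.integers(0, max(L - int(np.ceil(0.801 * L)), 1)))
            cov = min(cov, L)
        elif rng.random() < 0.5:
            # sub-threshold repeat content, strictly below 80%
            cov = int(np.floor(0.7 * L * rng.random()))
            if cov >= 1:
                lib = te_lib[int(rng.choice(len(te_lib), p=te_w))]
                planted = (lib[0], lib[1])
            else:
                continue
        else:
            continue
        off = int(rng.integers(0, L - cov + 1))
        cls, name = planted
        te_fraction[i] = cov / L
        driver_class[i] = cls
        driver_name[i] = name
        if row.vtype == "DEL":
            ref_rep_rows.append((row.chrom, row.start + off, row.start + off + cov,
                                 cls, name))
        else:
            alt_rep_rows.append((row.id, off, off + cov, cls, name))
    # drop planted flags where coverage was sub-threshold
    is_te &= te_fraction > 0.8
    is_simple &= te_fraction > 0.8

    # background repeats in otherwise unoccupied reference
    for _ in range(cfg.n_background_repeats):
        lib = te_lib[int(rng.choice(len(te_lib), p=te_w))]
        L = _draw_te_length(rng, lib[2], lib[3])
        got = _sample_from_pool(rng, pools["intergenic"], L, occ)
        if got is None:
            continue
        chrom, start = got
        occ.add(chrom, start, start + L)
        ref_rep_rows.append((chrom, start, start + L, lib[0], lib[1]))

    df["te_fraction"] = te_fraction
    df["driver_class"] = driver_class
    df["driver_name"] = driver_name
    df["is_te_driven"] = is_te
    df["is_simple_repeat"] = is_simple
    df["unit_length"] = unit_length

    # ----- genotypes ------------------------------------------------------
    n_var = len(df)
    n_pops = len(cfg.pop_names)
    anc_p = rng.uniform(0.05, 0.95, size=n_var)
    F_locus = np.full(n_var, cfg.F)
    sel_flag = np.zeros(n_var, dtype=bool)
    if cfg.n_selection_loci:
        candidates = np.flatnonzero((df["vtype"] != "SNP").to_numpy())
        chosen = rng.choice(candidates, size=min(cfg.n_selection_loci, len(candidates)),
                            replace=False)
        F_locus[chosen] = cfg.selection_F
        sel_flag[chosen] = True
    a = anc_p * (1 - F_locus) / F_locus
    b = (1 - anc_p) * (1 - F_locus) / F_locus
    pop_p = rng.beta(a[:, None], b[:, None], size=(n_var, n_pops))
    for r in np.flatnonzero(sel_flag):
        pop_p[r] = divergent_pop_freqs(rng, anc_p[r], cfg.selection_F, n_pops)
    dosages = np.empty((n_var, cfg.n_samples), dtype=np.int16)
    for k in range(n_pops):
        cols = slice(k * cfg.n_per_pop, (k + 1) * cfg.n_per_pop)
        dosages[:, cols] = rng.binomial(
            2, pop_p[:, k][:, None], size=(n_var, cfg.n_per_pop))

    samples = [f"{pop}_{j:02d}" for pop in cfg.pop_names
               for j in range(cfg.n_per_pop)]
    pop_map = {s: s.rsplit("_", 1)[0] for s in samples}

    # ----- e/sQTL SNP track and LD planting ------------------------------
    snp_rows = np.flatnonzero((df["vtype"] == "SNP").to_numpy())
    n_eqtl = int(cfg.eqtl_frac * len(snp_rows))
    eqtl_rows = np.sort(rng.choice(snp_rows, size=n_eqtl, replace=False)) \
        if n_eqtl else np.array([], dtype=int)
    eqtl_records = []
    for r in eqtl_rows:
        kind = "eQTL" if rng.random() < 0.6 else "sQTL"
        n_tis = 1 + int(rng.random() < 0.3)
        tis = rng.choice(len(cfg.tissues), size=n_tis, replace=False)
        for t in tis:
            eqtl_records.append((df.at[r, "chrom"], int(df.at[r, "start"]),
                                 int(df.at[r, "start"]) + 1, kind, cfg.tissues[t]))
    eqtl_track = IntervalTrack.from_records(eqtl_records, name="eqtl_snps")

    planted_tag = np.array([""] * n_var, dtype=object)
    if len(eqtl_rows):
        eqtl_by_chrom: dict[str, np.ndarray] = {}
        for chrom in cfg.chrom_names:
            sel = eqtl_rows[(df.loc[eqtl_rows, "chrom"] == chrom).to_numpy()]
            eqtl_by_chrom[chrom] = sel
        indel_rows = np.flatnonzero(
            ((df["vtype"] != "SNP") & ~sel_flag).to_numpy())
        for r in indel_rows:
            u = rng.random()
            if u >= cfg.tag_high_frac + cfg.tag_medium_frac:
                continue
            near = eqtl_by_chrom.get(df.at[r, "chrom"], np.array([], dtype=int))
            if not len(near):
                continue
            dist = np.abs(df.loc[near, "start"].to_numpy() - df.at[r, "start"])
            near = near[dist <= 1_000_000]
            if not len(near):
                continue
            src = int(near[rng.integers(0, len(near))])
            dosages[r] = dosages[src]
            if u < cfg.tag_high_frac:
                planted_tag[r] = "high"
            else:
                # resample ~30% of samples: correlation ~0.7, r2 ~0.5
                nsw = int(0.3 * cfg.n_samples)
                swap = rng.choice(cfg.n_samples, size=nsw, replace=False)
                p_src = dosages[src][dosages[src] != MISSING].mean() / 2
                dosages[r, swap] = rng.binomial(2, p_src, size=nsw)
                planted_tag[r] = "medium"

    # ----- planted QC failures and missingness ---------------------------
    miss_mask = rng.random(size=dosages.shape) < cfg.missing_rate
    sv_rows = np.flatnonzero((df["size_class"] == "Large").to_numpy())
    planted_high_missing = np.zeros(n_var, dtype=bool)
    planted_low_maf = np.zeros(n_var, dtype=bool)
    if len(sv_rows):
        n_hm = int(cfg.high_missing_frac * len(sv_rows))
        n_lm = int(cfg.low_maf_frac * len(sv_rows))
        special = rng.choice(sv_rows, size=min(n_hm + n_lm, len(sv_rows)),
                             replace=False)
        hm, lm = special[:n_hm], special[n_hm:n_hm + n_lm]
        for r in hm:
            rate = rng.uniform(0.35, 0.6)
            miss_mask[r] = rng.random(cfg.n_samples) < rate
            # guarantee the strict 30% cap is exceeded
            while miss_mask[r].mean() <= 0.3:
                miss_mask[r, rng.integers(0, cfg.n_samples)] = True
        for r in lm:
            dosages[r] = 0
            dosages[r, int(rng.integers(0, cfg.n_samples))] = 1  # maf = 1/(2N)
        planted_high_missing[hm] = True
        planted_low_maf[lm] = True
        # dosage rewrites invalidate any LD tag planted on these rows
        planted_tag[hm] = ""
        planted_tag[lm] = ""
    dosages[miss_mask] = MISSING

    # ----- QUAL / INFO ----------------------------------------------------
    quals = np.round(rng.uniform(35, 1500, size=n_var), 2)
    infos: list[dict] = []
    fail_rule = np.array([""] * n_var, dtype=object)
    snp_indel_rows = np.flatnonzero((df["size_class"] != "Large").to_numpy())
    fail_rows = set(rng.choice(
        snp_indel_rows, size=int(cfg.hard_filter_fail_frac * len(snp_indel_rows)),
        replace=False).tolist()) if len(snp_indel_rows) else set()
    for i, row in enumerate(df.itertuples()):
        if row.size_class == "Large":
            info = {"SVTYPE": row.vtype, "SVLEN": int(row.length)}
            if row.vtype == "DEL":
                info["END"] = int(row.end)
            infos.append(info)
            continue
        if row.vtype == "SNP":
            info = {"QD": round(rng.uniform(5, 35), 2),
                    "FS": round(rng.uniform(0, 30), 2),
                    "SOR": round(rng.uniform(0.5, 2.5), 2),
                    "MQ": round(rng.uniform(50, 60), 2),
                    "MQRankSum": round(rng.uniform(-3, 3), 2),
                    "ReadPosRankSum": round(rng.uniform(-3, 3), 2)}
            rules = ["QD", "QUAL", "SOR", "FS", "MQ", "MQRankSum", "ReadPosRankSum"]
            bad_vals = {"QD": 1.0, "SOR": 4.0, "FS": 70.0, "MQ": 30.0,
                        "MQRankSum": -13.0, "ReadPosRankSum": -9.0}
        else:
            info = {"QD": round(rng.uniform(5, 35), 2),
                    "FS": round(rng.uniform(0, 100), 2),
                    "ReadPosRankSum": round(rng.uniform(-5, 5), 2)}
            rules = ["QD", "QUAL", "FS", "ReadPosRankSum"]
            bad_vals = {"QD": 1.0, "FS": 250.0, "ReadPosRankSum": -21.0}
        if i in fail_rows:
            rule = rules[int(rng.integers(0, len(rules)))]
            if rule == "QUAL":
                quals[i] = round(rng.uniform(1, 29), 2)
            else:
                info[rule] = bad_vals[rule]
            fail_rule[i] = rule
        infos.append(info)

    # ----- assemble the VariantTable (VCF coordinate conversion) ----------
    pos = np.empty(n_var, dtype=np.int64)
    refs = np.empty(n_var, dtype=object)
    alts = np.empty(n_var, dtype=object)
    bases = np.array(list("ACGT"))
    for i, row in enumerate(df.itertuples()):
        if row.vtype == "SNP":
            pos[i] = row.start + 1
            r, al = rng.choice(4, size=2, replace=False)
            refs[i], alts[i] = bases[r], bases[al]
        elif row.size_class == "Large":
            pos[i] = row.start  # pad base before the event
            refs[i] = "N"
            alts[i] = f"<{row.vtype}>"
        elif row.vtype == "DEL":
            pos[i] = row.start  # 1-based pad base; deleted = [start, end)
            seq = "".join(rng.choice(4, size=row.length).astype(str))
            seq = "".join(bases[int(c)] for c in seq)
            refs[i] = "A" + seq
            alts[i] = "A"
        else:
            pos[i] = row.start
            seq = "".join(bases[int(c)] for c in rng.choice(4, size=row.length))
            refs[i] = "A"
            alts[i] = "A" + seq

    vdf = pd.DataFrame({
        "id": df["id"], "chrom": df["chrom"], "pos": pos,
        "start": df["start"].astype(np.int64), "end": df["end"].astype(np.int64),
        "vtype": df["vtype"], "length": df["length"].astype(np.int64),
        "ref": refs, "alt": alts, "qual": quals})
    chrom_rank = {c: i for i, c in enumerate(cfg.chrom_names)}
    order = np.lexsort((pos, vdf["chrom"].map(chrom_rank).to_numpy()))
    table = VariantTable(vdf.iloc[order].reset_index(drop=True), dosages[order],
                         samples, [infos[i] for i in order])

    # ----- annotation tracks ---------------------------------------------
    qtl_records = []
    for _ in range(cfg.n_qtl):
        chrom = cfg.chrom_names[int(rng.integers(0, len(cfg.chrom_names)))]
        L = int(rng.integers(5_000, 200_000))
        s = int(rng.integers(0, layout.chrom_lengths[chrom] - L))
        cat = QTL_CATEGORIES[int(rng.integers(0, len(QTL_CATEGORIES)))]
        qtl_records.append((chrom, s, s + L, cat))
    qtl_track = IntervalTrack.from_records(qtl_records, name="qtl")
    re_records = []
    for _ in range(cfg.n_re):
        chrom = cfg.chrom_names[int(rng.integers(0, len(cfg.chrom_names)))]
        L = int(rng.integers(200, 2000))
        s = int(rng.integers(0, layout.chrom_lengths[chrom] - L))
        tis = cfg.tissues[int(rng.integers(0, len(cfg.tissues)))]
        re_records.append((chrom, s, s + L, tis))
    re_track = IntervalTrack.from_records(re_records, name="regulatory")

    ref_repeats = IntervalTrack.from_records(
        sorted(ref_rep_rows), name="ref_repeats")
    alt_repeats = IntervalTrack.from_records(
        sorted(alt_rep_rows), name="alt_repeats")

    # ----- truth ----------------------------------------------------------
    truth_df = pd.DataFrame({
        "id": df["id"], "vtype": df["vtype"], "length": df["length"],
        "size_class": df["size_class"], "region": df["region"],
        "hotspot_member": df["hotspot_member"],
        "te_fraction": df["te_fraction"], "driver_class": df["driver_class"],
        "driver_name": df["driver_name"], "is_te_driven": df["is_te_driven"],
        "is_simple_repeat": df["is_simple_repeat"],
        "unit_length": df["unit_length"],
        "ancestral_p": anc_p, "F_locus": F_locus, "selection_locus": sel_flag,
        "planted_tag": planted_tag, "planted_fail_rule": fail_rule,
        "planted_high_missing": planted_high_missing,
        "planted_low_maf": planted_low_maf,
    }).set_index("id")
    freq_df = pd.DataFrame(pop_p, columns=list(cfg.pop_names),
                           index=df["id"]).reset_index()
    truth = SyntheticTruth(truth_df, hotspot_bins, freq_df, cfg)
    cohort = SyntheticCohort(table, layout, pop_map, models, qtl_track, re_track,
                             eqtl_track, ref_repeats, alt_repeats, truth)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": out / "cohort.vcf", "qtl": out / "qtl.bed",
            "regulatory": out / "regulatory.bed",
            "eqtl_snps": out / "eqtl_snps.bed", "gff": out / "genes.gff3",
            "ref_rmout": out / "repeats_ref.out",
            "alt_rmout": out / "repeats_alt.out", "pops": out / "pops.tsv",
            "genome": out / "genome.tsv", "truth": out / "truth.tsv",
            "config": out / "sim_config.json",
        }
        write_vcf(table, paths["vcf"], layout)
        write_bed(qtl_track, paths["qtl"])
        write_bed(re_track, paths["regulatory"])
        with open(paths["eqtl_snps"], "w") as fh:
            for r in eqtl_track.df.itertuples(index=False):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\t{r.sublabel}\n")
        write_gff3(models, paths["gff"])
        write_repeatmasker_out(sorted(ref_rep_rows), paths["ref_rmout"])
        write_repeatmasker_out(sorted(alt_rep_rows), paths["alt_rmout"])
        with open(paths["pops"], "w") as fh:
            for s in samples:
                fh.write(f"{s}\t{pop_map[s]}\n")
        write_genome_tsv(layout, paths["genome"])
        truth_df.to_csv(paths["truth"], sep="\t")
        cfg_dict = asdict(cfg)
        cfg_dict["region_mix"] = dict(cfg.region_mix)
        with open(paths["config"], "w") as fh:
            json.dump(cfg_dict, fh, indent=1, default=str)
        cohort.paths = {k: str(v) for k, v in paths.items()}
    return cohort


def make_ld_block(p_hap, n: int, rng=None, seed: int | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Paired diploid dosages for two loci with given haplotype frequencies.

    ``p_hap``: frequencies of haplotypes (AB, Ab, aB, ab) summing to 1,
    where A/B are the alt alleles at the two loci.  2n haplotypes are
    drawn i.i.d. and paired into n diploids.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    p = np.asarray(p_hap, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("haplotype frequencies must sum to 1")
    haps = rng.choice(4, size=2 * n, p=p)
    has_a = (haps < 2).astype(np.int16)       # AB or Ab carries A
    has_b = ((haps == 0) | (haps == 2)).astype(np.int16)
    dos_a = has_a[:n] + has_a[n:]
    dos_b = has_b[:n] + has_b[n:]
    return dos_a, dos_b
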