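"""Post-calling variant QC: hard filters, proximity dedup, missingness/MAF.

Every downstream analysis is stratified by the three-way size
classification — Small (1–10 bp), Medium (11–50 bp), Large (>50 bp).
Hard-filter thresholds mirror the standard GATK VariantFiltration
recommendations for SNPs and indels; SV-scale records that lack those INFO
annotations simply skip the untestable rules.  All inequalities are strict
exactly as stated: a record is removed when QD < 2.0, retained at
FS == 200.0, fails MAF at exactly 0.01 and missingness at exactly the cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MISSING, VariantTable

SIZE_CLASSES = ("Small", "Medium", "Large")

SMALL_MAX = 10   # bp, inclusive
MEDIUM_MAX = 50  # bp, inclusive; above is Large


def classify_size(length: int) -> str:
    """Map an indel/SV length (bp) to Small (1-10), Medium (11-50) or Large (>50)."""
    if length < 1:
        raise ValueError(f"variant length must be >= 1, got {length}")
    if length <= SMALL_MAX:
        return "Small"
    if length <= MEDIUM_MAX:
        return "Medium"
    return "Large"


def add_size_class(table: VariantTable) -> VariantTable:
    """Attach a ``size_class`` column (SNPs are left unclassified as "")."""
    lengths = table.df["length"].to_numpy()
    vtypes = table.df["vtype"].to_numpy()
    classes = np.where(
        vtypes == "SNP", "",
        np.where(lengths <= SMALL_MAX, "Small",
                 np.where(lengths <= MEDIUM_MAX, "Medium", "Large")))
    table.df["size_class"] = classes
    return table


@dataclass(frozen=True)
class FilterThresholds:
    """Hard-filter bounds (GATK-style) plus cohort-level missingness/MAF caps."""

    snp: dict = field(default_factory=lambda: {
        "QD_min": 2.0, "QUAL_min": 30.0, "SOR_max": 3.0, "FS_max": 60.0,
        "MQ_min": 40.0, "MQRankSum_min": -12.5, "ReadPosRankSum_min": -8.0})
    indel: dict = field(default_factory=lambda: {
        "QD_min": 2.0, "QUAL_min": 30.0, "FS_max": 200.0,
        "ReadPosRankSum_min": -20.0})
    indel_missing_max: float = 0.1
    sv_missing_max: float = 0.3
    sv_maf_min: float = 0.01
    proximity_bp: int = 10

    def __post_init__(self) -> None:
        if self.proximity_bp < 0:
            raise ValueError("proximity_bp must be >= 0")


def _rule_fires(rules: dict, qual: float, info: dict) -> str | None:
    """Name of the first hard-filter rule that fires, or None.

    Rules referencing an INFO key absent from the record are skipped, not
    failed (merged SV records lack GATK annotations).
    """
    for rule, bound in rules.items():
        key, kind = rule.rsplit("_", 1)
        if key == "QUAL":
            val = qual
            if val is None or (isinstance(val, float) and np.isnan(val)):
                continue
        else:
            val = info.get(key)
            if val is None:
                continue
        val = float(val)
        if kind == "min" and val < bound:
            return rule
        if kind == "max" and val > bound:
            return rule
    return None


def apply_hard_filters(table: VariantTable, thresholds: FilterThresholds | None = None
                       ) -> tuple[VariantTable, dict[str, int]]:
    """Remove records failing any applicable hard-filter rule.

    Returns the filtered table and a per-rule rejection tally (a record
    removed by its first firing rule counts once, under that rule).
    """
    thresholds = thresholds or FilterThresholds()
    keep = np.ones(len(table), dtype=bool)
    tally: dict[str, int] = {}
    vtypes = table.df["vtype"].to_numpy()
    quals = table.df["qual"].to_numpy()
    for i in range(len(table)):
        rules = thresholds.snp if vtypes[i] == "SNP" else thresholds.indel
        fired = _rule_fires(rules, quals[i], table.info[i])
        if fired is not None:
            keep[i] = False
            tally[fired] = tally.get(fired, 0) + 1
    return table.subset(keep), tally


_VTYPE_RANK = {"DEL": 0, "INS": 1, "SNP": 2}


def proximity_dedup(table: VariantTable, distance: int = 10) -> VariantTable:
    """Resolve indel clusters: of two indels within ``distance`` bp, drop the lower QUAL.

    Greedy per chromosome: sort candidates by QUAL descending (ties by
    position ascending, then DEL before INS), accept the best, discard any
    unaccepted indel whose start (POS) lies within ``distance`` bp of an
    accepted start, repeat.  No two survivors are within ``distance`` bp.
    SNPs pass through untouched, as do Large (SV-scale) records when a
    ``size_class`` column is present — the rule belongs to the small-indel
    calling path.
    """
    is_indel = table.df["vtype"].isin(["INS", "DEL"]).to_numpy()
    if "size_class" in table.df.columns:
        is_indel &= table.df["size_class"].isin(["Small", "Medium"]).to_numpy()
    keep = np.ones(len(table), dtype=bool)
    sub = table.df[is_indel]
    for _, grp in sub.groupby("chrom", sort=False):
        order = sorted(
            grp.index,
            key=lambda i: (-table.df.at[i, "qual"], table.df.at[i, "pos"],
                           _VTYPE_RANK[table.df.at[i, "vtype"]]))
        accepted_pos: list[int] = []
        for i in order:
            pos = table.df.at[i, "pos"]
            if any(abs(pos - a) <= distance for a in accepted_pos):
                keep[i] = False
            else:
                accepted_pos.append(pos)
    return table.subset(keep)


def genotype_stats(table: VariantTable, pop_map: dict[str, str] | None = None
                   ) -> pd.DataFrame:
    """Per-variant missing rate, alt/ minor allele frequency, and per-population AF.

    MAF is computed on non-missing chromosomes only; a variant with every
    genotype missing gets NaN frequencies and ``undefined=True``.
    """
    d = table.dosages
    missing = d == MISSING
    n_samples = d.shape[1] if d.ndim == 2 else 0
    miss_rate = missing.mean(axis=1) if n_samples else np.zeros(len(table))
    valid = ~missing
    n_chrom = 2 * valid.sum(axis=1)
    alt_count = np.where(valid, d, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(n_chrom > 0, alt_count / np.maximum(n_chrom, 1), np.nan)
    maf = np.minimum(p_alt, 1 - p_alt)
    out = pd.DataFrame({
        "id": table.df["id"].to_numpy(),
        "missing_rate": miss_rate,
        "alt_freq": p_alt,
        "maf": maf,
        "undefined": n_chrom == 0,
    })
    if pop_map is not None:
        cols = {}
        sample_pops = np.array([pop_map[s] for s in table.samples])
        for pop in sorted(set(sample_pops)):
            sel = sample_pops == pop
            v = valid[:, sel]
            nc = 2 * v.sum(axis=1)
            ac = np.where(v, d[:, sel], 0).sum(axis=1)
            cols[f"af_{pop}"] = np.where(nc > 0, ac / np.maximum(nc, 1), np.nan)
        out = pd.concat([out, pd.DataFrame(cols)], axis=1)
    return out


def filter_cohort(table: VariantTable, thresholds: FilterThresholds | None = None,
                  pop_map: dict[str, str] | None = None
                  ) -> tuple[VariantTable, pd.DataFrame]:
    """Apply cohort-level missingness/MAF filters by variant path.

    Small/Medium indels require missing rate < ``indel_missing_max``;
    Large (SV-scale) records require missing rate < ``sv_missing_max`` AND
    MAF > ``sv_maf_min`` (both strict).  SNPs use the indel missingness cap.
    Returns the retained table and the full per-variant stats table with a
    ``retained`` column.
    """
    thresholds = thresholds or FilterThresholds()
    if "size_class" not in table.df.columns:
        add_size_class(table)
    stats = genotype_stats(table, pop_map=pop_map)
    sizes = table.df["size_class"].to_numpy()
    miss = stats["missing_rate"].to_numpy()
    maf = stats["maf"].to_numpy()
    is_sv = sizes == "Large"
    keep = np.where(
        is_sv,
        (miss < thresholds.sv_missing_max) & (maf > thresholds.sv_maf_min),
        miss < thresholds.indel_missing_max,
    )
    keep &= ~stats["undefined"].to_numpy()
    stats["retained"] = keep
    return table.subset(keep), stats


def qc_pipeline(table: VariantTable, thresholds: FilterThresholds | None = None,
                pop_map: dict[str, str] | None = None
                ) -> tuple[VariantTable, dict]:
    """Full QC: hard filters -> proximity dedup (indels) -> cohort filters."""
    thresholds = thresholds or FilterThresholds()
    add_size_class(table)
    n0 = len(table)
    table, tally = apply_hard_filters(table, thresholds)
    n1 = len(table)
    table = proximity_dedup(table, thresholds.proximity_bp)
    n2 = len(table)
    table, stats = filter_cohort(table, thresholds, pop_map=pop_map)
    report = {
        "input": n0,
        "after_hard_filters": n1,
        "after_proximity_dedup": n2,
        "after_cohort_filters": len(table),
        "hard_filter_tally": tally,
    }
    return table, report
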