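"""ANNOVAR-style assignment of variants to genomic region groups.

Each variant gets exactly one region from: exonic regions and splice
sites, 5'/3' UTRs, intronic, noncoding-RNA, upstream/downstream flanks,
or intergenic.  When a variant's span (or insertion anchor) touches
several features the highest-precedence one wins:

    exonic_splicing > UTR5 > UTR3 > intronic > ncRNA
                    > upstream_downstream > intergenic

Defaults follow ANNOVAR: 1 kb up/downstream flanks and a 2 bp splice
window into each intron.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _intervals
from .io_formats import GeneModelSet, VariantTable

REGIONS = ("exonic_splicing", "UTR5", "UTR3", "intronic", "ncRNA",
           "upstream_downstream", "intergenic")
# higher value = higher precedence
PRECEDENCE = {r: len(REGIONS) - i for i, r in enumerate(REGIONS)}

DEFAULT_FLANK = 1000
SPLICE_WINDOW = 2


@dataclass
class RegionCall:
    variant_id: str
    region: str
    gene_ids: list[str]


@dataclass
class RegionIndex:
    """Per-chromosome merged interval arrays for each region label, plus genes."""

    tracks: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]
    genes: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]  # starts, ends, ids
    flank: int


def build_region_index(models: GeneModelSet, flank: int = DEFAULT_FLANK,
                       splice_window: int = SPLICE_WINDOW) -> RegionIndex:
    """Precompute region interval sets from gene models.

    Coding transcripts contribute exonic (exon minus UTR), UTR5/UTR3,
    splice windows (``splice_window`` bp into each intron, counted as
    exonic_splicing) and intronic intervals.  Non-coding genes contribute
    their whole span as ncRNA.  Every gene contributes ``flank`` bp of
    upstream/downstream on both sides.
    """
    per_label: dict[str, dict[str, list[tuple[int, int]]]] = {
        r: {} for r in REGIONS if r != "intergenic"}

    def add(label: str, chrom: str, s: int, e: int) -> None:
        if e > s:
            per_label[label].setdefault(chrom, []).append((s, e))

    coding_gene_ids = set(
        models.genes.loc[models.genes["biotype"] == "protein_coding", "gene_id"])
    tx_chrom = dict(zip(models.transcripts["tx_id"], models.transcripts["chrom"]))
    tx_gene = dict(zip(models.transcripts["tx_id"], models.transcripts["gene_id"]))

    for tx_id, exons in models.exons.items():
        chrom = tx_chrom.get(tx_id)
        if chrom is None:
            continue
        coding = tx_gene.get(tx_id) in coding_gene_ids
        if not coding:
            continue  # non-coding handled via gene spans below
        utrs5 = models.utr5.get(tx_id, [])
        utrs3 = models.utr3.get(tx_id, [])
        ex_s = np.array([s for s, _ in exons])
        ex_e = np.array([e for _, e in exons])
        utr_all = utrs5 + utrs3
        if utr_all:
            cds_s, cds_e = _intervals.subtract(
                ex_s, ex_e,
                np.array([s for s, _ in utr_all]), np.array([e for _, e in utr_all]))
        else:
            cds_s, cds_e = _intervals.merge(ex_s, ex_e)
        for s, e in zip(cds_s, cds_e):
            add("exonic_splicing", chrom, int(s), int(e))
        for s, e in utrs5:
            add("UTR5", chrom, s, e)
        for s, e in utrs3:
            add("UTR3", chrom, s, e)
        for s, e in models.introns(tx_id):
            add("intronic", chrom, s, e)
            add("exonic_splicing", chrom, s, min(s + splice_window, e))
            add("exonic_splicing", chrom, max(e - splice_window, s), e)

    for g in models.genes.itertuples(index=False):
        if g.biotype != "protein_coding":
            add("ncRNA", g.chrom, g.start, g.end)
        add("upstream_downstream", g.chrom, max(g.start - flank, 0), g.start)
        add("upstream_downstream", g.chrom, g.end, g.end + flank)

    tracks: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for label, chroms in per_label.items():
        tracks[label] = {}
        for chrom, ivals in chroms.items():
            s = np.array([a for a, _ in ivals])
            e = np.array([b for _, b in ivals])
            tracks[label][chrom] = _intervals.merge(s, e)

    genes: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, grp in models.genes.groupby("chrom", sort=False):
        order = np.argsort(grp["start"].to_numpy(), kind="stable")
        genes[str(chrom)] = (grp["start"].to_numpy()[order],
                             grp["end"].to_numpy()[order],
                             grp["gene_id"].to_numpy()[order])
    return RegionIndex(tracks, genes, flank)


def _touches(index: RegionIndex, label: str, chrom: str, s: int, e: int) -> bool:
    track = index.tracks[label].get(chrom)
    if track is None:
        return False
    return bool(_intervals.overlap_mask(
        np.array([s]), np.array([e]), track[0], track[1])[0])


def classify_region(chrom: str, start: int, end: int, index: RegionIndex,
                    variant_id: str = "") -> RegionCall:
    """Region call for one span (0-based half-open; zero-length = INS anchor)."""
    s, e = (start, start + 1) if end == start else (start, end)
    region = "intergenic"
    for label in REGIONS[:-1]:
        if _touches(index, label, chrom, s, e):
            region = label
            break
    gene_ids: list[str] = []
    g = index.genes.get(chrom)
    if g is not None:
        gs, ge, gid = g
        pad = index.flank if region == "upstream_downstream" else 0
        hit = (gs - pad < e) & (ge + pad > s)
        gene_ids = sorted(gid[hit])
    return RegionCall(variant_id=variant_id, region=region, gene_ids=gene_ids)


def classify_variants(table: VariantTable, models: GeneModelSet,
                      flank: int = DEFAULT_FLANK,
                      splice_window: int = SPLICE_WINDOW) -> pd.DataFrame:
    """Region call for every variant; returns a tidy per-variant table."""
    index = build_region_index(models, flank=flank, splice_window=splice_window)
    if "size_class" not in table.df.columns:
        from .variant_qc import add_size_class

        add_size_class(table)
    rows = []
    for row in table.df.itertuples(index=False):
        call = classify_region(row.chrom, row.start, row.end, index,
                               variant_id=row.id)
        rows.append((row.id, row.vtype, row.size_class, call.region,
                     ",".join(call.gene_ids)))
    return pd.DataFrame(rows, columns=["id", "vtype", "size_class", "region",
                                       "gene_ids"])


def region_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Percentage of variants per region, per (vtype x size class) row.

    Percentages within each row sum to 100 (up to floating rounding).
    """
    if len(calls) == 0:
        return pd.DataFrame(columns=["vtype", "size_class", *REGIONS, "n"])
    rows = []
    for (vtype, size), grp in calls.groupby(["vtype", "size_class"], sort=True):
        counts = grp["region"].value_counts()
        n = len(grp)
        pct = [100.0 * counts.get(r, 0) / n for r in REGIONS]
        rows.append((vtype, size, *pct, n))
    return pd.DataFrame(rows, columns=["vtype", "size_class", *REGIONS, "n"])
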