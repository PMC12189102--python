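"""Breakpoint-density hotspot detection in non-overlapping 100 kb bins.

A deletion contributes two breakpoints (one at each junction with the
reference — start bin and end bin, which may coincide); an insertion
contributes one (its anchor).  Bins whose breakpoint count ranks in the
genome-wide top 1% are hotspots; ties at the threshold count are included
so the result is independent of bin insertion order.  Partial terminal
bins are retained and counts are not length-normalised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenomeLayout, IntervalTrack, VariantTable

DEFAULT_BIN = 100_000


@dataclass
class BinCounts:
    """Per-bin breakpoint counts; bins tile each chromosome without overlap."""

    df: pd.DataFrame  # chrom, bin_index, start, end, count
    bin_size: int
    total_breakpoints: int


@dataclass
class HotspotSet:
    """Bins at or above the top-fraction count threshold."""

    bins: pd.DataFrame  # chrom, bin_index, start, end, count
    threshold_count: int
    member_variants: dict[tuple[str, int], list[str]]

    def __len__(self) -> int:
        return len(self.bins)

    def track(self) -> IntervalTrack:
        df = self.bins[["chrom", "start", "end"]].copy()
        df["label"] = "hotspot"
        df["sublabel"] = self.bins["count"].astype(str).to_numpy()
        return IntervalTrack(df, name="hotspots")


def n_bins(layout: GenomeLayout, bin_size: int = DEFAULT_BIN) -> dict[str, int]:
    return {c: -(-layout.chrom_lengths[c] // bin_size) for c in layout.chrom_names}


def count_breakpoints(table: VariantTable, layout: GenomeLayout,
                      bin_size: int = DEFAULT_BIN) -> BinCounts:
    """Bin every INS/DEL breakpoint into non-overlapping ``bin_size`` bins."""
    per_chrom = n_bins(layout, bin_size)
    frames = []
    offset = {}
    total_bins = 0
    for chrom in layout.chrom_names:
        offset[chrom] = total_bins
        total_bins += per_chrom[chrom]
    counts = np.zeros(total_bins, dtype=np.int64)
    members: dict[int, list[str]] = {}

    sub = table.df[table.df["vtype"].isin(["INS", "DEL"])]
    total_bp = 0
    for row in sub.itertuples(index=False):
        chrom_len = layout.chrom_lengths.get(row.chrom)
        if chrom_len is None:
            raise ValueError(f"variant chromosome {row.chrom} not in layout")
        if row.end > chrom_len or row.start < 0:
            raise ValueError(f"variant {row.id} outside chromosome {row.chrom}")
        if row.vtype == "DEL":
            # two junctions: start and end (end-1 to stay inside the chromosome)
            points = (row.start, max(row.end - 1, row.start))
        else:
            points = (min(row.start, chrom_len - 1),)
        for p in points:
            gbin = offset[row.chrom] + p // bin_size
            counts[gbin] += 1
            members.setdefault(gbin, []).append(row.id)
        total_bp += len(points)

    rows = []
    for chrom in layout.chrom_names:
        nb = per_chrom[chrom]
        clen = layout.chrom_lengths[chrom]
        for b in range(nb):
            rows.append((chrom, b, b * bin_size, min((b + 1) * bin_size, clen),
                         counts[offset[chrom] + b]))
    df = pd.DataFrame(rows, columns=["chrom", "bin_index", "start", "end", "count"])
    bc = BinCounts(df, bin_size, total_bp)
    # stash per-(chrom, bin_index) member lists
    flat_members: dict[tuple[str, int], list[str]] = {}
    for g, ids in members.items():
        # invert global bin index
        for chrom in layout.chrom_names:
            if g < offset[chrom] + per_chrom[chrom]:
                flat_members[(chrom, g - offset[chrom])] = ids
                break
    bc.df.attrs["members"] = flat_members
    return bc


def call_hotspots(bins: BinCounts, top_frac: float = 0.01) -> HotspotSet:
    """Bins whose count reaches the k-th ranked count, k = max(1, floor(top_frac * N))."""
    df = bins.df
    if len(df) == 0:
        raise ValueError("no bins")
    counts = df["count"].to_numpy()
    if counts.max() == 0:
        import warnings

        warnings.warn("all bin counts are zero; no hotspots")
        empty = df.iloc[0:0]
        return HotspotSet(empty, threshold_count=1, member_variants={})
    k = max(1, int(np.floor(top_frac * len(df))))
    threshold = int(np.sort(counts)[::-1][k - 1])
    sel = df[df["count"] >= threshold].reset_index(drop=True)
    members = bins.df.attrs.get("members", {})
    mv = {(r.chrom, r.bin_index): members.get((r.chrom, r.bin_index), [])
          for r in sel.itertuples(index=False)}
    return HotspotSet(sel, threshold_count=threshold, member_variants=mv)


def hotspot_qtl_overlap(hotspots: HotspotSet, qtl: IntervalTrack) -> pd.DataFrame:
    """Per-trait-category overlap: hotspots touching >=1 QTL, distinct QTLs hit.

    Overlap means >= 1 shared bp between the hotspot bin span and the QTL
    interval (half-open, so adjacency does not count).  A QTL is counted
    once per category even when hit by several hotspots; unlabelled QTLs
    are grouped under "Unassigned".
    """
    qdf = qtl.df.copy()
    qdf.loc[qdf["label"] == "", "label"] = "Unassigned"
    hs = hotspots.bins
    rows = []
    for cat, grp in qdf.groupby("label", sort=True):
        hit_hotspots = set()
        hit_qtls = 0
        by_chrom = {c: (g["start"].to_numpy(), g["end"].to_numpy())
                    for c, g in hs.groupby("chrom", sort=False)}
        for q in grp.itertuples(index=False):
            if q.chrom not in by_chrom:
                continue
            s, e = by_chrom[q.chrom]
            ov = (s < q.end) & (e > q.start)
            if ov.any():
                hit_qtls += 1
                for i in np.flatnonzero(ov):
                    hit_hotspots.add((q.chrom, int(s[i])))
        rows.append((cat, len(hit_hotspots), hit_qtls, len(grp)))
    return pd.DataFrame(rows, columns=["trait_category", "n_hotspots_overlapping",
                                       "n_qtls_hit", "n_qtls_total"])
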