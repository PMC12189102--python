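"""Transposable-element and simple-repeat content of insertions and deletions.

A variant is TE-driven when annotated repeat bases cover strictly more
than 80% of its length.  Coverage uses union (merged-interval) semantics:
overlapping repeat hits never double-count a base.  Deletions are measured
on their reference span against the reference repeat annotation;
insertions are measured on the inserted sequence's own coordinates against
a parallel annotation of the ALT sequences (query name = variant id) —
when that file is absent, insertions are skipped with a tally.

Only Medium and Large variants are considered: repeat elements are longer
than 10 bp, so Small variants cannot carry one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _intervals
from .io_formats import IntervalTrack, VariantTable

SIMPLE_CLASSES = {"Simple_repeat", "Low_complexity"}
DEFAULT_MIN_FRACTION = 0.8  # strictly-greater-than threshold

_UNIT_RE = re.compile(r"^\(([ACGTNacgtn]+)\)n$")


@dataclass
class RepeatCall:
    """Repeat content of one variant."""

    variant_id: str
    te_fraction: float            # merged repeat bases / variant length
    driver_class: str             # class/family of the longest contributor, or "none"
    driver_name: str
    is_te_driven: bool            # te_fraction > threshold, non-simple driver
    is_simple_repeat: bool        # fraction > threshold, simple-repeat driver
    unit_length: int | None       # for simple repeats, parsed from "(AT)n"-style names
    contributors: list[tuple[str, str, int]]  # (class, name, bases)


def parse_unit_length(name: str) -> int | None:
    """Repeat unit length from a simple-repeat name like ``(TG)n`` -> 2."""
    m = _UNIT_RE.match(name)
    return len(m.group(1)) if m else None


def te_fraction(start: int, end: int, length: int,
                rep_starts: np.ndarray, rep_ends: np.ndarray,
                rep_classes: np.ndarray, rep_names: np.ndarray
                ) -> tuple[float, list[tuple[str, str, int]]]:
    """Fraction of a span covered by repeats, with per-element contributions.

    The fraction uses the union of all repeat intervals clipped to the
    span, divided by ``length``; per-element contributions are each
    element's own clipped overlap (these may sum to more than the union).
    """
    if length < 1:
        raise ValueError("variant length must be >= 1")
    if len(rep_starts) == 0:
        return 0.0, []
    clip_s = np.maximum(rep_starts, start)
    clip_e = np.minimum(rep_ends, end)
    ov = clip_e - clip_s
    hit = ov > 0
    if not hit.any():
        return 0.0, []
    union = _intervals.total_intersection(
        np.array([start]), np.array([end]), rep_starts[hit], rep_ends[hit])
    contributors = [(str(rep_classes[i]), str(rep_names[i]), int(ov[i]))
                    for i in np.flatnonzero(hit)]
    return union / length, contributors


def classify_driver(contributors: list[tuple[str, str, int]]) -> tuple[str, str]:
    """(class, name) of the element contributing the most bases.

    Contributions of the same (class, name) are summed; ties break
    lexicographically on (class, name) for determinism.
    """
    if not contributors:
        return "none", ""
    agg: dict[tuple[str, str], int] = {}
    for cls, nm, bases in contributors:
        agg[(cls, nm)] = agg.get((cls, nm), 0) + bases
    best = min(agg.items(), key=lambda kv: (-kv[1], kv[0]))
    return best[0][0], best[0][1]


def annotate_repeats(table: VariantTable, ref_repeats: IntervalTrack,
                     alt_repeats: IntervalTrack | None = None,
                     min_fraction: float = DEFAULT_MIN_FRACTION
                     ) -> tuple[list[RepeatCall], dict]:
    """Repeat-content calls for every Medium/Large INS and DEL.

    Simple-repeat membership and TE membership are mutually exclusive,
    resolved by which category contributes more merged bases.  Returns the
    calls plus a tally of skipped records (Small variants, SNPs, and INS
    without ALT-sequence annotation).
    """
    ref_by_chrom = {
        c: (grp["start"].to_numpy(), grp["end"].to_numpy(),
            grp["label"].to_numpy(), grp["sublabel"].to_numpy())
        for c, grp in ref_repeats.df.groupby("chrom", sort=False)}
    alt_by_id = {}
    if alt_repeats is not None:
        alt_by_id = {
            c: (grp["start"].to_numpy(), grp["end"].to_numpy(),
                grp["label"].to_numpy(), grp["sublabel"].to_numpy())
            for c, grp in alt_repeats.df.groupby("chrom", sort=False)}

    calls: list[RepeatCall] = []
    tally = {"small_excluded": 0, "snp_excluded": 0, "ins_unannotated": 0}
    if "size_class" not in table.df.columns:
        from .variant_qc import add_size_class

        add_size_class(table)
    for row in table.df.itertuples(index=False):
        if row.vtype == "SNP":
            tally["snp_excluded"] += 1
            continue
        if row.size_class == "Small":
            tally["small_excluded"] += 1
            continue
        if row.vtype == "DEL":
            reps = ref_by_chrom.get(row.chrom)
            span = (row.start, row.end)
        else:
            if alt_repeats is None:
                tally["ins_unannotated"] += 1
                continue
            reps = alt_by_id.get(row.id)
            span = (0, row.length)
        if reps is None:
            frac, contrib = 0.0, []
        else:
            frac, contrib = te_fraction(span[0], span[1], row.length, *reps)
        simple_bases = sum(b for c, _, b in contrib if c in SIMPLE_CLASSES)
        te_bases = sum(b for c, _, b in contrib if c not in SIMPLE_CLASSES)
        simple_wins = simple_bases > te_bases
        pool = [t for t in contrib
                if (t[0] in SIMPLE_CLASSES) == simple_wins] or contrib
        cls, nm = classify_driver(pool)
        driven = frac > min_fraction
        is_simple = driven and simple_wins
        is_te = driven and not simple_wins and bool(contrib)
        calls.append(RepeatCall(
            variant_id=row.id, te_fraction=frac, driver_class=cls,
            driver_name=nm, is_te_driven=is_te, is_simple_repeat=is_simple,
            unit_length=parse_unit_length(nm) if is_simple else None,
            contributors=contrib))
    return calls, tally


def calls_frame(calls: list[RepeatCall], table: VariantTable) -> pd.DataFrame:
    meta = table.df.set_index("id")
    rows = []
    for c in calls:
        rows.append((c.variant_id, meta.at[c.variant_id, "vtype"],
                     meta.at[c.variant_id, "size_class"],
                     int(meta.at[c.variant_id, "length"]), c.te_fraction,
                     c.driver_class, c.driver_name, c.is_te_driven,
                     c.is_simple_repeat, c.unit_length))
    return pd.DataFrame(rows, columns=[
        "id", "vtype", "size_class", "length", "te_fraction", "driver_class",
        "driver_name", "is_te_driven", "is_simple_repeat", "unit_length"])


def simple_repeat_spectrum(calls: list[RepeatCall], table: VariantTable
                           ) -> tuple[pd.DataFrame, int]:
    """Counts per (unit_length 1-10 x vtype x size class) among simple repeats.

    Returns the table and the tally of simple-repeat calls whose name could
    not be parsed into a unit length.
    """
    df = calls_frame(calls, table)
    sr = df[df["is_simple_repeat"]]
    unparsed = int(sr["unit_length"].isna().sum())
    sr = sr.dropna(subset=["unit_length"])
    sr = sr[(sr["unit_length"] >= 1) & (sr["unit_length"] <= 10)]
    spectrum = (sr.groupby(["unit_length", "vtype", "size_class"])
                  .size().rename("count").reset_index())
    spectrum["unit_length"] = spectrum["unit_length"].astype(int)
    return spectrum, unparsed


def te_length_profile(calls: list[RepeatCall], table: VariantTable,
                      bin_width: int = 10) -> pd.DataFrame:
    """Histogram of TE-driven variant lengths per driver class."""
    df = calls_frame(calls, table)
    te = df[df["is_te_driven"]]
    rows = []
    for cls, grp in te.groupby("driver_class"):
        lengths = grp["length"].to_numpy()
        lo = (lengths.min() // bin_width) * bin_width
        hi = ((lengths.max() // bin_width) + 1) * bin_width
        edges = np.arange(lo, hi + bin_width, bin_width)
        counts, _ = np.histogram(lengths, bins=edges)
        for i, c in enumerate(counts):
            if c:
                rows.append((cls, int(edges[i]), int(edges[i + 1]), int(c)))
    return pd.DataFrame(rows, columns=["driver_class", "length_bin_start",
                                       "length_bin_end", "count"])
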