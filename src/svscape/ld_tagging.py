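"""LD between indels/SVs and SNPs, and tissue-resolved e/sQTL tagging.

r² is the squared Pearson correlation of unphased genotype dosages over
jointly non-missing samples (composite LD — the default for unphased
data).  Variants are categorised by their best in-window r² against
e/sQTL-flagged SNPs: high (r² >= 0.8), medium (0.2 <= r² < 0.8),
low (r² < 0.2); boundaries exactly as printed, left-closed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING, IntervalTrack, VariantTable

DEFAULT_WINDOW = 1_000_000
HIGH_R2 = 0.8
LOW_R2 = 0.2
TIE_TOL = 1e-9


def ld_category(r2: float) -> str:
    """high (r2 >= 0.8), medium (0.2 <= r2 < 0.8) or low (r2 < 0.2)."""
    if r2 >= HIGH_R2:
        return "high"
    if r2 >= LOW_R2:
        return "medium"
    return "low"


def dosage_r2(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (missing = -1 excluded).

    NaN when fewer than two jointly non-missing samples remain or either
    site is monomorphic among them.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    if len(a) < 2:
        return float("nan")
    va = a.var()
    vb = b.var()
    if va == 0 or vb == 0:
        return float("nan")
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(cov * cov / (va * vb))


@dataclass
class TagCall:
    """Best e/sQTL SNP tag for one variant."""

    variant_id: str
    best_snp: str
    max_r2: float
    category: str
    qtl_kinds: list[str]          # eQTL / sQTL kinds achieving max r2
    tissues: list[str]            # union of tissues over best SNPs (ties within tol)
    n_snps_tested: int


def _qtl_snp_table(snps: VariantTable, qtl_track: IntervalTrack) -> pd.DataFrame:
    """Join e/sQTL labels onto SNPs by position.

    ``qtl_track`` rows mark single-SNP positions with label = kind
    ("eQTL"/"sQTL") and sublabel = tissue; a SNP may carry several rows.
    """
    tagmap: dict[tuple[str, int], list[tuple[str, str]]] = {}
    for r in qtl_track.df.itertuples(index=False):
        for p in range(r.start, r.end):
            tagmap.setdefault((r.chrom, p), []).append((r.label, r.sublabel))
    rows = []
    for i, r in enumerate(snps.df.itertuples(index=False)):
        tags = tagmap.get((r.chrom, r.start))
        if tags:
            rows.append((i, r.id, r.chrom, r.start, tags))
    return pd.DataFrame(rows, columns=["row", "id", "chrom", "start", "tags"])


def tag_variants(variants: VariantTable, snps: VariantTable,
                 qtl_snp_track: IntervalTrack, window: int = DEFAULT_WINDOW
                 ) -> tuple[list[TagCall], int]:
    """Best-SNP LD tag per variant against e/sQTL SNPs within ±window/2...

    The window is centred on the variant anchor and extends ``window`` bp
    to each side.  Variants with no in-window e/sQTL SNP are excluded and
    tallied.  Ties in max r² (within 1e-9) contribute the union of their
    kinds and tissues.
    """
    qtl_snps = _qtl_snp_table(snps, qtl_snp_track)
    calls: list[TagCall] = []
    skipped = 0
    sample_align = variants.samples == snps.samples
    if not sample_align:
        raise ValueError("variant and SNP tables must share the same samples")
    by_chrom = {c: grp for c, grp in qtl_snps.groupby("chrom", sort=False)}
    for i, v in enumerate(variants.df.itertuples(index=False)):
        grp = by_chrom.get(v.chrom)
        if grp is None:
            skipped += 1
            continue
        center = v.start
        pos = grp["start"].to_numpy()
        sel = np.abs(pos - center) <= window
        if not sel.any():
            skipped += 1
            continue
        cand = grp[sel]
        r2s = np.array([
            dosage_r2(variants.dosages[i], snps.dosages[j])
            for j in cand["row"].to_numpy()])
        if np.all(np.isnan(r2s)):
            skipped += 1
            continue
        best = np.nanmax(r2s)
        winners = np.flatnonzero(np.abs(r2s - best) <= TIE_TOL)
        kinds, tissues = set(), set()
        for w in winners:
            for kind, tissue in cand.iloc[w]["tags"]:
                kinds.add(kind)
                if tissue:
                    tissues.add(tissue)
        calls.append(TagCall(
            variant_id=v.id,
            best_snp=str(cand.iloc[int(winners[0])]["id"]),
            max_r2=float(best), category=ld_category(float(best)),
            qtl_kinds=sorted(kinds), tissues=sorted(tissues),
            n_snps_tested=int(sel.sum())))
    return calls, skipped


def tag_frame(calls: list[TagCall], variants: VariantTable) -> pd.DataFrame:
    if "size_class" not in variants.df.columns:
        from .variant_qc import add_size_class

        add_size_class(variants)
    meta = variants.df.set_index("id")
    rows = []
    for c in calls:
        for kind in c.qtl_kinds:
            for tissue in (c.tissues or [""]):
                rows.append((c.variant_id, meta.at[c.variant_id, "vtype"],
                             meta.at[c.variant_id, "size_class"], c.best_snp,
                             c.max_r2, c.category, kind, tissue))
    return pd.DataFrame(rows, columns=["id", "vtype", "size_class", "best_snp",
                                       "max_r2", "category", "qtl_kind", "tissue"])


def tissue_summary(calls: list[TagCall], variants: VariantTable) -> pd.DataFrame:
    """Counts and within-(tissue, kind) proportions per LD category.

    Proportions sum to 1 over categories within each (tissue, qtl_kind,
    size_class) cell group.
    """
    df = tag_frame(calls, variants)
    if len(df) == 0:
        return pd.DataFrame(columns=["tissue", "qtl_kind", "size_class",
                                     "category", "count", "proportion"])
    counts = (df.groupby(["tissue", "qtl_kind", "size_class", "category"])
                .size().rename("count").reset_index())
    totals = counts.groupby(["tissue", "qtl_kind", "size_class"])["count"].transform("sum")
    counts["proportion"] = counts["count"] / totals
    return counts
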