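"""Pairwise population differentiation (Fst) scans.

Two estimators, both authored here and named in output metadata:

* Weir & Cockerham (1984) two-level variance components (a: among
  populations, b: among individuals within populations, c: within
  individuals) for diploid genotype data, per site; the estimator
  VCFtools' ``--weir-fst-pop`` computes.  Per-site Fst = a/(a+b+c); the
  windowed ("weighted") value is the ratio of sums.
* Hudson/Bhatia frequency-only estimator for SV-scale variants whose
  genotype-level annotations are unreliable:
  num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1),
  den = p1(1-p2) + p2(1-p1), with n in chromosomes.

Small/Medium variants are aggregated in 50 kb windows stepping 20 kb
(windows anchored at position 0, partial terminal windows kept); Large
variants are ranked per site.  The top 1% of ranked units (genome-wide,
ties at the threshold included) are candidate selection regions.
Negative per-site estimates are retained, not clamped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenomeLayout, VariantTable

WINDOW = 50_000
STEP = 20_000


# ---------------------------------------------------------------------------
# per-site estimators
# ---------------------------------------------------------------------------

def wc_components(dosages_pop1: np.ndarray, dosages_pop2: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham variance components (a, b, c) per site, r=2 populations.

    ``dosages_pop*``: (n_sites, n_ind) alt-allele dosage matrices with -1
    for missing; missing genotypes are excluded from sample sizes, allele
    frequencies and observed heterozygosity.  Sites with fewer than two
    non-missing diploids in either population get NaN components.
    """
    d1 = np.atleast_2d(np.asarray(dosages_pop1))
    d2 = np.atleast_2d(np.asarray(dosages_pop2))
    r = 2.0
    comps = []
    for d in (d1, d2):
        valid = d != MISSING
        n = valid.sum(axis=1).astype(float)                 # diploids
        ac = np.where(valid, d, 0).sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = ac / (2 * n)
        h = np.where(valid, d == 1, False).sum(axis=1) / np.maximum(n, 1)
        comps.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = comps
    ok = (n1 >= 2) & (n2 >= 2)

    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)

    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    bad = ~ok
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def wc_fst_site(dosages_pop1: np.ndarray, dosages_pop2: np.ndarray) -> pd.DataFrame:
    """Per-site Weir-Cockerham Fst with components.

    Fst = a/(a+b+c); NaN (flagged ``undefined``) when the denominator is
    zero — e.g. a site monomorphic in both populations.
    """
    a, b, c = wc_components(dosages_pop1, dosages_pop2)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(denom != 0, a / denom, np.nan)
    fst = np.where(np.isnan(denom), np.nan, fst)
    return pd.DataFrame({
        "a": a, "b": b, "c": c, "fst": fst,
        "undefined": np.isnan(fst),
    })


def hudson_fst_freq(p1, n1_chrom, p2, n2_chrom):
    """Hudson/Bhatia Fst from allele frequencies and chromosome counts.

    Vectorised; returns NaN where the denominator is zero (both
    populations fixed for the same allele) or a chromosome count is < 2.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1_chrom, dtype=float)
    n2 = np.asarray(n2_chrom, dtype=float)
    if np.any((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        out = np.where((den != 0) & (n1 >= 2) & (n2 >= 2), num / den, np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def wc_fst_overall(dosages_pop1: np.ndarray, dosages_pop2: np.ndarray) -> float:
    """Genome-wide Weir-Cockerham Fst: ratio of summed variance components.

    The ratio-of-sums aggregate is preferred over averaging per-site ratios,
    whose expectation is biased low when differentiation is appreciable.
    """
    a, b, c = wc_components(dosages_pop1, dosages_pop2)
    denom = np.nansum(a + b + c)
    return float(np.nansum(a) / denom) if denom != 0 else float("nan")


def hudson_fst_overall(p1, n1_chrom, p2, n2_chrom) -> float:
    """Genome-wide Hudson/Bhatia Fst: ratio of averaged numerator/denominator."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1_chrom, dtype=float)
    n2 = np.asarray(n2_chrom, dtype=float)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = np.isfinite(num) & np.isfinite(den)
    total = den[ok].sum()
    return float(num[ok].sum() / total) if total != 0 else float("nan")


# ---------------------------------------------------------------------------
# cohort-level scan
# ---------------------------------------------------------------------------

def pop_dosages(table: VariantTable, pop_map: dict[str, str]) -> dict[str, np.ndarray]:
    """Split the dosage matrix by population."""
    pops = np.array([pop_map[s] for s in table.samples])
    return {p: table.dosages[:, pops == p] for p in sorted(set(pops))}


def fst_sites(table: VariantTable, pop_map: dict[str, str],
              pair: tuple[str, str]) -> pd.DataFrame:
    """Per-variant Weir-Cockerham Fst for one breed pair, joined to coordinates."""
    split = pop_dosages(table, pop_map)
    for p in pair:
        if p not in split:
            raise ValueError(f"population {p} not in population map")
    res = wc_fst_site(split[pair[0]], split[pair[1]])
    res.insert(0, "id", table.df["id"].to_numpy())
    res.insert(1, "chrom", table.df["chrom"].to_numpy())
    res.insert(2, "pos", table.df["pos"].to_numpy())
    res.insert(3, "start", table.df["start"].to_numpy())
    return res


def windowed_fst(sites: pd.DataFrame, window: int = WINDOW, step: int = STEP
                 ) -> pd.DataFrame:
    """Sliding-window aggregation of per-site components.

    ``fst_weighted`` = sum(a)/sum(a+b+c) over usable sites in the window
    (the ratio-of-sums VCFtools calls "weighted"); ``fst_mean`` is the mean
    of per-site ratios.  Windows with no usable site are omitted.
    """
    rows = []
    usable = sites[~sites["undefined"]]
    for chrom, grp in usable.groupby("chrom", sort=False):
        pos = grp["start"].to_numpy()
        if len(pos) == 0:
            continue
        a = grp["a"].to_numpy()
        abc = a + grp["b"].to_numpy() + grp["c"].to_numpy()
        ratio = grp["fst"].to_numpy()
        last = pos.max()
        w = 0
        start = 0
        while start <= last:
            end = start + window
            sel = (pos >= start) & (pos < end)
            n = int(sel.sum())
            if n:
                denom = abc[sel].sum()
                fw = a[sel].sum() / denom if denom != 0 else np.nan
                rows.append((chrom, start, end, n, fw, ratio[sel].mean()))
            start += step
            w += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites",
                                       "fst_weighted", "fst_mean"])


def top_selection_regions(ranked: pd.DataFrame, value_col: str,
                          top_frac: float = 0.01) -> pd.DataFrame:
    """Top-fraction units by ``value_col``; k = max(1, floor(top_frac*N)), ties kept."""
    usable = ranked.dropna(subset=[value_col])
    if len(usable) == 0:
        raise ValueError("no ranked units with a defined statistic")
    vals = usable[value_col].to_numpy()
    k = max(1, int(np.floor(top_frac * len(usable))))
    threshold = np.sort(vals)[::-1][k - 1]
    return usable[usable[value_col] >= threshold].reset_index(drop=True)


def genes_in_regions(regions: pd.DataFrame, genes) -> list[str]:
    """Gene ids overlapping (>=1 bp) any region; regions need chrom/start/end."""
    gdf = genes.genes if hasattr(genes, "genes") else genes
    hits = set()
    for chrom, grp in regions.groupby("chrom", sort=False):
        sub = gdf[gdf["chrom"] == chrom]
        if not len(sub):
            continue
        gs = sub["start"].to_numpy()
        ge = sub["end"].to_numpy()
        gid = sub["gene_id"].to_numpy()
        for r in grp.itertuples(index=False):
            s = r.start
            e = r.end if r.end > r.start else r.start + 1
            hit = (gs < e) & (ge > s)
            hits.update(gid[hit])
    return sorted(hits)


def shared_genes(per_pair_genes: dict[tuple[str, str], list[str]]) -> pd.DataFrame:
    """Genes appearing in the top regions of more than one breed pair."""
    seen: dict[str, list[str]] = {}
    for pair, genes in per_pair_genes.items():
        tag = f"{pair[0]}__vs__{pair[1]}"
        for g in genes:
            seen.setdefault(g, []).append(tag)
    rows = [(g, len(pairs), ";".join(sorted(pairs)))
            for g, pairs in sorted(seen.items()) if len(pairs) > 1]
    return pd.DataFrame(rows, columns=["gene_id", "n_pairs", "pairs"])


def fst_scan(table: VariantTable, pop_map: dict[str, str],
             pair: tuple[str, str], layout: GenomeLayout | None = None,
             window: int = WINDOW, step: int = STEP, top_frac: float = 0.01,
             genes=None) -> dict:
    """Full differentiation scan for one breed pair, stratified by size class.

    Small/Medium indels: per-site WC Fst aggregated in sliding windows,
    top windows by ``fst_weighted``.  Large variants: Hudson Fst from
    per-population SV frequencies, top sites.  Returns a dict of frames
    keyed ``windows_small``, ``windows_medium``, ``top_small`` ... plus
    ``genes`` per stratum when gene models are supplied.
    """
    from .variant_qc import add_size_class

    if "size_class" not in table.df.columns:
        add_size_class(table)
    out: dict[str, object] = {"pair": pair, "estimators": {
        "small": "weir_cockerham_1984", "medium": "weir_cockerham_1984",
        "large": "hudson_bhatia_freq"}}
    for size in ("Small", "Medium"):
        sub = table.where(vtype=("INS", "DEL"), size_class=size)
        key = size.lower()
        if len(sub) == 0:
            continue
        sites = fst_sites(sub, pop_map, pair)
        wins = windowed_fst(sites, window=window, step=step)
        out[f"sites_{key}"] = sites
        out[f"windows_{key}"] = wins
        if len(wins):
            top = top_selection_regions(wins, "fst_weighted", top_frac)
            out[f"top_{key}"] = top
            if genes is not None:
                out[f"genes_{key}"] = genes_in_regions(top, genes)
    large = table.where(vtype=("INS", "DEL"), size_class="Large")
    if len(large):
        split = pop_dosages(large, pop_map)
        freqs = {}
        for p in pair:
            d = split[p]
            valid = d != MISSING
            nc = 2 * valid.sum(axis=1)
            ac = np.where(valid, d, 0).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                freqs[p] = (ac / np.maximum(nc, 1), nc)
        fst = hudson_fst_freq(freqs[pair[0]][0], freqs[pair[0]][1],
                              freqs[pair[1]][0], freqs[pair[1]][1])
        sites = pd.DataFrame({
            "id": large.df["id"].to_numpy(), "chrom": large.df["chrom"].to_numpy(),
            "start": large.df["start"].to_numpy(), "end": large.df["end"].to_numpy(),
            "fst": np.atleast_1d(fst)})
        out["sites_large"] = sites
        top = top_selection_regions(sites, "fst", top_frac)
        out["top_large"] = top
        if genes is not None:
            out["genes_large"] = genes_in_regions(top, genes)
    return out
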