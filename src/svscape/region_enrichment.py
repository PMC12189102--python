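"""Permutation Z-score tests for overlap between variants and genomic tracks.

The null model re-places each query element independently and uniformly at
random on its original chromosome, preserving its length (the classic
random-regions null).  With ``n_perm`` draws the Z-score is
``(observed - perm_mean) / perm_sd`` and the empirical p-value uses the
(1 + hits)/(n_perm + 1) correction, one-sided in the direction of
departure.  Positive Z means enrichment, negative depletion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _intervals
from .io_formats import GenomeLayout, IntervalTrack, VariantTable


@dataclass
class PermResult:
    """Observed overlap statistic versus its permutation distribution."""

    statistic: str           # "n_overlaps" or "bp_overlap"
    observed: float
    perm_values: np.ndarray
    n_perm: int
    seed: int | None
    degenerate: bool
    perm_mean: float
    perm_sd: float
    z: float                 # NaN when degenerate
    p_empirical: float
    direction: str           # "enrichment" or "depletion"


def _query_arrays(query) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (starts, ends) for an IntervalTrack or VariantTable.

    Variant spans follow the internal convention: deletions cover their
    reference span, insertions are zero-length anchors.
    """
    if isinstance(query, VariantTable):
        out = {}
        for chrom, grp in query.df.groupby("chrom", sort=False):
            out[str(chrom)] = (grp["start"].to_numpy(), grp["end"].to_numpy())
        return out
    return query.by_chrom()


def overlap_stat(query, reference: IntervalTrack, mode: str = "count") -> float:
    """Observed overlap between query elements and a reference track.

    mode="count": number of query elements sharing >=1 bp with the (merged)
    reference; a zero-length insertion anchor counts iff the point lies in
    an interval.  mode="bp": total overlapping bases after merging both sides.
    """
    if mode not in ("count", "bp"):
        raise ValueError("mode must be 'count' or 'bp'")
    ref = {c: _intervals.merge(s, e) for c, (s, e) in reference.by_chrom().items()}
    total = 0
    for chrom, (qs, qe) in _query_arrays(query).items():
        if chrom not in ref:
            continue
        ms, me = ref[chrom]
        if mode == "count":
            total += int(_intervals.overlap_mask(qs, qe, ms, me).sum())
        else:
            s, e = _intervals.merge(qs, qe)
            total += int(_intervals.covered_bases(s, e, ms, me).sum())
    return float(total)


def randomize_track(query, layout: GenomeLayout, mask: IntervalTrack | None = None,
                    rng: np.random.Generator | None = None,
                    seed: int | None = None) -> IntervalTrack:
    """Re-place each query element uniformly at random on its own chromosome.

    Lengths are preserved, placements may overlap each other, and masked
    regions are avoided (an element is never placed overlapping the mask).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    mask_by_chrom = {}
    if mask is not None:
        mask_by_chrom = {c: _intervals.merge(s, e) for c, (s, e) in mask.by_chrom().items()}
    records = []
    for chrom, (qs, qe) in sorted(_query_arrays(query).items()):
        clen = layout.chrom_lengths[chrom]
        lengths = qe - qs
        if chrom not in mask_by_chrom:
            space = clen - np.maximum(lengths, 1)  # anchors occupy one slot
            if (space < 0).any():
                raise ValueError(f"element longer than chromosome {chrom}")
            starts = (rng.random(len(lengths)) * (space + 1)).astype(np.int64)
            records.extend(zip([chrom] * len(lengths), starts.tolist(),
                               (starts + lengths).tolist()))
        else:
            ms, me = mask_by_chrom[chrom]
            # allowed gaps between masked blocks
            gap_s = np.concatenate([[0], me])
            gap_e = np.concatenate([ms, [clen]])
            for ln in lengths:
                # number of valid start positions per unmasked gap
                slots = (gap_e - gap_s - ln + 1).clip(min=0)
                if slots.sum() <= 0:
                    raise ValueError(
                        f"element of length {ln} cannot be placed on masked {chrom}")
                g = rng.choice(len(slots), p=slots / slots.sum())
                start = int(rng.integers(gap_s[g], gap_e[g] - ln + 1))
                records.append((chrom, start, start + ln))
    # zero-length anchors are invalid IntervalTrack rows; widen to 1 bp points
    records = [(c, s, max(e, s + 1)) for c, s, e in records]
    return IntervalTrack.from_records(records, name="randomized")


def permutation_z(query, reference: IntervalTrack, layout: GenomeLayout,
                  n_perm: int = 100, mode: str = "count",
                  seed: int | None = None,
                  mask: IntervalTrack | None = None) -> PermResult:
    """Permutation test of query/reference overlap with ``n_perm`` random placements."""
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    rng = np.random.default_rng(seed)
    observed = overlap_stat(query, reference, mode=mode)
    perm = np.empty(n_perm)
    for i in range(n_perm):
        rnd = randomize_track(query, layout, mask=mask, rng=rng)
        perm[i] = overlap_stat(rnd, reference, mode=mode)
    mean = float(perm.mean())
    sd = float(perm.std(ddof=1))
    degenerate = sd == 0.0
    z = float("nan") if degenerate else (observed - mean) / sd
    if observed >= mean:
        direction = "enrichment"
        hits = int((perm >= observed).sum())
    else:
        direction = "depletion"
        hits = int((perm <= observed).sum())
    p = (1 + hits) / (n_perm + 1)
    return PermResult(
        statistic="n_overlaps" if mode == "count" else "bp_overlap",
        observed=observed, perm_values=perm, n_perm=n_perm, seed=seed,
        degenerate=degenerate, perm_mean=mean, perm_sd=sd, z=z,
        p_empirical=p, direction=direction)


def enrichment_by_group(table: VariantTable, reference: IntervalTrack,
                        layout: GenomeLayout, n_perm: int = 100,
                        mode: str = "count", seed: int | None = None,
                        group_reference_by_label: bool = True) -> "pd.DataFrame":
    """One permutation test per (vtype x size class x reference label).

    Returns a tidy table with observed, permutation mean/sd, z and p per cell.
    """
    import pandas as pd

    seed_seq = np.random.SeedSequence(seed)
    labels = reference.labels() if group_reference_by_label else [None]
    rows = []
    groups = table.df.groupby(["vtype", "size_class"], sort=True).groups \
        if "size_class" in table.df.columns else {("all", "all"): table.df.index}
    for (vtype, size), idx in groups.items():
        if vtype == "SNP":
            continue
        sub = table.subset(np.asarray(idx))
        for label in labels:
            ref = reference if label is None else reference.subset(
                reference.df["label"] == label)
            if len(ref) == 0 or len(sub) == 0:
                continue
            child_seed = int(seed_seq.spawn(1)[0].generate_state(1)[0] % (2**31))
            res = permutation_z(sub, ref, layout, n_perm=n_perm, mode=mode,
                                seed=child_seed)
            rows.append((vtype, size, label if label is not None else "all",
                         res.observed, res.perm_mean, res.perm_sd, res.z,
                         res.p_empirical, res.direction, len(sub)))
    return pd.DataFrame(rows, columns=[
        "vtype", "size_class", "label", "observed", "perm_mean", "perm_sd",
        "z", "p_empirical", "direction", "n_query"])
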