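"""Independent brute-force oracles used to validate the library.

Everything here is deliberately written as direct, scalar, loop-based
transcriptions of the underlying definitions — separate code paths from
the vectorised implementations under test.
"""

from __future__ import annotations

from itertools import combinations


# --- Weir & Cockerham (1984), two populations, one site -------------------

def wc84_components(geno1: list[int], geno2: list[int]):
    """Direct transcription of the WC84 a/b/c components for diploid genotypes."""
    r = 2
    n1, n2 = len(geno1), len(geno2)
    p1 = sum(geno1) / (2 * n1)
    p2 = sum(geno2) / (2 * n2)
    h1 = sum(1 for g in geno1 if g == 1) / n1
    h2 = sum(1 for g in geno2 if g == 1) / n2
    nbar = (n1 + n2) / r
    nc = (n1 + n2 - (n1 * n1 + n2 * n2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4))
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar)
    c = hbar / 2
    return a, b, c


def hudson_fst(p1: float, n1: int, p2: float, n2: int) -> float:
    """Direct evaluation of the Hudson/Bhatia frequency estimator."""
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num / den


# --- greedy proximity dedup via exhaustive subset enumeration --------------

def dedup_exhaustive(indels: list[tuple[int, float, str]], d: int = 10) -> set[int]:
    """Survivor indices by enumerating every conflict-free subset.

    ``indels``: (pos, qual, vtype) per record.  Among all subsets in which
    no two members' positions are within d bp, the winner is the one that
    is first in priority order: iterate candidates sorted by (QUAL desc,
    pos asc, DEL before INS) and prefer subsets containing each successive
    candidate.  This is an independent definition of the greedy outcome.
    """
    n = len(indels)
    rank = {"DEL": 0, "INS": 1}
    priority = sorted(range(n), key=lambda i: (-indels[i][1], indels[i][0],
                                               rank[indels[i][2]]))

    def conflict_free(subset):
        return all(abs(indels[i][0] - indels[j][0]) > d
                   for i, j in combinations(subset, 2))

    candidates = [frozenset(s)
                  for k in range(n + 1)
                  for s in combinations(range(n), k)]
    candidates = [s for s in candidates if conflict_free(s)]
    for p in priority:
        with_p = [s for s in candidates if p in s]
        if with_p:
            candidates = with_p
    # exactly one subset survives: every retained element is forced in and
    # every discarded element conflicts with a retained one
    assert len(candidates) == 1
    return set(candidates[0])


# --- per-base region classification ----------------------------------------

REGION_ORDER = ["exonic_splicing", "UTR5", "UTR3", "intronic", "ncRNA",
                "upstream_downstream", "intergenic"]


def base_region(x: int, toy: dict, flank: int = 1000, splice: int = 2) -> str:
    """Region of a single base by direct rule evaluation.

    ``toy`` describes gene models: {"coding": [ {"span": (s,e), "exons": [...],
    "utr5": [...], "utr3": [...]} ], "noncoding": [ (s,e), ... ]}.
    """
    utr5 = any(s <= x < e for g in toy["coding"] for s, e in g["utr5"])
    utr3 = any(s <= x < e for g in toy["coding"] for s, e in g["utr3"])
    exonic = False
    intronic = False
    for g in toy["coding"]:
        exons = sorted(g["exons"])
        in_utr = any(s <= x < e for s, e in g["utr5"] + g["utr3"])
        if any(s <= x < e for s, e in exons) and not in_utr:
            exonic = True
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 <= x < s2:
                intronic = True
                if x < e1 + splice or x >= s2 - splice:
                    exonic = True  # splice window counts as exonic_splicing
    nc = any(s <= x < e for s, e in toy["noncoding"])
    spans = [g["span"] for g in toy["coding"]] + list(toy["noncoding"])
    updown = any((s - flank <= x < s) or (e <= x < e + flank) for s, e in spans)
    if exonic:
        return "exonic_splicing"
    if utr5:
        return "UTR5"
    if utr3:
        return "UTR3"
    if intronic:
        return "intronic"
    if nc:
        return "ncRNA"
    if updown:
        return "upstream_downstream"
    return "intergenic"


def span_region(start: int, end: int, toy: dict, flank: int = 1000) -> str:
    """Highest-precedence per-base label over a span (point for start==end)."""
    labels = {base_region(x, toy, flank=flank)
              for x in range(start, max(end, start + 1))}
    for lab in REGION_ORDER:
        if lab in labels:
            return lab
    return "intergenic"


# --- per-base interval coverage --------------------------------------------

def covered_fraction(start: int, end: int, intervals: list[tuple[int, int]]) -> float:
    """Fraction of [start, end) covered by >=1 interval, counted base by base."""
    length = end - start
    covered = sum(1 for x in range(start, end)
                  if any(s <= x < e for s, e in intervals))
    return covered / length
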