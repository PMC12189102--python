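# Methods

## Coordinate conventions

All internal interval arithmetic is 0-based half-open. VCF positions
(1-based) and RepeatMasker `.out` query coordinates (1-based inclusive)
are converted exactly once at ingest. A deletion's span covers the
deleted bases, excluding the VCF padding base; an insertion is a
zero-length anchor `[pos, pos)` — an inserted sequence occupies no
reference span — and overlaps an interval iff the anchor point lies
inside it. Overlap everywhere means ≥ 1 shared base; adjacency under the
half-open convention is not overlap.

## Size classes and QC

Lengths are |len(REF) − len(ALT)| for sequence-explicit records and
|SVLEN| (or END-derived) for symbolic ones. Small = 1–10 bp,
Medium = 11–50 bp, Large > 50 bp; the class partitions every positive
length. All QC inequalities are strict exactly as printed in the
thresholds table: a missing rate of exactly 0.1 fails the indel path, a
MAF of exactly 0.01 fails the SV path, FS of exactly 200.0 passes.
Hard-filter rules that reference an INFO key absent from a record are
skipped rather than failed, because merged SV records do not carry GATK
annotations. The 10 bp proximity rule is resolved greedily: sort
candidate indels by QUAL descending (ties: position ascending, DEL
before INS), accept the best, discard unaccepted indels whose start is
within 10 bp of an accepted start, repeat. The rule is applied per
chromosome and only to the Small/Medium (indel-calling) path. Note this
is *not* maximum-total-QUAL subset selection — a cluster {100/Q50,
105/Q60, 112/Q40} keeps only the Q60 record even though {Q50, Q40} is
conflict-free with higher total — it is the deterministic closure of the
published pairwise rule, and chains of three or more indels are
otherwise ambiguous.

## Hotspots

A deletion contributes two breakpoints (its two reference junctions,
which may fall in the same bin), an insertion one; the sum of bin counts
is therefore exactly 2·N_DEL + N_INS, which the tests assert on every
fixture. Bins are 100 kb, anchored at 0, partial terminal bins kept,
counts not length-normalised. Hotspots are the genome-wide top 1 %:
k = max(1, ⌊0.01·N_bins⌋), threshold = k-th ranked count, ties at the
threshold included so the call is order-independent. Per-chromosome
ranking is available as an option.

## Permutation enrichment

The null re-places each query element independently and uniformly on its
original chromosome, preserving its length (the random-regions null,
not circular rotation); placements may overlap each other, and an
optional mask excludes regions from placement. With n_perm = 100 the
Z-score is (observed − mean)/sd over permutations and the one-sided
empirical p uses the (1 + hits)/(n_perm + 1) correction, so p is never
zero. Degenerate permutation distributions (sd = 0) are flagged rather
than given a Z. Calibration: when the query itself is drawn from the
null, z over 200 replicates has |mean| ≤ 0.15 and sd within [0.7, 1.3]
(checked in the acceptance suite).

## Repeat content

Coverage uses union (merged-interval) semantics — the conservative
reading of "repeat length as a fraction of variant length" — and a
variant is TE-driven only when the fraction strictly exceeds 0.8. The
driver is the element class contributing the most (possibly
overlapping) bases, ties broken lexicographically. TE and simple-repeat
status are mutually exclusive, resolved by which category contributes
more bases. Deletions are measured on the reference span against the
reference annotation; insertions require a parallel annotation of the
ALT sequences (same `.out` layout, query = variant id) and are skipped
with a tally when it is absent — the package never runs RepeatMasker.
Small variants are excluded by construction: no repeat element fits in
≤ 10 bp.

## Region annotation

Single call per variant with precedence exonic/splice > UTR5 > UTR3 >
intronic > ncRNA > upstream/downstream > intergenic; a span touching
several features takes the highest-precedence touch. Flank 1 kb and
splice window 2 bp into the intron are the ANNOVAR defaults and are
configurable. Coding exons have their UTR portions subtracted; whole
spans of non-protein-coding genes count as ncRNA. The implementation is
validated against a per-base precedence-vote oracle on 200 random toy
gene models.

## Fst estimation

Per-site Weir & Cockerham (1984) two-level variance components for
diploid genotypes (the estimator VCFtools' `--weir-fst-pop` computes),
with missing genotypes excluded from counts and observed-heterozygosity
correction; negative per-site estimates are retained, not clamped.
Windows (50 kb, 20 kb step, anchored at 0, partial last window kept)
report both the ratio-of-sums `fst_weighted = Σa/Σ(a+b+c)` (primary) and
the mean of per-site ratios. Large variants use the Hudson/Bhatia
frequency-only estimator, as SV genotype-level annotations are less
reliable. Genome-wide aggregates are ratio-of-sums (WC) and
ratio-of-averaged-num/den (Hudson): averaging per-site *ratios* is
biased low once differentiation is appreciable (≈ 0.15 recovered at a
generating F of 0.2 under our own study conditions), which is why the
ratio-of-averages forms are the recovery statistics; both recover
F ∈ {0.02, 0.05, 0.2} to within ±0.01 on 5000-locus Balding–Nichols
cohorts. Top-1 % selection regions use the same k/tie rule as hotspots,
ranked genome-wide. All samples are treated as diploid, including X.

## LD tagging

Composite LD: r² is the squared Pearson correlation of unphased dosage
vectors over jointly non-missing samples — the default for unphased
data; on phased haplotype blocks it converges to the classical
D²/(p_A p_a p_B p_b) under random mating (tested). Categories are exactly
the printed half-open scheme: high r² ≥ 0.8, medium 0.2 ≤ r² < 0.8, low
r² < 0.2. The search window is ±1 Mb around the variant anchor
(configurable; no published value exists). Ties in the best r² within
1e-9 contribute the union of their SNPs' kinds and tissues.

## Synthetic cohorts

Balding–Nichols rather than coalescent simulation: it parameterises the
quantity under test (Fst) directly and runs in seconds. Ancestral
p ~ U(0.05, 0.95); per-pop p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F);
genotypes ~ Binomial(2, p_k); one global RNG stream per run, so equal
seeds give byte-identical files. Defaults mirror the five-breed study
design: 5 populations × 20 diploids (≈ 100 animals), background
F = 0.02 (the observed low-differentiation regime), small indels
dominating (80 % of indels, geometric lengths with mean ≈ 2.2 bp), SV
lengths drawn from a TE library whose SINE/Core-RTE (BOV-A2-like)
component is Normal(138, 9) — peaked in the 120–150 bp band — and LINE
components lognormal at kilobase scale; simple-repeat unit mix peaks at
2 bp and decreases to 10 bp; TE-driven fraction 0.44 among Large,
regions mixed ≈ 70 % intergenic / 19 % intronic. Planted structure:

* hotspot bins (1 % of bins, 20× rate multiplier) via relocation of a
  computed fraction q = (m−1)A_hot/(A + (m−1)A_hot) of indel/SV
  placements;
* region classes by sampling positions from precedence-purified feature
  pools, so each planted class is exactly what the classifier reports
  (the classifier itself is validated independently against the
  per-base oracle);
* planted sweeps: a selection locus redraws its per-pop frequencies
  until some pair's frequency divergence reaches the target F
  (`divergent_pop_freqs`). This conditioning is what "planting" must
  mean: an unconditioned Beta draw at F = 0.5 leaves both populations on
  the same side of the ancestral frequency about half the time, i.e. no
  sweep exists at the locus to detect;
* LD tags by copying (high) or 30 %-resampling (medium, r² ≈ 0.5) an
  e/sQTL SNP's dosages into a variant; planted QC failures (one
  hard-filter rule pushed past its bound; SV missingness > 30 %; MAF
  = 1/(2N) < 0.01).

What the generator does **not** emulate: LD decay along chromosomes
(background variants are independent), demographic history, mutation-
spectrum realism, or sequence content (no FASTA). Passing closed-loop
tests therefore demonstrates correct bookkeeping and estimator behaviour
under the stated statistical model, not performance on real read data.
Variant starts are kept > 10 bp apart (and spans disjoint) so planted
truth is not destroyed by the proximity rule or by overlapping repeat
annotations; proximity-rule behaviour itself is tested on dedicated
dense toys. One known interaction: region-mix placement concentrates
variants in small genic pools (a realistic clustering), so
hotspot-recall experiments use gene-free configurations to isolate the
planted breakpoint signal.

## Problem sizes

The default cohort is 7800 variants × 100 samples on a 10 Mb genome —
large enough for every statistic to stabilise, small enough that the
full pipeline runs in about half a minute on one CPU. Calibration
experiments use 5000-locus recovery sweeps, 100 planted-sweep
replicates, and 200-replicate permutation-null calibrations; the same
sizes are used by `scripts/acceptance.py`.

## Known limitations

* Only biallelic records are supported; multiallelic sites error or are
  skipped, splitting is out of the validated path.
* The X chromosome is treated as diploid for all samples.
* Enrichment p-values are reported raw per track label (no
  multiple-testing correction), matching common practice for these
  descriptive scans.
* Insertion repeat content depends entirely on a caller-provided ALT
  annotation; no sequence-level inference is attempted.
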