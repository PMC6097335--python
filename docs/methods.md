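# Methods

This note documents the models, parameter choices and numerical conventions
behind `enhscreen`, in the spirit of a methods supplement: what each stage
assumes, which knobs matter, and what the synthetic data does and does not
emulate.

## Expression normalization and the induction call

TU count tables (rows = strand-specific transcriptional units, columns =
samples with a condition/replicate annotation) pass through three steps.

**Coverage filter.** A TU is *detected* when it carries ≥ `min_reads` (20)
reads in at least one sample, applied to raw counts. The detected set is
the universe for everything downstream — in particular, only detected TUs
enter bidirectional pairing.

**Quantile normalization.** Each column is replaced by the per-rank
across-column means; ties within a column receive the mean of the
normalized values their ranks span (the standard "average" convention —
deterministic, and the only choice that keeps tied inputs tied). Note that
tie-averaging necessarily perturbs the column value multiset, so the
"sorted columns identical" identity holds exactly only for tie-free data;
with integer counts the columns agree up to tie adjustments.

**Fold change.** FC_r = log2(max(I_r, floor) / max(C_r, floor)) with
floor 10, applied to each expression level (never to the ratio), pairing
induced replicate r with control replicate r by index (an all-vs-control-
mean mode is available via `pairing="vs_mean"`). Flooring the levels keeps
fold changes finite and suppresses inflated ratios at low expression.

**Induction call.** A regulatory element is induced iff log2 FC ≥
log2(`min_fold`) (two-fold, inclusive) for *both* mates in *all*
replicates. This conjunction is deliberately strict: with two replicates it
is a four-way AND, which is what gives the near-zero false-positive rate
observed in the null simulations.

## Bidirectional pairing geometry

Opposite-strand TUs pair when their 5′ start sites (start for `+`, end−1
for `-`) are ≤ `max_sep` = 800 bp apart (inclusive). Pairing additionally
requires divergence — the minus-strand TSS at or left of the plus-strand
TSS, so the two TUs transcribe away from each other — because divergent
initiation is the defining eRNA signature; convergent opposite-strand
pairs are rejected (relaxable via `require_divergent=False`). Matching is
one-to-one and greedy by increasing start-site separation, ties broken by
leftmost coordinate, so no TU joins two elements and output order is
deterministic. The scan region of an element is
[min(TSS) − margin, max(TSS) + margin] (margin 200 bp, inclusive outer
base, stored half-open, clipped to chromosome bounds).

## Motif scanning with exact p-values

A PWM stores per-position base probabilities (rows A,C,G,T); a pseudocount
mixes each column with the background, p′ = (p + pc·bg)/(1 + pc) with
pc = 0.01, keeping log-odds finite. Windows score
Σ_i log2(p′[w_i, i]/bg[w_i]) in bits. For p-values, per-position log-odds
are discretized to integer milli-bits (granularity 1/1000 bit) and the
exact distribution of the integer total under the background model is
built by convolution; the reported p-value is the exact survival
probability at the window's integer score. A window is an occurrence when
p ≤ 1e-4 (the common default for motif scanning); occurrences must lie
fully inside the region, may overlap each other, and the minus strand is
scanned with the reverse-complement matrix (its own null distribution, so
non-uniform backgrounds are handled correctly). Ambiguous bases contribute
zero log-odds. Tests verify the discretized DP against full 4^L
enumeration — agreement is exact, because both operate on the same integer
scores.

One consequence of exact discrete p-values worth knowing: for a sharp
7-mer PWM, only words at the very top of the score distribution can reach
p ≤ 1e-4 (the best word has p = 4⁻⁷ ≈ 6.1e-5 under a uniform background),
so scanning behaves like a near-exact-match detector. The packaged AP-1
matrix makes the degenerate fourth position slightly asymmetric (C 50 /
G 48) precisely so that the maximum-score word is unique and detectable at
the default threshold on its own strand.

**Controls and enrichment.** Control sequences are the immediately
adjacent upstream and downstream intervals of the same length as the test
region (clipped or dropped at chromosome edges). Over-representation is a
one-sided Fisher's exact test on regions-with/without ≥ 1 occurrence; the
odds ratio is Haldane-corrected (+0.5 per cell) when any cell is zero.
Because the one-sided exact p includes the observed table, equal
proportions give a large p (≈ 0.67 for 5/10 vs 5/10), reaching exactly 1
only for degenerate tables.

## Guide design geometry

All coordinates 0-based; cut positions are between-base. A plus-strand PAM
is NGG at [p, p+3); the protospacer is the 20 nt at [p−20, p) and the
blunt cut sits 3 nt 5′ of the PAM, at coordinate p−3 (between protospacer
positions 17 and 18). A minus-strand PAM reads CCN on the top strand at
[p, p+3); the protospacer is revcomp([p+3, p+23)) and the cut is at p+6.
The "~3 nt before the PAM" rule is resolved to exactly 3, the standard
SpCas9 blunt-cut model. A guide is designable for motif [s, e) when its
cut lies in the inclusive window [s − margin, e + margin] (margin 5). The
signed offset is 0 for cuts inside the motif (between-base s..e), negative
upstream, positive downstream; a cut exactly at a motif edge has offset 0
(distance zero) while still being an edge cut. Duplicate spacer sequences
are collapsed library-wide, first occurrence kept and cross-references
recorded, so reported guide counts refer to distinct spacers. No GC,
homopolymer or off-target filters are applied by default — the design
criterion is purely geometric.

## Screen scoring

Counts are scaled to 1e6 per sample (CPM), floored at 50 *after*
normalization (the floor is stated on normalized counts), converted to
per-replicate log2 enrichment (induced vs control, paired by replicate
index), averaged arithmetically, and standardized:
z = (mean_fc − μ)/σ with μ, σ the library mean and sample SD (ddof = 1).
A degenerate library (σ = 0) yields all-zero Z with a warning. Ranking is
by Z only; no p-value/FDR machinery is attached, matching the screen's
ranking-plus-corroboration logic. The hit threshold (default 1.75) is
deliberately ambiguous between log2 and linear units in the literature
this workflow comes from, so `threshold_units` is a required argument
("log2" or "linear") rather than a silent default; guide hits are strict
(> threshold), and an element is corroborated when ≥ `min_guides_per_re`
(2) distinct hit guides target it. Note that in very small libraries the
planted/hit guides' own probability mass deflates every enrichment ratio
(the control denominator is 1/n while the induced numerator is
f/(n + k(f−1))), so absolute thresholds are only meaningful at realistic
library sizes; Z-ranking is scale-free.

## Edit profiling

Only M/I/D CIGAR operations are accepted (the amplicon use case needs
nothing else; anything further, including soft-clips, raises a clear
error). M compares read to reference base-by-base (ambiguous bases count
as mismatches), D increments the deletion count at every deleted reference
position, and I increments the insertion count at the between-base
coordinate preceding the inserted bases (SAM convention). No realignment
or indel left-shifting is performed. Counting is restricted to the
profiled region; reads partially overlapping it contribute only their
in-region events. The per-position invariant match + mismatch + deletion =
spanning-read depth holds exactly by construction and is asserted on
random CIGAR walks. `edit_fraction` reports, among reads overlapping a
window, the fraction carrying ≥ 1 event touching it (mismatch inside,
deletion overlapping, insertion at or between the window edges).

## The synthetic-data generator

The generator emulates the study conditions the pipeline is built for;
its defaults are the study conditions, not tuning knobs.

* **Loci.** Each locus occupies a 3,000-bp slot on one synthetic
  chromosome. An enhancer locus carries a divergent TU pair (1,000-bp TUs,
  start sites 300 bp apart) with exactly one planted motif instance — the
  consensus or its reverse complement, chosen at random — midway between
  the start sites. Decoy classes give the caller a specificity surface:
  unidirectional TUs, convergent opposite-strand pairs (start sites 300 bp
  apart), and divergent pairs separated by 900 bp (beyond the 800-bp
  window).
* **Designability.** A designable motif receives one PAM per strand whose
  cut falls strictly inside the motif; around every planted motif, all
  other GG/CC dinucleotides that could place a cut within the margin are
  ablated by substitution, so non-designable motifs admit no guide and
  designable motifs admit exactly two (matching the observation that most
  motifs are targeted by 2–3 guides). Planted designability is re-verified
  against the PAM/cut geometry at generation time; `designable_fraction`
  (default 0.62, the fraction reported in this kind of screen) is realized
  exactly by count.
* **Counts.** TU counts are negative binomial with
  var = μ + (cv·μ)², where `nb_dispersion` (0.1) is the extra-Poisson
  biological coefficient of variation between replicates (edgeR's BCV
  scale). Baseline means are per-TU log-normal,
  μ_i = `base_mean_reads` · exp(N(0, `baseline_log_sd`²)) with median 200
  and sd(ln) = 1 — real nascent-transcription levels span orders of
  magnitude, and that spread is precisely what makes cross-sample quantile
  normalization safe; with a flat baseline, column ranks are pure noise
  and quantile normalization corrupts fold changes. Induced loci have both
  mates' means multiplied by `induction_fold` (4) in induced-condition
  samples; two replicates per condition by default.
* **Screen.** Control samples draw multinomial counts around equal guide
  representation at `reads_per_guide` = 1,000 expected reads per guide
  (500–1,000× coverage is standard pooled-screen practice and makes the
  per-guide mean-enrichment noise ≈ 0.03 log2 units, small against the
  planted effects); induced samples multiply enriched guides'
  probabilities by their effect fold (4) before renormalization, 4
  replicates. Note the renormalization means a planted linear fold f
  yields an expected measured ratio f·n/(n + k(f−1)) for k planted guides
  among n.
* **What is not emulated.** Read-level sequencing, alignment, PCR bias,
  mappability, chromatin context, correlated noise between mates, and
  overdispersion beyond the multinomial in the screen. Passing tests
  demonstrate the *algorithms* recover planted signal under the stated
  noise model; they do not certify performance on real libraries with
  these artifacts.

All randomness derives from `SimulationConfig.seed` through per-stage
`numpy` generator streams, so a config is bit-reproducible.

## Validation scales and stochastic checks

The test suite and `scripts/acceptance.py` use: 20 random 50-kb genomes
for exact guide-design/oracle equivalence; 20 seeds of the 200-enhancer
configuration for caller recovery (sensitivity averaged across seeds; a
single seed has only 20 induced loci, so per-seed sensitivity fluctuates);
50 seeds with `induction_fold` = 1 for the false-positive rate; 1,000
Fisher trials at 5,000 regions per set for p-value uniformity; 100 screen
seeds at 1,000 guides; 10,000 random CIGAR walks for profile conservation.
These sizes keep each check well-resolved while the whole suite runs in
well under a minute of compute. Two checks are inherently stochastic: the
Kolmogorov–Smirnov statistic of 1,000 uniform draws has median ≈ 0.028 and
exceeds 0.05 for ~1–3% of random seeds even for perfectly calibrated
p-values (exact discrete tests additionally sit slightly above the
uniform floor), and per-seed caller sensitivity at 20 planted loci has
binomial noise ≈ 0.04.

## Known limitations

* The divergence requirement assumes TU strand calls are reliable; noisy
  strand assignment on real data would push true pairs into the rejected
  convergent class.
* Exact discrete p-values make sharp short PWMs behave like exact-match
  scanners at stringent thresholds; for permissive scanning of degenerate
  motifs, longer/softer PWMs or a higher threshold are appropriate.
* The screen model has no guide-efficiency variation; real screens show
  heterogeneous effects per guide, which the corroboration rule partly
  absorbs but the generator does not simulate.
* `edit_fraction` attributes events to reads as aligned; alignment
  ambiguity around homopolymers is not resolved.
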