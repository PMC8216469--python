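# Methods

## Interaction model and the enrichment test

The pipeline models a crosslink–ligate–sequence library as a mixture of
non-chimeric reads, intramolecular chimeras (two fragments of one
transcript) and intermolecular chimeras. Intermolecular ligation is assumed
to be abundance-driven: under the null, the probability that a chimera joins
features i and j is proportional to `a_i * a_j`, the product of their
relative abundances. A genuine interaction shows up as a pair whose chimera
count exceeds what its partners' overall ligation activity predicts.

For a pair (A, B) the test conditions on the margins: k = chimeras joining
A and B; K and n = all interaction-class chimeras involving A and B
respectively (both include k); N = all interaction-class chimeras in the
merged library. The raw P-value is the one-sided upper tail
`P(X >= k)` for `X ~ Hypergeometric(N, K, n)` — the probability of at least
k A–B joins if B's partners were drawn at random without replacement from
the library. The parameterisation is symmetric in (K, n). Only enrichment is
tested; self-pairs are intramolecular by construction and never tested.

N counts interaction-class reads only (intramolecular chimeras contribute to
expression estimates, not to N). Because each read consumes two marginal
slots, the hypergeometric mean `K*n/N` is roughly twice the abundance-model
expectation of k, which makes the test conservative; the null-calibration
check (below) quantifies this. A `total=` override on `test_all_pairs`
lets a caller count the whole library in N instead, for sensitivity
analysis; the default is the interaction-read total.

Raw P-values of all tested pairs (k >= `min_count`, default 1) are adjusted
with the Benjamini–Hochberg step-up: sort ascending, `q_i = p_i * m / i`,
enforce monotone non-decreasing from the largest p downward, cap at 1,
restore input order. Significance uses two nested sets: raw P < 0.05 and
adjusted P < 0.05 (FDR 0.05). Note that BH adjustment is not idempotent in
general; only constant vectors are fixed points. The implementation is
checked for exact agreement against the statsmodels reference and, for the
hypergeometric tail, against exhaustive enumeration over every population
N <= 30 and against `scipy.stats.hypergeom.sf` at realistic library sizes.

Numerics: the tail is computed from a log-gamma starting term and a
multiplicative recurrence. Above the distribution's mode the upper tail is
summed directly (terms decay geometrically; summation stops when a term
falls below 1e-18 of the accumulated sum), so tiny P-values keep full
relative precision; at or below the mode the complement of the lower tail
is used, where cancellation is harmless because the result is large.

## Read classification

Every position of the genome is covered by the annotation plus generated
`UA-start-stop` features (complement intervals of the annotated union, kept
when at least 30 nt — shorter than that is below any ligatable fragment).
Each alignment segment is assigned to the feature with maximal overlap;
ties go to the smaller feature, then lexicographic id. Strand is ignored:
the recovered orientation of a psoralen chimera is not informative and no
strandedness rule is assumed.

Two-segment reads are classified by the closest-edge separation of their
two features, computed on the circle (minimum of linear and wrap-around
gaps) when the chromosome is circular: same feature → intramolecular;
gap <= 50 nt → junction_artifact (boundary-spanning non-chimeric read);
gap <= 2000 bp → proximal_excluded; otherwise interaction, recorded under
the canonically ordered pair (A <= B), which makes the pipeline invariant
to fragment order within a read. Any segment with an ambiguous placement
(repeat) makes the read repeat_ambiguous. Unmapped reads, reads whose
segment overlaps no feature, reads with more than two segments and
single-fragment (non-chimeric) reads are all `unassigned`; the class
partition is exhaustive, so class tallies sum to the read count. The
junction/proximal boundary at 50 nt and the 2000 bp edge-to-edge threshold
applied before replicate merging are package choices where only the
2000 bp figure is externally fixed.

Replicate matrices over the same feature universe are summed element-wise;
marginals and N are recomputed after merging.

## Synthetic libraries

The generator emulates a duplicate bacterial crosslinking experiment at
desk scale. Defaults: one circular 100 kb chromosome; 60 genes (300–900 nt)
and 10 sRNAs (80–200 nt) placed non-overlapping with intergenic gaps that
are either exactly 0 (adjacent genes, exercising the junction class) or
>= 30 nt, scaled to fill the chromosome; log-normal relative abundances
(mu 0, sigma 1) — heavy-tailed expression is what structures the ligation
background the test must absorb; two replicates seeded as `seed + replicate`
for reproducible independence; fragments uniform within the feature,
25–60 nt (the post-digestion fragment length is not externally constrained
and is a free knob); 50% of reads chimeric, 20% of chimeras intramolecular.
Chimeric pairs (i, j) are drawn with probability proportional to
`a_i * a_j * e_ij`, where `e_ij` is the configured enrichment fold of a
planted pair and 1 otherwise; fragment order within the read is randomised.
Planted pairs are picked from features in the upper half of the abundance
distribution with edge separation beyond the distance threshold — detected
sRNA interactions involve expressed RNAs, and planting inside the excluded
proximity band would erase the signal by construction, not by statistics.

The genome sequence is random with all canonical 20-mers unique (and no
reverse-complement palindromes) outside explicitly flagged repeat regions,
which are created by duplicating an intergenic window. This guarantees the
built-in exact-match split aligner (20 nt seed, greedy extension, both
strands) places every fragment uniquely, and that repeat-region reads are
flagged ambiguous. An exact-match aligner can overrun a ligation junction
by a few nucleotides when the adjacent genomic base happens to match the
next read base (P = 1/4 per side); feature assignment is unaffected.
`emit_truth_alignments` bypasses sequence alignment entirely, placing
segments at the truth coordinates for exact conservation tests.

What the generator does not emulate: sequencing errors, adapter/quality
artefacts, rRNA contamination, paired-end mates, coverage biases, or
structure-dependent crosslinking efficiency. Passing tests therefore
demonstrate the correctness and calibration of the inference given
idealised fragments, not robustness to alignment noise in real libraries.

## Decay kinetics

`percent_t = 100 * (band_t/control_t) / (band_0/control_0)` removes loading
differences; any common rescaling of band and control cancels exactly.
Replicates are averaged on the percent scale before fitting (per-curve
averaging keeps the fit linear in the measured quantity; fitting
per-replicate and averaging half-lives is the main alternative and differs
only at second order for these noise levels).

Half-lives use ordinary least squares on `log10(percent)` vs minutes and
`t1/2 = -log10(2)/slope` — the log10 scale is deliberate, matching the
formula's constant. Biphasic decay is handled by a two-segment fit: the
breakpoint is searched over interior sample times with at least three
points per segment (segments share the breakpoint sample), the candidate
minimising total SSE is compared with the single line by BIC
(`n*ln(SSE/n) + k*ln(n)`, k = 2 vs 5), and the reported half-life always
comes from the first segment — the initial decay rate, before the slow
population dominates. SSE is floored at 1e-30 so exact fits keep the BIC
finite, with the parameter penalty then preferring the single line. A
non-negative first-segment slope, or an implied half-life beyond `t_max`
(default: the last sampled time), is reported censored as `">t_max"` —
a 30 min course cannot measure a 40 min half-life.

Standard curves are plain OLS with interpolation only: `log10(size)` vs
migration distance for ladders (size read back as `10^fit`), and intensity
vs fmol for absolute quantification (inverse regression; the sample
intensity must lie within the standards' observed range).

## Reporter and fitness statistics

Promoter activity: background fluorescence from the matched non-expressing
control is subtracted time-point by time-point (negative results floored at
0 with a warning), then `a_t = (GFP_t - GFP_{t-1}) / OD600_t` for t >= 1,
smoothed with a centred moving average (default 3 points) whose window
shrinks at the series edges. The statistic is linear in GFP at fixed OD.

Competition fitness: per-replicate ratio `cfu_A / cfu_B`, normalised by the
verified inoculum ratio, compared between assays with Welch's
unequal-variance t-test (Satterthwaite degrees of freedom, two-sided).
Ratios are tested untransformed by default with a log2 option; biological
replicates are the unit of analysis.

## Problem sizes and verification

The acceptance checks run the package at these scales, chosen to finish on
a single CPU in minutes: hypergeometric oracle equivalence over all
(k, K, n, N) with N <= 30 (87 295 cases, tolerance 1e-10); BH agreement on
1000 random vectors of length 1–200 (exact); noise-free conservation on a
10 000-read library (exact, including the intramolecular tallies);
planted-pair recovery and empirical FDR on 200-feature libraries with 1e5
chimeric reads split over two replicates, five pairs planted at 20-fold,
repeated across seeds (recall 5/5 per seed, mean FDR <= 0.10); null
calibration on the same libraries without planting (mean fraction of tested
pairs with raw P < 0.05 at most 0.08; observed ~0.002, reflecting the
factor-two conservatism above); half-life recovery (exact noiseless, median
error < 5% at 1% multiplicative noise with 7 points, biphasic initial slope
within 15%); closed-form reporter examples at 1e-9; and exact UA tiling on
100 random annotations.

## Known limitations

* The hypergeometric margins include k itself and N is the interaction
  total; alternative conventions (subtracting k, whole-library N) shift
  P-values slightly — the `total` override exposes the latter.
* Multi-placed reads are discarded (repeat_ambiguous), not rescued by
  random placement, so interactions inside repeat families are invisible.
* The toy aligner requires exact matches over unique seeds and exists to
  make the synthetic pipeline self-contained; real libraries should be
  aligned with a chimera-aware production aligner and ingested as SAM.
* Breakpoint selection for biphasic decay needs >= 6 time points and
  assumes a single rate change; three-phase decays will be under-fit.
* UA features shorter than 30 nt are not created, so fragments landing in
  such micro-gaps (impossible for generator output) fall back to
  `unassigned`.
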