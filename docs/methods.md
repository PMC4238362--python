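# Methods

## The system being modelled

An intron-spliced hairpin RNA (ihpRNA) transgene transcribes two arms of an
inverted repeat separated by a spliceable intron. After folding, the
double-stranded stem is diced into small RNAs that silence any mRNA sharing
the trigger sequence. The analyses here formalize the quantitative
observations made on this system: sRNA accumulates in discrete peaks along
the trigger; peak abundance decays with distance from the loop/intron;
secondary (transitive) sRNA appears only 3′ of the target region on the
mRNA; strong silencing shifts the endogenous size-class balance away from
23–24-nt heterochromatic siRNA; and cleavage products of the target are
uncapped and therefore sensitive to a 5′-phosphate-dependent exonuclease
(5′PDE).

## Coordinate conventions

All intervals are 0-based half-open internally; textual reports are 1-based
inclusive. The precursor's sense strand is the transcribed strand, arm 1
5′→3′. Loop distance of an arm-1 position p is `arm_length − 1 − p`, so the
position adjacent to the intron has distance 0; arm-2 positions fold onto
their arm-1 mirror, making loop distance a bijection from arm-1 positions
onto {0, …, arm_length − 1}. ihpRNA coordinates exclude the intron: only
its length enters the model, and the generator fills it with random
sequence (default 779 nt, a typical spacer-intron span).

## Mapping and normalization

Reads are matched exactly on both strands. At 18–30 nt, tolerant local
alignment collapses to exact matching for error-free reads, and exactness
makes every downstream count reproducible and testable against a
brute-force substring scan (a property the suite enforces). A k-mer
position index per (reference, read length) provides O(1) site lookup; a
`mismatches` knob is deliberately absent from the default path. Multi-hit
reads contribute their full count at every site by default (coverage-table
semantics); a fractional 1/n_sites policy is available. Per-million
denominators count reads retained after adapter trimming and the ≥ 18-nt
length filter — whether the denominator should count pre- or post-filter
reads is genuinely open, so the choice is recorded in outputs. Size-class
abundances are reported in tspm (thousand sequences per million reads):
401,000 matching reads per million ≡ 401 tspm.

## Peak formalization

"Peak" is defined operationally (the source observations identify peaks
visually): local maxima of a 10-nt boxcar-smoothed per-million profile,
accepted greedily by height with ≥ 30-nt apex separation, intervals
extended to half-height crossings, labelled in coordinate order. Peak
abundance is the per-million sum over the interval (apex height is also
reported; the sum is the more robust of the two defensible choices).
Periodicity is the mean ± SD of consecutive apex spacings (SD is NaN with a
single spacing). The loop-distance correlation standardizes each
construct's peak abundances to their mean before pooling, then applies the
Pearson t-test with n − 2 df, two-tailed.

## Locus calling and differential rules

A position qualifies when its per-million coverage in the size class of
interest is ≥ 10 in *every* library analyzed; maximal qualifying runs of
≥ 10 nt become loci (a 9-nt run is excluded by definition). Locus abundance
is the per-million sum over the interval. A call is significant only when
the silenced/control fold exceeds 1.5 in the same direction in both
silenced-vs-control comparisons; folds > 2 in both mark the call `strong`.
Infinite folds (control = 0) are reported as `inf` with a flag, never
dropped. Folds are rounded half-away-from-zero to one decimal. The control
library in the three-library rule is the wild-type library; the rule
generalizes to any library set by the same all-libraries conjunction.

## Transitivity index

Downstream/(upstream + downstream) per-million abundance over the
full-length target mRNA, a bounded [0, 1] quantity preferred over the raw
3′/5′ quotient because it orders cases identically while remaining defined
when the 5′ region is empty. Trigger-region coverage above an attribution
threshold (default 300 per million per nt) is attributed to hairpin
processing rather than mRNA-derived sRNA, and reported separately.

## Rare-codon (RCF) scoring

For codon j of amino acid i, `RCF_ij = −(X_ij − X_avg,i)/X_avg,i`: the
negated relative deviation of usage from the synonymous mean, chosen as the
natural reading of "the factor by which the actual usage differs from the
average" with the display negation folded in (a `negate=False` flag
recovers the raw deviation). Consequences used as exact test invariants:
scores sum to zero within each amino acid; single-codon amino acids score
0; rescaling one amino acid's usages leaves its scores unchanged. Windowed
profiles are 20-codon means sliding by one codon; ambiguous codons are
masked and window means taken over unmasked positions. ORF finding scans
the three forward frames (mRNA context), reporting the first ATG per
stop-to-stop segment, minimum length 50 codons by default; "secondary" is
defined here as the longest ORF in another frame whose span extends past
the primary's 3′ end, falling back to the longest remaining — a stated
convention, not an asserted standard. The bundled codon table
(`data/codon_usage_synthetic.tsv`) is synthetic — deterministic pseudo-
frequencies over the standard genetic code for tests and demos; organism
tables are supplied by the user as TSV.

## Treated/untreated RNA-Seq comparison

Abundance is reads per kilobase per million (count × 10⁹ / (length ×
total)). The treated library is rescaled by the median untreated/treated
abundance ratio over the capped normalizer set (median chosen for
robustness; the estimator is idempotent). Cap calls threshold the
normalized percent change at ±10% by default — the observed changes in the
motivating data (+16/+19%, −52%) are effects, not decision rules, so the
threshold is configurable. Region comparison flags 5′ depletion when the
silenced library's upstream per-nt mean falls below 0.5× the control's,
and 3′ 5′PDE sensitivity when the downstream mean drops ≥ 25% under
treatment. Whether percent changes should be computed before or after
rescaling is not fixed by the source; we compute them after.

## Phenotype statistics

Efficacy = (green + ½·yellow-green)/n per T2 family. GUS silencing of a T1
plant is 1 − activity/mean(wild-type), a transform chosen here (the
correlation's inputs were not specified beyond "silencing levels").
Correlation is per-family. The χ² test is the standard homogeneity test on
cumulative per-fragment counts without continuity correction.

## The synthetic-data generator

Generators are pure functions of (parameters, seed); every read is an exact
substring of its declared source, with no sequencing-error model (mapping
at these lengths is effectively exact; an error knob would only blur the
oracle tests). Study-condition defaults: transgene fraction 7.6% (midpoint
of the observed 5.7–9.6% range, treated as uniform across constructs since
no per-construct breakdown exists); transgene size mix 85/11/4% over
20–21/22/23–24 nt; peaks every 79 nt with weight exp(−d/300 nt) — the decay
length reflects the observation that most hairpin sRNA comes from the
~500–600 nt nearest the loop; read lengths uniform within a size class.
Endogenous reads come from planted genome features (hc_cluster → 23–24 nt,
mirna/tasirna → 20–21 nt, gene → 20–22 nt) with lognormal expression
weights; the default role mix (50/28/6/16%) puts the 20–21 and 23–24
classes near their observed wild-type tspm proportions. The toy genome
(2 × 120 kb by default, against the real system's five chromosomes)
concentrates hc_cluster features near centromeres with probability
c/(c+1), c = 4 by default; the pericentromeric window is centromere ± 10%
of the chromosome length (a window the source never defines — it shows
concentration without quantifying it).

Differential planting multiplies selected features' expected read counts by
the fold (Poisson-drawn where multiplied), rather than renormalizing a
fixed-total multinomial — renormalization would shrink realized per-million
folds below the planted value whenever up- and down-planted mass is
unbalanced. A detectability check warns when a planted locus's expected
coverage falls below the caller's 10-per-million floor. The RNA-Seq pair
samples both libraries to equal depth from compositions expr_i and
expr_i·k_i, where k_i = capped_i + (1 − capped_i)(1 − pde) is a molecule's
survival probability under treatment; target-mRNA coverage adds full-length
intervals for capped molecules and 3′-of-cleavage intervals for uncapped
ones. The phenotype generator shares a latent silencing strength between
assays through a Gaussian copula; the latent correlation is calibrated
analytically (copula inverse 2·sin(πr/6) plus attenuation for class-count
and triplicate-assay noise) so the empirical r between derived efficacy and
GUS silencing targets the requested value; anthocyanin class probabilities
((1−s)²/2, (1−s)²/2, 2s(1−s), s²) are chosen so E[efficacy | s] = s exactly.

What passing tests on these data do *not* show about real libraries:
genomic repeat structure, multi-mapping ambiguity, ligation and PCR biases,
sequencing error, partial adapter chimeras, and expression distributions
heavier-tailed than lognormal are all absent, so recovery rates here are
upper bounds on field performance.

## Problem sizes and numerics

Simulated libraries default to 1.5–2 × 10⁵ reads (the tests' and acceptance
script's chosen scale; the motivating libraries were ~6 × 10⁶) — large
enough that planted 2-fold differences sit many sampling SDs from the 1.5
threshold, small enough to keep the whole suite interactive. Locus-caller
equivalence is checked on 1,000 random length-500 coverage triples; the
loop-distance analysis uses 10 planted peaks per construct across all four
configurations. Degenerate inputs are flagged, not silently dropped:
zero-variance correlations, zero-denominator folds, undefined transitivity
(no flanking signal), and zero-expected χ² cells all return explicit
undefined markers or raise with guidance.

## Known limitations

Exact matching cannot place reads spanning polymorphisms or errors;
secondary-ORF ranking is one defensible convention among several; the
attribution of trigger-region reads to the hairpin is threshold-based, not
model-based; the χ² test assumes independent counts, which collapsed
multi-hit reads can violate; and the generator's pericentromeric window and
concentration are modelling choices, so pericentromeric fractions measured
on synthetic data characterize the pipeline, not any genome.
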