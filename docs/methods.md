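# Methods

This note records the statistical model behind `enhmotif`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
benchmarks do and do not demonstrate.

## Site model and scoring

A motif is a position weight matrix (PWM) of per-position base probabilities
p_jb. Count matrices (JASPAR PFM) receive a pseudocount of 0.25 per cell
before normalization — (c + 0.25)/(Σc + 1) per column — which prevents
log(0) while perturbing well-supported columns by under 3%. Probability
matrices (minimal MEME) are used verbatim; for scoring only, zero
probabilities are floored at 10⁻⁴. Information content is measured on the
*pre*-pseudocount probabilities when counts are available, so a
deterministic column contributes exactly 2 bits and the IC ≥ 10 filter has a
crisp meaning (≥ 5 fully specific positions' worth of information).

A length-L window s scores Σ_j log₂(p_j,s(j) / bg_s(j)). Two normalizations
of this score drive the site filters:

* **Relative match score** (s − s_min)/(s_max − s_min), where s_min and
  s_max are the worst and best attainable sums of the matrix. This is the
  MATCH-family "matrix similarity" applied to the full motif length; it is
  invariant to adding a constant to all log-odds entries of a column.
* **Site p-value** P(score of a random background word ≥ s), computed by
  exact dynamic-programming convolution of the per-column score
  distributions.

All log-odds entries are quantized to a 10⁻⁴ grid at construction
(TFM-PVALUE/MOODS-style). Window scores, the min/max normalization, and the
DP distribution then live on one integer lattice, so a p-value lookup is
exact for every attainable window score — the test suite verifies agreement
with brute-force enumeration over all 4^L words to < 10⁻⁶ (observed < 10⁻¹³)
for L ≤ 8 under uniform and skewed backgrounds. The quantization bounds the
score error of any window by L·5×10⁻⁵, negligible against per-column score
ranges of order 1–10.

The background defaults to uniform (0.25 each); an empirical,
strand-symmetrized composition of the scanned sequences is available per
run. Both strands are scanned; the minus strand is implemented as the
reverse-complemented matrix on the forward strand, which is arithmetically
identical to scanning the reverse-complemented sequence. Windows containing
N are skipped rather than scored (their probability is undefined). The
default thresholds — match ≥ 0.8 and p ≤ 0.05 — are the workflow's standard
operating point.

## Conservation (phylogenetic footprinting)

A predicted site is *conserved* when the orthologous sequence mapped to its
enhancer contains at least one window of the same motif with relative score
≥ the match threshold, on either strand. This is presence-level footprinting
against an explicit enhancer→ortholog sequence map: whole-genome alignment,
liftover and positional orthology are deliberately outside the package (the
map is an input), so "conserved" means "the motif also occurs in the
orthologous region", not "the aligned bases are identical". Enhancers
without an ortholog mapping are counted and treated as non-conserved.
Downstream statistics consume conserved sites only.

## Redundancy collapse

Motif libraries carry near-duplicate matrices whose enrichment signals are
not independent. Similarity between two PWMs is the maximum Pearson
correlation between flattened probability columns over all ungapped offsets
with ≥ 4 overlapping columns and both orientations (a Tomtom-style alignment
without the null model; an alignment where either window is constant
contributes −1). Pairs at similarity ≥ 0.8 are grouped by single linkage —
the simplest reading of "grouping by a similarity threshold", and pluggable
if a different linkage is wanted. Each group is represented by the member
present in the largest number of condition-B enhancers (where predictions
are made first), ties broken toward the lexicographically smaller motif id,
making the partition order-independent.

## Differential enrichment

For motif m, k_a of n_a condition-A enhancers and k_b of n_b condition-B
enhancers contain ≥ 1 conserved site (presence, not counts — overlapping or
repeated sites in one enhancer count once, so site multiplicity cannot leak
into the statistic). The effect size is the proportion ratio
(k_b/n_b)/(k_a/n_a), defined as +∞ when k_a = 0 < k_b and 1 when both are
zero. Significance is the one-sided hypergeometric over-representation tail
with population N = n_a + n_b, successes K = k_a + k_b and draws n_b —
the natural 2×2 margin when the test is named but its universe is not.
Identical site filters (including conservation) apply to both sets.
Bonferroni correction multiplies by the number of cluster representatives
actually tested, not the raw library size. Selection requires fold ≥ 1.5 and
corrected p ≤ 0.05; results rank by fold descending, then corrected p, then
motif id.

## Region–gene association and term statistics

Each gene has one canonical TSS (5′-most transcript start, chosen upstream).
A region is anchored at its midpoint and assigned to the gene with the
nearest TSS within 1 Mb (the GREAT single-nearest-gene association and cap).
Regulatory domains extend from each TSS to the midpoint toward each
neighbor, capped at 1 Mb and chromosome bounds; between TSSs t₁ < t₂ the
boundary sits at ⌊(t₁+t₂+1)/2⌋ so every base strictly nearer one TSS falls
in that gene's domain. A base exactly equidistant from two TSSs lands in the
right-hand domain, while the nearest-gene tie-break prefers the smaller gene
id — the single point where the two constructions can disagree; the
consistency property is asserted away from exact ties. Curated domain
exceptions of the original GREAT tool are knowingly not reproduced.

Term enrichment of a region set computes, per term, the binomial tail
P(Bin(n, p_term) ≥ k) with p_term = (bases of the term's gene domains) /
(bases of all domains) and n = regions whose midpoint falls in any domain —
GREAT's native statistic — and, side by side, a gene-level hypergeometric
(population = genes with domains, successes = term genes, draws = distinct
genes hit). Both are reported because the common reporting filter
("hypergeometric fold ≥ 2, FDR ≤ 0.05, ≥ 5 associated genes") references the
gene-level reading while the region-level binomial is the better-calibrated
statistic; `apply_term_filters` takes either. Gene-list over-representation
is a per-term hypergeometric tail against an explicit universe. All per-term
p-values are Benjamini–Hochberg adjusted (via statsmodels) and ranked by
FDR.

The predicted-target vs DE-set overlap test is a hypergeometric tail with
population = an explicit gene universe, successes = the DE set, draws = the
target set. The universe defaults to the genes tested for differential
expression — the defensible choice when no universe is stated — and is a
required, visible parameter precisely because the p-value is very sensitive
to it. "Downregulated" means fold ≥ 1.5 decrease with adjusted p ≤ 0.05,
applied as an input filter to a finished DE table; differential-expression
estimation itself is out of scope.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical structure* of a two-timepoint
enhancer study: two enhancer sets (default 300 each, 200 bp — a compact
enhancer core) in which each motif occurs with a set-specific per-enhancer
probability; ortholog copies in which each planted instance survives with a
set conservation rate (a failed instance window is re-randomized while
flanks stay identical, isolating the conservation filter from alignment
effects); an expression table with planted upregulated genes, a TF subset
matched to the motif library's ids, and effect sizes separated from the
filter thresholds so label recovery is exact; a knockdown DE table with a
designated target set overlapping the downregulated genes at a configured
rate; and gene-set collections with one term enriched at a known odds
ratio. Everything is a deterministic function of one integer seed.

The default motif library is a fixed benchmark constant (its own internal
seed): ten 16-bp matrices, one dominant base per column at probability 0.9
(≈ 22 bits IC), pairwise similarity kept below 0.7 by rejection. Sixteen
moderately specific columns are the deliberate operating point: at the 0.8
match threshold such a matrix admits ~1.6×10⁴ of the 4¹⁶ words (≈ 4×10⁻⁶ per
window), so an expected ~0.001 chance presences per 200-bp enhancer — the
presence counts that reach the enrichment test are dominated by planted
instances, and the realized proportion ratio stays near the planted 6.0.
Shorter or softer motifs at the same threshold admit background hits at
rates that visibly dilute the planted fold. Planted instances are sampled
per column from the PWM (so ~7% fail the 0.8 match, thinning both sets
equally and leaving the ratio unchanged); a consensus-only mode supports
exact-recall tests.

Not emulated: nucleosome or peak-shape structure, GC heterogeneity along a
sequence (a global GC option exists), read-level noise, motif grammar
(spacing/orientation constraints), indel-containing ortholog divergence, and
correlated motif co-occurrence. Passing benchmarks therefore demonstrate the
*statistical machinery* — calibration, recovery, exactness — on data
matching the model's assumptions, not performance on real chromatin.

## Benchmarks and their readings

* **Oracle equivalence.** DP site p-values vs enumeration over all 4^L
  words (L ≤ 8); hypergeometric and binomial tails vs exhaustive summation
  for populations ≤ 30. Observed disagreement is at float precision.
* **Planted recovery.** 50 sequence-level replicates of the full chain at
  300 enhancers/set. The fold estimate is *pooled* across replicates
  (ratio of summed proportions): the mean of per-replicate ratios is
  inflated by small denominators (observed ≈ 6.8 against a pooled ≈ 5.7–5.9),
  while the pooled ratio is consistent, with a delta-method standard error.
  The pooled fold sits slightly below 6.0 because rare background presences
  add equally to both sets. The "no null selected" requirement operates at
  the Bonferroni family-wise boundary: with nine nulls per replicate and
  family-wise error ≤ 0.05, about 95% of replicates are expected to be
  clean, so the ≥ 95% bar is tight by construction and holds through the
  discreteness of the hypergeometric test.
* **Type-I calibration.** 200 simulations with equal presence probabilities
  in both sets. Selection consumes only presence counts, so the null is
  simulated directly as binomial presence draws and pushed through the
  identical test/selection code; the sequence-level machinery is already
  exercised end-to-end by the recovery benchmark. Observed selection
  fraction ≈ 0.2–0.3% against the 5% bound (Bonferroni conservatism plus
  the fold gate).
* **Overlap-test calibration.** Under target sets drawn independently of
  the DE structure, the overlap count follows its hypergeometric null. The
  discrete p-value is super-uniform, so a KS test against Uniform(0,1)
  rejects even for a correct implementation; calibration is instead checked
  on the randomized probability integral transform of the count (exactly
  uniform under the null), plus a direct check that the p-values are never
  anti-conservative.

## Degenerate inputs and conventions

Coordinates are 0-based half-open everywhere. Scores outside a matrix's
attainable range are clamped with a warning (p = 1 at or below the minimum,
0 above the maximum). A PWM whose columns are all identical has zero score
span; every window then gets relative score 1. Expression rows with missing
q-values are excluded with a counted warning (significance cannot be
asserted). Empty motif files yield an empty library with a warning; an empty
target set yields overlap p = 1 with a warning. Gene symbols are matched
case-insensitively throughout (mouse/human capitalization differs). Result
tables serialize floats at 6 significant digits in a fixed column order, so
identical runs are byte-identical; every pipeline run writes its resolved
configuration next to its outputs.

## Known limitations

The conservation filter cannot distinguish positional orthology from mere
motif presence in the orthologous region. The enrichment test conditions on
presence, discarding within-enhancer site counts and positions (no
centrality or spacing statistics). GC-matched background resampling is not
implemented; the empirical-background option adjusts the site null but not
the enrichment null. Ontology annotations are taken as given in the GMT
(no DAG propagation). Domain construction supports one TSS per gene only.
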