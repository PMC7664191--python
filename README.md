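# enhmotif

Differential transcription-factor (TF) motif enrichment between two
condition-specific enhancer sets, with phylogenetic-footprint filtering of
binding-site predictions and GREAT-style region–gene statistics.

## The problem

Developmental transitions — the motivating case is the mouse placenta moving
from e7.5 to e9.5, when the labyrinth vasculature forms — are driven by TFs
acting through stage-specific enhancers (H3K27ac-marked distal elements).
Given enhancer calls for two conditions, a genome, orthologous sequences from
a second species, a motif library, and a two-condition expression table, the
question is: *which upregulated TFs have binding motifs over-represented in
the condition-specific enhancers?* Predicted targets of those TFs can then be
cross-checked against knockdown differential-expression (DE) data.

## The method

1. **Upregulated TF shortlist.** Keep genes with FPKM ≥ 10 in the later
   condition, fold ≥ 2 and q ≤ 0.05 (all inclusive), then intersect with a TF
   catalog (case-insensitive symbols).
2. **Conserved site prediction.** Motifs with information content
   IC = Σ_j (2 + Σ_b p_jb log₂ p_jb) ≥ 10 bits are scanned on both strands.
   A window scores s = Σ_j log₂(p_jb/bg_b); it is a site when the relative
   match score (s − s_min)/(s_max − s_min) ≥ 0.8 **and** the site p-value
   P(random background word ≥ s) ≤ 0.05, computed *exactly* by
   dynamic-programming convolution of the per-column score distributions on a
   10⁻⁴ score grid. A site is *conserved* when the enhancer's orthologous
   sequence contains a site of the same motif at the same match threshold.
3. **Redundancy collapse.** Motifs with best-offset, both-orientation Pearson
   similarity ≥ 0.8 are grouped (single linkage); the member present in the
   most enhancers represents its group.
4. **Differential enrichment.** With k of n enhancers per set containing ≥ 1
   conserved site, fold = (k_b/n_b)/(k_a/n_a) and significance is the
   one-sided hypergeometric tail P(X ≥ k_b) on the pooled 2×2 margin,
   Bonferroni-corrected over the representatives. Selection: fold ≥ 1.5,
   corrected p ≤ 0.05.
5. **Region–gene statistics.** Enhancers are assigned to their single nearest
   TSS (≤ 1 Mb); midpoint-split, 1 Mb-capped regulatory domains support a
   GREAT-style binomial term enrichment with a gene-level hypergeometric
   computed side by side, both BH-FDR adjusted. Gene-list over-representation
   and predicted-target vs DE-set overlap use hypergeometric tails against an
   explicit universe.

A synthetic-data generator plants motif instances at controlled per-enhancer
proportions and conservation rates (plus expression/DE/gene-set tables with
known truth), so every stage is benchmarked against ground truth without any
downloads.

## Worked example

```bash
enhmotif synth --seed 7 --outdir demo/inputs     # synthetic study, known truth
enhmotif run --config run.yaml --outdir demo/out # run.yaml points at demo/inputs
```

The synthetic study plants motif `TF01` in 30% of condition-B enhancers vs 5%
of condition-A enhancers (true proportion ratio 6.0, conservation rate 0.9)
among nine null motifs present at 5% in both sets. The run prints:

```
- genes_total: 2000
- genes_upregulated: 200
- tfs_upregulated: 26
- motifs_library: 10
- motifs_ic_pass: 10
- enhancers_a: 300
- enhancers_b: 300
- sites_a_conserved: 130
- sites_b_conserved: 190
- motif_clusters: 10
- motifs_enriched: 1

Selected motifs (fold desc):
- TF01: fold=6.4 (64/300 vs 10/300), p_bonf=2.9e-11
```

Reading: 64/300 condition-B enhancers carry a conserved TF01 site versus
10/300 in condition A, an enrichment fold of 6.4 (near the planted 6.0; the
gap is binomial counting noise), significant after Bonferroni correction over
the 10 motif-cluster representatives. No null motif passes. The output
directory also contains per-site tables, the cluster table, region–gene
assignments, per-motif term enrichment, the target/DE overlap test, and the
resolved configuration for exact reproduction.

The same stages are importable as a library (`enhmotif.scan`,
`enhmotif.enrichment`, `enhmotif.genesets`, ...) — see module docstrings.

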