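"""Benchmark harnesses: oracle equivalence, planted-motif recovery, type-I.

Three self-contained evaluations of the pipeline's statistics:

* :func:`pvalue_oracle_errors` — the DP site p-value against brute-force
  enumeration over all 4^L words, and the hypergeometric/binomial tails
  against exhaustive summation for small populations.
* :func:`planted_recovery` — the full sequence-level chain (generate,
  scan, conserve, collapse, test, select) on replicates with one motif
  planted at per-enhancer proportions 0.30 vs 0.05 (true ratio 6.0,
  conservation 0.9) among nine null motifs.
* :func:`type_i_calibration` — selection frequency under the null where
  both enhancer sets carry every motif at the same per-enhancer
  probability. Selection consumes only presence counts, so the null is
  simulated at the count level (binomial presence draws), which makes 200
  simulations cheap; the sequence-level machinery above is exercised by
  the recovery benchmark.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats

from . import enrichment, redundancy, scan
from .scan import PWM, SCORE_EPS
from .synthetic import SyntheticConfig, generate_enhancer_sets

logger = logging.getLogger(__name__)

PLANTED_MOTIF = "TF01"


# ---------------------------------------------------------------------------
# Oracle equivalence


def enumeration_pvalue(pwm: PWM, score: float) -> float:
    """P(random word scores >= score) by brute force over all 4^L words."""
    probs = np.maximum(pwm.probs, 1e-4)
    q = np.rint(np.log2(probs / pwm.background) / SCORE_EPS).astype(np.int64)
    qscore = int(np.rint(score / SCORE_EPS))
    L = pwm.length
    total = 0.0
    for word in itertools.product(range(4), repeat=L):
        if q[np.arange(L), word].sum() >= qscore:
            total += float(np.prod(pwm.background[list(word)]))
    return total


def hypergeom_tail_enum(k: int, N: int, K: int, n: int) -> float:
    return sum(comb(K, x) * comb(N - K, n - x) for x in range(k, min(K, n) + 1)) / comb(N, n)


def binom_tail_enum(k: int, n: int, p: float) -> float:
    return sum(comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))


def pvalue_oracle_errors(seed: int = 0, max_length: int = 8,
                         scores_per_pwm: int = 10) -> dict[str, float]:
    """Worst-case disagreement between the package's tails and enumeration.

    Returns the maximum absolute error of (a) the DP site p-value over a
    suite of random PWMs with L <= max_length, (b) the hypergeometric
    enrichment tail for every consistent configuration with population <=
    30, and (c) the binomial tail for a grid of small cases.
    """
    rng = np.random.default_rng(seed)
    dp_err = 0.0
    for length in range(3, max_length + 1):
        for bg in (None, np.array([0.4, 0.1, 0.1, 0.4])):
            pwm = PWM("bench", rng.dirichlet(np.full(4, 0.5), size=length), background=bg)
            lodq = pwm._scanner.q
            for _ in range(scores_per_pwm):
                word = rng.integers(0, 4, size=length)
                score = float(lodq[np.arange(length), word].sum()) * SCORE_EPS
                dp = scan.site_pvalue(pwm, score)
                dp_err = max(dp_err, abs(dp - enumeration_pvalue(pwm, score)))

    hyper_err = 0.0
    for n_a in (5, 10, 15):
        for n_b in (5, 10, 15):
            for k_a in range(0, n_a + 1, 2):
                for k_b in range(0, n_b + 1, 2):
                    expected = hypergeom_tail_enum(k_b, n_a + n_b, k_a + k_b, n_b)
                    got = enrichment.hypergeom_enrichment(k_b, n_b, k_a, n_a)
                    hyper_err = max(hyper_err, abs(got - expected))
    # the textbook worked case: population 10, 5 successes, 4 draws, 3 seen
    case = enrichment.hypergeom_enrichment(3, 4, 2, 6)
    hyper_err = max(hyper_err, abs(case - 55 / 210))

    binom_err = 0.0
    for n in (6, 12, 25, 30):
        for p in (0.1, 0.25, 0.5, 0.9):
            for k in range(0, n + 1, 3):
                got = float(stats.binom.sf(k - 1, n, p))
                binom_err = max(binom_err, abs(got - binom_tail_enum(k, n, p)))
    return {"dp_pvalue": dp_err, "hypergeom": hyper_err, "binomial": binom_err}


# ---------------------------------------------------------------------------
# Planted-motif recovery


@dataclass
class RecoveryResult:
    n_replicates: int
    n_clean: int            # replicates selecting the planted motif and nothing else
    n_planted_found: int
    n_null_selected: int
    pooled_fold: float
    pooled_fold_se: float
    mean_fold: float
    folds: list[float]

    @property
    def recovery_rate(self) -> float:
        return self.n_clean / self.n_replicates


def _run_replicate(config: SyntheticConfig):
    """One sequence-level pass: generate, scan, conserve, collapse, test."""
    out = generate_enhancer_sets(config)
    pwms = [s.pwm for s in config.motif_specs]
    names_a = [iv.name for iv in out.intervals_a]
    names_b = [iv.name for iv in out.intervals_b]
    seqs_a = {n: out.sequences[n] for n in names_a}
    seqs_b = {n: out.sequences[n] for n in names_b}
    sites_a = scan.scan_enhancers(pwms, seqs_a)
    sites_b = scan.scan_enhancers(pwms, seqs_b)
    sites_a = scan.conserved_only(
        scan.apply_conservation(sites_a, pwms, out.ortholog_map, out.ortholog_seqs)
    )
    sites_b = scan.conserved_only(
        scan.apply_conservation(sites_b, pwms, out.ortholog_map, out.ortholog_seqs)
    )
    motif_ids = [p.motif_id for p in pwms]
    presence_a = enrichment.count_presence(sites_a, names_a, motif_ids)
    presence_b = enrichment.count_presence(sites_b, names_b, motif_ids)
    clusters = redundancy.cluster_motifs(pwms, presence_b)
    representatives = [c.representative for c in clusters]
    results = enrichment.motif_enrichment(
        presence_b, len(names_b), presence_a, len(names_a), representatives
    )
    selected = enrichment.select_enriched(results)
    return results, selected, presence_a, presence_b


def planted_recovery(n_replicates: int = 50, n_enhancers: int = 300,
                     seed: int = 0) -> RecoveryResult:
    """Sequence-level recovery of the planted differential motif.

    A replicate counts as clean when selection reports the planted motif and
    no null motif. The pooled fold is the ratio of pooled presence
    proportions across replicates (a ratio of means, which unlike the mean
    of per-replicate ratios is not inflated by small denominators); its
    standard error comes from the delta method on the pooled counts.
    """
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    n_clean = n_found = n_null = 0
    folds: list[float] = []
    sum_ka = sum_kb = sum_na = sum_nb = 0
    for rep_seed in rep_seeds:
        config = SyntheticConfig(seed=int(rep_seed), n_enhancers_a=n_enhancers,
                                 n_enhancers_b=n_enhancers)
        results, selected, presence_a, presence_b = _run_replicate(config)
        selected_ids = {r.motif_id for r in selected}
        found = PLANTED_MOTIF in selected_ids
        nulls = selected_ids - {PLANTED_MOTIF}
        n_found += found
        n_null += bool(nulls)
        n_clean += found and not nulls
        planted = next(r for r in results if r.motif_id == PLANTED_MOTIF)
        folds.append(planted.fold)
        sum_ka += planted.k_a
        sum_kb += planted.k_b
        sum_na += planted.n_a
        sum_nb += planted.n_b
    pa, pb = sum_ka / sum_na, sum_kb / sum_nb
    pooled = pb / pa
    se = pooled * np.sqrt((1 - pa) / sum_ka + (1 - pb) / sum_kb)
    finite = [f for f in folds if np.isfinite(f)]
    return RecoveryResult(
        n_replicates=n_replicates, n_clean=n_clean, n_planted_found=n_found,
        n_null_selected=n_null, pooled_fold=float(pooled),
        pooled_fold_se=float(se), mean_fold=float(np.mean(finite)), folds=folds,
    )


# ---------------------------------------------------------------------------
# Type-I calibration


def type_i_calibration(n_sims: int = 200, n_enhancers: int = 300,
                       presence_prob: float = 0.05, n_motifs: int = 10,
                       seed: int = 0) -> dict[str, float]:
    """Fraction of motifs passing selection when both sets share one rate.

    Per-enhancer presence is a Bernoulli event, so the null is simulated
    directly as binomial presence counts per motif and set, then run through
    the enrichment test and selection exactly as in the pipeline.
    """
    rng = np.random.default_rng(seed)
    motif_ids = [f"m{j:02d}" for j in range(n_motifs)]
    n_pass = 0
    for _ in range(n_sims):
        pb = {m: int(rng.binomial(n_enhancers, presence_prob)) for m in motif_ids}
        pa = {m: int(rng.binomial(n_enhancers, presence_prob)) for m in motif_ids}
        results = enrichment.motif_enrichment(pb, n_enhancers, pa, n_enhancers, motif_ids)
        n_pass += len(enrichment.select_enriched(results))
    frac = n_pass / (n_sims * n_motifs)
    return {"n_sims": n_sims, "n_motifs": n_motifs, "fraction_selected": frac}
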