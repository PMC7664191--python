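"""Differential motif enrichment between two enhancer sets.

For each motif (cluster representative), presence is counted per enhancer —
an enhancer either contains at least one conserved predicted site or it does
not — giving counts k_a of n_a enhancers in condition A and k_b of n_b in
condition B. The enrichment statistic is the proportion ratio

    fold = (k_b / n_b) / (k_a / n_a)

and significance is a one-sided hypergeometric over-representation tail on
the pooled 2x2 margin: population N = n_a + n_b enhancers of which
K = k_a + k_b carry the motif; drawing the n_b condition-B enhancers, the
p-value is P(X >= k_b). Raw p-values are Bonferroni-corrected by the number
of representatives tested. Motifs pass at fold >= 1.5 and corrected
p <= 0.05 by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scan import BindingSite

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MotifEnrichmentResult:
    motif_id: str
    k_b: int
    n_b: int
    k_a: int
    n_a: int
    fold: float
    p_raw: float
    p_bonf: float
    passes: bool = False


def count_presence(
    sites: Iterable[BindingSite],
    enhancer_names: Iterable[str],
    motif_ids: Iterable[str] | None = None,
) -> dict[str, int]:
    """Per motif, the number of enhancers containing >=1 site.

    Multiple sites of a motif in one enhancer count once. ``enhancer_names``
    is the full enhancer set; a site referencing an enhancer outside it is an
    error. Motifs listed in ``motif_ids`` but hit nowhere get count 0.
    """
    universe = set(enhancer_names)
    hit: dict[str, set[str]] = {m: set() for m in (motif_ids or [])}
    for s in sites:
        if s.enhancer_name not in universe:
            raise KeyError(f"site references unknown enhancer {s.enhancer_name!r}")
        hit.setdefault(s.motif_id, set()).add(s.enhancer_name)
    return {m: len(enhs) for m, enhs in hit.items()}


def enrichment_fold(k_b: int, n_b: int, k_a: int, n_a: int) -> float:
    """Proportion ratio (k_b/n_b)/(k_a/n_a); +inf when k_a=0 < k_b; 1 when both 0."""
    if n_a <= 0 or n_b <= 0:
        raise ValueError("enhancer set sizes must be positive")
    if not (0 <= k_a <= n_a and 0 <= k_b <= n_b):
        raise ValueError("counts must satisfy 0 <= k <= n")
    if k_a == 0:
        return 1.0 if k_b == 0 else float("inf")
    return (k_b / n_b) / (k_a / n_a)


def hypergeom_enrichment(k_b: int, n_b: int, k_a: int, n_a: int) -> float:
    """One-sided over-representation tail P(X >= k_b).

    X ~ Hypergeometric(N = n_a + n_b, K = k_a + k_b, draws = n_b).
    """
    if not (0 <= k_a <= n_a and 0 <= k_b <= n_b):
        raise ValueError("counts must satisfy 0 <= k <= n")
    return float(stats.hypergeom.sf(k_b - 1, n_a + n_b, k_a + k_b, n_b))


def bonferroni(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Multiply each p by the number of tests, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = len(p) if m is None else m
    if m < 1:
        raise ValueError("need m >= 1 tests")
    return np.minimum(p * m, 1.0)


def motif_enrichment(
    presence_b: Mapping[str, int],
    n_b: int,
    presence_a: Mapping[str, int],
    n_a: int,
    motif_ids: Sequence[str] | None = None,
    fold_min: float = 1.5,
    p_max: float = 0.05,
) -> list[MotifEnrichmentResult]:
    """Fold and Bonferroni-corrected hypergeometric p per motif.

    The correction factor m is the number of motifs tested (the cluster
    representatives), not the raw library size.
    """
    ids = sorted(motif_ids if motif_ids is not None
                 else set(presence_b) | set(presence_a))
    raw = []
    for m_id in ids:
        k_b, k_a = presence_b.get(m_id, 0), presence_a.get(m_id, 0)
        raw.append(
            (m_id, k_b, k_a,
             enrichment_fold(k_b, n_b, k_a, n_a),
             hypergeom_enrichment(k_b, n_b, k_a, n_a))
        )
    p_bonf = bonferroni([r[4] for r in raw]) if raw else []
    results = [
        MotifEnrichmentResult(
            motif_id=m_id, k_b=k_b, n_b=n_b, k_a=k_a, n_a=n_a,
            fold=fold, p_raw=p_raw, p_bonf=float(pb),
            passes=bool(fold >= fold_min and pb <= p_max),
        )
        for (m_id, k_b, k_a, fold, p_raw), pb in zip(raw, p_bonf)
    ]
    return rank_results(results)


def rank_results(results: Iterable[MotifEnrichmentResult]) -> list[MotifEnrichmentResult]:
    """Fold descending, then corrected p ascending, then motif id."""
    return sorted(results, key=lambda r: (-r.fold, r.p_bonf, r.motif_id))


def select_enriched(
    results: Iterable[MotifEnrichmentResult],
    fold_min: float = 1.5,
    p_max: float = 0.05,
) -> list[MotifEnrichmentResult]:
    """Motifs with fold >= fold_min and Bonferroni-corrected p <= p_max."""
    kept = [r for r in results if r.fold >= fold_min and r.p_bonf <= p_max]
    return rank_results(kept)


def results_to_frame(results: Iterable[MotifEnrichmentResult]) -> pd.DataFrame:
    cols = ["motif_id", "k_b", "n_b", "k_a", "n_a", "fold", "p_raw", "p_bonf", "passes"]
    return pd.DataFrame([r.__dict__ for r in results], columns=cols)
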