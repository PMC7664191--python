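"""Collapsing redundant motifs before enrichment testing.

Binding-motif libraries are redundant: paralogous TFs and independently
curated matrices for the same factor produce near-identical PWMs whose
enrichment signals are not independent. Motifs are therefore grouped by
similarity and one representative per group is carried forward.

Similarity between two PWMs is the maximum, over all ungapped offsets with at
least four overlapping columns and over both orientations, of the Pearson
correlation between the flattened overlapping probability columns (a
Tomtom-style alignment score without the null model). Groups are formed by
single-linkage over pairs at or above the similarity threshold, and each
group's representative is the member present in the largest number of
enhancers (ties broken by lexicographic motif id).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .scan import PWM

logger = logging.getLogger(__name__)

MIN_OVERLAP = 4  # columns


@dataclass(frozen=True)
class MotifCluster:
    representative: str
    members: tuple[str, ...]
    occurrence_count: int


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return -1.0  # no signal at this alignment
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def pwm_similarity(pwm_a: PWM, pwm_b: PWM, min_overlap: int = MIN_OVERLAP) -> float:
    """Best-offset, both-orientation Pearson correlation of probability columns.

    Returns -1 when no offset yields at least ``min_overlap`` overlapping
    columns.
    """
    a = pwm_a.probs
    best = -1.0
    for b_mat in (pwm_b.probs, pwm_b.probs[::-1, ::-1]):
        la, lb = a.shape[0], b_mat.shape[0]
        for off in range(-(lb - min_overlap), la - min_overlap + 1):
            a_lo, a_hi = max(0, off), min(la, off + lb)
            if a_hi - a_lo < min_overlap:
                continue
            wa = a[a_lo:a_hi].ravel()
            wb = b_mat[a_lo - off : a_hi - off].ravel()
            best = max(best, _pearson(wa, wb))
    return best


def cluster_motifs(
    pwms: Sequence[PWM],
    occurrences: Mapping[str, int],
    sim_min: float = 0.8,
) -> list[MotifCluster]:
    """Single-linkage grouping of motifs with pairwise similarity >= sim_min.

    ``occurrences`` gives per-motif enhancer-presence counts used to pick each
    group's representative. Every input motif lands in exactly one cluster;
    the result is ordered by representative id and invariant to input order.
    """
    ids = sorted(p.motif_id for p in pwms)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate motif ids")
    by_id = {p.motif_id: p for p in pwms}
    parent = {m: m for m in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, mi in enumerate(ids):
        for mj in ids[i + 1 :]:
            if pwm_similarity(by_id[mi], by_id[mj]) >= sim_min:
                parent[find(mi)] = find(mj)

    groups: dict[str, list[str]] = {}
    for m in ids:
        groups.setdefault(find(m), []).append(m)

    clusters = []
    for members in groups.values():
        members = sorted(members)
        rep = min(members, key=lambda m: (-occurrences.get(m, 0), m))
        clusters.append(
            MotifCluster(
                representative=rep,
                members=tuple(members),
                occurrence_count=max(occurrences.get(m, 0) for m in members),
            )
        )
    clusters.sort(key=lambda c: c.representative)
    logger.info("motif redundancy: %d motifs -> %d clusters", len(ids), len(clusters))
    return clusters
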