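"""Conserved binding-site prediction in enhancer sequences.

The scanner models a transcription-factor motif as a position weight matrix
(PWM) of per-position base probabilities. A candidate site of length L at
offset ``i`` is scored with the log-odds sum

    score = sum_j log2(p[j, s[i+j]] / bg[s[i+j]])

and reported when both filters pass:

* relative match score ``(score - s_min) / (s_max - s_min) >= match_min``,
  where ``s_min``/``s_max`` are the worst and best attainable log-odds sums
  of the matrix (full-length MATCH-style similarity), and
* site significance ``P(score of a random background L-mer >= score) <=
  p_max``, computed exactly by dynamic-programming convolution of the
  per-column score distributions on a discretized score grid.

Both strands are scanned; windows containing N are skipped. A predicted site
is phylogenetically "conserved" when the orthologous sequence mapped to its
enhancer contains at least one site of the same motif at the same match
threshold on either strand; downstream enrichment consumes only conserved
sites.

Log-odds entries are quantized to a 1e-4 score grid at construction, so the
sliding-window scores, the min/max normalization and the DP distribution all
live on one exact integer lattice; p-value lookups are therefore exact for
every attainable word score. Zero probabilities are floored at 1e-4 for
scoring only (the stored probability matrix is untouched).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

logger = logging.getLogger(__name__)

BASES = "ACGT"
SCORE_EPS = 1e-4  # granularity of the log-odds score grid
_PROB_FLOOR = 1e-4  # floor for zero probabilities in log-odds only

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes A=0 C=1 G=2 T=3, anything else 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]


def uniform_background() -> np.ndarray:
    return np.full(4, 0.25)


def empirical_background(seqs: Iterable[str]) -> np.ndarray:
    """Base composition of a sequence collection (both strands, N ignored)."""
    counts = np.zeros(4)
    for seq in seqs:
        codes = encode_sequence(seq)
        counts += np.bincount(codes[codes < 4], minlength=4)
    # strand-symmetrize: scanning covers both strands
    counts = counts + counts[::-1]
    if counts.sum() == 0:
        return uniform_background()
    return counts / counts.sum()


class _Scanner:
    """Precomputed integer log-odds lattice and exact score distribution."""

    def __init__(self, probs: np.ndarray, background: np.ndarray):
        p = np.maximum(probs, _PROB_FLOOR)
        lod = np.log2(p / background)
        self.bg = background
        self.q = np.rint(lod / SCORE_EPS).astype(np.int64)  # (L, 4)
        self.qmin = int(self.q.min(axis=1).sum())
        self.qmax = int(self.q.max(axis=1).sum())
        # row 4 = N placeholder, never summed into a reported score
        self.q_ext = np.hstack([self.q, np.zeros((self.q.shape[0], 1), dtype=np.int64)])

    @cached_property
    def survival(self) -> np.ndarray:
        """P(random background word total >= qmin + i) on the integer grid."""
        dist = np.zeros(self.qmax - self.qmin + 1)
        dist[0] = 1.0  # index i tracks total - (partial minimum so far)
        for col in self.q:
            new = np.zeros_like(dist)
            base = col.min()
            for b in range(4):
                shift = int(col[b] - base)
                if shift == 0:
                    new += self.bg[b] * dist
                else:
                    new[shift:] += self.bg[b] * dist[: dist.size - shift]
            dist = new
        # after all columns: dist[i] = P(total == qmin + i)
        sf = np.cumsum(dist[::-1])[::-1]
        return np.minimum(sf, 1.0)

    def pvalue_of_int(self, qscore: int) -> float:
        if qscore <= self.qmin:
            return 1.0
        if qscore > self.qmax:
            return 0.0
        return float(self.survival[qscore - self.qmin])


@dataclass(frozen=True)
class PWM:
    """A position weight matrix over A, C, G, T.

    ``probs`` holds the (possibly pseudocounted) per-position probabilities
    used for scoring; ``raw_probs`` the pre-pseudocount probabilities on which
    information content is measured when raw counts were available.
    """

    motif_id: str
    probs: np.ndarray
    background: np.ndarray | None = None
    raw_probs: np.ndarray | None = None
    counts: np.ndarray | None = None

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError(f"PWM {self.motif_id!r}: probs must be (L, 4)")
        if np.any(probs < 0):
            raise ValueError(f"PWM {self.motif_id!r}: negative probability")
        if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError(f"PWM {self.motif_id!r}: columns must sum to 1")
        object.__setattr__(self, "probs", probs)
        bg = uniform_background() if self.background is None else np.asarray(self.background, float)
        if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-9 or np.any(bg <= 0):
            raise ValueError(f"PWM {self.motif_id!r}: invalid background")
        object.__setattr__(self, "background", bg)

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def with_background(self, background) -> "PWM":
        return replace(self, background=np.asarray(background, dtype=float))

    @cached_property
    def _scanner(self) -> _Scanner:
        return _Scanner(self.probs, self.background)

    @property
    def score_min(self) -> float:
        return self._scanner.qmin * SCORE_EPS

    @property
    def score_max(self) -> float:
        return self._scanner.qmax * SCORE_EPS

    @cached_property
    def information_content(self) -> float:
        return information_content(self)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(
            motif_id=self.motif_id,
            probs=self.probs[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
        )


def information_content(pwm: PWM) -> float:
    """Total information content in bits: sum_j (2 + sum_b p log2 p).

    Measured on the pre-pseudocount probabilities when the matrix came from
    raw counts, so a deterministic column contributes exactly 2 bits.
    """
    p = pwm.raw_probs if pwm.raw_probs is not None else pwm.probs
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return float(np.sum(2.0 + plogp.sum(axis=1)))


def filter_by_information_content(pwms: Sequence[PWM], ic_min: float = 10.0) -> list[PWM]:
    kept = [p for p in pwms if information_content(p) >= ic_min]
    logger.info("IC filter (>= %g bits): %d of %d motifs kept", ic_min, len(kept), len(pwms))
    return kept


@dataclass(frozen=True)
class BindingSite:
    """A located, scored, conservation-flagged motif occurrence."""

    motif_id: str
    enhancer_name: str
    offset: int  # leftmost position on the forward strand of the enhancer
    strand: str
    score: float
    rel_score: float
    p_value: float
    conserved: bool = False

    def as_dict(self) -> dict:
        return {
            "motif_id": self.motif_id,
            "enhancer_name": self.enhancer_name,
            "offset": self.offset,
            "strand": self.strand,
            "score": self.score,
            "rel_score": self.rel_score,
            "p_value": self.p_value,
            "conserved": self.conserved,
        }


def site_pvalue(pwm: PWM, score: float) -> float:
    """P(random background L-mer scores >= score), exact on the score grid.

    Scores outside [score_min, score_max] are clamped with a warning.
    """
    sc = pwm._scanner
    q = int(np.rint(score / SCORE_EPS))
    if q < sc.qmin or q > sc.qmax:
        logger.warning(
            "score %.4f outside attainable range [%.4f, %.4f] for %s; clamping",
            score, pwm.score_min, pwm.score_max, pwm.motif_id,
        )
        q = min(max(q, sc.qmin), sc.qmax)
    return sc.pvalue_of_int(q)


def _strand_scores(sc: _Scanner, codes: np.ndarray):
    """Integer window scores and validity mask for one strand."""
    L = sc.q.shape[0]
    n = codes.size - L + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool)
    win = sliding_window_view(codes, L)
    valid = (win != 4).all(axis=1)
    scores = sc.q_ext[np.arange(L), win].sum(axis=1)
    return scores, valid


def scan_sequence(
    pwm: PWM,
    sequence: str,
    enhancer_name: str = "",
    match_min: float = 0.8,
    p_max: float = 0.05,
) -> list[BindingSite]:
    """Report every site on either strand passing the match and p-value filters.

    Offsets index the forward strand of the scanned sequence regardless of the
    site's strand; a '-' site at offset i occupies ``sequence[i:i+L]`` whose
    reverse complement matches the motif.
    """
    if not 0 < match_min <= 1:
        raise ValueError("match_min must be in (0, 1]")
    sc = pwm._scanner
    L = pwm.length
    codes = encode_sequence(sequence)
    if codes.size < L:
        return []
    span = sc.qmax - sc.qmin
    sites: list[BindingSite] = []
    rc_codes = np.where(codes == 4, 4, 3 - codes)[::-1]
    for strand, strand_codes in (("+", codes), ("-", rc_codes)):
        scores, valid = _strand_scores(sc, strand_codes)
        if span == 0:
            rel = np.ones_like(scores, dtype=float)
        else:
            rel = (scores - sc.qmin) / span
        hit = valid & (rel >= match_min)
        for i in np.nonzero(hit)[0]:
            p = sc.pvalue_of_int(int(scores[i]))
            if p > p_max:
                continue
            offset = int(i) if strand == "+" else codes.size - L - int(i)
            sites.append(
                BindingSite(
                    motif_id=pwm.motif_id,
                    enhancer_name=enhancer_name,
                    offset=offset,
                    strand=strand,
                    score=float(scores[i]) * SCORE_EPS,
                    rel_score=float(rel[i]),
                    p_value=p,
                )
            )
    sites.sort(key=lambda s: (s.offset, s.strand))
    return sites


def scan_enhancers(
    pwms: Sequence[PWM],
    sequences: Mapping[str, str],
    match_min: float = 0.8,
    p_max: float = 0.05,
) -> list[BindingSite]:
    """Scan every motif against every enhancer sequence.

    Equivalent to per-sequence :func:`scan_sequence` calls, but vectorized:
    all sequences are concatenated with single-N separators (no window may
    span a boundary, since N windows are skipped) and the minus strand is
    scanned as the reverse-complement matrix on the forward strand.
    """
    names = list(sequences)
    if not names or not pwms:
        return []
    codes = [encode_sequence(sequences[n]) for n in names]
    lens = np.array([c.size for c in codes], dtype=np.int64)
    starts = np.zeros(len(names), dtype=np.int64)
    cat = np.full(int(lens.sum()) + len(names) - 1, 4, dtype=np.int8)
    pos = 0
    for i, c in enumerate(codes):
        starts[i] = pos
        cat[pos : pos + c.size] = c
        pos += c.size + 1

    name_rank = {n: i for i, n in enumerate(names)}
    sites: list[BindingSite] = []
    for pwm in pwms:
        sc = pwm._scanner
        L = pwm.length
        if cat.size < L:
            continue
        span = sc.qmax - sc.qmin
        rc_q = sc.q_ext.copy()
        rc_q[:, :4] = sc.q_ext[::-1, :4][:, ::-1]
        win = sliding_window_view(cat, L)
        valid = (win != 4).all(axis=1)
        motif_sites = []
        for strand, q in (("+", sc.q_ext), ("-", rc_q)):
            scores = q[np.arange(L), win].sum(axis=1)
            if span == 0:
                rel = np.ones_like(scores, dtype=float)
            else:
                rel = (scores - sc.qmin) / span
            hit = valid & (rel >= match_min)
            idx = np.nonzero(hit)[0]
            if idx.size == 0:
                continue
            pvals = sc.survival[np.minimum(scores[idx], sc.qmax) - sc.qmin]
            keep = pvals <= p_max
            idx, pvals = idx[keep], pvals[keep]
            seq_i = np.searchsorted(starts, idx, side="right") - 1
            offsets = idx - starts[seq_i]
            for g, si, off, p in zip(idx, seq_i, offsets, pvals):
                motif_sites.append(
                    BindingSite(
                        motif_id=pwm.motif_id,
                        enhancer_name=names[si],
                        offset=int(off),
                        strand=strand,
                        score=float(scores[g]) * SCORE_EPS,
                        rel_score=float(rel[g]),
                        p_value=float(p),
                    )
                )
        motif_sites.sort(key=lambda s: (name_rank[s.enhancer_name], s.offset, s.strand))
        sites.extend(motif_sites)
    return sites


def has_site(pwm: PWM, sequence: str, match_min: float) -> bool:
    """True when either strand contains >=1 window with rel_score >= match_min."""
    sc = pwm._scanner
    codes = encode_sequence(sequence)
    if codes.size < pwm.length:
        return False
    span = sc.qmax - sc.qmin
    threshold = sc.qmin + match_min * span
    for strand_codes in (codes, np.where(codes == 4, 4, 3 - codes)[::-1]):
        scores, valid = _strand_scores(sc, strand_codes)
        if np.any(valid & (scores >= threshold - 1e-9)):
            return True
    return False


def apply_conservation(
    sites: Sequence[BindingSite],
    pwms: Sequence[PWM],
    ortholog_map: Mapping[str, str],
    ortholog_seqs: Mapping[str, str],
    match_min: float = 0.8,
) -> list[BindingSite]:
    """Flag sites whose enhancer's ortholog also contains the motif.

    A site is conserved when the orthologous sequence mapped to its enhancer
    has at least one window of the same motif with rel_score >= match_min on
    either strand (presence-level phylogenetic footprinting; positional
    orthology is not required). Enhancers absent from the map are counted and
    left non-conserved.
    """
    by_id = {p.motif_id: p for p in pwms}
    cache: dict[tuple[str, str], bool] = {}
    no_ortholog: set[str] = set()
    out: list[BindingSite] = []
    for site in sites:
        if site.motif_id not in by_id:
            raise KeyError(f"site references unknown motif {site.motif_id!r}")
        orth_id = ortholog_map.get(site.enhancer_name)
        if orth_id is None:
            no_ortholog.add(site.enhancer_name)
            out.append(replace(site, conserved=False))
            continue
        if orth_id not in ortholog_seqs:
            raise KeyError(
                f"ortholog id {orth_id!r} (enhancer {site.enhancer_name!r}) "
                "missing from ortholog FASTA"
            )
        key = (site.motif_id, site.enhancer_name)
        if key not in cache:
            cache[key] = has_site(by_id[site.motif_id], ortholog_seqs[orth_id], match_min)
        out.append(replace(site, conserved=cache[key]))
    if no_ortholog:
        logger.info("%d enhancers had no ortholog mapping (treated as non-conserved)",
                    len(no_ortholog))
    return out


def conserved_only(sites: Iterable[BindingSite]) -> list[BindingSite]:
    return [s for s in sites if s.conserved]


def sites_to_frame(sites: Iterable[BindingSite]):
    import pandas as pd

    rows = [s.as_dict() for s in sites]
    cols = ["motif_id", "enhancer_name", "offset", "strand", "score",
            "rel_score", "p_value", "conserved"]
    return pd.DataFrame(rows, columns=cols)


def sites_from_frame(df) -> list[BindingSite]:
    return [
        BindingSite(
            motif_id=r.motif_id,
            enhancer_name=r.enhancer_name,
            offset=int(r.offset),
            strand=r.strand,
            score=float(r.score),
            rel_score=float(r.rel_score),
            p_value=float(r.p_value),
            conserved=bool(r.conserved),
        )
        for r in df.itertuples(index=False)
    ]
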