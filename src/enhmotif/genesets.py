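"""Functional enrichment of region sets and gene lists, and overlap tests.

Three statistics in the GREAT / over-representation-analysis family:

* region-based term enrichment — for each annotation term, the fraction
  ``p_term`` of the assignable genome (the union of all regulatory domains)
  covered by the domains of genes annotated to the term defines a binomial
  null for the number of regions whose midpoint lands in those domains:
  ``binom_p = P(Bin(n, p_term) >= k)``. A gene-based hypergeometric tail is
  computed in parallel (population = genes with domains, successes = genes
  annotated to the term, draws = distinct genes hit by the regions), so both
  the binomial and the hypergeometric readings of "fold enrichment" are
  available side by side.
* gene-list over-representation — a hypergeometric tail per term against an
  explicit gene universe (WebGestalt-style ORA).
* predicted-target vs differential-expression overlap — a hypergeometric
  tail on the overlap between a small predicted-target set and a
  differentially expressed gene set within an explicit universe.

All per-term p-values are Benjamini-Hochberg adjusted and results ranked by
FDR. Gene symbols are matched case-insensitively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats import GenomicInterval
from .regions import RegulatoryDomain

logger = logging.getLogger(__name__)

TERM_COLUMNS = [
    "term", "k_regions", "n_regions", "p_term", "fold_enrich", "binom_p",
    "binom_fdr", "gene_hits", "n_genes_term", "hyper_p", "hyper_fdr",
]


@dataclass(frozen=True)
class OverlapTestResult:
    target_set_size: int
    de_set_size: int
    universe_size: int
    overlap: int
    hyper_p: float


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _upper(genes: Iterable[str]) -> set[str]:
    return {g.upper() for g in genes}


def region_term_enrichment(
    regions: Sequence[GenomicInterval],
    domains: Sequence[RegulatoryDomain],
    term_annotation: Mapping[str, set[str]],
) -> pd.DataFrame:
    """GREAT-style per-term region enrichment (binomial + gene hypergeometric).

    Regions are anchored at their midpoint. Terms annotating no gene with a
    regulatory domain are skipped with a warning. Results ranked by binomial
    FDR, then raw p, then term.
    """
    dom_by_gene: dict[str, list[RegulatoryDomain]] = {}
    for d in domains:
        dom_by_gene.setdefault(d.gene_id.upper(), []).append(d)
    assignable = sum(d.width for d in domains)
    if assignable <= 0:
        raise ValueError("regulatory domains cover zero bases")

    # midpoint membership per region -> hit genes
    by_chrom: dict[str, list[RegulatoryDomain]] = {}
    for d in domains:
        by_chrom.setdefault(d.chrom, []).append(d)
    for ds in by_chrom.values():
        ds.sort(key=lambda d: d.start)
    region_genes: list[str | None] = []
    for r in regions:
        hit = None
        for d in by_chrom.get(r.chrom, []):
            if d.contains(r.midpoint):
                hit = d.gene_id.upper()
                break
        region_genes.append(hit)
    n_regions = sum(g is not None for g in region_genes)
    hit_genes = {g for g in region_genes if g is not None}
    genes_with_domains = set(dom_by_gene)

    rows = []
    for term in sorted(term_annotation):
        term_genes = _upper(term_annotation[term]) & genes_with_domains
        if not term_genes:
            logger.warning("term %r annotates no gene with a domain; skipped", term)
            continue
        term_bases = sum(d.width for g in term_genes for d in dom_by_gene[g])
        p_term = term_bases / assignable
        k = sum(g in term_genes for g in region_genes if g is not None)
        binom_p = float(stats.binom.sf(k - 1, n_regions, p_term)) if n_regions else 1.0
        gene_hits = len(hit_genes & term_genes)
        hyper_p = float(
            stats.hypergeom.sf(
                gene_hits - 1, len(genes_with_domains), len(term_genes), len(hit_genes)
            )
        )
        fold = (k / (n_regions * p_term)) if n_regions and p_term > 0 else 0.0
        rows.append(
            {"term": term, "k_regions": k, "n_regions": n_regions, "p_term": p_term,
             "fold_enrich": fold, "binom_p": binom_p, "gene_hits": gene_hits,
             "n_genes_term": len(term_genes), "hyper_p": hyper_p}
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=TERM_COLUMNS)
    df["binom_fdr"] = bh_fdr(df["binom_p"].to_numpy())
    df["hyper_fdr"] = bh_fdr(df["hyper_p"].to_numpy())
    df = df.sort_values(["binom_fdr", "binom_p", "term"], kind="mergesort")
    return df[TERM_COLUMNS].reset_index(drop=True)


def gene_list_ora(
    gene_list: Iterable[str],
    universe: Iterable[str],
    term_annotation: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Hypergeometric over-representation of each term in a gene list.

    Genes outside the universe are dropped (count logged). Fold is the ratio
    of the term's frequency in the list to its frequency in the universe.
    Ranked by FDR, then raw p, then term.
    """
    uni = _upper(universe)
    if not uni:
        raise ValueError("empty gene universe")
    listed = _upper(gene_list)
    dropped = len(listed - uni)
    if dropped:
        logger.info("%d listed genes absent from universe dropped", dropped)
    listed &= uni
    rows = []
    for term in sorted(term_annotation):
        term_genes = _upper(term_annotation[term]) & uni
        k = len(listed & term_genes)
        p = float(stats.hypergeom.sf(k - 1, len(uni), len(term_genes), len(listed)))
        if listed and term_genes:
            fold = (k / len(listed)) / (len(term_genes) / len(uni))
        else:
            fold = 0.0
        rows.append(
            {"term": term, "overlap": k, "list_size": len(listed),
             "term_size": len(term_genes), "universe_size": len(uni),
             "fold_enrich": fold, "hyper_p": p}
        )
    df = pd.DataFrame(
        rows, columns=["term", "overlap", "list_size", "term_size",
                       "universe_size", "fold_enrich", "hyper_p"]
    )
    if df.empty:
        df["fdr"] = []
        return df
    df["fdr"] = bh_fdr(df["hyper_p"].to_numpy())
    return df.sort_values(["fdr", "hyper_p", "term"], kind="mergesort").reset_index(drop=True)


def apply_term_filters(
    results: pd.DataFrame,
    fold_min: float = 2.0,
    fdr_max: float = 0.05,
    min_genes: int = 5,
    top: int | None = None,
    statistic: str = "hyper",
) -> pd.DataFrame:
    """Filter term results on fold, FDR and associated-gene count (inclusive).

    ``statistic`` selects which tail drives the FDR cutoff for region-based
    results ("hyper" matches the hypergeometric-fold reading; "binom" the
    native binomial). ``top`` truncates to the first N terms after filtering.
    """
    if results.empty:
        return results
    df = results
    if "fdr" in df.columns:  # gene-list ORA results
        fdr_col, gene_col = "fdr", "overlap"
    else:
        fdr_col = "hyper_fdr" if statistic == "hyper" else "binom_fdr"
        gene_col = "gene_hits"
    keep = (
        (df["fold_enrich"] >= fold_min)
        & (df[fdr_col] <= fdr_max)
        & (df[gene_col] >= min_genes)
    )
    out = df[keep].reset_index(drop=True)
    if top is not None:
        out = out.head(top)
    return out


def target_de_overlap(
    target_genes: Iterable[str],
    de_genes: Iterable[str],
    universe: Iterable[str],
) -> OverlapTestResult:
    """Hypergeometric tail for the overlap of predicted targets with a DE set.

    Population = universe, successes = DE genes, draws = target genes,
    p = P(X >= overlap). The universe is an explicit parameter; the natural
    default is the set of genes tested for differential expression.
    """
    uni = _upper(universe)
    targets = _upper(target_genes) & uni
    de = _upper(de_genes) & uni
    if not targets:
        logger.warning("empty target set; overlap p-value is 1")
        return OverlapTestResult(0, len(de), len(uni), 0, 1.0)
    overlap = len(targets & de)
    p = float(stats.hypergeom.sf(overlap - 1, len(uni), len(de), len(targets)))
    return OverlapTestResult(len(targets), len(de), len(uni), overlap, p)


def de_direction_sets(
    de_table: pd.DataFrame,
    fold_min: float = 1.5,
    padj_max: float = 0.05,
) -> tuple[set[str], set[str]]:
    """(upregulated, downregulated) gene sets from a log2fc/padj DE table.

    A gene is up when 2**log2fc >= fold_min, down when 2**(-log2fc) >=
    fold_min, in both cases requiring padj <= padj_max.
    """
    lfc_min = np.log2(fold_min)
    sig = de_table["padj"] <= padj_max
    up = set(de_table.loc[sig & (de_table["log2fc"] >= lfc_min), "gene"].str.upper())
    down = set(de_table.loc[sig & (de_table["log2fc"] <= -lfc_min), "gene"].str.upper())
    return up, down
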