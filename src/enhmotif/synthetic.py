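"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the statistical structure of a two-timepoint placenta
study: two condition-specific enhancer sets in which each motif occurs with a
controlled per-enhancer probability, orthologous copies of every enhancer in
which planted instances survive with a controlled conservation rate, a
two-condition expression table with planted upregulated genes and a TF
subset, a knockdown differential-expression table with a designated target
set overlapping the downregulated genes at a configured rate, and a gene-set
collection with one planted enriched term.

Design notes:

* The default motif library is a fixed set of ten 16-bp matrices (dominant
  base probability 0.9 per column, ~22 bits of information content,
  pairwise-dissimilar by construction), generated once from an internal seed
  so that the library is a constant of the benchmark while ``seed`` drives
  only the data noise. Sixteen informative columns keep the chance of a
  spurious match at the 0.8 relative-score threshold near 4e-6 per window,
  so presence calls are dominated by planted instances rather than
  background hits.
* Planted instances are sampled column-wise from the PWM (so their relative
  scores vary realistically); ``consensus_only`` plants exact consensus
  words for exact-recall tests.
* A conservation failure rerandomizes only the instance window of the
  ortholog copy, keeping flanks identical, so the conservation filter is
  isolated from alignment effects.

Every output is a deterministic function of the configuration (integer-state
generator, no hash-order dependence).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from . import formats
from .formats import GenomicInterval
from .scan import BASES, PWM
from .redundancy import pwm_similarity

logger = logging.getLogger(__name__)

_LIBRARY_SEED = 987654321  # fixed: the default library is a benchmark constant


@dataclass(frozen=True)
class MotifSpec:
    """One motif with its per-set planting and conservation probabilities."""

    pwm: PWM
    plant_prob_a: float
    plant_prob_b: float
    conservation_prob: float

    def __post_init__(self):
        for p in (self.plant_prob_a, self.plant_prob_b, self.conservation_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")


def random_pwm(rng: np.random.Generator, motif_id: str, length: int = 16,
               dominant: float = 0.9) -> PWM:
    """A PWM with one dominant base per column and the rest uniform."""
    probs = np.full((length, 4), (1 - dominant) / 3)
    cons = rng.integers(0, 4, size=length)
    probs[np.arange(length), cons] = dominant
    return PWM(motif_id=motif_id, probs=probs)


@lru_cache(maxsize=None)
def default_motif_library(n_motifs: int = 10, length: int = 16,
                          dominant: float = 0.9, max_similarity: float = 0.7,
                          seed: int = _LIBRARY_SEED) -> list[PWM]:
    """Fixed benchmark library of mutually dissimilar informative motifs.

    Memoized: identical parameters return the same PWM objects, so their
    precomputed score distributions are shared across replicates.
    """
    rng = np.random.default_rng(seed)
    pwms: list[PWM] = []
    while len(pwms) < n_motifs:
        cand = random_pwm(rng, f"TF{len(pwms) + 1:02d}", length, dominant)
        if all(pwm_similarity(cand, p) < max_similarity for p in pwms):
            pwms.append(cand)
    return pwms


@lru_cache(maxsize=None)
def default_motif_specs(planted_prob_a: float = 0.05, planted_prob_b: float = 0.30,
                        null_prob: float = 0.05, conservation_prob: float = 0.9,
                        n_motifs: int = 10) -> tuple[MotifSpec, ...]:
    """One differentially planted motif (the first) among null motifs.

    The planted motif occurs in 30% of condition-B enhancers versus 5% of
    condition-A enhancers (true proportion ratio 6.0); null motifs occur at
    5% in both sets. Planted instances are retained in the ortholog copy at
    rate 0.9.
    """
    pwms = default_motif_library(n_motifs=n_motifs)
    specs = [MotifSpec(pwms[0], planted_prob_a, planted_prob_b, conservation_prob)]
    specs += [MotifSpec(p, null_prob, null_prob, conservation_prob) for p in pwms[1:]]
    return tuple(specs)


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    n_enhancers_a: int = 300
    n_enhancers_b: int = 300
    enhancer_length: int = 200
    motif_specs: tuple[MotifSpec, ...] = field(default_factory=default_motif_specs)
    gc_content: float = 0.5
    consensus_only: bool = False
    frac_unmapped: float = 0.0
    # expression table
    n_genes: int = 2000
    n_tfs: int = 200
    frac_upregulated: float = 0.1
    de_effect: float = 2.0  # minimum planted log2 fold separation from cutoffs
    # knockdown DE table
    de_frac_down: float = 0.2
    de_frac_up: float = 0.2
    n_targets: int = 8
    target_overlap_rate: float | None = 0.5  # None: targets drawn independently
    # gene-set benchmark
    n_terms: int = 20
    term_size: int = 100
    ora_list_size: int = 100
    ora_odds_ratio: float = 5.0

    def __post_init__(self):
        for p in (self.gc_content, self.frac_unmapped, self.frac_upregulated,
                  self.de_frac_down, self.de_frac_up, self.target_overlap_rate):
            if p is not None and not 0 <= p <= 1:
                raise ValueError("fractions must be in [0, 1]")
        max_len = max((s.pwm.length for s in self.motif_specs), default=0)
        if self.motif_specs and self.enhancer_length < max_len:
            raise ValueError(
                f"enhancer_length {self.enhancer_length} < longest motif {max_len}"
            )


@dataclass
class SyntheticEnhancers:
    intervals_a: list[GenomicInterval]
    intervals_b: list[GenomicInterval]
    sequences: dict[str, str]  # enhancer name -> sequence (both sets)
    ortholog_seqs: dict[str, str]
    ortholog_map: dict[str, str]
    truth: pd.DataFrame  # one row per planted instance


def gene_universe(config: SyntheticConfig) -> list[str]:
    """The shared gene namespace of every synthetic table.

    The first ``n_tfs`` genes are transcription factors whose symbols match
    the motif library ids case-insensitively (``Tf01`` <-> motif ``TF01``);
    the remainder are ordinary genes. Expression, knockdown-DE, TSS and
    gene-set tables all draw from this one namespace so the pipeline stages
    interconnect.
    """
    genes = [f"Tf{i + 1:02d}" for i in range(config.n_tfs)]
    genes += [f"Gene{i + 1:04d}" for i in range(config.n_genes - config.n_tfs)]
    return genes


def _background_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _sample_instance(rng: np.random.Generator, pwm: PWM, consensus_only: bool) -> str:
    if consensus_only:
        return pwm.consensus
    cols = [rng.choice(4, p=pwm.probs[j]) for j in range(pwm.length)]
    return "".join(BASES[c] for c in cols)


def _rc(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def generate_enhancer_sets(config: SyntheticConfig) -> SyntheticEnhancers:
    """Two enhancer sets with planted motif instances and ortholog copies.

    Each enhancer independently receives at most one instance of each motif
    with its set's plant probability, at a uniform random offset and strand,
    rejection-placed so instances never overlap. The ortholog copy of an
    enhancer is identical except that each planted instance window is
    rerandomized with probability 1 - conservation_prob. The truth table
    records every plant (set, enhancer, motif, offset, strand, instance,
    conserved).
    """
    rng = np.random.default_rng(config.seed)
    bg = _background_probs(config.gc_content)
    seqs: dict[str, str] = {}
    ortho_seqs: dict[str, str] = {}
    ortho_map: dict[str, str] = {}
    intervals: dict[str, list[GenomicInterval]] = {"a": [], "b": []}
    truth_rows = []
    length = config.enhancer_length
    gap = 100

    for set_label, n_enh in (("a", config.n_enhancers_a), ("b", config.n_enhancers_b)):
        chrom = f"chr{set_label.upper()}"
        for i in range(n_enh):
            name = f"enh_{set_label}_{i + 1:04d}"
            start = gap + i * (length + gap)
            intervals[set_label].append(GenomicInterval(chrom, start, start + length, name))
            seq = list(rng.choice(list(BASES), size=length, p=bg))
            occupied = np.zeros(length, dtype=bool)
            plants = []
            for spec in config.motif_specs:
                prob = spec.plant_prob_a if set_label == "a" else spec.plant_prob_b
                if rng.random() >= prob:
                    continue
                L = spec.pwm.length
                offset = None
                for _ in range(200):  # rejection-place without overlap
                    cand = int(rng.integers(0, length - L + 1))
                    if not occupied[cand : cand + L].any():
                        offset = cand
                        break
                if offset is None:
                    logger.warning("no free slot for %s in %s; plant skipped",
                                   spec.pwm.motif_id, name)
                    continue
                occupied[offset : offset + L] = True
                instance = _sample_instance(rng, spec.pwm, config.consensus_only)
                strand = "+" if rng.random() < 0.5 else "-"
                seq[offset : offset + L] = list(instance if strand == "+" else _rc(instance))
                plants.append((spec, offset, strand, instance))
            seqs[name] = "".join(seq)

            orth = list(seqs[name])
            mapped = rng.random() >= config.frac_unmapped
            for spec, offset, strand, instance in plants:
                conserved = bool(rng.random() < spec.conservation_prob)
                if not conserved:
                    L = spec.pwm.length
                    orth[offset : offset + L] = list(rng.choice(list(BASES), size=L, p=bg))
                truth_rows.append(
                    {"set": set_label, "enhancer_name": name,
                     "motif_id": spec.pwm.motif_id, "offset": offset,
                     "strand": strand, "instance": instance,
                     "conserved": conserved and mapped}
                )
            if mapped:
                orth_id = f"orth_{name}"
                ortho_map[name] = orth_id
                ortho_seqs[orth_id] = "".join(orth)

    truth = pd.DataFrame(
        truth_rows,
        columns=["set", "enhancer_name", "motif_id", "offset", "strand",
                 "instance", "conserved"],
    )
    return SyntheticEnhancers(
        intervals_a=intervals["a"], intervals_b=intervals["b"],
        sequences=seqs, ortholog_seqs=ortho_seqs, ortholog_map=ortho_map,
        truth=truth,
    )


def generate_expression_table(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame, set[str]]:
    """Expression table, per-gene truth labels, and the TF catalog.

    The first ``n_tfs`` genes are transcription factors named after the motif
    library ids (``Tf01`` matches motif ``TF01``, case-insensitively), so the
    TFs of all library motifs exist in the table. Planted upregulated genes
    are separated from the filter thresholds (FPKM_b >= 15, fold >= 4,
    q <= 0.04); null genes have fold capped below 2 so recovery is exact.
    """
    rng = np.random.default_rng(config.seed + 1)
    n_motifs = len(config.motif_specs)
    if config.n_tfs < n_motifs:
        raise ValueError("n_tfs must cover the motif library")
    gene_ids = gene_universe(config)

    n_up = int(round(config.frac_upregulated * config.n_genes))
    n_up = max(n_up, n_motifs)
    # motif TFs are always upregulated: the scanned motifs belong to
    # upregulated TFs, as in the real workflow
    forced = list(range(n_motifs))
    others = np.arange(n_motifs, config.n_genes)
    extra = rng.choice(others, size=n_up - n_motifs, replace=False)
    up_idx = np.zeros(config.n_genes, dtype=bool)
    up_idx[forced] = True
    up_idx[extra] = True

    min_fold = 2.0 ** config.de_effect  # 4-fold at the default effect size
    fold = np.where(
        up_idx,
        rng.uniform(min_fold, 60.0, size=config.n_genes),
        np.clip(rng.lognormal(0.0, 0.25, size=config.n_genes), 0.3, 1.9),
    )
    fpkm_b = np.where(
        up_idx,
        rng.uniform(15.0, 500.0, size=config.n_genes),
        rng.lognormal(1.5, 1.5, size=config.n_genes),
    )
    fpkm_a = fpkm_b / fold
    q = np.where(
        up_idx,
        rng.uniform(0.0, 0.04, size=config.n_genes),
        rng.uniform(0.0, 1.0, size=config.n_genes),
    )
    table = pd.DataFrame(
        {"gene_id": gene_ids, "fpkm_a": fpkm_a, "fpkm_b": fpkm_b,
         "fold": fold, "q_value": q}
    )
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "is_upregulated": up_idx,
         "is_tf": [i < config.n_tfs for i in range(config.n_genes)]}
    )
    catalog = {g.upper() for g in gene_ids[: config.n_tfs]}
    return table, truth, catalog


def generate_de_table(config: SyntheticConfig) -> tuple[pd.DataFrame, dict]:
    """Knockdown DE table (gene, log2fc, padj) with a designated target set.

    ``round(target_overlap_rate * n_targets)`` targets are forced into the
    downregulated set; the remaining targets are forced non-significant. The
    truth dict records the target, up and down sets.
    """
    rng = np.random.default_rng(config.seed + 2)
    genes = gene_universe(config)
    n = config.n_genes
    n_down = int(round(config.de_frac_down * n))
    n_up = int(round(config.de_frac_up * n))
    perm = rng.permutation(n)
    down_idx, up_idx = perm[:n_down], perm[n_down : n_down + n_up]

    log2fc = rng.normal(0.0, 0.15, size=n).clip(-0.55, 0.55)
    padj = rng.uniform(0.0, 1.0, size=n)
    log2fc[down_idx] = -rng.uniform(0.8, 3.0, size=n_down)
    log2fc[up_idx] = rng.uniform(0.8, 3.0, size=n_up)
    padj[down_idx] = rng.uniform(0.0, 0.04, size=n_down)
    padj[up_idx] = rng.uniform(0.0, 0.04, size=n_up)

    if config.target_overlap_rate is None:
        # background: targets independent of the DE structure
        targets = list(rng.choice(n, size=config.n_targets, replace=False))
    else:
        n_in = int(round(config.target_overlap_rate * config.n_targets))
        null_idx = perm[n_down + n_up :]
        targets = list(rng.choice(down_idx, size=n_in, replace=False))
        targets += list(rng.choice(null_idx, size=config.n_targets - n_in, replace=False))
    table = pd.DataFrame({"gene": genes, "log2fc": log2fc, "padj": padj})
    truth = {
        "targets": {genes[i] for i in targets},
        "down": {genes[i] for i in down_idx},
        "up": {genes[i] for i in up_idx},
    }
    return table, truth


def generate_gene_set_benchmark(config: SyntheticConfig) -> tuple[dict[str, set[str]], list[str], list[str], str]:
    """(terms, universe, gene list, planted term) for the ORA benchmark.

    Terms draw ``term_size`` genes uniformly from the universe; the gene list
    draws ``ora_list_size`` genes without replacement with sampling weight
    ``ora_odds_ratio`` for members of the planted term (the first), odds 1
    for the rest.
    """
    rng = np.random.default_rng(config.seed + 3)
    universe = gene_universe(config)
    terms: dict[str, set[str]] = {}
    for t in range(config.n_terms):
        members = rng.choice(config.n_genes, size=config.term_size, replace=False)
        terms[f"TERM_{t + 1:03d}"] = {universe[i] for i in members}
    planted = "TERM_001"
    weights = np.ones(config.n_genes)
    planted_idx = [i for i, g in enumerate(universe) if g in terms[planted]]
    weights[planted_idx] = config.ora_odds_ratio
    weights /= weights.sum()
    chosen = rng.choice(config.n_genes, size=config.ora_list_size, replace=False, p=weights)
    gene_list = [universe[i] for i in chosen]
    return terms, universe, gene_list, planted


def generate_tss_table(config: SyntheticConfig, spacing: int | None = None) -> pd.DataFrame:
    """Canonical TSSs tiling the synthetic condition-B chromosome.

    One gene every other enhancer slot keeps nearest-gene assignment
    non-trivial (regions split between flanking genes).
    """
    rng = np.random.default_rng(config.seed + 4)
    slot = config.enhancer_length + 100
    spacing = spacing or 2 * slot
    n_tss = max(2, (config.n_enhancers_b * slot) // spacing)
    genes = [g for g in gene_universe(config) if not g.startswith("Tf")]
    if n_tss > len(genes):
        raise ValueError("not enough genes in the universe for the TSS table")
    rows = []
    for i in range(n_tss):
        jitter = int(rng.integers(-slot // 4, slot // 4 + 1))
        rows.append(
            {"gene_id": genes[i], "chrom": "chrB",
             "tss": max(0, i * spacing + spacing // 2 + jitter), "strand": "+"}
        )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])


def generate_all(config: SyntheticConfig, outdir) -> dict[str, Path]:
    """Write every pipeline input (plus truth tables) to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    enh = generate_enhancer_sets(config)
    paths["enhancers_a"] = outdir / "enhancers_a.bed"
    paths["enhancers_b"] = outdir / "enhancers_b.bed"
    formats.write_bed(enh.intervals_a, paths["enhancers_a"])
    formats.write_bed(enh.intervals_b, paths["enhancers_b"])
    paths["sequences"] = outdir / "enhancers.fa"
    formats.write_fasta(enh.sequences, paths["sequences"])
    paths["ortholog_seqs"] = outdir / "orthologs.fa"
    formats.write_fasta(enh.ortholog_seqs, paths["ortholog_seqs"])
    paths["ortholog_map"] = outdir / "ortholog_map.tsv"
    formats.write_ortholog_map(enh.ortholog_map, paths["ortholog_map"])
    paths["truth_sites"] = outdir / "truth_sites.tsv"
    formats.write_results(enh.truth, paths["truth_sites"])

    paths["motifs"] = outdir / "motifs.meme"
    formats.write_meme_minimal([s.pwm for s in config.motif_specs], paths["motifs"])

    expr, expr_truth, catalog = generate_expression_table(config)
    paths["expression"] = outdir / "expression.tsv"
    formats.write_results(expr, paths["expression"])
    paths["truth_expression"] = outdir / "truth_expression.tsv"
    formats.write_results(expr_truth, paths["truth_expression"])
    paths["tf_catalog"] = outdir / "tf_catalog.txt"
    paths["tf_catalog"].write_text("\n".join(sorted(catalog)) + "\n")

    de, de_truth = generate_de_table(config)
    paths["de_table"] = outdir / "de.tsv"
    formats.write_results(de, paths["de_table"])
    paths["targets"] = outdir / "targets.txt"
    paths["targets"].write_text("\n".join(sorted(de_truth["targets"])) + "\n")

    terms, universe, gene_list, planted = generate_gene_set_benchmark(config)
    paths["gmt"] = outdir / "terms.gmt"
    formats.write_gmt(terms, paths["gmt"])
    paths["universe"] = outdir / "universe.txt"
    paths["universe"].write_text("\n".join(universe) + "\n")
    paths["gene_list"] = outdir / "gene_list.txt"
    paths["gene_list"].write_text("\n".join(gene_list) + "\n")
    (outdir / "truth_planted_term.txt").write_text(planted + "\n")

    tss = generate_tss_table(config)
    paths["tss"] = outdir / "tss.tsv"
    formats.write_results(tss, paths["tss"])
    logger.info("synthetic inputs written to %s", outdir)
    return paths
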