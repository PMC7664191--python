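from math import comb

import numpy as np
import pandas as pd
import pytest

from enhmotif.formats import GenomicInterval
from enhmotif.genesets import (
    apply_term_filters,
    bh_fdr,
    de_direction_sets,
    gene_list_ora,
    region_term_enrichment,
    target_de_overlap,
)
from enhmotif.regions import RegulatoryDomain
from enhmotif.synthetic import SyntheticConfig, generate_gene_set_benchmark


def binom_tail_oracle(k, n, p):
    return sum(comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))


def hyper_tail_oracle(k, N, K, n):
    return sum(comb(K, x) * comb(N - K, n - x) for x in range(k, min(K, n) + 1)) / comb(N, n)


def make_domains(n_genes, width=100):
    return [
        RegulatoryDomain(f"G{i}", "chr1", i * width, (i + 1) * width, i * width + 1)
        for i in range(n_genes)
    ]


def regions_at(midpoints):
    return [
        GenomicInterval("chr1", m - 10, m + 10, f"r{j}") for j, m in enumerate(midpoints)
    ]


class TestRegionTermEnrichment:
    def test_small_case_matches_binomial_summation(self):
        # 4 genes with equal domains; term covers 1 gene -> p_term = 0.25;
        # 6 regions of which 4 hit the term gene's domain
        domains = make_domains(4)
        regions = regions_at([50, 50, 50, 50, 150, 250])
        df = region_term_enrichment(regions, domains, {"T": {"G0"}})
        row = df.iloc[0]
        assert row["p_term"] == pytest.approx(0.25)
        assert row["k_regions"] == 4 and row["n_regions"] == 6
        assert row["binom_p"] == pytest.approx(binom_tail_oracle(4, 6, 0.25), abs=1e-12)
        assert row["fold_enrich"] == pytest.approx(4 / (6 * 0.25))

    def test_term_covering_whole_assignable_genome(self):
        domains = make_domains(3)
        regions = regions_at([50, 150])
        df = region_term_enrichment(regions, domains, {"ALL": {"G0", "G1", "G2"}})
        row = df.iloc[0]
        assert row["p_term"] == pytest.approx(1.0)
        assert row["binom_p"] == pytest.approx(1.0)
        assert row["fold_enrich"] <= 1.0 + 1e-12

    def test_no_hits_gives_p_one(self):
        domains = make_domains(4)
        df = region_term_enrichment(regions_at([150, 250]), domains, {"T": {"G0"}})
        assert df.iloc[0]["k_regions"] == 0
        assert df.iloc[0]["binom_p"] == pytest.approx(1.0)

    def test_term_without_domain_genes_skipped(self, caplog):
        domains = make_domains(2)
        with caplog.at_level("WARNING"):
            df = region_term_enrichment(regions_at([50]), domains, {"T": {"NOPE"}})
        assert df.empty

    def test_gene_hypergeometric_column(self):
        domains = make_domains(6)
        # regions hit genes G0, G1, G2; term = {G0, G1, G5}
        df = region_term_enrichment(
            regions_at([50, 150, 250]), domains, {"T": {"G0", "G1", "G5"}}
        )
        row = df.iloc[0]
        assert row["gene_hits"] == 2
        assert row["hyper_p"] == pytest.approx(hyper_tail_oracle(2, 6, 3, 3), abs=1e-12)


class TestGeneListOra:
    TERMS = {"T1": {"A", "B", "C", "D", "E"}}
    UNIVERSE = list("ABCDEFGHIJ")

    def test_known_case_is_55_over_210(self):
        # universe 10, term 5, list 4, overlap 3
        df = gene_list_ora(["A", "B", "C", "F"], self.UNIVERSE, self.TERMS)
        assert df.iloc[0]["hyper_p"] == pytest.approx(55 / 210, abs=1e-12)
        assert df.iloc[0]["fold_enrich"] == pytest.approx((3 / 4) / (5 / 10))

    def test_list_equal_to_universe_gives_p_one_fold_one(self):
        df = gene_list_ora(self.UNIVERSE, self.UNIVERSE, self.TERMS)
        assert df.iloc[0]["hyper_p"] == pytest.approx(1.0)
        assert df.iloc[0]["fold_enrich"] == pytest.approx(1.0)

    def test_disjoint_list_gives_p_one(self):
        df = gene_list_ora(["F", "G"], self.UNIVERSE, self.TERMS)
        assert df.iloc[0]["hyper_p"] == pytest.approx(1.0)

    def test_genes_outside_universe_dropped(self):
        df = gene_list_ora(["A", "ZZZ"], self.UNIVERSE, self.TERMS)
        assert df.iloc[0]["list_size"] == 1

    def test_matching_is_case_insensitive(self):
        df = gene_list_ora(["a", "b", "c"], self.UNIVERSE, self.TERMS)
        assert df.iloc[0]["overlap"] == 3

    def test_planted_term_ranks_first(self):
        """A term enriched in the list at odds ratio 5 tops the FDR ranking
        in nearly all replicates."""
        wins = 0
        n_reps = 60
        for seed in range(n_reps):
            config = SyntheticConfig(seed=seed, motif_specs=())
            terms, universe, gene_list, planted = generate_gene_set_benchmark(config)
            df = gene_list_ora(gene_list, universe, terms)
            wins += df.iloc[0]["term"] == planted
        assert wins >= 0.95 * n_reps


class TestApplyTermFilters:
    def ora_frame(self):
        return pd.DataFrame(
            {"term": ["few", "edge", "weak", "lax"],
             "overlap": [4, 5, 9, 9],
             "fold_enrich": [9.0, 2.0, 1.9, 5.0],
             "hyper_p": [1e-4] * 4,
             "fdr": [1e-3, 0.05, 1e-3, 0.051]}
        )

    def test_all_three_filters_inclusive(self):
        out = apply_term_filters(self.ora_frame())
        # 'few' fails min_genes=5, 'weak' fails fold>=2, 'lax' fails fdr<=0.05
        assert out["term"].tolist() == ["edge"]

    def test_top_n_truncation(self):
        df = self.ora_frame()
        df["fold_enrich"] = 5.0
        df["overlap"] = 10
        df["fdr"] = 0.01
        assert len(apply_term_filters(df, top=2)) == 2

    def test_empty_frame_passes_through(self):
        empty = self.ora_frame().iloc[0:0]
        assert apply_term_filters(empty).empty


class TestTargetDeOverlap:
    def test_zero_overlap_gives_p_one(self):
        res = target_de_overlap(["A"], ["B"], ["A", "B", "C"])
        assert res.hyper_p == pytest.approx(1.0)

    def test_known_case_is_55_over_210(self):
        universe = [f"g{i}" for i in range(10)]
        res = target_de_overlap(universe[:3] + ["g9"], universe[:5], universe)
        assert (res.target_set_size, res.de_set_size, res.overlap) == (4, 5, 3)
        assert res.hyper_p == pytest.approx(55 / 210, abs=1e-12)

    def test_empty_targets_warn_and_p_one(self, caplog):
        with caplog.at_level("WARNING"):
            res = target_de_overlap([], ["A"], ["A", "B"])
        assert res.hyper_p == 1.0
        assert "empty target set" in caplog.text

    def test_universe_is_an_explicit_parameter(self):
        """The same overlap gets more significant as the universe grows,
        which is why the universe must be stated, never implied."""
        targets, de = [f"t{i}" for i in range(8)], [f"t{i}" for i in range(4)]
        small = target_de_overlap(targets, de, targets + [f"u{i}" for i in range(100)])
        big = target_de_overlap(targets, de, targets + [f"u{i}" for i in range(5000)])
        assert big.hyper_p < small.hyper_p


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]).tolist() == [0.2]

    def test_stepup_hand_computation(self):
        assert bh_fdr([0.01, 0.02, 0.03]).tolist() == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones_stay_one(self):
        assert bh_fdr([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_adjusted_at_least_raw_and_permutation_stable(self, rng):
        p = rng.uniform(size=40)
        adj = bh_fdr(p)
        assert np.all(adj >= p - 1e-15)
        perm = rng.permutation(40)
        assert sorted(bh_fdr(p[perm])) == pytest.approx(sorted(adj))


class TestDeDirectionSets:
    def test_directional_thresholds(self):
        df = pd.DataFrame(
            {"gene": ["up", "down", "weak", "unsig"],
             "log2fc": [1.0, -1.0, 0.3, -2.0],
             "padj": [0.01, 0.01, 0.01, 0.5]}
        )
        up, down = de_direction_sets(df)
        assert up == {"UP"} and down == {"DOWN"}
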