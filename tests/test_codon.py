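"""Codon frequencies, Mann-Whitney comparisons, ranking and enrichment."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hacseq.codon import (
    SENSE_CODONS,
    codon_change_summary,
    codon_frequencies,
    compare_codon_usage,
    cumulative_frequency_table,
    exact_mannwhitney_p,
    geneset_enrichment,
    rank_genes_by_codon,
)
from hacseq.ribo import TranscriptModel


def brute_force_mw_p(x, y):
    """Oracle: enumerate every group assignment with itertools.combinations."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    nx = len(x)
    n = len(pooled)
    mu = nx * (n - nx) / 2

    def u_of(idx):
        return ranks[list(idx)].sum() - nx * (nx + 1) / 2

    u_obs = u_of(range(nx))
    dev = abs(u_obs - mu)
    hits = sum(
        1
        for combo in itertools.combinations(range(n), nx)
        if abs(u_of(combo) - mu) >= dev - 1e-9
    )
    return hits / comb(n, nx)


def _gene(gene_id, codons):
    return TranscriptModel(gene_id, f"{gene_id}.t", "".join(codons), 0)


class TestCodonFrequencies:
    def test_hand_counted_fractions_exclude_stop(self):
        usage = codon_frequencies([_gene("g1", ["ATG", "AGT", "AGT", "TAA"])])
        assert usage.loc["g1", "AGT"] == pytest.approx(2 / 3)
        assert usage.loc["g1", "ATG"] == pytest.approx(1 / 3)
        assert usage.shape[1] == 61

    def test_single_codon_gene(self):
        usage = codon_frequencies([_gene("g1", ["GCT"] * 10 + ["TAA"])])
        assert usage.loc["g1", "GCT"] == 1.0

    def test_rows_sum_to_one(self, small_cds_models):
        models, _ = small_cds_models
        usage = codon_frequencies(models)
        assert np.allclose(usage.sum(axis=1), 1.0, atol=1e-9)

    def test_duplicate_gene_counted_once(self):
        g = _gene("g1", ["ATG", "AGT", "TAA"])
        usage = codon_frequencies([g, g])
        assert len(usage) == 1

    def test_internal_stop_warned_but_retained(self, caplog):
        with caplog.at_level("WARNING"):
            usage = codon_frequencies([_gene("g1", ["ATG", "TGA", "AGT", "TAA"])])
        assert "g1" in usage.index
        assert any("internal stop" in m for m in caplog.messages)


class TestExactMannWhitney:
    def test_separated_groups_p_one_tenth(self):
        # {1,2,3} vs {4,5,6}: U = 0; 2 of the C(6,3)=20 arrangements as extreme
        assert exact_mannwhitney_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_values_p_one(self):
        assert exact_mannwhitney_p([5, 5, 5], [5, 5, 5]) == 1.0

    def test_matches_scipy_exact_when_tie_free(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.permutation(100)[: rng.integers(2, 8)].astype(float)
            y = rng.permutation(100)[: rng.integers(2, 8)].astype(float) + 0.5
            expected = stats.mannwhitneyu(x, y, alternative="two-sided",
                                          method="exact").pvalue
            assert exact_mannwhitney_p(x, y) == pytest.approx(expected)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 6), min_size=2, max_size=8),
        st.lists(st.integers(0, 6), min_size=2, max_size=8),
    )
    def test_matches_combinations_oracle_with_ties(self, x, y):
        assert exact_mannwhitney_p(x, y) == pytest.approx(brute_force_mw_p(x, y))

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(1)
        rejections = 0
        n_trials = 1000
        for _ in range(n_trials):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            if exact_mannwhitney_p(x, y) <= 0.05:
                rejections += 1
        # discrete test: size is at most nominal, and close to it
        assert rejections / n_trials <= 0.07


class TestCompareCodonUsage:
    def test_identical_distributions_p_one(self, small_cds_models):
        models, _ = small_cds_models
        usage = codon_frequencies(models)
        genes = list(usage.index[:8])
        # B genes duplicated from A values: append copies with new ids
        dup = usage.loc[genes].copy()
        dup.index = [g + "_copy" for g in genes]
        full = pd.concat([usage, dup])
        result = compare_codon_usage(genes, list(dup.index), full)
        assert (result["mw_p"] == 1.0).all()

    def test_overlapping_sets_raise(self, small_cds_models):
        models, _ = small_cds_models
        usage = codon_frequencies(models)
        genes = list(usage.index[:4])
        with pytest.raises(ValueError, match="overlap"):
            compare_codon_usage(genes, genes, usage)

    def test_enriched_codon_detected(self):
        from hacseq.simulate import CdsSimConfig, simulate_cds_set

        models, truth = simulate_cds_set(
            CdsSimConfig(
                genes_per_group={"up": 300, "down": 300},
                group_multipliers={"down": {"AGT": 1.2}},
                mean_codons=150,
                seed=13,
            )
        )
        usage = codon_frequencies(models)
        down = [m.gene_id for m in models if m.gene_id.startswith("down")]
        up = [m.gene_id for m in models if m.gene_id.startswith("up")]
        result = compare_codon_usage(down, up, usage)
        assert result.loc["AGT", "mw_p"] < 0.01
        assert result.loc["AGT", "log2_mean_ratio_vs_b"] > 0

    def test_cumulative_curves_cover_sets(self, small_cds_models):
        models, _ = small_cds_models
        usage = codon_frequencies(models)
        genes = list(usage.index)
        table = cumulative_frequency_table(
            usage, {"A": genes[:30], "B": genes[30:]}, ["AGT", "AGC"]
        )
        assert set(table["set"]) == {"A", "B"}
        assert table["cumulative"].max() == 1.0


class TestCodonChangeSummary:
    def test_equal_sets_at_origin(self, small_cds_models):
        models, _ = small_cds_models
        usage = codon_frequencies(models)
        genes = list(usage.index)
        dup = usage.loc[genes[:20]].copy()
        dup.index = [g + "_copy" for g in genes[:20]]
        full = pd.concat([usage.loc[genes[:20]], dup])
        table = codon_change_summary(genes[:20], list(dup.index), full)
        assert np.allclose(table["log2_down_vs_up"], 0.0)

    def test_antisymmetric_under_set_swap(self, small_cds_models):
        models, _ = small_cds_models
        usage = codon_frequencies(models)
        genes = list(usage.index)
        a, b = genes[:30], genes[30:]
        forward = codon_change_summary(a, b, usage)
        backward = codon_change_summary(b, a, usage)
        assert np.allclose(
            forward["log2_down_vs_up"], -backward["log2_down_vs_up"], atol=1e-12
        )

    def test_doubled_codon_tops_ranking(self):
        from hacseq.simulate import CdsSimConfig, simulate_cds_set

        models, _ = simulate_cds_set(
            CdsSimConfig(
                genes_per_group={"up": 200, "down": 200},
                group_multipliers={"down": {"AGT": 2.0}},
                mean_codons=150,
                seed=17,
            )
        )
        usage = codon_frequencies(models)
        down = [m.gene_id for m in models if m.gene_id.startswith("down")]
        up = [m.gene_id for m in models if m.gene_id.startswith("up")]
        table = codon_change_summary(down, up, usage)
        assert table["log2_down_vs_up"].idxmax() == "AGT"
        assert table.loc["AGT", "rank_down_vs_up"] == 1


class TestRankGenesByCodon:
    def test_top_fraction_selected(self):
        usage = pd.DataFrame(
            {"AGT": np.linspace(0.01, 0.10, 10)},
            index=[f"g{i}" for i in range(10)],
        ).reindex(columns=list(SENSE_CODONS), fill_value=0.0)
        top = rank_genes_by_codon(usage, "AGT", top_fraction=0.2)
        assert top == ["g9", "g8"]

    def test_ties_broken_lexicographically(self):
        usage = pd.DataFrame(
            {"AGT": [0.05] * 4}, index=["d", "b", "c", "a"]
        ).reindex(columns=list(SENSE_CODONS), fill_value=0.0)
        assert rank_genes_by_codon(usage, "AGT", 0.5) == ["a", "b"]

    def test_unknown_codon_raises(self, small_cds_models):
        models, _ = small_cds_models
        usage = codon_frequencies(models)
        with pytest.raises(ValueError, match="unknown codon"):
            rank_genes_by_codon(usage, "TAA")

    def test_enriched_subset_recovered(self):
        from hacseq.simulate import CdsSimConfig, simulate_cds_set

        # long genes (~2000 codons) so per-gene frequency noise (which falls
        # as 1/sqrt(length)) cleanly separates a 2x enrichment of a codon
        # whose baseline frequency is only ~1.6%
        models, _ = simulate_cds_set(
            CdsSimConfig(
                genes_per_group={"base": 270, "rich": 30},
                group_multipliers={"rich": {"AGT": 2.0}},
                mean_codons=2000,
                sd_codons=200,
                seed=19,
            )
        )
        usage = codon_frequencies(models)
        top = set(rank_genes_by_codon(usage, "AGT", top_fraction=0.1))
        rich = {m.gene_id for m in models if m.gene_id.startswith("rich")}
        jaccard = len(top & rich) / len(top | rich)
        assert jaccard >= 0.9


class TestGenesetEnrichment:
    def test_full_overlap_p_one(self):
        genes = [f"g{i}" for i in range(10)]
        result = geneset_enrichment(genes, {"all": genes}, genes)
        assert result.loc["all", "p"] == pytest.approx(1.0)
        assert result.loc["all", "overlap"] == 10

    def test_matches_enumeration_oracle(self):
        # universe 100, set 10, selected 10, overlap 5: tail probability by
        # direct enumeration of the hypergeometric pmf
        universe = [f"g{i}" for i in range(100)]
        geneset = universe[:10]
        selected = universe[5:15]  # overlap = 5
        result = geneset_enrichment(selected, {"s": geneset}, universe)
        expected = sum(
            comb(10, k) * comb(90, 10 - k) for k in range(5, 11)
        ) / comb(100, 10)
        assert result.loc["s", "p"] == pytest.approx(expected)

    def test_planted_set_ranked_first(self):
        from hacseq.simulate import CdsSimConfig, simulate_cds_set

        models, _ = simulate_cds_set(
            CdsSimConfig(
                genes_per_group={"base": 270, "rich": 30},
                group_multipliers={"rich": {"AGT": 2.0}},
                mean_codons=150,
                seed=23,
            )
        )
        usage = codon_frequencies(models)
        selected = rank_genes_by_codon(usage, "AGT", 0.1)
        rich = [m.gene_id for m in models if m.gene_id.startswith("rich")]
        rng = np.random.default_rng(0)
        decoys = {
            f"decoy{j}": list(rng.choice([m.gene_id for m in models], 30, replace=False))
            for j in range(5)
        }
        result = geneset_enrichment(
            selected, {"cell-cycle-like": rich, **decoys}, usage.index
        )
        assert result.index[0] == "cell-cycle-like"

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError, match="universe"):
            geneset_enrichment(["g1"], {"s": ["g1"]}, [])
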