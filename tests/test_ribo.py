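"""Ribosome-profiling analysis: offsets, A-site assignment, occupancy, TE."""

import numpy as np
import pandas as pd
import pytest

from hacseq import ribo
from hacseq.ribo import (
    ASiteOffsets,
    TranscriptModel,
    assign_a_sites,
    calibrate_offsets,
    codon_occupancy,
    compute_te,
    differential_te,
)
from hacseq.simulate import (
    CdsSimConfig,
    RiboSimConfig,
    simulate_cds_set,
    simulate_ribo_experiment,
)


def _model(n_codons=20, gene_id="g1", cds_start=30):
    body = "GCT" * (n_codons - 2)
    return TranscriptModel(gene_id, f"{gene_id}.t1", "ATG" + body + "TAA", cds_start)


def _aln(rows):
    return pd.DataFrame(rows, columns=["transcript_id", "start", "length"])


class TestTranscriptModel:
    def test_frame_enforced(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            TranscriptModel("g", "t", "ATGC", 0)

    def test_validation_of_start_and_stop(self):
        ribo.validate_model(_model())
        with pytest.raises(ValueError, match="stop"):
            ribo.validate_model(
                TranscriptModel("g", "t", "ATG" + "GCT" * 3, 0)
            )

    def test_model_io_round_trip_keeps_longest_cds(self, tmp_path):
        models = [_model(20, "g1"), _model(30, "g2")]
        models.append(TranscriptModel("g2", "g2.t2", _model(10).cds_sequence, 30))
        ribo.write_transcript_models(models, tmp_path / "cds.fa", tmp_path / "m.tsv")
        loaded = ribo.load_transcript_models(tmp_path / "cds.fa", tmp_path / "m.tsv")
        by_gene = {m.gene_id: m for m in loaded}
        assert by_gene["g2"].n_codons == 30  # longest CDS wins


class TestCalibrateOffsets:
    def test_constructed_fixture_recovers_offset_12(self):
        model = _model(200, cds_start=30)
        rows = [(model.transcript_id, 30 - 12, 28)] * 600
        offsets = calibrate_offsets(_aln(rows), [model])
        assert offsets.offsets[28] == 12

    def test_mixed_lengths_recovered_per_length(self):
        models, _ = simulate_cds_set(
            CdsSimConfig(genes_per_group={"base": 50}, mean_codons=120, seed=1)
        )
        config = RiboSimConfig(
            models=models,
            rpf_length_probs={28: 0.5, 30: 0.5},
            offsets={28: 12, 30: 13},
            n_rpf_reads=60_000,
            replicates=1,
            seed=2,
        )
        result = simulate_ribo_experiment(config)
        offsets = calibrate_offsets(result.rpf_alignments[1], models)
        assert offsets.offsets[28] == 12
        assert offsets.offsets[30] == 13

    def test_empty_input_defaults_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            offsets = calibrate_offsets(_aln([]), [_model()])
        assert offsets.offset(28) == 12
        assert any("default" in m for m in caplog.messages)


class TestAssignASites:
    def test_a_site_arithmetic(self):
        # 5' end at cds_start with offset 12 -> P codon 4, A codon 5 (0-based)
        model = _model(20, cds_start=30)
        counts, skipped = assign_a_sites(
            _aln([(model.transcript_id, 30, 28)]), ASiteOffsets({28: 12}), [model]
        )
        assert skipped == 0
        assert counts["g1"][5] == 1.0
        assert counts["g1"].sum() == 1.0

    def test_read_past_stop_discarded(self):
        model = _model(20, cds_start=30)
        start_past = 30 + 3 * (model.n_codons - 1) - 12  # A site on the stop codon
        _, skipped = assign_a_sites(
            _aln([(model.transcript_id, start_past, 28)]), ASiteOffsets({28: 12}), [model]
        )
        assert skipped == 1

    def test_unmodelled_transcript_skipped_and_counted(self):
        model = _model()
        counts, skipped = assign_a_sites(
            _aln([("unknown.t1", 30, 28)]), ASiteOffsets(), [model]
        )
        assert skipped == 1

    def test_simulated_placements_recovered_exactly(self):
        models, _ = simulate_cds_set(
            CdsSimConfig(genes_per_group={"base": 20}, mean_codons=100, seed=3)
        )
        config = RiboSimConfig(
            models=models, n_rpf_reads=1000, replicates=1, start_boost=1.0, seed=4
        )
        result = simulate_ribo_experiment(config)
        counts, skipped = assign_a_sites(
            result.rpf_alignments[1], ASiteOffsets(dict(config.offsets)), models
        )
        assert skipped == 0
        total = sum(v.sum() for v in counts.values())
        assert total == 1000  # every simulated read lands where it was placed
        per_gene = {g: v.sum() for g, v in counts.items()}
        expected = result.rpf_gene_counts["rep1"]
        for gene, n in per_gene.items():
            assert n == expected[gene]

    def test_offset_shift_invariance(self):
        model = _model(50, cds_start=30)
        rows = [(model.transcript_id, 60 + 3 * k, 28) for k in range(5)]
        base, _ = assign_a_sites(_aln(rows), ASiteOffsets({28: 12}), [model])
        shifted_rows = [(tx, s - 2, lg) for tx, s, lg in rows]
        shifted, _ = assign_a_sites(
            _aln(shifted_rows), ASiteOffsets({28: 14}), [model]
        )
        assert np.array_equal(base["g1"], shifted["g1"])


class TestCodonOccupancy:
    def test_uniform_counts_give_unit_occupancy(self):
        models, _ = simulate_cds_set(
            CdsSimConfig(genes_per_group={"base": 10}, mean_codons=60, seed=5)
        )
        counts = {
            m.gene_id: np.full(m.n_codons, 10.0) for m in models
        }
        table = codon_occupancy(counts, models, min_gene_reads=1)
        assert np.allclose(table["occ_A"], 1.0)

    def test_hand_computed_normalised_density(self):
        # 12 codons -> 10 elongation positions; one position with 10 reads,
        # nine with 5: normalised density there = 10 / 5.5
        model = TranscriptModel("g1", "g1.t1", "ATG" + "AGT" + "GCT" * 9 + "TAA", 0)
        counts = np.zeros(model.n_codons)
        counts[1] = 10.0  # the single AGT instance sits at codon 1
        counts[2:11] = 5.0
        table = codon_occupancy({"g1": counts}, [model], min_gene_reads=1)
        assert table.loc["AGT", "occ_A"] == pytest.approx(10 / 5.5)

    def test_usage_weighted_mean_is_one(self):
        models, _ = simulate_cds_set(
            CdsSimConfig(genes_per_group={"base": 30}, mean_codons=80, seed=6)
        )
        rng = np.random.default_rng(0)
        counts = {m.gene_id: rng.poisson(8.0, size=m.n_codons).astype(float)
                  for m in models}
        table = codon_occupancy(counts, models, min_gene_reads=1)
        w = table["n_instances"].to_numpy()
        assert float((table["occ_A"] * w).sum() / w.sum()) == pytest.approx(1.0)

    def test_no_gene_passing_filter_raises(self):
        model = _model()
        with pytest.raises(ValueError, match="min_gene_reads"):
            codon_occupancy({"g1": np.zeros(model.n_codons)}, [model])

    def test_dwell_multiplier_recovered_with_flat_a_plus_one(self):
        models, _ = simulate_cds_set(
            CdsSimConfig(genes_per_group={"base": 150}, mean_codons=150, seed=7)
        )
        config = RiboSimConfig(
            models=models, dwell={"AGT": 2.0}, n_rpf_reads=200_000,
            replicates=1, seed=8,
        )
        result = simulate_ribo_experiment(config)
        offsets = calibrate_offsets(result.rpf_alignments[1], models)
        counts, _ = assign_a_sites(result.rpf_alignments[1], offsets, models)
        table = codon_occupancy(counts, models)
        assert table.loc["AGT", "occ_A"] == pytest.approx(2.0, abs=0.15)
        assert table.loc["AGT", "occ_A1"] == pytest.approx(1.0, abs=0.10)


class TestComputeTe:
    def test_te_definition(self):
        models = [_model(101, "g1"), _model(101, "g2")]
        rpf = pd.Series({"g1": 300.0, "g2": 100.0})
        rna = pd.Series({"g1": 100.0, "g2": 100.0})
        table = compute_te(rpf, rna, models)
        # densities share normalisation; same CDS length -> te ratio 3 vs 1
        assert table.loc["g1", "te"] / table.loc["g2", "te"] == pytest.approx(3.0)

    def test_low_rna_masked(self):
        models = [_model(101, "g1"), _model(101, "g2")]
        rpf = pd.Series({"g1": 300.0, "g2": 100.0})
        rna = pd.Series({"g1": 0.0, "g2": 100.0})
        table = compute_te(rpf, rna, models, min_rna=10)
        assert np.isnan(table.loc["g1", "te"])

    def test_simulated_te_recovered_within_20_percent(self):
        models, _ = simulate_cds_set(
            CdsSimConfig(genes_per_group={"base": 200}, mean_codons=120, seed=9)
        )
        target = models[0].gene_id
        config = RiboSimConfig(
            models=models, te={target: 1.5}, n_rpf_reads=300_000, n_rna_reads=300_000,
            replicates=1, emit_alignments=False, dispersion=0.0, seed=10,
        )
        result = simulate_ribo_experiment(config)
        table = compute_te(
            result.rpf_gene_counts["rep1"], result.rna_counts["rep1"], models
        )
        rel = table.loc[target, "te"] / table["te"].median()
        assert rel == pytest.approx(1.5, rel=0.2)


class TestDifferentialTe:
    @staticmethod
    def _null_tables(models, seed, n=300_000, reps=3):
        config = RiboSimConfig(
            models=models, n_rpf_reads=n, n_rna_reads=n, replicates=reps,
            emit_alignments=False, seed=seed,
        )
        r = simulate_ribo_experiment(config)
        return r.rpf_gene_counts, r.rna_counts

    def test_identical_tables_unchanged(self, small_cds_models):
        models, _ = small_cds_models
        rpf, rna = self._null_tables(models, seed=1)
        result = differential_te(rpf, rna, rpf.copy(), rna.copy(), models)
        assert (result["te_class"] == "unchanged").all()
        assert np.allclose(result["log2fc_te"], 0.0)

    def test_unreplicated_fold_change_only(self, small_cds_models):
        models, _ = small_cds_models
        rpf, rna = self._null_tables(models, seed=2, reps=1)
        rpf_b = rpf.copy()
        rpf_b.iloc[:5] *= 4  # boost a few genes (a global factor would cancel in CPM)
        result = differential_te(rpf, rna, rpf_b, rna, models)
        assert result["p"].isna().all()
        assert (result["te_class"].iloc[:5] == "TE-Up").all()
        assert (result["te_class"].iloc[5:] == "unchanged").all()

    def test_libsize_scaling_leaves_log2fc_unchanged(self, small_cds_models):
        models, _ = small_cds_models
        rpf_a, rna_a = self._null_tables(models, seed=3)
        rpf_b, rna_b = self._null_tables(models, seed=4)
        base = differential_te(rpf_a, rna_a, rpf_b, rna_b, models, pseudocount=0.0)
        scaled = differential_te(rpf_a, rna_a, rpf_b * 10, rna_b, models, pseudocount=0.0)
        assert np.allclose(base["log2fc_te"], scaled["log2fc_te"])

    def test_planted_te_down_flagged(self, small_cds_models):
        models, _ = small_cds_models
        down = [m.gene_id for m in models[:10]]
        rpf_a, rna_a = self._null_tables(models, seed=5, n=400_000)
        config = RiboSimConfig(
            models=models, te={g: 1 / 3 for g in down}, n_rpf_reads=400_000,
            n_rna_reads=400_000, replicates=3, emit_alignments=False, seed=6,
        )
        r = simulate_ribo_experiment(config)
        result = differential_te(rpf_a, rna_a, r.rpf_gene_counts, r.rna_counts, models)
        sub = result.loc[down]
        assert (sub["te_class"] == "TE-Down").mean() >= 0.8
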