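"""Monte-Carlo engine: sampling, filtering, classification, summaries."""

import numpy as np
import pandas as pd
import pytest
import yaml

from alleleinteract.engine import (
    DEFAULT_RANGES,
    ExperimentConfig,
    run_experiment,
    run_replicate,
    sample_allele,
    summarize_dominance,
)
from alleleinteract.metrics import (
    PhenotypeQuintet,
    allele_interaction,
    call_signs,
    gene_action,
)


@pytest.fixture(scope="module")
def small_neg():
    return run_experiment(ExperimentConfig("neg_auto", n_reps=800, seed=5))


@pytest.fixture(scope="module")
def small_pos():
    return run_experiment(ExperimentConfig("pos_auto", n_reps=800, seed=5))


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            ExperimentConfig("unknown_experiment")
        with pytest.raises(ValueError):
            ExperimentConfig("neg_auto", n_reps=0)
        with pytest.raises(ValueError):
            ExperimentConfig("neg_auto", zero_tol=1.5)
        with pytest.raises(ValueError):
            ExperimentConfig("neg_auto", ranges={"alpha": (300.0, 1.0)})

    def test_yaml_round_trip(self, tmp_path):
        cfg = ExperimentConfig(
            "pos_auto", variation="noncoding+coding", n_reps=7, seed=3,
            ranges={"alpha": (2.0, 20.0)}, zero_tol=0.1,
        )
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        loaded = ExperimentConfig.from_yaml(path)
        assert loaded.to_dict() == cfg.to_dict()
        assert loaded.ranges["alpha"] == (2.0, 20.0)
        assert loaded.ranges["theta"] == DEFAULT_RANGES["theta"]  # defaults merged


class TestSampling:
    def test_ranges_respected_and_noncoding_weight_unity(self, rng):
        cfg = ExperimentConfig("neg_auto")
        for _ in range(100):
            a = sample_allele(cfg, rng)
            assert 1 <= a.alpha <= 300
            assert 1 <= a.response.theta <= 300
            assert 1 <= a.response.p <= 4
            assert a.w == 1.0
            assert a.gamma == 1.0

    def test_coding_weights_and_bump_decay_sampled(self, rng):
        cfg = ExperimentConfig("bump_up_auto", variation="noncoding+coding")
        draws = [sample_allele(cfg, rng) for _ in range(100)]
        assert all(0.5 <= a.w <= 2.0 for a in draws)
        assert all(1.0 <= a.gamma <= 5.0 for a in draws)
        assert len({a.w for a in draws}) > 50  # actually varying


class TestExperiment:
    def test_reproducibility(self):
        cfg = ExperimentConfig("pos_auto", n_reps=60, seed=11)
        r1 = run_experiment(cfg)
        r2 = run_experiment(cfg)
        pd.testing.assert_frame_equal(r1.records, r2.records)
        pd.testing.assert_frame_equal(r1.motif_freq, r2.motif_freq)

    def test_conservation(self, small_pos):
        rec = small_pos.records
        assert small_pos.n_valid + small_pos.n_discarded == small_pos.n_reps
        assert (rec["valid"] == (rec["discard_reason"] == "")).all()
        # per-motif dominance counts sum to the motif's frequency count
        dom = summarize_dominance(small_pos)
        counts = rec.loc[rec.valid, "motif"].value_counts()
        for row in dom.itertuples():
            assert row.n == counts[row.motif]
            assert row.n_dominance_negative + row.n_dominance_zero + row.n_dominance_positive == row.n
            assert row.n_partial_or_additive + row.n_overdominant == row.n

    def test_null_filter_applies_to_homozygotes(self, small_pos):
        rec = small_pos.records
        nulls = rec[rec.discard_reason == "null_allele"]
        assert len(nulls) > 0  # positive feedback has an off state
        valid = rec[rec.valid]
        assert (np.minimum(valid.x11, valid.x22) >= small_pos.config.null_cutoff).all()

    def test_negative_feedback_never_null(self, small_neg):
        assert small_neg.n_valid == small_neg.n_reps

    def test_motif_pruning_keeps_raw_records(self, small_pos):
        t = small_pos.motif_freq
        assert set(t.columns) == {"motif", "count", "freq", "retained"}
        assert (t.loc[t.retained, "freq"] >= small_pos.config.motif_prune).all()
        # raw records keep pruned motifs
        assert set(small_pos.records.loc[small_pos.records.valid, "motif"]) == set(t.motif)
        assert small_pos.n_shown <= small_pos.n_valid

    def test_engine_classification_matches_scalar_calculus(self, small_pos):
        """Vectorized classification agrees with the per-quintet functions."""
        rec = small_pos.records[small_pos.records.valid].head(300)
        tol = small_pos.config.zero_tol
        for row in rec.itertuples():
            q = PhenotypeQuintet(row.x11, row.x12, row.x22, row.h1, row.h2)
            assert q.is_oriented
            t = allele_interaction(q)
            assert (row.d11, row.d12, row.d22) == pytest.approx(t.values())
            assert row.motif == call_signs(q, tol).canonical().token
            ga = gene_action(q, tol)
            assert row.a == pytest.approx(ga.a)
            assert row.d == pytest.approx(ga.d)
            assert row.dominance_class == ga.dominance_class

    def test_run_replicate_contract(self, rng):
        cfg = ExperimentConfig("neg_auto", n_reps=1, seed=0)
        rec = run_replicate(cfg, rng, replicate=4)
        assert rec.valid and rec.discard_reason is None
        assert rec.motif is not None and rec.motif.is_canonical
        assert rec.quintet.is_oriented is not None

    def test_two_locus_records_both_loci(self):
        r = run_experiment(ExperimentConfig("two_locus_neg_B", n_reps=150, seed=2))
        rec = r.records
        assert {"motif", "motif_locus2", "d11_locus2", "dominance_class_locus2"} <= set(rec.columns)
        assert r.motif_freq_locus2 is not None
        assert len(r.retained_motifs_locus2) >= 1
        dom2 = summarize_dominance(r, locus=2)
        assert set(dom2.motif) == r.retained_motifs_locus2

    def test_write_outputs(self, tmp_path, small_neg):
        small_neg.write(tmp_path)
        import json

        assert (tmp_path / "replicates.tsv").exists()
        assert (tmp_path / "motif_freq.tsv").exists()
        assert (tmp_path / "dominance_by_motif.tsv").exists()
        summary = json.loads((tmp_path / "summary.json").read_text())
        assert summary["n_valid"] == small_neg.n_valid
        assert summary["seed"] == small_neg.config.seed
        assert set(summary["retained_motifs"]) == small_neg.retained_motifs
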