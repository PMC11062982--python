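"""Determinism, validity and planted-truth contracts of the generators."""

import numpy as np
import pandas as pd
import pytest

from azoreg import compendium as cm
from azoreg import simulate as sim


class TestCompendiumGenerator:
    def test_same_seed_identical_output(self):
        cfg = sim.CompendiumSimConfig(
            n_datasets=4, n_genes=120, samples_per_dataset=(4, 8),
            total_samples=None, seed=42,
            planted_modules=(sim.PlantedModule(("tesA",), 0.9, 2),),
        )
        c1, t1 = sim.gen_compendium(cfg)
        c2, t2 = sim.gen_compendium(cfg)
        pd.testing.assert_frame_equal(c1.metadata, c2.metadata)
        for d1, d2 in zip(c1.datasets, c2.datasets):
            pd.testing.assert_frame_equal(d1.ranks, d2.ranks)
        assert t1.to_json() == t2.to_json()

    def test_percentile_validity_and_column_rank_structure(self, small_compendium):
        comp, _ = small_compendium
        for d in comp.datasets:
            vals = d.ranks.to_numpy()
            assert vals.min() >= 0 and vals.max() <= 100
            # each column is a valid average-rank percentile vector
            n = vals.shape[0]
            col_sums = vals.sum(axis=0)
            expected = n * (n + 1) / 2 / n * 100
            assert col_sums == pytest.approx(np.full(vals.shape[1], expected))

    def test_planted_module_correlates_in_designated_datasets(self, small_compendium):
        comp, truth = small_compendium
        mod = truth.modules[0]
        planted_ids = set(mod["dataset_ids"])
        in_r, out_r = [], []
        for d in comp.datasets:
            focal = d.ranks.loc["azoR"].to_numpy()
            for g in mod["genes"]:
                r = np.corrcoef(focal, d.ranks.loc[g].to_numpy())[0, 1]
                (in_r if d.dataset_id in planted_ids else out_r).append(r)
        assert np.mean(in_r) > 0.8  # target r = 0.95 on the rank scale
        assert abs(np.mean(out_r)) < 0.3

    def test_truth_references_existing_entities(self, small_compendium):
        comp, truth = small_compendium
        ds_ids = {d.dataset_id for d in comp.datasets}
        genes = set(comp.datasets[0].gene_ids)
        for mod in truth.modules:
            assert set(mod["dataset_ids"]) <= ds_ids
            assert set(mod["genes"]) <= genes

    def test_module_gene_overflow_rejected(self):
        with pytest.raises(sim.ConfigError, match="gene universe"):
            sim.CompendiumSimConfig(
                n_genes=5,
                planted_modules=(sim.PlantedModule(tuple("abcdefgh"), 0.9, 2),),
            )

    @pytest.mark.parametrize("bad_r", [0.0, 1.5, -0.2])
    def test_invalid_planted_r_rejected(self, bad_r):
        with pytest.raises(sim.ConfigError, match="planted r"):
            sim.PlantedModule(("a",), bad_r, 2)

    def test_metadata_omission_leaves_at_least_one_condition(self):
        cfg = sim.CompendiumSimConfig(n_datasets=10, n_genes=60,
                                      samples_per_dataset=(4, 6),
                                      total_samples=None,
                                      metadata_omission_rate=0.9, seed=8)
        comp, _ = sim.gen_compendium(cfg)
        for ds_id, grp in comp.metadata.groupby("dataset_id"):
            present = [k for k in cm.CONDITION_KEYS if grp[k].notna().any()]
            assert len(present) >= 1

    def test_null_config_focal_independent_of_metadata(self):
        """With no planted effects, condition tests should reject at chance
        level across the conditions of several seeded compendia."""
        rejections = trials = 0
        for seed in range(6):
            cfg = sim.CompendiumSimConfig(
                n_datasets=10, n_genes=150, samples_per_dataset=(8, 12),
                total_samples=None, condition_effects={}, planted_modules=(),
                seed=seed, metadata_omission_rate=0.0,
            )
            comp, _ = sim.gen_compendium(cfg)
            df = cm.analyze_conditions(comp, "azoR", alpha=0.05)
            tested = df[df["status"] == "tested"]
            trials += len(tested)
            rejections += int((tested["p_value"] < 0.05).sum())
        assert trials > 50
        assert rejections / trials <= 0.12  # small-sample slack around 0.05


class TestScreenGenerator:
    def test_same_seed_identical_plates(self):
        cfg = sim.ScreenSimConfig(n_mutants=200, seed=9)
        p1, _ = sim.gen_screen(cfg)
        p2, _ = sim.gen_screen(cfg)
        pd.testing.assert_frame_equal(p1, p2)

    def test_controls_present_on_every_plate(self, small_screen):
        cfg, plates, _ = small_screen
        for _, grp in plates.groupby("plate"):
            assert (grp["strain"] == sim.WT_STRAIN).sum() == cfg.wt_wells_per_plate
            assert (grp["strain"] == sim.KO_CONTROL_STRAIN).sum() == 1

    def test_no_effect_library_centers_at_100(self):
        from azoreg import screen as sc

        cfg = sim.ScreenSimConfig(
            n_mutants=400, class_probs={"neutral": 1.0},
            effect_multipliers={"neutral": 1.0}, seed=13,
        )
        plates, _ = sim.gen_screen(cfg)
        scored = sc.score_plates(plates)
        muts = scored[scored["strain"] != sim.KO_CONTROL_STRAIN]
        assert muts["normalized_pct"].mean() == pytest.approx(100, abs=2)

    def test_reduced_class_closed_form_expectation(self):
        cfg = sim.ScreenSimConfig(n_mutants=50, wt_decol_mean=60.0,
                                  class_probs={"reduced": 1.0},
                                  effect_multipliers={"reduced": 0.5}, seed=21)
        _, truth = sim.gen_screen(cfg)
        assert all(
            truth.true_decolorization[m] == pytest.approx(30.0)
            for m in truth.strain_class
        )

    def test_zero_mutants_rejected(self):
        with pytest.raises(sim.ConfigError, match="n_mutants"):
            sim.ScreenSimConfig(n_mutants=0)

    def test_nonpositive_multiplier_rejected(self):
        with pytest.raises(sim.ConfigError, match="multipliers"):
            sim.ScreenSimConfig(effect_multipliers={"neutral": 0.0},
                                class_probs={"neutral": 1.0})


class TestQpcrGenerator:
    def test_same_seed_identical_table(self):
        cfg = sim.QpcrSimConfig(seed=31)
        t1, _ = sim.gen_qpcr(cfg)
        t2, _ = sim.gen_qpcr(cfg)
        pd.testing.assert_frame_equal(t1, t2)

    def test_replicate_count_honored(self):
        ct, _ = sim.gen_qpcr(sim.QpcrSimConfig(replicates=4, seed=1))
        sizes = ct.groupby(["gene", "condition"]).size()
        assert (sizes == 4).all()

    def test_reference_with_planted_fold_rejected(self):
        with pytest.raises(sim.ConfigError, match="reference"):
            sim.QpcrSimConfig(planted_log2_fold={("ihfB", "MR_5mg_L"): 1.0})

    def test_unknown_planted_key_rejected(self):
        with pytest.raises(sim.ConfigError, match="unknown"):
            sim.QpcrSimConfig(planted_log2_fold={("nope", "MR_5mg_L"): 1.0})

    def test_null_folds_center_at_one(self):
        from azoreg import qpcr as qp

        folds = []
        for seed in range(10):
            ct, _ = sim.gen_qpcr(sim.QpcrSimConfig(planted_log2_fold={}, seed=seed))
            res = qp.ddct_fold_change(ct, "azoR", "ihfB", "control")
            folds += res[res["condition"] != "control"]["fold_change"].tolist()
        assert np.mean(folds) == pytest.approx(1.0, abs=0.15)


class TestMapGenerator:
    def test_same_seed_identical_reads(self):
        cfg = sim.MapSimConfig(genome_length=5_000, n_genes=5, n_insertions=4,
                               read_length=100, seed=2)
        d1, t1 = sim.gen_reference_and_reads(cfg)
        d2, t2 = sim.gen_reference_and_reads(cfg)
        assert d1.genome == d2.genome
        assert d1.reads == d2.reads
        assert t1.to_json() == t2.to_json()

    def test_reads_carry_transposon_end_and_planted_flank(self):
        cfg = sim.MapSimConfig(genome_length=5_000, n_genes=5, n_insertions=6,
                               read_length=100, ambiguous_rate=0.0, seed=3)
        data, truth = sim.gen_reference_and_reads(cfg)
        flank_len = cfg.read_length - len(cfg.transposon_end_seq)
        for (rid, seq), t in zip(data.reads, truth.insertions):
            assert seq.startswith(cfg.transposon_end_seq)
            flank = seq[len(cfg.transposon_end_seq):]
            pos0 = t["position"] - 1
            if t["strand"] == "+":
                assert flank == data.genome[pos0 : pos0 + flank_len]
            else:
                from azoreg.mapping import revcomp

                assert flank == revcomp(data.genome[pos0 - flank_len + 1 : pos0 + 1])

    def test_annotations_nonoverlapping_and_inside_genome(self):
        cfg = sim.MapSimConfig(genome_length=20_000, n_genes=25, seed=4)
        data, _ = sim.gen_reference_and_reads(cfg)
        ann = data.annotations.sort_values("start")
        assert (ann["start"] >= 1).all() and (ann["end"] <= cfg.genome_length).all()
        assert (ann["start"].iloc[1:].to_numpy() > ann["end"].iloc[:-1].to_numpy()).all()

    def test_read_longer_than_genome_rejected(self):
        with pytest.raises(sim.ConfigError, match="read_length"):
            sim.MapSimConfig(genome_length=100, read_length=200)

    def test_impossible_gene_placement_rejected(self):
        with pytest.raises(sim.ConfigError, match="place"):
            cfg = sim.MapSimConfig(genome_length=2_000, n_genes=10,
                                   gene_length_range=(500, 600), read_length=100,
                                   seed=5)
            sim.gen_reference_and_reads(cfg)
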