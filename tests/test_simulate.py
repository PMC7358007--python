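"""Generator correctness: planted truth, determinism, calibration."""

import numpy as np
import pandas as pd
import pytest

from transchrom.simulate import (
    SimulationConfig,
    generate_annotation,
    generate_cell_observations,
    generate_depth_profile,
    generate_expression_counts,
    generate_probe_trials,
)

from conftest import per_base_deleted_oracle


def tiny_config(**kw):
    defaults = dict(
        seed=1,
        chrom_start=1_000_001,
        chrom_end=2_000_000,
        n_pcg=15,
        n_npcg=5,
        n_krtap=3,
        planted_deletions=(),
        n_host_genes=50,
        bin_size=10_000,
        n_tissues=2,
        cells_per_tissue=50,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    def test_rejects_inverted_span(self):
        with pytest.raises(ValueError, match="chrom_start"):
            tiny_config(chrom_start=5, chrom_end=4)

    def test_rejects_overlapping_deletions(self):
        with pytest.raises(ValueError, match="disjoint"):
            tiny_config(
                planted_deletions=((1_100_001, 1_200_000), (1_150_001, 1_300_000))
            )

    def test_rejects_deletion_outside_span(self):
        with pytest.raises(ValueError, match="outside"):
            tiny_config(planted_deletions=((1, 100),))

    def test_rejects_bad_fractions(self):
        with pytest.raises(ValueError, match="retention_p"):
            tiny_config(retention_p=1.5)


class TestAnnotation:
    def test_no_deletions_means_no_deleted_genes(self):
        _, truth = generate_annotation(tiny_config())
        assert truth.deleted_genes == set()

    def test_full_span_deletion_flags_every_gene(self):
        cfg = tiny_config(planted_deletions=((1_000_001, 2_000_000),))
        table, truth = generate_annotation(cfg)
        assert truth.deleted_genes == set(table["gene_id"])

    def test_deleted_flags_match_per_base_oracle(self):
        # one deletion covering the central 10% of the span
        cfg = tiny_config(
            n_pcg=15, n_npcg=5, planted_deletions=((1_450_001, 1_550_000),)
        )
        table, truth = generate_annotation(cfg)
        assert truth.deleted_genes == per_base_deleted_oracle(
            table, cfg.planted_deletions
        )

    def test_gene_count_and_disjointness(self):
        cfg = tiny_config()
        table, _ = generate_annotation(cfg)
        assert len(table) == cfg.n_pcg + cfg.n_npcg
        ordered = table.sort_values("start")
        assert (ordered["end"].to_numpy()[:-1] < ordered["start"].to_numpy()[1:]).all()
        assert table["start"].min() >= cfg.chrom_start
        assert table["end"].max() <= cfg.chrom_end

    def test_krtap_genes_are_pcg_without_ortholog(self):
        table, _ = generate_annotation(tiny_config())
        krtap = table[table["family"] == "KRTAP"]
        assert len(krtap) == 3
        assert (krtap["biotype"] == "PCG").all()
        assert (krtap["ortholog_id"] == "").all()

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="packing"):
            generate_annotation(
                SimulationConfig(
                    seed=0,
                    chrom_start=1,
                    chrom_end=10_000,
                    n_pcg=400,
                    n_npcg=400,
                    n_krtap=0,
                    planted_deletions=(),
                )
            )


class TestDepthProfile:
    def test_noiseless_flat_profile(self):
        cfg = tiny_config(depth_noise=0.0, depth_mean=120.0)
        _, truth = generate_annotation(cfg)
        profile = generate_depth_profile(cfg, truth)
        assert np.all(profile.bin_counts == 120.0)

    def test_noiseless_deletion_is_exactly_zero(self):
        cfg = tiny_config(
            depth_noise=0.0,
            depth_mean=120.0,
            planted_deletions=((1_100_001, 1_200_000),),
        )
        _, truth = generate_annotation(cfg)
        profile = generate_depth_profile(cfg, truth)
        inside = np.array(
            [
                profile.bin_interval(i)[0] >= 1_100_001
                and profile.bin_interval(i)[1] <= 1_200_000
                for i in range(profile.n_bins)
            ]
        )
        assert np.all(profile.bin_counts[inside] == 0.0)
        assert np.all(profile.bin_counts[~inside] == 120.0)

    def test_deleted_bins_stay_near_background(self):
        cfg = tiny_config(planted_deletions=((1_100_001, 1_200_000),), seed=3)
        _, truth = generate_annotation(cfg)
        profile = generate_depth_profile(cfg, truth)
        inside = [
            i
            for i in range(profile.n_bins)
            if profile.bin_interval(i)[0] >= 1_100_001
            and profile.bin_interval(i)[1] <= 1_200_000
        ]
        # expected background is 2% of depth_mean
        assert profile.bin_counts[inside].mean() <= 0.05 * cfg.depth_mean

    def test_fixed_seed_reproducible(self):
        cfg = tiny_config(seed=11)
        _, truth = generate_annotation(cfg)
        a = generate_depth_profile(cfg, truth)
        b = generate_depth_profile(cfg, truth)
        assert np.array_equal(a.bin_counts, b.bin_counts)


class TestExpressionCounts:
    def test_zero_dispersion_recovers_configured_ratio(self):
        cfg = tiny_config(nb_dispersion=0.0, dosage_log_sd=0.0, ortholog_fraction=1.0)
        ann, truth = generate_annotation(cfg)
        eu, tc, libs = generate_expression_counts(cfg, ann, truth)
        from transchrom.dosage import dosage_records, fpkm_table

        eu_f = fpkm_table(eu, {k: v for k, v in libs.items() if k.startswith("Eu")})
        tc_f = fpkm_table(tc, {k: v for k, v in libs.items() if k.startswith("Tc")})
        pairs = ann[(ann["family"] == "other") & (ann["ortholog_id"] != "")]
        recs = dosage_records(pairs, tc_f, tc_f, eu_f)
        assert recs, "some pairs must pass the expression filter"
        for r in recs:
            assert r.r_tot == pytest.approx(1.5, rel=0.05)

    def test_null_trans_effect_leaves_host_genes_unchanged(self):
        cfg = tiny_config(
            nb_dispersion=0.0, trans_down_frac=0.0, trans_up_frac=0.0
        )
        ann, truth = generate_annotation(cfg)
        eu, tc, _ = generate_expression_counts(cfg, ann, truth)
        host_eu = eu[eu["compartment"] == "host"].set_index("gene_id")
        host_tc = tc[tc["compartment"] == "host"].set_index("gene_id")
        for col in ("count_1", "count_2"):
            pd.testing.assert_series_equal(host_eu[col], host_tc[col])

    def test_deleted_human_genes_emit_zero_counts(self):
        cfg = tiny_config(
            planted_deletions=((1_100_001, 1_600_000),), ortholog_fraction=1.0
        )
        ann, truth = generate_annotation(cfg)
        _, tc, _ = generate_expression_counts(cfg, ann, truth)
        human = tc[tc["compartment"] == "human_transchromosome"]
        deleted = human[human["gene_id"].isin(truth.deleted_genes)]
        assert len(deleted) > 0
        assert (deleted[["count_1", "count_2"]].to_numpy() == 0).all()

    def test_euploid_table_has_no_human_genes(self):
        cfg = tiny_config()
        ann, truth = generate_annotation(cfg)
        eu, _, _ = generate_expression_counts(cfg, ann, truth)
        assert "human_transchromosome" not in set(eu["compartment"])


class TestCellObservations:
    @pytest.mark.parametrize("p,expected", [(1.0, 1), (0.0, 0)])
    def test_boundary_retention(self, p, expected):
        cfg = tiny_config(retention_p=p)
        _, truth = generate_annotation(cfg)
        cells = generate_cell_observations(cfg, truth)
        assert (cells["detected"] == expected).all()

    def test_binomial_expectation_over_replicates(self):
        # 10k replicate tissues of 200 cells at p=0.96: mean positives ~ 192
        cfg = SimulationConfig(
            seed=5,
            chrom_start=1,
            chrom_end=100_000,
            n_pcg=2,
            n_npcg=1,
            n_krtap=0,
            planted_deletions=(),
            retention_p=0.96,
            cells_per_tissue=200,
            n_tissues=10_000,
            n_host_genes=10,
        )
        _, truth = generate_annotation(cfg)
        cells = generate_cell_observations(cfg, truth)
        positives = cells.groupby("tissue")["detected"].sum()
        se = np.sqrt(200 * 0.96 * 0.04 / 10_000)
        assert positives.mean() == pytest.approx(192.0, abs=3 * se)

    def test_calibration_across_tissues(self):
        # >= 1000 replicate tissues: empirical mean retention within 3 MC SE
        cfg = SimulationConfig(
            seed=9,
            chrom_start=1,
            chrom_end=100_000,
            n_pcg=2,
            n_npcg=1,
            n_krtap=0,
            planted_deletions=(),
            retention_p=0.92,
            cells_per_tissue=100,
            n_tissues=1000,
            n_host_genes=10,
        )
        _, truth = generate_annotation(cfg)
        cells = generate_cell_observations(cfg, truth)
        p_hat = cells["detected"].mean()
        se = np.sqrt(0.92 * 0.08 / (100 * 1000))
        assert abs(p_hat - 0.92) <= 3 * se


class TestProbeTrials:
    def test_no_forgetting_with_unit_decay(self):
        from transchrom.behavior import retained_memory

        trials = generate_probe_trials(5, 0.3, 1.0, seed=2, noise=0.0)
        for _, t in trials.groupby("animal_id"):
            assert retained_memory(t).tolist() == [100.0, 100.0, 100.0]

    def test_half_decay_gives_exact_50_percent_day2(self):
        from transchrom.behavior import retained_memory

        trials = generate_probe_trials(5, 0.3, 0.5, seed=2, noise=0.0)
        for _, t in trials.groupby("animal_id"):
            rm = retained_memory(t)
            assert rm[2] == pytest.approx(50.0)
            assert rm[3] == pytest.approx(25.0)

    def test_baseline_never_zero(self):
        trials = generate_probe_trials(50, 0.05, 0.8, seed=3, noise=0.05)
        day1 = trials[trials["day"] == 1]
        assert (day1["time_fraction_in_zone"] > 0).all()

    def test_fractions_in_unit_interval(self):
        trials = generate_probe_trials(20, 0.9, 1.2, seed=4, noise=0.3)
        assert trials["time_fraction_in_zone"].between(0, 1).all()


class TestDeterminism:
    def test_identical_config_gives_identical_outputs(self):
        cfg = tiny_config(seed=42, planted_deletions=((1_200_001, 1_300_000),))
        a_ann, a_truth = generate_annotation(cfg)
        b_ann, b_truth = generate_annotation(cfg)
        pd.testing.assert_frame_equal(a_ann, b_ann)
        assert a_truth.deleted_genes == b_truth.deleted_genes
        a_eu, a_tc, _ = generate_expression_counts(cfg, a_ann, a_truth)
        b_eu, b_tc, _ = generate_expression_counts(cfg, b_ann, b_truth)
        pd.testing.assert_frame_equal(a_eu, b_eu)
        pd.testing.assert_frame_equal(a_tc, b_tc)
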