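import math

import numpy as np
import pytest

from pulsedyn.errors import ConfigError
from pulsedyn.quant_io import apply_quality_filters, read_protein_groups, write_table
from pulsedyn.replicate_union import merge_replicates
from pulsedyn.synthetic_data import (
    PERSISTENCE_TIMES_H,
    RESUSCITATION_TIMES_H,
    SimulationConfig,
    make_cluster_scenario,
    simulate_experiment,
)
from pulsedyn.turnover_kinetics import fit_merged_courses


def roundtrip(table, config, tmp_path, name="sim.tsv"):
    path = tmp_path / name
    write_table(table, path)
    return read_protein_groups(path, config.design())


class TestDefaults:
    def test_time_grids(self):
        assert len(PERSISTENCE_TIMES_H) == 17
        assert len(RESUSCITATION_TIMES_H) == 21
        assert PERSISTENCE_TIMES_H[0] == 0.0 and RESUSCITATION_TIMES_H[0] == 0.0

    def test_config_validation_names_field(self):
        with pytest.raises(ConfigError, match="plateau"):
            SimulationConfig(plateau=1.5)
        with pytest.raises(ConfigError, match="pool_purity"):
            SimulationConfig(pool_purity=0.0)
        with pytest.raises(ConfigError, match="rate_bounds"):
            SimulationConfig(rate_bounds_per_h=(0.1, 0.01))
        with pytest.raises(ConfigError, match="n_proteins"):
            SimulationConfig(n_proteins=0)


class TestSimulateExperiment:
    def test_determinism_byte_identical(self, tmp_path):
        cfg = SimulationConfig.persistence_defaults(n_proteins=30, seed=11)
        t1, _ = simulate_experiment(cfg)
        t2, _ = simulate_experiment(
            SimulationConfig.persistence_defaults(n_proteins=30, seed=11)
        )
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_table(t1, p1)
        write_table(t2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seed_differs(self):
        t1, _ = simulate_experiment(SimulationConfig(n_proteins=10, seed=1))
        t2, _ = simulate_experiment(SimulationConfig(n_proteins=10, seed=2))
        assert not t1.equals(t2)

    def test_noiseless_ratios_exact(self, tmp_path):
        cfg = SimulationConfig(
            condition="persistence", n_proteins=25, seed=3,
            noise_cv=0.0, dropout=None, plateau=1.0, pool_purity=1.0,
            ratio_count_low_fraction=0.0,
        )
        table, truth = simulate_experiment(cfg)
        records = roundtrip(table, cfg, tmp_path)
        for rec in records:
            k = truth[rec.protein_id].true_k_per_h
            for (_, t), r in rec.ratio_hl.items():
                assert r == pytest.approx(math.expm1(k * t), rel=1e-10)

    def test_noiseless_rate_recovery_machine_precision(self, tmp_path):
        cfg = SimulationConfig(
            condition="persistence", n_proteins=25, seed=4,
            noise_cv=0.0, dropout=None, ratio_count_low_fraction=0.0,
        )
        table, truth = simulate_experiment(cfg)
        merged = merge_replicates(apply_quality_filters(roundtrip(table, cfg, tmp_path)))
        fits = fit_merged_courses(merged)
        assert len(fits) == 25
        for fit in fits:
            assert fit.k == pytest.approx(truth[fit.protein_id].true_k_per_h, rel=1e-10)

    def test_truth_half_life_identity(self):
        _, truth = simulate_experiment(SimulationConfig(n_proteins=10, seed=5))
        for rec in truth.values():
            assert rec.true_half_life_h * rec.true_k_per_h == pytest.approx(
                math.log(2), rel=1e-12
            )

    def test_fraction_expectation_matches_truth(self):
        # heavy/(heavy+light) should be centered on I(t) despite channel noise
        cfg = SimulationConfig(
            condition="resuscitation", n_proteins=1000, seed=6,
            noise_cv=0.1, dropout=None, plateau=0.9, pool_purity=0.95,
            rate_bounds_per_h=(0.2, 0.2000001),
        )
        table, truth = simulate_experiment(cfg)
        from pulsedyn.quant_io import ColumnMap

        columns = ColumnMap()
        t = 4.0
        fracs, expected = [], []
        for rep in ("rep1", "rep2", "rep3"):
            h = table[columns.intensity_heavy(rep, t)].to_numpy(float)
            l = table[columns.intensity_light(rep, t)].to_numpy(float)
            fracs.append(h / (h + l))
        frac = np.concatenate(fracs)
        ks = np.array([truth[pid].true_k_per_h for pid in table[columns.protein_id]])
        i_true = 0.9 * 0.95 * (1 - np.exp(-ks * t))
        assert np.mean(frac) == pytest.approx(np.mean(i_true), abs=0.005)

    def test_control_columns_present_and_blank(self, tmp_path):
        cfg = SimulationConfig(n_proteins=5, seed=7, dropout=(8.0, 2.0))
        table, _ = simulate_experiment(cfg)
        from pulsedyn.quant_io import ColumnMap

        columns = ColumnMap()
        assert columns.ratio("rep1", 0.0) in table.columns
        records = roundtrip(table, cfg, tmp_path)
        for rec in records:
            assert all(t > 0 for (_, t) in rec.ratio_hl)

    def test_dropout_removes_low_intensity_cells(self, tmp_path):
        cfg_dense = SimulationConfig(n_proteins=200, seed=8, dropout=None)
        cfg_drop = SimulationConfig(n_proteins=200, seed=8, dropout=(9.0, 1.5))
        n_dense = sum(
            len(r.ratio_hl)
            for r in roundtrip(simulate_experiment(cfg_dense)[0], cfg_dense, tmp_path, "a.tsv")
        )
        n_drop = sum(
            len(r.ratio_hl)
            for r in roundtrip(simulate_experiment(cfg_drop)[0], cfg_drop, tmp_path, "b.tsv")
        )
        assert n_drop < n_dense

    def test_ratio_count_filter_exercised(self, tmp_path):
        cfg = SimulationConfig(n_proteins=100, seed=9, ratio_count_low_fraction=0.3)
        records = roundtrip(simulate_experiment(cfg)[0], cfg, tmp_path)
        counts = [c for r in records for c in r.ratio_count.values()]
        assert any(c == 1 for c in counts)
        filtered = apply_quality_filters(records)
        assert sum(len(r.ratio_hl) for r in filtered) < sum(
            len(r.ratio_hl) for r in records
        )


class TestClusterScenario:
    def test_labels_assigned_per_group(self):
        cfg = SimulationConfig(condition="resuscitation", seed=10)
        _, truth = make_cluster_scenario(3, 4, [0.01, 0.1, 1.0], cfg)
        labels = [truth[f"SYN{i + 1:05d}"].true_cluster for i in range(12)]
        assert labels == [1] * 4 + [2] * 4 + [3] * 4

    def test_duplicate_rates_rejected(self):
        with pytest.raises(ConfigError, match="distinct"):
            make_cluster_scenario(2, 3, [0.1, 0.1], SimulationConfig(seed=1))

    def test_wrong_rate_count_rejected(self):
        with pytest.raises(ConfigError, match="2 rates"):
            make_cluster_scenario(2, 3, [0.1], SimulationConfig(seed=1))

    def test_single_cluster(self):
        _, truth = make_cluster_scenario(1, 5, [0.2], SimulationConfig(seed=12))
        assert {r.true_cluster for r in truth.values()} == {1}

    def test_noiseless_two_groups_separable(self, tmp_path):
        from sklearn.metrics import adjusted_rand_score

        from pulsedyn.profile_clustering import build_profile_matrix, cluster_profiles
        from pulsedyn.turnover_kinetics import profiles_from_records

        cfg = SimulationConfig(
            condition="resuscitation", seed=13, noise_cv=0.0, dropout=None,
            ratio_count_low_fraction=0.0, plateau=0.95,
        )
        table, truth = make_cluster_scenario(2, 8, [0.01, 0.5], cfg)
        records = apply_quality_filters(roundtrip(table, cfg, tmp_path))
        matrix = build_profile_matrix(profiles_from_records(records), cfg.design())
        result = cluster_profiles(matrix, n_clusters=2)
        pred = [result.assignment[pid] for pid in matrix.protein_ids]
        true = [truth[pid].true_cluster for pid in matrix.protein_ids]
        assert adjusted_rand_score(true, pred) == 1.0
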