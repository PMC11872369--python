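import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from suitsurv import sdm
from suitsurv.geo import EnvGridStack, GridTransform
from suitsurv.sdm import (
    ModelMatrixConfig,
    build_training_region,
    estimate_autocorr_range_km,
    evaluate,
    fit_presence_envelope,
    fit_sdm,
    make_block_partition,
    make_random_partition,
    max_tss,
    rank_auc,
    run_model_matrix,
    sample_pa_es,
    sample_pa_ge,
)
from suitsurv.synthetic import EnvFieldSpec, gen_env_stack

from conftest import make_occ


def flat_env(shape=(10, 10)):
    return EnvGridStack({"env1": np.zeros(shape)},
                        GridTransform(0, shape[0], 1, 1))


class TestTrainingRegion:
    def test_discrete_disk_cell_count(self):
        occ = make_occ([(4.5, 5.5)])
        region = build_training_region(occ, flat_env(), buffer_km=2)
        assert region.mask.sum() == 13  # discrete disk of radius 2

    def test_buffer_larger_than_grid_covers_valid_cells(self):
        occ = make_occ([(4.5, 5.5)])
        region = build_training_region(occ, flat_env(), buffer_km=1000)
        assert region.mask.all()

    def test_occurrences_always_inside_their_mask(self, virtual_world):
        region = build_training_region(virtual_world["occ"],
                                       virtual_world["env"], buffer_km=10)
        env = virtual_world["env"]
        row, col = env.cell_of(virtual_world["occ"]["lon"].to_numpy(),
                               virtual_world["occ"]["lat"].to_numpy())
        assert region.mask[row, col].all()


class TestGeographicExclusion:
    def test_exclusion_leaves_exactly_the_far_cells(self):
        env = flat_env((5, 5))
        occ = make_occ([(0.5, 4.5)])  # top-left cell
        region = build_training_region(occ, env, buffer_km=100)
        pa = sample_pa_ge(region, occ, env, exclusion_km=3.0, n=14,
                          replicate_seed=0)
        # eligibility enumeration: cells with centre distance > 3 from (0.5,4.5)
        gx, gy = env.center_grids()
        dist = np.hypot(gx - 0.5, gy - 4.5)
        assert (dist > 3).sum() == 14
        row, col = env.cell_of(pa.points["lon"].to_numpy(),
                               pa.points["lat"].to_numpy())
        assert (dist[row, col] > 3).all()

    @pytest.mark.parametrize("seed", range(3))
    def test_every_point_outside_exclusion_radius(self, virtual_world, seed):
        env, occ = virtual_world["env"], virtual_world["occ"]
        region = build_training_region(occ, env, buffer_km=50)
        pa = sample_pa_ge(region, occ, env, exclusion_km=5.0, n=300,
                          replicate_seed=seed)
        from suitsurv.geo import cross_distance_km
        d = cross_distance_km(pa.points["lon"].to_numpy(),
                              pa.points["lat"].to_numpy(),
                              occ["lon"].to_numpy(), occ["lat"].to_numpy(),
                              geographic=False)
        assert d.min(axis=1).min() > 5.0

    def test_shortfall_is_an_error_naming_counts(self):
        env = flat_env((5, 5))
        occ = make_occ([(0.5, 4.5)])
        region = build_training_region(occ, env, buffer_km=100)
        with pytest.raises(ValueError, match="14 eligible"):
            sample_pa_ge(region, occ, env, exclusion_km=3.0, n=15)


class TestPresenceEnvelope:
    def test_chi2_coverage_of_multivariate_normal(self):
        rng = np.random.default_rng(0)
        X = rng.multivariate_normal([1.0, -1.0, 0.0],
                                    [[1, 0.3, 0], [0.3, 1, 0], [0, 0, 2]],
                                    size=5000)
        envl = fit_presence_envelope(X, quantile=0.95)
        assert envl.contains(X).mean() == pytest.approx(0.95, abs=0.03)

    def test_mean_inside_extreme_outside(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((200, 2))
        envl = fit_presence_envelope(X)
        assert envl.contains(X.mean(axis=0)[None, :])[0]
        assert not envl.contains(np.array([[10.0, 0.0]]))[0]

    def test_collinear_presences_rejected(self):
        x = np.linspace(0, 1, 50)
        X = np.c_[x, 2 * x]
        with pytest.raises(ValueError, match="collinear"):
            fit_presence_envelope(X)


class TestEnvironmentalSimilarityPAs:
    def test_envelope_accepting_everything_is_an_error(self):
        env = flat_env((6, 6))  # constant environment: nothing is dissimilar
        occ = make_occ([(0.5, 5.5), (2.5, 3.5)])
        region = build_training_region(occ, env, buffer_km=100)
        rng = np.random.default_rng(0)
        envl = fit_presence_envelope(rng.standard_normal((50, 1)) * 5,
                                     quantile=0.999)
        with pytest.raises(ValueError, match="dissimilar"):
            sample_pa_es(region, envl, env, n=3)

    def test_bimodal_environment_targets_the_other_mode(self):
        """Presences in one environmental cluster: nearly all pseudo-
        absences land in the other cluster."""
        rng = np.random.default_rng(2)
        vals = np.zeros((40, 40))
        vals[:, 20:] = 5.0  # two clusters: 0 and 5
        env = EnvGridStack({"env1": vals + rng.normal(0, 0.1, (40, 40))},
                           GridTransform(0, 40, 1, 1))
        # presences spread over the low-mode half
        cells = rng.choice(20, size=(100, 2))
        occ = make_occ([(c + 0.5, r + 0.5) for c, r in cells])
        region = build_training_region(occ, env, buffer_km=1000)
        presence_env = env.sample(occ["lon"].to_numpy(), occ["lat"].to_numpy())
        envl = fit_presence_envelope(presence_env, quantile=0.99)
        pa = sample_pa_es(region, envl, env, n=200, replicate_seed=3)
        pa_env = env.sample(pa.points["lon"].to_numpy(),
                            pa.points["lat"].to_numpy())
        assert (pa_env > 2.5).mean() >= 0.95

    def test_all_sampled_cells_fail_the_envelope(self, virtual_world):
        env, occ = virtual_world["env"], virtual_world["occ"]
        region = build_training_region(occ, env, buffer_km=200)
        presence_env = env.sample(occ["lon"].to_numpy(), occ["lat"].to_numpy())
        envl = fit_presence_envelope(presence_env)
        pa = sample_pa_es(region, envl, env, n=200, replicate_seed=4)
        pa_env = env.sample(pa.points["lon"].to_numpy(),
                            pa.points["lat"].to_numpy())
        assert (~envl.contains(pa_env)).all()


class TestBlockPartition:
    def test_white_noise_collapses_to_minimum_block(self):
        env = gen_env_stack(EnvFieldSpec(2, (80, 80), autocorr_range=0,
                                         seed=1))
        est = estimate_autocorr_range_km(env, seed=0)
        assert est <= 3.0  # collapses towards the 1-km cell floor

    def test_known_range_recovered_within_factor_two(self):
        env = gen_env_stack(EnvFieldSpec(1, (200, 200), autocorr_range=20,
                                         seed=5))
        est = estimate_autocorr_range_km(env, seed=1)
        assert 10 <= est <= 40

    def test_every_occurrence_assigned_exactly_one_fold(self, virtual_world):
        env, occ = virtual_world["env"], virtual_world["occ"]
        region = build_training_region(occ, env, buffer_km=200)
        part = make_block_partition(occ, env, region, k=4, block_size_km=15,
                                    seed=0)
        assert part.occurrence_folds.shape == (len(occ),)
        assert set(part.occurrence_folds) <= {0, 1, 2, 3}
        assert part.fold_presence_counts.sum() == len(occ)

    def test_all_presences_in_one_block_degenerate(self):
        env = flat_env((20, 20))
        occ = make_occ([(2.2, 17.8), (2.4, 17.6), (2.6, 17.4)])
        region = build_training_region(occ, env, buffer_km=100)
        part = make_block_partition(occ, env, region, k=4, block_size_km=10,
                                    seed=0)
        assert part.fold_presence_counts.max() == 3
        assert (part.occurrence_folds == part.occurrence_folds[0]).all()

    def test_oversized_block_falls_back_to_strips(self):
        env = flat_env((10, 10))
        occ = make_occ([(1.5, 8.5), (8.5, 1.5)])
        region = build_training_region(occ, env, buffer_km=100)
        part = make_block_partition(occ, env, region, k=4,
                                    block_size_km=500, seed=0)
        assert part.fallback_strips

    def test_reassignment_seed_changes_folds(self, virtual_world):
        env, occ = virtual_world["env"], virtual_world["occ"]
        region = build_training_region(occ, env, buffer_km=200)
        p1 = make_block_partition(occ, env, region, block_size_km=15, seed=1)
        p2 = make_block_partition(occ, env, region, block_size_km=15, seed=2)
        assert (p1.occurrence_folds != p2.occurrence_folds).any()


class TestRandomPartition:
    def test_quarter_of_presences_held_out(self):
        occ = make_occ([(i, 0) for i in range(100)])
        pa = pd.DataFrame({"lon": np.arange(40.0), "lat": np.zeros(40)})
        splits = make_random_partition(occ, pa, runs=3, seed=0)
        for s in splits:
            assert len(s["occ_test"]) == 25
            assert len(s["pa_test"]) == 10
            assert set(s["occ_test"]).isdisjoint(s["occ_train"])
            assert set(s["pa_test"]).isdisjoint(s["pa_train"])

    def test_different_seeds_different_test_sets(self):
        occ = make_occ([(i, 0) for i in range(60)])
        pa = pd.DataFrame({"lon": np.arange(60.0), "lat": np.zeros(60)})
        a = make_random_partition(occ, pa, runs=1, seed=1)[0]
        b = make_random_partition(occ, pa, runs=1, seed=2)[0]
        assert set(a["occ_test"]) != set(b["occ_test"])


class TestModelFit:
    def test_separable_classes_reach_training_auc_one(self):
        p = np.linspace(2, 3, 30)[:, None]
        a = np.linspace(-3, -2, 60)[:, None]
        m = fit_sdm(p, a, ["x"], seed=0)
        assert rank_auc(m.predict_values(p), m.predict_values(a)) == 1.0

    def test_predictions_always_in_unit_interval(self, virtual_world):
        env, occ = virtual_world["env"], virtual_world["occ"]
        region = build_training_region(occ, env, buffer_km=50)
        pa = sample_pa_ge(region, occ, env, 5.0, 400, 1)
        m = fit_sdm(env.sample(occ["lon"].to_numpy(), occ["lat"].to_numpy()),
                    env.sample(pa.points["lon"].to_numpy(),
                               pa.points["lat"].to_numpy()),
                    env.layer_names, seed=1)
        pred = m.predict_grid(env)
        ok = np.isfinite(pred)
        assert ((pred[ok] >= 0) & (pred[ok] <= 1)).all()

    def test_shuffled_labels_give_chance_level_auc(self, virtual_world):
        env, occ = virtual_world["env"], virtual_world["occ"]
        region = build_training_region(occ, env, buffer_km=50)
        pa = sample_pa_ge(region, occ, env, 5.0, 300, 2)
        both = np.vstack([
            env.sample(occ["lon"].to_numpy(), occ["lat"].to_numpy())[:250],
            env.sample(pa.points["lon"].to_numpy(),
                       pa.points["lat"].to_numpy())[:250]])
        labels = np.random.default_rng(5).permutation(
            np.r_[np.ones(250), np.zeros(250)])
        m = fit_sdm(both[labels == 1], both[labels == 0], env.layer_names,
                    seed=3)
        pred = m.predict_values(both)
        assert 0.4 <= rank_auc(pred[labels == 1], pred[labels == 0]) <= 0.6

    def test_virtual_species_suitability_recovered(self, virtual_world):
        """Spearman correlation between predicted and true suitability
        over in-region cells >= 0.8 (parameter recovery)."""
        env, occ = virtual_world["env"], virtual_world["occ"]
        region = build_training_region(occ, env, buffer_km=50)
        pa = sample_pa_ge(region, occ, env, 5.0, 800, 3)
        m = fit_sdm(env.sample(occ["lon"].to_numpy(), occ["lat"].to_numpy()),
                    env.sample(pa.points["lon"].to_numpy(),
                               pa.points["lat"].to_numpy()),
                    env.layer_names, seed=4)
        pred = m.predict_grid(env)
        rho = spearmanr(pred[region.mask],
                        virtual_world["suitability"][region.mask]).statistic
        assert rho >= 0.8

    def test_missing_target_layer_named(self, virtual_world, env_small):
        env, occ = virtual_world["env"], virtual_world["occ"]
        m = fit_sdm(env.sample(occ["lon"][:50].to_numpy(),
                               occ["lat"][:50].to_numpy()),
                    np.zeros((50, 3)), env.layer_names, seed=0)
        bad = EnvGridStack({"other": np.zeros((5, 5))},
                           GridTransform(0, 5, 1, 1))
        with pytest.raises(ValueError, match="env1"):
            m.predict_grid(bad)

    def test_serialization_round_trip(self):
        m = fit_sdm(np.random.default_rng(0).normal(1, 1, (30, 2)),
                    np.random.default_rng(1).normal(-1, 1, (60, 2)))
        m2 = sdm.FittedSDM.from_dict(m.to_dict())
        X = np.random.default_rng(2).normal(0, 1, (20, 2))
        np.testing.assert_allclose(m.predict_values(X), m2.predict_values(X))


class TestEvaluation:
    def test_perfect_ranking(self):
        assert rank_auc([0.9, 0.8], [0.2, 0.1]) == 1.0
        tss, _ = max_tss(np.array([0.9, 0.8]), np.array([0.2, 0.1]))
        assert tss == 1.0

    def test_interleaved_predictions_exhaustive_threshold_scan(self):
        """AUC 0.5 but max TSS 0.5: a threshold isolating the top
        presence gives sens 0.5, spec 1.0."""
        p = np.array([0.6, 0.2])
        a = np.array([0.5, 0.3])
        assert rank_auc(p, a) == 0.5
        tss, thr = max_tss(p, a)
        assert tss == pytest.approx(0.5)
        assert 0.5 < thr <= 0.6
        # brute-force oracle over the same grid
        best = max((p >= t).mean() + (a < t).mean() - 1
                   for t in sdm.TSS_THRESHOLDS)
        assert tss == pytest.approx(best)

    def test_constant_predictions_are_chance(self):
        assert rank_auc([0.4, 0.4], [0.4, 0.4]) == 0.5
        tss, _ = max_tss(np.array([0.4, 0.4]), np.array([0.4, 0.4]))
        assert tss == pytest.approx(0.0)

    def test_auc_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(0)
        p, a = rng.beta(3, 2, 50), rng.beta(2, 3, 80)
        assert rank_auc(p ** 3, a ** 3) == pytest.approx(rank_auc(p, a))
        assert rank_auc(np.log(p), np.log(a)) == pytest.approx(rank_auc(p, a))

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            rank_auc([], [0.1])


@pytest.fixture(scope="module")
def matrix(virtual_world):
    cfg = ModelMatrixConfig(
        "vsp", {"all": virtual_world["env"].layer_names},
        pa_strategies=("GE",), cv_strategies=("random",),
        pa_n=300, pa_exclusion_km=5.0, buffer_km=50,
        pa_replicates=2, cv_runs=3, master_seed=11)
    return run_model_matrix(virtual_world["occ"], virtual_world["env"], cfg)


class TestModelMatrix:
    def test_runs_times_replicates_models(self, matrix):
        models, metrics = matrix
        assert len(models) == 2 * 3
        assert len(metrics) == 6
        assert set(metrics["pa_replicate"]) == {0, 1}
        assert set(metrics["cv_run"]) == {0, 1, 2}

    def test_same_master_seed_identical_metrics(self, virtual_world, matrix):
        cfg = ModelMatrixConfig(
            "vsp", {"all": virtual_world["env"].layer_names},
            pa_strategies=("GE",), cv_strategies=("random",),
            pa_n=300, pa_exclusion_km=5.0, buffer_km=50,
            pa_replicates=2, cv_runs=3, master_seed=11)
        _, metrics2 = run_model_matrix(virtual_world["occ"],
                                       virtual_world["env"], cfg)
        pd.testing.assert_frame_equal(matrix[1], metrics2)

    def test_calibration_auc_exceeds_validation_on_average(self, matrix):
        _, metrics = matrix
        assert metrics["auc_cal"].mean() >= metrics["auc_val"].mean() - 0.01
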