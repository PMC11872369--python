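import numpy as np
import pandas as pd
import pytest
from scipy.optimize import curve_fit
from scipy.special import expit
from scipy.stats import chisquare

from suitsurv import synthetic
from suitsurv.synthetic import (
    EnvFieldSpec,
    InventorySimSpec,
    SpecError,
    VirtualSpeciesSpec,
    gen_env_stack,
    gen_inventory,
    gen_true_suitability,
    sample_occurrences,
    survival_probability,
)


class TestEnvStackGeneration:
    def test_white_noise_layers_are_uncorrelated(self):
        st = gen_env_stack(EnvFieldSpec(2, (200, 200), autocorr_range=0,
                                        seed=1))
        r = np.corrcoef(st.as_array().reshape(2, -1))[0, 1]
        assert abs(r) < 0.05

    def test_target_correlations_recovered(self):
        C = np.array([[1.0, 0.6, 0.3], [0.6, 1.0, 0.2], [0.3, 0.2, 1.0]])
        st = gen_env_stack(EnvFieldSpec(3, (150, 150), autocorr_range=10,
                                        layer_correlation=C, seed=3))
        emp = np.corrcoef(st.as_array().reshape(3, -1))
        assert np.abs(emp - C).max() < 0.1

    def test_same_spec_same_seed_bit_identical(self):
        spec = EnvFieldSpec(2, (50, 50), autocorr_range=5, seed=9)
        a = gen_env_stack(spec).as_array()
        b = gen_env_stack(EnvFieldSpec(2, (50, 50), autocorr_range=5,
                                       seed=9)).as_array()
        np.testing.assert_array_equal(a, b)

    def test_variogram_effective_range_recovered(self):
        """Exponential-variogram fit on a generated layer recovers the
        requested autocorrelation range to within a factor ~2."""
        st = gen_env_stack(EnvFieldSpec(1, (200, 200), autocorr_range=20,
                                        seed=5))
        z = st.layers["env1"]
        rng = np.random.default_rng(0)
        idx = rng.choice(z.size, 3000, replace=False)
        r, c = np.unravel_index(idx, z.shape)
        v = z[r, c]
        d = np.hypot(r[:, None] - r[None, :], c[:, None] - c[None, :]).ravel()
        g = (0.5 * (v[:, None] - v[None, :]) ** 2).ravel()
        sel = (d > 0) & (d < 60)
        bins = np.linspace(0, 60, 31)
        bi = np.digitize(d[sel], bins)
        bd = np.array([d[sel][bi == i].mean() for i in range(1, 31)])
        bg = np.array([g[sel][bi == i].mean() for i in range(1, 31)])
        p, _ = curve_fit(lambda h, s, a: s * (1 - np.exp(-3 * h / a)),
                         bd, bg, p0=[1.0, 10.0], maxfev=10000)
        assert 10 <= p[1] <= 40

    def test_non_psd_correlation_rejected(self):
        C = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(SpecError, match="semidefinite"):
            EnvFieldSpec(3, (20, 20), layer_correlation=C)


class TestTrueSuitability:
    def test_closed_form_values_on_toy_grid(self, tiny_grid):
        spec = VirtualSpeciesSpec(optima=[0.0], breadths=[1.0])
        suit = gen_true_suitability(tiny_grid, spec)
        expected = np.exp(-0.5 * np.array([[0.0, 1.0], [4.0, 9.0]]))
        np.testing.assert_allclose(suit, expected, rtol=1e-12)
        assert suit[0, 0] == 1.0                      # at the optimum
        assert suit[0, 1] == pytest.approx(np.exp(-0.5))  # one breadth away

    def test_layer_permutation_invariance(self, env_small):
        spec = VirtualSpeciesSpec(optima=[0.5, -0.2, 0.1],
                                  breadths=[0.8, 1.1, 0.9])
        suit = gen_true_suitability(env_small, spec)
        perm = [2, 0, 1]
        permuted_env = synthetic.EnvGridStack(
            {n: env_small.layers[env_small.layer_names[p]]
             for n, p in zip(env_small.layer_names, perm)},
            env_small.transform, env_small.crs)
        spec_p = VirtualSpeciesSpec(optima=np.array(spec.optima)[perm],
                                    breadths=np.array(spec.breadths)[perm])
        np.testing.assert_allclose(
            gen_true_suitability(permuted_env, spec_p), suit, rtol=1e-12)

    def test_nodata_propagates(self, env_small):
        env = synthetic.EnvGridStack(
            {k: v.copy() for k, v in env_small.layers.items()},
            env_small.transform, env_small.crs)
        env.layers["env1"][0, 0] = np.nan
        suit = gen_true_suitability(
            env, VirtualSpeciesSpec(optima=[0, 0, 0], breadths=[1, 1, 1]))
        assert np.isnan(suit[0, 0])
        assert np.isfinite(suit[1:]).all()


class TestOccurrenceSampling:
    def test_uniform_suitability_unbiased_sampling_is_uniform(self):
        """Chi-square goodness of fit against uniform occupancy, pooled
        over 50 replicates, should not reject at alpha = 0.01."""
        from suitsurv.geo import EnvGridStack, GridTransform
        env = EnvGridStack({"env1": np.zeros((10, 10))},
                           GridTransform(0, 10, 1, 1))
        suit = np.ones((10, 10))
        counts = np.zeros(100)
        for rep in range(50):
            spec = VirtualSpeciesSpec(optima=[0], breadths=[1],
                                      n_occurrences=40, seed=rep)
            occ = sample_occurrences(suit, env, spec)
            row, col = env.cell_of(occ["lon"].to_numpy(),
                                   occ["lat"].to_numpy())
            np.add.at(counts, row * 10 + col, 1)
        assert chisquare(counts).pvalue > 0.01

    def test_single_positive_cell_receives_all_occurrences(self):
        from suitsurv.geo import EnvGridStack, GridTransform
        env = EnvGridStack({"env1": np.zeros((5, 5))},
                           GridTransform(0, 5, 1, 1))
        suit = np.zeros((5, 5))
        suit[2, 3] = 1.0
        occ = sample_occurrences(
            suit, env, VirtualSpeciesSpec(optima=[0], breadths=[1],
                                          n_occurrences=1, seed=0))
        assert env.cell_of(occ.loc[0, "lon"], occ.loc[0, "lat"]) == (2, 3)

    def test_shortfall_of_positive_cells_is_an_error(self):
        from suitsurv.geo import EnvGridStack, GridTransform
        env = EnvGridStack({"env1": np.zeros((3, 3))},
                           GridTransform(0, 3, 1, 1))
        suit = np.zeros((3, 3))
        suit[0, 0] = 1.0
        with pytest.raises(SpecError, match="positive-weight"):
            sample_occurrences(
                suit, env, VirtualSpeciesSpec(optima=[0], breadths=[1],
                                              n_occurrences=5, seed=0))

    def test_fixed_seed_reproduces_point_set(self, virtual_world):
        spec = virtual_world["spec"]
        a = sample_occurrences(virtual_world["suitability"],
                               virtual_world["env"], spec)
        b = sample_occurrences(virtual_world["suitability"],
                               virtual_world["env"], spec)
        pd.testing.assert_frame_equal(a, b)


class TestInventory:
    def test_saturated_logistic_gives_full_survival(self):
        spec = InventorySimSpec(species=[("a", "s", True)], gardens=["G"],
                                n_individuals=50, baseline_logit=10.0, seed=0)
        inv = gen_inventory(spec)
        assert (inv["status"] == "alive").all()

    def test_section_effect_matches_logistic_expectation(self):
        """Empirical SR difference between sections tracks the closed-form
        logistic difference at n = 500."""
        b = 0.5
        spec = InventorySimSpec(
            species=[("lo", "hit", True), ("hi", "ref", True)],
            gardens=["G"], n_individuals=500, baseline_logit=b,
            section_effects={"hit": -2.0}, seed=3)
        inv = gen_inventory(spec)
        sr = inv.groupby("species")["status"].apply(
            lambda s: (s == "alive").mean())
        expected = expit(b - 2.0) - expit(b)
        assert (sr["lo"] - sr["hi"]) == pytest.approx(expected, abs=0.06)

    def test_convergence_to_logistic_mean(self):
        spec = InventorySimSpec(species=[("a", "s", True)], gardens=["G"],
                                n_individuals=2000, baseline_logit=1.0,
                                seed=11)
        inv = gen_inventory(spec)
        sr = (inv["status"] == "alive").mean()
        assert sr == pytest.approx(survival_probability(spec, "s", "G"),
                                   abs=0.03)

    def test_every_death_has_a_cause_from_the_mix(self):
        spec = InventorySimSpec(species=[("a", "s", True)], gardens=["G"],
                                n_individuals=300, baseline_logit=-1.0,
                                seed=2)
        inv = gen_inventory(spec)
        dead = inv[inv["status"] == "dead"]
        assert len(dead) > 0
        assert dead["death_cause"].isin(synthetic.DEATH_CAUSES).all()
        assert inv.loc[inv["status"] == "alive", "death_cause"].isna().all()

    def test_fixed_seed_reproduces_table(self):
        spec = InventorySimSpec(species=[("a", "s", True)], gardens=["G1", "G2"],
                                n_individuals=30, seed=5)
        pd.testing.assert_frame_equal(gen_inventory(spec), gen_inventory(spec))

    def test_cause_mix_must_sum_to_one(self):
        with pytest.raises(SpecError, match="probability"):
            InventorySimSpec(species=[("a", "s", True)], gardens=["G"],
                             cause_mix={"climate": 0.5, "pest": 0.2})
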