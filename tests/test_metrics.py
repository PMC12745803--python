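"""Clone-based robustness/variability estimators, season metrics, exploration."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import grnca as g
from grnca.evolution import RunTrace
from grnca.metrics import (
    improvement_slope,
    mds_embed,
    variability_bias,
)

DEV = g.DevelopmentConfig(n_genes=4, n_cells=8, n_rows=8)
MUT = g.MutationConfig()


def make_target(rule=30, n_ones=4):
    ic = g.manual_spaced_ic(DEV.n_cells, n_ones)
    return g.generate_target(rule, ic, DEV.n_rows - 1)


def synthetic_trace(mean_fit, env, max_fit=None):
    mean_fit = np.asarray(mean_fit, dtype=float)
    env = np.asarray(env, dtype=int)
    max_fit = mean_fit if max_fit is None else np.asarray(max_fit, dtype=float)
    return RunTrace(
        generation=np.arange(mean_fit.size), env=env, max_fit=max_fit,
        mean_fit=mean_fit, switches=[], snapshots=[], dual=[], seed=0, config={},
    )


class TestMutationalRobustness:
    def test_disabled_operator_means_perfect_robustness(self):
        w = np.random.default_rng(0).normal(size=(4, 6))
        rep = g.mutational_robustness(
            w, make_target(), g.MutationConfig(sd=0.0), DEV,
            n_clones=50, rng=np.random.default_rng(1),
        )
        assert rep.phenotypic_robustness == 0.0
        assert rep.fitness_robustness == 0.0

    def test_fixed_seed_is_reproducible(self):
        w = np.random.default_rng(2).normal(size=(4, 6))
        reps = [
            g.mutational_robustness(w, make_target(), MUT, DEV, n_clones=100,
                                    rng=np.random.default_rng(7))
            for _ in range(2)
        ]
        assert reps[0] == reps[1]

    def test_phenotype_change_vanishes_with_the_mutation_step(self):
        """Development is smooth, so tiny steps move the phenotype less."""
        w = np.zeros((4, 6))
        values = []
        for sd in (0.5, 0.05, 0.005):
            rep = g.mutational_robustness(
                w, make_target(), g.MutationConfig(rate=1.0, sd=sd), DEV,
                n_clones=200, rng=np.random.default_rng(3),
            )
            values.append(rep.phenotypic_robustness)
        assert values[0] > values[1] > values[2] > 0

    def test_dense_noise_variant_touches_every_weight(self):
        w = np.zeros((4, 6))
        dense = g.mutational_robustness(
            w, make_target(), g.MutationConfig(rate=0.0, sd=0.5), DEV,
            n_clones=100, rng=np.random.default_rng(4), dense=True,
        )
        sparse = g.mutational_robustness(
            w, make_target(), g.MutationConfig(rate=0.0, sd=0.5), DEV,
            n_clones=100, rng=np.random.default_rng(4),
        )
        assert sparse.phenotypic_robustness == 0.0
        assert dense.phenotypic_robustness > 0.0

    def test_correlates_with_population_variability(self):
        """Genotypes whose clones move far in phenotype also spread more."""
        rng = np.random.default_rng(5)
        target = make_target()
        rob, var = [], []
        for scale in np.linspace(0.1, 3.0, 12):
            w = rng.normal(0, scale, size=(4, 6))
            seed = int(rng.integers(2**31))
            rep = g.mutational_robustness(w, target, MUT, DEV, n_clones=150,
                                          rng=np.random.default_rng(seed))
            vmap = g.variability_map(w, target.ic, MUT, DEV, n_clones=150,
                                     rng=np.random.default_rng(seed))
            rob.append(rep.phenotypic_robustness)
            var.append(vmap.grid.mean())
        rho, _ = spearmanr(rob, var)
        assert rho > 0


class TestVariabilityMap:
    def test_disabled_operator_gives_a_zero_map(self):
        w = np.random.default_rng(0).normal(size=(4, 6))
        vmap = g.variability_map(w, make_target().ic, g.MutationConfig(sd=0.0),
                                 DEV, n_clones=20, rng=np.random.default_rng(1))
        # identical clones: SD is zero up to summation round-off
        assert np.allclose(vmap.grid, 0.0, atol=1e-12)

    def test_clamped_seed_row_never_varies(self):
        w = np.random.default_rng(2).normal(size=(4, 6))
        vmap = g.variability_map(w, make_target().ic, MUT, DEV, n_clones=50,
                                 rng=np.random.default_rng(3))
        assert not vmap.grid[0].any()
        assert vmap.grid[1:].max() > 0

    def test_bias_summary_splits_agreeing_and_differing_positions(self):
        ta, tb = make_target(30, 4), make_target(30, 2)
        pair = g.LandscapePair(mode="ic_switch", target_a=ta, target_b=tb)
        w = np.random.default_rng(4).normal(size=(4, 6))
        vmap = g.variability_map(w, ta.ic, MUT, DEV, n_clones=50,
                                 rng=np.random.default_rng(5))
        bias = variability_bias(vmap, pair)
        assert bias["n_agree"] + bias["n_differ"] == ta.grid.size
        assert bias["mean_sd_agree"] >= 0

    def test_identical_targets_leave_the_differing_set_absent(self):
        ta = make_target()
        pair = g.LandscapePair(mode="ic_switch", target_a=ta, target_b=ta)
        w = np.random.default_rng(6).normal(size=(4, 6))
        vmap = g.variability_map(w, ta.ic, MUT, DEV, n_clones=20,
                                 rng=np.random.default_rng(7))
        bias = variability_bias(vmap, pair)
        assert bias["mean_sd_differ"] is None
        assert bias["n_differ"] == 0


class TestDualFitness:
    def test_identical_targets_give_identical_columns(self):
        ta = make_target()
        pair = g.LandscapePair(mode="ic_switch", target_a=ta, target_b=ta)
        w = np.random.default_rng(0).normal(size=(20, 4, 6))
        _, fits = g.dual_fitness(w, pair, DEV, sample_fraction=0.5,
                                 rng=np.random.default_rng(1))
        assert fits.shape == (10, 2)
        assert np.array_equal(fits[:, 0], fits[:, 1])

    def test_full_sample_reports_everyone(self):
        ta, tb = make_target(30, 4), make_target(30, 2)
        pair = g.LandscapePair(mode="ic_switch", target_a=ta, target_b=tb)
        w = np.random.default_rng(2).normal(size=(7, 4, 6))
        idx, fits = g.dual_fitness(w, pair, DEV, sample_fraction=1.0,
                                   rng=np.random.default_rng(3))
        assert idx.tolist() == list(range(7))
        assert fits.shape == (7, 2)


class TestSeasonMetrics:
    def test_constant_fitness_means_no_drops_and_flat_slopes(self):
        # five seasons so both environments see >= 2 switches
        trace = synthetic_trace([0.5] * 10, [0, 0, 1, 1, 0, 0, 1, 1, 0, 0])
        summary = g.season_metrics(trace)
        switched = summary.seasons[summary.seasons["season"] > 0]
        assert np.allclose(switched["drop"], 0.0)
        assert np.allclose(summary.slopes["drop_slope"], 0.0)

    def test_collinear_post_switch_values_recover_the_exact_slope(self):
        # env 0 seasons land at post-switch 0.2, 0.3, 0.4 at season idx 2, 4, 6
        mean = [0.5, 0.5] + [0.9, 0.9, 0.2, 0.2, 0.9, 0.9, 0.3, 0.3,
                             0.9, 0.9, 0.4, 0.4]
        env = [0, 0] + [1, 1, 0, 0, 1, 1, 0, 0, 1, 1, 0, 0]
        summary = g.season_metrics(synthetic_trace(mean, env))
        env0 = summary.slopes.set_index("env").loc[0]
        assert env0["post_switch_slope"] == pytest.approx(0.1 / 2)  # per season index
        assert env0["post_switch_r2"] == pytest.approx(1.0)

    def test_step_drop_is_the_pre_minus_post_difference(self):
        trace = synthetic_trace([0.9, 0.9, 0.6, 0.8], [0, 0, 1, 1])
        summary = g.season_metrics(trace)
        assert summary.seasons.loc[1, "drop"] == pytest.approx(0.3)
        assert summary.seasons.loc[1, "post_switch"] == pytest.approx(0.6)

    def test_recovery_length_counts_generations_to_regain_pre_switch(self):
        trace = synthetic_trace([0.9, 0.9, 0.6, 0.7, 0.95, 0.95], [0, 0, 1, 1, 1, 1])
        summary = g.season_metrics(trace)
        assert summary.seasons.loc[1, "recovery"] == 2

    def test_unrecovered_season_is_capped_at_its_length(self):
        trace = synthetic_trace([0.9, 0.9, 0.2, 0.3], [0, 0, 1, 1])
        summary = g.season_metrics(trace)
        assert summary.seasons.loc[1, "recovery"] == 2  # season length cap

    def test_single_season_trace_rejected(self):
        with pytest.raises(ValueError):
            g.season_metrics(synthetic_trace([0.5, 0.6], [0, 0]))


class TestOffspringImprovement:
    def test_disabled_mutation_never_improves(self):
        w = np.random.default_rng(0).normal(size=(5, 4, 6))
        frac = g.offspring_improvement_fraction(
            w, make_target(), g.MutationConfig(sd=0.0), DEV, lam=4,
            rng=np.random.default_rng(1),
        )
        assert frac == 0.0

    def test_fraction_is_a_probability_and_reproducible(self):
        w = np.zeros((3, 4, 6))
        kwargs = dict(mcfg=g.MutationConfig(rate=1.0, sd=0.01), devcfg=DEV, lam=9)
        a = g.offspring_improvement_fraction(w, make_target(), rng=np.random.default_rng(2), **kwargs)
        b = g.offspring_improvement_fraction(w, make_target(), rng=np.random.default_rng(2), **kwargs)
        assert a == b
        assert 0.0 <= a <= 1.0

    def test_slope_over_switches(self):
        assert improvement_slope([0.1, 0.2, 0.3]) == pytest.approx(0.1)


class TestExploration:
    def test_identical_snapshots_travel_nowhere(self):
        w = np.random.default_rng(0).normal(size=(4, 6))
        report = g.genotype_exploration([[w, w, w], [w, w, w]], seed=0)
        assert not report.distance_from_start.any()
        assert not report.distance_from_previous.any()
        assert report.replicate_weight_sd == 0.0

    def test_unit_weight_change_is_unit_distance(self):
        w = np.zeros((4, 6))
        w2 = w.copy()
        w2[1, 3] += 1.0
        report = g.genotype_exploration([[w, w2]], seed=0)
        assert report.distance_from_start[0].tolist() == [0.0, 1.0]
        assert report.distance_from_previous[0, 1] == 1.0

    def test_mds_recovers_an_exactly_embeddable_triangle(self):
        d = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        coords, stress = mds_embed(d, seed=0)
        from scipy.spatial.distance import pdist, squareform
        recovered = squareform(pdist(coords))
        assert np.allclose(recovered, d, atol=1e-3)

    def test_mismatched_snapshot_counts_rejected(self):
        w = np.zeros((4, 6))
        with pytest.raises(ValueError):
            g.genotype_exploration([[w, w, w], [w, w]], seed=0)


class TestDifficultyAndBestEffect:
    def test_single_plateau_trace(self):
        trace = synthetic_trace([0.2, 0.8, 0.8], [0, 0, 0])
        assert g.difficulty([trace]) == pytest.approx(0.8)

    def test_average_over_replicates(self):
        t1 = synthetic_trace([0.7, 0.7], [0, 0])
        t2 = synthetic_trace([0.9, 0.9], [0, 0])
        assert g.difficulty([t1, t2]) == pytest.approx(0.8)

    def test_identical_treatments_have_zero_effect(self):
        t = synthetic_trace([0.5, 0.9], [0, 0])
        out = g.best_effect_summary([t], [t], [t])
        assert all(v == 0.0 for v in out.values())

    def test_effect_is_the_difference_of_best_values(self):
        var = synthetic_trace([0.5, 0.9], [0, 1])
        sta = synthetic_trace([0.5, 0.8], [0, 0])
        out = g.best_effect_summary([var], [sta], [sta])
        assert out["delta_mean_env1"] == pytest.approx(0.1)
        assert out["delta_max_env1"] == pytest.approx(0.1)
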