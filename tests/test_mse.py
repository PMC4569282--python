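"""Management strategy evaluation: operating model, control rule, trials."""

import numpy as np
import pytest

from turtlelrp.distributions import ConfigurationError, Dist
from turtlelrp.life_history import build_transition_matrix
from turtlelrp.mse import (
    ObservationModel,
    PopulationState,
    RiskSurface,
    TrialConfig,
    density_adjusted_matrix,
    init_population,
    observe_and_set_limit,
    project_annual,
    project_lrp_trajectory,
    run_base_trials,
    run_rebuild_trials,
    tune,
)

K = 10_000.0


@pytest.fixture(scope="module")
def matrix(means_matrix):
    return means_matrix


@pytest.fixture(scope="module")
def base_surface():
    cfg = TrialConfig(objective="nmnp", approach="tag", n_sims=500, seed=42)
    return run_base_trials(cfg)


@pytest.fixture(scope="module")
def rebuild_result():
    cfg = TrialConfig(objective="rebuild", approach="tag", n_sims=300,
                      horizon=200, seed=13)
    return run_rebuild_trials(cfg, percentile=15.0, f_a_grid=[0.0, 0.1, 0.5, 1.0])


class TestInitialization:
    def test_stable_start_hits_requested_adult_equivalents(self, matrix):
        st = init_population(matrix, K, 0.1, "stable")
        assert st.adult_equivalents() == pytest.approx(0.1 * K, rel=1e-12)

    def test_skewed_start_has_larger_adult_share(self, matrix):
        stable = init_population(matrix, K, 0.1, "stable")
        skewed = init_population(matrix, K, 0.1, "skewed")
        assert skewed.adult_equivalents() == pytest.approx(0.1 * K, rel=1e-12)
        assert skewed.adults / skewed.n.sum() > stable.adults / stable.n.sum()

    def test_nonpositive_capacity_rejected(self, matrix):
        with pytest.raises(ConfigurationError):
            init_population(matrix, 0.0, 0.1)


class TestProjection:
    def test_small_population_grows_at_lambda_m(self, matrix):
        st = init_population(matrix, K, 0.001, "stable")
        for _ in range(5):
            st = project_annual(st)
        annualized = (st.adult_equivalents() / (0.001 * K)) ** (1 / 5)
        assert annualized == pytest.approx(1.05, rel=0.01)

    def test_equilibrium_at_carrying_capacity(self, matrix):
        """At K the density-adjusted growth rate is 1; from the matched
        structure the state is exactly stationary."""
        adj = density_adjusted_matrix(matrix, 1.0)
        n0 = adj.w * (K / float(adj.w @ matrix.v))
        st = PopulationState(n=n0, K=K, matrix=matrix)
        nxt = project_annual(st)
        assert abs(nxt.adult_equivalents() - K) < 1e-6
        assert np.allclose(nxt.n, st.n, rtol=1e-9)

    def test_logistic_sustainable_yield_holds_half_k(self, matrix):
        """Removing 0.5(lambda_m - 1) N_MNP each year holds a population at
        N_MNP = 0.5 K (the maximum-net-productivity equilibrium)."""
        adj = density_adjusted_matrix(matrix, 1.0 + 0.05 / 2)
        n0 = adj.w * (0.5 * K / float(adj.w @ matrix.v))
        st = PopulationState(n=n0, K=K, matrix=matrix)
        quota = 0.5 * 0.05 * (0.5 * K)
        for _ in range(100):
            st = project_annual(st, quota, units="adult_equivalents")
            assert st.adult_equivalents() == pytest.approx(0.5 * K, rel=0.01)

    def test_excessive_quota_zeroes_population(self, matrix):
        st = init_population(matrix, K, 0.01, "stable")
        nxt = project_annual(st, removals=10 * K, units="adult_equivalents")
        assert np.all(nxt.n == 0.0)

    def test_negative_removals_rejected(self, matrix):
        st = init_population(matrix, K, 0.1)
        with pytest.raises(ConfigurationError):
            project_annual(st, removals=-1.0)


class TestControlRule:
    def test_zero_cv_point_growth_gives_exact_quota(self, matrix, rng):
        st = init_population(matrix, K, 0.1)
        st.n *= 100.0 / st.n.sum()  # head count 100
        obs = ObservationModel(cv=0.0, lambda_hat=Dist.point(1.05))
        quota = observe_and_set_limit(st, obs, percentile=37.0, f_a=1.0, rng=rng)
        assert quota == pytest.approx(2.5, rel=1e-9)

    def test_bias_multiplier_is_linear(self, matrix):
        st = init_population(matrix, K, 0.1)
        obs1 = ObservationModel(cv=0.5)
        obs2 = ObservationModel(cv=0.5, bias=2.0)
        q1 = observe_and_set_limit(st, obs1, 15.0, 0.6, np.random.default_rng(4))
        q2 = observe_and_set_limit(st, obs2, 15.0, 0.6, np.random.default_rng(4))
        assert q2 == pytest.approx(2.0 * q1, rel=1e-12)

    def test_quota_monotone_in_percentile(self, matrix):
        st = init_population(matrix, K, 0.1)
        obs = ObservationModel(cv=0.5)
        q15 = observe_and_set_limit(st, obs, 15.0, 0.6, np.random.default_rng(9))
        q50 = observe_and_set_limit(st, obs, 50.0, 0.6, np.random.default_rng(9))
        assert q15 < q50


class TestBaseTrials:
    def test_risk_monotone_in_percentile_and_fa(self, base_surface):
        surface = base_surface
        r = surface.risk
        for fa in r.columns:
            assert np.all(np.diff(r[fa].to_numpy()) >= 0)
        assert np.all(r[1.0].to_numpy() >= r[0.6].to_numpy())

    def test_negligible_adjustment_factor_means_negligible_risk(self):
        cfg = TrialConfig(objective="nmnp", approach="tag", n_sims=300, seed=7,
                          f_a_values=(1e-6,), percentiles=(15.0,))
        surf = run_base_trials(cfg)
        assert float(surf.risk.iloc[0, 0]) <= 0.01

    def test_scale_invariance_in_carrying_capacity(self):
        cfg = TrialConfig(objective="nmnp", approach="tag", n_sims=300, seed=8,
                          percentiles=(15.0, 50.0))
        a = run_base_trials(cfg, K=10_000.0)
        b = run_base_trials(cfg, K=100_000.0)
        assert np.array_equal(a.risk.values, b.risk.values)

    def test_determinism_under_seed(self):
        cfg = TrialConfig(objective="nmnp", approach="survey", n_sims=200, seed=5,
                          percentiles=(15.0,))
        a = run_base_trials(cfg)
        b = run_base_trials(cfg)
        assert np.array_equal(a.risk.values, b.risk.values)

    def test_published_tuning_for_tag(self):
        """The printed base-trial result: with f_a = 0.6 the 5% risk
        criterion admits the 15th percentile for the tag approach, while
        f_a = 1 admits (at most) only the extreme tail."""
        cfg = TrialConfig(objective="nmnp", approach="tag", n_sims=2000, seed=11)
        t = tune(run_base_trials(cfg))
        assert t.per_fa[0.6] in (10.0, 15.0, 20.0)
        assert t.per_fa[1.0] in (None, 2.5)


class TestTuning:
    def _surface(self, risk_values):
        import pandas as pd
        cfg = TrialConfig(objective="nmnp", percentiles=(2.5, 15.0, 50.0),
                          f_a_values=(0.6,))
        df = pd.DataFrame(risk_values, index=pd.Index((2.5, 15.0, 50.0), name="percentile"),
                          columns=pd.Index((0.6,), name="f_a"))
        return RiskSurface(risk=df, violation="", outcomes={}, config=cfg)

    def test_all_safe_returns_max_percentile(self):
        t = tune(self._surface([[0.0], [0.0], [0.0]]))
        assert t.per_fa[0.6] == 50.0

    def test_none_admissible(self):
        t = tune(self._surface([[1.0], [1.0], [1.0]]))
        assert t.per_fa[0.6] is None
        assert "no admissible percentile" in repr(t)

    def test_default_tolerances_by_objective(self):
        assert tune(self._surface([[0.04], [0.04], [0.06]])).per_fa[0.6] == 15.0


class TestRebuildTrials:
    def test_zero_removals_ratio_exactly_one(self, rebuild_result):
        rebuild = rebuild_result
        assert np.all(rebuild.ratios[0] == 1.0)

    def test_ratios_never_below_one(self, rebuild_result):
        rebuild = rebuild_result
        assert np.all(rebuild.ratios >= 1.0)

    def test_delay_monotone_in_adjustment_factor(self, rebuild_result):
        rebuild = rebuild_result
        means = rebuild.ratios.mean(axis=1)
        assert np.all(np.diff(means) >= 0)
        assert np.all(np.diff(rebuild.frac_within_1p1) <= 0)

    def test_low_adjustment_factor_rebuilds_on_time(self, rebuild_result):
        rebuild = rebuild_result
        """At f_a = 0.1 more than 75% of populations rebuild within 10% of
        the unimpacted time."""
        i = list(rebuild.f_a_values).index(0.1)
        assert rebuild.frac_within_1p1[i] > 0.75


class TestTrajectory:
    def test_rebuilding_population_limit_rises(self):
        cfg = TrialConfig(objective="ncollapse", approach="tag", n_sims=200, seed=3)
        traj = project_lrp_trajectory(cfg, percentile=15.0, f_a=0.6, horizon=60)
        med = traj["lrp_median"].to_numpy()
        decades = med[::10]
        assert np.all(np.diff(decades) >= 0)
        assert med[-1] > med[0]

    def test_initial_limit_proportional_to_fa(self):
        cfg = TrialConfig(objective="ncollapse", approach="tag", n_sims=200, seed=3)
        a = project_lrp_trajectory(cfg, percentile=15.0, f_a=0.3, horizon=1)
        b = project_lrp_trajectory(cfg, percentile=15.0, f_a=0.6, horizon=1)
        assert b["lrp_median"].iloc[0] == pytest.approx(2 * a["lrp_median"].iloc[0],
                                                        rel=1e-9)
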