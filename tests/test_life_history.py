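"""The age-structured matrix model: fertilities, survival solve, eigenstructure."""

from dataclasses import replace

import numpy as np
import pytest

from turtlelrp.distributions import ConfigurationError, Dist
from turtlelrp.life_history import (
    InfeasibleParameters,
    LifeHistoryConfig,
    adult_equivalents,
    assemble_matrix,
    build_transition_matrix,
    compute_fertilities,
    derive_hatchling_survival,
    eigen_structure,
    sample_params,
    solve_juvenile_survival,
)


class TestHatchlingSurvival:
    def test_means_round_to_printed_value(self, means_params):
        p = derive_hatchling_survival(means_params)
        assert p == pytest.approx(0.4 * (1 - 9.7 / 29.9) * 0.55, rel=1e-12)
        assert round(p, 2) == 0.15

    @pytest.mark.parametrize("erosion,emergence,first_day,expected", [
        (1.0, 0.4, 0.55, 0.0),     # total nest loss
        (0.0, 1.0, 1.0, 1.0),      # identity
    ])
    def test_degenerate_cases(self, means_params, erosion, emergence, first_day, expected):
        p = replace(means_params, erosion=erosion, emergence=emergence,
                    first_day_survival=first_day)
        assert derive_hatchling_survival(p) == expected


class TestFertilities:
    def test_means_product(self, means_params):
        f = compute_fertilities(means_params)
        # P_adult * PF * (1/RI) * CF * CS at the parameter means
        assert f.f_adult == pytest.approx(0.92 * (27.5 / 38) * 0.4 * 5.5 * 78, rel=1e-12)
        assert f.f_adult == pytest.approx(114.2, abs=0.1)
        assert f.f_alpha == pytest.approx(f.f_adult * 0.68, rel=1e-12)

    def test_neophyte_factor_one_gives_equal_fertilities(self, means_params):
        f = compute_fertilities(replace(means_params, f_neo=1.0))
        assert f.f_alpha == f.f_adult

    def test_no_females_no_fertility(self, means_params):
        f = compute_fertilities(replace(means_params, pf=0.0))
        assert f.f_adult == 0.0 and f.f_alpha == 0.0


class TestSampling:
    def test_means_mode_uses_closed_form_beta_mean(self, life_cfg):
        assert life_cfg.means().pf == pytest.approx(27.5 / 38.0, rel=1e-12)

    def test_degenerate_spec_returns_points(self, rng):
        cfg = LifeHistoryConfig(dists={
            "lambda_m": Dist.point(1.05), "p_adult": Dist.point(0.9),
            "erosion": Dist.point(0.3), "emergence": Dist.point(0.4),
            "pf": Dist.point(0.72)})
        p = sample_params(rng, cfg)
        assert (p.lambda_m, p.p_adult, p.erosion, p.emergence, p.pf) == \
            (1.05, 0.9, 0.3, 0.4, 0.72)
        assert p.p_alpha == p.p_adult

    def test_growth_rate_mean_matches_uniform(self, rng, life_cfg):
        draws = np.array([sample_params(rng, life_cfg).lambda_m for _ in range(20_000)])
        assert draws.mean() == pytest.approx(1.05, abs=0.001)
        assert draws.min() >= 1.04 and draws.max() <= 1.06

    def test_fixed_parameters_returned_as_is(self, rng, life_cfg):
        p = sample_params(rng, life_cfg)
        assert (p.alpha, p.ri, p.cf, p.cs, p.f_neo, p.first_day_survival) == \
            (13, 2.5, 5.5, 78.0, 0.68, 0.55)


class TestJuvenileSurvivalSolve:
    def test_round_trip_reaches_target_eigenvalue(self, means_params):
        tm = build_transition_matrix(means_params, target_lambda=1.05)
        assert tm.entries.shape == (14, 14)
        assert tm.lam == pytest.approx(1.05, abs=1e-6)

    def test_two_class_reduction_closed_form(self):
        # [[0, F], [s, P]] with F=1, P=0: lambda = sqrt(F s), so lambda=1 -> s=1
        lam, _, _ = eigen_structure(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert lam == pytest.approx(1.0, abs=1e-12)

    def test_unreachable_target_raises(self, means_params):
        fert = compute_fertilities(means_params)
        with pytest.raises(InfeasibleParameters):
            # below the adult-survival floor
            solve_juvenile_survival(means_params, fert, 0.90)
        with pytest.raises(InfeasibleParameters):
            # requires survivorship product > 1
            solve_juvenile_survival(means_params, fert, 2.0)

    def test_curve_is_nondecreasing_and_consistent(self, means_params):
        fert = compute_fertilities(means_params)
        c = solve_juvenile_survival(means_params, fert, 1.05)
        assert len(c.by_age) == means_params.alpha + 1
        assert np.all(np.diff(c.by_age) >= -1e-12)
        assert np.all((c.by_age > 0) & (c.by_age <= 1))
        gm = np.exp(np.mean(np.log(c.by_age[: means_params.alpha - 1])))
        assert gm == pytest.approx(c.geometric_mean_juvenile, abs=1e-9)

    def test_steeper_curve_preserves_geometric_mean_and_eigenvalue(self, means_params):
        fert = compute_fertilities(means_params)
        base = solve_juvenile_survival(means_params, fert, 1.05)
        steep = solve_juvenile_survival(means_params, fert, 1.05, slope_multiplier=1.5)
        assert steep.geometric_mean_juvenile == pytest.approx(
            base.geometric_mean_juvenile, rel=1e-9)
        tm = build_transition_matrix(means_params, 1.05, slope_multiplier=1.5)
        assert tm.lam == pytest.approx(1.05, abs=1e-6)
        # steeper: lower at age 0, rises faster
        assert steep.by_age[0] < base.by_age[0]

    def test_random_draw_round_trips(self, rng, life_cfg):
        """Every accepted draw reproduces its own growth rate within 1e-6,
        with strictly positive eigenvectors and age-increasing reproductive
        value."""
        for _ in range(50):
            p = sample_params(rng, life_cfg)
            tm = build_transition_matrix(p)
            assert abs(tm.lam - p.lambda_m) < 1e-6
            assert np.all(tm.w > 0) and np.all(tm.v > 0)
            assert np.all(np.diff(tm.v) >= -1e-12)


class TestRoundTripProperty:
    """Characteristic-equation solve then assembly reproduces any reachable
    growth target, for arbitrary parameter combinations in the configured
    ranges."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(lam=st.floats(1.01, 1.10),
           p_adult=st.floats(0.85, 0.96),
           pf=st.floats(0.4, 0.9),
           erosion=st.floats(0.05, 0.6),
           emergence=st.floats(0.1, 0.9))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_solved_matrix_hits_target(self, lam, p_adult, pf, erosion, emergence):
        from dataclasses import replace
        base = LifeHistoryConfig().means()
        p = replace(base, lambda_m=lam, p_adult=p_adult, p_alpha=p_adult,
                    pf=pf, erosion=erosion, emergence=emergence)
        try:
            tm = build_transition_matrix(p)
        except InfeasibleParameters:
            return  # out-of-reach targets must raise, not mis-solve
        assert abs(tm.lam - lam) < 1e-6
        assert np.all(tm.w > 0) and np.all(tm.v > 0)

    def test_matrix_frame_round_trips(self, means_matrix):
        df = means_matrix.to_frame()
        assert df.shape == (14, 14)
        assert np.array_equal(df.to_numpy(), means_matrix.entries)
        assert df.index[-1] == "adult"


class TestEigenStructure:
    def test_identity_matrix(self):
        lam, w, v = eigen_structure(np.eye(3))
        assert lam == 1.0
        assert np.allclose(w, 1.0) and np.allclose(v, 1.0)

    def test_hand_checkable_two_class_case(self):
        lam, w, v = eigen_structure(np.array([[0.0, 2.0], [0.5, 0.0]]))
        assert lam == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(w, [2.0, 1.0])
        assert np.allclose(v, [0.5, 1.0])

    def test_pure_survival_process(self, means_params):
        fert = compute_fertilities(means_params)
        curve = solve_juvenile_survival(means_params, fert, 1.05)
        from turtlelrp.life_history import FertilityPair
        tm = assemble_matrix(means_params, FertilityPair(0.0, 0.0), curve)
        assert tm.lam == pytest.approx(means_params.p_adult, abs=1e-9)

    def test_matrix_layout(self, means_matrix, means_params):
        A = means_matrix.entries
        a = means_params.alpha
        assert A[a, a] == means_params.p_adult
        row0 = np.flatnonzero(A[0])
        assert list(row0) == [a - 1, a]
        assert A[0, a] >= A[0, a - 1] > 0

    def test_dimension_mismatch_rejected(self, means_params):
        from turtlelrp.life_history import FertilityPair, SurvivalCurve
        bad = SurvivalCurve(by_age=np.full(5, 0.5), geometric_mean_juvenile=0.5)
        with pytest.raises(ConfigurationError):
            assemble_matrix(means_params, FertilityPair(1.0, 1.0), bad)


class TestAdultEquivalents:
    def test_unit_values_give_head_count(self):
        n = np.array([5.0, 3.0, 2.0])
        assert adult_equivalents(n, np.ones(3)) == 10.0

    def test_adults_only(self, means_matrix):
        n = np.zeros(14)
        n[-1] = 10.0
        assert adult_equivalents(n, means_matrix.v) == pytest.approx(10.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            adult_equivalents(np.ones(3), np.ones(4))

    def test_means_case_stable_population_value(self, means_matrix):
        """Adult equivalents per adult at stable structure: the multiplier
        linking local adults to the published adult-equivalent estimate."""
        total = adult_equivalents(means_matrix.w, means_matrix.v)
        assert 2.0 < total < 4.0
        # naive-approach cross-check (approximate: curve details shift it)
        local_adults = 0.01 * 318 * 2.5 / (27.5 / 38)
        assert local_adults * total == pytest.approx(32.6, rel=0.15)
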