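"""Tests of the two-stage expression model: simulation, moments,
auto-correlation, and decay-rate estimation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import noisetissue as nt
from noisetissue import _kernels
from noisetissue.errors import (
    EstimationError,
    ParameterError,
    UndefinedCorrelationError,
)


class TestTranslationRateDraws:
    def test_zero_variance_is_degenerate(self):
        spec = nt.ExtrinsicSpec(45.0, 0.0)
        assert nt.draw_translation_rate(spec, seed=0) == 45.0
        assert nt.draw_translation_rate(spec, seed=123) == 45.0

    def test_negative_variance_rejected(self):
        with pytest.raises(ParameterError):
            nt.ExtrinsicSpec(45.0, -1.0)

    def test_sample_mean_and_positivity(self, reference_extrinsic):
        draws = nt.draw_translation_rate(reference_extrinsic, seed=7, size=100_000)
        assert (draws > 0).all()
        # 3 x SE of the mean with SD 10 over 1e5 draws
        assert abs(draws.mean() - 45.0) < 0.1
        assert abs(draws.std() - 10.0) < 0.15

    def test_deterministic_given_seed(self, reference_extrinsic):
        a = nt.draw_translation_rate(reference_extrinsic, seed=5, size=10)
        b = nt.draw_translation_rate(reference_extrinsic, seed=5, size=10)
        np.testing.assert_array_equal(a, b)

    def test_cv(self, reference_extrinsic):
        assert reference_extrinsic.cv == pytest.approx(10.0 / 45.0)


class TestMoments:
    def test_stationary_values(self, reference_params):
        m = nt.moments_two_stage(reference_params, float("inf"))
        assert m.mean_mrna == pytest.approx(2.0)
        assert m.var_mrna == pytest.approx(2.0)
        assert m.mean_protein == pytest.approx(1000.0)
        # mean * (1 + v1 / (d0 + d1))
        assert m.var_protein == pytest.approx(1000.0 * (1 + 45.0 / 1.215))

    def test_empty_start_is_zero_at_t0(self, reference_params):
        m = nt.moments_two_stage(reference_params, 0.0)
        assert m == (0.0, 0.0, 0.0, 0.0, 0.0)

    def test_long_time_approaches_stationary(self, reference_params):
        m = nt.moments_two_stage(reference_params, 200.0)
        s = nt.moments_two_stage(reference_params, float("inf"))
        assert m.mean_protein == pytest.approx(s.mean_protein, rel=1e-6)
        assert m.var_protein == pytest.approx(s.var_protein, rel=1e-4)

    def test_degenerate_equal_decay_rates_branch(self):
        p_eq = nt.TwoStageParams(2.0, 0.5, 10.0, 0.5)
        p_near = nt.TwoStageParams(2.0, 0.5, 10.0, 0.5 + 1e-9)
        m_eq = nt.moments_two_stage(p_eq, 2.0, initial_state=(5, 0))
        m_near = nt.moments_two_stage(p_near, 2.0, initial_state=(5, 0))
        assert m_eq.mean_protein == pytest.approx(m_near.mean_protein, rel=1e-6)
        assert np.isfinite(m_eq.var_protein)

    def test_nonstationary_rates_rejected(self):
        with pytest.raises(ParameterError):
            nt.moments_two_stage(nt.TwoStageParams(1.0, 0.0, 1.0, 1.0), 1.0)


class TestSSA:
    def test_empty_state_is_absorbing_without_transcription(self):
        p = nt.TwoStageParams(0.0, 1.125, 45.0, 0.09)
        traj = nt.ssa_two_stage(p, 45.0, t_conversion=3.0, t_end=6.0,
                                initial_state=(0, 0, 0), seed=1)
        assert (traj.mrna == 0).all()
        assert (traj.green == 0).all()
        assert (traj.red == 0).all()

    def test_conversion_bookkeeping_is_exact_for_frozen_pools(self):
        # no production, no decay: the green pool transfers exactly to red
        p = nt.TwoStageParams(0.0, 1.0, 0.0, 0.0)
        traj = nt.ssa_two_stage(p, 0.0, t_conversion=2.0, t_end=4.0,
                                initial_state=(0, 137, 5), seed=2)
        i = np.searchsorted(traj.times, 2.0)
        assert traj.green[i - 1] == 137 and traj.red[i - 1] == 5
        assert traj.green[i] == 0 and traj.red[i] == 142
        assert traj.red[-1] == 142

    def test_total_protein_conserved_across_conversion(self, reference_params):
        # with d1 = 0 no protein ever dies, so green + red is non-decreasing
        p = nt.TwoStageParams(2.25, 1.125, 45.0, 0.0)
        traj = nt.ssa_two_stage(p, 45.0, t_conversion=1.0, t_end=2.0,
                                initial_state=(2, 50, 0), seed=3)
        total = traj.green + traj.red
        assert (np.diff(total) >= 0).all()
        i = np.searchsorted(traj.times, 1.0)
        assert traj.green[i] == 0

    def test_stationary_ensemble_mean_matches_closed_form(self, reference_params):
        # long-run green mean before conversion ~ v0*v1/(d0*d1) = 1000
        rng = np.random.default_rng(42)
        greens = [
            nt.stationary_state(reference_params, 45.0, seed=rng)[1] for _ in range(300)
        ]
        m = nt.moments_two_stage(reference_params, float("inf"))
        se = math.sqrt(m.var_protein / len(greens))
        assert abs(np.mean(greens) - 1000.0) < 3 * se

    @pytest.mark.parametrize("t_check", [1.0, 3.0, 6.0])
    def test_ensemble_moments_match_ode_oracle(self, reference_params, t_check):
        """SSA ensemble mean/variance against the moment ODEs, from an
        empty initial state (the post-conversion situation)."""
        n = 10_000
        rng = np.random.default_rng(int(t_check * 100))
        seeds = rng.integers(0, 2**28, n) * 8
        m0s = np.zeros(n, dtype=np.int64)
        g0s = np.zeros(n, dtype=np.int64)
        mm, gg = _kernels.ensemble_moments_grid(
            2.25, 1.125, 45.0, 0.09, m0s, g0s, np.array([t_check]), seeds)
        mm = mm[:, 0].astype(float)
        gg = gg[:, 0].astype(float)
        oracle = nt.moments_two_stage(reference_params, t_check, initial_state=(0, 0))
        for sample, mean_o, var_o in [(mm, oracle.mean_mrna, oracle.var_mrna),
                                      (gg, oracle.mean_protein, oracle.var_protein)]:
            se_mean = sample.std() / math.sqrt(n)
            assert abs(sample.mean() - mean_o) < 3 * se_mean
            mu4 = np.mean((sample - sample.mean()) ** 4)
            se_var = math.sqrt(max(mu4 - sample.var() ** 2, 0.0) / n)
            assert abs(sample.var() - var_o) < 3 * se_var


class TestBirthDeathAutocorr:
    def test_self_correlation_is_one(self):
        assert nt.autocorr_birth_death(0.09, 3.0, 3.0) == 1.0

    def test_reference_value(self):
        assert nt.autocorr_birth_death(0.09, 3.0, 6.0) == pytest.approx(0.5748673, abs=1e-6)

    def test_zero_decay_limit(self):
        assert nt.autocorr_birth_death(0.0, 3.0, 6.0) == pytest.approx(math.sqrt(0.5))

    @pytest.mark.parametrize("d,t1,t2", [(0.09, 6.0, 3.0), (0.09, 0.0, 3.0), (-1.0, 1.0, 2.0)])
    def test_invalid_arguments(self, d, t1, t2):
        with pytest.raises(ParameterError):
            nt.autocorr_birth_death(d, t1, t2)

    def test_against_exact_distributional_oracle(self):
        """Immigration-death from zero is Poisson at every time; X(t2) given
        X(t1) is a binomial survivor count plus independent Poisson influx.
        Sampling that transition exactly gives an independent check."""
        d, t1, t2, beta, n = 0.09, 3.0, 6.0, 90.0, 200_000
        rng = np.random.default_rng(99)
        mu1 = beta / d * -math.expm1(-d * t1)
        mu_new = beta / d * -math.expm1(-d * (t2 - t1))
        x1 = rng.poisson(mu1, n)
        x2 = rng.binomial(x1, math.exp(-d * (t2 - t1))) + rng.poisson(mu_new, n)
        r_mc = np.corrcoef(x1, x2)[0, 1]
        se = (1 - r_mc**2) / math.sqrt(n)
        assert abs(r_mc - nt.autocorr_birth_death(d, t1, t2)) < 3 * se


class TestTwoStageAutocorrMC:
    def test_bound_and_monotonicity_small(self, reference_params):
        n = 5000
        bound = nt.autocorr_birth_death(0.09, 3.0, 6.0)
        rs = {}
        for var in (0.0, 100.0):
            est = nt.autocorr_two_stage_mc(reference_params, nt.ExtrinsicSpec(45.0, var),
                                           3.0, 6.0, n, seed=21)
            assert est.r >= bound - 3 * est.se
            rs[var] = est.r
        assert rs[100.0] > rs[0.0]

    def test_reproducible_given_seed(self, reference_params, reference_extrinsic):
        a = nt.autocorr_two_stage_mc(reference_params, reference_extrinsic, 3, 6, 500, seed=4)
        b = nt.autocorr_two_stage_mc(reference_params, reference_extrinsic, 3, 6, 500, seed=4)
        assert a == b

    def test_too_few_trajectories_rejected(self, reference_params, reference_extrinsic):
        with pytest.raises(ParameterError):
            nt.autocorr_two_stage_mc(reference_params, reference_extrinsic, 3, 6, 50, seed=0)

    def test_degenerate_ensemble_raises(self, reference_extrinsic):
        silent = nt.TwoStageParams(0.0, 1.125, 45.0, 0.09)  # nothing is ever made
        with pytest.raises(UndefinedCorrelationError):
            nt.autocorr_two_stage_mc(silent, reference_extrinsic, 3, 6, 200, seed=0)


class TestDecayRateEstimation:
    def test_reference_pair(self):
        est = nt.estimate_decay_rate([100.0], [76.338], 3.0)
        assert est.rate == pytest.approx(0.0900, abs=5e-5)

    def test_no_decay(self):
        est = nt.estimate_decay_rate([50.0, 80.0], [50.0, 80.0], 3.0)
        assert est.rate == 0.0

    @given(rate=st.floats(0.0, 2.0), dt=st.floats(0.1, 10.0),
           start=st.lists(st.floats(1.0, 1000.0), min_size=1, max_size=20))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_exact_on_noise_free_exponential(self, rate, dt, start):
        a = np.asarray(start)
        b = a * math.exp(-rate * dt)
        est = nt.estimate_decay_rate(a, b, dt)
        assert est.rate == pytest.approx(rate, abs=1e-9)

    def test_non_positive_pairs_excluded_and_counted(self):
        est = nt.estimate_decay_rate([100.0, -1.0, 50.0], [76.0, 10.0, 0.0], 3.0)
        assert est.n_used == 1
        assert est.n_excluded == 2

    def test_all_excluded_raises(self):
        with pytest.raises(EstimationError):
            nt.estimate_decay_rate([0.0, -5.0], [1.0, 1.0], 3.0)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ParameterError):
            nt.estimate_decay_rate([1.0, 2.0], [1.0], 3.0)
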