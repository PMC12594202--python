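import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stngpe.plasticity import (PlasticityParams, classify_outcome,
                               cubic_null_trajectory, efficacy_drift,
                               efficacy_step)


@pytest.fixture(scope="module")
def pp():
    return PlasticityParams()


class TestDrift:
    def test_fixed_points_below_depression_threshold(self, pp):
        ca = pp.theta_d_stn / 2
        for rho in (0.0, 0.5, 1.0):
            assert efficacy_drift(rho, ca, pp) == pytest.approx(0.0)

    def test_flows_to_down_state_from_quarter(self, pp):
        ca = pp.theta_d_stn / 2
        drift = efficacy_drift(0.25, ca, pp)
        assert drift == pytest.approx(-0.25 * 0.75 * 0.25 / pp.tau_rho)
        assert drift < 0

    def test_high_calcium_fixed_point_near_rate_balance(self, pp):
        # gamma terms dominate: rho* ~ gamma_p / (gamma_p + gamma_d)
        ca = 10 * pp.theta_p_stn
        rho_star = pp.gamma_p / (pp.gamma_p + pp.gamma_d)
        assert efficacy_drift(rho_star - 0.02, ca, pp) > 0
        assert efficacy_drift(min(rho_star + 0.02, 1.0), ca, pp) < 0

    def test_heaviside_includes_zero(self, pp):
        # H(0) = 1: calcium exactly at threshold engages depression
        drift_at = efficacy_drift(0.5, pp.theta_d_stn, pp)
        drift_below = efficacy_drift(0.5, pp.theta_d_stn - 1e-12, pp)
        assert drift_at < drift_below

    def test_population_specific_thresholds(self, pp):
        ca = (pp.theta_d_gpe + pp.theta_d_stn) / 2  # between the two
        assert efficacy_drift(0.5, ca, pp, "GPe") < efficacy_drift(
            0.5, ca, pp, "STN")

    def test_rho_out_of_range_rejected(self, pp):
        with pytest.raises(ValueError):
            efficacy_drift(1.2, 0.0, pp)


class TestStep:
    def test_sigma_zero_is_deterministic_drift(self, pp):
        from dataclasses import replace

        p0 = replace(pp, sigma=0.0)
        rng = np.random.default_rng(0)
        rho = 0.4
        ca = 2 * pp.theta_p_stn
        out = efficacy_step(rho, ca, 1.0, rng, p0)
        assert out == pytest.approx(rho + 1.0 * efficacy_drift(rho, ca, p0))

    def test_no_noise_below_depression_threshold(self, pp):
        ca = pp.theta_d_stn / 2
        a = efficacy_step(0.4, ca, 1.0, np.random.default_rng(1), pp)
        b = efficacy_step(0.4, ca, 1.0, np.random.default_rng(2), pp)
        assert a == b  # different rngs, same result: noise gated off

    def test_seeded_trajectory_reproducible(self, pp):
        ca = 2 * pp.theta_d_stn

        def run(seed):
            rng = np.random.default_rng(seed)
            rho = 0.5
            for _ in range(500):
                rho = efficacy_step(rho, ca, 1.0, rng, pp)
            return rho

        assert run(7) == run(7)
        assert run(7) != run(8)

    def test_clipping_to_unit_interval(self, pp):
        from dataclasses import replace

        noisy = replace(pp, sigma=500.0)
        rng = np.random.default_rng(3)
        ca = 2 * pp.theta_p_stn
        vals = [float(efficacy_step(0.5, ca, 10.0, rng, noisy))
                for _ in range(50)]
        assert all(0.0 <= v <= 1.0 for v in vals)
        assert min(vals) == 0.0 and max(vals) == 1.0  # noise huge: clipped

    @settings(max_examples=30, deadline=None)
    @given(rho0=st.floats(0.01, 0.99), seed=st.integers(0, 2**31 - 1))
    def test_bounds_invariant(self, pp, rho0, seed):
        rng = np.random.default_rng(seed)
        rho = rho0
        for ca in (0.0, pp.theta_d_stn, pp.theta_p_stn, 1.0):
            rho = float(efficacy_step(rho, ca, 5.0, rng, pp))
            assert 0.0 <= rho <= 1.0


def test_bistability_retention_below_threshold(pp):
    """With calcium below theta_d and no noise, the distance to the nearest
    stable fixed point (0 or 1) never increases."""
    from dataclasses import replace

    p0 = replace(pp, sigma=0.0)
    rng = np.random.default_rng(0)
    ca = pp.theta_d_stn * 0.5
    for rho0 in (0.05, 0.3, 0.45, 0.55, 0.8, 0.97):
        rho = rho0
        dist = min(rho, 1 - rho)
        for _ in range(10_000):  # 1000 s at dt = 100 ms
            rho = float(efficacy_step(rho, ca, 100.0, rng, p0))
            d = min(rho, 1 - rho)
            assert d <= dist + 1e-12
            dist = d


def test_heterosynaptic_copotentiation_shared_segment(pp):
    """One excitatory and one inhibitory efficacy on the same segment both
    potentiate under the same supra-theta_p calcium transient."""
    rng = np.random.default_rng(5)
    rho_exc, rho_inh = 0.33, 0.33
    ca = 1.5 * pp.theta_p_stn
    for _ in range(2000):  # 2 s of supra-threshold calcium at 1-ms steps
        rho_exc = float(efficacy_step(rho_exc, ca, 1.0, rng, pp))
        rho_inh = float(efficacy_step(rho_inh, ca, 1.0, rng, pp))
    assert rho_exc > 0.8 and rho_inh > 0.8


class TestClassifyOutcome:
    def test_equal_windows_are_none(self):
        assert classify_outcome([0.4, 0.4], [0.4, 0.4]) == "none"

    def test_clear_potentiation(self):
        assert classify_outcome([0.33] * 5, [0.66] * 5) == "LTP"

    def test_clear_depression(self):
        assert classify_outcome([0.5] * 5, [0.3] * 5) == "LTD"

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError):
            classify_outcome([0.4], [0.4], elapsed_s=-1.0)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            classify_outcome([], [0.4])

    def test_null_trajectory_correction(self):
        # 0.33 relaxes toward the down state on its own; ending where the
        # cubic null predicts is "none", staying pinned at 0.33 is "LTP"
        null = cubic_null_trajectory(0.33, 150.0)
        assert null < 0.2
        assert classify_outcome([0.33], [null], elapsed_s=150.0) == "none"
        assert classify_outcome([0.33], [0.33], elapsed_s=150.0) == "LTP"

    def test_null_trajectory_fixed_points(self):
        for rho in (0.0, 0.5, 1.0):
            assert cubic_null_trajectory(rho, 500.0) == pytest.approx(rho)
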