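import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stngpe.engine import default_model
from stngpe.synapses import (SynapseInstance, TransmitterParams,
                             conductance_from_efficacy, default_transmitters,
                             gating_step, measure_nmda_ampa_ratio, mg_block,
                             register_spike, synaptic_current)


@pytest.fixture(scope="module")
def tp():
    return default_transmitters()


def _make_exc(rho=0.5, g=1.0):
    return SynapseInstance(pre=0, post=0, segment=0, syn_type="CS", rho=rho,
                           w_min=g, w_max=g)


class TestGating:
    def test_free_decay_matches_exponential_factor(self, tp):
        syn = _make_exc()
        syn.gating["AMPA"][:] = [0.0, 0.4, 0.1]
        dt = 0.03125
        gating_step(syn, t=100.0, dt=dt, params=tp)  # no active pulse
        assert syn.gating["AMPA"][1] == pytest.approx(
            0.4 * (1 - dt / tp["AMPA"].tau_fast), rel=1e-9)

    def test_held_release_fixed_point(self, tp):
        # with f_pre held at 1, s_fast -> phi nu_fast / (phi + 1/tau_fast)
        p = tp["AMPA"]
        syn = _make_exc()
        dt = 0.01
        for i in range(200_000):
            syn.fpre_until = np.inf
            gating_step(syn, i * dt, dt, tp)
        expected = p.phi * p.nu_fast / (p.phi + 1.0 / p.tau_fast)
        assert syn.gating["AMPA"][1] == pytest.approx(expected, rel=1e-3)

    def test_retrigger_extends_pulse(self):
        syn = _make_exc()
        register_spike(syn, 0.0)
        register_spike(syn, 0.5)
        assert syn.fpre_until == pytest.approx(1.5)
        register_spike(syn, 0.2)  # earlier spike must not shorten it
        assert syn.fpre_until == pytest.approx(1.5)

    def test_components_stay_in_unit_interval_and_decay(self, tp):
        syn = _make_exc()
        dt = 0.03125
        register_spike(syn, 0.0)
        t = 0.0
        peak = 0.0
        for _ in range(int(50 / dt)):
            gating_step(syn, t, dt, tp)
            t += dt
            for s in syn.gating.values():
                assert np.all(s >= -1e-12) and np.all(s <= 1.0 + 1e-12)
                peak = max(peak, float(np.sum(s)))
        assert 0.0 < peak <= 3.0
        # decays to ~0 within 10x the slowest time constant after release
        t_max = 10 * max(tp["NMDA"].tau_slow, tp["AMPA"].tau_slow)
        for _ in range(int(t_max / dt)):
            gating_step(syn, t, dt, tp)
            t += dt
        assert sum(float(np.sum(s)) for s in syn.gating.values()) < 1e-3


class TestMgBlock:
    def test_value_at_zero_mV(self):
        assert mg_block(0.0, "Ca") == pytest.approx(0.625)
        assert mg_block(0.0, "syn") == pytest.approx(0.625)

    def test_limits(self):
        assert mg_block(1e3, "Ca") == pytest.approx(1.0)
        assert mg_block(-1e3, "syn") == pytest.approx(0.0, abs=1e-12)

    def test_ca_pathway_steeper(self):
        v = -60.0
        assert mg_block(v, "Ca") < mg_block(v, "syn")


class TestConductance:
    def test_endpoints_and_midpoint(self):
        assert conductance_from_efficacy(0.0, 1.0, 4.0) == 1.0
        assert conductance_from_efficacy(1.0, 1.0, 4.0) == 4.0
        assert conductance_from_efficacy(0.5, 1.0, 4.0) == 2.5

    def test_rho_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            conductance_from_efficacy(1.5, 1.0, 4.0)

    @settings(max_examples=50, deadline=None)
    @given(r1=st.floats(0, 1), r2=st.floats(0, 1))
    def test_monotone_in_rho(self, r1, r2):
        lo, hi = min(r1, r2), max(r1, r2)
        assert (conductance_from_efficacy(lo, 0.5, 2.0)
                <= conductance_from_efficacy(hi, 0.5, 2.0))

    def test_down_and_up_states_bracket_baseline(self, model):
        # w_min = g/2, w_max = 2g: rho=0 halves and rho=1 doubles the
        # conductance relative to the mean initial efficacy of 1/3
        w_min, w_max = model.w_bounds("CS")
        g_mid = conductance_from_efficacy(1 / 3, w_min, w_max)
        assert conductance_from_efficacy(0.0, w_min, w_max) == pytest.approx(
            0.5 * g_mid)
        assert conductance_from_efficacy(1.0, w_min, w_max) == pytest.approx(
            2.0 * g_mid)


class TestSynapticCurrent:
    def test_zero_at_reversal(self, tp):
        syn = _make_exc()
        syn.gating["AMPA"][:] = 0.3
        cur = synaptic_current(syn, tp["AMPA"].E_rev, tp)
        assert cur["AMPA"] == pytest.approx(0.0)

    def test_zero_gating_means_zero_current(self, tp):
        syn = _make_exc()
        cur = synaptic_current(syn, -55.0, tp)
        assert all(v == pytest.approx(0.0) for v in cur.values())

    def test_nmda_pairing_scales_with_ampa(self, tp):
        s1 = _make_exc(g=1.0)
        s2 = _make_exc(g=2.0)
        for s in (s1, s2):
            s.gating["AMPA"][:] = 0.2
            s.gating["NMDA"][:] = 0.2
        c1 = synaptic_current(s1, -40.0, tp)
        c2 = synaptic_current(s2, -40.0, tp)
        for key in ("AMPA", "NMDA_syn", "NMDA_Ca"):
            assert c2[key] == pytest.approx(2 * c1[key])

    def test_inhibitory_current_sign(self, tp):
        syn = SynapseInstance(pre=0, post=0, segment=1, syn_type="GS",
                              rho=0.5, w_min=0.1, w_max=0.4)
        syn.gating["GABAa"][:] = 0.3
        cur = synaptic_current(syn, -55.0, tp)
        # V above E_GABA: hyperpolarizing (negative in inward-positive terms)
        assert cur["GABAa"] < 0


def test_nmda_ampa_ratio_calibration():
    """Depolarized NMDA vs hyperpolarized AMPA peak-current ratio is 0.25."""
    ratio = measure_nmda_ampa_ratio()
    assert ratio == pytest.approx(0.25, abs=0.05)
    assert ratio == pytest.approx(0.25, abs=0.005)  # calibrated exactly


def test_invalid_transmitter_params_rejected():
    with pytest.raises(ValueError):
        TransmitterParams("AMPA", phi=1.0, nu_fast=0.8, nu_slow=0.3,
                          tau_rise=1.0, tau_fast=2.0, tau_slow=8.0)
    with pytest.raises(ValueError):
        TransmitterParams("AMPA", phi=1.0, nu_fast=0.5, nu_slow=0.3,
                          tau_rise=0.0, tau_fast=2.0, tau_slow=8.0)
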