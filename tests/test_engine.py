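import numpy as np
import pytest

from stngpe.connectivity import TYPE_CODES, TYPE_NAMES
from stngpe.engine import (NetworkConfig, build_network, default_model,
                           events_from_trains, rebound_volley_min_v,
                           single_stn_setup)


def _micro_cfg(**kw):
    base = dict(n_stn=4, n_gpe=12, n_ctx=40, n_msn=120, in_degree=5, seed=7,
                synaptic_plasticity=True, structural_plasticity=False)
    base.update(kw)
    return NetworkConfig(**base)


class TestBuild:
    def test_mean_indegree_matches_target(self, model):
        net = build_network(NetworkConfig(scale_factor=10.0, seed=1), model)
        stats = net.indegrees()
        for name in TYPE_NAMES:
            assert stats[name]["mean"] == pytest.approx(10.0)

    def test_scaling_preserves_indegree_and_ratio(self, model):
        cfg = NetworkConfig(scale_factor=10.0, seed=1)
        assert cfg.sizes == {"stn": 25, "gpe": 75, "ctx": 250, "msn": 750}
        net = build_network(cfg, model)
        assert net.n_gpe == 3 * net.n_stn
        assert net.indegrees()["CS"]["mean"] == pytest.approx(10.0)

    def test_same_seed_reproduces_wiring_and_state(self, model):
        a = build_network(_micro_cfg(), model)
        b = build_network(_micro_cfg(), model)
        assert a.state_hash() == b.state_hash()
        c = build_network(_micro_cfg(seed=8), model)
        assert a.state_hash() != c.state_hash()

    def test_no_gg_self_loops(self, model):
        net = build_network(NetworkConfig(scale_factor=25.0, seed=3), model)
        t = net.table
        gg = t.type_code == TYPE_CODES["GG"]
        assert not np.any(t.pre[gg] + net.n_stn == t.post[gg])

    def test_initial_state_ranges(self, model):
        net = build_network(_micro_cfg(), model)
        assert net.V.min() >= -80.0 and net.V.max() <= 50.0
        assert net.gates.min() >= 0.0 and net.gates.max() <= 1.0
        plastic = net.table.plastic
        assert abs(net.table.rho[plastic].mean() - 0.33) < 0.05

    def test_empty_population_rejected(self, model):
        with pytest.raises(ValueError):
            NetworkConfig(scale_factor=1000.0).sizes


class TestDeterminism:
    def test_seeded_run_bit_identical(self, model):
        from stngpe.afferents import afferent_state, generate_train
        from dataclasses import replace

        def run_once():
            net = build_network(_micro_cfg(), model)
            st = afferent_state("healthy")
            rng = net.rngs["afferents"]
            ctx = generate_train(replace(st["CTX"], n=net.n_ctx), 2.0, rng)
            msn = generate_train(replace(st["iMSN"], n=net.n_msn), 2.0, rng)
            res = net.run(2000.0, events_from_trains(ctx, net.cfg.dt),
                          events_from_trains(msn, net.cfg.dt))
            return res, net.state_hash()

        r1, h1 = run_once()
        r2, h2 = run_once()
        assert h1 == h2
        assert np.array_equal(r1.spike_neuron, r2.spike_neuron)
        assert np.array_equal(r1.spike_t_ms, r2.spike_t_ms)


class TestKernelAgainstReference:
    """The compiled kernel reproduces a step composed from the reference
    gate/channel/calcium functions (Strang splitting by hand)."""

    def _reference_steps(self, params, V, ca, gates, bias, dt, n_steps):
        from stngpe.neurons import (nernst_potential, steady_state,
                                    time_constant)

        specs = {g.name: g for g in params.gating}
        used = set()
        for _, gkey, gate_pow, _ in params.channels:
            if getattr(params, gkey) != 0.0 or gkey == "g_leak":
                used.update(n for n, _ in gate_pow)

        def relax(dt_half):
            for name in used:
                spec = specs[name]
                M = ca[0] if spec.driver == "calcium" else V[0]
                xinf = float(steady_state(spec, M))
                tau = float(time_constant(spec, M))
                gates[name] = xinf + (gates[name] - xinf) * np.exp(-dt_half / tau)

        def rhs(v, cs):
            eca = float(nernst_potential(max(cs, params.ca_floor), params))
            act = {
                "Na": gates["m"] ** 3 * gates["h"],
                "K": gates["n"] ** 4,
                "T": gates["p"] ** 2 * gates["q"],
                "Ca-K": gates["r"] ** 2,
                "A": gates["a"] ** 2 * gates["b"],
                "L": gates["c"] ** 2 * gates["d1"] * gates["d2"],
                "leak": 1.0,
            }
            rev = {"Na": params.E_Na, "K": params.E_K, "Ca": eca,
                   "leak": params.E_leak}
            i_tot, i_cav = 0.0, 0.0
            for name, gkey, _, rkey in params.channels:
                cur = getattr(params, gkey) * act[name] * (v - rev[rkey])
                i_tot += cur
                if rkey == "Ca":
                    i_cav += cur
            dv = (-i_tot + bias) / params.C
            dcs = -params.k_conv * i_cav - params.k_ca * cs
            return dv, dcs

        for _ in range(n_steps):
            relax(dt / 2)
            dv1, dc1 = rhs(V[0], ca[0])
            vm, cm = V[0] + dt / 2 * dv1, ca[0] + dt / 2 * dc1
            dv2, dc2 = rhs(vm, cm)
            V[0] += dt * dv2
            ca[0] = max(ca[0] + dt * dc2, 0.0)
            relax(dt / 2)
        return V[0], ca[0], gates

    @pytest.mark.parametrize("pop", ["STN", "GPe"])
    def test_single_neuron_step_parity(self, model, pop):
        cfg = NetworkConfig(n_stn=1, n_gpe=1, n_ctx=1, n_msn=1, in_degree=0,
                            seed=5, synaptic_plasticity=False,
                            structural_plasticity=False)
        net = build_network(cfg, model)
        idx = 0 if pop == "STN" else 1
        params = model.stn if pop == "STN" else model.gpe
        net.V[:] = -55.0
        net.gates[:] = 0.4
        net.ca_soma[:] = 0.02
        net.ca_seg[:] = 0.02
        from stngpe.neurons import GATE_NAMES

        gates = {n: 0.4 for n in GATE_NAMES}
        V = [net.V[idx]]
        ca = [net.ca_soma[idx]]
        n_steps = 64  # 2 ms
        net.run(n_steps * cfg.dt)
        v_ref, ca_ref, g_ref = self._reference_steps(
            params, V, ca, gates, params.I_bias, cfg.dt, n_steps)
        assert net.V[idx] == pytest.approx(v_ref, abs=1e-3)
        assert net.ca_soma[idx] == pytest.approx(ca_ref, abs=1e-6)
        gi = {n: i for i, n in enumerate(GATE_NAMES)}
        used = set()
        for _, gkey, gate_pow, _ in params.channels:
            if getattr(params, gkey) != 0.0 or gkey == "g_leak":
                used.update(n for n, _ in gate_pow)
        for name in used:
            assert net.gates[idx, gi[name]] == pytest.approx(
                g_ref[name], abs=1e-5)


def test_integrator_order_of_convergence(model):
    """Richardson study on a smooth trajectory: global order ~ 2."""
    from stngpe.neurons import NeuronParams

    m = default_model(stn=NeuronParams("STN", I_bias=0.5, g_leak=0.1,
                                       g_L=6.0, g_T=3.5, g_CaK=2.0))

    def v_end(dt):
        cfg = NetworkConfig(n_stn=1, n_gpe=1, n_ctx=1, n_msn=1, in_degree=0,
                            seed=9, dt=dt, synaptic_plasticity=False,
                            structural_plasticity=False)
        net = build_network(cfg, m)
        net.V[:] = -70.0
        net.gates[:] = 0.3
        net.ca_soma[:] = 0.01
        net.ca_seg[:] = 0.01
        net.run(100.0)
        return net.V[0]

    ref = v_end(0.0005)
    dts = [0.05, 0.025, 0.0125, 0.00625]
    errs = [abs(v_end(dt) - ref) for dt in dts]
    slope = np.polyfit(np.log(dts), np.log(errs), 1)[0]
    assert slope == pytest.approx(2.0, abs=0.3)


def test_single_neuron_against_high_resolution_oracle(model):
    """Production integrator at dt = 0.03125 ms matches an adaptive
    high-accuracy integration of the same ODEs: every spike within 1 ms."""
    from scipy.integrate import solve_ivp

    from stngpe.neurons import (GATE_NAMES, NeuronState, ionic_currents,
                                steady_state, time_constant)

    params = model.stn
    specs = [params.gate_spec(n) for n in GATE_NAMES]

    def rhs(t, y):
        V, ca = y[0], max(y[1], params.ca_floor)
        gates = dict(zip(GATE_NAMES, y[2:]))
        st = NeuronState.__new__(NeuronState)
        st.V, st.gates, st.ca_soma = V, gates, ca
        st.ca_seg = np.zeros(3)
        cur = ionic_currents(st, params)
        dV = (-sum(cur.values()) + params.I_bias) / params.C
        dca = (-params.k_conv * (cur["T"] + cur.get("L", 0.0))
               - params.k_ca * y[1])
        dg = [(float(steady_state(s, ca if s.driver == "calcium" else V))
               - gates[s.name]) / float(time_constant(
                   s, ca if s.driver == "calcium" else V)) for s in specs]
        return [dV, dca] + dg

    net = single_stn_setup(model, 0, 0, seed=1)
    net.run(3000.0)
    y0 = [net.V[0], net.ca_soma[0]] + list(net.gates[0])
    T = 600.0
    sol = solve_ivp(rhs, (0.0, T), y0, method="RK45", rtol=1e-8, atol=1e-10,
                    max_step=0.5)
    V, t = sol.y[0], sol.t
    cross = np.nonzero((V[:-1] < -10.0) & (V[1:] >= -10.0))[0]
    sp_ref = t[cross] + ((-10.0 - V[cross]) / (V[cross + 1] - V[cross])) * (
        t[cross + 1] - t[cross])
    res = net.run(T)
    sp = res.spikes_of(0) - res.t0_ms
    assert len(sp) == len(sp_ref)
    assert np.abs(sp - sp_ref).max() < 1.0


def test_resting_state_without_input_or_bias(model):
    """With synaptic input and bias removed, both populations settle to a
    finite resting potential."""
    from dataclasses import replace
    from stngpe.neurons import NeuronParams

    m = default_model(
        stn=replace(model.stn, I_bias=0.0),
        gpe=replace(model.gpe, I_bias=0.0))
    cfg = NetworkConfig(n_stn=2, n_gpe=2, n_ctx=1, n_msn=1, in_degree=0,
                        seed=2, synaptic_plasticity=False,
                        structural_plasticity=False)
    net = build_network(cfg, m)
    net.run(3000.0)
    res = net.run(1000.0, probe_v=list(range(4)), stride=32)
    assert np.isfinite(net.V).all()
    assert res.spike_t_ms.size == 0
    assert np.all(res.v_probe.std(axis=1) < 2.0)  # settled, not oscillating


def test_rebound_volley_constraint(model):
    """A synchronized release from 10 GPe afferents drives the tuned STN
    neuron below -75 mV."""
    assert rebound_volley_min_v(model, seed=0) <= -75.0


def test_plasticity_switch_factorization(model):
    """Efficacies are frozen with synaptic plasticity off and move with it
    on; the switch composes with the structural switch."""
    from stngpe.afferents import afferent_state, generate_train
    from dataclasses import replace

    def run(syn_on):
        net = build_network(_micro_cfg(synaptic_plasticity=syn_on), model)
        rho0 = net.table.rho.copy()
        st = afferent_state("healthy")
        rng = net.rngs["afferents"]
        ctx = generate_train(replace(st["CTX"], n=net.n_ctx), 1.0, rng)
        net.run(1000.0, events_from_trains(ctx, net.cfg.dt))
        return rho0, net.table.rho

    rho0_off, rho_off = run(False)
    rho0_on, rho_on = run(True)
    assert np.array_equal(rho0_off, rho_off)
    assert not np.array_equal(rho0_on, rho_on)


def test_scaled_down_rate_fidelity(model):
    """In-degree-preserving scaling keeps healthy-state rates within
    +-2 Hz across a factor-2 change of network size."""
    from stngpe.engine import measure_rates

    rates = {}
    for scale in (5.0, 10.0):
        cfg = NetworkConfig(scale_factor=scale, seed=13,
                            synaptic_plasticity=False,
                            structural_plasticity=False)
        stn, gpe, _, _ = measure_rates(cfg, model, duration_ms=6000.0,
                                       warmup_ms=2000.0)
        rates[scale] = (stn, gpe)
    assert abs(rates[5.0][0] - rates[10.0][0]) <= 2.0
    assert abs(rates[5.0][1] - rates[10.0][1]) <= 2.0


def test_nonfinite_state_aborts_with_diagnostic(model):
    from dataclasses import replace

    bad = default_model(stn=replace(model.stn, I_bias=1e9))
    cfg = NetworkConfig(n_stn=1, n_gpe=1, n_ctx=1, n_msn=1, in_degree=0,
                        seed=1, synaptic_plasticity=False,
                        structural_plasticity=False)
    net = build_network(cfg, bad)
    with pytest.raises(FloatingPointError, match="non-finite"):
        net.run(400.0)
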