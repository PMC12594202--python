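import numpy as np
import pytest

from stngpe.connectivity import TYPE_CODES, SynapseTable, indegree_stats
from stngpe.structural import (ElementState, StructuralParams,
                               connectivity_update, element_derivatives,
                               lowpass_step)


@pytest.fixture()
def sp():
    return StructuralParams()


class TestLowpass:
    def test_derivative_zero_at_equality(self):
        assert lowpass_step(0.3, 0.3, 1.0) == pytest.approx(0.3)

    def test_exponential_approach(self):
        ca_l, target = 0.0, 1.0
        dt = 1.0  # ms
        for _ in range(10_000):  # 10 s
            ca_l = lowpass_step(ca_l, target, dt)
        assert ca_l == pytest.approx(1 - np.exp(-1.0), abs=2e-4)

    def test_step_response_63_percent_at_tau(self):
        # reaches 1 - 1/e ~ 63.2% of a step after 10 s
        ca_l = 0.0
        for _ in range(100_000):
            ca_l = lowpass_step(ca_l, 1.0, 0.1)
        assert ca_l == pytest.approx(0.632, abs=0.001)


class TestElementDerivatives:
    def test_homeostatic_fixed_point(self):
        d_exc, d_inh = element_derivatives(0.05, 0.05, 1.0)
        assert d_exc == 0.0 and d_inh == 0.0

    def test_zero_calcium_grows_excitation(self):
        d_exc, d_inh = element_derivatives(0.0, 0.05, 1800.0)
        assert d_exc == pytest.approx(1 / 1800.0)
        assert d_inh == pytest.approx(-1 / 1800.0)

    def test_double_target_shrinks_excitation(self):
        d_exc, d_inh = element_derivatives(0.1, 0.05, 1800.0)
        assert d_exc == pytest.approx(-1 / 1800.0)
        assert d_inh == pytest.approx(1 / 1800.0)

    def test_exact_antisymmetry(self):
        ca = np.linspace(0, 0.2, 11)
        d_exc, d_inh = element_derivatives(ca, 0.05, 1800.0)
        assert np.all(d_exc == -d_inh)

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ValueError):
            element_derivatives(0.1, 0.0, 1800.0)


def _micro_table(n_stn=2, n_gpe=4):
    """Tiny hand-built table: per-type wiring rules respected."""
    t = SynapseTable()
    # 2 CS per STN, 2 GS per STN, 2 SG per GPe, 2 GG + 1 MS per GPe
    for post in range(n_stn):
        t.append([0, 1], [post, post], [0, 1], [TYPE_CODES["CS"]] * 2, [0.3, 0.3])
        t.append([0, 1], [post, post], [0, 1], [TYPE_CODES["GS"]] * 2, [0.3, 0.3])
    for g in range(n_gpe):
        post = n_stn + g
        t.append([0, 1], [post, post], [0, 1], [TYPE_CODES["SG"]] * 2, [0.3, 0.3])
        pre_gg = [(g + 1) % n_gpe, (g + 2) % n_gpe]
        t.append(pre_gg, [post, post], [0, 1], [TYPE_CODES["GG"]] * 2, [0.3, 0.3])
        t.append([g], [post], [2], [TYPE_CODES["MS"]], [1.0])
    return t


class TestConnectivityUpdate:
    def setup_method(self):
        self.n_stn, self.n_gpe, self.n_ctx = 2, 4, 10
        self.pop = np.array([0] * 2 + [1] * 4, dtype=np.int8)

    def _elements(self, table):
        exc = np.bincount(table.post[table.excitatory], minlength=6)
        inh_mask = (~table.excitatory) & table.plastic
        inh = np.bincount(table.post[inh_mask], minlength=6)
        return ElementState.balanced(exc, inh, self.pop)

    def test_no_vacancy_means_no_change(self, sp):
        table = _micro_table()
        els = self._elements(table)
        h0 = table.state_hash()
        log = connectivity_update(table, els, np.random.default_rng(0),
                                  self.n_stn, self.n_gpe, self.n_ctx, sp)
        assert log == {"formed": 0, "removed": 0}
        assert table.state_hash() == h0

    def test_formation_expectation_is_binomial(self, sp):
        """n vacant elements with unlimited partners form ~0.1 n synapses."""
        formed = []
        for seed in range(300):
            table = _micro_table()
            els = self._elements(table)
            els.z_exc[0] += 10.0  # 10 vacant excitatory elements on one STN
            log = connectivity_update(table, els, np.random.default_rng(seed),
                                      self.n_stn, self.n_gpe, self.n_ctx, sp)
            formed.append(log["formed"])
        mean = np.mean(formed)
        # Binomial(10, 0.1): mean 1.0, SE of the mean ~ 0.055
        assert mean == pytest.approx(1.0, abs=0.2)

    def test_new_synapses_are_type_consistent(self, sp):
        table = _micro_table()
        els = self._elements(table)
        els.z_exc += 5.0
        els.z_inh += 5.0
        for seed in range(10):
            connectivity_update(table, els, np.random.default_rng(seed),
                                self.n_stn, self.n_gpe, self.n_ctx, sp)
        table.validate(self.n_stn, self.n_gpe, self.n_ctx, 10)
        assert np.all((table.rho >= 0) & (table.rho <= 1))

    def test_removal_spares_ms_edges(self, sp):
        table = _micro_table()
        els = self._elements(table)
        ms_before = np.sum(table.type_code == TYPE_CODES["MS"])
        # drop inhibitory availability by 2 on one GPe neuron -> 2 GG removed
        gpe_idx = 2
        els.z_inh[gpe_idx] -= 2.0
        n_gg_before = np.sum((table.type_code == TYPE_CODES["GG"])
                             & (table.post == gpe_idx))
        log = connectivity_update(table, els, np.random.default_rng(1),
                                  self.n_stn, self.n_gpe, self.n_ctx, sp)
        n_gg_after = np.sum((table.type_code == TYPE_CODES["GG"])
                            & (table.post == gpe_idx))
        assert log["removed"] == 2
        assert n_gg_before - n_gg_after == 2
        assert np.sum(table.type_code == TYPE_CODES["MS"]) == ms_before

    def test_indegree_stats(self):
        table = _micro_table()
        stats = indegree_stats(table, 2, 4)
        assert stats["CS"]["mean"] == pytest.approx(2.0)
        assert stats["GG"]["mean"] == pytest.approx(2.0)
        ref = indegree_stats(table, 2, 4)
        # remove half of the CS edges -> CS mean halves, others unchanged
        rows = np.nonzero(table.type_code == TYPE_CODES["CS"])[0][:2]
        table.remove(rows)
        stats2 = indegree_stats(table, 2, 4, reference=ref)
        assert stats2["CS"]["mean"] == pytest.approx(1.0)
        assert stats2["CS"]["pct_change"] == pytest.approx(-50.0)
        assert stats2["GG"]["pct_change"] == pytest.approx(0.0)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            indegree_stats(SynapseTable(), 2, 4)


def test_structural_off_keeps_wiring_constant(model):
    """With structural plasticity disabled the graph hash is invariant."""
    from stngpe.engine import NetworkConfig, build_network

    cfg = NetworkConfig(n_stn=4, n_gpe=12, n_ctx=40, n_msn=120, in_degree=5,
                        seed=2, synaptic_plasticity=True,
                        structural_plasticity=False)
    net = build_network(cfg, model)
    h0 = net.table.state_hash()
    net.run(1000.0)
    assert net.table.state_hash() == h0


def test_ms_edges_fixed_during_structural_run(model):
    """MS (iMSN->GPe) edges are bit-identical across a structural run even
    while plastic types rewire."""
    from dataclasses import replace

    from stngpe.engine import NetworkConfig, build_network

    m = replace(model, structural=replace(model.structural, tau_z=2_000.0,
                                          ca_target_stn=0.002,
                                          ca_target_gpe=0.001))
    cfg = NetworkConfig(n_stn=4, n_gpe=12, n_ctx=40, n_msn=120, in_degree=5,
                        seed=2, synaptic_plasticity=False,
                        structural_plasticity=True)
    net = build_network(cfg, m)

    def ms_key(t):
        mask = t.type_code == TYPE_CODES["MS"]
        return np.sort(t.pre[mask] * 1000 + t.post[mask])

    ms0 = ms_key(net.table)
    net.run(3000.0)
    rewired = sum(log["formed"] + log["removed"]
                  for log in net.run(3000.0).structural_log)
    assert np.array_equal(ms_key(net.table), ms0)
    assert rewired > 0  # the low targets force rewiring of plastic types
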