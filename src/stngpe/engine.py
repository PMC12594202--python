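"""Network construction and time-stepping orchestration.

The :class:`Network` owns all state arrays (neurons, synapse table, element
bookkeeping) and advances them by calling the compiled kernel in blocks of
simulated time (200 ms by default, the connectivity-update cadence).
Structural plasticity runs between kernel blocks: dendritic-element counts
are integrated from the block-end low-pass calcium and the synapse table is
rewired every 200 ms of simulated time.

All randomness flows through named, seeded streams (wiring, initial state,
afferent realizations, plasticity noise, structural updates) so each can be
re-seeded independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .afferents import AfferentConfig, afferent_state, generate_train
from .connectivity import (POST_POP, PRE_KIND, TYPE_CODES, TYPE_NAMES,
                           SynapseTable, indegree_stats)
from .neurons import GATE_NAMES, NeuronParams
from .plasticity import PlasticityParams
from .structural import (UPDATE_INTERVAL_MS, ElementState, StructuralParams,
                         connectivity_update, element_derivatives)
from .synapses import G_NMDA_SYN_OVER_AMPA, TransmitterParams, default_transmitters

__all__ = [
    "NetworkConfig",
    "ModelParams",
    "Network",
    "RunResult",
    "build_network",
    "events_from_trains",
    "default_model",
    "tune_weights",
    "check_constraints",
]

GATE_INDEX = {n: i for i, n in enumerate(GATE_NAMES)}


@dataclass(frozen=True)
class ModelParams:
    """All biophysical parameters of the model (both populations).

    ``weights`` maps synapse type to the baseline fast conductance g_base
    (mS/cm^2); plastic types use w_min = g_base/2 and w_max = 2 g_base so
    that the mean initial efficacy of 1/3 sits exactly halfway between a 50%
    reduction (rho = 0) and a 100% increase (rho = 1).  MS synapses are
    non-plastic with fixed conductance g_base.
    """

    stn: NeuronParams
    gpe: NeuronParams
    transmitters: dict
    plasticity: PlasticityParams
    structural: StructuralParams
    weights: dict
    g_nmda_ca_frac: float = 1.0
    v_thresh: float = -10.0
    refractory_ms: float = 1.0

    def w_bounds(self, syn_type: str) -> tuple[float, float]:
        g = self.weights[syn_type]
        if syn_type == "MS":
            return g, g
        return 0.5 * g, 2.0 * g


def default_model(**overrides) -> ModelParams:
    """Shipped parameter set (source-model kinetics + calibrated values).

    Calibration targets: isolated STN pacemaking near 10 Hz; isolated GPe
    near 30 Hz; network healthy-state rates 10/30 Hz; a 10-synapse GPe volley
    hyperpolarizing the STN below -75 mV; 30-Hz iMSN input silencing the GPe;
    NMDA:AMPA peak-current ratio 0.25; plasticity-protocol outcomes.
    """
    kw = dict(
        stn=NeuronParams("STN", I_bias=2.0, g_leak=0.1, g_L=6.0, g_T=3.5,
                         g_CaK=2.0),
        gpe=NeuronParams("GPe", g_A=0.0, g_L=0.0, g_T=2.5, g_CaK=0.4,
                         I_bias=2.0),
        transmitters=default_transmitters(),
        plasticity=PlasticityParams(),
        structural=StructuralParams(),
        weights={"CS": 0.145, "GS": 0.15, "SG": 0.15, "GG": 0.1, "MS": 0.3},
    )
    kw.update(overrides)
    return ModelParams(**kw)


@dataclass(frozen=True)
class NetworkConfig:
    """Network topology and simulation switches.

    Base population sizes follow the 1:3 STN:GPe ratio (250:750) with 2500
    cortical and 7500 iMSN generators; ``scale_factor`` divides all sizes
    uniformly while preserving in-degrees and afferent rates.
    """

    n_stn: int = 250
    n_gpe: int = 750
    n_ctx: int = 2500
    n_msn: int = 7500
    scale_factor: float = 1.0
    dt: float = 0.03125
    seed: int = 0
    synaptic_plasticity: bool = True
    structural_plasticity: bool = True
    in_degree: int = 10
    rho_init_mean: float = 0.33
    rho_init_sd: float = 0.033

    def scaled(self, name: str) -> int:
        n = int(round(getattr(self, name) / self.scale_factor))
        if n < 1:
            raise ValueError(f"scale_factor {self.scale_factor} empties {name}")
        return n

    @property
    def sizes(self) -> dict:
        return {k: self.scaled("n_" + k) for k in ("stn", "gpe", "ctx", "msn")}


@dataclass
class RunResult:
    """Output of one :meth:`Network.run` call."""

    spike_neuron: np.ndarray
    spike_t_ms: np.ndarray
    t_probe_ms: np.ndarray
    v_probe: np.ndarray | None = None
    ca_probe: np.ndarray | None = None
    rho_probe: np.ndarray | None = None
    t_block_ms: np.ndarray | None = None
    ca_l_blocks: np.ndarray | None = None
    structural_log: list = field(default_factory=list)
    t0_ms: float = 0.0
    t1_ms: float = 0.0
    occ_d: np.ndarray | None = None  # (n, 3) steps at/above theta_d
    occ_p: np.ndarray | None = None
    n_steps: int = 0

    def spikes_of(self, idx) -> np.ndarray:
        """Spike times (ms) of the given neuron indices."""
        mask = np.isin(self.spike_neuron, np.atleast_1d(idx))
        return self.spike_t_ms[mask]


def events_from_trains(trains, dt: float, t_offset_ms: float = 0.0):
    """Convert per-generator spike trains (seconds) to sorted step events."""
    steps = []
    gens = []
    for g, tr in enumerate(trains):
        st = np.round((np.asarray(tr) * 1000.0 + t_offset_ms) / dt).astype(np.int64)
        steps.append(st)
        gens.append(np.full(st.size, g, dtype=np.int64))
    if not steps:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
    steps = np.concatenate(steps)
    gens = np.concatenate(gens)
    order = np.argsort(steps, kind="stable")
    return steps[order], gens[order]


#: voltage grid of the kernel lookup tables (mV); calcium-driven gates use a
#: 0..CA_TAB_MAX uM grid with the same number of points
V_TAB_LO, V_TAB_HI = -150.0, 60.0
CA_TAB_MAX = 2.0
N_TAB = 10_501


def _pack_population_params(stn: NeuronParams, gpe: NeuronParams, dt: float):
    """Tabulate both populations' gate kinetics for the kernel.

    Steady states and half-step relaxation factors exp(-dt/(2 tau)) are
    sampled from the reference kinetics on a fine driver grid (0.02 mV /
    2e-4 uM resolution); the kernel interpolates linearly.
    """
    from .neurons import steady_state, time_constant

    pops = (stn, gpe)
    n_g = len(GATE_NAMES)
    gisca = np.zeros(n_g, dtype=np.uint8)
    guse = np.zeros((2, n_g), dtype=np.uint8)
    xinf_tab = np.zeros((2, n_g, N_TAB))
    relax_tab = np.ones((2, n_g, N_TAB))
    m0 = np.zeros(n_g)
    inv_dm = np.zeros(n_g)
    v_grid = np.linspace(V_TAB_LO, V_TAB_HI, N_TAB)
    ca_grid = np.linspace(0.0, CA_TAB_MAX, N_TAB)
    for p, params in enumerate(pops):
        used = set()
        for _, gkey, gate_pow, _ in params.channels:
            if getattr(params, gkey) != 0.0 or gkey == "g_leak":
                used.update(name for name, _ in gate_pow)
        for gi, name in enumerate(GATE_NAMES):
            spec = params.gate_spec(name)
            is_ca = spec.driver == "calcium"
            gisca[gi] = 1 if is_ca else 0
            grid = ca_grid if is_ca else v_grid
            m0[gi] = grid[0]
            inv_dm[gi] = (N_TAB - 1) / (grid[-1] - grid[0])
            xinf_tab[p, gi] = steady_state(spec, grid)
            relax_tab[p, gi] = np.exp(-0.5 * dt / time_constant(spec, grid))
            guse[p, gi] = 1 if name in used else 0
    gcond = np.zeros((2, 7))
    for p, params in enumerate(pops):
        gcond[p] = [params.g_Na, params.g_K, params.g_T, params.g_CaK,
                    params.g_A, params.g_L, params.g_leak]
    Cm = np.array([stn.C, gpe.C])
    return xinf_tab, relax_tab, m0, inv_dm, gisca, guse, gcond, Cm


class Network:
    """Simulation state of one STN-GPe network realization."""

    def __init__(self, cfg: NetworkConfig, model: ModelParams,
                 table: SynapseTable, rng_streams: dict):
        self.cfg = cfg
        self.model = model
        self.table = table
        self.rngs = rng_streams
        s = cfg.sizes
        self.n_stn, self.n_gpe = s["stn"], s["gpe"]
        self.n_ctx, self.n_msn = s["ctx"], s["msn"]
        self.n = self.n_stn + self.n_gpe
        self.pop = np.zeros(self.n, dtype=np.int8)
        self.pop[self.n_stn:] = 1
        self.step_count = 0
        self.block_count = 0

        init = rng_streams["init"]
        self.V = init.uniform(-80.0, 50.0, size=self.n)
        self.gates = init.uniform(0.0, 1.0, size=(self.n, len(GATE_NAMES)))
        self.ca_soma = np.full(self.n, 0.005)
        self.ca_seg = np.full((self.n, 3), 0.005)
        self.ca_L = np.full(self.n, 0.005)
        self.bias = np.where(self.pop == 0, model.stn.I_bias, model.gpe.I_bias)
        self.inj = np.zeros(self.n)
        self.last_spike = np.full(self.n, -(10 ** 9), dtype=np.int64)

        (self._xinf_tab, self._relax_tab, self._m0, self._inv_dm, self._gisca,
         self._guse, self._gcond, self._Cm) = _pack_population_params(
            model.stn, model.gpe, cfg.dt)
        from .synapses import mg_block
        v_grid = np.linspace(V_TAB_LO, V_TAB_HI, N_TAB)
        self._mgs_tab = mg_block(v_grid, "syn")
        self._mgc_tab = mg_block(v_grid, "Ca")
        self._inv_dv_tab = (N_TAB - 1) / (V_TAB_HI - V_TAB_LO)
        tp = np.zeros((3, 6))
        for row, name in ((0, "GABAa"), (1, "AMPA"), (2, "NMDA")):
            t = model.transmitters[name]
            tp[row] = [t.phi, t.nu_fast, t.nu_slow, t.tau_rise, t.tau_fast,
                       t.tau_slow]
        self._tp = tp
        self._E_gaba = model.transmitters["GABAa"].E_rev
        self._E_ampa = model.transmitters["AMPA"].E_rev
        self._E_nsyn = model.transmitters["NMDA"].E_rev
        self._E_nca = model.transmitters["NMDA"].E_rev_ca

        self.elements = ElementState.balanced(
            *self._bound_counts(), pop=self.pop)
        self._refresh_synapse_arrays()
        # per-pathway blocking flags (protocol use)
        m = len(table)
        self.on_ampa = np.ones(m, dtype=np.uint8)
        self.on_nmda = np.ones(m, dtype=np.uint8)
        self.on_gaba = np.ones(m, dtype=np.uint8)

    # -- bookkeeping ------------------------------------------------------
    def _bound_counts(self):
        exc = np.bincount(self.table.post[self.table.excitatory],
                          minlength=self.n)
        inh_mask = (~self.table.excitatory) & self.table.plastic
        inh = np.bincount(self.table.post[inh_mask], minlength=self.n)
        return exc, inh

    def _refresh_synapse_arrays(self) -> None:
        """Rebuild derived per-synapse arrays and CSR adjacency."""
        t = self.table
        m = len(t)
        tc = t.type_code.astype(np.int64)
        self.sy_exc = t.excitatory.astype(np.uint8)
        self.sy_plastic = t.plastic.astype(np.uint8)
        self.sy_pop = POST_POP[tc].astype(np.int8)
        wmin = np.empty(5)
        wmax = np.empty(5)
        for name, code in TYPE_CODES.items():
            wmin[code], wmax[code] = self.model.w_bounds(name)
        self.sy_wmin = wmin[tc]
        self.sy_wmax = wmax[tc]
        # CSR: internal neuron -> outgoing synapse rows
        pre_kind = PRE_KIND[tc]
        internal = (pre_kind == 0) | (pre_kind == 1)
        pre_global = np.where(pre_kind == 0, t.pre, t.pre + self.n_stn)
        self.out_ptr, self.out_syn = _csr(pre_global[internal],
                                          np.nonzero(internal)[0], self.n)
        self.ctx_ptr, self.ctx_syn = _csr(t.pre[pre_kind == 2],
                                          np.nonzero(pre_kind == 2)[0],
                                          self.n_ctx)
        self.msn_ptr, self.msn_syn = _csr(t.pre[pre_kind == 3],
                                          np.nonzero(pre_kind == 3)[0],
                                          self.n_msn)

    def block_synapses(self, *, types=(), ampa=None, nmda=None, gaba=None,
                       invert=False) -> None:
        """Enable/disable transmission pathways for the given synapse types.

        ``types`` selects synapses by type name; with ``invert`` the
        complement is selected.  Each of ``ampa``/``nmda``/``gaba`` set to
        True re-enables, False blocks, None leaves untouched.
        """
        codes = [TYPE_CODES[t] for t in types]
        mask = np.isin(self.table.type_code, codes)
        if invert:
            mask = ~mask
        for flag, arr in ((ampa, self.on_ampa), (nmda, self.on_nmda),
                          (gaba, self.on_gaba)):
            if flag is not None:
                arr[mask] = 1 if flag else 0

    @property
    def t_ms(self) -> float:
        return self.step_count * self.cfg.dt

    def indegrees(self, reference: dict | None = None) -> dict:
        return indegree_stats(self.table, self.n_stn, self.n_gpe, reference)

    def state_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for a in (self.V, self.gates, self.ca_soma, self.ca_seg, self.ca_L,
                  self.table.rho, self.table.s):
            h.update(np.ascontiguousarray(a).tobytes())
        h.update(self.table.state_hash().encode())
        return h.hexdigest()

    # -- simulation -------------------------------------------------------
    def run(self, duration_ms: float, ctx_events=None, msn_events=None, *,
            stride: int = 32, probe_v=(), probe_ca=(), probe_rho=(),
            pulses=(), releases=(), record_ca_l: bool = False,
            max_rate_hz: float = 400.0, plasticity: bool | None = None) -> RunResult:
        """Advance the network by ``duration_ms``.

        ``ctx_events``/``msn_events`` are (step, generator) arrays with steps
        absolute (relative to the network's running step counter at offset 0
        of this call).  ``pulses`` are (t_start_ms, t_end_ms, amplitude,
        neuron_index_or_None) injected-current intervals; ``releases`` are
        (t_ms, synapse_rows) manual presynaptic release events, both relative
        to the start of this call.  Probes are recorded every ``stride``
        steps.
        """
        cfg = self.cfg
        dt = cfg.dt
        n_steps_total = int(round(duration_ms / dt))
        step_start = self.step_count
        block_steps = int(round(UPDATE_INTERVAL_MS / dt))

        ctx_ev = ctx_events if ctx_events is not None else (
            np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64))
        msn_ev = msn_events if msn_events is not None else (
            np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64))
        ctx_ev = (ctx_ev[0] + step_start, ctx_ev[1])
        msn_ev = (msn_ev[0] + step_start, msn_ev[1])

        # segment boundaries: 200-ms grid + pulse edges + release times
        bounds = set(range(0, n_steps_total + 1, block_steps))
        bounds.add(n_steps_total)
        for (t0, t1, _, _) in pulses:
            bounds.add(int(round(t0 / dt)))
            bounds.add(int(round(t1 / dt)))
        for (t0, _) in releases:
            bounds.add(int(round(t0 / dt)))
        bounds = sorted(b for b in bounds if 0 <= b <= n_steps_total)

        pv_idx = np.asarray(probe_v, dtype=np.int64)
        pca = list(probe_ca)
        pca_n = np.asarray([c[0] for c in pca], dtype=np.int64)
        pca_seg = np.asarray([c[1] for c in pca], dtype=np.int64)
        pr_syn = np.asarray(probe_rho, dtype=np.int64)

        all_spn, all_spt = [], []
        all_tp, all_pv, all_pca, all_pr = [], [], [], []
        occ_d = np.zeros((self.n, 3), dtype=np.int64)
        occ_p = np.zeros((self.n, 3), dtype=np.int64)
        t_blocks, ca_l_blocks = [], []
        struct_log = []
        if plasticity is None:
            plasticity = cfg.synaptic_plasticity
        plast_on = 1 if plasticity else 0

        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            n_steps = b1 - b0
            if n_steps == 0:
                continue
            g0 = step_start + b0
            # injected currents active on this segment
            self.inj[:] = 0.0
            t_mid = (b0 + 0.5) * dt
            for (t0, t1, amp, who) in pulses:
                if t0 <= t_mid < t1:
                    if who is None:
                        self.inj[:] += amp
                    else:
                        self.inj[who] += amp
            # manual releases scheduled at this boundary
            for (t0, rows) in releases:
                if int(round(t0 / dt)) == b0:
                    t_abs = g0 * dt
                    self.table.fpre_until[np.asarray(rows)] = np.maximum(
                        self.table.fpre_until[np.asarray(rows)], t_abs + 1.0)

            lo_c = np.searchsorted(ctx_ev[0], g0)
            hi_c = np.searchsorted(ctx_ev[0], g0 + n_steps)
            lo_m = np.searchsorted(msn_ev[0], g0)
            hi_m = np.searchsorted(msn_ev[0], g0 + n_steps)

            n_rec = len(range(0, n_steps, stride))
            pv_buf = np.zeros((pv_idx.size, n_rec))
            pca_buf = np.zeros((pca_n.size, n_rec))
            pr_buf = np.zeros((pr_syn.size, n_rec))
            cap = int(self.n * n_steps * dt / 1000.0 * max_rate_hz) + 1024
            sp_n = np.zeros(cap, dtype=np.int64)
            sp_step = np.zeros(cap, dtype=np.int64)
            noise_seed = np.random.SeedSequence(
                (cfg.seed, 7919, self.block_count)).generate_state(1)[0]

            p = self.model.plasticity
            count = _kernels.run_block(
                g0, n_steps, dt,
                self.pop, self.V, self.gates, self.ca_soma, self.ca_seg,
                self.ca_L, self.bias, self.inj, self.last_spike,
                self._guse, self._gisca, self._xinf_tab, self._relax_tab,
                self._m0, self._inv_dm, N_TAB,
                self._mgs_tab, self._mgc_tab, V_TAB_LO, self._inv_dv_tab,
                self._gcond, self._Cm,
                self.model.stn.E_Na, self.model.stn.E_K, self.model.stn.E_leak,
                self.model.stn.ca_out,
                8.314462618 * self.model.stn.temperature / (2 * 96485.33212) * 1e3,
                self.model.stn.ca_floor, self.model.stn.k_ca,
                self.model.stn.k_conv, self.model.v_thresh,
                int(round(self.model.refractory_ms / dt)),
                self.table.post, self.table.seg.astype(np.int64), self.sy_exc,
                self.sy_plastic, self.sy_pop, self.table.rho, self.table.s,
                self.table.fpre_until, self.sy_wmin, self.sy_wmax,
                self.on_ampa, self.on_nmda, self.on_gaba,
                self._tp, self._E_gaba, self._E_ampa, self._E_nsyn,
                self._E_nca, G_NMDA_SYN_OVER_AMPA, self.model.g_nmda_ca_frac,
                self.out_ptr, self.out_syn, self.ctx_ptr, self.ctx_syn,
                self.msn_ptr, self.msn_syn,
                ctx_ev[0][lo_c:hi_c], ctx_ev[1][lo_c:hi_c],
                msn_ev[0][lo_m:hi_m], msn_ev[1][lo_m:hi_m],
                plast_on, p.tau_rho, p.gamma_p, p.gamma_d, p.sigma,
                np.array([p.theta_d_stn, p.theta_d_gpe]),
                np.array([p.theta_p_stn, p.theta_p_gpe]),
                noise_seed, self.model.structural.tau_ca_l,
                sp_n, sp_step,
                stride, pv_idx, pv_buf, pca_n, pca_seg, pca_buf, pr_syn,
                pr_buf, occ_d, occ_p)
            self.block_count += 1
            self.step_count = g0 + n_steps
            ok = np.isfinite(self.V) & (np.abs(self.V) < 1e6)
            if not ok.all():
                bad = np.nonzero(~ok)[0]
                raise FloatingPointError(
                    f"non-finite or diverging membrane potential at "
                    f"t={self.t_ms:.3f} ms for neuron(s) {bad[:10].tolist()}; "
                    f"state diagnostic: dt={dt}, n_syn={len(self.table)}")

            all_spn.append(sp_n[:count].copy())
            all_spt.append(sp_step[:count] * dt)
            all_tp.append((g0 + np.arange(0, n_steps, stride)) * dt)
            all_pv.append(pv_buf)
            all_pca.append(pca_buf)
            all_pr.append(pr_buf)

            # structural plasticity on the 200-ms grid
            at_grid = self.step_count % block_steps == 0
            if cfg.structural_plasticity and at_grid:
                self._structural_update(n_steps_since=block_steps)
            if record_ca_l and at_grid:
                t_blocks.append(self.step_count * dt)
                ca_l_blocks.append(self.ca_L.copy())
            if cfg.structural_plasticity and at_grid:
                struct_log.append(self._last_struct)

        res = RunResult(
            spike_neuron=np.concatenate(all_spn) if all_spn else np.zeros(0, np.int64),
            spike_t_ms=np.concatenate(all_spt) if all_spt else np.zeros(0),
            t_probe_ms=np.concatenate(all_tp) if all_tp else np.zeros(0),
            v_probe=np.concatenate(all_pv, axis=1) if pv_idx.size else None,
            ca_probe=np.concatenate(all_pca, axis=1) if pca_n.size else None,
            rho_probe=np.concatenate(all_pr, axis=1) if pr_syn.size else None,
            t_block_ms=np.asarray(t_blocks) if t_blocks else None,
            ca_l_blocks=np.asarray(ca_l_blocks) if ca_l_blocks else None,
            structural_log=struct_log,
            t0_ms=step_start * dt, t1_ms=self.step_count * dt,
            occ_d=occ_d, occ_p=occ_p, n_steps=n_steps_total)
        return res

    def _structural_update(self, n_steps_since: int) -> None:
        sp = self.model.structural
        dt_ms = n_steps_since * self.cfg.dt
        target = np.where(self.pop == 0, sp.ca_target_stn, sp.ca_target_gpe)
        d_exc, d_inh = element_derivatives(self.ca_L, target, sp.tau_z)
        self.elements.z_exc += dt_ms * d_exc
        self.elements.z_inh += dt_ms * d_inh
        m_before = len(self.table)
        log = connectivity_update(self.table, self.elements,
                                  self.rngs["structural"], self.n_stn,
                                  self.n_gpe, self.n_ctx, sp)
        self._last_struct = log
        if log["formed"] or log["removed"]:
            # blocking flags follow the table; new synapses default to open
            if log["removed"] or len(self.table) != m_before:
                self.on_ampa = np.ones(len(self.table), dtype=np.uint8)
                self.on_nmda = np.ones(len(self.table), dtype=np.uint8)
                self.on_gaba = np.ones(len(self.table), dtype=np.uint8)
            self._refresh_synapse_arrays()


def _csr(pre_idx: np.ndarray, rows: np.ndarray, n_src: int):
    """Build CSR (ptr, rows) adjacency from parallel (source, synapse-row)."""
    order = np.argsort(pre_idx, kind="stable")
    sorted_pre = pre_idx[order]
    ptr = np.zeros(n_src + 1, dtype=np.int64)
    np.add.at(ptr, sorted_pre + 1, 1)
    np.cumsum(ptr, out=ptr)
    return ptr, rows[order].astype(np.int64)


def _truncated_normal(rng, mean, sd, size):
    x = rng.normal(mean, sd, size=size)
    return np.clip(x, 0.0, 1.0)


def build_network(cfg: NetworkConfig, model: ModelParams | None = None) -> Network:
    """Wire a network: per-type mean in-degree ``cfg.in_degree``, random
    pairing, random segments, truncated-normal initial efficacies."""
    model = model if model is not None else default_model()
    ss = np.random.SeedSequence(cfg.seed)
    names = ("wiring", "init", "afferents", "plasticity", "structural")
    rngs = {n: np.random.default_rng(s) for n, s in zip(names, ss.spawn(len(names)))}
    wiring = rngs["wiring"]
    s = cfg.sizes
    n_stn, n_gpe, n_ctx, n_msn = s["stn"], s["gpe"], s["ctx"], s["msn"]
    table = SynapseTable()
    src_sizes = {"CS": n_ctx, "GS": n_gpe, "SG": n_stn, "GG": n_gpe, "MS": n_msn}
    for name in TYPE_NAMES:
        code = TYPE_CODES[name]
        n_post = n_stn if POST_POP[code] == 0 else n_gpe
        post_off = 0 if POST_POP[code] == 0 else n_stn
        k = cfg.in_degree * n_post
        pre = wiring.integers(0, src_sizes[name], size=k)
        post = wiring.integers(0, n_post, size=k) + post_off
        if name == "GG":  # no self-loops
            bad = pre + n_stn == post
            while np.any(bad):
                pre[bad] = wiring.integers(0, n_gpe, size=int(bad.sum()))
                bad = pre + n_stn == post
        seg = wiring.integers(0, 3, size=k)
        rho = _truncated_normal(wiring, cfg.rho_init_mean, cfg.rho_init_sd, k)
        if name == "MS":
            rho = np.full(k, 1.0)  # fixed conductance, efficacy unused
        table.append(pre, post, seg, np.full(k, code), rho)
    table.validate(n_stn, n_gpe, n_ctx, n_msn)
    return Network(cfg, model, table, rngs)


# ---------------------------------------------------------------------------
# weight tuning against the model-fitting constraints
# ---------------------------------------------------------------------------

def _healthy_events(net: Network, duration_ms: float, state: str = "healthy"):
    st = afferent_state(state)
    rng = net.rngs["afferents"]
    T = duration_ms / 1000.0
    ctx = generate_train(replace(st["CTX"], n=net.n_ctx), T, rng)
    msn = generate_train(replace(st["iMSN"], n=net.n_msn), T, rng)
    return (events_from_trains(ctx, net.cfg.dt),
            events_from_trains(msn, net.cfg.dt))


def measure_rates(cfg: NetworkConfig, model: ModelParams, duration_ms: float,
                  warmup_ms: float = 2000.0, state: str = "healthy"):
    """Population-mean STN/GPe rates (Hz) in a fresh network realization."""
    net = build_network(cfg, model)
    ctx_ev, msn_ev = _healthy_events(net, warmup_ms + duration_ms, state)
    net.run(warmup_ms, ctx_ev, msn_ev)
    # reuse remaining events (steps absolute within the same stream)
    res = net.run(duration_ms,
                  (ctx_ev[0] - int(round(warmup_ms / cfg.dt)), ctx_ev[1]),
                  (msn_ev[0] - int(round(warmup_ms / cfg.dt)), msn_ev[1]))
    stn_rate = np.sum(res.spike_neuron < net.n_stn) / net.n_stn / (duration_ms / 1e3)
    gpe_rate = np.sum(res.spike_neuron >= net.n_stn) / net.n_gpe / (duration_ms / 1e3)
    return stn_rate, gpe_rate, net, res


def rebound_volley_min_v(model: ModelParams, n_afferents: int = 10,
                         window_ms: float = 100.0, seed: int = 0,
                         n_volleys: int = 5) -> float:
    """Minimum STN membrane potential after a synchronized GPe volley.

    One tuned STN neuron with ``n_afferents`` GPe->STN synapses receives a
    simultaneous release from all of them during tonic firing.  The response
    depth depends on the firing phase at which the volley lands, so the
    volley is delivered at ``n_volleys`` phases (spacings incommensurate
    with the firing period) and the deepest hyperpolarization is reported —
    the capability the pallido-subthalamic weight is tuned for.
    """
    net = single_stn_setup(model, n_cs=0, n_gs=n_afferents, seed=seed)
    rows = np.nonzero(net.table.type_code == TYPE_CODES["GS"])[0]
    # the weight-tuning constraints are defined with plasticity disabled
    net.run(1000.0, plasticity=False)  # settle into tonic firing
    vmin = np.inf
    for k in range(n_volleys):
        res = net.run(window_ms, releases=[(0.0, rows)], probe_v=[0],
                      stride=1, plasticity=False)
        vmin = min(vmin, float(res.v_probe[0].min()))
        # desynchronize the next volley from the firing period
        net.run(237.0, plasticity=False)
    return vmin


def single_stn_setup(model: ModelParams, n_cs: int = 10, n_gs: int = 10,
                     seed: int = 0, rho_init=(0.33, 0.033)) -> Network:
    """One STN neuron with CS and GS synapses (GS sources silenced).

    The GS presynaptic GPe neurons get a strongly negative bias so they never
    fire; GS releases are driven manually or left silent.  Used by the
    slice-experiment protocols and the rebound-volley measurement.
    """
    n_gpe = max(n_gs, 1)
    cfg = NetworkConfig(n_stn=1, n_gpe=n_gpe, n_ctx=max(n_cs, 1), n_msn=1,
                        scale_factor=1.0, seed=seed, in_degree=0,
                        synaptic_plasticity=True, structural_plasticity=False,
                        rho_init_mean=rho_init[0], rho_init_sd=rho_init[1])
    net = build_network(cfg, model)
    rng = net.rngs["wiring"]
    pre_cs = np.arange(n_cs) % max(n_cs, 1)
    pre_gs = np.arange(n_gs) % n_gpe
    if n_cs:
        net.table.append(pre_cs, np.zeros(n_cs, dtype=np.int64),
                         rng.integers(0, 3, size=n_cs),
                         np.full(n_cs, TYPE_CODES["CS"]),
                         _truncated_normal(rng, *rho_init, n_cs))
    if n_gs:
        net.table.append(pre_gs, np.zeros(n_gs, dtype=np.int64),
                         rng.integers(0, 3, size=n_gs),
                         np.full(n_gs, TYPE_CODES["GS"]),
                         _truncated_normal(rng, *rho_init, n_gs))
    net.bias[1:] = -100.0  # silence the placeholder GPe sources
    net.on_ampa = np.ones(len(net.table), dtype=np.uint8)
    net.on_nmda = np.ones(len(net.table), dtype=np.uint8)
    net.on_gaba = np.ones(len(net.table), dtype=np.uint8)
    net._refresh_synapse_arrays()
    # settle the neuron from a reproducible state
    net.V[0] = -60.0
    net.gates[0] = [0.1, 0.6, 0.1, 0.2, 0.2, 0.3, 0.5, 0.05, 0.4, 0.9, 0.01]
    return net


def check_constraints(model: ModelParams, seed: int = 0,
                      scale_factor: float = 5.0,
                      duration_ms: float = 20_000.0) -> dict:
    """Evaluate the model-fitting constraints; returns measured values + flags.

    Constraints: healthy STN 10+-1 Hz and GPe 30+-1 Hz (plasticity off);
    10-afferent GPe volley drives STN below -75 mV; 30-Hz iMSN input
    transiently silences the GPe; peak beta below 10x the 0-100-Hz mean.
    """
    from .analysis import beta_peak_ratio, population_rate, welch_psd

    cfg = NetworkConfig(scale_factor=scale_factor, seed=seed,
                        synaptic_plasticity=False, structural_plasticity=False)
    stn_rate, gpe_rate, net, res = measure_rates(cfg, model, duration_ms)
    rate = population_rate(res.spike_t_ms[res.spike_neuron < net.n_stn]
                           - res.t0_ms, net.n_stn, duration_ms)
    try:
        ratio = beta_peak_ratio(welch_psd(rate))
    except ValueError:
        ratio = np.nan
    vmin = rebound_volley_min_v(model, seed=seed)
    gpe_silenced = _msn_silencing(model, seed=seed)
    report = {
        "stn_rate_hz": float(stn_rate),
        "gpe_rate_hz": float(gpe_rate),
        "volley_min_v_mv": vmin,
        "beta_peak_ratio": float(ratio),
        "msn_30hz_silences_gpe": bool(gpe_silenced),
        "pass_stn_rate": bool(abs(stn_rate - 10.0) <= 1.0),
        "pass_gpe_rate": bool(abs(gpe_rate - 30.0) <= 1.0),
        "pass_rebound": bool(vmin <= -75.0),
        "pass_beta": bool(ratio < 10.0),
    }
    report["all_pass"] = all(report[k] for k in
                             ("pass_stn_rate", "pass_gpe_rate", "pass_rebound",
                              "pass_beta", "msn_30hz_silences_gpe"))
    return report


def _msn_silencing(model: ModelParams, seed: int = 0,
                   rate_hz: float = 30.0) -> bool:
    """Does sustained ``rate_hz`` iMSN input transiently silence a GPe neuron?

    One GPe neuron with its 10 MS synapses; afferents switch from silence to
    Poisson at ``rate_hz`` for 500 ms; silenced means the firing rate in the
    stimulated window (after a 100-ms onset) drops below 10% of the
    autonomous rate.
    """
    cfg = NetworkConfig(n_stn=1, n_gpe=1, n_ctx=1, n_msn=10, seed=seed,
                        in_degree=0, synaptic_plasticity=False,
                        structural_plasticity=False)
    net = build_network(cfg, model)
    rng = net.rngs["wiring"]
    k = 10
    net.table.append(np.arange(k) % net.n_msn, np.full(k, 1, dtype=np.int64),
                     rng.integers(0, 3, size=k), np.full(k, TYPE_CODES["MS"]),
                     np.full(k, 1.0))
    net.on_ampa = np.ones(len(net.table), dtype=np.uint8)
    net.on_nmda = np.ones(len(net.table), dtype=np.uint8)
    net.on_gaba = np.ones(len(net.table), dtype=np.uint8)
    net._refresh_synapse_arrays()
    base = net.run(1000.0, plasticity=False)  # settle tonic firing
    base_rate = np.sum(base.spike_neuron == 1) / 1.0
    rng_aff = net.rngs["afferents"]
    T = 0.5
    trains = [np.sort(rng_aff.uniform(0.0, T, rng_aff.poisson(rate_hz * T)))
              for _ in range(net.n_msn)]
    ev = events_from_trains(trains, cfg.dt)
    res = net.run(500.0, msn_events=ev, plasticity=False)
    gpe_spikes = res.spike_t_ms[res.spike_neuron == 1] - res.t0_ms
    stim_rate = np.sum(gpe_spikes > 100.0) / 0.4
    return stim_rate < 0.1 * max(base_rate, 1.0)


def calibrate_ca_targets(model: ModelParams, seed: int = 0,
                         scale_factor: float = 5.0,
                         duration_ms: float = 10_000.0,
                         warmup_ms: float = 5_000.0) -> ModelParams:
    """Set the structural-plasticity calcium targets from a reference run.

    The per-population targets Ca* are the steady-state population means of
    the low-pass somatic calcium in a healthy-state simulation with
    structural plasticity disabled, as the homeostatic rule prescribes.
    Returns a model with the measured targets installed.
    """
    cfg = NetworkConfig(scale_factor=scale_factor, seed=seed,
                        synaptic_plasticity=False, structural_plasticity=False)
    _, _, net, _ = measure_rates(cfg, model, duration_ms, warmup_ms)
    return replace(model, structural=replace(
        model.structural,
        ca_target_stn=float(net.ca_L[:net.n_stn].mean()),
        ca_target_gpe=float(net.ca_L[net.n_stn:].mean())))


def tune_weights(model: ModelParams, seed: int = 0, max_iter: int = 8,
                 scale_factor: float = 5.0, duration_ms: float = 10_000.0,
                 targets=(10.0, 30.0)) -> tuple[ModelParams, dict]:
    """Iterative multiplicative adjustment of CS and GG weights toward the
    target healthy-state firing rates (plasticity disabled).

    GS and MS weights are pinned by the rebound and silencing constraints and
    are not moved; STN rate is steered by the CS weight and GPe rate by the
    GG weight.  Returns the adjusted model and a tuning report.
    """
    history = []
    weights = dict(model.weights)
    for it in range(max_iter):
        m = replace(model, weights=dict(weights))
        cfg = NetworkConfig(scale_factor=scale_factor, seed=seed + it,
                            synaptic_plasticity=False,
                            structural_plasticity=False)
        stn, gpe, _, _ = measure_rates(cfg, m, duration_ms)
        history.append({"iter": it, "weights": dict(weights),
                        "stn_rate": float(stn), "gpe_rate": float(gpe)})
        ok_stn = abs(stn - targets[0]) <= 1.0
        ok_gpe = abs(gpe - targets[1]) <= 1.0
        if ok_stn and ok_gpe:
            break
        if not ok_stn:
            weights["CS"] = float(np.clip(
                weights["CS"] * (targets[0] / max(stn, 1e-2)) ** 0.5,
                1e-4, 10.0))
        if not ok_gpe:
            weights["GG"] = float(np.clip(
                weights["GG"] * (max(gpe, 1e-2) / targets[1]) ** 0.5,
                1e-4, 10.0))
    final = replace(model, weights=dict(weights))
    report = {"history": history, "final_weights": dict(weights),
              "converged": bool(ok_stn and ok_gpe)}
    return final, report
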