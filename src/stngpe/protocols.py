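"""In-silico plasticity and step-change experiment protocols.

Two slice-style protocols probe the calcium-plasticity rule on a single STN
neuron:

* **Cortical stimulation** (heterosynaptic): all synaptic currents onto the
  STN are blocked except CTX->STN NMDA receptors; trains of correlated
  cortical firing (300-ms windows every 5 s) drive NMDA calcium influx into
  the dendritic segments.  Strong (50 Hz) windows potentiate both CS and GS
  synapses; weak (8 Hz) windows depress; healthy input leaves them unchanged.
* **Rebound bursting** (monosynaptic): all synaptic transmission is blocked
  and hyperpolarizing current pulses (0.1 Hz) de-inactivate T-type calcium
  channels; the rebound burst's calcium transient decides between no change,
  depression and potentiation as a function of burst strength.

The step-change experiment runs a full (scaled-down) network from a healthy
state into one of the parkinsonian afferent states while recording rates,
calcium, in-degrees, efficacies and beta power.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .afferents import afferent_state, generate_train
from .analysis import integral_beta, population_rate, welch_psd
from .connectivity import TYPE_CODES
from .engine import (ModelParams, Network, NetworkConfig, build_network,
                     default_model, events_from_trains, single_stn_setup)
from .plasticity import classify_outcome

__all__ = [
    "ProtocolResult",
    "run_cortical_stim_protocol",
    "run_rebound_protocol",
    "run_step_change",
    "rebound_spike_count",
]

#: ISI criterion (ms) terminating a rebound burst
BURST_ISI_MS = 15.0


@dataclass
class ProtocolResult:
    """Efficacy traces and classified outcome of a plasticity protocol."""

    t_ms: np.ndarray
    rho_cs: np.ndarray  # (n_cs, n_t)
    rho_gs: np.ndarray  # (n_gs, n_t)
    ca_seg: np.ndarray  # (3, n_t)
    outcome_cs: str = "none"
    outcome_gs: str = "none"
    spike_t_ms: np.ndarray | None = None
    burst_spike_counts: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)


def _classify(rho: np.ndarray, t: np.ndarray, t_start: float, t_end: float) -> str:
    """Outcome from the population-mean efficacy before/after the protocol.

    Judged against the cubic null trajectory over the elapsed time, i.e.
    relative to how the efficacies would have evolved without any calcium
    threshold crossing (the experimental "control pathway").
    """
    mean = rho.mean(axis=0)
    pre = mean[t <= t_start]
    post = mean[t >= t_end]
    elapsed_s = (np.mean(t[t >= t_end]) - np.mean(t[t <= t_start])) / 1e3
    return classify_outcome(pre, post, elapsed_s=elapsed_s)


def _stim_trains(kind: str, n_gens: int, duration_s: float, rng,
                 window_s: float = 0.3, period_s: float = 5.0,
                 baseline_rate: float = 3.2):
    """Cortical trains for the stimulation protocol.

    ``strong``/``weak``: Poisson at 50/8 Hz inside the stimulation windows
    and at the healthy mean rate outside; ``control``: the healthy cortical
    pause-burst statistics, untouched.
    """
    if kind == "control":
        cfg = replace(afferent_state("healthy")["CTX"], n=n_gens)
        return generate_train(cfg, duration_s, rng)
    rate_in = {"strong": 50.0, "weak": 8.0}[kind]
    trains = []
    for _ in range(n_gens):
        spikes = []
        t0 = 0.0
        while t0 < duration_s:
            # stimulation window
            k = rng.poisson(rate_in * window_s)
            spikes.append(t0 + np.sort(rng.uniform(0.0, window_s, size=k)))
            # inter-window baseline
            gap = min(period_s - window_s, duration_s - t0 - window_s)
            if gap > 0:
                k = rng.poisson(baseline_rate * gap)
                spikes.append(t0 + window_s + np.sort(rng.uniform(0.0, gap, size=k)))
            t0 += period_s
        tr = np.concatenate(spikes)
        trains.append(np.sort(tr[tr < duration_s]))
    return trains


def run_cortical_stim_protocol(kind: str = "strong",
                               model: ModelParams | None = None,
                               seed: int = 0, duration_s: float = 150.0,
                               baseline_s: float = 10.0,
                               n_afferents: int = 10,
                               rho_init: tuple | None = None,
                               stride: int = 640) -> ProtocolResult:
    """Cortically evoked heterosynaptic plasticity on one STN neuron.

    All synaptic currents onto the STN are blocked except CTX->STN NMDA.
    ``kind`` is ``"strong"`` (50-Hz windows), ``"weak"`` (8-Hz windows) or
    ``"control"`` (healthy cortical input).  Initial efficacies are
    (0.33, 0.033) by default and (0.5, 0.05) for the weak protocol, matching
    the depression experiments.
    """
    if kind not in ("strong", "weak", "control"):
        raise ValueError(f"unknown protocol kind {kind!r}")
    model = model if model is not None else default_model()
    if rho_init is None:
        rho_init = (0.5, 0.05) if kind == "weak" else (0.33, 0.033)
    net = single_stn_setup(model, n_cs=n_afferents, n_gs=n_afferents,
                           seed=seed, rho_init=rho_init)
    # block everything except CS NMDA
    net.block_synapses(types=("CS",), ampa=False, nmda=True)
    net.block_synapses(types=("GS",), gaba=False)
    net.run(3000.0, plasticity=False)  # settle the initial transient
    rng = net.rngs["afferents"]
    total_s = baseline_s + duration_s + 5.0
    trains = _stim_trains(kind, n_afferents, duration_s, rng)
    trains = [tr + baseline_s for tr in trains]
    ctx_ev = events_from_trains(trains, net.cfg.dt)
    rows_cs = np.nonzero(net.table.type_code == TYPE_CODES["CS"])[0]
    rows_gs = np.nonzero(net.table.type_code == TYPE_CODES["GS"])[0]
    res = net.run(total_s * 1000.0, ctx_events=ctx_ev,
                  probe_rho=np.concatenate([rows_cs, rows_gs]),
                  probe_ca=[(0, 0), (0, 1), (0, 2)], stride=stride)
    t = res.t_probe_ms - res.t0_ms
    rho_cs = res.rho_probe[:rows_cs.size]
    rho_gs = res.rho_probe[rows_cs.size:]
    out = ProtocolResult(
        t_ms=t, rho_cs=rho_cs, rho_gs=rho_gs, ca_seg=res.ca_probe,
        spike_t_ms=res.spikes_of(0) - res.t0_ms,
        meta={"kind": kind, "seed": seed, "rho_init": rho_init,
              "occ_d_s": res.occ_d[0] * net.cfg.dt / 1e3,
              "occ_p_s": res.occ_p[0] * net.cfg.dt / 1e3})
    t_stim0 = baseline_s * 1000.0
    t_stim1 = (baseline_s + duration_s) * 1000.0
    out.outcome_cs = _classify(rho_cs, t, t_stim0, t_stim1)
    out.outcome_gs = _classify(rho_gs, t, t_stim0, t_stim1)
    return out


def rebound_spike_count(spike_t_ms: np.ndarray, t_release_ms: float,
                        isi_cut_ms: float = BURST_ISI_MS) -> int:
    """Spikes in the rebound burst following a pulse release.

    Counts from the first post-release spike until the first inter-spike
    interval exceeding ``isi_cut_ms`` (tonic firing of the model is slower
    than this cut; intra-burst intervals are faster).
    """
    s = spike_t_ms[spike_t_ms >= t_release_ms]
    if s.size == 0:
        return 0
    k = 1
    for i in range(1, s.size):
        if s[i] - s[i - 1] > isi_cut_ms:
            break
        k += 1
    return k


def run_rebound_protocol(amplitude: float, model: ModelParams | None = None,
                         seed: int = 0, n_pulses: int = 10,
                         period_s: float = 10.0, pulse_ms: float = 500.0,
                         baseline_s: float = 5.0,
                         rho_init: tuple = (0.33, 0.033),
                         stride: int = 640) -> ProtocolResult:
    """Rebound-burst plasticity on an isolated STN neuron.

    ``amplitude`` is the hyperpolarizing pulse current (uA/cm^2, must be
    negative); ``n_pulses`` pulses of ``pulse_ms`` are delivered at
    1/``period_s`` Hz with all synaptic transmission blocked.  Returns the
    per-pulse rebound spike counts alongside the efficacy outcome.
    """
    if amplitude >= 0:
        raise ValueError("rebound pulses must hyperpolarize (amplitude < 0)")
    model = model if model is not None else default_model()
    net = single_stn_setup(model, n_cs=10, n_gs=10, seed=seed,
                           rho_init=rho_init)
    net.block_synapses(types=(), invert=True, ampa=False, nmda=False,
                       gaba=False)  # isolate: block everything
    net.run(3000.0, plasticity=False)  # settle the initial transient
    rows_cs = np.nonzero(net.table.type_code == TYPE_CODES["CS"])[0]
    rows_gs = np.nonzero(net.table.type_code == TYPE_CODES["GS"])[0]
    t_total = (baseline_s + n_pulses * period_s) * 1000.0
    pulses = [(baseline_s * 1000.0 + k * period_s * 1000.0,
               baseline_s * 1000.0 + k * period_s * 1000.0 + pulse_ms,
               amplitude, 0) for k in range(n_pulses)]
    res = net.run(t_total, pulses=pulses,
                  probe_rho=np.concatenate([rows_cs, rows_gs]),
                  probe_ca=[(0, 0), (0, 1), (0, 2)], stride=stride)
    t = res.t_probe_ms - res.t0_ms
    spikes = res.spikes_of(0) - res.t0_ms
    counts = [rebound_spike_count(spikes, p[1]) for p in pulses]
    rho_cs = res.rho_probe[:rows_cs.size]
    rho_gs = res.rho_probe[rows_cs.size:]
    out = ProtocolResult(
        t_ms=t, rho_cs=rho_cs, rho_gs=rho_gs, ca_seg=res.ca_probe,
        spike_t_ms=spikes, burst_spike_counts=counts,
        meta={"amplitude": amplitude, "seed": seed, "rho_init": rho_init,
              "occ_d_s": res.occ_d[0] * net.cfg.dt / 1e3,
              "occ_p_s": res.occ_p[0] * net.cfg.dt / 1e3})
    out.outcome_cs = _classify(rho_cs, t, baseline_s * 1000.0,
                               t_total - period_s * 500.0)
    out.outcome_gs = _classify(rho_gs, t, baseline_s * 1000.0,
                               t_total - period_s * 500.0)
    return out


@dataclass
class StepChangeResult:
    """Recorder output of a step-change experiment."""

    t_rate_s: np.ndarray
    stn_rate_hz: np.ndarray
    gpe_rate_hz: np.ndarray
    t_block_s: np.ndarray
    ca_l_stn: np.ndarray
    ca_l_gpe: np.ndarray
    indegree_t: list
    indegrees: list
    mean_rho: list
    beta_t_s: np.ndarray | None = None
    beta_power_stn: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def run_step_change(pre_state: str, post_state: str,
                    pre_s: float = 30.0, post_s: float = 60.0,
                    cfg: NetworkConfig | None = None,
                    model: ModelParams | None = None, alpha: float | None = None,
                    rate_bin_s: float = 1.0, beta: bool = False,
                    net: Network | None = None) -> StepChangeResult:
    """Step-like switch of afferent activity with full recording.

    Runs ``pre_s`` seconds in ``pre_state``, then switches cortical and iMSN
    generators to ``post_state`` (or the alpha-interpolated state) and
    continues for ``post_s`` seconds.  Desk-scale durations default to tens
    of seconds; the stationary-state experiments of the original protocol
    use hours of simulated time at full scale.
    """
    model = model if model is not None else default_model()
    cfg = cfg if cfg is not None else NetworkConfig(scale_factor=5.0)
    if net is None:
        net = build_network(cfg, model)
    rng = net.rngs["afferents"]

    t_rate, stn_r, gpe_r = [], [], []
    t_blk, cal_s, cal_g = [], [], []
    ind_t, inds, rhos = [], [], []
    beta_chunks = []

    ref = net.indegrees()

    def _run_phase(state_name, dur_s, t_off):
        st = (afferent_state(state_name) if alpha is None or state_name == pre_state
              else afferent_state(state_name, alpha=alpha))
        ctx_cfg = replace(st["CTX"], n=net.n_ctx)
        msn_cfg = replace(st["iMSN"], n=net.n_msn)
        shared = None
        ctx = generate_train(ctx_cfg, dur_s, rng, shared_onsets=shared)
        msn = generate_train(msn_cfg, dur_s, rng)
        res = net.run(dur_s * 1000.0, events_from_trains(ctx, cfg.dt),
                      events_from_trains(msn, cfg.dt), record_ca_l=True)
        sp_t = res.spike_t_ms - res.t0_ms
        is_stn = res.spike_neuron < net.n_stn
        nbin = int(round(dur_s / rate_bin_s))
        for b in range(nbin):
            lo, hi = b * rate_bin_s * 1e3, (b + 1) * rate_bin_s * 1e3
            w = (sp_t >= lo) & (sp_t < hi)
            t_rate.append(t_off + (b + 0.5) * rate_bin_s)
            stn_r.append(np.sum(w & is_stn) / net.n_stn / rate_bin_s)
            gpe_r.append(np.sum(w & ~is_stn) / net.n_gpe / rate_bin_s)
        if res.t_block_ms is not None:
            for tb, cal in zip(res.t_block_ms, res.ca_l_blocks):
                t_blk.append(t_off + (tb - res.t0_ms) / 1e3)
                cal_s.append(cal[:net.n_stn].mean())
                cal_g.append(cal[net.n_stn:].mean())
        ind_t.append(t_off + dur_s)
        inds.append(net.indegrees(reference=ref))
        tab = net.table
        rhos.append({name: float(tab.rho[tab.type_code == code].mean())
                     for name, code in TYPE_CODES.items() if name != "MS"})
        if beta:
            r = population_rate(sp_t[is_stn], net.n_stn, dur_s * 1000.0)
            try:
                beta_chunks.append((t_off + dur_s / 2,
                                    integral_beta(welch_psd(r))))
            except ValueError:
                pass

    _run_phase(pre_state, pre_s, 0.0)
    _run_phase(post_state, post_s, pre_s)

    return StepChangeResult(
        t_rate_s=np.asarray(t_rate), stn_rate_hz=np.asarray(stn_r),
        gpe_rate_hz=np.asarray(gpe_r), t_block_s=np.asarray(t_blk),
        ca_l_stn=np.asarray(cal_s), ca_l_gpe=np.asarray(cal_g),
        indegree_t=ind_t, indegrees=inds, mean_rho=rhos,
        beta_t_s=np.asarray([b[0] for b in beta_chunks]) if beta_chunks else None,
        beta_power_stn=np.asarray([b[1] for b in beta_chunks]) if beta_chunks else None,
        meta={"pre": pre_state, "post": post_state, "alpha": alpha})
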