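"""Three-component transmitter-gating synapses (GABA_A, AMPA, NMDA).

Each transmitter is described by rise, fast and slow gating components driven
by a 1-ms presynaptic release pulse ``f_pre``:

    ds_rise/dt = +Phi (1 - s_fast - s_slow) f_pre - s_rise / tau_rise
    ds_fast/dt =  Phi (nu_fast - s_fast)    f_pre - s_fast / tau_fast
    ds_slow/dt =  Phi (nu_slow - s_slow)    f_pre - s_slow / tau_slow

and the synaptic current is ``-g (s_rise + s_fast + s_slow) (V - E_rev)``.
NMDA receptors split into a nonspecific cationic pathway and a calcium
pathway, each with its own magnesium-block factor and reversal; the
nonspecific NMDA conductance is tied to the AMPA conductance by
``g_NMDA,syn = 1.7 g_AMPA`` so that the NMDA:AMPA peak-current ratio measured
under depolarized/hyperpolarized holding potentials is 0.25.

The fast conductances (AMPA, GABA_A) are linear in the synapse efficacy
``rho`` between per-type bounds ``w_min`` and ``w_max``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TransmitterParams",
    "SynapseInstance",
    "SYNAPSE_TYPES",
    "EXCITATORY_TYPES",
    "INHIBITORY_TYPES",
    "gating_step",
    "mg_block",
    "synaptic_current",
    "conductance_from_efficacy",
    "register_spike",
    "measure_nmda_ampa_ratio",
]

#: synapse-type labels: cortex->STN, GPe->STN, STN->GPe, GPe->GPe, iMSN->GPe
SYNAPSE_TYPES = ("CS", "GS", "SG", "GG", "MS")
EXCITATORY_TYPES = ("CS", "SG")
INHIBITORY_TYPES = ("GS", "GG", "MS")

#: duration of the presynaptic release pulse (ms)
RELEASE_PULSE_MS = 1.0

#: ratio of nonspecific NMDA conductance to AMPA conductance
G_NMDA_SYN_OVER_AMPA = 1.7


@dataclass(frozen=True)
class TransmitterParams:
    """Kinetics and reversal(s) of one transmitter type."""

    transmitter: str  # "GABAa" | "AMPA" | "NMDA"
    phi: float  # activation rate during release (1/ms)
    nu_fast: float
    nu_slow: float
    tau_rise: float
    tau_fast: float
    tau_slow: float
    E_rev: float = 0.0  # mV; for NMDA this is the nonspecific-pathway reversal
    E_rev_ca: float = 90.0  # mV; NMDA calcium-pathway reversal (unused otherwise)

    def __post_init__(self) -> None:
        if self.transmitter not in ("GABAa", "AMPA", "NMDA"):
            raise ValueError(f"unknown transmitter {self.transmitter!r}")
        if min(self.tau_rise, self.tau_fast, self.tau_slow) <= 0:
            raise ValueError("gating time constants must be positive")
        if self.nu_fast + self.nu_slow > 1.0 + 1e-12:
            raise ValueError("nu_fast + nu_slow must not exceed 1")


# Receptor-typical default kinetics (table-S4 stand-ins; phi of NMDA is
# calibrated against the 0.25 NMDA:AMPA ratio constraint, see docs/methods.md).
def default_transmitters() -> dict:
    return {
        "AMPA": TransmitterParams("AMPA", phi=2.0, nu_fast=0.8, nu_slow=0.2,
                                  tau_rise=0.6, tau_fast=2.0, tau_slow=8.0,
                                  E_rev=0.0),
        "NMDA": TransmitterParams("NMDA", phi=0.20882, nu_fast=0.6, nu_slow=0.4,
                                  tau_rise=4.0, tau_fast=60.0, tau_slow=250.0,
                                  E_rev=0.0, E_rev_ca=90.0),
        "GABAa": TransmitterParams("GABAa", phi=2.0, nu_fast=0.8, nu_slow=0.2,
                                   tau_rise=0.6, tau_fast=6.0, tau_slow=25.0,
                                   E_rev=-80.0),
    }


@dataclass
class SynapseInstance:
    """One synapse: endpoints, segment, efficacy and gating state.

    Excitatory synapses (CS, SG) carry AMPA and NMDA receptors; inhibitory
    synapses (GS, GG, MS) carry GABA_A receptors.  ``gating`` maps transmitter
    name to the (rise, fast, slow) component array.  ``fpre_until`` is the
    simulation time (ms) until which the release pulse is active.
    """

    pre: int
    post: int
    segment: int
    syn_type: str
    rho: float = 0.33
    w_min: float = 0.0
    w_max: float = 0.0
    fpre_until: float = -np.inf
    gating: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.syn_type not in SYNAPSE_TYPES:
            raise ValueError(f"unknown synapse type {self.syn_type!r}")
        if self.segment not in range(3):
            raise ValueError("segment must be 0, 1 or 2")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must lie in [0, 1]")
        if not self.gating:
            names = ("AMPA", "NMDA") if self.excitatory else ("GABAa",)
            self.gating = {n: np.zeros(3) for n in names}

    @property
    def excitatory(self) -> bool:
        return self.syn_type in EXCITATORY_TYPES

    @property
    def plastic(self) -> bool:
        return self.syn_type != "MS"

    def fpre(self, t: float) -> float:
        return 1.0 if t < self.fpre_until else 0.0


def register_spike(syn: SynapseInstance, t: float) -> None:
    """Presynaptic spike at time ``t``: (re)trigger the 1-ms release pulse.

    A spike landing inside an active pulse extends it (``fpre_until`` is the
    max of old and new expiry).
    """
    syn.fpre_until = max(syn.fpre_until, t + RELEASE_PULSE_MS)


def gating_step(syn: SynapseInstance, t: float, dt: float, params: dict) -> None:
    """Forward-Euler update of all gating components of ``syn`` over [t, t+dt).

    ``params`` maps transmitter name to :class:`TransmitterParams`.
    """
    f = syn.fpre(t)
    for name, s in syn.gating.items():
        p = params[name]
        rise, fast, slow = s
        d_rise = p.phi * (1.0 - fast - slow) * f - rise / p.tau_rise
        d_fast = p.phi * (p.nu_fast - fast) * f - fast / p.tau_fast
        d_slow = p.phi * (p.nu_slow - slow) * f - slow / p.tau_slow
        s[0] = rise + dt * d_rise
        s[1] = fast + dt * d_fast
        s[2] = slow + dt * d_slow


def mg_block(V, pathway: str):
    """Voltage-dependent magnesium-block removal factor of NMDA receptors.

    ``pathway`` is "Ca" (calcium component, steeper voltage dependence) or
    "syn" (nonspecific cationic component).
    """
    V = np.asarray(V, dtype=float)
    if pathway == "Ca":
        return 1.0 / (1.0 + 0.6 * np.exp(-0.124 * V))
    if pathway == "syn":
        return 1.0 / (1.0 + 0.6 * np.exp(-0.062 * V))
    raise ValueError("pathway must be 'Ca' or 'syn'")


def conductance_from_efficacy(rho, w_min, w_max):
    """Linear efficacy-to-conductance map ``g = w_min + (w_max - w_min) rho``."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0.0) or np.any(rho > 1.0):
        raise ValueError("rho must lie in [0, 1]")
    if np.any(np.asarray(w_min) > np.asarray(w_max)):
        raise ValueError("w_min must not exceed w_max")
    return w_min + (w_max - w_min) * rho


def synaptic_current(syn: SynapseInstance, V_post: float, params: dict,
                     g_nmda_ca_frac: float = 0.1) -> dict:
    """Per-pathway synaptic currents (inward-positive convention).

    Returns a dict with keys ``GABAa`` or ``AMPA``/``NMDA_syn``/``NMDA_Ca``.
    GABA_A/AMPA: ``-g (sum s) (V - E_rev)``; each NMDA pathway additionally
    carries its magnesium-block factor.  ``g_NMDA,syn = 1.7 g_AMPA`` and the
    calcium-pathway conductance is ``g_nmda_ca_frac * g_NMDA,syn``.
    """
    g_fast = conductance_from_efficacy(syn.rho, syn.w_min, syn.w_max)
    out = {}
    if syn.excitatory:
        s_ampa = float(np.sum(syn.gating["AMPA"]))
        s_nmda = float(np.sum(syn.gating["NMDA"]))
        pa = params["AMPA"]
        pn = params["NMDA"]
        g_nsyn = G_NMDA_SYN_OVER_AMPA * g_fast
        g_nca = g_nmda_ca_frac * g_nsyn
        out["AMPA"] = -g_fast * s_ampa * (V_post - pa.E_rev)
        out["NMDA_syn"] = -g_nsyn * float(mg_block(V_post, "syn")) * s_nmda * (V_post - pn.E_rev)
        out["NMDA_Ca"] = -g_nca * float(mg_block(V_post, "Ca")) * s_nmda * (V_post - pn.E_rev_ca)
    else:
        pg = params["GABAa"]
        s_gaba = float(np.sum(syn.gating["GABAa"]))
        out["GABAa"] = -g_fast * s_gaba * (V_post - pg.E_rev)
    return out


def measure_nmda_ampa_ratio(params: dict | None = None,
                            v_nmda: float = 40.0, v_ampa: float = -80.0,
                            g_ampa: float = 1.0, dt: float = 0.03125,
                            t_max: float = 600.0) -> float:
    """NMDA:AMPA peak-current ratio under the voltage-clamp convention.

    A single presynaptic spike is delivered to a voltage-clamped compartment;
    the NMDA nonspecific-current peak is measured at the depolarized holding
    potential ``v_nmda`` (+40 mV) and the AMPA peak at the hyperpolarized
    ``v_ampa`` (-80 mV).  Returns |peak NMDA| / |peak AMPA|.
    """
    if params is None:
        params = default_transmitters()
    syn = SynapseInstance(pre=0, post=0, segment=0, syn_type="CS",
                          rho=1.0, w_min=g_ampa, w_max=g_ampa)
    register_spike(syn, 0.0)
    n = int(round(t_max / dt))
    peak_ampa = 0.0
    peak_nmda = 0.0
    for i in range(n):
        t = i * dt
        cur_a = synaptic_current(syn, v_ampa, params)
        cur_n = synaptic_current(syn, v_nmda, params)
        peak_ampa = max(peak_ampa, abs(cur_a["AMPA"]))
        peak_nmda = max(peak_nmda, abs(cur_n["NMDA_syn"]))
        gating_step(syn, t, dt, params)
    return peak_nmda / peak_ampa
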