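"""Conductance-based STN and GPe point-neuron models.

Both populations are single-compartment Hodgkin-Huxley-type neurons of the
Otsuka subthalamic family.  STN neurons carry seven ionic currents (Na, Kv3,
T-type Ca, Ca-activated K, A-type K, L-type Ca, leak); the prototypic GPe
variant omits the A- and L-type currents.  Gating variables relax toward a
logistic steady state with voltage- (or, for the ``d2`` and ``r`` gates,
somatic-calcium-) dependent time constants.

Somatic calcium is driven by the T- and L-type channel currents plus the
calcium component of all NMDA receptor currents on the neuron; three isolated
dendritic segments carry their own calcium pools that see the same
voltage-gated calcium currents but only the NMDA currents of synapses
assigned to that segment.

Units: membrane potential in mV, time in ms, currents in uA/cm^2,
conductances in mS/cm^2, calcium concentrations in uM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GATE_NAMES",
    "CA_DRIVEN_GATES",
    "GatingSpec",
    "NeuronParams",
    "NeuronState",
    "steady_state",
    "time_constant",
    "nernst_potential",
    "ionic_currents",
    "total_ionic_current",
    "calcium_derivatives",
    "N_SEGMENTS",
]

#: number of isolated dendritic segments per neuron
N_SEGMENTS = 3

#: canonical gate ordering used by all array-based state layouts
GATE_NAMES = ("m", "h", "n", "p", "q", "a", "b", "c", "d1", "d2", "r")

#: gates whose driver is the somatic calcium concentration, not voltage
CA_DRIVEN_GATES = ("d2", "r")

# physical constants (SI)
GAS_CONSTANT = 8.314462618  # J / (mol K)
FARADAY = 96485.33212  # C / mol
CA_VALENCE = 2


@dataclass(frozen=True)
class GatingSpec:
    """Kinetic description of one gating variable.

    The steady state is ``x_inf(M) = 1 / (1 + exp((M + theta) / k))`` where
    the driver ``M`` is the membrane potential (mV) for voltage-driven gates
    and the somatic calcium concentration (uM) for ``d2`` and ``r``.

    ``tau_class`` selects the timescale curve:

    * ``"fast"``:  ``tau = tau0 + tau1 / (1 + exp(-(M + theta1) / sigma1))``
    * ``"slow"``:  ``tau = tau0 + tau1 / (exp((M + theta1) / sigma1)
      + exp((M + theta2) / sigma2))``

    A constant timescale is a "fast" spec with ``tau1 = 0``.
    """

    name: str
    theta: float
    k: float
    tau_class: str  # "fast" | "slow"
    tau0: float
    tau1: float = 0.0
    theta1: float = 0.0
    sigma1: float = 1.0
    theta2: float = 0.0
    sigma2: float = 1.0
    driver: str = "voltage"  # "voltage" | "calcium"

    def __post_init__(self) -> None:
        if self.name not in GATE_NAMES:
            raise ValueError(f"unknown gate name {self.name!r}")
        if self.tau_class not in ("fast", "slow"):
            raise ValueError(f"tau_class must be 'fast' or 'slow', got {self.tau_class!r}")
        if self.tau0 < 0 or self.tau1 < 0:
            raise ValueError("tau0 and tau1 must be non-negative")
        want_ca = self.name in CA_DRIVEN_GATES
        if (self.driver == "calcium") != want_ca:
            raise ValueError(
                f"gate {self.name!r}: driver must be 'calcium' exactly for gates "
                f"{CA_DRIVEN_GATES}, 'voltage' otherwise"
            )


def steady_state(spec: GatingSpec, M):
    """Logistic steady-state (in)activation of a gate at driver value ``M``.

    Strictly monotone in ``M`` and bounded in (0, 1); the sign of ``spec.k``
    decides whether the gate activates (k < 0) or inactivates (k > 0) with
    increasing driver.
    """
    return 1.0 / (1.0 + np.exp((M + spec.theta) / spec.k))


def time_constant(spec: GatingSpec, M):
    """Gate relaxation time constant (ms) at driver value ``M``."""
    if spec.tau_class == "fast":
        tau = spec.tau0 + spec.tau1 / (1.0 + np.exp(-(M + spec.theta1) / spec.sigma1))
    else:
        tau = spec.tau0 + spec.tau1 / (
            np.exp((M + spec.theta1) / spec.sigma1)
            + np.exp((M + spec.theta2) / spec.sigma2)
        )
    if np.any(np.asarray(tau) <= 0.0):
        raise ValueError(f"non-positive time constant for gate {spec.name!r}; bad parameters")
    return tau


# --- default gating kinetics -------------------------------------------------
# Source-model (Otsuka-type STN) kinetics, converted to the x_inf convention
# above (theta = -theta_half, k = -slope of the source form).

def _stn_gating() -> tuple[GatingSpec, ...]:
    return (
        GatingSpec("m", 40.0, -8.0, "fast", 0.2, 3.0, 53.0, -0.7),
        GatingSpec("h", 45.5, 6.4, "slow", 0.0, 24.5, 50.0, -15.0, 50.0, 16.0),
        GatingSpec("n", 41.0, -14.0, "slow", 0.0, 11.0, 40.0, -40.0, 40.0, 50.0),
        GatingSpec("p", 56.0, -6.7, "slow", 5.0, 0.33, 27.0, -10.0, 102.0, 15.0),
        GatingSpec("q", 85.0, 5.8, "slow", 0.0, 400.0, 50.0, -15.0, 50.0, 16.0),
        GatingSpec("a", 45.0, -14.7, "fast", 1.0, 1.0, 40.0, -0.5),
        GatingSpec("b", 90.0, 7.5, "slow", 0.0, 200.0, 60.0, -30.0, 40.0, 10.0),
        GatingSpec("c", 30.6, -5.0, "slow", 45.0, 10.0, 27.0, -20.0, 50.0, 15.0),
        GatingSpec("d1", 60.0, 7.5, "slow", 400.0, 500.0, 40.0, -15.0, 20.0, 20.0),
        GatingSpec("d2", -0.1, 0.02, "fast", 130.0, 0.0, driver="calcium"),
        GatingSpec("r", -0.17, -0.08, "fast", 2.0, 0.0, driver="calcium"),
    )


def _gpe_gating() -> tuple[GatingSpec, ...]:
    # Prototypic GPe: same channel family, same kinetic forms; the A- and
    # L-type gates are carried for layout uniformity but their conductances
    # are zero for GPe neurons.
    return _stn_gating()


# channel table: (name, conductance key, gate powers, reversal)
# reversal is one of "Na", "K", "Ca" (Nernst), "leak"
STN_CHANNELS = (
    ("Na", "g_Na", (("m", 3), ("h", 1)), "Na"),
    ("K", "g_K", (("n", 4),), "K"),
    ("T", "g_T", (("p", 2), ("q", 1)), "Ca"),
    ("Ca-K", "g_CaK", (("r", 2),), "K"),
    ("A", "g_A", (("a", 2), ("b", 1)), "K"),
    ("L", "g_L", (("c", 2), ("d1", 1), ("d2", 1)), "Ca"),
    ("leak", "g_leak", (), "leak"),
)

GPE_CHANNELS = tuple(ch for ch in STN_CHANNELS if ch[0] not in ("A", "L"))


@dataclass
class NeuronParams:
    """Biophysical parameters of one population (STN or GPe).

    Conductances in mS/cm^2, capacitance in uF/cm^2, bias current in uA/cm^2.
    ``k_conv`` converts an outward-positive calcium current (uA/cm^2) into a
    concentration rate (uM/ms); it absorbs the 1/(Z F) factor together with
    the (unprinted) effective volume-to-area ratio of the calcium pool and is
    treated as a single calibration constant.
    """

    population: str  # "STN" | "GPe"
    C: float = 1.0
    g_Na: float = 49.0
    g_K: float = 57.0
    g_T: float = 5.0
    g_CaK: float = 1.0
    g_A: float = 5.0
    g_L: float = 15.0
    g_leak: float = 0.35
    E_Na: float = 40.0
    E_K: float = -90.0
    E_leak: float = -60.0
    I_bias: float = 0.0
    ca_out: float = 2.0  # uM, as printed (physiological would be ~2 mM)
    temperature: float = 303.15  # K
    k_ca: float = 2.0  # ms^-1 calcium removal rate
    k_conv: float = 5.182e-3  # uM cm^2 / (ms uA)
    ca_floor: float = 1e-12  # uM floor before the Nernst log
    gating: tuple[GatingSpec, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.population not in ("STN", "GPe"):
            raise ValueError("population must be 'STN' or 'GPe'")
        if not self.gating:
            self.gating = _stn_gating() if self.population == "STN" else _gpe_gating()
        for key in ("g_Na", "g_K", "g_T", "g_CaK", "g_A", "g_L", "g_leak"):
            if getattr(self, key) < 0:
                raise ValueError(f"{key} must be non-negative")
        if self.population == "GPe" and (self.g_A != 0.0 or self.g_L != 0.0):
            raise ValueError("GPe neurons carry no A- or L-type currents")

    @property
    def channels(self):
        return STN_CHANNELS if self.population == "STN" else GPE_CHANNELS

    def gate_spec(self, name: str) -> GatingSpec:
        for g in self.gating:
            if g.name == name:
                return g
        raise KeyError(name)


@dataclass
class NeuronState:
    """Dynamic state of a single neuron."""

    V: float
    gates: dict
    ca_soma: float = 0.005
    ca_seg: np.ndarray = field(default_factory=lambda: np.full(N_SEGMENTS, 0.005))
    ca_L: float = 0.005

    def __post_init__(self) -> None:
        self.ca_seg = np.asarray(self.ca_seg, dtype=float)
        for name, x in self.gates.items():
            if not (0.0 <= x <= 1.0):
                raise ValueError(f"gate {name} out of [0,1]: {x}")
        if self.ca_soma < 0 or np.any(self.ca_seg < 0) or self.ca_L < 0:
            raise ValueError("calcium concentrations must be non-negative")

    @classmethod
    def resting(cls, params: NeuronParams, V: float = -60.0, ca: float = 0.005):
        gates = {
            g.name: float(steady_state(g, V if g.driver == "voltage" else ca))
            for g in params.gating
        }
        return cls(V=V, gates=gates, ca_soma=ca, ca_seg=np.full(N_SEGMENTS, ca), ca_L=ca)


def nernst_potential(ca_in, params: NeuronParams | None = None):
    """Calcium reversal potential (mV) from the Nernst equation.

    ``E_Ca = (R T / Z F) ln(ca_out / ca_in)`` with T = 303.15 K, Z = 2 and
    ca_out = 2 uM by default.  ``ca_in`` is floored at ``params.ca_floor``
    to avoid the logarithmic singularity at zero.
    """
    if params is None:
        params = NeuronParams("STN")
    ca = np.maximum(np.asarray(ca_in, dtype=float), params.ca_floor)
    scale = GAS_CONSTANT * params.temperature / (CA_VALENCE * FARADAY) * 1e3  # mV
    return scale * np.log(params.ca_out / ca)


def ionic_currents(state: NeuronState, params: NeuronParams) -> dict:
    """Per-channel ionic currents (uA/cm^2), outward-positive.

    Calcium-channel currents use the Nernst reversal evaluated at the somatic
    calcium concentration.
    """
    e_ca = float(nernst_potential(state.ca_soma, params))
    rev = {"Na": params.E_Na, "K": params.E_K, "Ca": e_ca, "leak": params.E_leak}
    out = {}
    for name, gkey, gate_pow, rkey in params.channels:
        g = getattr(params, gkey)
        act = 1.0
        for gname, p in gate_pow:
            act *= state.gates[gname] ** p
        out[name] = g * act * (state.V - rev[rkey])
    return out


def total_ionic_current(state: NeuronState, params: NeuronParams) -> float:
    return float(sum(ionic_currents(state, params).values()))


def calcium_derivatives(state: NeuronState, nmda_ca_per_segment, params: NeuronParams):
    """Time derivatives of somatic and segmental calcium (uM/ms).

    ``nmda_ca_per_segment`` is the outward-positive summed NMDA calcium
    current (uA/cm^2) of the synapses assigned to each of the three segments.
    The somatic pool sees the total over segments; every pool sees the full
    T- and L-type currents.  dCa/dt = -k_conv * I_Ca_total - k_ca * Ca.
    """
    nmda = np.asarray(nmda_ca_per_segment, dtype=float)
    if nmda.shape != (N_SEGMENTS,):
        raise ValueError(f"expected {N_SEGMENTS} per-segment NMDA currents")
    cur = ionic_currents(state, params)
    i_cav = cur["T"] + cur.get("L", 0.0)
    d_soma = -params.k_conv * (i_cav + nmda.sum()) - params.k_ca * state.ca_soma
    d_seg = -params.k_conv * (i_cav + nmda) - params.k_ca * state.ca_seg
    return d_soma, d_seg
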