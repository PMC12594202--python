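"""Homeostatic structural plasticity (calcium-based element bookkeeping).

Each neuron owns continuous counts of available excitatory and inhibitory
dendritic elements, ``z_exc`` and ``z_inh``, which grow or shrink linearly
with the deviation of the low-pass-filtered somatic calcium ``Ca_L`` from a
per-population target ``Ca*``:

    tau_z dz_exc/dt = 1 - Ca_L / Ca*
    tau_z dz_inh/dt = -1 + Ca_L / Ca*

Axonal elements are static at 200 per neuron and polarity, so formation is
limited by the dendritic side only.  Every 200 ms of simulated time, each
vacant dendritic element (``floor(z - bound)``) forms a synapse with
probability 0.1, pairing with a random presynaptic partner of the
type-appropriate population; when ``floor(z)`` falls below the bound count,
randomly chosen synapses of that polarity are removed.  iMSN->GPe synapses
live outside this bookkeeping entirely (fixed edge set).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import TYPE_CODES, SynapseTable

__all__ = [
    "StructuralParams",
    "ElementState",
    "lowpass_step",
    "element_derivatives",
    "connectivity_update",
    "UPDATE_INTERVAL_MS",
    "AXONAL_ELEMENTS",
]

#: cadence of connectivity updates (ms of simulated time)
UPDATE_INTERVAL_MS = 200.0
#: static axonal element count per neuron and polarity
AXONAL_ELEMENTS = 200
#: per-element synapse formation probability per update
FORMATION_PROB = 0.1


@dataclass(frozen=True)
class StructuralParams:
    """Targets and time constants of the homeostatic rule.

    ``tau_z`` defaults to 1800 s (the model-fitting value); the alternative
    printed value of 3600 s can be configured.  ``tau_ca_l`` is the low-pass
    filter time constant for somatic calcium.  Times in ms, calcium in uM.
    """

    tau_ca_l: float = 10_000.0  # ms (10 s)
    tau_z: float = 1_800_000.0  # ms (1800 s)
    ca_target_stn: float = 0.0036
    ca_target_gpe: float = 0.0018
    formation_prob: float = FORMATION_PROB
    rho_init_mean: float = 0.33
    rho_init_sd: float = 0.033

    def ca_target(self, population: str) -> float:
        if population == "STN":
            return self.ca_target_stn
        if population == "GPe":
            return self.ca_target_gpe
        raise ValueError(population)


@dataclass
class ElementState:
    """Per-neuron dendritic element state for one network.

    ``z_exc``/``z_inh`` are continuous available counts; bound counts are
    derived from the synapse table on demand.  ``pop`` is 0 for STN, 1 for
    GPe (indexing the per-population calcium targets).
    """

    z_exc: np.ndarray
    z_inh: np.ndarray
    pop: np.ndarray  # int8, 0=STN 1=GPe

    @classmethod
    def balanced(cls, bound_exc: np.ndarray, bound_inh: np.ndarray,
                 pop: np.ndarray) -> "ElementState":
        """Start with available counts equal to the bound counts (no vacancy)."""
        return cls(z_exc=bound_exc.astype(float).copy(),
                   z_inh=bound_inh.astype(float).copy(),
                   pop=np.asarray(pop, dtype=np.int8))


def lowpass_step(ca_l, ca_soma, dt, tau_ca_l: float = 10_000.0):
    """One Euler step of the 10-s low-pass filter of somatic calcium."""
    ca_l = np.asarray(ca_l, dtype=float)
    return ca_l + dt * (np.asarray(ca_soma, dtype=float) - ca_l) / tau_ca_l


def element_derivatives(ca_l, ca_target, tau_z):
    """(dz_exc/dt, dz_inh/dt) in elements/ms; exactly antisymmetric."""
    if np.any(np.asarray(ca_target) <= 0):
        raise ValueError("calcium target must be positive")
    d_exc = (1.0 - np.asarray(ca_l, dtype=float) / ca_target) / tau_z
    return d_exc, -d_exc


def _bound_counts(table: SynapseTable, n_neurons: int):
    """Bound plastic dendritic elements per neuron and polarity."""
    exc = np.bincount(table.post[table.excitatory], minlength=n_neurons)
    inh_mask = (~table.excitatory) & table.plastic
    inh = np.bincount(table.post[inh_mask], minlength=n_neurons)
    return exc, inh


def connectivity_update(table: SynapseTable, elements: ElementState,
                        rng: np.random.Generator, n_stn: int, n_gpe: int,
                        n_ctx: int, params: StructuralParams) -> dict:
    """One 200-ms connectivity update: form and remove synapses in place.

    For each neuron and polarity, each vacant dendritic element forms a new
    synapse with probability ``params.formation_prob``; the presynaptic
    partner is uniform over the type-appropriate source population (GG
    excludes self), the segment uniform over {0,1,2} and the initial efficacy
    drawn from the network's truncated-normal initialization.  When
    ``floor(z) < bound``, synapses of that polarity are removed uniformly at
    random until the bound matches.  Returns formation/removal counts.
    """
    n_neurons = n_stn + n_gpe
    bound_exc, bound_inh = _bound_counts(table, n_neurons)
    new = {"pre": [], "post": [], "seg": [], "type_code": []}
    remove_rows: list[np.ndarray] = []
    n_formed = 0
    n_removed = 0

    for polarity, z_all, bound_all in (
        ("exc", elements.z_exc, bound_exc),
        ("inh", elements.z_inh, bound_inh),
    ):
        vacant = np.floor(z_all - bound_all).astype(np.int64)
        floor_z = np.floor(z_all).astype(np.int64)
        for i in np.nonzero(vacant > 0)[0]:
            k = rng.binomial(int(vacant[i]), params.formation_prob)
            if k == 0:
                continue
            is_stn = elements.pop[i] == 0
            if polarity == "exc":
                tc = TYPE_CODES["CS"] if is_stn else TYPE_CODES["SG"]
                n_src = n_ctx if is_stn else n_stn
                pre = rng.integers(0, n_src, size=k)
            else:
                tc = TYPE_CODES["GS"] if is_stn else TYPE_CODES["GG"]
                pre = rng.integers(0, n_gpe, size=k)
                if not is_stn:  # no GG self-loops
                    self_idx = i - n_stn
                    while np.any(pre == self_idx):
                        pre[pre == self_idx] = rng.integers(0, n_gpe,
                                                            size=int(np.sum(pre == self_idx)))
            new["pre"].extend(pre.tolist())
            new["post"].extend([i] * k)
            new["seg"].extend(rng.integers(0, 3, size=k).tolist())
            new["type_code"].extend([tc] * k)
            n_formed += k
        # removal: floor(z) below the bound count
        deficit = bound_all - floor_z
        for i in np.nonzero(deficit > 0)[0]:
            if polarity == "exc":
                mask = table.excitatory & (table.post == i)
            else:
                mask = (~table.excitatory) & table.plastic & (table.post == i)
            rows = np.nonzero(mask)[0]
            k = min(int(deficit[i]), rows.size)
            if k > 0:
                remove_rows.append(rng.choice(rows, size=k, replace=False))
                n_removed += k

    if remove_rows:
        table.remove(np.concatenate(remove_rows))
    if new["pre"]:
        k = len(new["pre"])
        rho = np.clip(rng.normal(params.rho_init_mean, params.rho_init_sd, size=k),
                      0.0, 1.0)
        table.append(new["pre"], new["post"], new["seg"], new["type_code"], rho)
    return {"formed": int(n_formed), "removed": int(n_removed)}
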