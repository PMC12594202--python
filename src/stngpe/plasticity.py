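"""Calcium-threshold synaptic efficacy dynamics (bistable two-threshold rule).

The efficacy ``rho`` of each plastic synapse follows

    tau_rho drho/dt = -rho (1-rho) (0.5-rho)
                      + gamma_p (1-rho) H(ca - theta_p)
                      - gamma_d rho     H(ca - theta_d)
                      + sigma sqrt(tau_rho) H(ca - theta_d) xi(t)

where ``ca`` is the calcium concentration of the postsynaptic dendritic
segment the synapse sits on, ``H`` the Heaviside function (H(0) = 1) and
``xi`` zero-mean unit white noise.  Without calcium the cubic term makes
rho = 0 and rho = 1 stable and rho = 0.5 unstable.  Potentiation and
depression thresholds are shared between excitatory and inhibitory synapses
on the same neuron (one pair per population), which makes plasticity
heterosynaptic: all synapses on a segment see the same calcium transient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PlasticityParams",
    "efficacy_drift",
    "efficacy_step",
    "classify_outcome",
]


@dataclass(frozen=True)
class PlasticityParams:
    """Parameters of the two-threshold calcium plasticity rule.

    Thresholds are per postsynaptic population (uM); rates are shared across
    synapse types.  ``tau_rho`` is in ms to match the integrator time base.
    """

    tau_rho: float = 30_000.0  # ms (30 s)
    gamma_p: float = 250.0
    gamma_d: float = 25.0
    sigma: float = 0.2
    theta_d_stn: float = 0.022
    theta_p_stn: float = 0.045
    theta_d_gpe: float = 0.015
    theta_p_gpe: float = 0.030

    def __post_init__(self) -> None:
        if not (self.theta_p_stn > self.theta_d_stn > 0):
            raise ValueError("require theta_p > theta_d > 0 for STN")
        if not (self.theta_p_gpe > self.theta_d_gpe > 0):
            raise ValueError("require theta_p > theta_d > 0 for GPe")
        if min(self.gamma_p, self.gamma_d, self.sigma) < 0:
            raise ValueError("gamma_p, gamma_d, sigma must be non-negative")

    def thresholds(self, population: str) -> tuple[float, float]:
        """(theta_d, theta_p) for a postsynaptic population."""
        if population == "STN":
            return self.theta_d_stn, self.theta_p_stn
        if population == "GPe":
            return self.theta_d_gpe, self.theta_p_gpe
        raise ValueError(population)


def _heaviside(x):
    # H(0) = 1 by convention (measure-zero event, fixed for reproducibility)
    return np.where(np.asarray(x, dtype=float) >= 0.0, 1.0, 0.0)


def efficacy_drift(rho, ca_seg, p: PlasticityParams, population: str = "STN"):
    """Deterministic part of drho/dt (1/ms) at segment calcium ``ca_seg``."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0.0) or np.any(rho > 1.0):
        raise ValueError("rho must lie in [0, 1]")
    theta_d, theta_p = p.thresholds(population)
    cubic = -rho * (1.0 - rho) * (0.5 - rho)
    pot = p.gamma_p * (1.0 - rho) * _heaviside(np.asarray(ca_seg) - theta_p)
    dep = -p.gamma_d * rho * _heaviside(np.asarray(ca_seg) - theta_d)
    return (cubic + pot + dep) / p.tau_rho


def efficacy_step(rho, ca_seg, dt, rng: np.random.Generator,
                  p: PlasticityParams, population: str = "STN"):
    """One Euler-Maruyama step of the efficacy SDE; result clipped to [0, 1].

    Noise (std ``sigma * sqrt(dt / tau_rho)`` per step) is injected only while
    the segment calcium is at or above the depression threshold.
    """
    rho = np.asarray(rho, dtype=float)
    theta_d, _ = p.thresholds(population)
    drift = efficacy_drift(rho, ca_seg, p, population)
    gate = _heaviside(np.asarray(ca_seg) - theta_d)
    out = rho + dt * drift
    if p.sigma > 0.0:
        noise = rng.standard_normal(size=np.shape(rho))
        out = out + p.sigma * np.sqrt(dt / p.tau_rho) * gate * noise
    return np.clip(out, 0.0, 1.0)


def cubic_null_trajectory(rho0: float, elapsed_s: float,
                          tau_rho_s: float = 30.0) -> float:
    """Efficacy after ``elapsed_s`` under the calcium-free cubic dynamics.

    Integrates ``tau_rho drho/dt = -rho (1-rho) (0.5-rho)`` from ``rho0``;
    this is the null trajectory of a synapse whose calcium never crosses the
    depression threshold (the attractor dynamics slowly pull any efficacy
    away from the unstable point at 0.5).
    """
    if elapsed_s < 0:
        raise ValueError("windows overlap (negative elapsed time)")
    rho = float(rho0)
    dt = min(1.0, tau_rho_s / 30.0)
    t = 0.0
    while t < elapsed_s:
        h = min(dt, elapsed_s - t)
        rho += h * (-rho * (1.0 - rho) * (0.5 - rho)) / tau_rho_s
        t += h
    return min(max(rho, 0.0), 1.0)


def classify_outcome(rho_pre, rho_post, baseline_sd: float | None = None,
                     tol_factor: float = 2.0, band_floor: float = 0.05,
                     elapsed_s: float | None = None,
                     tau_rho_s: float = 30.0) -> str:
    """Classify a protocol outcome as ``"none"``, ``"LTD"`` or ``"LTP"``.

    Compares the mean efficacy of the post-protocol window against the
    expected calcium-free evolution of the baseline mean (the cubic null
    trajectory over ``elapsed_s``; the plain baseline mean if ``elapsed_s``
    is None).  A change beyond ``tol_factor`` times the pooled baseline
    standard deviation (floored at ``band_floor`` for near-deterministic
    baselines) counts as plasticity.
    """
    pre = np.asarray(rho_pre, dtype=float)
    post = np.asarray(rho_post, dtype=float)
    if pre.size == 0 or post.size == 0:
        raise ValueError("empty window")
    sd = float(np.std(pre)) if baseline_sd is None else float(baseline_sd)
    band = max(tol_factor * sd, band_floor)
    expected = float(np.mean(pre))
    if elapsed_s is not None:
        expected = cubic_null_trajectory(expected, elapsed_s, tau_rho_s)
    delta = float(np.mean(post)) - expected
    if delta > band:
        return "LTP"
    if delta < -band:
        return "LTD"
    return "none"
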