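"""Poisson and pause-burst spike generators for cortical and iMSN afferents.

Each afferent population is a set of independent spike generators.  A
fraction ``P_b`` of them cycle through three phases: a burst (Poisson count
``n_b ~ Poisson(f_b d_b)`` of spikes with Exponential(1/f_b) intervals from
the burst onset), an inter-burst spiking phase at the compensating rate
``f_s`` lasting until ``d_p`` before the next onset, and a silent pause.
Burst-onset intervals are Normal(d_ob, 0.1 s), truncated so cycles do not
overlap.  The compensating rate

    f_s = (f_bar d_ob - f_b d_b) / (d_ob - d_b - d_p)

makes the long-run mean rate of every generator equal ``f_bar``.  The
remaining generators are homogeneous Poisson at ``f_bar``.

Three named activity states are provided (healthy, hyperactive iMSNs,
PD bursting) plus a linear interpolation ``x(alpha)`` between the two
parkinsonian states.  In the PD-burst state all bursting generators (CTX and
iMSN) share one burst-onset clock, producing in-phase low-frequency bursts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "AfferentConfig",
    "STATE_TABLE",
    "inter_burst_rate",
    "generate_train",
    "interpolate_state",
    "afferent_state",
    "mean_rate",
]

#: SD of the burst-onset interval distribution (s)
ONSET_SD_S = 0.1


@dataclass(frozen=True)
class AfferentConfig:
    """Pause-burst statistics of one afferent population.

    Rates in Hz, durations in seconds.  ``d_ob = 1/F_B`` is the mean
    inter-burst-onset interval.  ``correlated`` marks populations whose
    bursting generators share a single onset clock.
    """

    population: str  # "CTX" | "iMSN"
    n: int
    f_bar: float
    P_b: float
    F_B: float
    d_b: float
    d_p: float
    f_b: float
    correlated: bool = False
    onset_jitter: float = 0.0  # per-generator onset jitter SD (s)
    clamp_fs: bool = False  # floor the compensating rate at zero

    def __post_init__(self) -> None:
        if not (0.0 <= self.P_b <= 1.0):
            raise ValueError("P_b must lie in [0, 1]")
        if self.P_b > 0.0:
            if self.F_B <= 0.0:
                raise ValueError("bursting config requires F_B > 0")
            if self.d_ob <= self.d_b + self.d_p:
                raise ValueError("require d_ob > d_b + d_p")
            if (not self.clamp_fs
                    and self.f_bar * self.d_ob < self.f_b * self.d_b):
                raise ValueError("burst alone exceeds the target mean rate")

    @property
    def d_ob(self) -> float:
        return 1.0 / self.F_B if self.F_B > 0 else np.inf


# Activity states: (CTX, iMSN) parameter rows.
STATE_TABLE: dict[str, dict[str, AfferentConfig]] = {
    "healthy": {
        "CTX": AfferentConfig("CTX", 2500, f_bar=3.2, P_b=0.2, F_B=0.2,
                              d_b=0.2, d_p=0.0, f_b=50.0),
        "iMSN": AfferentConfig("iMSN", 7500, f_bar=2.1, P_b=0.7, F_B=0.22,
                               d_b=0.34, d_p=0.0, f_b=20.0),
    },
    "hyperactive_imsn": {
        "CTX": AfferentConfig("CTX", 2500, f_bar=3.2, P_b=0.2, F_B=0.2,
                              d_b=0.2, d_p=0.0, f_b=50.0),
        "iMSN": AfferentConfig("iMSN", 7500, f_bar=10.0, P_b=0.0, F_B=0.0,
                               d_b=0.0, d_p=0.0, f_b=0.0),
    },
    "pd_burst": {
        "CTX": AfferentConfig("CTX", 2500, f_bar=3.2, P_b=1.0, F_B=0.5,
                              d_b=0.5, d_p=0.6, f_b=10.0, correlated=True),
        "iMSN": AfferentConfig("iMSN", 7500, f_bar=10.0, P_b=1.0, F_B=0.5,
                               d_b=0.26, d_p=0.6, f_b=34.0, correlated=True),
    },
}


def inter_burst_rate(cfg: AfferentConfig) -> float:
    """Compensating spiking-phase rate f_s (Hz) for a bursting generator.

    Interpolated states (``clamp_fs``) may pass through parameter mixes whose
    burst budget alone exceeds the target mean rate; their compensating rate
    is floored at zero (the mean rate then slightly exceeds f_bar).
    """
    denom = cfg.d_ob - cfg.d_b - cfg.d_p
    if denom <= 0:
        raise ValueError("d_ob - d_b - d_p must be positive")
    num = cfg.f_bar * cfg.d_ob - cfg.f_b * cfg.d_b
    if num < 0:
        if cfg.clamp_fs:
            return 0.0
        raise ValueError("burst alone exceeds the target mean rate")
    return num / denom


def _onset_times(T: float, cfg: AfferentConfig, rng: np.random.Generator) -> np.ndarray:
    """Burst-onset sequence over [0, T] seconds for one onset clock."""
    lo = cfg.d_b + cfg.d_p  # truncation: non-overlapping burst cycles
    onsets = [rng.uniform(0.0, cfg.d_ob)]
    while onsets[-1] < T:
        gap = rng.normal(cfg.d_ob, ONSET_SD_S)
        onsets.append(onsets[-1] + max(gap, lo))
    return np.asarray(onsets)


def _burst_cycle_spikes(t_on: float, t_next: float, cfg: AfferentConfig,
                        f_s: float, rng: np.random.Generator) -> np.ndarray:
    """Spikes of one burst cycle: burst, then f_s spiking until t_next - d_p."""
    spikes = []
    n_b = rng.poisson(cfg.f_b * cfg.d_b)
    t_last = t_on
    if n_b > 0:
        isi = rng.exponential(1.0 / cfg.f_b, size=n_b)
        burst = t_on + np.cumsum(isi)
        spikes.append(burst)
        t_last = burst[-1]
    # spiking mode starts after the last burst spike
    t_end = t_next - cfg.d_p
    if f_s > 0 and t_end > t_last:
        k = rng.poisson(f_s * (t_end - t_last))
        if k:
            spikes.append(t_last + rng.uniform(0.0, t_end - t_last, size=k))
    if not spikes:
        return np.empty(0)
    return np.sort(np.concatenate(spikes))


def generate_train(cfg: AfferentConfig, T: float, rng: np.random.Generator,
                   shared_onsets: np.ndarray | None = None) -> list[np.ndarray]:
    """Spike times (seconds, sorted) for each of the ``cfg.n`` generators.

    The first ``round(P_b n)`` generators are pause-burst, the rest
    homogeneous Poisson at ``f_bar``.  For a correlated population a single
    onset clock is drawn (or supplied via ``shared_onsets`` to phase-lock
    several populations); per-generator spike sampling stays independent.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    n_burst = int(round(cfg.P_b * cfg.n))
    trains: list[np.ndarray] = []
    f_s = inter_burst_rate(cfg) if n_burst > 0 else 0.0
    common = None
    if n_burst > 0 and cfg.correlated:
        common = shared_onsets if shared_onsets is not None else _onset_times(T, cfg, rng)
    for _ in range(n_burst):
        onsets = common if common is not None else _onset_times(T, cfg, rng)
        if cfg.onset_jitter > 0 and common is not None:
            onsets = onsets + rng.normal(0.0, cfg.onset_jitter, size=onsets.size)
        spikes = [
            _burst_cycle_spikes(onsets[k], onsets[k + 1], cfg, f_s, rng)
            for k in range(len(onsets) - 1)
        ]
        tr = np.concatenate(spikes) if spikes else np.empty(0)
        trains.append(tr[(tr >= 0) & (tr < T)])
    for _ in range(cfg.n - n_burst):
        k = rng.poisson(cfg.f_bar * T)
        trains.append(np.sort(rng.uniform(0.0, T, size=k)))
    return trains


def mean_rate(trains: list[np.ndarray], T: float) -> float:
    """Empirical population-mean firing rate (Hz)."""
    return sum(tr.size for tr in trains) / (len(trains) * T)


def interpolate_state(alpha: float) -> dict[str, AfferentConfig]:
    """Interpolate every parameter between the two parkinsonian states.

    ``alpha = 0`` gives the hyperactive-iMSNs state, ``alpha = 1`` the
    PD-burst state; parameters interpolate element-wise linearly.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    out = {}
    for pop in ("CTX", "iMSN"):
        a = STATE_TABLE["hyperactive_imsn"][pop]
        b = STATE_TABLE["pd_burst"][pop]
        fields = ("f_bar", "P_b", "F_B", "d_b", "d_p", "f_b")
        vals = {f: (1 - alpha) * getattr(a, f) + alpha * getattr(b, f) for f in fields}
        out[pop] = replace(b, correlated=alpha > 0.0, clamp_fs=True, **vals)
    return out


def afferent_state(name: str, alpha: float | None = None) -> dict[str, AfferentConfig]:
    """Look up a named activity state, or interpolate if ``alpha`` is given."""
    if alpha is not None:
        return interpolate_state(alpha)
    try:
        return STATE_TABLE[name]
    except KeyError:
        raise KeyError(f"unknown afferent state {name!r}; "
                       f"choose from {sorted(STATE_TABLE)}") from None
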