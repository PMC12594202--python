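# stngpe

A conductance-based spiking-network simulator of the subthalamo-pallidal
(STN–GPe) circuit with calcium-dependent synaptic **and** structural
plasticity, built to study how parkinsonian changes of striatal and cortical
input statistics reorganize the circuit's synapses and its beta-band
(13–30 Hz) oscillations.  It is aimed at computational neuroscientists who
want a tested, seedable reference implementation of this model family —
for replaying the in-silico slice protocols, running step-change
experiments at desk scale, or extending the plasticity rules.

## The model

* **Neurons.** 250 STN and 750 prototypic GPe single-compartment
  Hodgkin–Huxley-type neurons (Otsuka-family kinetics).  STN carries
  `I_Na, I_K, I_T, I_Ca-K, I_A, I_L, I_leak`; the GPe variant omits the A-
  and L-type currents.  Gates relax as `dx/dt = (x∞ − x)/τ_x(M)` with
  logistic steady states `x∞ = 1/(1+exp((M+Θ_x)/k_x))`; the `d2` and `r`
  gates are driven by somatic calcium.  The calcium reversal follows the
  Nernst equation at each instant.
* **Calcium.** Each neuron has a somatic pool and three isolated dendritic
  segments: `d[Ca]/dt = −k_conv·(I_T + I_L + Σ I_NMDA,Ca) − k_Ca·[Ca]`, with
  each segment seeing only the NMDA currents of synapses assigned to it.
* **Synapses.** Rise/fast/slow transmitter gating (GABA_A, AMPA, NMDA) driven
  by 1-ms release pulses; NMDA splits into a nonspecific and a calcium
  pathway, each with its own magnesium-block factor, and
  `g_NMDA,syn = 1.7 g_AMPA` so the NMDA:AMPA peak-current ratio is 0.25.
  The fast conductance is linear in the efficacy:
  `g = w_min + (w_max − w_min)ρ`.
* **Synaptic plasticity.** The two-threshold bistable calcium rule
  `τ_ρ dρ/dt = −ρ(1−ρ)(0.5−ρ) + γ_p(1−ρ)H(Ca−θ_p) − γ_d ρ H(Ca−θ_d) + noise`
  on every CS (CTX→STN), GS (GPe→STN), SG (STN→GPe) and GG (GPe→GPe)
  synapse.  Thresholds are shared across all synapses of a neuron, which
  makes plasticity heterosynaptic through the shared segment calcium.
* **Structural plasticity.** Dendritic element counts follow
  `τ_z dz_exc/dt = 1 − Ca_L/Ca*` (and its mirror image for inhibition),
  where `Ca_L` is a 10-s low-pass of somatic calcium; every 200 ms vacant
  elements form synapses with probability 0.1 and deficits remove them.
  iMSN→GPe synapses are fixed.
* **Inputs.** 2500 cortical and 7500 iMSN pause-burst Poisson generators
  with three activity states (healthy, hyperactive iMSNs, PD bursting) and a
  linear interpolation `x(α)` between the two parkinsonian states.

## Worked example

```python
from stngpe import NetworkConfig, default_model, check_constraints
from stngpe.protocols import run_rebound_protocol

report = check_constraints(default_model(), seed=5, duration_ms=20_000.0)
print(report)
r = run_rebound_protocol(-3.7, seed=3)
print(r.outcome_gs, r.burst_spike_counts[:3])
```

prints (elided):

```
{'stn_rate_hz': 9.84, 'gpe_rate_hz': 29.72, 'volley_min_v_mv': -75.87,
 'beta_peak_ratio': 0.34, 'msn_30hz_silences_gpe': True, ..., 'all_pass': True}
LTP [17, 17, 17]
```

The constraint report says the tuned healthy-state network fires at
9.8 Hz (STN) and 29.7 Hz (GPe), a synchronized volley from 10 pallidal
afferents hyperpolarizes an STN neuron to −75.9 mV (deep enough to
de-inactivate T-type calcium channels), sustained 30-Hz striatal input
silences the GPe, and the healthy state shows no exaggerated beta peak.
The rebound protocol at −3.7 μA/cm² evokes 17-spike rebound bursts whose
calcium transients cross the potentiation threshold: the pallidal synapses
onto the neuron undergo LTP.  At −3.15 μA/cm² the same protocol yields
8-spike bursts and LTD.

A command-line interface mirrors the library:

```bash
stngpe tune --seed 5 --out tuning.json
stngpe protocol rebound --amplitude -3.7 --seed 3
stngpe step-change --pre healthy --post pd_burst --scale 5 --seed 1
stngpe dump-config --out defaults.yaml
```

## Layout

| module | contents |
| --- | --- |
| `stngpe.neurons` | gating kinetics, ionic currents, calcium dynamics |
| `stngpe.synapses` | transmitter gating, magnesium block, efficacy→conductance |
| `stngpe.plasticity` | two-threshold efficacy rule, outcome classification |
| `stngpe.structural` | element bookkeeping, connectivity updates |
| `stngpe.afferents` | pause-burst generators, activity states, α-interpolation |
| `stngpe.connectivity` | synapse table, wiring rules, graph export |
| `stngpe.engine` | network build, Strang-splitting integrator, tuning |
| `stngpe.protocols` | cortical-stimulation / rebound / step-change protocols |
| `stngpe.analysis` | population rates, Welch PSD, beta power |
| `stngpe.io`, `stngpe.cli` | config, snapshots, manifests, CLI |

See `docs/methods.md` for modelling assumptions, parameter provenance and
numerical choices.
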