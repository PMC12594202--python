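# Methods

This note records the modelling assumptions, parameter provenance and
numerical choices behind `stngpe`, in the spirit of a model-description
supplement.  Units throughout: mV, ms, μA/cm², mS/cm², μM.

## Neuron models

STN and GPe neurons are single-compartment conductance-based models of the
Otsuka subthalamic family.  The STN carries Na, Kv3-type K, T-type Ca,
Ca-activated K, A-type K, L-type Ca and leak currents; the prototypic GPe
variant carries the same channel family without the A- and L-type currents.
Gating kinetics (steady states and voltage/calcium-dependent time constants)
use the source model's functional forms and kinetic constants.  Two gates are
calcium-driven: `d2` (L-type inactivation, midpoint 0.1 μM) and `r`
(Ca-K activation, midpoint 0.17 μM).

Because the original parameter supplement is not part of this package's
inputs, maximal conductances and bias currents were re-calibrated against the
published behavioural constraints rather than copied:

| parameter | value | calibration target |
| --- | --- | --- |
| STN `g_leak` | 0.1 | −3.15 / −3.7 μA/cm² pulses reach ≈ −78 / −82 mV |
| STN `g_T` | 3.5 | graded rebound bursts (1 → 8 → 17 spikes for −2.5/−3.15/−3.7) |
| STN `g_L` | 6.0 | firing-rate-driven somatic calcium (see below) |
| STN `g_CaK` | 2.0 | burst termination within a few hundred ms |
| STN `I_bias` | 2.0 | tonic pacemaking ≈ 26 Hz isolated |
| GPe `g_T` | 2.5 | inhibition-driven rebound calcium in GPe |
| GPe `I_bias` | 2.0 | network GPe rate 30 ± 1 Hz |
| weights CS/GS/SG/GG/MS | .145/.15/.15/.10/.30 | rates 10/30 Hz, volley ≤ −75 mV, 30-Hz iMSN silencing, beta ratio < 10 |

The reversal constants are E_Na = 40, E_K = −90, E_leak = −60 mV; the calcium
reversal is the Nernst potential of the somatic pool against an external
concentration of 2 μM at 303.15 K.  The 2-μM figure is kept exactly as the
model family states it, although physiological extracellular calcium is
three orders of magnitude higher; only the logarithmic ratio enters the
dynamics, so this is a parameterization choice, not a physical claim.  The
concentration is floored at 1e−12 μM before the logarithm.

## Calcium dynamics

Somatic and segmental pools obey
`d[Ca]/dt = −k_conv (I_T + I_L + Σ I_NMDA,Ca) − k_Ca [Ca]` with removal rate
`k_Ca = 2 ms⁻¹` (a deliberately fast proxy signal: calcium here tracks the
instantaneous calcium current on a sub-millisecond timescale).  The printed
model gives no explicit current-to-concentration factor; `k_conv`
(default 5.182e-3 μM·cm²/(ms·μA)) absorbs 1/(ZF) together with the effective
shell volume and is treated as a single calibration constant.  All
calcium-source currents are accumulated in the outward-positive sign
convention so that the negative sign in the equation yields influx; the
membrane equation likewise uses the physical convention
`C dV/dt = −ΣI_ion + I_bias − Σ g s (V−E_rev)`.

With these choices the two populations' calcium budgets are deliberately
different: STN somatic calcium is dominated by the L-type current (per-spike
influx, hence firing-rate-driven, with a T-type component that grows with
prior hyperpolarization), while GPe calcium is carried by its T-type current
(inhibition-driven) and by NMDA influx from subthalamic input.  At the
reduced desk scale and over tens of seconds, a step to hyperactive iMSN
input leaves the STN calcium nearly unchanged — the gain from faster firing
and the loss of inhibition-driven T-calcium almost cancel — so the
homeostatic-rewiring tests exercise the rule with an elevated-cortical-drive
input, which raises Ca_L in both populations unambiguously.

## Synapses

Each transmitter (GABA_A, AMPA, NMDA) has rise/fast/slow gating components
driven by a 1-ms presynaptic release pulse.  The rise equation is
implemented with a positive drive, `ds_rise/dt = +Φ(1−s_fast−s_slow)f_pre −
s_rise/τ_rise`: with a negative drive the summed gating would turn negative
at release onset for any ν_fast+ν_slow ≤ 1, i.e. a negative conductance.
A new spike during an active pulse extends the pulse (`fpre_until` takes the
max).  Kinetic constants are receptor-typical values for this model family
(AMPA: Φ=2, τ = 0.6/2/8 ms; NMDA: τ = 4/60/250 ms; GABA_A: Φ=2,
τ = 0.6/6/25 ms); the NMDA activation rate Φ = 0.20882 is the solution of
the calibration constraint that the NMDA:AMPA peak-current ratio equal 0.25
under the documented voltage-clamp convention (NMDA nonspecific peak at
+40 mV, AMPA peak at −80 mV, single release).

The NMDA calcium-pathway conductance is `g_NMDA,Ca = 1.0 × g_NMDA,syn`
against a fixed +90 mV reversal with the steeper magnesium factor.  A much
smaller fraction leaves the dendritic calcium signal too weak for any
protocol to separate from baseline; the value is calibrated so the
stimulation protocols reproduce their outcomes (this conductance is the
model's only knob scaling NMDA calcium against a fixed voltage-gated
background).

Efficacy maps linearly to conductance between `w_min = g_base/2` and
`w_max = 2 g_base`.  This is the exact solution of the constraint that the
mean initial efficacy of 1/3 sit halfway between a 50% reduction (ρ=0) and a
100% increase (ρ=1) of the baseline conductance.

## Synaptic plasticity

The efficacy rule is the bistable two-threshold calcium model with
`τ_ρ = 30 s`; the noise term is read as `σ√τ_ρ H(Ca−θ_d) ξ(t)` (the source
model's scaling), giving a per-step Euler–Maruyama increment of
`σ√(dt/τ_ρ)` while calcium is at or above the depression threshold.
`H(0) = 1` by convention.  ρ is clipped to [0, 1] after each step.

Thresholds and rates were calibrated from *exact* supra-threshold occupancy
times (counted per integration step inside the kernel, since the
sub-millisecond calcium transients are invisible to any down-sampled probe):

* θ_STN,d = 0.022 μM, θ_STN,p = 0.045 μM, θ_GPe,d = 0.015, θ_GPe,p = 0.030;
* γ_p = 250, γ_d = 25, σ = 0.2.

These place healthy-state activity almost entirely below θ_d, the weak
(8-Hz) stimulation protocol and the −3.15 μA/cm² rebound bursts between the
thresholds, and the strong (50-Hz) protocol and −3.7 μA/cm² bursts above
θ_p.

**Outcome classification.** The cubic term alone moves an efficacy of 0.33
toward the down state over minutes (0.33 is not a fixed point of the
bistable dynamics).  Protocol outcomes are therefore classified against the
*cubic null trajectory* — the calcium-free evolution of the baseline mean
over the elapsed time — exactly as experimental LTP/LTD is judged against an
unstimulated control pathway.  The decision band is twice the baseline
standard deviation with a floor of 0.05 for near-deterministic baselines.

**Rebound boundary.** The depression→potentiation transition sits between
8-spike bursts (−3.15 μA/cm², LTD) and 17-spike bursts (−3.7 μA/cm², LTP);
a rebound burst is counted from the first post-release spike until the first
inter-spike interval above 15 ms.  The transition lies at somewhat stronger
bursts than the slice experiments report — the same shift the original
model family observed.  Hyperpolarizing pulses last 500 ms (the published
protocol prints amplitude and repetition rate but not duration).

## Structural plasticity

Dendritic element counts integrate `τ_z dz/dt = ±(1 − Ca_L/Ca*)` with
`τ_Ca,L = 10 s` and `τ_z = 1800 s` by default (the model-fitting value; the
alternatively printed 3600 s is a supported configuration).  Connectivity
updates run every 200 ms: each vacant element (`⌊z − bound⌋`) forms a
synapse with probability 0.1 with a uniformly chosen presynaptic partner of
the type-appropriate population (no GG self-loops; axonal elements are
static at 200 per neuron and never limit formation); when `⌊z⌋ < bound`,
uniformly chosen synapses of that polarity are removed.  New synapses get a
uniform random segment and an efficacy from the network's truncated-normal
initialization (mean 0.33) — the model family is silent on newborn-synapse
efficacy.  iMSN→GPe synapses live entirely outside the element bookkeeping
(fixed edge set, never counted, never removed).  Element growth is
integrated per 200-ms block from the block-end Ca_L; the quadrature error is
negligible against the 10-s filter timescale.

Ca* is not a free constant: it is *defined* as the healthy-state steady
value of Ca_L measured with structural plasticity disabled, and
`calibrate_ca_targets` implements that measurement as a first-class
operation.  Desk-scale runs should calibrate at their own scale and seed
(the shipped defaults carry values measured at scale 1/5).

## Afferent generators

Pause-burst generators follow the three-phase cycle (burst → compensating
spiking → pause) with Normal(d_ob, 0.1 s) onset intervals truncated at
`d_b + d_p` so cycles cannot overlap.  The number of burst spikes is
Poisson(f_b·d_b) with Exponential(1/f_b) intervals from the onset; the
spiking phase starts after the last burst spike.  In the PD-burst state all
bursting generators (cortical and striatal) share one onset clock — in-phase
low-frequency bursting — with per-generator spike sampling independent and
an optional per-generator onset jitter (default 0).  The α-interpolation
between the hyperactive-iMSN and PD-burst states is element-wise linear in
every table parameter; intermediate cortical mixes can demand a negative
compensating rate (the interpolated burst budget alone exceeds the target
mean), in which case the compensating rate is floored at zero and the
realized mean rate sits slightly above f̄.  Directly constructed configs
still reject such parameter sets.

## Integration

Neuron ODEs advance by Strang splitting at dt = 0.03125 ms: a half-step
exact exponential relaxation of all gates at frozen voltage/calcium, a full
explicit-midpoint step of voltage plus the four calcium pools at frozen
gates, then a second gating half-step.  Synaptic gating, efficacies and the
structural low-pass advance by forward Euler / Euler–Maruyama at the same
dt.  Spikes are detected as upward crossings of −10 mV with a 1-ms
refractory period (the threshold sits above all subthreshold oscillations of
both cell models) and trigger 1-ms release pulses at the targets from the
next step.

The compiled kernel interpolates gate steady states, half-step relaxation
factors and magnesium-block factors from tables built with the exact
reference functions on a 0.02-mV (2e-4-μM) grid; interpolation errors are
below 1e−5 per step and the test suite asserts single-step parity between
kernel and reference path.  A Richardson study on a smooth trajectory gives
a global order of ≈ 2.1, and the production step size reproduces every spike
of a high-accuracy adaptive integration of the same single-neuron ODEs to
within 1 ms over the test horizon.  Calcium pools are clamped at zero after
each step; non-finite state aborts the run with a diagnostic.

All randomness flows through five named seeded streams (wiring, initial
state, afferents, plasticity noise, structural updates), so e.g. structural
randomness can be varied while holding afferent realizations fixed.  Runs
are bit-reproducible for a fixed seed.

## Problem sizes and what the tests show

The packaged experiments run at a reduced, in-degree-preserving scale
(default 1/5: 50 STN, 150 GPe, 500 CTX, 1500 iMSN generators, mean in-degree
10 per type) with measurement windows of 60 s for rates and spectra and tens
of seconds for step-change experiments; the original stationary-state
protocol (hours of simulated time at full scale, 10 network realizations) is
available through the same interfaces but is a cluster-scale undertaking.
Consequences of the reduced conditions: firing-rate and spectral checks
carry a few-percent realization noise; structural-plasticity checks shorten
τ_z to make element dynamics observable and assert the *signed* rewiring
response to an elevated-calcium input rather than the long-horizon in-degree
magnitudes; and the synthetic afferents emulate the target populations'
rate/burst statistics only — no corticostriatal coupling, no slow state
drifts, no electrode or measurement noise, so passing tests certify the
model mechanics, not quantitative agreement with any particular animal
preparation.

## Known limitations

* Single-compartment neurons with three isolated calcium segments; no
  dendritic cable or diffusion.
* No short-term plasticity; no conduction delays.
* The GPe variant is not an autonomous pacemaker at the default bias; its
  30-Hz network rate is sustained by subthalamic drive and rebound dynamics.
* The rebound LTD→LTP boundary sits at stronger bursts than slice
  experiments report (see above).
* At desk scale the hyperactive-iMSN step leaves STN somatic calcium nearly
  unchanged; long-horizon, full-scale calcium transients are not validated
  here.
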