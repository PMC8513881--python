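# Methods

This note documents the models, the numerical choices and the places
where the design was genuinely open, in enough detail to reproduce or
modify every analysis.

## Short-term plasticity model family

Synaptic efficacy is tracked by a facilitation variable *f* and a
depression variable *d*, both confined to [0, 1]:

    df/dt = (f0 − f)/τf + a (1 − f) Σs δ(t − ts)
    dd/dt = (1 − d)/τd − f d Σs δ(t − ts)

The evoked amplitude for stimulus *n* is g·fⁿᵉ·dⁿ (e = 1 or 2)
evaluated on the state *before* that stimulus increments the variables;
the incremented values propagate to the next stimulus. Because the
inter-stimulus dynamics are linear, the per-interval update is exact:

    f(n+1) = f0 − (f0 − f⁺) e^(−Δt/τf),  f⁺ = f(n) + a(1 − f(n))
    d(n+1) = 1 − (1 − d⁺) e^(−Δt/τd),    d⁺ = d(n)(1 − f(n))

Optional extensions make the increment *a* and the baseline *f₀*
themselves dynamic (the `afd` and `f0`-dynamic variants); when *f₀* is
dynamic the coupled linear system is solved in closed form, with the
equal-time-constant degenerate case handled by its analytic limit. A
time-dependent conductance-scale variant exists for completeness; its
multiplier is (1 + g_dyn/g_max) with g_dyn starting at zero.

Steady states under regular spiking at interval Δt are the fixed points
of the per-spike map, e.g.

    d∞ = (1 − E) / (1 − (1 − f∞) E),   E = e^(−Δt/τd).

(The sign in the denominator follows from the fixed-point derivation and
is verified against long-train iteration to 1e-8.) Burst responses are
initialised at these steady states (a₀ → a∞, f₀ → f∞, d₀ → d∞).

Default parameter sets are the fitted pathway models: excitatory
(`f2`): g = 6.6 nS, τf = 3.3 s, f₀ = 0.3, a = 0.15; inhibitory (`afd`):
g = 26.0 nS, τf = 1.4 s, f₀ = 0.05, τd = 0.8 s, τa = 8.0 s, a₀ = 0.08,
b = 0.11. Neuromodulator conditions change only the reported fields:
ACh halves the excitatory conductance (6.6 → 3.3 nS) and reshapes the
inhibitory pathway (g 26.0 → 6.7 nS, f₀ 0.05 → 0.16); NA slows
inhibitory recovery from depression (τd 0.8 → 1.6 s).

Units: seconds, nS, mV; currents in pA. EPSCs are referenced to a
−70 mV holding potential with a +10 mV glutamatergic reversal, IPSCs to
+10 mV with a −70 mV GABAergic reversal, so both pathways see an 80 mV
driving force.

## Observation model and inference

The likelihood treats each observed amplitude as Gaussian around the
model amplitude A with an amplitude-dependent spread. The source
formula "N(A, A/2)" is ambiguous about whether A/2 is an sd, a variance
or a precision (the historical pymc APIs differed); we take it as the
**variance** by default, σ = √(A/2), i.e. a mean-scaled variance with
roughly 10% relative noise at a 50 pA amplitude and 4% at 300 pA, which
matches realistic evoked-response variability. The proportional-sd
reading (σ = A/2, a 50% coefficient of variation) is available through
`noise_model="sd"`; under it the posterior mode of the conductance
scale on a single 100-stimulus train genuinely wanders by ±50% across
noise realisations (verified by multi-start optimisation of the exact
log-posterior), so no estimator can recover the generating conductance
reliably — a useful illustration of the g–f₀–a redundancy. A floor of
1e-3 pA on the spread guards near-zero amplitudes. The synthetic-data
generator uses the same observation model and clips draws at zero,
since evoked amplitudes are reported as non-negative magnitudes; the
clipped mass is ≈1% of points and biases means by well under one
standard error.

Priors: Exponential(scale 10 nS) on conductance scales, Beta(1, 3) on
baselines and increments (biasing towards the small values expected of
strongly facilitating, low-release synapses), Uniform(0.01 s, 20 s) on
time constants.

Sampling is component-wise random-walk Metropolis–Hastings (numba-
compiled). Proposal scales adapt towards 20–40% acceptance during
burn-in only and freeze afterwards, so the kept chain targets the exact
posterior. Defaults: 50 000 kept sweeps after 10 000 burn-in. AIC/BIC
are evaluated at the maximum-likelihood sample with n = number of
stimuli; weights are w_i ∝ exp(−Δ_i/2) where Δ_i is the mean (over
datasets, when arrays are supplied) of |C_i − min_m C_m|. Point
estimates follow the pathway convention: MAP for the narrow unimodal
excitatory posteriors, posterior mean for the broader inhibitory ones.
Parameter-recovery experiments report the median over three independent
synthetic recordings, mirroring the multi-cell structure of the
original recordings and halving the single-recording spread.

Posterior-predictive p-values: for each of 500 posterior draws θ,
simulate data and compare discrepancies D(x|θ) = Σ(x − A(θ))²;
p = Pr[D(x_sim) > D(x_obs)], with 0.025 < p < 0.975 deemed adequate.

## Stimulus generators

The naturalistic protocol draws inter-stimulus intervals from a
two-component Cox process: candidate ISI ~ Exponential(λ_i), rejected
and resampled while smaller than a refractory draw N(μ_i, σ_i²), with
the component chosen Bernoulli(π) per interval. Defaults: λ₁ = 3.0 Hz,
λ₂ = 0.25 Hz, μ = 6/2.5 ms, σ = 120/10 ms, π = 0.55, 99 ISIs → 100
stimuli. (The resulting protocol lasts ≈200 s; the source text's
"525 seconds" is inconsistent with its own parameters, which we follow.)
The log-ISI distribution is bimodal with modes ≈0.4 s and ≈4 s.

Burst drive is an inhomogeneous Poisson process: rate `burst_rate`
inside periodic windows (duration 200–250 ms, period 20 s), `base_rate`
(0.2 Hz) elsewhere. Correlated populations use a thinned mother
process: each child keeps each mother spike with probability c, giving
pairwise spike-count correlation exactly c.

## CA3 network model

Neurons follow adaptive quadratic-integrate-and-fire dynamics

    C dv/dt = k(v − vr)(v − vt) − u − gE(v − vE) − gI(v − vI)
    du/dt   = a[b(v − vr) − u]

with reset v ← c, u ← u + d at v ≥ v_peak. Excitatory cells: C = 24 pF,
k = 1.5, a = 10 Hz, b = 2 nS, c = −63 mV, d = 60 pA, vr = −75 mV,
vt = −58 mV, v_peak = 29 mV; fast-spiking inhibitory cells: C = 16 pF,
a = 900 Hz, c = −80 mV, d = 400 pA, vr = −65 mV, vt = −50 mV,
v_peak = 28 mV. Reversals +10 / −80 mV. Cholinergic modulation changes
only: c → −61 mV, d → 50 pA, vr → −70 mV (E cells), vr → −63 mV
(I cells) and the EE conductance 0.5 → 0.25 nS; noradrenaline changes
nothing but enables recurrent plasticity (as does ACh); without either,
plasticity is off and no ensembles can form.

Synapses are exponential: τ = 10 ms (EE, EI), 20 ms (IE, II). Plastic
weights w are dimensionless in [0, 1] and deliver g̃·w nS per
presynaptic spike (g̃ = 0.5 nS excitatory, 1.0 nS inhibitory), so
weight matrices and the WME are reported on the effective g̃·w scale;
non-plastic EI/II synapses use w = 0.3. The mossy-fiber input is one
fiber per ensemble, 3.0 nS scaled by the excitatory f² model
(f₀ = 0.3, a = 0.15, τf = 3.3 s, state never reset), delivered to a
dedicated feed-forward conductance with **τ = 20 ms**. The feed-forward
decay is not specified with the recurrent values; the slower constant
reflects mossy-fiber EPSC kinetics and is what makes the synapse a
reliable conditional detonator: the measured single-pulse detonation
threshold is 2.08 nS at control rest (1.17 nS under ACh) against
late-burst pulses of ≈2 nS, so 30 Hz bursts detonate under control
parameters, 20 Hz bursts only under ACh. With the 10 ms recurrent value
the thresholds are 2.48/1.43 nS and detonation would depend on chance
Poisson pulse clustering.

### Plasticity

EE and IE synapses follow the symmetric rule Δw = η(e^(−|Δt|/τ_stdp) − z)
per pre–post pair within a cutoff window (`stdp_update` exposes the
literal formula; τ_stdp = 20 ms). In the simulation the rule is applied
with spike traces:

* the kernel term is exact all-pairs, **including** exactly coincident
  pairs — ensemble cells receive identical input and spike in the same
  0.1 ms step, so the Δt = 0 term dominates ensemble wiring;
* the −z term is applied once per triggering spike, gated by the
  partner having at least one spike inside a soft 100 ms pair window
  (a pair-count trace capped at 1). Silent partners are never
  depressed; coincident pairs see η(1 − z), so no potentiation is
  possible at the rate ceiling (z ≥ 1); sustained high-rate episodes
  (z ≫ 1) strongly depress, producing the weight "resetting" that
  stabilises runaway ensembles.

Two rejected alternatives and why: applying −z per event to *all*
synapses slowly drains the weights of partners that are silent during
other ensembles' bursts (an overlap "sag" that prevents convergence to
the target matrix), while an uncapped per-pair −z·count self-limits
formation near z ≈ 1 so control networks stall below saturation. η and
z integrate postsynaptic spikes (increments ξ = 0.02 and 1/ρ_max = 0.1;
τ_η = 100 ms, τ_z = 1 s, ρ_max = 10 Hz); the triggering spike's own η
increment is visible to the updates it causes (η is a fast calcium-like
burst detector) whereas z's is not (z is a slow rate tracker). IE
synapses use fixed η = 0.1, z = 0.05 — potentiation-dominated, so
feedback inhibition tracks co-activity and contains reignition
cascades; these two constants are not given by the source and were
chosen so that inhibition stabilises ensemble maintenance without
blocking detonation.

Integration is forward Euler at dt = 0.1 ms (halving dt changes the
two-cell outcome by < 5%). All weights start at zero; v = v_rest,
u = 0. Simulations are bit-reproducible given the seed.

### Experiments

Eight ensembles of eight cells; with ring overlap k, neighbouring
ensembles share k cells and n_E = 8(8 − k); n_I stays 16. Each ensemble's
fiber fires 0.2 Hz Poisson background plus 250 ms burst windows every
20 s at the test frequency. Burst slots are assigned by a stride-3
modular order so cyclically ring-adjacent (cell-sharing) ensembles burst
≥ 7.5 s apart — outside the mossy facilitation window (τf = 3.3 s);
with adjacent scheduling, facilitated background spikes coinciding with
a neighbour's burst ignite spillover cascades through the shared cells.

Formation is declared when the weight-matrix error
WME = Σ|W − W_target| (W_target = g̃·1 within ensembles, 0 elsewhere)
stays below 2% of its all-zero value for the final 20 s of a 400 s run.
The 2% threshold is our operationalisation; its sensitivity matters in
exactly one regime: ACh with overlap 3 converges to a fully discrete
structure (all within-ensemble weights saturated, largest cross weight
≈ 0.16·g̃) but a slow diffuse creep of small cross weights — wired when
a facilitated background spike coincides with the temporally adjacent
ensemble's burst — leaves the final WME at ≈5% of baseline in about a
third of runs, versus ≥50% for genuinely collapsed configurations. Any
threshold below ~10% therefore reports a maximal stable ACh overlap of
2 in those runs and 3 otherwise, while control/NA capacity (1) and the
frequency experiment are insensitive to the threshold over 1–10%.

Retrieval is quantified by the discrimination index: the target
ensemble's population rate integrated around its last drive burst,
divided by the sum over itself and its two ring neighbours; rates are
spike trains smoothed by a causal exponential kernel (100 ms, unit
area) and the per-spike window integrals are computed exactly. D = 1
means interference-free retrieval, 1/3 means none.

## What the synthetic data do and do not show

The generator emulates evoked-amplitude trains only: deterministic STP
dynamics plus independent Gaussian amplitude noise. It does not emulate
raw current traces, stimulus artefacts, series-resistance drift,
failures of minimal stimulation, or cell-to-cell parameter variability
(all replicates share one ground truth). Passing recovery tests
therefore shows the estimator is consistent under the model's own
assumptions at realistic noise, not that the model family is correct
for real recordings; model-selection results likewise quantify
discriminability between variants of this family only.

## Known limitations

* The build-up experiment (2, 10, 10+5 cells) reproduces rapid stable
  wiring under sparse mossy drive and rise–reset cycling under dense
  correlated perforant-path drive, but not the published intermediate
  pattern (10 cells without inhibition destabilising under mossy drive;
  2 cells wiring stably under perforant-path drive): the gated
  depression resets reignition before runaway at every size, and the
  correlated drive saturates the rate tracker at every size.
* Ensemble cells are homogeneous, so within-ensemble spikes are exactly
  synchronous; real heterogeneity would spread pair lags over a few ms
  with little effect at τ_stdp = 20 ms.
* The compartmental (dendritic) level is out of scope; its conclusion
  enters only as the plasticity-enabled switch of the neuromodulator
  conditions.
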