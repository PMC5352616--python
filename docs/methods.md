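# Methods

`anfsim` simulates single cat auditory nerve fibers (ANFs) under
extracellular electrical stimulation, as delivered by a cochlear implant.
This note documents the model, its parameters, the calibrations the package
ships, the numerical choices, and known limitations.

## Model

A fiber is represented by two exponential integrate-and-fire point neurons —
the *peripheral* and the *central* axon — reflecting the observation that
cathodic and anodic current depolarize the fiber at different sites, with
different spike latencies. Each axon integrates

    C dV/dt = h(V) − I_sub − I_supra + I_noise + I_stim
    h(V)    = −g_L (V − E_L) + g_L ΔT exp((V − v_threshold)/ΔT)

by forward Euler at dt = 1 μs. Crossing `v_threshold` starts an exponential
upswing rather than registering a spike; the spike is registered when V
reaches `v_peak`, after which V is reset to `v_reset`. Because the upswing
is finite-speed, a sufficiently strong opposing current delivered during it
cancels the developing spike — this is what makes the second phase of a
charge-balanced pulse raise thresholds without any explicit "activation
time" parameter.

Two adaptive currents provide sub- and suprathreshold adaptation:

    τ_sub   dI_sub/dt   = a_sub   (V − E_L) − I_sub
    τ_supra dI_supra/dt = a_supra (V − E_L) − I_supra

The stimulus is split sample-wise into anodic (I⁺) and cathodic (I⁻) parts
and routed as

    I_stim(central)    =  β I⁻ + I⁺
    I_stim(peripheral) = −(I⁻ + β I⁺)

so the peripheral axon is excited by cathodic current and the central axon
by anodic current, each inhibited by the opposite polarity compressed by β.
The fiber's spike is the first spike of either axon (OR gate). Every fiber
spike (i) adds an offset `b` to the suprathreshold adaptation current of
*both* axons, each decaying with its own τ_supra, and (ii) opens a dead-time
gate: for the next 500 μs the stimulus drive is removed from both axons
while noise and the adaptation currents keep integrating, and no fiber spike
can be emitted. The measured absolute refractory period is *longer* than
this gate (≈600 μs) because the post-spike adaptation state must also decay
— the package treats the measured ARP as a validation output, not an input.

Each axon receives an independent membrane-noise current: a Gaussian process
with power spectral density ∝ 1/f^α, synthesized by frequency-domain shaping
(white Gaussian spectrum × f^(−α/2), DC bin zeroed, inverse transform,
rescale). The per-trial series has mean exactly 0 and sample SD exactly σ.

## Parameters

Membrane and coupling constants (the published set for the cat fiber;
units are mV–μs–nF–mS–μA, which are mutually consistent, so the values are
used verbatim):

| quantity | peripheral | central |
|---|---|---|
| g_L (mS) | 1.1 | 2.7 |
| C (nF) | 856.96 | 1772.4 |
| ΔT (mV) | 10 | 4 |
| τ_sub (μs) | 250 | 250 |
| τ_supra (μs) | 4500 | 2500 |

Shared: E_L = −80 mV, v_threshold = −70 mV, v_peak = 24 mV,
v_reset = −84 mV, a_sub = 2 mS, a_supra = 3 mS, α = 0.8, β = 0.75,
dead time = 500 μs.

Note a peripheral peculiarity: with ΔT = v_threshold − E_L = 10 mV, h(V) ≥ 0
everywhere with a degenerate tangent at −70 mV, so the passive membrane
alone has no stable rest; the adaptation conductances create the actual
resting point (−79.29 mV peripheral, −79.88 mV central). Simulations start
at this zero-noise fixed point with the matching steady adaptation currents
(starting at E_L instead differs only transiently).

### Package calibrations

Two quantities are needed but not published as numbers; both ship as
explicit defaults with the calibration scripts that produced them:

* **Noise SDs** (`scripts/calibrate_noise.py`): σ_peripheral = 9.0 μA and
  σ_central = 16.5 μA give firing-efficiency relative spreads (RS = σ/θ) of
  ≈0.05 for 39-μs cathodic and ≈0.07 for 39-μs anodic monophasic pulses —
  mid-range of cat single-fiber measurements (roughly 0.01–0.12, cathodic
  typically tighter than anodic). RS scales nearly linearly with σ over this
  range while θ is almost unaffected.
* **Spike-triggered offset** (`scripts/calibrate_b.py`): b = 20 μA.
  Selection criteria, evaluated at 1000 pps / +1 dB re single-pulse
  threshold: the first (0–4 ms) window of the adaptive PSTH must dominate
  all later windows (it does by ≈5×), and the pooled inter-spike-interval
  histogram must peak near 5 ms rather than at the 1-ms pulse period. b = 10
  puts the ISI mode at the pulse period; b ≥ 40 pushes it beyond 7 ms.

## Stimuli

All waveforms live on the 1-μs integration grid (off-grid durations are
rejected, not rounded), with 1000 μs of pre-stimulus padding and
configurable post-padding (default 3000 μs) so onset transients and late
spikes are captured. Levels are linear current amplitudes in μA; protocol
levels quoted "in dB re threshold" convert as 20·log10 of the amplitude
ratio, with the reference threshold recomputed per pulse shape.

Pulse trains use a symmetric biphasic pulse of 25 μs/phase, cathodic
leading, for the whole 200–10,000 pps battery: 25 μs/phase is the
conventional high-rate phase duration and the longest that leaves a clear
inter-pulse silent interval at the 100-μs period of a 10,000-pps train (a
40-μs/phase pulse would occupy 80 % of that period, approaching a continuous
square wave). Train onsets are placed at the nearest grid point to k/rate.

## Response statistics

* **Firing efficiency**: binomial maximum-likelihood probit fit of spike
  probability vs level (integrated Gaussian with mean θ and SD σ); the
  threshold is θ, the relative spread σ/θ. The threshold search brackets
  the 0→1 transition on a geometric grid, then fits a fixed refined grid
  across it; for a noise-free fiber it falls back to bisection (σ = 0).
* **Latency/jitter**: mean and SD of first-spike times relative to stimulus
  onset (single- and paired-pulse protocols are single-spike contexts).
* **Vector strength**: resultant length of spike phases at the pulse-rate
  period, spikes in the first 50 ms excluded. Rate-battery summaries
  (VS vs pulse rate) average per-repetition VS; level-battery summaries
  (VS vs spike rate) pool spikes across repetitions, which stays defined at
  rates of a few spikes per second where single repetitions carry too few
  spikes.
* **Fano factor**: variance-to-mean ratio of per-trial spike counts. (The
  ratio of SD to mean appears in some verbal definitions, but the
  variance-to-mean form is the standard Fano factor and matches the scale
  of the published comparisons; the package computes variance/mean.)
* **ISI histograms** (1-ms bins, half-open), **PSTH** (1-ms bins) and
  **adaptive PSTH** (windows 0–4, 4–12, 12–24, 24–48, 48–100, 100–200,
  200–300 ms), all in spikes/s.
* **Summation**: equal-level paired-pulse thresholds vs delay fit with the
  saturating exponential T(Δ) = T∞ − A·exp(−Δ/τ) (the classical summation
  form; the asymptote is left free). The summation latency is the mean
  first-spike latency at the summation threshold for the shortest (100-μs)
  delay.
* **Strength–duration**: OLS of threshold vs 1/duration; intercept =
  rheobase, slope/intercept = chronaxie.

## Numerical and semantic choices

* Forward Euler with all right-hand sides evaluated at the start-of-step
  state; dt = 1 μs everywhere (exposed only for convergence tests). The
  fused two-axon loop is JIT-compiled (numba) and unit-tested for exact
  parity against the readable single-step reference implementation.
* The exponential argument is clamped at (v_peak − v_threshold + 20)/ΔT,
  reachable only above v_peak, so dynamics below the spike peak are exact.
* Spike time = the Euler step at which V first reaches v_peak, reported
  relative to stimulus onset.
* Only the axon that reached v_peak is reset; the partner axon's voltage is
  untouched (the cross-axon couplings are exactly the OR gate, the shared
  offset b, and the shared dead-time gate).
* An axon that reaches v_peak *during* the dead time is reset silently: the
  fiber is absolutely refractory, so no event is recorded, no b is applied
  and the gate is not re-opened. This prevents a spurious synchronized
  spike at gate release.
* If both axons cross v_peak in the same step the OR gate emits one event,
  attributed to the axon with the larger overshoot (tie → peripheral).
* Per-trial noise streams derive from a root seed via seed sequences; the
  two axons always draw from independent streams; rerunning with the same
  master seed reproduces every spike time exactly.

## Problem sizes

Firing-efficiency fits use 500 trials per level on an 8-level grid
(bracketing stage: 32 trials/level); paired-pulse latency statistics use
1000 trials; vector-strength statistics use 100 repetitions of 300-ms
trains for the rate battery and 20 repetitions per level for the level
battery. These match the scale of the original protocols; every size is an
argument, and the calibration scripts default to lighter sweeps.

## What the synthetic conditions do and do not show

All inputs are synthesized stimuli; there is no animal data in the loop.
Passing tests therefore demonstrate the internal consistency of the model
and the faithfulness of its implementation — thresholds, latencies,
refractoriness, adaptation and phase locking as *model predictions* — not
agreement with any particular fiber. Known limitations of the model family
apply: it is a pair of point neurons (no cable structure, soma, or
antidromic propagation; no ECAP), its parameters are phenomenological
rather than channel-level, it does not reproduce the near-shutdown of real
fibers at 10,000 pps, and species differences (cat vs human polarity
sensitivity) require re-parameterization, not structural change.

Two further caveats found during validation, documented rather than hidden:

* The model's equal-level summation thresholds rise almost linearly over
  delays of 100–300 μs (the residual depolarization decays with an
  effective constant of roughly 450–550 μs, set by C/g_L and the
  subthreshold adaptation loop), so the exponential summation fit is poorly
  identified on that delay window and the fitted τ is much longer than the
  published model prediction; the summation *latencies* are reproduced.
* At 10,000 pps both axons contribute sustained spikes locked to their
  respective (cathodic vs anodic) phases of the pulse, i.e. roughly half a
  period apart, so the fiber-level vector strength depends sharply on the
  phase-duration-to-period ratio and on the peripheral/central balance; the
  package's value at +1 dB is below the published model prediction.
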