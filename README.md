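# anfsim

Simulation of single **auditory nerve fibers (ANFs) under electrical
stimulation**, for researchers studying cochlear-implant coding: how pulse
shape, polarity, rate and level map onto spike timing statistics of the
electrically stimulated cat ANF.

A fiber is modeled as a network of **two exponential integrate-and-fire
point neurons** — a peripheral and a central axon — with opposite polarity
sensitivity. Each axon integrates

```
C dV/dt = h(V) − I_sub − I_supra + I_noise + I_stim
h(V)    = −g_L (V − E_L) + g_L ΔT exp((V − v_threshold)/ΔT)
```

with subthreshold and suprathreshold adaptation currents
(`τ dI/dt = a (V − E_L) − I`), independent Gaussian 1/f^α membrane noise per
axon, and a stimulus split by polarity:
`I_central = β I⁻ + I⁺`, `I_peripheral = −(I⁻ + β I⁺)` — so cathodic current
excites the peripheral axon and anodic current the central one. A spike from
either axon is the fiber's spike (OR gate); each spike adds an offset `b` to
both axons' suprathreshold adaptation currents and gates the stimulus off
for a 500-μs dead time. Spikes are detected at `v_peak`, not at threshold
crossing, so opposing current during the exponential upswing can cancel a
developing spike — this reproduces monophasic/biphasic threshold
differences, facilitation, accommodation, refractoriness and spike-rate
adaptation without extra mechanisms.

The package provides:

* `anfsim.stimulus` — monophasic, symmetric biphasic (± interphase gap),
  pseudomonophasic pulses, paired-pulse protocols and pulse trains on a
  1-μs grid;
* `anfsim.noise` — seeded 1/f^α Gaussian noise synthesis with a spectral
  slope checker;
* `anfsim.axon` / `anfsim.engine` / `anfsim.fiber` — the reference
  single-step dynamics and the JIT-compiled two-axon simulator;
* `anfsim.stats` — firing-efficiency (probit) fits, threshold search,
  latency/jitter, vector strength, Fano factor, ISI/PSTH/adaptive-PSTH,
  summation and strength–duration fits;
* `anfsim.experiments` + the `anfsim` CLI — complete, seeded protocols
  (single-pulse, paired-pulse, pulse-train batteries).

See `docs/methods.md` for the model's assumptions, parameter table,
calibrations and limitations.

## Worked example

Threshold, relative spread, latency and jitter for 39-μs monophasic pulses
of both polarities:

```python
import numpy as np
from anfsim import (PulseSpec, make_monophasic, default_fiber_params,
                    find_threshold, run_trials, latency_stats,
                    ThresholdSearchConfig)

params = default_fiber_params()
for polarity in ("cathodic", "anodic"):
    factory = lambda level: make_monophasic(
        PulseSpec("monophasic", polarity, ppd1=39, amplitude=level))
    fit = find_threshold(factory, params,
                         search_cfg=ThresholdSearchConfig(n_refine=500),
                         master_seed=1)
    trains = run_trials(factory(fit.theta), params, 500, master_seed=2)
    latency, jitter = latency_stats(trains, window=(0, np.inf))
    print(f"{polarity:9s} theta = {fit.theta:6.1f} uA   RS = {fit.rs:.3f}   "
          f"latency = {latency:5.0f} us   jitter = {jitter:4.0f} us")
```

prints

```
cathodic  theta =  573.3 uA   RS = 0.053   latency =   398 us   jitter =  118 us
anodic    theta =  775.3 uA   RS = 0.070   latency =   261 us   jitter =  101 us
```

i.e. the cathodic threshold is lower than the anodic one, while anodic
responses (central axon) are ~140 μs faster — the polarity/site dissociation
at the heart of the model. `theta` is the 50 % point of the integrated-
Gaussian firing-efficiency fit; `RS` (= σ/θ) is the fiber's normalized
dynamic range; latency and jitter are the mean and SD of first-spike times
at threshold.

The same is available from the shell:

```
anfsim threshold --shape monophasic --polarity cathodic --ppd1 39 --seed 1
anfsim simulate --shape biphasic --polarity cathodic --ppd1 50 --ppd2 50 \
       --amplitude 1200 --n-trials 20 --seed 7
anfsim experiment monophasic_single_pulse --seed 1 --outdir results/
```

`anfsim experiment` names include `monophasic_single_pulse`, `paired_summation`,
`refractory_recovery`, `vs_vs_rate`, `train_apsth`; each writes tidy CSV/JSON
plus a manifest with the resolved seeds and runtimes.

The two shipped calibrations (per-axon noise SD; spike-triggered adaptation
offset) can be re-derived with `scripts/calibrate_noise.py` and
`scripts/calibrate_b.py`.

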