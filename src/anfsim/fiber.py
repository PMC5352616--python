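"""Two-axon fiber: polarity split, parallel axons, OR gate, refractory gate.

The stimulus current is decomposed sample-wise into its anodic part I⁺ and
cathodic part I⁻ and routed to the two axons as

    I_stim(central)    =  β·I⁻ + I⁺
    I_stim(peripheral) = −(I⁻ + β·I⁺)

so that the peripheral axon is excited by cathodic and the central axon by
anodic current, with the opposing (inhibitory) polarity compressed by β.
Both axons integrate in parallel with independent 1/f^α noise streams; a
spike from either axon is the fiber's spike (OR gate).  Each fiber spike adds
the offset ``b`` to the suprathreshold adaptation current of both axons and
removes the stimulus drive from both for the dead time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import engine
from .axon import AxonParams, resting_state
from .noise import NoiseSpec, generate_noise
from .stimulus import StimulusWaveform

__all__ = ["FiberParams", "SpikeTrain", "split_stimulus", "simulate_trial",
           "run_trials", "spike_trains_to_csv"]

SOURCE_NAMES = ("peripheral", "central")


@dataclass(frozen=True)
class FiberParams:
    """Axon constants plus the fiber-level couplings."""

    peripheral: AxonParams
    central: AxonParams
    beta: float                 # inhibitory compression, dimensionless
    b: float                    # spike-triggered suprathreshold offset, μA
    dead_time: float            # post-spike stimulus gate, μs
    noise_peripheral: NoiseSpec = field(default_factory=NoiseSpec)
    noise_central: NoiseSpec = field(default_factory=NoiseSpec)

    def __post_init__(self):
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError("beta must lie in [0, 1]")
        if self.b < 0:
            raise ValueError("b must be non-negative")
        if self.dead_time < 0:
            raise ValueError("dead_time must be non-negative")

    def with_noise(self, sigma_peripheral: float, sigma_central: float) -> "FiberParams":
        from dataclasses import replace
        return replace(
            self,
            noise_peripheral=replace(self.noise_peripheral, sigma=sigma_peripheral),
            noise_central=replace(self.noise_central, sigma=sigma_central),
        )


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times of one trial, μs relative to stimulus onset."""

    spike_times: np.ndarray
    sources: np.ndarray         # 0 = peripheral, 1 = central
    trial_seed: int
    stimulus_id: str = ""
    dead_time: float = 0.0

    def __post_init__(self):
        times = np.asarray(self.spike_times, dtype=np.float64)
        sources = np.asarray(self.sources, dtype=np.int8)
        object.__setattr__(self, "spike_times", times)
        object.__setattr__(self, "sources", sources)
        if times.size != sources.size:
            raise ValueError("spike_times and sources must have equal length")
        if times.size > 1:
            isi = np.diff(times)
            if np.any(isi <= 0):
                raise ValueError("spike times must be strictly increasing")
            if self.dead_time and np.any(isi < self.dead_time - 1e-9):
                raise ValueError("inter-spike interval below the dead time")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def first_spike(self, after: float = -np.inf):
        """First spike time at or after ``after`` (μs re onset), or None."""
        sel = self.spike_times[self.spike_times >= after]
        return float(sel[0]) if sel.size else None

    def source_names(self):
        return [SOURCE_NAMES[s] for s in self.sources]


def split_stimulus(w: StimulusWaveform, beta: float):
    """Polarity-split inputs ``(central_input, peripheral_input)`` in μA."""
    samples = w.samples
    i_pos = np.where(samples > 0, samples, 0.0)   # anodic charge I⁺
    i_neg = np.where(samples < 0, samples, 0.0)   # cathodic charge I⁻
    central = beta * i_neg + i_pos
    peripheral = -(i_neg + beta * i_pos)
    return central, peripheral


_REST_CACHE: dict = {}


def _resting_cached(p: AxonParams):
    state = _REST_CACHE.get(p)
    if state is None:
        state = resting_state(p)
        _REST_CACHE[p] = state
    return state


def _axon_tuple(p: AxonParams):
    return (p.g_L, p.C, p.delta_T, p.E_L, p.v_threshold, p.v_peak, p.v_reset,
            p.tau_sub, p.tau_supra, p.a_sub, p.a_supra, p.exp_arg_cap)


def simulate_trial(w: StimulusWaveform, p: FiberParams, seed: int) -> SpikeTrain:
    """Run one trial; fresh independent noise per axon derived from ``seed``."""
    central_in, peripheral_in = split_stimulus(w, p.beta)
    n = w.n_samples
    ss = np.random.SeedSequence(seed)
    child_p, child_c = ss.spawn(2)
    if p.noise_peripheral.sigma > 0:
        noise_p = generate_noise(n, w.dt, p.noise_peripheral,
                                 rng=np.random.default_rng(child_p))
    else:
        noise_p = np.zeros(n)
    if p.noise_central.sigma > 0:
        noise_c = generate_noise(n, w.dt, p.noise_central,
                                 rng=np.random.default_rng(child_c))
    else:
        noise_c = np.zeros(n)

    rest_p = _resting_cached(p.peripheral)
    rest_c = _resting_cached(p.central)
    (gl_p, c_p, dT_p, el_p, vth_p, vpk, vrs_p, tsub_p, tsupra_p,
     asub_p, asupra_p, cap_p) = _axon_tuple(p.peripheral)
    (gl_c, c_c, dT_c, el_c, vth_c, _, vrs_c, tsub_c, tsupra_c,
     asub_c, asupra_c, cap_c) = _axon_tuple(p.central)
    dead_steps = int(round(p.dead_time / w.dt))

    spike_idx, sources = engine.run_fiber(
        peripheral_in, central_in, noise_p, noise_c, w.dt,
        gl_p, c_p, dT_p, el_p, vth_p, vpk, vrs_p, tsub_p, tsupra_p,
        asub_p, asupra_p, cap_p,
        gl_c, c_c, dT_c, el_c, vth_c, vrs_c, tsub_c, tsupra_c,
        asub_c, asupra_c, cap_c,
        rest_p.V, rest_p.I_sub, rest_p.I_supra,
        rest_c.V, rest_c.I_sub, rest_c.I_supra,
        p.b, dead_steps,
    )
    times = spike_idx * w.dt - w.t0
    return SpikeTrain(spike_times=times, sources=sources, trial_seed=int(seed),
                      dead_time=p.dead_time)


def trial_seeds(master_seed: int, n_trials: int) -> np.ndarray:
    """Deterministic, independent per-trial seeds below 2**31."""
    rng = np.random.default_rng(master_seed)
    return rng.integers(0, 2 ** 31 - 1, size=n_trials)


def run_trials(w: StimulusWaveform, p: FiberParams, n_trials: int,
               master_seed: int) -> list[SpikeTrain]:
    """Repeat :func:`simulate_trial` with per-trial seeds derived from
    ``master_seed``; reproducible and order-independent."""
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    seeds = trial_seeds(master_seed, n_trials)
    return [simulate_trial(w, p, int(s)) for s in seeds]


def spike_trains_to_csv(trains, path, metadata: dict | None = None) -> None:
    """Write trains as CSV rows (trial, spike_time_us, source); optional JSON
    metadata sidecar at ``path + '.json'``."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["trial", "spike_time_us", "source"])
        for i, tr in enumerate(trains):
            for t, s in zip(tr.spike_times, tr.sources):
                writer.writerow([i, f"{t:.1f}", SOURCE_NAMES[s]])
    if metadata is not None:
        with open(str(path) + ".json", "w") as fh:
            json.dump(metadata, fh, indent=2, default=str)
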