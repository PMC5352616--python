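"""Experiment protocols: single-pulse, paired-pulse and pulse-train studies.

Each function is a self-contained, seeded protocol mapping model parameters
to summary statistics.  Levels for conditioners, probes and trains are
expressed in dB re the single-pulse threshold of the same pulse shape
(20·log10 of the current-amplitude ratio), with reference thresholds
computed by the FE threshold search within each protocol.

Default problem sizes follow the original protocols (≈500–1000 trials per
level for FE fits, 100 train repetitions for vector-strength statistics);
every size is an explicit argument so that smoke-scale runs are available.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .fiber import FiberParams, run_trials
from .params import default_fiber_params
from .stats import (ThresholdSearchConfig, apsth, find_threshold,
                    isi_histogram, latency_stats, spike_probability,
                    vector_strength, fit_summation_tau)
from .stimulus import (PulseSpec, db_to_scale, make_biphasic, make_monophasic,
                       make_paired, make_pseudomonophasic, make_pulse_train)

__all__ = [
    "pseudomonophasic_threshold", "monophasic_threshold", "biphasic_threshold",
    "summation_experiment", "latency_differences", "emergent_arp",
    "train_vector_strength", "vs_rate_curve", "train_apsth", "train_isi",
]

# Phase duration of the symmetric biphasic train pulse.  One pulse shape
# serves the whole 200–10,000 pps battery; 25 μs/phase is the conventional
# high-rate choice and the longest that still leaves a clear inter-pulse
# silent interval at a 100-μs period.
TRAIN_PPD = 25.0
TRAIN_DURATION_MS = 300.0


def _cfg(n_trials, **kw):
    return ThresholdSearchConfig(n_refine=n_trials, **kw)


def monophasic_threshold(polarity: str, ppd: float, p: FiberParams | None = None,
                         n_trials: int = 500, seed: int = 0):
    """FE threshold fit for a monophasic pulse of the given polarity/duration."""
    p = p or default_fiber_params()
    factory = lambda lv: make_monophasic(
        PulseSpec("monophasic", polarity, ppd, amplitude=lv))
    return find_threshold(factory, p, search_cfg=_cfg(n_trials), master_seed=seed)


def biphasic_threshold(polarity: str, ppd: float, ipg: float = 0.0,
                       p: FiberParams | None = None, n_trials: int = 500,
                       seed: int = 0):
    """FE threshold for a symmetric biphasic pulse (optionally with an IPG)."""
    p = p or default_fiber_params()
    shape = "biphasic_ipg" if ipg > 0 else "biphasic"
    factory = lambda lv: make_biphasic(
        PulseSpec(shape, polarity, ppd, ppd, ipg=ipg, amplitude=lv))
    return find_threshold(factory, p, search_cfg=_cfg(n_trials), master_seed=seed)


def pseudomonophasic_threshold(polarity: str, ppd1: float = 40.0,
                               ppd2: float = 160.0,
                               p: FiberParams | None = None,
                               n_trials: int = 500, seed: int = 0):
    """FE threshold for a charge-balanced pseudomonophasic pulse."""
    p = p or default_fiber_params()
    factory = lambda lv: make_pseudomonophasic(
        PulseSpec("pseudomonophasic", polarity, ppd1, ppd2, amplitude=lv))
    return find_threshold(factory, p, search_cfg=_cfg(n_trials), master_seed=seed)


def summation_experiment(polarity: str, p: FiberParams | None = None,
                         delays=(100, 133, 166, 200, 233, 266, 300),
                         ppd: float = 50.0, n_trials: int = 400,
                         n_latency_trials: int = 1000, seed: int = 0):
    """Equal-level paired-pulse summation protocol.

    Two identical monophasic pulses at a common level; the summation
    threshold is the FE threshold over the common amplitude at each delay.
    A saturating exponential T(Δ) = T∞ − A·exp(−Δ/τ) fit across delays gives
    the summation time constant; the summation latency is the mean
    first-spike latency at the summation threshold for the shortest delay.

    Returns a dict with delays, thresholds, tau, asymptote, latency and jitter.
    """
    p = p or default_fiber_params()
    rng = np.random.default_rng(seed)
    thresholds = []
    fits = []
    for d in delays:
        def factory(lv, d=d):
            pulse = make_monophasic(PulseSpec("monophasic", polarity, ppd, amplitude=lv))
            return make_paired(pulse, 1.0, 1.0, float(d))
        fit = find_threshold(factory, p, search_cfg=_cfg(n_trials),
                             master_seed=int(rng.integers(2**31 - 1)))
        fits.append(fit)
        thresholds.append(fit.theta)
    try:
        tau, asymptote = fit_summation_tau(np.asarray(delays, float), thresholds)
    except ValueError:
        tau, asymptote = np.nan, np.nan

    d0 = delays[0]
    pulse = make_monophasic(PulseSpec("monophasic", polarity, ppd,
                                      amplitude=thresholds[0]))
    pair = make_paired(pulse, 1.0, 1.0, float(d0))
    trains = run_trials(pair, p, n_latency_trials, int(rng.integers(2**31 - 1)))
    latency, jitter = latency_stats(trains, window=(0.0, np.inf))
    return {
        "delays_us": np.asarray(delays, float),
        "thresholds_uA": np.asarray(thresholds, float),
        "tau_us": tau,
        "asymptote_uA": asymptote,
        "latency_us": latency,
        "jitter_us": jitter,
        "fits": fits,
    }


def latency_differences(probs=(0.1, 0.9), p: FiberParams | None = None,
                        ppd: float = 39.0, n_trials: int = 1000,
                        n_fit_trials: int = 500, seed: int = 0):
    """Cathodic-minus-anodic mean first-spike latency for monophasic pulses
    at levels evoking each requested spike probability.

    One FE fit per polarity is shared across all probability levels.
    Returns ``{prob: (difference_us, latency_cathodic, latency_anodic)}``.
    """
    p = p or default_fiber_params()
    rng = np.random.default_rng(seed)
    fits = {
        polarity: monophasic_threshold(polarity, ppd, p, n_trials=n_fit_trials,
                                       seed=int(rng.integers(2**31 - 1)))
        for polarity in ("cathodic", "anodic")
    }
    out = {}
    for prob in probs:
        lats = {}
        for polarity in ("cathodic", "anodic"):
            level = fits[polarity].level_at(prob)
            pulse = make_monophasic(PulseSpec("monophasic", polarity, ppd,
                                              amplitude=level))
            trains = run_trials(pulse, p, n_trials, int(rng.integers(2**31 - 1)))
            lats[polarity], _ = latency_stats(trains, window=(0.0, np.inf))
        out[prob] = (lats["cathodic"] - lats["anodic"],
                     lats["cathodic"], lats["anodic"])
    return out


def emergent_arp(p: FiberParams | None = None, conditioner_db: float = 2.0,
                 probe_cap_db: float = 6.0, ppd: float = 100.0,
                 delays=np.arange(400.0, 1001.0, 25.0),
                 n_trials: int = 200, n_fit_trials: int = 500, seed: int = 0,
                 probe_window_us: float = 2500.0):
    """Emergent absolute refractory period from the variable-probe protocol.

    A cathodic monophasic conditioner fixed above single-pulse threshold is
    followed by an identical-shape probe at increasing interpulse intervals
    (onset to onset).  At each interval the probe is driven at a generous
    level cap; the ARP estimate is the largest interval at which not a single
    probe-evoked spike is observed.

    Returns ``(arp_us, per_delay_probe_probability, single_pulse_theta)``.
    """
    p = p or default_fiber_params()
    rng = np.random.default_rng(seed)
    fit = monophasic_threshold("cathodic", ppd, p, n_trials=n_fit_trials,
                               seed=int(rng.integers(2**31 - 1)))
    cond_level = fit.theta * db_to_scale(conditioner_db)
    cap_scale = db_to_scale(probe_cap_db) / db_to_scale(conditioner_db)
    probs = []
    arp = 0.0
    for d in delays:
        pulse = make_monophasic(PulseSpec("monophasic", "cathodic", ppd,
                                          amplitude=cond_level),
                                post_pad=probe_window_us + float(d) + 1000.0)
        pair = make_paired(pulse, 1.0, cap_scale, float(d))
        trains = run_trials(pair, p, n_trials, int(rng.integers(2**31 - 1)))
        prob = spike_probability(trains, window_start=float(d),
                                 window_end=float(d) + probe_window_us)
        probs.append(prob)
        if prob == 0.0:
            arp = float(d)
    return arp, np.asarray(probs), fit.theta


def _train_factory(rate: float, polarity: str = "cathodic",
                   ppd: float = TRAIN_PPD, duration_ms: float = TRAIN_DURATION_MS):
    def factory(level):
        pulse = make_biphasic(PulseSpec("biphasic", polarity, ppd, ppd,
                                        amplitude=level), post_pad=0.0)
        return make_pulse_train(pulse, rate, duration_ms)
    return factory


def train_vector_strength(rate: float, level_db: float = 1.0,
                          p: FiberParams | None = None, n_reps: int = 100,
                          n_fit_trials: int = 500, seed: int = 0,
                          polarity: str = "cathodic"):
    """Mean per-repetition vector strength for a 300-ms biphasic pulse train.

    The level is ``level_db`` dB re the single-pulse threshold of the same
    biphasic pulse; spikes in the first 50 ms are discarded.  Repetitions
    without any retained spike are skipped.

    Returns ``(mean_vs, sd_vs, mean_rate_spikes_per_s)``.
    """
    p = p or default_fiber_params()
    rng = np.random.default_rng(seed)
    fit = biphasic_threshold(polarity, TRAIN_PPD, p=p, n_trials=n_fit_trials,
                             seed=int(rng.integers(2**31 - 1)))
    level = fit.theta * db_to_scale(level_db)
    trains = run_trials(_train_factory(rate, polarity)(level), p, n_reps,
                        int(rng.integers(2**31 - 1)))
    period = 1e6 / rate
    vs_vals = []
    for tr in trains:
        try:
            vs_vals.append(vector_strength(tr.spike_times, period))
        except ValueError:
            continue
    if not vs_vals:
        raise ValueError("no repetition retained spikes after the 50-ms discard")
    total = sum(int(np.sum((tr.spike_times >= 0)
                           & (tr.spike_times < TRAIN_DURATION_MS * 1000)))
                for tr in trains)
    rate_out = total / (n_reps * TRAIN_DURATION_MS * 1e-3)
    return float(np.mean(vs_vals)), float(np.std(vs_vals)), rate_out


def vs_rate_curve(rate: float, p: FiberParams | None = None,
                  level_db_grid=np.arange(-14.0, 6.1, 2.0), n_reps: int = 20,
                  n_fit_trials: int = 500, seed: int = 0,
                  rate_range=(4.0, 500.0), polarity: str = "cathodic"):
    """Vector strength as a function of spike rate for one pulse rate.

    Levels span the dynamic range of the train response; at each level the VS
    is computed over the spikes pooled across repetitions (robust at low
    rates, where single repetitions carry few spikes).  Levels whose spike
    rate falls outside ``rate_range`` are dropped.

    Returns a dict with levels, spike rates, VS values and the maximum VS.
    """
    p = p or default_fiber_params()
    rng = np.random.default_rng(seed)
    fit = biphasic_threshold(polarity, TRAIN_PPD, p=p, n_trials=n_fit_trials,
                             seed=int(rng.integers(2**31 - 1)))
    factory = _train_factory(rate, polarity)
    period = 1e6 / rate
    levels, rates, vs_vals = [], [], []
    for db in level_db_grid:
        level = fit.theta * db_to_scale(float(db))
        trains = run_trials(factory(level), p, n_reps,
                            int(rng.integers(2**31 - 1)))
        total = sum(int(np.sum((tr.spike_times >= 0)
                               & (tr.spike_times < TRAIN_DURATION_MS * 1000)))
                    for tr in trains)
        spike_rate = total / (n_reps * TRAIN_DURATION_MS * 1e-3)
        if not (rate_range[0] <= spike_rate <= rate_range[1]):
            continue
        pooled = np.concatenate([tr.spike_times for tr in trains])
        try:
            vs = vector_strength(pooled, period)
        except ValueError:
            continue
        levels.append(level)
        rates.append(spike_rate)
        vs_vals.append(vs)
    if not vs_vals:
        raise ValueError("no level produced spike rates inside rate_range")
    return {
        "levels_uA": np.asarray(levels),
        "spike_rates": np.asarray(rates),
        "vs": np.asarray(vs_vals),
        "max_vs": float(np.max(vs_vals)),
    }


def train_apsth(rate: float, level_db: float = 1.0,
                p: FiberParams | None = None, n_reps: int = 24,
                n_fit_trials: int = 300, seed: int = 0,
                polarity: str = "cathodic"):
    """Adaptive PSTH of the train response; returns (centers_ms, rates)."""
    p = p or default_fiber_params()
    rng = np.random.default_rng(seed)
    fit = biphasic_threshold(polarity, TRAIN_PPD, p=p, n_trials=n_fit_trials,
                             seed=int(rng.integers(2**31 - 1)))
    level = fit.theta * db_to_scale(level_db)
    trains = run_trials(_train_factory(rate, polarity)(level), p, n_reps,
                        int(rng.integers(2**31 - 1)))
    return apsth(trains)


def train_isi(rate: float, level_db: float = 1.0, p: FiberParams | None = None,
              n_reps: int = 24, n_fit_trials: int = 300, seed: int = 0,
              polarity: str = "cathodic"):
    """Pooled ISI histogram of the train response; returns (bin_left_ms, counts)."""
    p = p or default_fiber_params()
    rng = np.random.default_rng(seed)
    fit = biphasic_threshold(polarity, TRAIN_PPD, p=p, n_trials=n_fit_trials,
                             seed=int(rng.integers(2**31 - 1)))
    level = fit.theta * db_to_scale(level_db)
    trains = run_trials(_train_factory(rate, polarity)(level), p, n_reps,
                        int(rng.integers(2**31 - 1)))
    return isi_histogram(trains)
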