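"""Response statistics: firing-efficiency fits, thresholds, latency, jitter,
vector strength, Fano factor, ISI/PSTH histograms, summation and
strength-duration fits.

The firing-efficiency (FE) function is the probability of evoking a spike as
a function of stimulus level, fit as an integrated Gaussian Φ((L − θ)/σ) by
binomial maximum likelihood (probit regression).  θ is the 50 %-probability
level and defines the threshold; the relative spread RS = σ/θ is the
normalized dynamic range of the fiber.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.optimize import curve_fit
from scipy.stats import norm

from .fiber import FiberParams, SpikeTrain, run_trials

__all__ = [
    "FiringEfficiencyFit", "ResponseSummary", "ThresholdSearchConfig",
    "fit_fe", "find_threshold", "latency_stats", "vector_strength",
    "fano_factor", "isi_histogram", "psth", "apsth", "rate_level",
    "fit_summation_tau", "fit_strength_duration", "spike_probability",
]

APSTH_WINDOWS_MS = ((0, 4), (4, 12), (12, 24), (24, 48),
                    (48, 100), (100, 200), (200, 300))


@dataclass(frozen=True)
class FiringEfficiencyFit:
    """Integrated-Gaussian fit of spike probability vs level."""

    theta: float                    # 50 % level, μA
    sigma: float                    # spread, μA
    levels: np.ndarray = field(default_factory=lambda: np.empty(0))
    probs: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_per_level: int = 0

    def __post_init__(self):
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    @property
    def rs(self) -> float:
        """Relative spread σ/θ."""
        return self.sigma / self.theta

    def prob_at(self, level):
        if self.sigma == 0:
            return (np.asarray(level) >= self.theta).astype(float)
        return norm.cdf((np.asarray(level) - self.theta) / self.sigma)

    def level_at(self, prob: float) -> float:
        """Level giving the requested spike probability (inverse FE)."""
        if not 0 < prob < 1:
            raise ValueError("prob must lie strictly between 0 and 1")
        return float(self.theta + self.sigma * norm.ppf(prob))


@dataclass(frozen=True)
class ResponseSummary:
    mean_latency: float     # μs
    jitter: float           # μs, SD of first-spike latencies
    spike_rate: float = np.nan   # spikes/s
    fano: float = np.nan
    vs: float = np.nan

    def __post_init__(self):
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")
        if np.isfinite(self.vs) and not (0.0 <= self.vs <= 1.0 + 1e-12):
            raise ValueError("vector strength must lie in [0, 1]")


def fit_fe(levels, spike_counts, n_per_level) -> FiringEfficiencyFit:
    """Binomial maximum-likelihood probit fit of the FE function.

    ``n_per_level`` may be a scalar or per-level array.  Raises when the data
    cannot identify both parameters (all outcomes 0 or all 1, or fewer than
    three distinct levels).
    """
    levels = np.asarray(levels, dtype=np.float64)
    counts = np.asarray(spike_counts, dtype=np.float64)
    n = np.broadcast_to(np.asarray(n_per_level, dtype=np.float64), counts.shape)
    if np.unique(levels).size < 3:
        raise ValueError("need at least 3 distinct levels to fit the FE function")
    if counts.sum() == 0 or (n - counts).sum() == 0:
        raise ValueError(
            "all-zero or all-one outcomes: widen the level grid so it spans "
            "probabilities on both sides of 0.5"
        )
    endog = np.column_stack([counts, n - counts])
    exog = sm.add_constant(levels)
    model = sm.GLM(endog, exog, family=sm.families.Binomial(sm.families.links.Probit()))
    res = model.fit()
    intercept, slope = res.params
    if slope <= 0:
        raise ValueError("non-increasing FE fit; widen or refine the level grid")
    sigma = 1.0 / slope
    theta = -intercept * sigma
    return FiringEfficiencyFit(theta=float(theta), sigma=float(sigma),
                               levels=levels, probs=counts / n,
                               n_per_level=int(np.max(n)))


def spike_probability(trains, window_start: float = -np.inf,
                      window_end: float = np.inf) -> float:
    """Fraction of trials with at least one spike in the window (μs re onset)."""
    hits = sum(
        1 for tr in trains
        if np.any((tr.spike_times >= window_start) & (tr.spike_times < window_end))
    )
    return hits / len(trains)


@dataclass(frozen=True)
class ThresholdSearchConfig:
    """Two-stage FE threshold search: geometric bracketing of the 0→1
    transition, then a probit fit on a fixed refined grid across it."""

    level_lo: float = 10.0          # μA, coarse sweep start
    level_hi: float = 1e5           # μA, coarse sweep ceiling
    coarse_factor: float = 1.25
    n_coarse: int = 32              # trials/level in the bracketing stage
    n_refine: int = 500             # trials/level in the fitting stage
    n_levels: int = 8               # refined grid size
    grid_halfwidth: float = 0.18    # refined grid span, fraction of the bracket center
    window_start: float = 0.0       # spike-counting window, μs re onset
    window_end: float = np.inf
    max_widen: int = 4              # grid-widening attempts if outcomes degenerate


def _probe(pulse_factory, level, p, n_trials, seed, cfg):
    trains = run_trials(pulse_factory(level), p, n_trials, seed)
    hits = spike_probability(trains, cfg.window_start, cfg.window_end)
    return hits, trains


def find_threshold(pulse_factory, p: FiberParams, n_trials: int | None = None,
                   search_cfg: ThresholdSearchConfig | None = None,
                   master_seed: int = 0) -> FiringEfficiencyFit:
    """FE threshold of the fiber for a level-parameterized stimulus.

    ``pulse_factory(level_uA)`` must return the stimulus waveform at that
    level.  For a noise-free fiber the FE function is a step and the step
    location is found by bisection (σ = 0).
    """
    cfg = search_cfg or ThresholdSearchConfig()
    if n_trials is not None:
        from dataclasses import replace
        cfg = replace(cfg, n_refine=n_trials)
    deterministic = (p.noise_peripheral.sigma == 0 and p.noise_central.sigma == 0)

    # --- stage 1: geometric bracketing of the transition
    seeds = iter(np.random.default_rng(master_seed).integers(0, 2**31 - 1, 10_000))
    level = cfg.level_lo
    prev_level = None
    bracket = None
    n_probe = 1 if deterministic else cfg.n_coarse
    while level <= cfg.level_hi:
        prob, _ = _probe(pulse_factory, level, p, n_probe, int(next(seeds)), cfg)
        if prob >= 0.5:
            if prev_level is None:
                raise ValueError(
                    f"spike probability already ≥ 0.5 at the lowest level "
                    f"{cfg.level_lo} μA; lower level_lo"
                )
            bracket = (prev_level, level)
            break
        prev_level = level
        level *= cfg.coarse_factor
    if bracket is None:
        raise ValueError(
            f"no 0→1 transition found up to {cfg.level_hi} μA; raise level_hi"
        )

    if deterministic:
        lo, hi = bracket
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            prob, _ = _probe(pulse_factory, mid, p, 1, int(next(seeds)), cfg)
            if prob >= 0.5:
                hi = mid
            else:
                lo = mid
            if hi - lo <= 1e-6 * hi:
                break
        theta = 0.5 * (lo + hi)
        return FiringEfficiencyFit(theta=theta, sigma=0.0,
                                   levels=np.array([lo, hi]),
                                   probs=np.array([0.0, 1.0]), n_per_level=1)

    # --- stage 2: fixed refined grid across the bracket, probit ML fit
    center = 0.5 * (bracket[0] + bracket[1])
    halfwidth = cfg.grid_halfwidth
    for attempt in range(cfg.max_widen + 1):
        grid = np.linspace(center * (1 - halfwidth), center * (1 + halfwidth),
                           cfg.n_levels)
        counts = np.empty(cfg.n_levels)
        for i, lv in enumerate(grid):
            prob, _ = _probe(pulse_factory, lv, p, cfg.n_refine, int(next(seeds)), cfg)
            counts[i] = prob * cfg.n_refine
        try:
            fit = fit_fe(grid, counts, cfg.n_refine)
        except ValueError:
            halfwidth *= 1.6
            continue
        # recenter once if the fitted theta fell near the grid edge
        if not (grid[0] <= fit.theta <= grid[-1]) and attempt < cfg.max_widen:
            center = max(fit.theta, 1e-9)
            halfwidth *= 1.3
            continue
        return fit
    raise ValueError("threshold search failed to identify the FE transition")


def latency_stats(trains, window=(-np.inf, np.inf)):
    """Mean and SD (jitter) of first-spike latencies, μs re stimulus onset."""
    lats = []
    for tr in trains:
        sel = tr.spike_times[(tr.spike_times >= window[0]) & (tr.spike_times < window[1])]
        if sel.size:
            lats.append(sel[0])
    if len(lats) < 2:
        raise ValueError("need at least 2 spiking trials for latency statistics")
    lats = np.asarray(lats)
    return float(lats.mean()), float(lats.std(ddof=1))


def vector_strength(spike_times, period: float, discard_before: float = 50_000.0) -> float:
    """Phase-locking index in [0, 1] at period ``period`` (μs).

    ``spike_times`` are μs re stimulus onset; spikes earlier than
    ``discard_before`` (default 50 ms) are excluded to remove onset effects.
    """
    t = np.asarray(spike_times, dtype=np.float64)
    t = t[t >= discard_before]
    if t.size == 0:
        raise ValueError("no spikes after the discard window; VS undefined")
    phases = 2.0 * np.pi * t / period
    vs = np.hypot(np.cos(phases).sum(), np.sin(phases).sum()) / t.size
    return float(min(vs, 1.0))


def fano_factor(counts) -> float:
    """Variance-to-mean ratio of per-trial spike counts."""
    counts = np.asarray(counts, dtype=np.float64)
    if counts.size < 2:
        raise ValueError("need at least 2 trials")
    mean = counts.mean()
    if mean == 0:
        raise ValueError("zero mean spike count; Fano factor undefined")
    return float(counts.var(ddof=1) / mean)


def isi_histogram(trains, bin_ms: float = 1.0, max_ms: float = 50.0):
    """Pooled inter-spike-interval histogram with half-open bins [k, k+1) ms.

    Returns ``(bin_left_ms, counts)``.
    """
    edges = np.arange(0.0, max_ms + bin_ms, bin_ms)
    isis = []
    for tr in trains:
        if tr.n_spikes >= 2:
            isis.append(np.diff(tr.spike_times) / 1000.0)
    if isis:
        counts, _ = np.histogram(np.concatenate(isis), bins=edges)
    else:
        counts = np.zeros(edges.size - 1, dtype=int)
    return edges[:-1], counts


def psth(trains, bin_ms: float = 1.0, duration_ms: float = 300.0):
    """Peri-stimulus time histogram in spikes/s per bin across trials.

    Returns ``(bin_left_ms, rate)``.
    """
    edges = np.arange(0.0, duration_ms + bin_ms, bin_ms)
    all_t = np.concatenate([tr.spike_times for tr in trains]) / 1000.0
    counts, _ = np.histogram(all_t, bins=edges)
    rate = counts / (len(trains) * bin_ms * 1e-3)
    return edges[:-1], rate


def apsth(trains, windows_ms=APSTH_WINDOWS_MS):
    """Adaptive PSTH: spike rate in progressively widening windows.

    Returns ``(window_centers_ms, rate)`` with rate in spikes/s.
    """
    centers = np.array([(a + b) / 2 for a, b in windows_ms], dtype=float)
    rates = np.empty(len(windows_ms))
    for i, (a, b) in enumerate(windows_ms):
        total = sum(
            int(np.sum((tr.spike_times >= a * 1000.0) & (tr.spike_times < b * 1000.0)))
            for tr in trains
        )
        rates[i] = total / (len(trains) * (b - a) * 1e-3)
    return centers, rates


def rate_level(pulse_train_factory, p: FiberParams, levels, n_trials: int,
               master_seed: int = 0, duration_ms: float = 300.0,
               pulse_rate: float | None = None):
    """Mean spike rate (spikes/s) per stimulus level; optionally also the
    rate normalized by the pulse rate (spike probability per pulse)."""
    rates = np.empty(len(levels))
    seeds = np.random.default_rng(master_seed).integers(0, 2**31 - 1, len(levels))
    for i, lv in enumerate(levels):
        trains = run_trials(pulse_train_factory(lv), p, n_trials, int(seeds[i]))
        total = sum(
            int(np.sum((tr.spike_times >= 0) & (tr.spike_times < duration_ms * 1000.0)))
            for tr in trains
        )
        rates[i] = total / (n_trials * duration_ms * 1e-3)
    if pulse_rate is not None:
        return rates, rates / pulse_rate
    return rates


def fit_summation_tau(delays, equal_level_thresholds):
    """Saturating-exponential fit T(Δ) = T∞ − A·exp(−Δ/τ) to summation
    thresholds vs interpulse delay.  Returns ``(tau_us, asymptote)``."""
    delays = np.asarray(delays, dtype=np.float64)
    thr = np.asarray(equal_level_thresholds, dtype=np.float64)
    if delays.size < 4:
        raise ValueError("need at least 4 delay points")
    if np.ptp(thr) < 1e-9 * np.abs(thr).max():
        raise ValueError("thresholds are constant; summation tau unidentifiable")

    def model(d, t_inf, a, tau):
        return t_inf - a * np.exp(-d / tau)

    p0 = (thr.max(), max(thr.max() - thr.min(), 1e-6), np.ptp(delays) / 2)
    try:
        popt, _ = curve_fit(model, delays, thr, p0=p0, maxfev=20_000,
                            bounds=([0.0, 0.0, 1.0], [np.inf, np.inf, 1e7]))
    except RuntimeError as exc:
        resid = thr - model(delays, *p0)
        raise ValueError(f"summation fit did not converge; residuals {resid}") from exc
    t_inf, a, tau = popt
    return float(tau), float(t_inf)


def fit_strength_duration(durations, thresholds):
    """Weiss-law fit: OLS of threshold vs 1/duration.

    The intercept is the rheobase (threshold for arbitrarily long pulses);
    slope/intercept is the chronaxie (duration at twice rheobase).
    Returns ``(rheobase_uA, chronaxie_us)``.
    """
    durations = np.asarray(durations, dtype=np.float64)
    thr = np.asarray(thresholds, dtype=np.float64)
    if durations.size < 3:
        raise ValueError("need at least 3 durations")
    x = 1.0 / durations
    coeffs = np.polyfit(x, thr, 1)
    slope, intercept = coeffs[0], coeffs[1]
    if intercept <= 0:
        raise ValueError("negative rheobase intercept: strength-duration data "
                         "do not follow the inverse-duration law")
    return float(intercept), float(slope / intercept)
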