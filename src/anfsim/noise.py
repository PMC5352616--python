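"""Gaussian 1/f^α membrane-noise synthesis.

The membrane noise current of each axon is a zero-mean Gaussian process whose
power spectral density falls as 1/f^α.  α = 0 gives white noise; α = 1 or 2
give spectra decaying at 3 or 6 dB per octave.  Synthesis is by frequency-
domain shaping: a white Gaussian sequence is Fourier transformed, each bin is
weighted by f^(−α/2) (DC zeroed), and the result is inverse transformed and
rescaled to the requested standard deviation.  Linear filtering preserves
Gaussianity, and the rescale makes the sample SD exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NoiseSpec", "generate_noise", "psd_slope"]


@dataclass(frozen=True)
class NoiseSpec:
    """Spectral exponent, target SD (μA) and RNG seed for one noise stream."""

    alpha: float = 0.8
    sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def generate_noise(n_samples: int, dt: float, spec: NoiseSpec,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Synthesize one noise-current series of ``n_samples`` steps (μA).

    ``rng`` overrides ``spec.seed`` when given (used for per-trial streams).
    The returned series has mean exactly 0 (DC bin removed) and sample SD
    exactly ``spec.sigma``.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be at least 2")
    if spec.sigma == 0.0:
        return np.zeros(n_samples)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    white = rng.standard_normal(n_samples)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=dt)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-spec.alpha / 2.0)
    series = np.fft.irfft(spectrum * shaping, n=n_samples)
    sd = series.std()
    if sd == 0.0:  # pathological draw; cannot occur with sigma > 0 in practice
        raise RuntimeError("degenerate noise draw")
    return series * (spec.sigma / sd)


def psd_slope(series: np.ndarray, dt: float) -> float:
    """Least-squares slope of the log-periodogram vs log-frequency (DC excluded).

    For 1/f^α noise the expected slope is −α.  Raises on (near-)constant input,
    for which the periodogram is degenerate.
    """
    series = np.asarray(series, dtype=np.float64)
    if series.size < 256:
        raise ValueError("need at least 256 samples to estimate a spectral slope")
    if np.ptp(series) == 0:
        raise ValueError("constant series has no defined spectral slope")
    power = np.abs(np.fft.rfft(series)) ** 2
    freqs = np.fft.rfftfreq(series.size, d=dt)
    keep = (freqs > 0) & (power > 0)
    logf = np.log10(freqs[keep])
    logp = np.log10(power[keep])
    slope = np.polyfit(logf, logp, 1)[0]
    return float(slope)
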