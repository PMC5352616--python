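"""Stimulus waveform synthesis for cochlear-implant style pulsatile stimulation.

All waveforms are sampled extracellular current in microamperes on a fixed
time grid (default 1 μs).  Sign convention: positive samples are anodic
current, negative samples cathodic.  Charge-balanced shapes (symmetric
biphasic, pseudomonophasic) sum to zero charge by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

DEFAULT_DT = 1.0            # μs, integration grid shared with the Euler engine
DEFAULT_PRE_PAD = 1000.0    # μs of silence before stimulus onset
DEFAULT_POST_PAD = 3000.0   # μs of silence after stimulus offset

__all__ = [
    "StimulusWaveform",
    "PulseSpec",
    "make_monophasic",
    "make_biphasic",
    "make_pseudomonophasic",
    "make_paired",
    "make_pulse_train",
]


@dataclass(frozen=True)
class StimulusWaveform:
    """Sampled current waveform.

    Attributes
    ----------
    samples : ndarray
        Current per time step, μA.
    dt : float
        Step duration, μs.
    t0 : float
        Time of stimulus onset within the buffer, μs.
    markers : dict
        Named onset times (μs, buffer coordinates), e.g. probe onset in a
        paired-pulse stimulus.
    """

    samples: np.ndarray
    dt: float = DEFAULT_DT
    t0: float = DEFAULT_PRE_PAD
    markers: dict = field(default_factory=dict)

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(samples)):
            raise ValueError("waveform samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Total buffer duration, μs."""
        return self.n_samples * self.dt

    @property
    def times(self) -> np.ndarray:
        """Sample times (left edges), μs."""
        return np.arange(self.n_samples) * self.dt

    @property
    def charge(self) -> float:
        """Net charge, μA·μs (pC)."""
        return float(self.samples.sum() * self.dt)

    def scaled(self, factor: float) -> "StimulusWaveform":
        """Linearly scale the current; used by level sweeps."""
        return replace(self, samples=self.samples * factor)

    def to_csv(self, path) -> None:
        """Two-column CSV export: time_us, current_uA."""
        np.savetxt(
            path,
            np.column_stack([self.times, self.samples]),
            delimiter=",",
            header="time_us,current_uA",
            comments="",
        )


@dataclass(frozen=True)
class PulseSpec:
    """Specification of a single stimulus pulse.

    ``amplitude`` is the magnitude of the leading phase (μA, positive);
    polarity is carried by ``leading_polarity``.
    """

    shape: str                      # monophasic | biphasic | biphasic_ipg | pseudomonophasic
    leading_polarity: str           # anodic | cathodic
    ppd1: float                     # leading phase duration, μs
    ppd2: float = 0.0               # second phase duration, μs
    ipg: float = 0.0                # interphase gap, μs
    amplitude: float = 1.0          # leading phase magnitude, μA

    def __post_init__(self):
        if self.shape not in {"monophasic", "biphasic", "biphasic_ipg", "pseudomonophasic"}:
            raise ValueError(f"unknown pulse shape {self.shape!r}")
        if self.leading_polarity not in {"anodic", "cathodic"}:
            raise ValueError(f"unknown polarity {self.leading_polarity!r}")
        if self.ppd1 <= 0:
            raise ValueError("ppd1 must be positive")
        if self.shape != "monophasic" and self.ppd2 <= 0:
            raise ValueError("ppd2 must be positive for two-phase shapes")
        if self.ipg < 0:
            raise ValueError("ipg must be non-negative")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive (polarity is leading_polarity)")

    @property
    def leading_sign(self) -> float:
        return 1.0 if self.leading_polarity == "anodic" else -1.0

    def flipped(self) -> "PulseSpec":
        other = "cathodic" if self.leading_polarity == "anodic" else "anodic"
        return replace(self, leading_polarity=other)


def _n_steps(duration: float, dt: float, name: str) -> int:
    n = duration / dt
    n_round = round(n)
    if abs(n - n_round) > 1e-9 or n_round < 0:
        raise ValueError(
            f"{name}={duration} μs is not a multiple of the time grid dt={dt} μs"
        )
    return int(n_round)


def _assemble(phases, dt, pre_pad, post_pad):
    """Concatenate (n_steps, amplitude) phase segments with padding."""
    n_pre = _n_steps(pre_pad, dt, "pre_pad")
    n_post = _n_steps(post_pad, dt, "post_pad")
    body = np.concatenate([np.full(n, a) for n, a in phases]) if phases else np.empty(0)
    samples = np.concatenate([np.zeros(n_pre), body, np.zeros(n_post)])
    return StimulusWaveform(samples=samples, dt=dt, t0=n_pre * dt)


def make_monophasic(spec: PulseSpec, dt: float = DEFAULT_DT, *,
                    pre_pad: float = DEFAULT_PRE_PAD,
                    post_pad: float = DEFAULT_POST_PAD) -> StimulusWaveform:
    """Rectangular monophasic pulse of a single polarity."""
    if spec.shape != "monophasic":
        raise ValueError(f"spec.shape={spec.shape!r}, expected 'monophasic'")
    n1 = _n_steps(spec.ppd1, dt, "ppd1")
    return _assemble([(n1, spec.leading_sign * spec.amplitude)], dt, pre_pad, post_pad)


def make_biphasic(spec: PulseSpec, dt: float = DEFAULT_DT, *,
                  pre_pad: float = DEFAULT_PRE_PAD,
                  post_pad: float = DEFAULT_POST_PAD) -> StimulusWaveform:
    """Symmetric charge-balanced biphasic pulse, optionally with an interphase gap."""
    if spec.shape not in {"biphasic", "biphasic_ipg"}:
        raise ValueError(f"spec.shape={spec.shape!r}, expected 'biphasic' or 'biphasic_ipg'")
    if spec.ppd2 != spec.ppd1:
        raise ValueError(
            f"symmetric biphasic pulse requires ppd2 == ppd1 (got ppd1={spec.ppd1}, ppd2={spec.ppd2})"
        )
    n1 = _n_steps(spec.ppd1, dt, "ppd1")
    ng = _n_steps(spec.ipg, dt, "ipg")
    a = spec.leading_sign * spec.amplitude
    return _assemble([(n1, a), (ng, 0.0), (n1, -a)], dt, pre_pad, post_pad)


def make_pseudomonophasic(spec: PulseSpec, dt: float = DEFAULT_DT, *,
                          pre_pad: float = DEFAULT_PRE_PAD,
                          post_pad: float = DEFAULT_POST_PAD) -> StimulusWaveform:
    """Charge-balanced pulse with a short leading phase and a longer, lower-amplitude
    second phase of the opposite polarity (second amplitude = amplitude·ppd1/ppd2)."""
    if spec.shape != "pseudomonophasic":
        raise ValueError(f"spec.shape={spec.shape!r}, expected 'pseudomonophasic'")
    if spec.ppd2 < spec.ppd1:
        raise ValueError(
            f"pseudomonophasic second phase must be at least as long as the leading "
            f"phase (ppd1={spec.ppd1}, ppd2={spec.ppd2})"
        )
    n1 = _n_steps(spec.ppd1, dt, "ppd1")
    ng = _n_steps(spec.ipg, dt, "ipg")
    n2 = _n_steps(spec.ppd2, dt, "ppd2")
    a = spec.leading_sign * spec.amplitude
    a2 = -a * spec.ppd1 / spec.ppd2
    return _assemble([(n1, a), (ng, 0.0), (n2, a2)], dt, pre_pad, post_pad)


def make_pulse(spec: PulseSpec, dt: float = DEFAULT_DT, **kw) -> StimulusWaveform:
    """Dispatch on ``spec.shape``."""
    maker = {
        "monophasic": make_monophasic,
        "biphasic": make_biphasic,
        "biphasic_ipg": make_biphasic,
        "pseudomonophasic": make_pseudomonophasic,
    }[spec.shape]
    return maker(spec, dt, **kw)


def make_paired(pulse: StimulusWaveform, conditioner_scale: float,
                probe_scale: float, delay: float, *,
                allow_overlap: bool = False) -> StimulusWaveform:
    """Conditioner + probe pair built from one pulse template.

    The template's active region (from ``t0`` to the last nonzero sample) is
    placed at the conditioner onset and again at ``delay`` μs later, scaled by
    ``conditioner_scale`` and ``probe_scale`` respectively.  ``delay`` is
    onset-to-onset.  Marker ``probe_onset`` records the probe onset time.
    """
    if delay < 0:
        raise ValueError("delay must be non-negative")
    dt = pulse.dt
    d_steps = _n_steps(delay, dt, "delay")
    i0 = _n_steps(pulse.t0, dt, "t0")
    nz = np.nonzero(pulse.samples)[0]
    pulse_len = (nz[-1] - i0 + 1) if nz.size else 0
    if not allow_overlap and d_steps < pulse_len:
        raise ValueError(
            f"delay {delay} μs overlaps the {pulse_len * dt} μs pulse; "
            "pass allow_overlap=True to permit superposition"
        )
    n = max(pulse.n_samples, i0 + d_steps + (pulse.n_samples - i0))
    samples = np.zeros(n)
    samples[: pulse.n_samples] += conditioner_scale * pulse.samples
    samples[i0 + d_steps:] += probe_scale * pulse.samples[i0: i0 + (n - i0 - d_steps)]
    markers = {"conditioner_onset": pulse.t0, "probe_onset": pulse.t0 + delay}
    return StimulusWaveform(samples=samples, dt=dt, t0=pulse.t0, markers=markers)


def make_pulse_train(pulse: StimulusWaveform, rate: float, duration: float,
                     *, post_pad: float = 1000.0) -> StimulusWaveform:
    """Periodic train of identical pulses.

    Parameters
    ----------
    rate : float
        Pulse rate, pulses per second.
    duration : float
        Train duration, ms.  The number of pulse onsets is
        ``round(duration_s × rate)`` and onsets are placed at the grid point
        nearest ``k/rate``.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    dt = pulse.dt
    period_us = 1e6 / rate
    i0 = _n_steps(pulse.t0, dt, "t0")
    nz = np.nonzero(pulse.samples)[0]
    pulse_len = (nz[-1] - i0 + 1) if nz.size else 0
    if period_us < pulse_len * dt - 1e-9:
        max_rate = 1e6 / (pulse_len * dt)
        raise ValueError(
            f"pulses of {pulse_len * dt} μs overlap at {rate} pps; "
            f"maximum feasible rate is {max_rate:.0f} pps"
        )
    n_pulses = int(round(duration * 1e-3 * rate))
    body = np.zeros(int(round(duration * 1e3 / dt)) + pulse_len)
    template = pulse.samples[i0: i0 + pulse_len] if pulse_len else np.empty(0)
    onsets = []
    for k in range(n_pulses):
        j = int(round(k * period_us / dt))
        body[j: j + pulse_len] += template
        onsets.append(j * dt + pulse.t0)
    samples = np.concatenate(
        [np.zeros(i0), body, np.zeros(_n_steps(post_pad, dt, "post_pad"))]
    )
    markers = {"pulse_onsets": np.asarray(onsets), "train_duration_us": duration * 1e3}
    return StimulusWaveform(samples=samples, dt=dt, t0=pulse.t0, markers=markers)


def db_to_scale(db: float) -> float:
    """dB re a reference current amplitude → linear scale factor (20·log10)."""
    return 10.0 ** (db / 20.0)
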