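"""Single-axon exponential integrate-and-fire dynamics.

Each axon of the fiber is a point neuron obeying

    C dV/dt = h(V) − I_sub − I_supra + I_noise + I_stim
    h(V)    = −g_L (V − E_L) + g_L ΔT exp((V − v_threshold)/ΔT)
    τ_sub   dI_sub/dt   = a_sub   (V − E_L) − I_sub
    τ_supra dI_supra/dt = a_supra (V − E_L) − I_supra

advanced by forward Euler.  Crossing v_threshold does not itself signal a
spike: the exponential term then drives the voltage upward, and a spike is
registered only when V reaches v_peak, after which V is reset to v_reset.
A strong opposing current delivered during the upswing can still pull the
voltage back below threshold, cancelling the developing spike.

Units are mV–μs–nF–mS–μA, which are mutually consistent
(nF·mV/μs = μA = mS·mV), so the standard cat-fiber parameter values are used
verbatim.

This module is the readable reference implementation used by unit tests and
the convergence checks; the fiber-level simulator runs an equivalent fused
loop (see :mod:`anfsim.engine`) for speed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

__all__ = ["AxonParams", "AxonState", "h_of_v", "step", "detect_and_reset",
           "resting_state"]

# Margin above v_peak at which the exponential argument is clamped to avoid
# overflow.  Unreachable below v_peak, so dynamics are unaffected.
EXP_CLAMP_MARGIN = 20.0  # mV


@dataclass(frozen=True)
class AxonParams:
    """Membrane and adaptation constants of one axon."""

    g_L: float          # membrane conductance, mS
    C: float            # membrane capacitance, nF
    delta_T: float      # slope factor of the exponential upswing, mV
    E_L: float          # resting potential, mV
    v_threshold: float  # threshold potential (exponential knee), mV
    v_peak: float       # spike-detection voltage, mV
    v_reset: float      # post-spike reset voltage, mV
    tau_sub: float      # subthreshold adaptation time constant, μs
    tau_supra: float    # suprathreshold adaptation time constant, μs
    a_sub: float        # subthreshold adaptation conductance, mS
    a_supra: float      # suprathreshold adaptation conductance, mS

    def __post_init__(self):
        for name in ("g_L", "C", "delta_T", "tau_sub", "tau_supra"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("a_sub", "a_supra"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (self.v_reset < self.v_threshold < self.v_peak):
            raise ValueError("require v_reset < v_threshold < v_peak")

    @property
    def tau_m(self) -> float:
        """Passive membrane time constant C/g_L, μs."""
        return self.C / self.g_L

    @property
    def exp_arg_cap(self) -> float:
        return (self.v_peak - self.v_threshold + EXP_CLAMP_MARGIN) / self.delta_T


@dataclass
class AxonState:
    """Instantaneous state advanced by the Euler stepper."""

    V: float            # membrane potential, mV
    I_sub: float = 0.0  # subthreshold adaptation current, μA
    I_supra: float = 0.0
    t: float = 0.0      # μs


def h_of_v(V: float, p: AxonParams) -> float:
    """Passive leak plus exponential spike-initiation current, μA."""
    arg = (V - p.v_threshold) / p.delta_T
    arg = min(arg, p.exp_arg_cap)
    return -p.g_L * (V - p.E_L) + p.g_L * p.delta_T * np.exp(arg)


def step(state: AxonState, I_stim: float, I_noise: float, dt: float,
         p: AxonParams, stim_gated: bool = False) -> AxonState:
    """One forward-Euler update.

    During the post-spike dead time the caller sets ``stim_gated``: the
    stimulus drive is removed while noise and the adaptation currents keep
    integrating.  The returned voltage is capped at v_peak; spike detection
    and reset are the caller's job (:func:`detect_and_reset`).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    stim = 0.0 if stim_gated else I_stim
    dV = (h_of_v(state.V, p) - state.I_sub - state.I_supra + I_noise + stim) / p.C
    V = state.V + dt * dV
    I_sub = state.I_sub + dt * (p.a_sub * (state.V - p.E_L) - state.I_sub) / p.tau_sub
    I_supra = state.I_supra + dt * (p.a_supra * (state.V - p.E_L) - state.I_supra) / p.tau_supra
    V = min(V, p.v_peak)
    new = AxonState(V=V, I_sub=I_sub, I_supra=I_supra, t=state.t + dt)
    if not (np.isfinite(V) and np.isfinite(I_sub) and np.isfinite(I_supra)):
        raise FloatingPointError(f"non-finite axon state at t={new.t} μs")
    return new


def detect_and_reset(state: AxonState, p: AxonParams):
    """Spike test at v_peak; on a spike the voltage is reset to v_reset while
    both adaptation currents carry over unchanged.

    Returns ``(spiked, spike_time, state)``.
    """
    if state.V >= p.v_peak:
        return True, state.t, replace_state(state, V=p.v_reset)
    return False, None, state


def replace_state(state: AxonState, **kw) -> AxonState:
    return replace(state, **kw)


def resting_state(p: AxonParams) -> AxonState:
    """Zero-noise fixed point of the full system.

    Setting all time derivatives to zero gives
    ``h(V*) = (a_sub + a_supra)(V* − E_L)`` with the adaptation currents at
    their steady values ``a·(V* − E_L)``.  The root below v_threshold is the
    stable resting point used to initialize every simulation.
    """
    g = lambda V: h_of_v(V, p) - (p.a_sub + p.a_supra) * (V - p.E_L)
    lo = p.E_L - 10.0
    hi = p.v_threshold - 1e-6
    if g(lo) * g(hi) > 0:
        # no sign change (e.g. degenerate tangent case): scan for a bracket
        vs = np.linspace(lo, hi, 2001)
        gs = np.array([g(v) for v in vs])
        idx = np.nonzero(np.sign(gs[:-1]) * np.sign(gs[1:]) < 0)[0]
        if idx.size == 0:
            # fall back to the minimum-|g| point
            v_star = float(vs[np.argmin(np.abs(gs))])
        else:
            v_star = brentq(g, vs[idx[0]], vs[idx[0] + 1])
    else:
        v_star = brentq(g, lo, hi)
    dv = v_star - p.E_L
    return AxonState(V=float(v_star), I_sub=p.a_sub * dv, I_supra=p.a_supra * dv, t=0.0)
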