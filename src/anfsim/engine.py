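"""Fused forward-Euler loop for the two-axon fiber.

Semantically identical to stepping two :mod:`anfsim.axon` neurons on a common
clock with the fiber-level couplings (OR gate, shared spike-triggered
adaptation offset, post-spike stimulus gate); unit tests assert parity with
the reference stepper.  JIT-compiled with numba when available.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

SRC_PERIPHERAL = 0
SRC_CENTRAL = 1


@njit(cache=True)
def run_fiber(stim_p, stim_c, noise_p, noise_c, dt,
              # peripheral axon constants
              gl_p, c_p, dT_p, el_p, vth_p, vpk, vrs_p, tsub_p, tsupra_p,
              asub_p, asupra_p, cap_p,
              # central axon constants
              gl_c, c_c, dT_c, el_c, vth_c, vrs_c, tsub_c, tsupra_c,
              asub_c, asupra_c, cap_c,
              # initial states (V, I_sub, I_supra) per axon
              v0_p, isub0_p, isupra0_p, v0_c, isub0_c, isupra0_c,
              # fiber couplings
              b, dead_steps):
    """Advance both axons over the whole buffer; return spike indices/sources.

    A fiber spike is recorded when either axon's voltage reaches v_peak
    outside the dead time.  The spiking axon is reset to its v_reset, the
    offset ``b`` is added to the suprathreshold adaptation current of BOTH
    axons, and the stimulus input to both axons is removed for ``dead_steps``
    Euler steps while noise and adaptation keep integrating.  An axon that
    reaches v_peak inside the dead time is silently reset (no fiber event:
    the fiber is absolutely refractory).
    """
    n = stim_p.shape[0]
    max_spikes = n // (dead_steps + 1) + 2
    spike_idx = np.empty(max_spikes, dtype=np.int64)
    sources = np.empty(max_spikes, dtype=np.int8)
    n_spikes = 0

    vp, isubp, isuprap = v0_p, isub0_p, isupra0_p
    vc, isubc, isuprac = v0_c, isub0_c, isupra0_c
    last_spike = -(dead_steps + 1)  # index units; far in the past

    for j in range(n):
        gated = (j - last_spike) < dead_steps
        sp = 0.0 if gated else stim_p[j]
        sc = 0.0 if gated else stim_c[j]

        # peripheral update (all terms use start-of-step state)
        arg = (vp - vth_p) / dT_p
        if arg > cap_p:
            arg = cap_p
        h = -gl_p * (vp - el_p) + gl_p * dT_p * np.exp(arg)
        vp_new = vp + dt * (h - isubp - isuprap + noise_p[j] + sp) / c_p
        isubp = isubp + dt * (asub_p * (vp - el_p) - isubp) / tsub_p
        isuprap = isuprap + dt * (asupra_p * (vp - el_p) - isuprap) / tsupra_p

        # central update
        arg = (vc - vth_c) / dT_c
        if arg > cap_c:
            arg = cap_c
        h = -gl_c * (vc - el_c) + gl_c * dT_c * np.exp(arg)
        vc_new = vc + dt * (h - isubc - isuprac + noise_c[j] + sc) / c_c
        isubc = isubc + dt * (asub_c * (vc - el_c) - isubc) / tsub_c
        isuprac = isuprac + dt * (asupra_c * (vc - el_c) - isuprac) / tsupra_c

        crossed_p = vp_new >= vpk
        crossed_c = vc_new >= vpk
        k = j + 1
        if crossed_p or crossed_c:
            if (k - last_spike) >= dead_steps or last_spike < 0:
                # fiber spike via the OR gate
                if crossed_p and crossed_c:
                    src = SRC_PERIPHERAL if vp_new >= vc_new else SRC_CENTRAL
                elif crossed_p:
                    src = SRC_PERIPHERAL
                else:
                    src = SRC_CENTRAL
                spike_idx[n_spikes] = k
                sources[n_spikes] = src
                n_spikes += 1
                isuprap += b
                isuprac += b
                last_spike = k
            # reset every axon that ran away (recorded or refractory)
            if crossed_p:
                vp_new = vrs_p
            if crossed_c:
                vc_new = vrs_c
        if vp_new > vpk:
            vp_new = vpk
        if vc_new > vpk:
            vc_new = vpk
        vp, vc = vp_new, vc_new

        if not (np.isfinite(vp) and np.isfinite(vc)
                and np.isfinite(isubp) and np.isfinite(isuprap)
                and np.isfinite(isubc) and np.isfinite(isuprac)):
            raise FloatingPointError("non-finite fiber state")

    return spike_idx[:n_spikes], sources[:n_spikes]
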