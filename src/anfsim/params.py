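"""Default model constants for the cat auditory nerve fiber.

The membrane, adaptation and fiber-level constants are the published values
for the dual-site model (peripheral and central axon).  Two quantities are
not published as numbers and ship here as package calibrations (see
docs/methods.md):

* the per-axon noise SDs ``sigma`` — chosen with scripts/calibrate_noise.py so
  that the relative spread of the firing-efficiency function for 39-μs
  monophasic pulses falls in the range measured in cat fibers for each
  polarity;
* the spike-triggered suprathreshold adaptation offset ``b`` — chosen with
  scripts/calibrate_b.py so that 1000-pps pulse-train responses at +1 dB show
  a dominant onset followed by a sustained-rate reduction in the adaptive
  peri-stimulus time histogram.
"""

from __future__ import annotations

from .axon import AxonParams
from .fiber import FiberParams
from .noise import NoiseSpec

__all__ = ["PERIPHERAL", "CENTRAL", "default_fiber_params",
           "NOISE_SIGMA_PERIPHERAL", "NOISE_SIGMA_CENTRAL", "NOISE_ALPHA",
           "ADAPT_OFFSET_B"]

#: Peripheral axon — cathodically excited, slower membrane, longer latencies.
PERIPHERAL = AxonParams(
    g_L=1.1,            # mS
    C=856.96,           # nF
    delta_T=10.0,       # mV
    E_L=-80.0,          # mV
    v_threshold=-70.0,  # mV
    v_peak=24.0,        # mV
    v_reset=-84.0,      # mV
    tau_sub=250.0,      # μs
    tau_supra=4500.0,   # μs
    a_sub=2.0,          # mS
    a_supra=3.0,        # mS
)

#: Central axon — anodically excited, faster membrane, shorter latencies.
CENTRAL = AxonParams(
    g_L=2.7,
    C=1772.4,
    delta_T=4.0,
    E_L=-80.0,
    v_threshold=-70.0,
    v_peak=24.0,
    v_reset=-84.0,
    tau_sub=250.0,
    tau_supra=2500.0,
    a_sub=2.0,
    a_supra=3.0,
)

NOISE_ALPHA = 0.8       # spectral exponent of the membrane noise

# Package calibrations (μA); see module docstring and docs/methods.md.
NOISE_SIGMA_PERIPHERAL = 9.0
NOISE_SIGMA_CENTRAL = 16.5
ADAPT_OFFSET_B = 20.0

BETA = 0.75             # inhibitory compression of the opposing polarity
DEAD_TIME = 500.0       # μs, post-spike stimulus gate


def default_fiber_params(*, sigma_peripheral: float = NOISE_SIGMA_PERIPHERAL,
                         sigma_central: float = NOISE_SIGMA_CENTRAL,
                         b: float = ADAPT_OFFSET_B,
                         beta: float = BETA,
                         dead_time: float = DEAD_TIME,
                         alpha: float = NOISE_ALPHA) -> FiberParams:
    """Fiber parameters with the published constants and package calibrations."""
    return FiberParams(
        peripheral=PERIPHERAL,
        central=CENTRAL,
        beta=beta,
        b=b,
        dead_time=dead_time,
        noise_peripheral=NoiseSpec(alpha=alpha, sigma=sigma_peripheral),
        noise_central=NoiseSpec(alpha=alpha, sigma=sigma_central),
    )
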