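"""Calibration of the spike-triggered suprathreshold adaptation offset ``b``.

``b`` is the increment added to the suprathreshold adaptation current of both
axons at every fiber spike; the published parameter set introduces the offset
but does not print its magnitude.  The package default was chosen with this
script against the documented pulse-train behavior of the model at 1000 pps,
+1 dB re single-pulse threshold:

* the first (0–4 ms) window of the adaptive PSTH must dominate all later
  windows (strong onset), followed by a substantially reduced sustained rate;
* the pooled ISI histogram at that condition peaks near 5 ms rather than at
  the 1-ms pulse period (the fiber skips pulses in the sustained response).

Run:  python scripts/calibrate_b.py [--n-reps 24] [--seed 5]
"""

import argparse

import numpy as np

from anfsim.experiments import train_apsth, train_isi
from anfsim.params import default_fiber_params


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--n-reps", type=int, default=24)
    ap.add_argument("--seed", type=int, default=5)
    ap.add_argument("--b-values", type=float, nargs="+",
                    default=[10, 20, 40, 80])
    args = ap.parse_args()

    for b in args.b_values:
        p = default_fiber_params(b=b)
        centers, rates = train_apsth(1000.0, 1.0, p, n_reps=args.n_reps,
                                     seed=args.seed)
        bins, counts = train_isi(1000.0, 1.0, p, n_reps=args.n_reps,
                                 seed=args.seed + 1)
        mode_ms = bins[np.argmax(counts)] + 0.5 if counts.sum() else np.nan
        onset = rates[0]
        sustained = rates[-1]
        print(f"b={b:6.1f} μA  aPSTH onset={onset:7.1f} sp/s  "
              f"sustained={sustained:7.1f} sp/s  ratio={onset / max(sustained, 1e-9):6.2f}  "
              f"ISI mode~{mode_ms:.1f} ms  windows={np.round(rates, 0)}")


if __name__ == "__main__":
    main()
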