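"""Steady-state firing-rate heterogeneity and response linearity.

Runs the three homeostatic conditions (diffusive, non-diffusive,
non-diffusive with variable targets) to steady state at desk scale,
then freezes homeostasis and redraws the inputs to measure response
linearity.  Writes per-neuron rate/threshold tables and a condition
summary under results/.

Expected outcome: the diffusive network keeps a broad, right-skewed rate
distribution with near-uniform thresholds and the most linear response;
the non-diffusive network collapses the rate distribution and responds
nonlinearly; variable targets restore breadth but not linearity.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from diffhomeo.experiments import REDUCED, experiment_steady_and_linearity


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    res = experiment_steady_and_linearity(seed=args.seed, scale=REDUCED)

    rows, details = [], []
    for mode, r in res.items():
        s = r["rate_summary"]
        rows.append(dict(
            condition=mode, seed=args.seed, n=REDUCED.n,
            rate_mean_hz=s.mean, rate_variance=s.variance, rate_skewness=s.skewness,
            threshold_sd_mv=float(r["thresholds"].std()),
            r2=r["r2"],
            pop_rate_before=r["pop_rate_before"], pop_rate_after=r["pop_rate_after"],
        ))
        details.append(pd.DataFrame(dict(
            condition=mode, neuron=np.arange(REDUCED.n),
            input_hz=r["drive"].rates, rate_hz=s.rates,
            threshold_mv=r["thresholds"], dmu=r["dmu"], dnu=r["dnu"],
        )))

    summary = pd.DataFrame(rows)
    summary.to_csv(args.out / "steady_state_summary.csv", index=False)
    pd.concat(details).to_csv(args.out / "steady_state_neurons.csv", index=False)
    print(summary.to_string(index=False))
    print("\nKey contrasts: rate variance (diffusive vs non-diffusive), "
          "R2 ordering, and the population-rate jump after input redraw "
          "(non-diffusive only).")


if __name__ == "__main__":
    main()
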