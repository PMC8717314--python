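"""Posterior predictive check of the fitted growth model.

Loads the posterior draws and the interval data, simulates replicate
increment datasets draw by draw, and reports the sum-of-squares Bayesian
p-value (≈0.5 indicates an adequate model; near 0 or 1 flags misfit).

Usage: python analysis/04_posterior_check.py [--fit DIR] [--intervals PATH] [--seed N]
"""

import argparse
import json
import os
import sys

from salgrowth import ModelData
from salgrowth.mcmc import PosteriorSamples
from salgrowth.ppc import bayesian_p_value


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--fit", default="results/fit")
    ap.add_argument("--intervals", default="results/intervals.csv")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default=None, help="default: <fit>/ppc.json")
    args = ap.parse_args(argv)

    data = ModelData.from_csv(args.intervals)
    samples = PosteriorSamples.load_csv(os.path.join(args.fit, "draws.csv"))
    result = bayesian_p_value(samples, data, seed=args.seed)

    out = args.out or os.path.join(args.fit, "ppc.json")
    with open(out, "w") as fh:
        json.dump(
            {"bayesian_p": result.bayesian_p, "n_draws_used": result.n_draws_used,
             "seed": args.seed}, fh, indent=1,
        )
    print(f"Bayesian p-value (sum of squares): {result.bayesian_p:.3f} "
          f"over {result.n_draws_used} draws")
    print("model adequate" if 0.05 <= result.bayesian_p <= 0.95 else "MISFIT FLAGGED")
    print(f"wrote {out}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
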