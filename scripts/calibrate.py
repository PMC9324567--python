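#!/usr/bin/env python
"""Calibrate species presets against their reference observables.

Grid-searches the per-species constants (diffusion of the a- and
s-objects, agitation, nutrient stock) so that the mean final population
of the limited-nutrient protocol matches the species' reference value
at its reference horizon (74 cells at 100 iterations, 76 at 150, 85 at
400). The search is two-stage: kinetic constants set the time scale of
the sigmoid, then the nutrient stock is bisected to set its plateau.

The shipped presets in msystems.mbac were produced with this procedure;
rerun it after any change to the rule inventory or engine dynamics.

Usage:  python scripts/calibrate.py --species ecoli --runs 10 --seed 1
"""

from __future__ import annotations

import argparse
import dataclasses

import numpy as np

from msystems.core import run
from msystems.mbac import build_mbac, preset

REFERENCE = {"ecoli": 74.0, "slactis": 76.0, "lacidophilus": 85.0}


def mean_final(params, n_runs: int, seed: int) -> float:
    finals = []
    for k in range(n_runs):
        res = run(build_mbac(params), params.target_iterations,
                  np.random.default_rng(seed * 1000 + k))
        finals.append(res.census["cells"].iloc[-1])
    return float(np.mean(finals))


def calibrate_budget(params, target: float, n_runs: int, seed: int,
                     lo: int = 800, hi: int = 4000, iters: int = 7):
    """Bisect the nutrient stock (initial ambient amount = budget) to
    hit the target mean final population."""
    best = None
    for _ in range(iters):
        mid = (lo + hi) // 2
        p = dataclasses.replace(params, nutrient_budget=mid, env_target=mid)
        m = mean_final(p, n_runs, seed)
        print(f"  stock {mid}: mean final {m:.1f}")
        best = (mid, m)
        if m < target:
            lo = mid
        else:
            hi = mid
    return best


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--species", default="ecoli", choices=sorted(REFERENCE))
    ap.add_argument("--runs", type=int, default=10)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args(argv)

    params = preset(args.species)
    target = REFERENCE[args.species]
    print(f"{args.species}: current preset gives "
          f"{mean_final(params, args.runs, args.seed):.1f} "
          f"(target {target} at {params.target_iterations} iterations)")
    stock, mean = calibrate_budget(params, target, args.runs, args.seed)
    print(f"best stock {stock} -> mean final {mean:.1f}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
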