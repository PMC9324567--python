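"""Injury operators and survival/recovery protocols.

An injury is an unprescribed transition: removing a tile (tearing a hole
in the membrane, with consequent loss of the protions it carried),
removing a protion alone, breaking a bond between attached tiles without
destroying them, or the sudden appearance of floating objects inside a
membrane. No repair-specific machinery exists: recovery uses only the
nine growth rules, re-assembling the missing parts the same way they
were first built.

Two protocols are implemented on single cells grown under unlimited
nutrients:

* sequential: injuries inflicted at random times to randomly chosen
  parts prior to septum division;
* simultaneous: all injuries inflicted at the same time, just before
  cell division (on the adult, septum-complete cell).

Survival means the injured cell still completes a division (adulthood
and reproduction) within three times the uninjured mean generation
time. The recovery ratio compares the injured generation time to the
uninjured mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import make_configuration, run, step
from .mbac import SpeciesParams, build_mbac

__all__ = [
    "Injury",
    "SurvivalEstimate",
    "INJURY_KINDS",
    "INJECTION_MULTISET",
    "inflict",
    "random_injury",
    "sample_component_injuries",
    "mean_generation_time",
    "survival_experiment",
    "recovery_time_experiment",
    "survival_sweep",
    "first_crossing_below",
    "RUN_CAP_FACTOR",
]

INJURY_KINDS = ("remove_tile", "remove_protion", "break_bond", "inject_floats")

#: objects dropped inside the cell by an inject_floats injury
INJECTION_MULTISET = {"a": 2, "s": 2}

#: survival cutoff: a run survives if it divides within this multiple of
#: the uninjured mean generation time
RUN_CAP_FACTOR = 3.0


@dataclass
class Injury:
    """One injury event.

    target: a tile id (remove_tile / remove_protion), a bond (frozenset
    of (tile id, connector) pairs) for break_bond, or a (compartment,
    multiset) pair for inject_floats (compartment None = random).
    time: iteration index for scheduled injuries or "simultaneous".
    """

    kind: str
    target: object = None
    time: int | str = "simultaneous"

    def __post_init__(self):
        if self.kind not in INJURY_KINDS:
            raise ValueError(f"unknown injury kind {self.kind!r}")


def inflict(cfg, sys, injury: Injury, rng: np.random.Generator | None = None):
    """Apply one injury to a configuration (in place, returns cfg).

    A missing target raises a KeyError naming the component. The
    resulting configuration may lie outside the normally reachable set.
    """
    asm = sys.assembly
    rng = rng or np.random.default_rng(0)
    if injury.kind == "remove_tile":
        asm.remove_tile(cfg, injury.target)
    elif injury.kind == "remove_protion":
        asm.remove_protion(cfg, injury.target)
    elif injury.kind == "break_bond":
        asm.break_bond(cfg, injury.target)
    elif injury.kind == "inject_floats":
        comp, multiset = injury.target if injury.target else (None, INJECTION_MULTISET)
        asm.inject_floats(cfg, sys, dict(multiset), rng, compartment=comp)
    return cfg


def sample_component_injuries(cfg, sys, k: int, rng: np.random.Generator) -> list[Injury]:
    """k simultaneous injuries to k distinct components of the cell.

    Each of the cell's components (tiles, rods included) can be hit
    once; a hit deletes the component, with consequent deletion of the
    protions placed on it. k equal to the component count removes the
    whole cell.
    """
    comps = sys.assembly.components(cfg)
    k = min(k, len(comps))
    chosen = rng.choice(len(comps), size=k, replace=False)
    return [Injury("remove_tile", comps[int(i)]) for i in chosen]


def random_injury(cfg, sys, rng: np.random.Generator) -> Injury | None:
    """Draw one random injury: kind uniform over the four kinds, target
    uniform over the currently eligible components of that kind (a kind
    with no eligible target is redrawn)."""
    asm = sys.assembly
    kinds = list(INJURY_KINDS)
    while kinds:
        kind = kinds[int(rng.integers(len(kinds)))]
        if kind == "remove_tile":
            targets = asm.components(cfg)
            if targets:
                return Injury(kind, targets[int(rng.integers(len(targets)))])
        elif kind == "remove_protion":
            targets = asm.protion_targets(cfg)
            if targets:
                return Injury(kind, targets[int(rng.integers(len(targets)))])
        elif kind == "break_bond":
            asm.ensure_bonds(cfg)
            bonds = sorted(cfg.active_bonds(), key=lambda b: sorted(b))
            if bonds:
                return Injury(kind, bonds[int(rng.integers(len(bonds)))])
        else:
            if asm.state(cfg).compartments:
                return Injury(kind, (None, INJECTION_MULTISET))
        kinds.remove(kind)
    return None


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------


def _grow_to_adult(sys, rng, max_iter: int):
    """Run from the seed until a complete, not-yet-divided septum exists
    (the adult, one step before division). Returns (cfg, t) or (cfg, None)."""
    cfg = make_configuration(sys)
    asm = sys.assembly
    for _ in range(max_iter):
        step(cfg, sys, rng)
        if asm.has_pending_division(cfg):
            return cfg, cfg.iteration
    return cfg, None


def _run_until_division(cfg, sys, rng, cap: int) -> int | None:
    """Continue until the first completed division; None if the cap (in
    total iterations) passes first."""
    asm = sys.assembly
    while cfg.iteration < cap:
        step(cfg, sys, rng)
        if asm.divisions(cfg) >= 1:
            return cfg.iteration
    return None


def mean_generation_time(
    params: SpeciesParams,
    n_runs: int = 20,
    rng: np.random.Generator | int | None = None,
    max_iter: int = 400,
) -> float:
    """Mean uninjured generation time (iterations from a single seeded
    tile to the first completed division) under unlimited nutrients."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    times = []
    for _ in range(n_runs):
        sys = build_mbac(params.injury_variant())
        sub = np.random.default_rng(int(rng.integers(2**31)))
        cfg = make_configuration(sys)
        t = _run_until_division(cfg, sys, sub, max_iter)
        if t is not None:
            times.append(t)
    if not times:
        raise RuntimeError("uninjured growth never divided within the iteration cap")
    return float(np.mean(times))


@dataclass
class SurvivalEstimate:
    n_injuries: int
    n_runs: int
    p_survive: float
    mean_recovery_ratio: float | None  # None: undefined (no survivors)

    def __post_init__(self):
        if not 0.0 <= self.p_survive <= 1.0:
            raise ValueError("p_survive must lie in [0, 1]")


def survival_experiment(
    params: SpeciesParams,
    n_injuries: int,
    schedule: str = "simultaneous_predivision",
    n_runs: int = 100,
    rng: np.random.Generator | int | None = None,
    g0: float | None = None,
    sampling: str = "components",
) -> SurvivalEstimate:
    """Estimate the survival probability under n_injuries random injuries.

    schedule "simultaneous_predivision": all injuries at once on the
    adult cell just before division. schedule "random_times": injuries
    at random times during growth, prior to septum division. Nutrients
    are unlimited in both. Survival = a completed division within
    RUN_CAP_FACTOR times the uninjured mean generation time.

    sampling "components": n distinct components are deleted (with
    consequent loss of their protions) — the simultaneous protocol over
    the adult's component inventory. sampling "kinds": each injury draws
    its kind uniformly over the four kinds and its target uniformly over
    the kind's eligible targets (with replacement across injuries).
    """
    if schedule not in ("simultaneous_predivision", "random_times"):
        raise ValueError(f"unknown schedule {schedule!r}")
    if sampling not in ("components", "kinds"):
        raise ValueError(f"unknown sampling {sampling!r}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if g0 is None:
        g0 = mean_generation_time(params, rng=np.random.default_rng(int(rng.integers(2**31))))
    cap = int(math.ceil(RUN_CAP_FACTOR * g0))
    survivors = 0
    ratios = []
    for _ in range(n_runs):
        sub = np.random.default_rng(int(rng.integers(2**31)))
        sys = build_mbac(params.injury_variant())
        if schedule == "simultaneous_predivision":
            cfg, t_adult = _grow_to_adult(sys, sub, cap)
            if t_adult is None:
                continue  # never reached adulthood: not a survivor
            if sampling == "components":
                for inj in sample_component_injuries(cfg, sys, n_injuries, sub):
                    if inj.target in cfg.tiles:  # may already be gone:
                        inflict(cfg, sys, inj, sub)  # detached with a neighbour

            else:
                for _k in range(n_injuries):
                    inj = random_injury(cfg, sys, sub)
                    if inj is None:
                        break
                    inflict(cfg, sys, inj, sub)
        else:
            cfg = make_configuration(sys)
            times = sorted(int(t) for t in sub.integers(1, max(int(g0), 2), n_injuries))
            pending = list(times)
            asm = sys.assembly
            while cfg.iteration < cap and asm.divisions(cfg) < 1:
                # remaining injuries land before division with a septum
                while pending and (
                    pending[0] <= cfg.iteration or asm.has_pending_division(cfg)
                ):
                    pending.pop(0)
                    inj = random_injury(cfg, sys, sub)
                    if inj is not None:
                        inflict(cfg, sys, inj, sub)
                step(cfg, sys, sub)
        if sys.assembly.divisions(cfg) >= 1:
            t_div = cfg.iteration
        else:
            t_div = _run_until_division(cfg, sys, sub, cap)
        if t_div is not None:
            survivors += 1
            ratios.append(t_div / g0)
    return SurvivalEstimate(
        n_injuries=n_injuries,
        n_runs=n_runs,
        p_survive=survivors / n_runs,
        mean_recovery_ratio=float(np.mean(ratios)) if ratios else None,
    )


def recovery_time_experiment(
    params: SpeciesParams,
    n_injuries: int,
    n_runs: int = 100,
    rng: np.random.Generator | int | None = None,
    g0: float | None = None,
    sampling: str = "components",
) -> float | None:
    """Mean ratio of injured to uninjured generation time, averaged over
    surviving runs only; None (undefined) when no run survives."""
    est = survival_experiment(
        params, n_injuries, "simultaneous_predivision", n_runs, rng, g0,
        sampling=sampling,
    )
    return est.mean_recovery_ratio


def survival_sweep(
    params: SpeciesParams,
    counts,
    n_runs: int = 100,
    rng: np.random.Generator | int | None = None,
    schedule: str = "simultaneous_predivision",
    sampling: str = "components",
) -> pd.DataFrame:
    """Survival estimates over a sweep of injury counts (shared uninjured
    baseline). Columns: n_injuries, p_survive, mean_recovery_ratio."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    g0 = mean_generation_time(params, rng=np.random.default_rng(int(rng.integers(2**31))))
    rows = []
    for k in counts:
        est = survival_experiment(params, int(k), schedule, n_runs, rng, g0,
                                  sampling=sampling)
        rows.append(
            {
                "n_injuries": est.n_injuries,
                "p_survive": est.p_survive,
                "mean_recovery_ratio": est.mean_recovery_ratio,
            }
        )
    return pd.DataFrame(rows)


def first_crossing_below(sweep: pd.DataFrame, threshold: float = 0.5) -> int | None:
    """Smallest injury count whose survival probability is below the
    threshold; None if survival never drops that far."""
    below = sweep[sweep["p_survive"] < threshold]
    return int(below["n_injuries"].min()) if len(below) else None
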