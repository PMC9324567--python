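"""The M-system formalism and discrete-time simulation engine.

An M system lives in continuous 3-D space and discrete time. It contains
floating objects (shapeless positioned particles), rigid tiles bonded
through glued connectors, and protions (channel/catalyst sites fixed on
tiles). Interactions are reaction rules of exactly four kinds —
metabolic (transport across a tile), creation (tile synthesis from
floating objects), destruction (tile annihilation), and division
(severing a completed septum) — every one an instance of the reaction
form u -> v on multisets of objects. Each iteration applies Brownian
motion to all floating objects first, then a maximal conflict-free
subset of applicable rule instances in an order randomized by the run's
generator; a reactant can be consumed by at most one instance. One
iteration corresponds to one simulated minute.

Where new tiles go and how compartments form is delegated to an
*assembly model* (`MSystem.assembly`): the engine owns time, motion,
transport, conflict resolution and bookkeeping, while the assembly model
owns slot geometry (where each creation rule may place its tile, what
counts as a completed septum). `mbac` supplies the bacterial chain
assembly; `SimpleCellAssembly` is a minimal static assembly used for
bench-top configurations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .geometry import Connector, Pose, TileShape, reflect_into_box

__all__ = [
    "FloatingObjectSpec",
    "GlueRelation",
    "ProtionSpec",
    "TileSpec",
    "MetabolicRule",
    "CreationRule",
    "DestructionRule",
    "DivisionRule",
    "Environment",
    "MSystem",
    "PlacedTile",
    "Floats",
    "Configuration",
    "RuleInstance",
    "applicable_instances",
    "step",
    "run",
    "SimulationResult",
    "SimpleCellAssembly",
    "ENV",
]

#: Location code of the environment (outside every compartment).
ENV = -1


# ---------------------------------------------------------------------------
# object specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FloatingObjectSpec:
    """A small shapeless object floating in the medium.

    mobility scales the per-iteration Brownian step (step = mobility *
    interaction radius); env_concentration is the ambient copy number the
    environment maintains while the nutrient budget lasts (0 for objects
    that are only produced internally).
    """

    name: str
    radius: float = 0.05
    mobility: float = 1.0
    env_concentration: float = 0.0

    def __post_init__(self):
        if self.radius < 0 or self.mobility < 0 or self.env_concentration < 0:
            raise ValueError(f"floating object {self.name!r}: negative parameter")


class GlueRelation:
    """Symmetric glue-match relation over glue labels."""

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()):
        self._pairs = frozenset(frozenset(p) for p in pairs)

    def matches(self, g1: str, g2: str) -> bool:
        return frozenset((g1, g2)) in self._pairs

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(p)) for p in self._pairs)


@dataclass(frozen=True)
class ProtionSpec:
    """A protein-like channel/catalyst at a fixed site on its host tile."""

    name: str
    site: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass(frozen=True)
class TileSpec:
    name: str
    shape: TileShape
    connectors: tuple[Connector, ...] = ()
    protions: tuple[ProtionSpec, ...] = ()

    def __post_init__(self):
        sites = [tuple(np.round(c.midpoint(), 9)) for c in self.connectors]
        if len(set(sites)) != len(sites):
            raise ValueError(f"tile {self.name!r}: connector sites must be distinct")


# ---------------------------------------------------------------------------
# the four rule kinds
# ---------------------------------------------------------------------------


def _as_multiset(m) -> dict[str, int]:
    out = dict(m)
    for k, v in out.items():
        if v < 1:
            raise ValueError(f"multiset count for {k!r} must be >= 1")
    return out


@dataclass(frozen=True)
class MetabolicRule:
    """Transport across a protion channel: consumed objects on one side
    of the host tile become the produced objects on the other side."""

    name: str
    protion: str
    consumed: Mapping[str, int]
    produced: Mapping[str, int]
    consumed_side: str = "out"
    produced_side: str = "in"

    def __post_init__(self):
        object.__setattr__(self, "consumed", _as_multiset(self.consumed))
        object.__setattr__(self, "produced", _as_multiset(self.produced))
        if sum(self.consumed.values()) < 1:
            raise ValueError(f"metabolic rule {self.name!r}: consumed must be nonempty")
        for s in (self.consumed_side, self.produced_side):
            if s not in ("in", "out"):
                raise ValueError(f"metabolic rule {self.name!r}: side must be in/out")


@dataclass(frozen=True)
class CreationRule:
    """Tile synthesis: floating objects near a matching free connector
    are consumed and a new tile of the given type attaches there."""

    name: str
    consumed: Mapping[str, int]
    tile: str
    at_glue: str

    def __post_init__(self):
        object.__setattr__(self, "consumed", _as_multiset(self.consumed))
        if sum(self.consumed.values()) < 1:
            raise ValueError(
                f"creation rule {self.name!r}: tiles can only be created from "
                "floating objects (consumed must be nonempty)"
            )


@dataclass(frozen=True)
class DestructionRule:
    """Tile annihilation. `tiles` is the family of tile types the rule
    annihilates (one rule may cover a family, e.g. all auxiliary rods)."""

    name: str
    tiles: tuple[str, ...]
    consumed: Mapping[str, int] = field(default_factory=dict)
    produced: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if isinstance(self.tiles, str):
            object.__setattr__(self, "tiles", (self.tiles,))
        else:
            object.__setattr__(self, "tiles", tuple(self.tiles))
        object.__setattr__(self, "consumed", dict(self.consumed))
        object.__setattr__(self, "produced", dict(self.produced))


@dataclass(frozen=True)
class DivisionRule:
    """Concludes cell division once septum formation is complete.

    The trigger is structural: the septum ring is a closed cycle in the
    bond graph and the wall bond graph minus the septum bonds has exactly
    two components. The assembly model evaluates it.
    """

    name: str = "division"


Rule = MetabolicRule | CreationRule | DestructionRule | DivisionRule


# ---------------------------------------------------------------------------
# system definition
# ---------------------------------------------------------------------------


@dataclass
class Environment:
    """Axis-aligned environment box and nutrient supply policy.

    The environment maintains each floating species at its
    env_concentration copy number by injecting objects every iteration,
    drawing on `nutrient_budget` total injections (None = unlimited).
    """

    box_lo: tuple[float, float, float]
    box_hi: tuple[float, float, float]
    nutrient_budget: int | None = None

    def __post_init__(self):
        lo, hi = np.asarray(self.box_lo, float), np.asarray(self.box_hi, float)
        if not np.all(hi > lo):
            raise ValueError("environment box must have positive extent")
        if self.nutrient_budget is not None and self.nutrient_budget < 0:
            raise ValueError("nutrient budget must be >= 0 or None")

    @property
    def lo(self) -> np.ndarray:
        return np.asarray(self.box_lo, float)

    @property
    def hi(self) -> np.ndarray:
        return np.asarray(self.box_hi, float)


@dataclass
class MSystem:
    """A complete M-system definition."""

    floating_specs: dict[str, FloatingObjectSpec]
    tile_specs: dict[str, TileSpec]
    glue_relation: GlueRelation
    rules: list[Rule]
    interaction_radius: float
    environment: Environment
    seed_tiles: list[tuple[str, Pose]] = field(default_factory=list)
    assembly: "object | None" = None

    def __post_init__(self):
        self.validate()

    def validate(self):
        if self.interaction_radius <= 0:
            raise ValueError("interaction radius must be > 0")
        protion_names = {
            p.name for t in self.tile_specs.values() for p in t.protions
        }
        for rule in self.rules:
            if isinstance(rule, MetabolicRule):
                if rule.protion not in protion_names:
                    raise ValueError(
                        f"rule {rule.name!r} references undeclared protion "
                        f"{rule.protion!r}"
                    )
                labels = set(rule.consumed) | set(rule.produced)
            elif isinstance(rule, CreationRule):
                if rule.tile not in self.tile_specs:
                    raise ValueError(
                        f"rule {rule.name!r} references undeclared tile {rule.tile!r}"
                    )
                labels = set(rule.consumed)
            elif isinstance(rule, DestructionRule):
                for t in rule.tiles:
                    if t not in self.tile_specs:
                        raise ValueError(
                            f"rule {rule.name!r} references undeclared tile {t!r}"
                        )
                labels = set(rule.consumed) | set(rule.produced)
            else:
                labels = set()
            missing = labels - set(self.floating_specs)
            if missing:
                raise ValueError(
                    f"rule {rule.name!r} references undeclared floating objects "
                    f"{sorted(missing)}"
                )
        for name, _pose in self.seed_tiles:
            if name not in self.tile_specs:
                raise ValueError(f"seed tile references undeclared tile {name!r}")

    @property
    def species_index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(sorted(self.floating_specs))}

    def rules_of(self, kind) -> list:
        return [r for r in self.rules if isinstance(r, kind)]


# ---------------------------------------------------------------------------
# configuration state
# ---------------------------------------------------------------------------


@dataclass
class PlacedTile:
    spec: str
    pose: Pose
    protion_alive: list[bool] = field(default_factory=list)


class Floats:
    """Positioned floating objects as flat arrays.

    species: integer codes per MSystem.species_index; loc: ENV (-1) for
    the environment or a compartment id. Additions are buffered and
    merged lazily so that indices into the arrays stay valid within one
    rule-application phase (new objects append at the end).
    """

    def __init__(self, n_species: int):
        self.pos = np.empty((0, 3), dtype=float)
        self.species = np.empty(0, dtype=np.int64)
        self.loc = np.empty(0, dtype=np.int64)
        self.n_species = n_species
        self._pending: list = []

    def add(self, species: int, positions: np.ndarray, loc: int = ENV):
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        self._pending.append((species, positions, loc))

    def flush(self):
        if not self._pending:
            return
        pos = [self.pos] + [p for _, p, _ in self._pending]
        sp = [self.species] + [
            np.full(len(p), s, dtype=np.int64) for s, p, _ in self._pending
        ]
        lc = [self.loc] + [
            np.full(len(p), l, dtype=np.int64) for _, p, l in self._pending
        ]
        self.pos = np.vstack(pos)
        self.species = np.concatenate(sp)
        self.loc = np.concatenate(lc)
        self._pending = []

    def remove(self, idx):
        self.flush()
        keep = np.ones(len(self.pos), dtype=bool)
        keep[np.asarray(idx, dtype=np.int64)] = False
        self.pos = self.pos[keep]
        self.species = self.species[keep]
        self.loc = self.loc[keep]

    def count(self, species: int | None = None, loc: int | None = None) -> int:
        self.flush()
        m = np.ones(len(self.pos), dtype=bool)
        if species is not None:
            m &= self.species == species
        if loc is not None:
            m &= self.loc == loc
        return int(m.sum())

    def __len__(self) -> int:
        self.flush()
        return len(self.pos)


@dataclass
class Configuration:
    """Complete simulation state: placed tiles and bonds, positioned
    floating objects, compartments, step counter."""

    tiles: dict[int, PlacedTile] = field(default_factory=dict)
    bonds: set = field(default_factory=set)           # frozenset({(id, conn_idx), ...})
    broken_bonds: set = field(default_factory=set)    # injured bonds pending re-glue
    floats: Floats | None = None
    iteration: int = 0
    next_tile_id: int = 0
    budget_remaining: int | None = None
    assembly_state: object | None = None   # owned by the assembly model
    # bookkeeping for the conservation invariant
    consumed_by_rules: dict[str, int] = field(default_factory=dict)
    produced_by_rules: dict[str, int] = field(default_factory=dict)
    injected: dict[str, int] = field(default_factory=dict)

    def place_tile(self, spec: TileSpec, pose: Pose) -> int:
        tid = self.next_tile_id
        self.tiles[tid] = PlacedTile(spec.name, pose, [True] * len(spec.protions))
        self.next_tile_id += 1
        return tid

    def tile_count(self) -> int:
        return len(self.tiles)

    def bond_count(self) -> int:
        return len(self.bonds - self.broken_bonds)

    def active_bonds(self) -> set:
        return self.bonds - self.broken_bonds


def make_configuration(sys: MSystem) -> Configuration:
    cfg = Configuration()
    cfg.floats = Floats(len(sys.floating_specs))
    cfg.budget_remaining = sys.environment.nutrient_budget
    for name, pose in sys.seed_tiles:
        cfg.place_tile(sys.tile_specs[name], pose)
    if sys.assembly is not None:
        sys.assembly.initialize(cfg, sys)
    return cfg


# ---------------------------------------------------------------------------
# rule instances and the engine
# ---------------------------------------------------------------------------


@dataclass
class RuleInstance:
    """One applicable (rule, bound objects) pair.

    float_idx: indices into cfg.floats of the reactant floating objects.
    token: assembly-model payload describing where/how to apply.
    """

    rule: Rule
    float_idx: tuple[int, ...] = ()
    site: np.ndarray | None = None
    compartment: int | None = None
    token: object = None


class _FloatIndex:
    """Per-step KD-tree lookup of floats by (species, side)."""

    def __init__(self, cfg: Configuration, sys: MSystem):
        cfg.floats.flush()
        self.cfg = cfg
        self.sys = sys
        self._trees: dict = {}

    def _tree(self, code: int, loc):
        key = (code, loc)
        if key not in self._trees:
            from scipy.spatial import cKDTree

            fl = self.cfg.floats
            m = fl.species == code
            if loc is not None:
                m = m & (fl.loc == loc)
            idx = np.nonzero(m)[0]
            tree = cKDTree(fl.pos[idx]) if len(idx) else None
            self._trees[key] = (tree, idx)
        return self._trees[key]

    def gather(self, need: Mapping[str, int], sites: np.ndarray, radius: float, loc):
        """For each site, reactant float indices for the multiset `need`
        within `radius` on side `loc` (None = any side), nearest-first;
        None where the site cannot be served."""
        sp = self.sys.species_index
        n_sites = len(sites)
        out: list[tuple | None] = [() for _ in range(n_sites)]
        for label, k in need.items():
            tree, idx = self._tree(sp[label], loc)
            if tree is None or len(idx) < k:
                return [None] * n_sites
            d, j = tree.query(sites, k=k, distance_upper_bound=radius)
            d = np.atleast_2d(d.reshape(n_sites, -1))
            j = np.atleast_2d(j.reshape(n_sites, -1))
            ok = np.all(np.isfinite(d), axis=1)
            for s in range(n_sites):
                if out[s] is None:
                    continue
                if not ok[s]:
                    out[s] = None
                else:
                    out[s] = out[s] + tuple(int(idx[x]) for x in j[s])
        return out


def applicable_instances(cfg: Configuration, sys: MSystem) -> list[RuleInstance]:
    """Every (rule, bound objects) instance whose reactants all lie
    within the interaction radius of the reaction site and satisfy the
    in/out side constraints."""
    r = sys.interaction_radius
    instances: list[RuleInstance] = []
    asm = sys.assembly
    if asm is None:
        return instances
    fidx = _FloatIndex(cfg, sys)

    # metabolic transport at protion channels (grouped by reactant side)
    for rule in sys.rules_of(MetabolicRule):
        sites = asm.metabolic_sites(cfg, sys, rule)
        if not sites:
            continue
        groups: dict = {}
        for tile_id, site, comp in sites:
            loc = comp if rule.consumed_side == "in" else ENV
            groups.setdefault(loc, []).append((tile_id, site, comp))
        for loc, grp in groups.items():
            pts = np.array([s for _, s, _ in grp])
            for (tile_id, site, comp), got in zip(grp, fidx.gather(rule.consumed, pts, r, loc)):
                if got is not None:
                    instances.append(RuleInstance(rule, got, site, comp, token=tile_id))

    # creation at open slots (grouped by rule and side)
    slots = asm.creation_slots(cfg, sys)
    groups = {}
    for slot in slots:
        groups.setdefault((slot.rule.name, slot.loc), []).append(slot)
    for (_, loc), grp in groups.items():
        rule = grp[0].rule
        pts = np.array([s.site for s in grp])
        for slot, got in zip(grp, fidx.gather(rule.consumed, pts, r, loc)):
            if got is not None:
                instances.append(
                    RuleInstance(rule, got, slot.site, slot.compartment, token=slot)
                )

    # destruction
    for rule in sys.rules_of(DestructionRule):
        sites = asm.destruction_sites(cfg, sys, rule)
        if not sites:
            continue
        if rule.consumed:
            pts = np.array([s for _, s, _ in sites])
            gots = fidx.gather(rule.consumed, pts, r, None)
        else:
            gots = [()] * len(sites)
        for (tile_id, site, comp), got in zip(sites, gots):
            if got is not None:
                instances.append(RuleInstance(rule, got, site, comp, token=tile_id))

    # division
    for rule in sys.rules_of(DivisionRule):
        for token in asm.division_triggers(cfg, sys):
            instances.append(RuleInstance(rule, (), None, None, token=token))
    return instances


@dataclass
class Slot:
    """An open creation site published by the assembly model."""

    rule: CreationRule
    site: np.ndarray
    compartment: int | None = None
    loc: int | None = None  # side constraint for reactants (None = any)
    token: object = None


def _record(counter: dict, multiset: Mapping[str, int]):
    for k, v in multiset.items():
        counter[k] = counter.get(k, 0) + v


def step(cfg: Configuration, sys: MSystem, rng: np.random.Generator) -> Configuration:
    """Advance one iteration in place (and return cfg).

    Phases: nutrient supply; Brownian displacement of every floating
    object; rule application of a maximal conflict-free instance subset
    in rng-shuffled order (each object consumed at most once); re-glue of
    intact adjacent connectors; iteration count + 1.
    """
    asm = sys.assembly
    env = sys.environment
    fl = cfg.floats

    if asm is not None:
        asm.supply(cfg, sys, rng)

    # Brownian phase: displacement of norm mobility * r, uniform direction
    if len(fl):
        steps = np.array(
            [sys.floating_specs[n].mobility for n in sorted(sys.floating_specs)]
        ) * sys.interaction_radius
        d = rng.standard_normal((len(fl), 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        fl.pos = fl.pos + d * steps[fl.species][:, None]
        fl.pos = reflect_into_box(fl.pos, env.lo, env.hi)
        if asm is not None:
            asm.confine(cfg, sys, rng)

    # rule phase
    instances = applicable_instances(cfg, sys)
    order = rng.permutation(len(instances))
    consumed = np.zeros(len(fl.pos), dtype=bool)
    consumed_tiles: set[int] = set()
    to_remove: list[int] = []
    for i in order:
        inst = instances[int(i)]
        if any(consumed[j] for j in inst.float_idx):
            continue
        rule = inst.rule
        if isinstance(rule, MetabolicRule):
            if inst.token in consumed_tiles:
                continue  # one transport per channel per iteration
            consumed_tiles.add(inst.token)
            for j in inst.float_idx:
                consumed[j] = True
            to_remove.extend(inst.float_idx)
            asm.apply_metabolic(cfg, sys, rule, inst, rng)
            _record(cfg.consumed_by_rules, rule.consumed)
            _record(cfg.produced_by_rules, rule.produced)
        elif isinstance(rule, CreationRule):
            if not asm.slot_still_open(cfg, sys, inst.token):
                continue
            for j in inst.float_idx:
                consumed[j] = True
            to_remove.extend(inst.float_idx)
            asm.apply_creation(cfg, sys, rule, inst, rng)
            _record(cfg.consumed_by_rules, rule.consumed)
        elif isinstance(rule, DestructionRule):
            if inst.token in consumed_tiles or inst.token not in cfg.tiles:
                continue
            consumed_tiles.add(inst.token)
            for j in inst.float_idx:
                consumed[j] = True
            to_remove.extend(inst.float_idx)
            asm.apply_destruction(cfg, sys, rule, inst, rng)
            _record(cfg.consumed_by_rules, rule.consumed)
            _record(cfg.produced_by_rules, rule.produced)
        elif isinstance(rule, DivisionRule):
            asm.apply_division(cfg, sys, rule, inst, rng)
    if to_remove:
        fl.remove(to_remove)

    # spontaneous re-glue: matching connectors of tiles still in contact
    # re-bond; injured bonds persist only one iteration unless a tile left
    cfg.broken_bonds.clear()

    cfg.iteration += 1
    return cfg


@dataclass
class SimulationResult:
    census: pd.DataFrame
    final: Configuration
    system: MSystem


def census_record(cfg: Configuration, sys: MSystem) -> dict:
    sp = sys.species_index
    rec = {
        "iteration": cfg.iteration,
        "cells": sys.assembly.cell_count(cfg) if sys.assembly else 0,
        "tiles": cfg.tile_count(),
    }
    for name, code in sp.items():
        rec[f"{name}_count"] = cfg.floats.count(species=code)
    return rec


def run(
    sys: MSystem,
    n_iter: int,
    rng: np.random.Generator | int | None = None,
    cfg: Configuration | None = None,
    stop_when=None,
) -> SimulationResult:
    """Run the system for n_iter iterations from its seed configuration.

    Deterministic given the seed: identical trajectories and bit-stable
    censuses. `stop_when(cfg)` optionally ends the run early (used by
    injury protocols waiting for a division).
    """
    if n_iter < 0:
        raise ValueError("n_iter must be >= 0")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(0 if rng is None else int(rng))
    if cfg is None:
        cfg = make_configuration(sys)
    records = [census_record(cfg, sys)]
    for _ in range(n_iter):
        step(cfg, sys, rng)
        records.append(census_record(cfg, sys))
        if stop_when is not None and stop_when(cfg):
            break
    return SimulationResult(pd.DataFrame.from_records(records), cfg, sys)


# ---------------------------------------------------------------------------
# a minimal static assembly model for bench-top configurations
# ---------------------------------------------------------------------------


class SimpleCellAssembly:
    """A fixed single compartment (axis-aligned box) with manually placed
    tiles and manually declared creation slots.

    Geometry never changes except by tile placement at declared slots;
    used to exercise the engine (transport radius, conflict resolution,
    conservation) under fully controlled conditions.
    """

    def __init__(self, cell_lo=None, cell_hi=None):
        self.cell_lo = None if cell_lo is None else np.asarray(cell_lo, float)
        self.cell_hi = None if cell_hi is None else np.asarray(cell_hi, float)
        self.slots: list[Slot] = []
        self.filled: set = set()

    # -- engine hooks -------------------------------------------------
    def initialize(self, cfg, sys):
        pass

    def supply(self, cfg, sys, rng):
        env = sys.environment
        for name in sorted(sys.floating_specs):
            spec = sys.floating_specs[name]
            code = sys.species_index[name]
            target = int(round(spec.env_concentration))
            have = cfg.floats.count(species=code, loc=ENV)
            want = target - have
            if want <= 0:
                continue
            if cfg.budget_remaining is not None:
                want = min(want, cfg.budget_remaining)
                cfg.budget_remaining -= want
            if want > 0:
                pts = rng.uniform(env.lo, env.hi, size=(want, 3))
                cfg.floats.add(code, pts, ENV)
                cfg.injected[name] = cfg.injected.get(name, 0) + want

    def confine(self, cfg, sys, rng):
        if self.cell_lo is None:
            return
        inside = cfg.floats.loc == 0
        if inside.any():
            cfg.floats.pos[inside] = reflect_into_box(
                cfg.floats.pos[inside], self.cell_lo, self.cell_hi
            )

    def metabolic_sites(self, cfg, sys, rule):
        out = []
        for tid, pt in cfg.tiles.items():
            spec = sys.tile_specs[pt.spec]
            for k, pr in enumerate(spec.protions):
                if pr.name == rule.protion and pt.protion_alive[k]:
                    from .geometry import to_world

                    out.append((tid, to_world(pt.pose, np.asarray(pr.site)), 0))
        return out

    def creation_slots(self, cfg, sys):
        return [s for s in self.slots if s.token not in self.filled]

    def slot_still_open(self, cfg, sys, slot):
        return slot.token not in self.filled

    def destruction_sites(self, cfg, sys, rule):
        out = []
        for tid, pt in cfg.tiles.items():
            if pt.spec in rule.tiles:
                out.append((tid, pt.pose.position, 0))
        return out

    def division_triggers(self, cfg, sys):
        return []

    # -- appliers -----------------------------------------------------
    def apply_metabolic(self, cfg, sys, rule, inst, rng):
        sp = sys.species_index
        loc = 0 if rule.produced_side == "in" else ENV
        for label, k in rule.produced.items():
            jitter = rng.normal(0.0, 0.05, size=(k, 3))
            base = inst.site if self.cell_lo is None else (self.cell_lo + self.cell_hi) / 2
            cfg.floats.add(sp[label], base + jitter, loc)

    def apply_creation(self, cfg, sys, rule, inst, rng):
        slot = inst.token
        self.filled.add(slot.token)
        cfg.place_tile(sys.tile_specs[rule.tile], Pose(slot.site))

    def apply_destruction(self, cfg, sys, rule, inst, rng):
        del cfg.tiles[inst.token]
        sp = sys.species_index
        for label, k in rule.produced.items():
            cfg.floats.add(sp[label], np.tile(inst.site, (k, 1)), inst.compartment)

    def apply_division(self, cfg, sys, rule, inst, rng):
        pass

    def cell_count(self, cfg):
        return 1 if cfg.tiles else 0
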