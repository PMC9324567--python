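"""The bacterial M system: tile inventory, nine rules, chain assembly.

The model grows simulated bacterial cells whose membranes are closed
octagonal prisms (octagonal tiles, consistent with a dodecahedral cell
wall built from octagons): two octagonal pole discs cap a ring stack of
rectangular wall plates, eight per ring, each plate carrying one
nutrient-transport protion. A cell elongates by inserting a second ring
of wall plates next to its newest pole (growth displaces the distal part
of the assembly along the cell axis, the incompressible-wall
abstraction); three kinds of small auxiliary rod tiles then assemble a
ring at the mid-cell seam and template eight triangular septum slices
that close the mid-plane. When the septum disc is complete, the division
rule splits the compartment in two; the septum becomes the shared new
pole of both daughters (as septa become poles in real bacteria), the
spent rods are annihilated by the destruction rule, and each daughter
restarts the cycle. Nothing schedules division explicitly: its timing
emerges from nutrient transport and diffusion.

Object inventory (exactly as the rule count requires):

* four 2-D tile types: seed pole, pole, wall plate, septum slice;
* three rod tile types: septum seed rod, arc rod, bridge rod;
* two floating objects: nutrient `a` (supplied by the environment) and
  division signal `s` (released inside the cell by transport);
* one protion type (`pore`, one per wall plate);
* nine rules: 1 metabolic + 6 creation + 1 destruction + 1 division.

An adult cell just before its first division comprises exactly 34
injurable components: 2 poles + 16 wall plates + 8 septum slices + 8
rods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .core import (
    ENV,
    Configuration,
    CreationRule,
    DestructionRule,
    DivisionRule,
    Environment,
    FloatingObjectSpec,
    GlueRelation,
    MetabolicRule,
    MSystem,
    ProtionSpec,
    Slot,
    TileSpec,
)
from .geometry import Connector, Pose, TileShape

__all__ = [
    "SpeciesParams",
    "preset",
    "PRESET_NAMES",
    "build_mbac",
    "ChainAssembly",
    "ADULT_COMPONENT_COUNT",
]

# geometry of the octagonal cross-section (tile edge length 1)
EDGE = 1.0
N_POS = 8
R8 = EDGE / (2.0 * math.sin(math.pi / N_POS))   # circumradius ~1.3066
A8 = EDGE / (2.0 * math.tan(math.pi / N_POS))   # apothem      ~1.2071
RING_H = 1.0                                     # ring (wall plate) height

ADULT_COMPONENT_COUNT = 34

#: reference ambient nutrient density (objects per unit volume) of the
#: standard growth medium; the unlimited-supply protocols maintain it
REF_AMBIENT_DENSITY = 0.1104

#: per-iteration object exchange rates through membrane holes, per
#: unit open wall fraction: interior objects leak out faster than the
#: (dilute) environment drifts in
BREACH_ESCAPE = 0.50
BREACH_ADMIT = 0.02

#: pore channels idle once the compartment holds this many nutrient
#: objects (gradient-driven transport saturates at concentration
#: balance; prevents unbounded intracellular stockpiling)
IMPORT_SATURATION = 5

#: exponent of the membrane-integrity factor (1 - open fraction) that
#: scales a breached compartment's import capacity: channels fail both
#: individually and collectively as the gradient collapses
INTEGRITY_EXPONENT = 2.8

_VERT_ANG = math.pi / N_POS + 2.0 * math.pi * np.arange(N_POS) / N_POS


_VERTS = np.column_stack(
    [R8 * np.cos(_VERT_ANG), R8 * np.sin(_VERT_ANG), np.zeros(N_POS)]
)
_FACETS = np.array(
    [
        np.append((_VERTS[p, :2] + _VERTS[(p + 1) % N_POS, :2]) / 2.0 / A8, 0.0)
        for p in range(N_POS)
    ]
)


def _vertex(k: int) -> np.ndarray:
    return _VERTS[k % N_POS]


def _facet_dir(p: int) -> np.ndarray:
    """Unit outward normal of facet p (between vertices p and p+1)."""
    return _FACETS[p % N_POS]


# ---------------------------------------------------------------------------
# species parameters and presets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesParams:
    """Calibration constants distinguishing the simulated species.

    The species differ only in the diffusion (mobility) constants of the
    a- and s-objects, the ambient nutrient level, and the nutrient
    budget; the rule inventory is identical. diffusion_* are Brownian
    step multipliers (step = diffusion * interaction radius per
    iteration, i.e. per simulated minute); env_target is the ambient
    copy number of `a` the environment maintains while the budget lasts;
    nutrient_budget None means unlimited supply (injury protocols).
    """

    name: str
    diffusion_a: float
    diffusion_s: float
    env_target: int
    nutrient_budget: int | None
    target_iterations: int
    interaction_radius: float = 0.8
    box: tuple[float, float, float] = (9.0, 9.0, 190.0)
    z0: float = 1.0
    #: nutrient objects pre-placed around the seeded tile (the "rich
    #: medium" initial condition); drawn from the budget
    initial_bolus: int = 40
    #: per-iteration probability that an environment float is carried to
    #: a new uniform position (culture agitation; the well-mixed
    #: reservoir approximation). Interior objects are never mixed.
    mix_rate: float = 0.3

    def __post_init__(self):
        if self.diffusion_a <= 0 or self.diffusion_s <= 0:
            raise ValueError("diffusion rates must be > 0")
        if self.env_target < 0:
            raise ValueError("env_target must be >= 0")
        if self.nutrient_budget is not None and self.nutrient_budget < 0:
            raise ValueError("nutrient_budget must be >= 0 or None")

    def injury_variant(self) -> "SpeciesParams":
        """Unlimited-nutrient single-cell conditions for injury protocols:
        same kinetic constants, unlimited budget, compact box held at the
        reference ambient nutrient density."""
        box = (9.0, 9.0, 20.0)
        target = int(round(REF_AMBIENT_DENSITY * box[0] * box[1] * box[2]))
        return replace(self, nutrient_budget=None, box=box,
                       env_target=max(target, 40))


# Calibrated so that 100-run mean final populations under the limited
# nutrient protocol reproduce the reference doubling times (generation
# time ~16 min for E. coli at 100 iterations, ~24 min at 150, ~62 at 400).
_PRESETS = {
    "ecoli": SpeciesParams(
        name="ecoli", diffusion_a=2.4, diffusion_s=2.0,
        env_target=2250, nutrient_budget=2250, target_iterations=100,
        interaction_radius=1.1, mix_rate=0.45,
    ),
    "slactis": SpeciesParams(
        name="slactis", diffusion_a=1.1, diffusion_s=1.1,
        env_target=1780, nutrient_budget=1780, target_iterations=150,
        interaction_radius=1.1, mix_rate=0.20,
    ),
    "lacidophilus": SpeciesParams(
        name="lacidophilus", diffusion_a=0.5, diffusion_s=0.7,
        env_target=1980, nutrient_budget=1980, target_iterations=400,
        interaction_radius=1.1, mix_rate=0.045,
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(species: str) -> SpeciesParams:
    """Calibrated parameters for one of the three modelled species."""
    try:
        return _PRESETS[species]
    except KeyError:
        raise KeyError(
            f"unknown species {species!r}; expected one of {sorted(_PRESETS)}"
        ) from None


# ---------------------------------------------------------------------------
# tile specs, glues, rules
# ---------------------------------------------------------------------------

_GLUE_PAIRS = [
    ("band", "band"), ("band", "rim"), ("side", "side"),
    ("rodend", "rodend"), ("band", "rodend"), ("wedge", "wedge"),
]


def _pole_spec(name: str) -> TileSpec:
    shape = TileShape.regular_polygon(N_POS, EDGE)
    conns = tuple(
        Connector(np.array([_vertex(k), _vertex(k + 1)]), "rim")
        for k in range(N_POS)
    )
    return TileSpec(name, shape, conns)


def _wall_spec() -> TileSpec:
    shape = TileShape.rectangle(EDGE, RING_H)
    h = RING_H / 2.0
    conns = (
        Connector(np.array([[-0.5, -h, 0.0], [0.5, -h, 0.0]]), "band"),
        Connector(np.array([[-0.5, h, 0.0], [0.5, h, 0.0]]), "band"),
        Connector(np.array([[-0.5, -h, 0.0], [-0.5, h, 0.0]]), "side"),
        Connector(np.array([[0.5, -h, 0.0], [0.5, h, 0.0]]), "side"),
    )
    return TileSpec("wall", shape, conns, (ProtionSpec("pore", (0.0, 0.0, 0.0)),))


def _slice_spec() -> TileSpec:
    v0, v1 = _vertex(0), _vertex(1)
    shape = TileShape("polygon2D", np.array([[0.0, 0.0, 0.0], v0, v1]))
    mid = (v0 + v1) / 2.0
    conns = (
        Connector(np.array([v0, v1]), "band"),           # outer edge, lower side
        Connector(mid * 0.999, "band"),                  # outer edge, upper side
        Connector(np.array([[0.0, 0.0, 0.0], v0]), "wedge"),
        Connector(np.array([[0.0, 0.0, 0.0], v1]), "wedge"),
        Connector(mid * 0.95, "rodend"),                 # rod anchor
    )
    return TileSpec("slice", shape, conns)


def _rod_spec(name: str) -> TileSpec:
    shape = TileShape.rod(EDGE)
    conns = (
        Connector(np.array([0.0, 0.0, 0.0]), "rodend"),
        Connector(np.array([EDGE, 0.0, 0.0]), "rodend"),
        Connector(np.array([EDGE * 0.5, 0.0, 0.0]), "band"),
        Connector(np.array([EDGE * 0.25, 0.0, 0.0]), "band"),
        Connector(np.array([EDGE * 0.75, 0.0, 0.0]), "rodend"),
    )
    return TileSpec(name, shape, conns)


#: creation costs, in floating objects per tile
WALL_COST = {"a": 1}
POLE_COST = {"a": 1}
SLICE_COST = {"a": 1}
ROD_SEED_COST = {"s": 2}
ROD_ARC_COST = {"s": 1}
ROD_BRIDGE_COST = {"s": 1}

ROD_TYPES = ("rod_seed", "rod_arc", "rod_bridge")


def _rules() -> list:
    return [
        # one metabolic rule: nutrient import through the pore channel,
        # releasing one division-signal object per transported nutrient
        MetabolicRule("import_a", "pore", {"a": 1}, {"a": 1, "s": 1}),
        # six creation rules
        CreationRule("make_wall", WALL_COST, "wall", "band"),
        CreationRule("make_pole", POLE_COST, "pole", "rim"),
        CreationRule("make_slice", SLICE_COST, "slice", "band"),
        CreationRule("make_rod_seed", ROD_SEED_COST, "rod_seed", "rodend"),
        CreationRule("make_rod_arc", ROD_ARC_COST, "rod_arc", "rodend"),
        CreationRule("make_rod_bridge", ROD_BRIDGE_COST, "rod_bridge", "rodend"),
        # one destruction rule: annihilate the spent auxiliary rods
        DestructionRule("clear_rods", ROD_TYPES),
        # one division rule
        DivisionRule("divide"),
    ]


def build_mbac(params: SpeciesParams) -> MSystem:
    """Assemble the bacterial M system for one species.

    Seeded with a single seed-pole tile; 7 tile specs, 2 floating
    specs, 1 protion spec, 9 rules.
    """
    if not isinstance(params, SpeciesParams):
        raise TypeError("params must be a SpeciesParams")
    floating = {
        "a": FloatingObjectSpec("a", mobility=params.diffusion_a,
                                env_concentration=params.env_target),
        "s": FloatingObjectSpec("s", mobility=params.diffusion_s),
    }
    tiles = {
        t.name: t
        for t in (
            _pole_spec("seed_pole"),
            _pole_spec("pole"),
            _wall_spec(),
            _slice_spec(),
            _rod_spec("rod_seed"),
            _rod_spec("rod_arc"),
            _rod_spec("rod_bridge"),
        )
    }
    wx, wy, wz = params.box
    env = Environment((0.0, 0.0, 0.0), (wx, wy, wz),
                      nutrient_budget=params.nutrient_budget)
    axis = np.array([wx / 2.0, wy / 2.0, 0.0])
    seed_pose = Pose(axis + np.array([0.0, 0.0, params.z0]))
    sys = MSystem(
        floating_specs=floating,
        tile_specs=tiles,
        glue_relation=GlueRelation(_GLUE_PAIRS),
        rules=_rules(),
        interaction_radius=params.interaction_radius,
        environment=env,
        seed_tiles=[("seed_pole", seed_pose)],
        assembly=ChainAssembly(params),
    )
    return sys


# ---------------------------------------------------------------------------
# chain assembly state
# ---------------------------------------------------------------------------


@dataclass
class Disc:
    """A transverse disc element: a pole (one octagon tile) or a septum
    (eight slice tiles templated by eight rods)."""

    kind: str                       # "pole" | "septum"
    tiles: dict = field(default_factory=dict)   # pos -> tile id (pole: {0: tid})
    rods: dict = field(default_factory=dict)    # pos -> tile id
    divided: bool = False
    ever_complete: bool = False
    birth: int = 0
    z: float = 0.0

    @property
    def complete(self) -> bool:
        return len(self.tiles) == (1 if self.kind == "pole" else N_POS)

    @property
    def is_boundary(self) -> bool:
        """Bounds a compartment: poles always; septa once divided."""
        if self.kind == "pole":
            return self.ever_complete or self.complete
        return self.divided


@dataclass
class Ring:
    walls: dict = field(default_factory=dict)   # pos -> tile id
    ever_complete: bool = False
    z_lo: float = 0.0

    @property
    def complete(self) -> bool:
        return len(self.walls) == N_POS


@dataclass
class ChainState:
    elements: list = field(default_factory=list)
    compartments: list = field(default_factory=list)
    tile_index: dict = field(default_factory=dict)  # tid -> (element, pos, role)
    birth_counter: int = 0
    divisions: int = 0
    bonds_dirty: bool = True  # bond set is derived lazily from contact


class ChainAssembly:
    """Assembly model of the bacterial chain (engine geometry hooks plus
    the injury operations of the experimental protocols)."""

    def __init__(self, params: SpeciesParams):
        self.params = params
        wx, wy, _ = params.box
        self.axis = np.array([wx / 2.0, wy / 2.0])
        # outward facet normals (8, 2) for octagon containment tests
        self._normals = np.stack([_facet_dir(p)[:2] for p in range(N_POS)])

    # -- state access -------------------------------------------------
    @staticmethod
    def state(cfg: Configuration) -> ChainState:
        return cfg.assembly_state

    def initialize(self, cfg: Configuration, sys: MSystem):
        st = ChainState()
        cfg.assembly_state = st
        if len(cfg.tiles) != 1:
            raise ValueError("the bacterial model is seeded with a single tile")
        (seed_tid,) = cfg.tiles
        d0 = Disc("pole", tiles={0: seed_tid}, ever_complete=True,
                  birth=self._stamp(st))
        ring1 = Ring()
        d1 = Disc("pole", birth=self._stamp(st))
        st.elements = [d0, ring1, d1]
        st.tile_index[seed_tid] = (d0, 0, "disc")
        self._relayout(st)
        self._rebuild_compartments(cfg)
        self._rebuild_bonds(cfg)
        # nutrient-rich medium around the seed: a deterministic bolus of
        # a-objects (part of the initial configuration), budget-counted
        bolus = self.params.initial_bolus
        if cfg.budget_remaining is not None:
            bolus = min(bolus, cfg.budget_remaining)
            cfg.budget_remaining -= bolus
        if bolus > 0:
            r0 = np.random.default_rng(12345)
            pts = self._world(np.zeros(2), self.params.z0 + RING_H / 2.0) \
                + r0.uniform(-1, 1, size=(bolus, 3)) * np.array([2.2, 2.2, 1.6])
            lo = np.asarray(sys.environment.box_lo, float) + 0.05
            hi = np.asarray(sys.environment.box_hi, float) - 0.05
            pts = np.clip(pts, lo, hi)
            cfg.floats.add(sys.species_index["a"], pts, ENV)
            cfg.injected["a"] = cfg.injected.get("a", 0) + bolus

    def _stamp(self, st: ChainState) -> int:
        st.birth_counter += 1
        return st.birth_counter

    # -- layout -------------------------------------------------------
    def _relayout(self, st: ChainState):
        z = self.params.z0
        for el in st.elements:
            if isinstance(el, Disc):
                el.z = z
            else:
                el.z_lo = z
                z += RING_H

    def _world(self, xy_local: np.ndarray, z: float) -> np.ndarray:
        return np.array([self.axis[0] + xy_local[0], self.axis[1] + xy_local[1], z])

    # -- compartments -------------------------------------------------
    def _rebuild_compartments(self, cfg: Configuration):
        st = self.state(cfg)
        comps = []
        boundary_idx = [
            i for i, el in enumerate(st.elements)
            if isinstance(el, Disc) and el.is_boundary
        ]
        for a, b in zip(boundary_idx[:-1], boundary_idx[1:]):
            inner = st.elements[a + 1 : b]
            if not any(isinstance(e, Ring) for e in inner):
                continue
            comp = {
                "id": len(comps),
                "lo": a,
                "hi": b,
                "z_lo": st.elements[a].z,
                "z_hi": st.elements[b].z,
            }
            comps.append(comp)
        st.compartments = comps
        self._refresh_openness(cfg)
        # reassign interior floats to compartments by z position
        fl = cfg.floats
        if fl is not None and len(fl):
            interior = fl.loc != ENV
            if interior.any():
                z = fl.pos[interior, 2]
                new_loc = np.full(z.shape, ENV, dtype=np.int64)
                for comp in comps:
                    m = (z >= comp["z_lo"] - 1e-9) & (z <= comp["z_hi"] + 1e-9)
                    new_loc[m] = comp["id"]
                fl.loc[interior] = new_loc

    def _refresh_openness(self, cfg: Configuration):
        """Hole fraction per compartment: missing tiles at positions that
        were built once (growing rings that were never complete are
        construction sites, not holes)."""
        st = self.state(cfg)
        for comp in st.compartments:
            holes = 0
            total = 0
            for el in st.elements[comp["lo"] : comp["hi"] + 1]:
                if isinstance(el, Ring):
                    if el.ever_complete:
                        total += N_POS
                        holes += N_POS - len(el.walls)
                elif el.ever_complete or el.complete:
                    n = 1 if el.kind == "pole" else N_POS
                    total += n
                    holes += n - len(el.tiles)
            comp["open_frac"] = holes / total if total else 1.0
            comp["closed"] = holes == 0 and total > 0

    def _comp_of_element(self, st: ChainState, idx: int):
        for comp in st.compartments:
            if comp["lo"] <= idx <= comp["hi"]:
                return comp
        return None

    # -- engine hooks: supply and confinement -------------------------
    def supply(self, cfg, sys, rng):
        env = sys.environment
        fl = cfg.floats
        # culture agitation: environment floats recirculate
        mix = self.params.mix_rate
        if mix > 0 and len(fl):
            m = (fl.loc == ENV) & (rng.random(len(fl.pos)) < mix)
            if m.any():
                fl.pos[m] = rng.uniform(env.lo, env.hi, size=(int(m.sum()), 3))
        spec = sys.floating_specs["a"]
        code = sys.species_index["a"]
        target = int(round(spec.env_concentration))
        want = target - cfg.floats.count(species=code, loc=ENV)
        if want <= 0:
            return
        if cfg.budget_remaining is not None:
            want = min(want, cfg.budget_remaining)
            cfg.budget_remaining -= want
        if want > 0:
            pts = rng.uniform(env.lo, env.hi, size=(want, 3))
            cfg.floats.add(code, pts, ENV)
            cfg.injected["a"] = cfg.injected.get("a", 0) + want

    def _inside_octagon(self, xy: np.ndarray, margin: float = 0.0) -> np.ndarray:
        rel = xy - self.axis
        d = rel @ self._normals.T
        return np.all(d < A8 - margin, axis=1)

    def _clamp_octagon(self, xy: np.ndarray, margin: float) -> np.ndarray:
        rel = xy - self.axis
        for k in range(N_POS):
            n = self._normals[k]
            d = rel @ n
            over = d > A8 - margin
            if over.any():
                rel[over] -= np.outer(d[over] - (A8 - margin), n)
        return rel + self.axis

    def _push_out(self, xy: np.ndarray) -> np.ndarray:
        rel = xy - self.axis
        r = np.linalg.norm(rel, axis=1, keepdims=True)
        r = np.where(r < 1e-9, 1.0, r)
        return self.axis + rel / r * (R8 + 0.15)

    def confine(self, cfg, sys, rng):
        """Keep interior floats in their compartment and environment
        floats out of closed compartments. Injury holes exchange objects
        with the environment in proportion to the open wall fraction."""
        st = self.state(cfg)
        fl = cfg.floats
        if not len(fl):
            return
        for comp in st.compartments:
            m = fl.loc == comp["id"]
            if m.any():
                f = comp.get("open_frac", 0.0)
                if f > 0:
                    esc = m & (rng.random(len(fl.pos)) < BREACH_ESCAPE * f)
                    if esc.any():
                        fl.pos[esc] = np.column_stack(
                            [self._push_out(fl.pos[esc, :2]), fl.pos[esc, 2]]
                        )
                        fl.loc[esc] = ENV
                        m = m & ~esc
                if m.any():
                    z = np.clip(fl.pos[m, 2], comp["z_lo"] + 0.02, comp["z_hi"] - 0.02)
                    xy = self._clamp_octagon(fl.pos[m, :2], 0.05)
                    fl.pos[m] = np.column_stack([xy, z])
        # environment floats must stay out of closed compartments
        env_m = fl.loc == ENV
        if env_m.any():
            pos = fl.pos[env_m]
            inside_xy = self._inside_octagon(pos[:, :2])
            for comp in st.compartments:
                in_z = (pos[:, 2] > comp["z_lo"]) & (pos[:, 2] < comp["z_hi"])
                hit = inside_xy & in_z
                if not hit.any():
                    continue
                f = comp.get("open_frac", 0.0)
                admit = rng.random(hit.sum()) < BREACH_ADMIT * f
                idx = np.nonzero(env_m)[0][hit]
                if admit.any():
                    fl.loc[idx[admit]] = comp["id"]
                out = idx[~admit]
                if len(out):
                    fl.pos[out, :2] = self._push_out(fl.pos[out, :2])

    # -- engine hooks: sites and slots --------------------------------
    def metabolic_sites(self, cfg, sys, rule):
        """(tile id, outer site, compartment) per live pore channel.

        Channels of a compartment already holding IMPORT_SATURATION
        nutrient objects idle (transport runs down the gradient only).
        """
        st = self.state(cfg)
        fl = cfg.floats
        code = sys.species_index["a"]
        out = []
        for comp in st.compartments:
            if fl.count(species=code, loc=comp["id"]) >= IMPORT_SATURATION:
                continue
            sites = []
            for el in st.elements[comp["lo"] + 1 : comp["hi"]]:
                if not isinstance(el, Ring):
                    continue
                zc = el.z_lo + RING_H / 2.0
                for p, tid in el.walls.items():
                    pt = cfg.tiles[tid]
                    if pt.protion_alive and pt.protion_alive[0]:
                        site = self._world(_facet_dir(p)[:2] * (A8 + 0.1), zc)
                        sites.append((tid, site, comp["id"]))
            # a breached membrane cannot maintain gradients: import
            # capacity scales with wall integrity (1 - open fraction)
            f = comp.get("open_frac", 0.0)
            if f > 0:
                keep = (1.0 - f) ** INTEGRITY_EXPONENT
                sites = sites[: int(round(keep * len(sites)))]
            out.extend(sites)
        return out

    def creation_slots(self, cfg, sys):
        st = self.state(cfg)
        rules = {r.name: r for r in sys.rules if isinstance(r, CreationRule)}
        slots: list[Slot] = []
        for i, el in enumerate(st.elements):
            comp = self._comp_of_element(st, i)
            cid = comp["id"] if comp else None
            loc = cid if cid is not None else ENV
            if isinstance(el, Ring):
                if el.complete:
                    continue
                zc = el.z_lo + RING_H / 2.0
                for p in range(N_POS):
                    if p in el.walls or not self._anchored(st, i, p):
                        continue
                    inset = (A8 - 0.15) if cid is not None else (A8 + 0.15)
                    site = self._world(_facet_dir(p)[:2] * inset, zc)
                    slots.append(Slot(rules["make_wall"], site, cid, loc,
                                      token=("wall", el, p)))
            elif el.kind == "pole":
                if el.tiles:
                    continue
                # a pole closes an open rim of a complete adjacent ring
                ring = self._adjacent_complete_ring(st, i)
                if ring is not None:
                    site = self._world(np.zeros(2), el.z)
                    slots.append(Slot(rules["make_pole"], site, cid, loc,
                                      token=("pole", el, 0)))
            else:  # septum disc
                if el.divided:
                    for p in range(N_POS):
                        if p not in el.tiles and self._anchored(st, i, p):
                            mid = (_vertex(p)[:2] + _vertex(p + 1)[:2]) / 3.0
                            site = self._world(mid, el.z)
                            slots.append(Slot(rules["make_slice"], site, cid, loc,
                                              token=("slice", el, p)))
                    continue
                if not self._septum_ready(st, i):
                    continue
                have = set(el.rods)
                for p in range(N_POS):
                    if p in have:
                        if p not in el.tiles:
                            mid = (_vertex(p)[:2] + _vertex(p + 1)[:2]) / 3.0
                            site = self._world(mid, el.z)
                            slots.append(Slot(rules["make_slice"], site, cid, loc,
                                              token=("slice", el, p)))
                        continue
                    nnb = ((p - 1) % N_POS in have) + ((p + 1) % N_POS in have)
                    if not have:
                        rname = "make_rod_seed"
                    elif nnb == 1:
                        rname = "make_rod_arc"
                    elif nnb == 2:
                        rname = "make_rod_bridge"
                    else:
                        continue
                    mid = (_vertex(p)[:2] + _vertex(p + 1)[:2]) / 2.0
                    site = self._world(mid * ((A8 - 0.12) / A8), el.z)
                    slots.append(Slot(rules[rname], site, cid, loc,
                                      token=("rod", el, p)))
        return slots

    def _column_anchor(self, st, i, p) -> bool:
        """A tile exists in column p of a neighbouring element (empty
        elements are transparent: virtual growth bands have no
        thickness until built)."""
        for rng_ in (range(i - 1, -1, -1), range(i + 1, len(st.elements))):
            for j in rng_:
                entry = self._column_entry(st.elements[j], p)
                if entry is not None:
                    break
            else:
                entry = None
            if entry is not None:
                return True
        return False

    def _anchored(self, st, i, p) -> bool:
        """A creation slot must offer a connector of an existing tile to
        glue to: a lateral neighbour in the same element or a column
        neighbour in an adjacent element. Without an anchor nothing can
        self-assemble there (a fully destroyed region cannot regrow)."""
        el = st.elements[i]
        items = el.walls if isinstance(el, Ring) else el.tiles
        if (p - 1) % N_POS in items or (p + 1) % N_POS in items:
            return True
        if not isinstance(el, Ring) and (p - 1) % N_POS in el.rods:
            return True
        return self._column_anchor(st, i, p)

    def _adjacent_complete_ring(self, st, i):
        for j in (i - 1, i + 1):
            if 0 <= j < len(st.elements):
                el = st.elements[j]
                if isinstance(el, Ring) and el.complete:
                    return el
        return None

    def _septum_ready(self, st, i) -> bool:
        """Rods assemble only between two complete rings."""
        lo = st.elements[i - 1] if i > 0 else None
        hi = st.elements[i + 1] if i + 1 < len(st.elements) else None
        return (
            isinstance(lo, Ring) and lo.complete
            and isinstance(hi, Ring) and hi.complete
        )

    def slot_still_open(self, cfg, sys, slot: Slot) -> bool:
        kind, el, p = slot.token
        if kind == "wall":
            return p not in el.walls
        if kind == "pole":
            return not el.tiles
        if kind == "slice":
            return p not in el.tiles
        if kind == "rod":
            return p not in el.rods
        return False

    def destruction_sites(self, cfg, sys, rule):
        """Spent rods: the rods of a divided septum."""
        st = self.state(cfg)
        out = []
        for i, el in enumerate(st.elements):
            if isinstance(el, Disc) and el.kind == "septum" and el.divided:
                for p, tid in el.rods.items():
                    mid = (_vertex(p)[:2] + _vertex(p + 1)[:2]) / 2.0
                    comp = self._comp_of_element(st, i)
                    out.append((tid, self._world(mid, el.z),
                                comp["id"] if comp else None))
        return out

    def division_triggers(self, cfg, sys):
        st = self.state(cfg)
        return [
            el for el in st.elements
            if isinstance(el, Disc) and el.kind == "septum"
            and el.complete and not el.divided
        ]

    # -- engine hooks: rule application -------------------------------
    def apply_metabolic(self, cfg, sys, rule, inst, rng):
        """Import through the pore: products appear just inside the wall."""
        tid = inst.token
        entry = self.state(cfg).tile_index.get(tid)
        if entry is None:
            return
        el, p, _role = entry
        zc = el.z_lo + RING_H / 2.0
        sp = sys.species_index
        comp = inst.compartment
        for label, k in rule.produced.items():
            inward = _facet_dir(p)[:2] * (A8 - 0.35)
            pts = np.column_stack([
                np.tile(self._world(inward, zc)[:2], (k, 1)),
                np.full(k, zc),
            ]) + rng.normal(0.0, 0.15, size=(k, 3))
            loc = comp if rule.produced_side == "in" else ENV
            cfg.floats.add(sp[label], pts, loc)

    def apply_creation(self, cfg, sys, rule, inst, rng):
        st = self.state(cfg)
        kind, el, p = inst.token.token if isinstance(inst.token, Slot) else inst.token
        spec = sys.tile_specs[rule.tile]
        if kind == "wall":
            pose = self._wall_pose(el.z_lo, p)
            tid = cfg.place_tile(spec, pose)
            el.walls[p] = tid
            st.tile_index[tid] = (el, p, "wall")
            if el.complete:
                el.ever_complete = True
        elif kind == "pole":
            pose = Pose(self._world(np.zeros(2), el.z))
            tid = cfg.place_tile(spec, pose)
            el.tiles[0] = tid
            el.ever_complete = True
            st.tile_index[tid] = (el, 0, "disc")
            self._on_closure(cfg, sys)
        elif kind == "slice":
            rot = Rotation.from_euler("z", p * 2.0 * math.pi / N_POS)
            pose = Pose.from_rotation(rot, self._world(np.zeros(2), el.z))
            tid = cfg.place_tile(spec, pose)
            el.tiles[p] = tid
            st.tile_index[tid] = (el, p, "disc")
            if el.complete:
                el.ever_complete = True
        elif kind == "rod":
            v = _vertex(p)
            rot = Rotation.from_euler(
                "z", math.atan2(_vertex(p + 1)[1] - v[1], _vertex(p + 1)[0] - v[0])
            )
            pose = Pose.from_rotation(rot, self._world(v[:2], el.z))
            tid = cfg.place_tile(spec, pose)
            el.rods[p] = tid
            st.tile_index[tid] = (el, p, "rod")
        st.bonds_dirty = True
        # openness only changes when repairing or completing built walls
        if kind != "rod" and getattr(el, "ever_complete", False):
            self._refresh_openness(cfg)

    def _wall_pose(self, z_lo: float, p: int) -> Pose:
        n = _facet_dir(p)
        # local: rectangle in z=0 plane, +y up; world: normal -> n, +y -> +z
        ey = np.array([0.0, 0.0, 1.0])
        ex = np.cross(ey, n)
        mat = np.column_stack([ex, ey, n])
        return Pose.from_rotation(
            Rotation.from_matrix(mat),
            self._world(n[:2] * A8, z_lo + RING_H / 2.0),
        )

    def _on_closure(self, cfg, sys):
        """First full enclosure (or pole repair / division): rebuild
        compartments and lay the growth template of any newly closed
        one-ring compartment. Template insertion shifts element indices,
        so the compartment list is re-derived after every insertion."""
        st = self.state(cfg)
        self._rebuild_compartments(cfg)
        changed = True
        while changed:
            changed = False
            for comp in st.compartments:
                rings = [
                    e for e in st.elements[comp["lo"] : comp["hi"] + 1]
                    if isinstance(e, Ring)
                ]
                has_septum = any(
                    isinstance(e, Disc) and e.kind == "septum" and not e.divided
                    for e in st.elements[comp["lo"] + 1 : comp["hi"]]
                )
                if len(rings) == 1 and not has_septum:
                    self._lay_growth_template(cfg, comp)
                    changed = True
                    break

    def _lay_growth_template(self, cfg, comp):
        """Insert an empty ring next to the compartment's newest disc and
        an empty septum disc between it and the old ring; distal elements
        are displaced by one ring height."""
        st = self.state(cfg)
        lo, hi = st.elements[comp["lo"]], st.elements[comp["hi"]]
        grow_hi = hi.birth >= lo.birth
        new_ring = Ring()
        new_sep = Disc("septum", birth=self._stamp(st))
        if grow_hi:
            at = comp["hi"]
            st.elements[at:at] = [new_sep, new_ring]
            z_ins = hi.z
        else:
            at = comp["lo"] + 1
            st.elements[at:at] = [new_ring, new_sep]
            z_ins = lo.z
        self._relayout(st)
        fl = cfg.floats
        if fl is not None and len(fl):
            m = (fl.loc != ENV) & (fl.pos[:, 2] >= z_ins - 1e-9)
            fl.pos[m, 2] += RING_H
        self._rebuild_compartments(cfg)

    def apply_destruction(self, cfg, sys, rule, inst, rng):
        tid = inst.token
        st = self.state(cfg)
        entry = st.tile_index.pop(tid, None)
        if entry is None or tid not in cfg.tiles:
            return
        el, p, _role = entry
        el.rods.pop(p, None)
        del cfg.tiles[tid]
        self._drop_bonds_of(cfg, tid)
        sp = sys.species_index
        for label, k in rule.produced.items():
            cfg.floats.add(sp[label], np.tile(inst.site, (k, 1)), inst.compartment)

    def apply_division(self, cfg, sys, rule, inst, rng):
        st = self.state(cfg)
        el = inst.token
        if not (isinstance(el, Disc) and el.kind == "septum"
                and el.complete and not el.divided):
            return  # stale trigger within this step
        el.divided = True
        el.birth = self._stamp(st)
        st.divisions += 1
        self._rebuild_compartments(cfg)
        self._on_closure(cfg, sys)

    def cell_count(self, cfg) -> int:
        st = self.state(cfg)
        if st.compartments:
            return len(st.compartments)
        return 1 if cfg.tiles else 0

    # -- bonds ---------------------------------------------------------
    #
    # Bonds are derived from contact: within an element, laterally
    # adjacent tiles bond; across elements, each of the eight positional
    # columns bonds consecutive tiles (a pole spans all columns). A rod
    # occupies its seam column only until the septum slice displaces it,
    # so a complete septum's bonds are exactly the cut severing the two
    # daughter walls. Connector indices follow the tile definitions.

    _COL_CONN = {  # role -> (lower-side connector, upper-side connector)
        "wall": (0, 1),
        "disc_pole": (None, None),  # rim connector = column position
        "slice": (0, 1),
        "rod": (2, 3),
    }

    def _column_entry(self, el, p):
        """(tid, role) occupying column p of an element, or None."""
        if isinstance(el, Ring):
            tid = el.walls.get(p)
            return (tid, "wall") if tid is not None else None
        if el.kind == "pole":
            tid = el.tiles.get(0)
            return (tid, "pole") if tid is not None else None
        if p in el.tiles:
            return (el.tiles[p], "slice")
        if p in el.rods:
            return (el.rods[p], "rod")
        return None

    def _conn_idx(self, role, side, p):
        if role == "pole":
            return p
        return {"wall": (0, 1), "slice": (0, 1), "rod": (2, 3)}[role][side]

    def _column_bonds(self, st, p):
        bonds = set()
        col = [
            self._column_entry(el, p)
            for el in st.elements
        ]
        col = [c for c in col if c is not None]
        for (ta, ra), (tb, rb) in zip(col[:-1], col[1:]):
            bonds.add(frozenset({(ta, self._conn_idx(ra, 1, p)),
                                 (tb, self._conn_idx(rb, 0, p))}))
        return bonds

    def _lateral_bonds(self, el):
        bonds = set()
        if isinstance(el, Ring):
            items = el.walls
            conns = (3, 2)  # right edge of p to left edge of p+1
        else:
            if el.kind == "pole":
                return bonds
            items = el.tiles
            conns = (3, 2)
            # slice-to-rod anchors and rod-to-rod ends
            for p, rid in el.rods.items():
                if p in el.tiles:
                    bonds.add(frozenset({(el.tiles[p], 4), (rid, 4)}))
                q = (p + 1) % N_POS
                if q in el.rods:
                    bonds.add(frozenset({(rid, 1), (el.rods[q], 0)}))
        for p, tid in items.items():
            q = (p + 1) % N_POS
            if q in items:
                bonds.add(frozenset({(tid, conns[0]), (items[q], conns[1])}))
        return bonds

    def _rebuild_bonds(self, cfg):
        st = self.state(cfg)
        bonds = set()
        for p in range(N_POS):
            bonds |= self._column_bonds(st, p)
        for el in st.elements:
            bonds |= self._lateral_bonds(el)
        cfg.bonds = bonds
        st.bonds_dirty = False

    def ensure_bonds(self, cfg):
        """Bonds derive from contact and are rebuilt lazily; call this
        before reading cfg.bonds."""
        if self.state(cfg).bonds_dirty:
            self._rebuild_bonds(cfg)

    def _drop_bonds_of(self, cfg, tid):
        self.state(cfg).bonds_dirty = True

    # -- injuries ------------------------------------------------------
    def components(self, cfg) -> list[int]:
        """All injurable components (tile ids, rods included)."""
        return sorted(cfg.tiles)

    def protion_targets(self, cfg) -> list[int]:
        return sorted(
            tid for tid, pt in cfg.tiles.items()
            if pt.protion_alive and any(pt.protion_alive)
        )

    def remove_tile(self, cfg, tid: int):
        st = self.state(cfg)
        entry = st.tile_index.pop(tid, None)
        if entry is None:
            raise KeyError(f"no such component: tile {tid}")
        el, p, role = entry
        if role == "wall":
            el.walls.pop(p, None)
        elif role == "rod":
            el.rods.pop(p, None)
        else:
            el.tiles.pop(p, None)
        del cfg.tiles[tid]
        self._after_damage(cfg)

    def remove_protion(self, cfg, tid: int):
        pt = cfg.tiles.get(tid)
        if pt is None or not pt.protion_alive:
            raise KeyError(f"no such component: protion on tile {tid}")
        pt.protion_alive = [False] * len(pt.protion_alive)

    def break_bond(self, cfg, bond: frozenset):
        self.ensure_bonds(cfg)
        if bond not in cfg.bonds:
            raise KeyError(f"no such component: bond {sorted(bond)}")
        cfg.broken_bonds.add(bond)
        self._cull_detached(cfg)

    def inject_floats(self, cfg, sys, multiset: dict, rng,
                      compartment: int | None = None):
        st = self.state(cfg)
        if not st.compartments:
            return
        if compartment is None:
            compartment = int(rng.integers(len(st.compartments)))
        comp = st.compartments[compartment]
        sp = sys.species_index
        for label, k in multiset.items():
            if k <= 0:
                continue
            z = rng.uniform(comp["z_lo"] + 0.1, comp["z_hi"] - 0.1, size=k)
            xy = self.axis + rng.uniform(-0.5, 0.5, size=(k, 2))
            cfg.floats.add(sp[label], np.column_stack([xy, z]), comp["id"])
        cfg.floats.flush()

    def _after_damage(self, cfg):
        self._rebuild_bonds(cfg)
        self._cull_detached(cfg)
        self._rebuild_compartments(cfg)

    def _cull_detached(self, cfg):
        """Tiles no longer bonded to the main assembly drift off and are
        lost; the largest connected piece (the one holding the seed end)
        is kept."""
        import networkx as nx

        st = self.state(cfg)
        if not cfg.tiles:
            return
        self.ensure_bonds(cfg)
        g = nx.Graph()
        g.add_nodes_from(cfg.tiles)
        for b in cfg.active_bonds():
            (ta, _), (tb, _) = tuple(b)
            g.add_edge(ta, tb)
        comps = list(nx.connected_components(g))
        if len(comps) <= 1:
            return
        keep = max(comps, key=lambda c: (len(c), -min(c)))
        lost = set(cfg.tiles) - keep
        for tid in lost:
            entry = st.tile_index.pop(tid, None)
            if entry is not None:
                el, p, role = entry
                if role == "wall":
                    el.walls.pop(p, None)
                elif role == "rod":
                    el.rods.pop(p, None)
                else:
                    el.tiles.pop(p, None)
            del cfg.tiles[tid]
        self._rebuild_bonds(cfg)
        self._rebuild_compartments(cfg)

    # -- observables ----------------------------------------------------
    def has_pending_division(self, cfg) -> bool:
        """A complete, not-yet-divided septum exists: the cell is adult,
        one step from dividing."""
        st = self.state(cfg)
        return any(
            isinstance(el, Disc) and el.kind == "septum"
            and el.complete and not el.divided
            for el in st.elements
        )

    def divisions(self, cfg) -> int:
        return self.state(cfg).divisions
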