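import numpy as np
import pytest

from msystems.core import (
    Configuration,
    CreationRule,
    DestructionRule,
    Environment,
    FloatingObjectSpec,
    GlueRelation,
    MetabolicRule,
    MSystem,
    ProtionSpec,
    SimpleCellAssembly,
    Slot,
    TileSpec,
    applicable_instances,
    make_configuration,
    run,
    step,
)
from msystems.geometry import Connector, Pose, TileShape
from msystems.mbac import build_mbac, preset

ENV_BOX = Environment((0, 0, 0), (10, 10, 10))


def bench_system(rules, slots=(), cell=((4, 4, 4), (6, 6, 6)), env=None):
    """A bench-top system: one wall tile with a pore protion on a fixed
    cubic compartment; creation slots declared explicitly."""
    wall = TileSpec(
        "wall",
        TileShape.rectangle(1, 1),
        (Connector(np.array([[-0.5, 0, 0], [0.5, 0, 0]]), "g"),),
        (ProtionSpec("pore", (0.0, 0.0, 0.0)),),
    )
    brick = TileSpec("brick", TileShape.rectangle(1, 1),
                     (Connector(np.array([0.5, 0.0, 0.0]), "g"),))
    asm = SimpleCellAssembly(*cell) if cell else SimpleCellAssembly()
    asm.slots = list(slots)
    sys = MSystem(
        floating_specs={
            "a": FloatingObjectSpec("a", mobility=0.0),
            "s": FloatingObjectSpec("s", mobility=0.0),
        },
        tile_specs={"wall": wall, "brick": brick},
        glue_relation=GlueRelation([("g", "g")]),
        rules=list(rules),
        interaction_radius=1.0,
        environment=env or ENV_BOX,
        seed_tiles=[("wall", Pose((4.0, 5.0, 5.0)))],
        assembly=asm,
    )
    return sys


TRANSPORT = MetabolicRule("import", "pore", {"a": 1}, {"a": 1})


class TestValidation:
    def test_rule_referencing_undeclared_tile(self):
        with pytest.raises(ValueError, match="undeclared tile"):
            bench_system([CreationRule("c", {"a": 1}, "ghost", "g")])

    def test_rule_referencing_undeclared_float(self):
        with pytest.raises(ValueError, match="undeclared floating"):
            bench_system([CreationRule("c", {"x": 1}, "brick", "g")])

    def test_rule_referencing_undeclared_protion(self):
        with pytest.raises(ValueError, match="undeclared protion"):
            bench_system([MetabolicRule("m", "ghost", {"a": 1}, {"a": 1})])

    def test_positive_radius_required(self):
        sys = bench_system([])
        sys.interaction_radius = 0.0
        with pytest.raises(ValueError, match="radius"):
            sys.validate()

    def test_creation_requires_reactants(self):
        with pytest.raises(ValueError, match="floating objects"):
            CreationRule("c", {}, "brick", "g")


class TestApplicability:
    def test_empty_configuration(self):
        sys = bench_system([TRANSPORT])
        cfg = Configuration()
        cfg.tiles.clear()
        cfg = make_configuration(sys)
        cfg.tiles.clear()
        assert applicable_instances(cfg, sys) == []

    def test_nutrient_beyond_interaction_radius(self):
        sys = bench_system([TRANSPORT])
        cfg = make_configuration(sys)
        # protion site at (4,5,5); nutrient 2r away
        cfg.floats.add(0, np.array([4.0, 5.0, 7.0]))
        assert applicable_instances(cfg, sys) == []

    def test_nutrient_within_half_radius_gives_one_instance(self):
        # hand-checked single-step oracle: one a at r/2 from the pore of
        # the only wall tile -> exactly one metabolic instance
        sys = bench_system([TRANSPORT])
        cfg = make_configuration(sys)
        cfg.floats.add(0, np.array([4.0, 5.0, 5.5]))
        inst = applicable_instances(cfg, sys)
        assert len(inst) == 1
        assert inst[0].rule is TRANSPORT
        assert inst[0].float_idx == (0,)


class TestStep:
    def test_no_rules_no_objects_only_counter_advances(self, rng):
        sys = bench_system([])
        cfg = make_configuration(sys)
        tiles_before = dict(cfg.tiles)
        step(cfg, sys, rng)
        assert cfg.iteration == 1
        assert cfg.tiles == tiles_before
        assert len(cfg.floats) == 0

    def test_transport_conserves_nutrient_count(self, rng):
        sys = bench_system([TRANSPORT])
        cfg = make_configuration(sys)
        cfg.floats.add(0, np.array([[4.0, 5.0, 5.5], [4.0, 5.0, 4.6]]))
        for _ in range(5):
            step(cfg, sys, rng)
        # pure transport: total a unchanged, some moved inside
        assert cfg.floats.count(species=0) == 2
        assert cfg.floats.count(species=0, loc=0) >= 1

    def test_competing_creations_consume_one_nutrient_once(self):
        # two slots, one nutrient in range of both: exactly one fires,
        # under every ordering of the conflict resolution
        for seed in range(24):
            slots = [
                Slot(CreationRule("c", {"a": 1}, "brick", "g"),
                     np.array([5.0, 5.0, 5.0]), None, None, token="s1"),
                Slot(CreationRule("c", {"a": 1}, "brick", "g"),
                     np.array([5.2, 5.0, 5.0]), None, None, token="s2"),
            ]
            sys = bench_system([slots[0].rule], slots=slots)
            cfg = make_configuration(sys)
            cfg.floats.add(0, np.array([5.1, 5.0, 5.0]))
            step(cfg, sys, np.random.default_rng(seed))
            assert cfg.tile_count() == 2  # seed wall + exactly one brick
            assert cfg.floats.count(species=0) == 0

    def test_destruction_produces_floats(self, rng):
        rule = DestructionRule("d", ("brick",), produced={"s": 2})
        slots = [Slot(CreationRule("c", {"a": 1}, "brick", "g"),
                      np.array([5.0, 5.0, 5.0]), None, None, token="s1")]
        sys = bench_system([slots[0].rule, rule], slots=slots)
        cfg = make_configuration(sys)
        cfg.floats.add(0, np.array([5.0, 5.0, 5.0]))
        step(cfg, sys, rng)
        assert cfg.tile_count() == 2
        step(cfg, sys, rng)
        assert cfg.tile_count() == 1  # brick annihilated
        assert cfg.floats.count(species=1) == 2


class TestRun:
    def test_negative_iterations_rejected(self):
        sys = bench_system([])
        with pytest.raises(ValueError):
            run(sys, -1)

    def test_zero_iterations_initial_census_only(self):
        res = run(bench_system([]), 0)
        assert len(res.census) == 1
        assert res.census["iteration"].iloc[0] == 0

    def test_fixed_seed_bit_reproducibility(self, ecoli_params):
        # identical trajectories, bit-stable census
        r1 = run(build_mbac(ecoli_params), 25, np.random.default_rng(5))
        r2 = run(build_mbac(ecoli_params), 25, np.random.default_rng(5))
        assert r1.census.equals(r2.census)
        assert np.array_equal(r1.final.floats.pos, r2.final.floats.pos)
        assert r1.final.bonds == r2.final.bonds

    def test_stop_when(self):
        sys = bench_system([])
        res = run(sys, 50, stop_when=lambda c: c.iteration >= 3)
        assert res.final.iteration == 3


class TestConservation:
    def test_objects_change_only_through_rules(self, ecoli_params):
        """Census bookkeeping: every object now present was injected or
        produced by a rule; every object gone was consumed by a rule."""
        sys = build_mbac(ecoli_params)
        res = run(sys, 40, np.random.default_rng(2))
        cfg = res.final
        sp = sys.species_index
        for label in ("a", "s"):
            inflow = cfg.injected.get(label, 0) + cfg.produced_by_rules.get(label, 0)
            outflow = cfg.consumed_by_rules.get(label, 0)
            assert cfg.floats.count(species=sp[label]) == inflow - outflow


class TestBondValidity:
    def test_all_bonds_connect_matching_glues(self, adult_cell):
        cfg, sys = adult_cell
        sys.assembly.ensure_bonds(cfg)
        assert cfg.bond_count() > 0
        for bond in cfg.active_bonds():
            (ta, ca), (tb, cb) = sorted(bond)
            ga = sys.tile_specs[cfg.tiles[ta].spec].connectors[ca].glue
            gb = sys.tile_specs[cfg.tiles[tb].spec].connectors[cb].glue
            assert sys.glue_relation.matches(ga, gb), (
                f"bond {bond}: glues {ga!r}/{gb!r} do not match"
            )

    def test_each_connector_bound_at_most_once(self, adult_cell):
        cfg, sys = adult_cell
        sys.assembly.ensure_bonds(cfg)
        seen = {}
        for bond in cfg.active_bonds():
            for end in bond:
                seen[end] = seen.get(end, 0) + 1
        assert max(seen.values()) == 1
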