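import copy

import numpy as np
import pytest

from msystems.injury import (
    Injury,
    SurvivalEstimate,
    inflict,
    random_injury,
    sample_component_injuries,
    survival_experiment,
    survival_sweep,
)
from msystems.injury import first_crossing_below, mean_generation_time


@pytest.fixture
def injured_copy(adult_cell):
    """Deep copy of the adult configuration so tests can mutate it."""
    cfg, sys = adult_cell
    return copy.deepcopy(cfg), sys


class TestInflict:
    def test_remove_wall_tile_opens_hole(self, injured_copy, rng):
        cfg, sys = injured_copy
        asm = sys.assembly
        wall = next(t for t, pt in cfg.tiles.items() if pt.spec == "wall")
        n0 = len(cfg.tiles)
        inflict(cfg, sys, Injury("remove_tile", wall), rng)
        assert len(cfg.tiles) == n0 - 1
        st = asm.state(cfg)
        assert any(c["open_frac"] > 0 for c in st.compartments)

    def test_break_bond_retains_tiles(self, injured_copy, rng):
        cfg, sys = injured_copy
        sys.assembly.ensure_bonds(cfg)
        n_tiles, n_bonds = len(cfg.tiles), cfg.bond_count()
        bond = sorted(cfg.active_bonds(), key=lambda b: sorted(b))[0]
        inflict(cfg, sys, Injury("break_bond", bond), rng)
        assert len(cfg.tiles) == n_tiles
        assert cfg.bond_count() == n_bonds - 1

    def test_inject_zero_objects_is_noop(self, injured_copy, rng):
        cfg, sys = injured_copy
        n = len(cfg.floats)
        inflict(cfg, sys, Injury("inject_floats", (0, {})), rng)
        assert len(cfg.floats) == n

    def test_inject_floats_appear_inside(self, injured_copy, rng):
        cfg, sys = injured_copy
        n_in = int((cfg.floats.loc >= 0).sum())
        inflict(cfg, sys, Injury("inject_floats", (0, {"a": 3, "s": 2})), rng)
        assert int((cfg.floats.loc >= 0).sum()) == n_in + 5

    def test_remove_protion_disables_channel(self, injured_copy, rng):
        cfg, sys = injured_copy
        tid = sys.assembly.protion_targets(cfg)[0]
        inflict(cfg, sys, Injury("remove_protion", tid), rng)
        assert not any(cfg.tiles[tid].protion_alive)
        assert tid in cfg.tiles  # the tile itself survives

    def test_missing_target_names_component(self, injured_copy, rng):
        cfg, sys = injured_copy
        with pytest.raises(KeyError, match="no such component"):
            inflict(cfg, sys, Injury("remove_tile", 99999), rng)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown injury kind"):
            Injury("teleport", 0)


class TestSampling:
    def test_component_sampling_distinct_targets(self, injured_copy):
        cfg, sys = injured_copy
        injs = sample_component_injuries(cfg, sys, 20, np.random.default_rng(0))
        targets = [i.target for i in injs]
        assert len(targets) == len(set(targets)) == 20
        assert all(i.kind == "remove_tile" for i in injs)

    def test_kind_sampling_draws_eligible_targets(self, injured_copy):
        cfg, sys = injured_copy
        g = np.random.default_rng(0)
        kinds = {random_injury(cfg, sys, g).kind for _ in range(40)}
        assert kinds == {"remove_tile", "remove_protion", "break_bond",
                         "inject_floats"}


class TestEstimates:
    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError):
            SurvivalEstimate(0, 10, 1.2, None)

    def test_uninjured_growth_always_survives(self, ecoli_params):
        est = survival_experiment(ecoli_params, 0, n_runs=5, rng=1)
        assert est.p_survive == 1.0
        assert est.mean_recovery_ratio == pytest.approx(1.0, abs=0.25)

    def test_removing_every_component_is_lethal(self, ecoli_params):
        est = survival_experiment(ecoli_params, 34, n_runs=5, rng=1)
        assert est.p_survive == 0.0
        assert est.mean_recovery_ratio is None  # undefined, not a number

    def test_recovery_ratio_at_least_one_under_mild_injury(self, ecoli_params):
        # repair consumes extra creation-rule firings, so surviving runs
        # take at least as long as the uninjured baseline
        est = survival_experiment(ecoli_params, 6, n_runs=6, rng=2)
        assert est.p_survive > 0
        assert est.mean_recovery_ratio >= 1.0

    def test_sequential_schedule_runs(self, ecoli_params):
        est = survival_experiment(
            ecoli_params, 3, schedule="random_times", n_runs=4, rng=3
        )
        assert 0.0 <= est.p_survive <= 1.0

    def test_unknown_schedule(self, ecoli_params):
        with pytest.raises(ValueError, match="unknown schedule"):
            survival_experiment(ecoli_params, 1, schedule="nightly")

    def test_generation_time_positive(self, ecoli_params):
        g0 = mean_generation_time(ecoli_params, n_runs=4, rng=0)
        assert 10 < g0 < 120

    def test_sweep_frame_and_crossing_helper(self, ecoli_params):
        df = survival_sweep(ecoli_params, [0, 34], n_runs=4, rng=4)
        assert list(df.columns) == ["n_injuries", "p_survive",
                                    "mean_recovery_ratio"]
        assert df["p_survive"].iloc[0] == 1.0
        assert df["p_survive"].iloc[-1] == 0.0
        assert first_crossing_below(df) == 34
        assert first_crossing_below(df.iloc[:1]) is None

    def test_self_healing_uses_only_growth_rules(self, ecoli_params, injured_copy):
        # no repair-specific rule exists: the rule inventory is the nine
        # growth rules whether or not the cell is injured
        from msystems.mbac import build_mbac

        sys = build_mbac(ecoli_params)
        names = sorted(r.name for r in sys.rules)
        _, sys_injured = injured_copy
        assert sorted(r.name for r in sys_injured.rules) == names
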