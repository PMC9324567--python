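"""Serialization: model JSON dialect, census CSV, digraphs, snapshots.

The model document is a JSON object with sections floating_objects,
glue_relation, tiles, rules, environment, seed_tiles and an optional
assembly section naming the assembly model (the bacterial chain presets
serialize their species parameters there). Parsing is validating:
errors name the JSON path of the offending field. parse o serialize is
the identity on canonical documents.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import networkx as nx
import numpy as np

from .configspace import TransitionDigraph
from .core import (
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
    TileSpec,
)
from .geometry import Connector, Pose, TileShape

__all__ = [
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
    "model_hash",
    "export_snapshot",
    "write_edge_list",
    "read_edge_list",
    "write_graphml",
    "demo_digraph",
    "make_fixture",
    "FIXTURE_NAMES",
]


class ModelError(ValueError):
    """A schema violation, naming the JSON path of the offending field."""


def _err(path: str, msg: str) -> ModelError:
    return ModelError(f"{path}: {msg}")


# ---------------------------------------------------------------------------
# model document
# ---------------------------------------------------------------------------


def _rule_to_dict(rule) -> dict:
    if isinstance(rule, MetabolicRule):
        return {
            "type": "metabolic",
            "name": rule.name,
            "protion": rule.protion,
            "consumed": dict(rule.consumed),
            "produced": dict(rule.produced),
            "consumed_side": rule.consumed_side,
            "produced_side": rule.produced_side,
        }
    if isinstance(rule, CreationRule):
        return {
            "type": "creation",
            "name": rule.name,
            "consumed": dict(rule.consumed),
            "tile": rule.tile,
            "at_glue": rule.at_glue,
        }
    if isinstance(rule, DestructionRule):
        return {
            "type": "destruction",
            "name": rule.name,
            "tiles": list(rule.tiles),
            "consumed": dict(rule.consumed),
            "produced": dict(rule.produced),
        }
    return {"type": "division", "name": rule.name}


def model_to_dict(sys: MSystem) -> dict:
    doc = {
        "floating_objects": [
            {
                "name": f.name,
                "radius": f.radius,
                "mobility": f.mobility,
                "env_concentration": f.env_concentration,
            }
            for f in (sys.floating_specs[k] for k in sorted(sys.floating_specs))
        ],
        "glue_relation": [list(p) for p in sys.glue_relation.pairs],
        "tiles": [
            {
                "name": t.name,
                "shape": {
                    "kind": t.shape.kind,
                    "vertices": np.round(t.shape.vertices, 12).tolist(),
                },
                "connectors": [
                    {
                        "site": np.round(np.atleast_2d(c.site), 12).tolist(),
                        "glue": c.glue,
                        "attach_angle": c.attach_angle,
                    }
                    for c in t.connectors
                ],
                "protions": [
                    {"name": p.name, "site": list(p.site)} for p in t.protions
                ],
            }
            for t in (sys.tile_specs[k] for k in sorted(sys.tile_specs))
        ],
        "rules": [_rule_to_dict(r) for r in sys.rules],
        "interaction_radius": sys.interaction_radius,
        "environment": {
            "box_lo": list(sys.environment.lo),
            "box_hi": list(sys.environment.hi),
            "nutrient_budget": sys.environment.nutrient_budget,
        },
        "seed_tiles": [
            {
                "tile": name,
                "position": np.round(pose.position, 12).tolist(),
                "orientation": np.round(pose.orientation, 12).tolist(),
            }
            for name, pose in sys.seed_tiles
        ],
    }
    asm = sys.assembly
    if asm is not None and type(asm).__name__ == "ChainAssembly":
        from dataclasses import asdict

        doc["assembly"] = {
            "type": "bacterial_chain",
            "species_params": asdict(asm.params),
        }
    else:
        doc["assembly"] = None
    return doc


def _parse_rule(d: dict, path: str):
    kind = d.get("type")
    try:
        if kind == "metabolic":
            return MetabolicRule(
                d["name"], d["protion"], d["consumed"], d["produced"],
                d.get("consumed_side", "out"), d.get("produced_side", "in"),
            )
        if kind == "creation":
            return CreationRule(d["name"], d["consumed"], d["tile"], d["at_glue"])
        if kind == "destruction":
            return DestructionRule(
                d["name"], tuple(d["tiles"]), d.get("consumed", {}),
                d.get("produced", {}),
            )
        if kind == "division":
            return DivisionRule(d.get("name", "division"))
    except KeyError as e:
        raise _err(f"{path}.{e.args[0]}", "missing required field") from None
    except (TypeError, ValueError) as e:
        raise _err(path, str(e)) from None
    raise _err(f"{path}.type", f"unknown rule type {kind!r}")


def model_from_dict(doc: dict) -> MSystem:
    try:
        floats = {}
        for i, f in enumerate(doc["floating_objects"]):
            path = f"$.floating_objects[{i}]"
            try:
                floats[f["name"]] = FloatingObjectSpec(
                    f["name"], f.get("radius", 0.05), f.get("mobility", 1.0),
                    f.get("env_concentration", 0.0),
                )
            except (KeyError, ValueError) as e:
                raise _err(path, str(e)) from None
        tiles = {}
        for i, t in enumerate(doc["tiles"]):
            path = f"$.tiles[{i}]"
            try:
                shape = TileShape(t["shape"]["kind"], np.asarray(t["shape"]["vertices"]))
                conns = tuple(
                    Connector(
                        np.asarray(c["site"]).squeeze(),
                        c["glue"],
                        c.get("attach_angle", 0.0),
                    )
                    for c in t.get("connectors", [])
                )
                prots = tuple(
                    ProtionSpec(p["name"], tuple(p["site"]))
                    for p in t.get("protions", [])
                )
                tiles[t["name"]] = TileSpec(t["name"], shape, conns, prots)
            except (KeyError, ValueError) as e:
                raise _err(path, str(e)) from None
        rules = [
            _parse_rule(r, f"$.rules[{i}]") for i, r in enumerate(doc["rules"])
        ]
        env = doc["environment"]
        environment = Environment(
            tuple(env["box_lo"]), tuple(env["box_hi"]), env.get("nutrient_budget")
        )
        seeds = []
        for i, s in enumerate(doc.get("seed_tiles", [])):
            path = f"$.seed_tiles[{i}]"
            if s["tile"] not in tiles:
                raise _err(f"{path}.tile", f"undeclared tile {s['tile']!r}")
            seeds.append(
                (
                    s["tile"],
                    Pose(
                        np.asarray(s["position"]),
                        np.asarray(s.get("orientation", [0.0, 0.0, 0.0, 1.0])),
                    ),
                )
            )
        assembly = None
        asm = doc.get("assembly")
        if asm is not None:
            if asm.get("type") != "bacterial_chain":
                raise _err("$.assembly.type", f"unknown assembly {asm.get('type')!r}")
            from .mbac import ChainAssembly, SpeciesParams

            sp = dict(asm["species_params"])
            sp["box"] = tuple(sp["box"])
            assembly = ChainAssembly(SpeciesParams(**sp))
        try:
            return MSystem(
                floating_specs=floats,
                tile_specs=tiles,
                glue_relation=GlueRelation(
                    tuple(p) for p in doc.get("glue_relation", [])
                ),
                rules=rules,
                interaction_radius=doc["interaction_radius"],
                environment=environment,
                seed_tiles=seeds,
                assembly=assembly,
            )
        except ValueError as e:
            raise _err("$", str(e)) from None
    except KeyError as e:
        raise _err(f"$.{e.args[0]}", "missing required section") from None


def save_model(sys: MSystem, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(model_to_dict(sys), indent=1, sort_keys=True) + "\n")
    return path


def load_model(path) -> MSystem:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return model_from_dict(json.loads(path.read_text()))


def model_hash(sys: MSystem) -> str:
    blob = json.dumps(model_to_dict(sys), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# snapshots
# ---------------------------------------------------------------------------


def export_snapshot(cfg: Configuration, sys: MSystem, path, fmt: str = "json") -> Path:
    """Write the full state (json) or the placed polygon tiles (obj,
    one face per polygon tile; rods become line elements)."""
    path = Path(path)
    if fmt == "json":
        doc = {
            "iteration": cfg.iteration,
            "tiles": [
                {
                    "id": tid,
                    "spec": pt.spec,
                    "position": np.round(pt.pose.position, 9).tolist(),
                    "orientation": np.round(pt.pose.orientation, 9).tolist(),
                    "protion_alive": list(pt.protion_alive),
                }
                for tid, pt in sorted(cfg.tiles.items())
            ],
            "bonds": sorted(sorted(map(list, b)) for b in cfg.active_bonds()),
            "floats": {
                "positions": np.round(cfg.floats.pos, 9).tolist(),
                "species": cfg.floats.species.tolist(),
                "location": cfg.floats.loc.tolist(),
            },
        }
        path.write_text(json.dumps(doc, indent=1) + "\n")
        return path
    if fmt != "obj":
        raise ValueError(f"unknown snapshot format {fmt!r}")
    lines = ["# msystems snapshot", f"# iteration {cfg.iteration}"]
    v_off = 1
    for tid, pt in sorted(cfg.tiles.items()):
        shape = sys.tile_specs[pt.spec].shape
        verts = shape.placed(pt.pose)
        lines.append(f"o tile_{tid}_{pt.spec}")
        for v in verts:
            lines.append(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}")
        n = len(verts)
        if shape.kind == "polygon2D":
            lines.append("f " + " ".join(str(v_off + k) for k in range(n)))
        else:
            lines.append(f"l {v_off} {v_off + 1}")
        v_off += n
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# digraph I/O
# ---------------------------------------------------------------------------


def write_edge_list(g: TransitionDigraph, path) -> Path:
    """Whitespace edge list; a '# root <node>' header records the root,
    '# node <n>' lines record isolated nodes."""
    path = Path(path)
    lines = []
    if g.root is not None:
        lines.append(f"# root {g.root}")
    for n in sorted(map(str, nx.isolates(g.graph))):
        lines.append(f"# node {n}")
    for u, v in sorted((str(a), str(b)) for a, b in g.arcs):
        lines.append(f"{u} {v}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_edge_list(path) -> TransitionDigraph:
    path = Path(path)
    root = None
    arcs = []
    nodes = []
    for ln in path.read_text().splitlines():
        ln = ln.strip()
        if not ln:
            continue
        if ln.startswith("#"):
            parts = ln[1:].split()
            if parts[:1] == ["root"]:
                root = parts[1]
            elif parts[:1] == ["node"]:
                nodes.append(parts[1])
            continue
        u, v = ln.split()
        arcs.append((u, v))
    return TransitionDigraph.from_arcs(arcs, root=root, nodes=nodes)


def write_graphml(g: TransitionDigraph, path) -> Path:
    path = Path(path)
    h = nx.DiGraph(g.graph)
    if g.root is not None:
        h.graph["root"] = str(g.root)
    nx.write_graphml(h, path)
    return path


# ---------------------------------------------------------------------------
# named fixtures
# ---------------------------------------------------------------------------


def demo_digraph(which: str) -> TransitionDigraph:
    """Benchmark configuration spaces with known decompositions.

    "reentrant": one h-component covering the whole graph; C7 and C8
    are unreachable from the root yet homeostatic (they transition back
    into the cycle). "threefold": three 2-node h-components fed from a
    2-node morphogenetic phase. "closure": a cycle whose forward
    closure is the entire graph (three leaves merge into the single
    h-component).
    """
    if which == "reentrant":
        arcs = [
            ("C0", "C1"), ("C1", "C2"), ("C2", "C3"), ("C3", "C4"),
            ("C4", "C5"), ("C5", "C6"), ("C6", "C3"),
            ("C7", "C8"), ("C8", "C3"),
        ]
        # the cycle C3..C6 absorbs everything upstream (C0-C2, C7-C8)
        return TransitionDigraph.from_arcs(arcs, root="C0")
    if which == "threefold":
        arcs = [
            ("C0", "C1"),
            ("C1", "C2"), ("C1", "C4"), ("C1", "C6"),
            ("C2", "C3"), ("C3", "C2"),
            ("C4", "C5"), ("C5", "C4"),
            ("C6", "C7"), ("C7", "C6"),
        ]
        return TransitionDigraph.from_arcs(arcs, root="C0")
    if which == "closure":
        arcs = [
            ("C0", "C1"), ("C1", "C2"), ("C2", "C0"),
            ("C2", "C3"), ("C3", "C4"),
            ("C1", "C5"), ("C3", "C6"), ("C4", "C7"),
        ]
        return TransitionDigraph.from_arcs(arcs, root="C0")
    raise KeyError(f"unknown demo digraph {which!r}")


FIXTURE_NAMES = (
    "digraph_reentrant", "digraph_threefold", "digraph_closure",
    "toy_chain", "toy_reversible", "gompertz_demo",
)


def make_fixture(name: str, out_dir=".") -> Path:
    """Emit a named fixture file (digraph edge lists, toy configuration
    spaces, a synthetic noiseless sigmoidal census)."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if name.startswith("digraph_"):
        g = demo_digraph(name[len("digraph_"):])
        return write_edge_list(g, out_dir / f"{name}.edges")
    if name in ("toy_chain", "toy_reversible"):
        from .configspace import ToyChainSystem, enumerate_configspace

        toy = ToyChainSystem(3, reversible=(name == "toy_reversible"))
        g = enumerate_configspace(toy)
        return write_edge_list(g, out_dir / f"{name}.edges")
    if name == "gompertz_demo":
        from .kinetics import synthetic_census

        a, mu, lam = math.log(80.0), 0.1, 10.0
        census = synthetic_census("gompertz", a, mu, lam, t_max=100)
        path = out_dir / "gompertz_demo.csv"
        df = census.runs[0].assign(run=0)[["run", "iteration", "cells"]]
        header = f"# gompertz census: A={a} mu={mu} lam={lam} (noiseless)\n"
        path.write_text(header + df.to_csv(index=False))
        return path
    raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
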