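"""Built-in example networks, a seeded random-network generator, and an
independent brute-force enumerator used for cross-checking.

Each built-in fixture returns the model ready to simulate (classified, with
reverse edges added), the published initial condition, and a dictionary of
expected outcomes transcribed from the source analyses (0-based edge
indices)."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace

import numpy as np

from .engine import EngineConfig, Terminal
from .model import (
    Interaction,
    Kind,
    NetworkModel,
    Speed,
    ValidationError,
    augment_reverse_edges,
    as_state,
    classify_and_default,
)

__all__ = [
    "FIXTURE_NAMES",
    "build_fixture",
    "RandomNetworkParams",
    "generate_random_network",
    "oracle_enumerate",
]


def _prepare(nodes, edges, observables=()):
    model = NetworkModel(list(nodes), list(edges), list(observables))
    return augment_reverse_edges(classify_and_default(model))


# --------------------------------------------------------------------------
# built-in networks
# --------------------------------------------------------------------------

def _conversion_basic():
    # A -> B gated by activator C; the reverse direction is auto-added.
    model = _prepare(
        ["A", "B", "C"],
        [Interaction(0, inputs=(0,), outputs=(1,), activators=(2,))],
    )
    expected = {
        "n_nodes": 3,
        "n_edges": 2,
        "x0": (1, 0, 1),
        "sequences": [(0,)],
        "states": {(0,): [(1, 0, 1), (0, 1, 1)]},
        "terminals": {(0,): Terminal.DEAD_END},
        # with the activator absent and the product present, only the
        # reverse edge fires
        "x0_reverse": (0, 1, 0),
        "sequences_reverse": [(1,)],
        "states_reverse": {(1,): [(0, 1, 0), (1, 0, 0)]},
    }
    return model, as_state(expected["x0"]), expected


def _transcription_basic():
    # transcript B is written whenever driver A is present
    model = _prepare(["A", "B"], [Interaction(0, outputs=(1,), activators=(0,))])
    expected = {
        "n_nodes": 2,
        "n_edges": 1,
        "x0": (1, 0),
        "sequences": [(0,)],
        "states": {(0,): [(1, 0), (1, 1)]},
        "terminals": {(0,): Terminal.DEAD_END},
    }
    return model, as_state(expected["x0"]), expected


def _speed_example():
    # A + B -> A.B ; C + A.B -> A + B.C ; A.B -> Apoptosis (slow in reality)
    nodes = ["A", "B", "C", "A.B", "B.C", "Apoptosis"]
    edges = [
        Interaction(0, inputs=(0, 1), outputs=(3,)),
        Interaction(1, inputs=(2, 3), outputs=(0, 4)),
        Interaction(2, inputs=(3,), outputs=(5,)),
    ]
    model = _prepare(nodes, edges)
    expected = {
        "n_nodes": 6,
        "n_edges": 3,
        "x0": (1, 1, 1, 0, 0, 0),
        # without time-scale labels both orders are possible ...
        "sequences": [(0, 1), (0, 2)],
        "states": {
            (0, 1): [(1, 1, 1, 0, 0, 0), (0, 0, 1, 1, 0, 0), (1, 0, 0, 0, 1, 0)],
            (0, 2): [(1, 1, 1, 0, 0, 0), (0, 0, 1, 1, 0, 0), (0, 0, 1, 0, 0, 1)],
        },
        # ... labeling the apoptosis process slow keeps only the first
        "slow_edge": 2,
        "sequences_slow": [(0, 1)],
    }
    return model, as_state(expected["x0"]), expected


def _priority_example():
    # A + B -> A.B ; C + A.B -> A + B.C (outranks) ; D + A.B -> B + A.D
    nodes = ["A", "B", "C", "D", "A.B", "B.C", "A.D"]
    edges = [
        Interaction(0, inputs=(0, 1), outputs=(4,)),
        Interaction(1, inputs=(2, 4), outputs=(0, 5), priority_above={2}),
        Interaction(2, inputs=(3, 4), outputs=(1, 6)),
    ]
    model = _prepare(nodes, edges)
    expected = {
        "n_nodes": 7,
        "n_edges": 3,
        "x0": (1, 1, 1, 1, 0, 0, 0),
        "sequences": [(0, 1)],
        "states": {
            (0, 1): [
                (1, 1, 1, 1, 0, 0, 0),
                (0, 0, 1, 1, 1, 0, 0),
                (1, 0, 0, 1, 0, 1, 0),
            ],
        },
        # dropping the priority relation restores both alternatives
        "sequences_unprioritized": [(0, 1), (0, 2)],
    }
    return model, as_state(expected["x0"]), expected


def _illustrative():
    """Twelve-node didactic network exercising every rule at once:
    an inhibitor, a slow transcription, a priority pair and a reverse edge."""
    nodes = [f"n{i}" for i in range(1, 13)]
    edges = [
        Interaction(0, inputs=(0, 1), outputs=(7,), inhibitors=(2,)),
        Interaction(1, outputs=(8,), activators=(3,)),  # transcription, slow
        Interaction(2, inputs=(3, 4), outputs=(9,)),
        Interaction(3, inputs=(5, 9), outputs=(3, 10), activators=(7,), priority_above={4}),
        Interaction(4, inputs=(6, 9), outputs=(11,)),
    ]
    model = _prepare(nodes, edges)  # reverse of e4 appended as e6
    x0 = (1, 1, 0, 1, 1, 1, 1, 0, 0, 0, 0, 0)
    expected = {
        "n_nodes": 12,
        "n_edges": 6,
        "x0": x0,
        "sequences": [(2, 4, 0), (0, 2, 3, 1)],
        "states": {
            (2, 4, 0): [
                x0,
                (1, 1, 0, 0, 0, 1, 1, 0, 0, 1, 0, 0),
                (1, 1, 0, 0, 0, 1, 0, 0, 0, 0, 0, 1),
                (0, 0, 0, 0, 0, 1, 0, 1, 0, 0, 0, 1),
            ],
            (0, 2, 3, 1): [
                x0,
                (0, 0, 0, 1, 1, 1, 1, 1, 0, 0, 0, 0),
                (0, 0, 0, 0, 0, 1, 1, 1, 0, 1, 0, 0),
                (0, 0, 0, 1, 0, 0, 1, 1, 0, 0, 1, 0),
                (0, 0, 0, 1, 0, 0, 1, 1, 1, 0, 1, 0),
            ],
        },
        "terminals": {
            (2, 4, 0): Terminal.DEAD_END,
            (0, 2, 3, 1): Terminal.DEAD_END,
        },
        # hand trace of the first expansions (enabled set, then filtered)
        "trace_step1": ((0, 1, 2), (0, 2)),
    }
    return model, as_state(x0), expected


def _bak1_mcl1():
    """BAK1/MCL1 apoptosis switch.

    BAK1 dimerizes (e1) and the dimer triggers apoptosis (e2, slow); MCL1
    binds BAK1 with higher affinity than BAK1 binds itself, so the
    sequestration e3 outranks e1, and MCL1 can also strip BAK1 out of an
    existing dimer (e4). Apoptosis is the observable (visible under a
    microscope).
    """
    nodes = ["BAK1", "MCL1", "BAK1.BAK1", "Apoptosis", "MCL1.BAK1"]
    edges = [
        Interaction(0, inputs=(0,), outputs=(2,)),
        Interaction(1, inputs=(2,), outputs=(3,), speed=Speed.SLOW),
        Interaction(2, inputs=(0, 1), outputs=(4,), priority_above={0}),
        Interaction(3, inputs=(1, 2), outputs=(0, 4)),
    ]
    model = _prepare(nodes, edges, observables=[3])
    x0 = (2, 1, 0, 0, 0)
    expected = {
        "n_nodes": 5,
        "n_edges": 4,
        "x0": x0,
        "sequences": [(2, 0, 1)],
        "states": {
            (2, 0, 1): [
                (2, 1, 0, 0, 0),
                (1, 0, 0, 0, 1),
                (0, 0, 1, 0, 1),
                (0, 0, 0, 1, 1),
            ],
        },
        "terminals": {(2, 0, 1): Terminal.DEAD_END},
        "observable_final": 1,  # apoptosis takes place
    }
    return model, as_state(x0), expected


def _map_kinase():
    """MAP kinase cascade with the ERK negative feedback.

    GRB2.SOS activates RAS (e1), active RAS phosphorylates RAF (e2), pRAF
    phosphorylates ERK (e3), and pERK dissociates GRB2.SOS (e4) — the
    feedback. All four conversions are activator-gated, so reverse edges
    e5-e8 are added automatically, and the loop relaxes back to the initial
    state: the single trajectory is an oscillation.
    """
    nodes = ["RAS.GDP", "RAS.GTP", "GRB2.SOS", "RAF", "pRAF", "ERK", "pERK", "GRB2", "SOS"]
    edges = [
        Interaction(0, inputs=(0,), outputs=(1,), activators=(2,)),
        Interaction(1, inputs=(3,), outputs=(4,), activators=(1,)),
        Interaction(2, inputs=(5,), outputs=(6,), activators=(4,)),
        Interaction(3, inputs=(2,), outputs=(7, 8), activators=(6,)),
    ]
    model = _prepare(nodes, edges)  # e5..e8 auto-generated
    x0 = (1, 0, 1, 1, 0, 1, 0, 0, 0)
    cyc = (0, 1, 2, 3, 4, 5, 6, 7)
    expected = {
        "n_nodes": 9,
        "n_edges": 8,
        "x0": x0,
        "sequences": [cyc],
        "states": {
            cyc: [
                (1, 0, 1, 1, 0, 1, 0, 0, 0),
                (0, 1, 1, 1, 0, 1, 0, 0, 0),
                (0, 1, 1, 0, 1, 1, 0, 0, 0),
                (0, 1, 1, 0, 1, 0, 1, 0, 0),
                (0, 1, 0, 0, 1, 0, 1, 1, 1),
                (1, 0, 0, 0, 1, 0, 1, 1, 1),
                (1, 0, 0, 1, 0, 0, 1, 1, 1),
                (1, 0, 0, 1, 0, 1, 0, 1, 1),
                (1, 0, 1, 1, 0, 1, 0, 0, 0),
            ],
        },
        "terminals": {cyc: Terminal.CYCLE},
        "cycle_start": 0,
    }
    return model, as_state(x0), expected


_BUILDERS = {
    "conversion_basic": _conversion_basic,
    "transcription_basic": _transcription_basic,
    "speed_example": _speed_example,
    "priority_example": _priority_example,
    "illustrative": _illustrative,
    "bak1_mcl1": _bak1_mcl1,
    "map_kinase": _map_kinase,
}

FIXTURE_NAMES = tuple(_BUILDERS)


def build_fixture(name: str):
    """Return (model, x0, expected) for a built-in network."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
    return builder()


# --------------------------------------------------------------------------
# random networks (property-test input; no biological realism intended)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RandomNetworkParams:
    n_nodes: int = 5
    n_edges: int = 4
    max_initial_value: int = 2
    p_activator: float = 0.3
    p_inhibitor: float = 0.15
    p_transcription: float = 0.2
    p_slow: float = 0.2
    p_priority: float = 0.2
    seed: int = 0


def generate_random_network(params: RandomNetworkParams):
    """Seeded random valid network; a pure function of the parameters."""
    if params.n_nodes < 1 or params.n_edges < 0:
        raise ValidationError("need at least one node and a non-negative edge count")
    rng = np.random.default_rng(params.seed)
    n = params.n_nodes
    edges: list[Interaction] = []
    for j in range(params.n_edges):
        if rng.random() < params.p_transcription:
            edges.append(
                Interaction(
                    j,
                    outputs=(int(rng.integers(n)),),
                    activators=(int(rng.integers(n)),),
                )
            )
            continue
        n_in = 2 if rng.random() < 0.3 else 1
        n_out = 2 if rng.random() < 0.3 else 1
        inputs = tuple(int(rng.integers(n)) for _ in range(n_in))
        outputs = tuple(int(rng.integers(n)) for _ in range(n_out))
        activators = set()
        inhibitors = set()
        if rng.random() < params.p_activator:
            activators.add(int(rng.integers(n)))
        if rng.random() < params.p_inhibitor:
            c = int(rng.integers(n))
            if c not in activators:
                inhibitors.add(c)
        speed = Speed.SLOW if rng.random() < params.p_slow else None
        edges.append(
            Interaction(
                j,
                inputs=inputs,
                outputs=outputs,
                activators=tuple(activators),
                inhibitors=tuple(inhibitors),
                speed=speed,
            )
        )

    # random acyclic priority relation; flipping a cycle-creating arc is
    # always safe because both directions closing a cycle would need a
    # pre-existing one
    above: dict[int, set[int]] = {j: set() for j in range(params.n_edges)}

    def _reaches(src: int, dst: int) -> bool:
        stack, seen = [src], set()
        while stack:
            u = stack.pop()
            if u == dst:
                return True
            if u in seen:
                continue
            seen.add(u)
            stack.extend(above[u])
        return False

    for a in range(params.n_edges):
        for b in range(a + 1, params.n_edges):
            if rng.random() >= params.p_priority:
                continue
            hi, lo = (a, b) if rng.random() < 0.5 else (b, a)
            if _reaches(lo, hi):
                hi, lo = lo, hi
            above[hi].add(lo)
    edges = [replace(e, priority_above=frozenset(above[e.index])) for e in edges]

    nodes = [f"N{i + 1}" for i in range(n)]
    model = _prepare(nodes, edges)
    x0 = as_state(int(v) for v in rng.integers(0, params.max_initial_value + 1, size=n))
    return model, x0


# --------------------------------------------------------------------------
# independent enumeration oracle
# --------------------------------------------------------------------------

def oracle_enumerate(model: NetworkModel, x0, config: EngineConfig | None = None) -> set[tuple[int, ...]]:
    """Plain recursive depth-first enumeration of all trajectory sequences.

    Written independently of the engine: enablement, filtering and firing
    are re-derived inline from the update rules. Branch merging is emulated
    by a first-visit-wins memo on (depth, state, latch) — depth-first
    preorder visits same-depth prefixes in the same lexicographic order the
    breadth-first engine creates them, so the surviving sequences coincide.
    Returns the set of recorded edge-index sequences.
    """
    if config is None:
        config = EngineConfig()
    x0 = tuple(int(v) for v in x0)
    recorded: set[tuple[int, ...]] = set()
    visited: set[tuple] = set()

    def can_fire(e: Interaction, x, latch: dict) -> bool:
        if any(x[i] > 0 for i in e.inhibitors):
            return False
        if e.kind is Kind.TRANSCRIPTION:
            if any(x[a] == 0 for a in e.activators):
                return False
            return latch.get(e.index) != tuple(x[a] for a in e.activators)
        need = Counter(e.inputs)
        if any(x[i] < c for i, c in need.items()):
            return False
        return all(x[a] > 0 for a in e.activators)

    def apply(e: Interaction, x, latch: dict):
        v = list(x)
        latch = dict(latch)
        if e.kind is Kind.TRANSCRIPTION:
            for o in e.outputs:
                v[o] = 1
            latch[e.index] = tuple(x[a] for a in e.activators)
        else:
            for i in e.inputs:
                v[i] -= 1
            for o in e.outputs:
                v[o] += 1
        return tuple(v), latch

    def rec(x, latch: dict, seq: tuple[int, ...], hist: tuple):
        key = (len(seq), x, frozenset(latch.items()))
        if key in visited:
            return
        visited.add(key)
        if len(seq) >= config.max_steps:
            recorded.add(seq)
            return
        candidates = [e for e in model.edges if can_fire(e, x, latch)]
        if any(e.speed is Speed.FAST for e in candidates):
            candidates = [e for e in candidates if e.speed is not Speed.SLOW]
        ids = {e.index for e in candidates}
        candidates = [
            e for e in candidates
            if not any(e.index in model.edges[f].priority_above for f in ids if f != e.index)
        ]
        if not candidates:
            if seq:
                recorded.add(seq)
            return
        for e in candidates:
            x2, latch2 = apply(e, x, latch)
            if x2 in hist:
                recorded.add(seq + (e.index,))
            else:
                rec(x2, latch2, seq + (e.index,), hist + (x2,))

    rec(x0, {}, (), (x0,))
    return recorded
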