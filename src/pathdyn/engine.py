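"""Asynchronous discrete dynamics and exhaustive trajectory enumeration.

Semantics
---------
States are vectors of non-negative integers, one entry per entity. Exactly
one process fires per abstract time step (asynchronous update); whenever
several processes could fire, every alternative is explored, so the result
of a simulation is the *set* of all dynamic trajectories rather than a
single run. This set is the model's representation of dynamics uncertainty:
incomplete knowledge about process timing is kept, not resolved by sampling.

Enablement:

* a conversion fires when every input entity holds at least as many tokens
  as the process consumes, every activator is nonzero and every inhibitor
  is zero (reverse edges encode "forward activator absent" as inhibitors,
  see :func:`pathdyn.model.augment_reverse_edges`);
* a transcription fires when its activators are nonzero, inhibitors zero,
  and its latch is stale — i.e. the process has not yet fired, or the
  activator value has changed since it last fired. The latch models the
  fact that a transcript readout is not re-written while its driver is
  unchanged.

Firing a conversion decrements each input once per occurrence and increments
each output once per occurrence; control nodes are untouched. Firing a
transcription sets its outputs to 1 and records the activator values in the
latch.

Uncertainty reduction: before branching, the set of co-enabled processes is
filtered — slow processes are dropped whenever a fast one is co-enabled, and
a process is dropped when a co-enabled process explicitly outranks it in the
priority relation.

Enumeration is a level-synchronous breadth-first search. Frontier branches
that reach the same (state, latch) pair at the same depth are merged,
keeping the earliest-generated process sequence (branches are expanded in
creation order and processes in ascending index, so "earliest" is
well-defined and deterministic). A branch terminates when nothing is
enabled (dead end) or when its new state repeats a state already seen on
that branch (cycle); the recorded cyclic sequence ends with the firing that
closed the cycle. A configurable step limit guards against models that
accumulate tokens without bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping, Optional, Sequence

from .model import Interaction, Kind, NetworkModel, Speed, as_state

logger = logging.getLogger(__name__)

__all__ = [
    "Terminal",
    "EngineConfig",
    "LatchRegister",
    "Trajectory",
    "TrajectorySet",
    "StepTrace",
    "UpdateResult",
    "DisabledEdgeError",
    "is_enabled",
    "fire_edge",
    "enabled_edges",
    "filter_speed_priority",
    "states_update",
    "detect_cycle",
    "enumerate_trajectories",
    "replay",
]


class DisabledEdgeError(RuntimeError):
    """A process was fired in a state where it is not enabled."""


class Terminal(Enum):
    DEAD_END = "dead_end"
    CYCLE = "cycle"
    STEP_LIMIT = "step_limit"


@dataclass(frozen=True)
class EngineConfig:
    """Enumeration parameters.

    max_steps bounds the trajectory length; the in-text examples all
    terminate naturally well below the default. Only the asynchronous
    update mode is implemented ("sync" is reserved).
    """

    max_steps: int = 1000
    mode: str = "async"

    def __post_init__(self) -> None:
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.mode not in ("async", "sync"):
            raise ValueError(f"unknown update mode {self.mode!r}")


class LatchRegister(Mapping):
    """Immutable map: transcription edge index -> activator values at last firing.

    An absent entry means the edge has never fired. Part of the branch state:
    copied on branching and compared when merging branches.
    """

    __slots__ = ("_items",)

    def __init__(self, items=()):
        self._items = dict(items)

    def updated(self, edge_index: int, values: tuple[int, ...]) -> "LatchRegister":
        new = dict(self._items)
        new[edge_index] = values
        return LatchRegister(new)

    def key(self) -> frozenset:
        return frozenset(self._items.items())

    def __getitem__(self, k):
        return self._items[k]

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __eq__(self, other):
        return isinstance(other, LatchRegister) and self._items == other._items

    def __hash__(self):
        return hash(self.key())

    def __repr__(self):
        return f"LatchRegister({self._items!r})"


@dataclass(frozen=True)
class Trajectory:
    """One dynamic trajectory: the fired process sequence and its state history."""

    edge_sequence: tuple[int, ...]
    states: tuple[tuple[int, ...], ...]
    terminal: Terminal
    cycle_start: Optional[int] = None  # index in `states` where the repeat lands

    def __post_init__(self) -> None:
        if len(self.states) != len(self.edge_sequence) + 1:
            raise ValueError("a trajectory needs one more state than firings")


class TrajectorySet:
    """Ordered, duplicate-free (by edge sequence) collection of trajectories."""

    def __init__(self, trajectories: Sequence[Trajectory] = ()):
        self._trajectories: list[Trajectory] = []
        self._seqs: set[tuple[int, ...]] = set()
        for t in trajectories:
            self.add(t)

    def add(self, traj: Trajectory) -> bool:
        if not traj.edge_sequence:
            raise ValueError("empty trajectories are never recorded")
        if traj.edge_sequence in self._seqs:
            return False
        self._seqs.add(traj.edge_sequence)
        self._trajectories.append(traj)
        return True

    def sequences(self) -> set[tuple[int, ...]]:
        return set(self._seqs)

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self._trajectories)

    def __len__(self) -> int:
        return len(self._trajectories)

    def __getitem__(self, i) -> Trajectory:
        return self._trajectories[i]

    def __eq__(self, other):
        return isinstance(other, TrajectorySet) and self._trajectories == other._trajectories

    def __repr__(self):
        return f"TrajectorySet({self._trajectories!r})"


# --------------------------------------------------------------------------
# enablement and firing
# --------------------------------------------------------------------------

def _activator_values(edge: Interaction, x) -> tuple[int, ...]:
    return tuple(x[a] for a in edge.activators)


def is_enabled(edge: Interaction, x, latch: Optional[LatchRegister] = None) -> bool:
    """Can this process fire in state ``x``?"""
    if any(x[i] > 0 for i in edge.inhibitors):
        return False
    if edge.kind is Kind.TRANSCRIPTION:
        if any(x[a] == 0 for a in edge.activators):
            return False
        last = latch.get(edge.index) if latch is not None else None
        return last != _activator_values(edge, x)
    # conversion: each input must hold as many tokens as the firing consumes
    for node, need in edge.input_counts().items():
        if x[node] < need:
            return False
    return all(x[a] > 0 for a in edge.activators)


def fire_edge(
    edge: Interaction, x, latch: Optional[LatchRegister] = None
) -> tuple[tuple[int, ...], LatchRegister]:
    """Apply one firing; returns a fresh state and latch (inputs unmodified)."""
    if latch is None:
        latch = LatchRegister()
    if not is_enabled(edge, x, latch):
        raise DisabledEdgeError(f"edge e{edge.index + 1} is not enabled in state {list(x)}")
    values = list(x)
    if edge.kind is Kind.TRANSCRIPTION:
        for o in set(edge.outputs):
            values[o] = 1
        latch = latch.updated(edge.index, _activator_values(edge, x))
    else:
        for i in edge.inputs:
            values[i] -= 1
        for o in edge.outputs:
            values[o] += 1
    return tuple(values), latch


def enabled_edges(model: NetworkModel, x, latch: Optional[LatchRegister] = None) -> list[int]:
    """All enabled processes in canonical (ascending index) order."""
    return [e.index for e in model.edges if is_enabled(e, x, latch)]


def filter_speed_priority(ev: Sequence[int], model: NetworkModel) -> list[int]:
    """Prune the co-enabled set by speed, then by the priority relation.

    Slow processes are dropped when any fast process is co-enabled. Then a
    process is dropped when some co-enabled survivor of the speed filter
    outranks it; removal is simultaneous, so a chain a > b > c with all three
    present keeps only a. Both rules act pairwise among co-enabled processes
    only — an absent outranker never suppresses anything.
    """
    edges = [model.edges[i] for i in ev]
    if any(e.speed is Speed.FAST for e in edges):
        edges = [e for e in edges if e.speed is not Speed.SLOW]
    present = {e.index for e in edges}
    survivors = [
        e.index
        for e in edges
        if not any(e.index in model.edges[f].priority_above for f in present if f != e.index)
    ]
    return survivors


@dataclass(frozen=True)
class UpdateResult:
    """Outcome of one state-update call: the surviving successors plus the
    co-enabled set before and after filtering (for tracing/debugging)."""

    successors: tuple[tuple[tuple[int, ...], tuple[int, ...], LatchRegister], ...]
    dead_end: bool
    enabled: tuple[int, ...]
    filtered: tuple[int, ...]


def states_update(
    x_in,
    s_in: tuple[int, ...],
    latch: LatchRegister,
    model: NetworkModel,
    config: Optional[EngineConfig] = None,
) -> UpdateResult:
    """Expand one branch: find, filter and fire every admissible process.

    Each successor is produced from a fresh copy of ``x_in``. An empty
    filtered set marks a dead end (the caller records ``s_in`` if non-empty).
    """
    ev = enabled_edges(model, x_in, latch)
    filtered = filter_speed_priority(ev, model)
    if not filtered:
        return UpdateResult((), True, tuple(ev), ())
    successors = []
    for idx in filtered:
        x_new, latch_new = fire_edge(model.edges[idx], x_in, latch)
        successors.append((x_new, s_in + (idx,), latch_new))
    return UpdateResult(tuple(successors), False, tuple(ev), tuple(filtered))


def detect_cycle(state_history: Sequence[tuple[int, ...]], x_new) -> bool:
    """True iff the new state repeats any state already on this branch."""
    x_new = tuple(x_new)
    return any(tuple(s) == x_new for s in state_history)


@dataclass(frozen=True)
class StepTrace:
    """One expansion record, mirroring the worked hand-trace of the method."""

    step: int
    prefix: tuple[int, ...]
    state: tuple[int, ...]
    enabled: tuple[int, ...]
    filtered: tuple[int, ...]


def enumerate_trajectories(
    model: NetworkModel,
    x0,
    config: Optional[EngineConfig] = None,
    trace: Optional[list[StepTrace]] = None,
) -> TrajectorySet:
    """Exhaustively enumerate every dynamic trajectory from ``x0``.

    Level-synchronous BFS over branches ``(state, latch, sequence, history)``.
    See the module docstring for the merge/cycle/dead-end semantics. The
    result is fully deterministic. If ``trace`` is a list, one
    :class:`StepTrace` per branch expansion is appended to it.
    """
    if config is None:
        config = EngineConfig()
    if config.mode != "async":
        raise NotImplementedError("synchronous update mode is reserved and not implemented")
    x0 = as_state(x0)
    if len(x0) != len(model.nodes):
        raise ValueError(f"initial condition has {len(x0)} entries for {len(model.nodes)} nodes")

    result = TrajectorySet()
    # branch = (state, latch, sequence, history)
    frontier = [(x0, LatchRegister(), (), (x0,))]
    k = 0
    while frontier and k < config.max_steps:
        k += 1
        new_frontier = []
        seen: set[tuple] = set()
        for x, latch, seq, hist in frontier:
            upd = states_update(x, seq, latch, model, config)
            if trace is not None:
                trace.append(StepTrace(k, seq, x, upd.enabled, upd.filtered))
            logger.debug(
                "step %d, prefix %s: E_v=%s -> %s",
                k,
                model.sequence_labels(seq),
                model.sequence_labels(upd.enabled),
                model.sequence_labels(upd.filtered),
            )
            if upd.dead_end:
                if seq:
                    result.add(Trajectory(seq, hist, Terminal.DEAD_END))
                continue
            for x_new, seq_new, latch_new in upd.successors:
                if detect_cycle(hist, x_new):
                    start = hist.index(x_new)
                    result.add(Trajectory(seq_new, hist + (x_new,), Terminal.CYCLE, start))
                    continue
                key = (x_new, latch_new.key())
                if key in seen:
                    continue  # merged: identical state+latch reached this step already
                seen.add(key)
                new_frontier.append((x_new, latch_new, seq_new, hist + (x_new,)))
        frontier = new_frontier

    if frontier:
        logger.warning(
            "step limit %d reached with %d live branch(es); trajectories truncated",
            config.max_steps,
            len(frontier),
        )
        for x, latch, seq, hist in frontier:
            result.add(Trajectory(seq, hist, Terminal.STEP_LIMIT))
    return result


def replay(model: NetworkModel, x0, s: Sequence[int]) -> list[tuple[int, ...]]:
    """Re-run a process sequence, asserting enablement at every step.

    Returns the full state history (x0 included). Used to verify that every
    recorded trajectory is sound.
    """
    if not s:
        raise ValueError("cannot replay an empty sequence")
    x = as_state(x0)
    latch = LatchRegister()
    history = [x]
    for step, idx in enumerate(s, start=1):
        edge = model.edges[idx]
        if not is_enabled(edge, x, latch):
            raise DisabledEdgeError(
                f"replay failed at step {step}: edge {model.edge_label(idx)} "
                f"is not enabled in state {list(x)}"
            )
        x, latch = fire_edge(edge, x, latch)
        history.append(x)
    return history
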