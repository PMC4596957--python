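"""Network model types for interaction-based pathway dynamics.

A pathway is modeled as a hypergraph ``M = (N, E)``: named biological
entities (genes, proteins, complexes, metabolites) carrying non-negative
integer values, connected by hyper-edges that each represent one biological
process with input, output, activator and inhibitor roles.

Two process kinds are distinguished structurally:

* **conversion** — reactants (inputs) are consumed and products (outputs)
  produced, optionally gated by activators/inhibitors (complex assembly,
  phosphorylation, ...).
* **transcription** — no inputs; a 0/1 output records whether transcription
  has occurred, driven solely by an activator (BioPAX Template Reaction).

Every conversion gated by an activator is assumed reversible when the
activator is absent and the products present; :func:`augment_reverse_edges`
materializes those reverse processes as extra edges.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "Kind",
    "Speed",
    "Interaction",
    "NetworkModel",
    "ValidationError",
    "as_state",
    "classify_and_default",
    "augment_reverse_edges",
]


class ValidationError(ValueError):
    """A network model violates a structural invariant."""


class Kind(str, Enum):
    CONVERSION = "conversion"
    TRANSCRIPTION = "transcription"


class Speed(str, Enum):
    FAST = "fast"
    SLOW = "slow"


def as_state(values: Iterable[int]) -> tuple[int, ...]:
    """Normalize an initial condition / state to a tuple of non-negative ints."""
    out = tuple(int(v) for v in values)
    if any(v < 0 for v in out):
        raise ValidationError(f"state entries must be non-negative, got {out}")
    return out


@dataclass(frozen=True)
class Interaction:
    """One biological process (hyper-edge).

    ``inputs``/``outputs`` are multisets of node indices (a node occurring
    twice is consumed/produced twice per firing); ``activators`` and
    ``inhibitors`` are sets of control-node indices whose values gate the
    process but are never changed by it.
    """

    index: int
    inputs: tuple[int, ...] = ()
    outputs: tuple[int, ...] = ()
    activators: tuple[int, ...] = ()
    inhibitors: tuple[int, ...] = ()
    kind: Optional[Kind] = None
    speed: Optional[Speed] = None
    priority_above: frozenset[int] = frozenset()
    reverse_of: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "inputs", tuple(sorted(self.inputs)))
        object.__setattr__(self, "outputs", tuple(sorted(self.outputs)))
        object.__setattr__(self, "activators", tuple(sorted(set(self.activators))))
        object.__setattr__(self, "inhibitors", tuple(sorted(set(self.inhibitors))))
        object.__setattr__(self, "priority_above", frozenset(self.priority_above))

    @property
    def is_reverse(self) -> bool:
        return self.reverse_of is not None

    def input_counts(self) -> Counter:
        return Counter(self.inputs)


@dataclass
class NetworkModel:
    """The 2-tuple M = (N, E) plus the declared observable nodes."""

    nodes: list[str] = field(default_factory=list)
    edges: list[Interaction] = field(default_factory=list)
    observables: list[int] = field(default_factory=list)

    # -- naming helpers (user-facing labels are 1-based, e.g. e1, n1) -----
    def node_index(self, name: str) -> int:
        try:
            return self.nodes.index(name)
        except ValueError:
            raise KeyError(f"unknown entity {name!r}") from None

    def edge_label(self, index: int) -> str:
        return f"e{index + 1}"

    def sequence_labels(self, seq: Sequence[int]) -> tuple[str, ...]:
        return tuple(self.edge_label(i) for i in seq)

    def validate(self) -> None:
        """Check all structural invariants; raise ValidationError on failure."""
        m = len(self.nodes)
        if len(set(self.nodes)) != m:
            raise ValidationError("entity names must be unique")
        if any((not n) or n.split() != [n] for n in self.nodes):
            raise ValidationError("entity names must be non-empty single tokens")

        for e in self.edges:
            refs = (*e.inputs, *e.outputs, *e.activators, *e.inhibitors)
            if any(i < 0 or i >= m for i in refs):
                raise ValidationError(f"edge {self.edge_label(e.index)} references an unknown node index")
            if set(e.activators) & set(e.inhibitors):
                raise ValidationError(
                    f"edge {self.edge_label(e.index)} has a node that is both activator and inhibitor"
                )
            if e.index in e.priority_above:
                raise ValidationError(f"edge {self.edge_label(e.index)} outranks itself")
            if any(j < 0 or j >= len(self.edges) for j in e.priority_above):
                raise ValidationError(f"edge {self.edge_label(e.index)} priority references an unknown edge")
            if e.kind is Kind.TRANSCRIPTION:
                if e.inputs or not e.activators or not e.outputs:
                    raise ValidationError(
                        f"transcription edge {self.edge_label(e.index)} must have no inputs, "
                        "at least one activator and one output"
                    )
            elif e.kind is Kind.CONVERSION:
                if not e.inputs or not e.outputs:
                    raise ValidationError(
                        f"conversion edge {self.edge_label(e.index)} must have inputs and outputs"
                    )
            if e.reverse_of is not None:
                fwd = self.edges[e.reverse_of]
                if fwd.kind is not None and fwd.kind is not Kind.CONVERSION:
                    raise ValidationError("reverse edge must point at a conversion")
                if not fwd.activators:
                    raise ValidationError("reverse edge must point at an activator-gated conversion")

        if [e.index for e in self.edges] != list(range(len(self.edges))):
            raise ValidationError("edge indices must be 0..|E|-1 in order")

        # reverse edges sit after all originals, ordered like their originals
        rev_positions = [e.index for e in self.edges if e.is_reverse]
        fwd_positions = [e.index for e in self.edges if not e.is_reverse]
        if rev_positions and fwd_positions and min(rev_positions) < max(fwd_positions):
            raise ValidationError("reverse edges must appear after all original edges")
        rev_targets = [e.reverse_of for e in self.edges if e.is_reverse]
        if rev_targets != sorted(rev_targets):
            raise ValidationError("reverse edges must follow the order of their originals")

        g = nx.DiGraph()
        g.add_nodes_from(range(len(self.edges)))
        for e in self.edges:
            g.add_edges_from((e.index, j) for j in e.priority_above)
        if not nx.is_directed_acyclic_graph(g):
            raise ValidationError("priority relation contains a cycle")

        if any(i < 0 or i >= m for i in self.observables):
            raise ValidationError("observable references an unknown node index")


def classify_and_default(model: NetworkModel) -> NetworkModel:
    """Assign process kinds and default speed labels.

    An edge with no inputs and at least one activator is a transcription
    process (default slow — transcription operates on a much longer time
    scale than binding/conversion events); every other edge is a conversion
    (default fast). Explicit speed labels from the input file are kept.
    """
    new_edges = []
    for e in model.edges:
        if not e.inputs and not e.activators:
            raise ValidationError(
                f"edge {model.edge_label(e.index)} has neither inputs nor activators "
                "and cannot be classified"
            )
        kind = Kind.TRANSCRIPTION if (not e.inputs and e.activators) else Kind.CONVERSION
        speed = e.speed
        if speed is None:
            speed = Speed.SLOW if kind is Kind.TRANSCRIPTION else Speed.FAST
        new_edges.append(replace(e, kind=kind, speed=speed))
    out = NetworkModel(list(model.nodes), new_edges, list(model.observables))
    out.validate()
    return out


def augment_reverse_edges(model: NetworkModel) -> NetworkModel:
    """Add the reverse direction of every activator-gated conversion.

    The reverse edge consumes the forward outputs and re-produces the forward
    inputs; it is enabled exactly when the forward outputs are all nonzero and
    the forward activators are all zero. The latter condition is encoded by
    listing the forward activators as inhibitors of the reverse edge, so the
    ordinary conversion enablement rule applies unchanged. Idempotent.
    """
    edges = list(model.edges)
    already = {e.reverse_of for e in edges if e.is_reverse}
    for e in model.edges:
        if e.is_reverse or e.kind is not Kind.CONVERSION or not e.activators:
            continue
        if e.index in already:
            continue
        rev = Interaction(
            index=len(edges),
            inputs=e.outputs,
            outputs=e.inputs,
            inhibitors=e.activators,
            kind=Kind.CONVERSION,
            speed=e.speed,
            reverse_of=e.index,
        )
        logger.debug("added reverse edge %s for %s", model.edge_label(rev.index), model.edge_label(e.index))
        edges.append(rev)
    out = NetworkModel(list(model.nodes), edges, list(model.observables))
    out.validate()
    return out
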