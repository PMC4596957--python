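"""Reading and writing the simple-text pathway format.

The input dialect is block-structured. Each process is a block of keyword
lines::

    Process 1
    Input A B
    Output D
    Activator C
    Inhibitor X

followed (after the list of processes) by the initial condition section::

    Entity Value
    A 1
    B 1
    C 1
    D 0

Optional extension lines: ``Speed fast|slow`` and
``Priority > <process#> [<process#> ...]`` inside a process block (the
legacy string form ``e2prio>e3prio`` is also accepted), and top-level
``Observable <name> [<name> ...]`` lines declaring the measurable entities.

Entity names are case-sensitive whitespace-free tokens; ``.`` is allowed
inside names for complexes such as ``GRB2.SOS``. Node order follows the
Entity/Value section; entities mentioned only in processes are appended in
order of first mention with initial value 0 (logged as a warning).
"""

from __future__ import annotations

import logging
from typing import IO, Union

from .model import Interaction, Kind, NetworkModel, Speed, as_state

logger = logging.getLogger(__name__)

__all__ = ["ParseError", "parse_network", "serialize_network", "write_report"]

_ROLE_KEYWORDS = {"Input", "Output", "Activator", "Inhibitor"}


class ParseError(ValueError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        prefix = f"line {line}: " if line is not None else ""
        super().__init__(prefix + message)


def _fmt_vec(x) -> str:
    return "[" + ", ".join(str(int(v)) for v in x) + "]^T"


def parse_network(text: Union[str, IO[str]]) -> tuple[NetworkModel, tuple[int, ...]]:
    """Parse a process file into an (unclassified) model and initial condition.

    Returns the model exactly as written: kinds are unassigned and speeds set
    only where an explicit ``Speed`` line appears. Run
    :func:`pathdyn.model.classify_and_default` and
    :func:`pathdyn.model.augment_reverse_edges` before simulating.
    """
    if hasattr(text, "read"):
        text = text.read()

    blocks: list[dict] = []
    current: dict | None = None
    entity_order: list[str] = []
    entity_values: dict[str, int] = {}
    observables: list[str] = []
    priority_pairs: set[tuple[int, int]] = set()  # (winner process#, loser process#)
    seen_numbers: set[int] = set()
    in_entities = False

    for lineno, raw in enumerate(text.splitlines(), start=1):
        tokens = raw.split()
        if not tokens:
            current = None
            continue
        kw = tokens[0]

        if kw == "Process":
            in_entities = False
            if len(tokens) != 2:
                raise ParseError("Process line must be 'Process <number>'", lineno)
            try:
                num = int(tokens[1])
            except ValueError:
                raise ParseError(f"invalid process number {tokens[1]!r}", lineno) from None
            if num in seen_numbers:
                raise ParseError(f"duplicate process number {num}", lineno)
            seen_numbers.add(num)
            current = {"num": num, "Input": [], "Output": [], "Activator": [],
                       "Inhibitor": [], "speed": None, "line": lineno}
            blocks.append(current)
            continue

        if kw == "Entity":
            if tokens == ["Entity", "Value"]:
                in_entities = True
                current = None
                continue
            raise ParseError("expected 'Entity Value' section header", lineno)

        if kw == "Observable":
            if len(tokens) < 2:
                raise ParseError("Observable line lists at least one entity", lineno)
            observables.extend(tokens[1:])
            in_entities = False
            current = None
            continue

        if kw in _ROLE_KEYWORDS:
            if current is None:
                raise ParseError(f"{kw} line outside a Process block", lineno)
            if len(tokens) < 2:
                raise ParseError(f"{kw} line lists at least one entity", lineno)
            current[kw].extend(tokens[1:])
            continue

        if kw == "Speed":
            if current is None:
                raise ParseError("Speed line outside a Process block", lineno)
            if len(tokens) != 2 or tokens[1] not in ("fast", "slow"):
                raise ParseError("Speed line must be 'Speed fast' or 'Speed slow'", lineno)
            current["speed"] = Speed(tokens[1])
            continue

        if kw == "Priority":
            if current is None:
                raise ParseError("Priority line outside a Process block", lineno)
            priority_pairs |= _parse_priority(tokens[1:], current["num"], lineno)
            continue

        if in_entities:
            if len(tokens) != 2:
                raise ParseError("entity line must be '<name> <value>'", lineno)
            name, value = tokens
            try:
                val = int(value)
            except ValueError:
                raise ParseError(f"invalid initial value {value!r}", lineno) from None
            if val < 0:
                raise ParseError(f"negative initial value for {name}", lineno)
            if name in entity_values:
                raise ParseError(f"duplicate entity {name!r}", lineno)
            entity_values[name] = val
            entity_order.append(name)
            continue

        raise ParseError(f"unknown keyword {kw!r}", lineno)

    if not blocks:
        raise ParseError("input contains no Process block")

    # node order: Entity section first, then first mention in processes
    names = list(entity_order)
    index = {n: i for i, n in enumerate(names)}

    def intern(name: str) -> int:
        if name not in index:
            logger.warning("entity %r not listed in Entity/Value section; initial value set to 0", name)
            index[name] = len(names)
            names.append(name)
        return index[name]

    num_to_pos = {b["num"]: pos for pos, b in enumerate(blocks)}
    edges = []
    for pos, b in enumerate(blocks):
        if b["Input"] and not b["Output"]:
            raise ParseError("process has inputs but no Output (missing Output on a conversion)", b["line"])
        if not b["Input"] and not b["Output"]:
            raise ParseError("process defines neither Input nor Output", b["line"])
        above = frozenset(
            num_to_pos[lo] for (hi, lo) in priority_pairs if hi == b["num"]
        )
        edges.append(
            Interaction(
                index=pos,
                inputs=tuple(intern(n) for n in b["Input"]),
                outputs=tuple(intern(n) for n in b["Output"]),
                activators=tuple(intern(n) for n in b["Activator"]),
                inhibitors=tuple(intern(n) for n in b["Inhibitor"]),
                speed=b["speed"],
                priority_above=above,
            )
        )

    for hi, lo in priority_pairs:
        for num in (hi, lo):
            if num not in num_to_pos:
                raise ParseError(f"Priority references unknown process number {num}")

    obs_idx = []
    for name in observables:
        if name not in index:
            raise ParseError(f"Observable references unknown entity {name!r}")
        obs_idx.append(index[name])

    model = NetworkModel(names, edges, obs_idx)
    model.validate()
    x0 = as_state(entity_values.get(n, 0) for n in names)
    return model, x0


def _parse_priority(args: list[str], own_num: int, lineno: int) -> set[tuple[int, int]]:
    """Parse 'Priority > 2 3' or the legacy 'Priority e2prio>e3prio' form."""
    pairs: set[tuple[int, int]] = set()
    if args and args[0] == ">":
        if len(args) < 2:
            raise ParseError("'Priority >' lists at least one process number", lineno)
        for tok in args[1:]:
            try:
                pairs.add((own_num, int(tok)))
            except ValueError:
                raise ParseError(f"invalid process number {tok!r} in Priority line", lineno) from None
        return pairs
    for tok in args:
        for op in (">", "<"):
            if op in tok:
                left, _, right = tok.partition(op)
                try:
                    a = int(left.removeprefix("e").removesuffix("prio"))
                    b = int(right.removeprefix("e").removesuffix("prio"))
                except ValueError:
                    raise ParseError(f"cannot parse priority label {tok!r}", lineno) from None
                pairs.add((a, b) if op == ">" else (b, a))
                break
        else:
            raise ParseError(f"cannot parse priority label {tok!r}", lineno)
    return pairs


def serialize_network(model: NetworkModel, x0) -> str:
    """Write a model back to the text dialect (reverse edges are omitted;
    they are regenerated by :func:`~pathdyn.model.augment_reverse_edges`)."""
    lines: list[str] = []
    originals = [e for e in model.edges if not e.is_reverse]
    proc_num = {e.index: k + 1 for k, e in enumerate(originals)}
    for e in originals:
        lines.append(f"Process {proc_num[e.index]}")
        if e.inputs:
            lines.append("Input " + " ".join(model.nodes[i] for i in e.inputs))
        if e.outputs:
            lines.append("Output " + " ".join(model.nodes[i] for i in e.outputs))
        if e.activators:
            lines.append("Activator " + " ".join(model.nodes[i] for i in e.activators))
        if e.inhibitors:
            lines.append("Inhibitor " + " ".join(model.nodes[i] for i in e.inhibitors))
        if e.speed is not None:
            lines.append(f"Speed {e.speed.value}")
        targets = sorted(j for j in e.priority_above)
        if targets:
            nums = []
            for j in targets:
                if j not in proc_num:
                    raise ValueError("cannot serialize a priority relation over a reverse edge")
                nums.append(str(proc_num[j]))
            lines.append("Priority > " + " ".join(nums))
        lines.append("")
    lines.append("Entity Value")
    for name, value in zip(model.nodes, x0):
        lines.append(f"{name} {int(value)}")
    if model.observables:
        lines.append("")
        lines.append("Observable " + " ".join(model.nodes[i] for i in model.observables))
    return "\n".join(lines) + "\n"


def write_report(model: NetworkModel, x0, trajectories) -> str:
    """Render the trajectory report.

    Header with the initial condition, then per trajectory its process
    sequence and the state vector after every time step. Cyclic trajectories
    are annotated ``(sequence repeats)``; branches cut by the step limit are
    annotated ``(step limit reached)``.
    """
    from .engine import Terminal  # local import to avoid a cycle

    lines = [f"Dynamic Trajectories for Initial Condition: x0 = {_fmt_vec(x0)}", ""]
    trajs = list(trajectories)
    if not trajs:
        lines.append("No dynamic trajectory.")
        return "\n".join(lines) + "\n"
    for t_num, traj in enumerate(trajs, start=1):
        labels = model.sequence_labels(traj.edge_sequence)
        lines.append(f"Trajectory t{t_num} = {{{', '.join(labels)}}}")
        lines.append(f"State Vector Updates for t{t_num}:")
        for k, edge in enumerate(traj.edge_sequence, start=1):
            lines.append(f"Time Step {k}: {model.edge_label(edge)}")
            lines.append(f"x{k} = {_fmt_vec(traj.states[k])}")
        if traj.terminal is Terminal.CYCLE:
            lines.append("(sequence repeats)")
        elif traj.terminal is Terminal.STEP_LIMIT:
            lines.append("(step limit reached)")
        lines.append("")
    return "\n".join(lines[:-1]) + "\n"
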