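import re

import pytest

from pathdyn import Terminal

APPENDIX_TEXT = """\
Process 1
Input A B
Output D
Activator C

Entity Value
A 1
B 1
C 1
D 0
"""


@pytest.fixture
def appendix_text():
    return APPENDIX_TEXT


_VEC = re.compile(r"\[([^\]]*)\]\^T")
_TRAJ = re.compile(r"Trajectory t(\d+) = \{([^}]*)\}")
_STEP = re.compile(r"Time Step (\d+): e(\d+)")


def read_report(text):
    """Test-only reader for the trajectory report dialect.

    Returns (x0, trajectories) where each trajectory is a dict with 0-based
    edge sequence, the full state history including x0, and the terminal
    annotation (dead_end when unannotated).
    """
    lines = text.splitlines()
    header = lines[0]
    assert header.startswith("Dynamic Trajectories for Initial Condition: x0 = ")
    x0 = tuple(int(v) for v in _VEC.search(header).group(1).split(","))
    trajectories = []
    current = None
    for line in lines[1:]:
        m = _TRAJ.match(line)
        if m:
            seq = tuple(int(tok.strip().lstrip("e")) - 1 for tok in m.group(2).split(","))
            current = {"sequence": seq, "states": [x0], "terminal": Terminal.DEAD_END}
            trajectories.append(current)
            continue
        if line.startswith("x") and "=" in line and current is not None:
            current["states"].append(
                tuple(int(v) for v in _VEC.search(line).group(1).split(","))
            )
        elif line == "(sequence repeats)":
            current["terminal"] = Terminal.CYCLE
        elif line == "(step limit reached)":
            current["terminal"] = Terminal.STEP_LIMIT
        elif line == "No dynamic trajectory.":
            assert not trajectories
    return x0, trajectories
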