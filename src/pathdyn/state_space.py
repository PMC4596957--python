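"""Linear state-space view of enumerated trajectories.

Each firing x_k -> x_{k+1} along a trajectory can be written as a linear
update x_{k+1} = A_{k+1} x_k, and observable read-outs as y_k = C x_k,
giving a discrete-time time-varying linear system per trajectory.

Any matrix satisfying A x_k = x_{k+1} works; we take the minimum-Frobenius-
norm rank-one solution

    A = x_{k+1} x_k^T / (x_k^T x_k)

computed in exact rational arithmetic, which satisfies the constraint by
construction. C is the 0/1 selector of the declared observable nodes.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Sequence

import numpy as np

from .engine import Trajectory
from .model import NetworkModel

__all__ = ["transition_matrix", "observation_matrix", "trajectory_to_system"]


def transition_matrix(x_k: Sequence[int], x_k1: Sequence[int]) -> np.ndarray:
    """Exact rational matrix A with A @ x_k == x_k1 (minimum-norm solution)."""
    xk = [int(v) for v in x_k]
    x1 = [int(v) for v in x_k1]
    if len(xk) != len(x1):
        raise ValueError("state vectors must have equal length")
    denom = sum(v * v for v in xk)
    if denom == 0:
        raise ValueError("no transition matrix can map the all-zero state to a nonzero state")
    m = len(xk)
    a = np.empty((m, m), dtype=object)
    for i in range(m):
        for j in range(m):
            a[i, j] = Fraction(x1[i] * xk[j], denom)
    return a


def observation_matrix(model: NetworkModel) -> np.ndarray:
    """0/1 selector C of the declared observables: y = C @ x."""
    if not model.observables:
        raise ValueError(
            "model declares no observables; add an 'Observable <name> ...' line "
            "to the input file (or set model.observables)"
        )
    c = np.zeros((len(model.observables), len(model.nodes)), dtype=int)
    for row, node in enumerate(model.observables):
        c[row, node] = 1
    return c


def trajectory_to_system(
    model: NetworkModel, trajectory: Trajectory
) -> tuple[list[np.ndarray], np.ndarray, list[np.ndarray]]:
    """Compile a trajectory into (A_1..A_K, C, y_0..y_K)."""
    states = trajectory.states
    if len(states) < 2:
        raise ValueError("trajectory must contain at least one step")
    mats = []
    for k in range(len(states) - 1):
        mats.append(transition_matrix(states[k], states[k + 1]))
    c = observation_matrix(model)
    ys = [c @ np.asarray(x, dtype=int) for x in states]
    return mats, c, ys
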