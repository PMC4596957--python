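# pathdyn

Qualitative dynamical modeling of interaction-based pathway networks, for
biologists and modelers who have curated process knowledge (of the kind
exported from interaction databases such as PID, Reactome or Pathway
Commons) but not the rate constants that ODE models demand, and who want
every possible outcome enumerated rather than a single sampled run.

## The model

A pathway is a hypergraph **M = (N, E)**: entities *N* (genes, proteins,
complexes, metabolites) carrying non-negative integer values
**x ∈ ℤ≥0^m**, and hyper-edges *E*, one per biological process, each with
input, output, activator and inhibitor roles. Two process kinds are
distinguished structurally:

* **Conversion** (complex assembly, phosphorylation, …): enabled when every
  input carries enough tokens, every activator is nonzero and every
  inhibitor is zero; firing moves one token per role occurrence —
  Petri-net-style `input −1, output +1`, control nodes untouched. Every
  activator-gated conversion automatically gains a **reverse edge** that
  fires when the activator is absent and the products present.
* **Transcription** (BioPAX Template Reaction): no inputs; firing sets the
  0/1 output when the activator is present, Boolean-style, and a latch
  prevents re-writing the output until the activator level changes.

Updates are **asynchronous**: exactly one process fires per abstract time
step. Where several processes are co-enabled, qualitative knowledge prunes
the alternatives — *slow* processes (transcription by default) are deferred
while a *fast* one is co-enabled, and an explicitly outranked process is
dropped when its outranker is co-enabled. Whatever ambiguity remains is
**dynamics uncertainty**: the engine explores every remaining alternative by
breadth-first search and returns the complete set of dynamic trajectories
*T* = {t = (e_i, e_j, …)}, each ending in a dead end or a cycle. Each
trajectory can additionally be compiled into a linear discrete-time
time-varying system x_{k+1} = A_{k+1} x_k, y_k = C x_k over the declared
observable entities.

## Worked example

The BAK1/MCL1 apoptosis switch ships as a built-in fixture: BAK1 dimerizes
(e1), the dimer triggers apoptosis (e2, slow), and MCL1 sequesters BAK1
with higher affinity than BAK1 self-binding, so sequestration (e3) outranks
dimerization, with e4 letting MCL1 strip BAK1 out of an existing dimer.

```bash
pathdyn fixtures export --name bak1_mcl1 --out bak1.txt
pathdyn run -i bak1.txt
```

prints

```
Dynamic Trajectories for Initial Condition: x0 = [2, 1, 0, 0, 0]^T

Trajectory t1 = {e3, e1, e2}
State Vector Updates for t1:
Time Step 1: e3
x1 = [1, 0, 0, 0, 1]^T
Time Step 2: e1
x2 = [0, 0, 1, 0, 1]^T
Time Step 3: e2
x3 = [0, 0, 0, 1, 1]^T
```

Entities are ordered (BAK1, MCL1, BAK1.BAK1, Apoptosis, MCL1.BAK1). With
two units of BAK1 but only one of MCL1, sequestration fires first (e3,
outranking e1), the leftover BAK1 dimerizes (e1), and the dimer commits the
cell to apoptosis (e2): the Apoptosis entry of the final state — the
declared observable, `y = [1]` — is 1. There is exactly one trajectory:
the priority and speed labels have removed all dynamics uncertainty.
Adding `--state-space` appends the transition matrices A_1..A_3 (exact
rationals) and the observable read-outs y_0..y_3 for each trajectory.

The same library API:

```python
import pathdyn as pd

model, x0, _ = pd.build_fixture("map_kinase")
(trajectory,) = pd.enumerate_trajectories(model, x0)
print(trajectory.edge_sequence, trajectory.terminal)
# (0, 1, 2, 3, 4, 5, 6, 7) Terminal.CYCLE  — the ERK negative-feedback oscillation
```

Other fixtures: `pathdyn fixtures list`. Input files use a simple
block-structured text dialect (`Process / Input / Output / Activator /
Inhibitor`, then `Entity Value` initial conditions, with optional `Speed`,
`Priority` and `Observable` lines) — see `docs/methods.md`.

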