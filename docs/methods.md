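# Methods

## Model and update semantics

A network is `M = (N, E)`: entities with non-negative integer values and
hyper-edges with input/output multisets and activator/inhibitor sets. The
entity "value" is a qualitative abstraction — a thresholded concentration or
an on/off expression level — not a calibrated concentration, and values of
different entities are not comparable.

**Conversion firing** consumes one token per input occurrence and produces
one per output occurrence; control nodes are unchanged. Enablement requires
each input entity to hold at least as many tokens as the firing consumes
(an input listed twice needs value ≥ 2 — the pairwise "nonzero" reading
would let a firing drive a value negative), all activators nonzero and all
inhibitors zero.

**Transcription firing** (structurally: no inputs, ≥ 1 activator) sets its
output to 1 and latches the activator values. The edge re-enables only when
the activator values differ from the latched ones, *and* only while the
activators are nonzero — an enabled process always has nonzero activators,
so the "set output to 0 when the activator is absent" branch of the update
rule is unreachable; a transcript read-out, once written, persists. The
latch starts empty, so a transcription with an active driver is enabled at
step 0 even if its output is already 1 in the initial condition (firing it
then reproduces the same state, which the cycle rule closes immediately).

**Reverse edges.** Every activator-gated conversion gains an automatic
reverse edge (products → reactants) enabled exactly when the forward
products are all nonzero and the forward activators all zero. Internally
the reverse edge simply lists the forward activators as its inhibitors, so
the ordinary conversion rule implements the semantics with no special case.
Forward *inhibitors* are not consulted by the reverse edge — the source
semantics are silent here and we chose the narrower condition; flip side:
a reverse process can run while the forward process's inhibitor is present.
Transcriptions and ungated conversions get no reverse. Augmentation is
idempotent; reverse edges carry the forward speed, no priority relations,
and appear after all original edges.

## Uncertainty and its reduction

Asynchronous update: one firing per abstract time step (a step does not
correspond to wall-clock time). When several processes are co-enabled, the
co-enabled set is filtered:

1. **speed** — slow edges are dropped iff at least one fast edge is
   co-enabled (a lone slow edge fires normally and costs one step);
2. **priority** — an edge is dropped iff a co-enabled edge from step 1's
   survivors explicitly outranks it. Removal is simultaneous: in a chain
   a > b > c with all three co-enabled, only a survives. Priority is a
   strict partial order among explicitly related edges (declared cycles are
   a validation error); unrelated edges never suppress each other, and an
   absent outranker suppresses nothing.

Every surviving alternative spawns a branch; the result is the complete
trajectory set, not a sample. Defaults: conversions are fast, transcriptions
slow, matching the time-scale gap between binding/catalysis and
transcription-level events; an explicit `Speed` line overrides either.

## Enumeration algorithm

Level-synchronous breadth-first search over branches
`(state, latch, sequence, history)`:

* **dead end** — empty filtered co-enabled set: the branch's sequence is
  recorded (empty sequences never are, so an inert initial condition yields
  an empty trajectory set);
* **cycle** — a successor state equal to any state already on the branch
  (the initial condition included) closes the branch; the recorded sequence
  ends with the firing that closed the cycle and `cycle_start` marks where
  the repeat lands;
* **merging** — frontier branches reaching identical `(state, latch)` at the
  same depth are merged, keeping the earliest-generated sequence. Branches
  are expanded in creation order and edges in ascending index, so the kept
  representative is the lexicographically earliest interleaving; this is
  what makes two firing orders of independent processes count as one
  trajectory. The latch participates in the merge key: two branches with
  equal states but different transcription histories have different
  futures, so merging on state alone would be unsound (no worked example
  discriminates the two keyings; we chose the conservative one).
* **step limit** — `max_steps` (default 1000) bounds branch length; models
  that accumulate tokens without bound (e.g. an autocatalytic A → A + B)
  never revisit a state, so a guard is required. Surviving branches are
  recorded with a `step_limit` flag and a logged warning, not an exception.

Recorded sequences are deduplicated exactly; everything is deterministic —
no randomness exists anywhere in the engine.

`mode="sync"` is reserved and raises `NotImplementedError`: simultaneous
multi-edge firing is a documented capability of this model family but has
no specified semantics to implement against.

## State-space view

Each step of a trajectory is expressed as `x_{k+1} = A_{k+1} x_k` with the
minimum-Frobenius-norm rank-one solution
`A = x_{k+1} x_kᵀ / (x_kᵀ x_k)`, computed in exact rational arithmetic
(`fractions.Fraction` in an object ndarray), so `A x_k = x_{k+1}` holds
exactly and the published worked instance is reproduced digit for digit.
Any matrix satisfying the constraint is mathematically admissible; the
minimum-norm choice is canonical, not asserted to be the only one. The
all-zero state has no pre-image and is rejected. `C` is the 0/1 selector of
the declared observables, one row per observable in declaration order.

## Input dialect

Block-structured text: `Process <n>` followed by `Input`, `Output`,
`Activator`, `Inhibitor` lines (whitespace-separated case-sensitive entity
tokens; `.` allowed in names for complexes), then an `Entity Value` section
giving the initial condition. The base dialect has no fields for speed,
priority or observables, so the package adds optional extension lines —
`Speed fast|slow` and `Priority > <process#> ...` inside a block (the
legacy string form `e2prio>e3prio` is accepted), and top-level
`Observable <name> ...` lines. Files without extension lines remain valid
and get the defaults. Node order follows the Entity section; entities
mentioned only in processes are appended with initial value 0 and a logged
warning (pathway descriptions typically list only the nonzero species).
Serialization omits reverse edges (they are regenerated), and
parse ∘ serialize is the identity on classified, augmented models.

## Built-in fixtures and the verification oracle

Seven networks ship as code: two one-edge teaching cases (gated conversion
with its reverse; transcription), the speed and priority micro-examples, a
twelve-node illustrative network exercising every rule at once, the
BAK1/MCL1 apoptosis switch (observable: Apoptosis), and the MAP-kinase
cascade with the ERK negative feedback whose single trajectory is an
eight-step oscillation through four auto-generated reverse edges. Expected
trajectory sets, state histories and terminal statuses are stored with each
fixture and asserted in the tests. In the BAK1/MCL1 network the fourth
process (MCL1 stripping BAK1 from an existing dimer) is constrained by the
published trajectory rather than spelled out in text; the shipped edge is
the biologically standard sequestration reaction consistent with that
trajectory. The ErbB2/ErbB3 receptor network is not shipped — its edge list
exists only in figure form — and its check activates only when a user
supplies a transcription under `data/`.

`fixtures.generate_random_network` produces small seeded networks (sizes,
role probabilities and value ranges chosen to stress every rule: ~20 %
transcriptions, occasional duplicate inputs, inhibitors, slow labels and
priority pairs). They exist to stress the semantics, not to resemble
biology: no conservation structure, no realistic connectivity. Passing the
randomized suites therefore demonstrates correctness of the update/
enumeration semantics, not predictive validity on real pathways.

`fixtures.oracle_enumerate` is an independent re-implementation used only
for cross-checking: a plain recursive depth-first enumeration with inline
enablement/filter/firing rules. Branch merging is emulated with a
first-visit-wins memo on `(depth, state, latch)`; depth-first preorder
visits equal-depth prefixes in exactly the lexicographic order in which the
breadth-first engine creates them, so both produce identical sequence sets.
The test suite checks this equality on 200+ seeded random networks (≤ 6
nodes, ≤ 5 edges, initial values ≤ 2, `max_steps` 25 — deliberately small
so exhaustive enumeration of both routes stays fast) alongside replay
soundness, non-negativity and the reverse-edge precondition on every
produced trajectory.

## Known limitations

* Synchronous update is unimplemented (reserved flag).
* BioPAX/OWL and SBML are not parsed; inputs must already be in the text
  dialect.
* Trajectory counts can grow combinatorially with branching; the engine is
  exhaustive by design and makes no attempt to sample or bound the set
  beyond `max_steps`.
* Reverse-edge enablement ignores forward inhibitors (see above); models
  that need the stricter reading can add the inhibitors to the reverse
  process explicitly in the input file.
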