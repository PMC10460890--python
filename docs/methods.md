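# Methods notes

## Model and update semantics

Networks are synchronous Boolean systems. Rules are parsed exactly as
written (BoolNet `targets, factors` dialect; `!`, `&`, `|`, parentheses,
constants 0/1) and are never simplified at parse time, so writing a
model back to disk is bit-exact. Nodes that never appear as a target are
inputs; under synchronous update an input holds its value (identity
self-rule). This models sustained stimuli: the IO relationship is
evaluated at fixed input conditions, and curated signaling models treat
stimuli the same way. Whether inputs should instead be free-running
during the robustness sweeps is genuinely open; we hold them, and the
choice is localized in `BooleanNetwork.step_function` if a variant is
needed. A node with a *constant* rule (e.g. after an intervention) is
not an input: it has a rule, just one with no remaining regulators.

Attractors are stored in canonical rotation (lexicographically smallest
state first, node-declaration order), which gives cycles set semantics
and makes every tie-break deterministic. `sample_attractors` switches to
exhaustive enumeration whenever `2^N ≤ n_samples`, so small networks are
always exact.

## Expanded network and LDOI

Edges of the expanded network are generated from the **complete** set of
prime implicants (Blake canonical form, Quine–McCluskey merge phase) of
each rule and of its complement — not from a minimal cover. A minimal
cover would drop consensus implicants and with them valid sufficiency
edges, making the LDOI smaller than it should be; completeness makes the
closure maximal-informative while absorption (e.g. `(E | C) & C → C`)
still disappears. Composite AND nodes are deduplicated by member set.

LDOI is a breadth-first closure: a literal enters when a single-literal
parent is in, or when all members of a composite parent are in. A
literal whose negation is a *seed* is never added and is recorded as a
conflict; a derived contradiction between two non-seed literals keeps
the earlier-derived literal (deterministic BFS order: declaration order,
OFF before ON) and flags the later one. Constant-rule literals are roots
of every closure. Interventions are applied both ways at once — the rule
is replaced by a constant (which severs upstream edges, so nothing
back-propagates through the complement DNF) *and* the literal is seeded.

The inferred 0.5 means "not determined by canalization", nothing more.
The sound direction (an inferred 0/1 equals the exact attractor-averaged
output value) is asserted against a brute-force oracle in the tests; the
converse — that 0.5 implies a genuinely mixed output — is not claimed
and not enforced, since the LDOI is sufficient, not necessary.

## Classification and the reverse-control search

Only internal nodes are classified; inputs and outputs are excluded.
The C2 search uses candidates restricted to C1-node fixations plus the
override of the mutated node, with the total number of simultaneously
fixed nodes bounded by `1 + budget` (default budget 1, i.e. a
double-fixation search: the surviving mutation plus one control, or the
override plus one control). This keeps the search quadratic in network
size. Raising the budget can only move nodes out of C3, never into it.
`find_reverse_controls` itself is more general: any candidate pool, any
set-size budget, optional total-fixation cap; it returns *all* minimal
restoring sets sorted by (size, lexicographic), not just one witness.

Multi-mutation alteration profiles (cell lines) are mapped gene → node
through the packaged annotation table (GOF → fix to 1, LOF → fix to 0);
unresolvable genes are reported and skipped rather than failing, because
profile tables routinely include genes outside the model. Note the
CDKN2A row maps to the p14 node (p21 is CDKN1A).

## Measures

* **V** = 1 − N_C3/N_internal.
* **D** = N_sp/N_p. A matched instance is an (input node, input state,
  output node) triple for which some profile with that input at that
  state infers the output ≠ 0.5 — so an input–output pair can count
  twice, once per input state. N_sp counts directed simple paths of
  length (edge count) strictly less than twice the shortest-path length.
  Undefined (raises) when no profile is deterministic.
* **B_m** averages, over all 2N single-node fixations, the fraction of
  primary-attractor states retained: |A_o ∩ A_k| / |A_o| on raw state
  tuples, so states reachable only in the mutated network are ignored by
  construction. "Primary" = largest sampled basin, ties to the
  lexicographically smallest cycle; `all_attractors=True` compares the
  union of all sampled attractor states instead, and `mask_mutated=True`
  drops the mutated coordinate before intersecting (a variant reading;
  the plain intersection is the default because it, and only it,
  reproduces the closed-form checks: a single self-activator and a
  network of tautology rules both give B_m = 0.5 exactly).
* **B_p** is normalized by N·|S| so it is a true fraction in [0, 1].

Default sampling is 2^10 initial states per attractor estimate, with one
explicit seed threaded through every stochastic call; nothing uses
global random state.

## Random ensemble

Random rules follow the canalizing form: a uniformly drawn canalizing
regulator x_c, canalizing value b and canalized value a force half the
truth table; the other 2^(k−1) rows are fair coins. When the sampled
table happens to be constant, the emitted expression is a tautology or
contradiction that still references every regulator, so the interaction
structure — and hence the degree sequence — is preserved exactly even
for degenerate draws.

The configuration model pairs out-stubs to in-stubs uniformly and
repairs self-loops and parallel edges by degree-preserving random edge
swaps (regulator lists cannot repeat a node), raising an error if no
collision-free pairing is found. IO roles of generated networks follow
from topology alone: in-degree 0 = input, out-degree 0 = output.

The reference template set for the ensemble study is synthetic (the
published study drew degree sequences from ten curated signaling models
whose identities are in supplementary material we do not reproduce):
five networks of 16–24 nodes, 2–4 inputs, 2 outputs, mean in-degree
≈ 2.5 — the scale and density typical of curated signaling models —
generated once from a fixed seed so the set is a stable reference.
Networks without a single deterministic IO profile are discarded before
any measure is computed. The scaled-down study run in the test suite
uses 10 replicates per template (50 networks, 2^8 samples per attractor
estimate) and checks only the *sign* of the V–D and V–B_p Pearson
correlations; correlation magnitudes at this scale are small (r ≈ 0.15
and ≈ 0.27 at the reference seed) and noisier than a full 100× run.

The logic-uncertainty analysis (`perturb_logic` +
`classification_consistency`) redraws the rules of a chosen fraction of
non-input nodes (canalizing form, same regulators, topology unchanged)
and reports the mean fraction of internal nodes keeping their C0–C3
class.

## What the synthetic generators do and do not emulate

The random-network generator reproduces the degree heterogeneity,
canalizing logic and sustained-input conventions of curated signaling
models, but not their curated feedback structure, pathway modularity or
biased truth tables beyond single-variable canalization. Passing tests
therefore demonstrate correctness of the algorithms and the direction of
the ensemble-level trends, not quantitative agreement with any
particular published model; benchmarks against published networks run
only when those models are supplied as `.bnet` files under `models/`.

## Numerical/engineering notes

Truth tables are enumerated per rule (in-degrees in practice ≤ ~6;
prime-implicant computation is exponential in in-degree and guarded only
by practicality). The synchronous step is compiled once per network into
a tuple expression, and attractor searches share a per-network
state → attractor memo, which is what keeps the exhaustive oracles and
the B_p double loop (|S|·N attractor lookups) cheap. The exact-IO oracle
refuses networks above 20 nodes by default.
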