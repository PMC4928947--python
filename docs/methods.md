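# Methods

## The consensus model

Given `N` subject braingraphs over a shared set of ROI-labeled vertices, each
undirected edge `e` has a support count `c(e)` — the number of subjects whose
graph contains it.  The consensus graph `G_k` keeps the edges with
`c(e) ≥ k`.  The family is nested (`E(G_{k+1}) ⊆ E(G_k)`), `G_1` is the union
of the subject edge sets and `G_N` their intersection.  Edge weights are
aggregated (median by default, mean/sum available) purely for export; no
analysis step depends on them.  A `min_edge_weight` filter, when used, acts
per subject *before* counting, mirroring a minimum-edge-weight selector
applied to each individual connectome; a subject whose edges are all filtered
away still counts toward `N`.

The minimum-edge-confidence percentage maps to the threshold as
`k = ceil(pct/100 · N)` clamped to `[1, N]`.  The ceiling is the only rounding
consistent with both conventional endpoints used throughout the docs and
tests: 26% of 96 subjects → k = 25, and 100% → k = N.  The product is rounded
to 9 decimals before the ceiling so that exactly-representable percentages
(30% of 10) are not pushed up by floating-point noise.

## Sweep semantics and the isolation statistic

Decreasing `k` from `N` to 1 adds at step `k` exactly the edges with
`c(e) = k`.  All of a step's edges appear **atomically**: each is classified
by its endpoints' degrees in `G_{k+1}` (with `G_{N+1}` the empty graph), never
against edges added "earlier within" the same step.  Consensus graphs have no
intra-step order, so this is the only classification that makes the result
independent of edge enumeration order.  Classes: `iso_iso` (both endpoints
isolated before the step), `iso_conn` (exactly one), `conn_conn` (neither).

The buildup statistic is the running count of `iso_iso` edges over steps
`ℓ = 0 … N−1` (`k = N − ℓ`).  Counting edges with *both* endpoints previously
isolated is the implemented reading; the library also exposes an
`any_isolated` variant (at least one previously isolated endpoint) so the two
readings can be compared.  A shrub-like growth — new edges attaching to the
existing graph — keeps the `iso_iso` count low; uniform-random edge placement
does not.

## The uniform-random null

The null replays the real step sizes on the same number of vertices: each
step draws that many new edges uniformly without replacement from all
unordered pairs not yet present, classifying each against the pre-step graph
with the same rule.  Sampling steps sequentially without replacement from a
uniform universe is equivalent to consuming one uniform random permutation of
all vertex pairs, which is how it is implemented (one permutation per
repetition, vectorized per-step classification).  Repetition `r` of a run
seeds an independent substream `(seed, r)` of NumPy's PCG64 family, so runs
are reproducible and trivially parallelizable.  The comparison reports
per-step null mean and sample SD (`ddof = 1`) and the z-score of the real
final cumulative count under the Monte-Carlo null.  The edge universe is all
pairs of the population's vertices, not just the union graph's edges: the
null is meant to model placement with no structure at all.  No
degree-preserving or geometry-aware nulls are provided.

## Component tree

Sweeping `k` downward, a new numbered node is created whenever a step
produces a multi-vertex connected component whose vertex set differs from
every component of `G_{k+1}`; its children are the prior components (numbered
nodes) and prior isolated vertices (named ROI leaves) it absorbs.  Components
that persist unchanged spawn nothing, and an edge internal to an existing
component changes no vertex set, so it spawns nothing either.  Labels are
consecutive integers in creation order, so numbered labels strictly increase
and birth thresholds strictly decrease from child to parent.  Within one
step, sibling creations are ordered by each component's lexicographically
smallest member — a convention chosen only for determinism; nothing
downstream depends on it.

Colors: a component born purely from isolated vertices takes a fresh color
(consecutive integers in creation order), shared with its named leaves;
isolated vertices attaching to an existing component inherit its color; in a
general merge the parent takes the color of the child with the largest member
count.  On an equal-size tie the older (smaller-labeled) child wins —
stability over recency; a named leaf counts as size 1 and can therefore never
out-size a numbered child.  Coloring recomputes everything from the
structure, so it is idempotent.

GraphML export writes child→parent edges with node attributes `kind`
(named/numbered), `label`, `birth_k` (numbered only) and `color`.

## Edge orientation

Each edge appears at exactly one transition, `G_{c(e)+1} → G_{c(e)}`.  If
exactly one endpoint `v` was isolated in `G_{c+1}` and the other endpoint `u`
was connected there, the edge is directed `v → u`.  `iso_iso` edges are
undirectable ("isolated edges"), as are `conn_conn` edges; both are reported
with their transition `k` and a reason.  A vertex attaching with several
simultaneous edges to previously connected vertices yields several directed
edges all tailed at it; a partner that becomes connected only within the same
step does not count as connected (its state is judged in `G_{c+1}` only).
Because every edge is judged exactly once, conflicting orientations cannot
arise.  The developmental reading — axonal growth proceeding from unconnected
toward already-connected tissue — is motivation only; the toolkit asserts
nothing biological.

## Synthetic populations

The generator lays down a ground-truth growth sequence (one event per age
rank) and then samples subjects so that support decreases with age,
letting every analysis module be tested closed-loop against a known answer.

Event kinds: `attach` (new vertex → existing connected vertex; ground-truth
direction), `de_novo_pair` (two new vertices; an isolated edge), `internal`
(absent pair between already-connected vertices).  The sequence starts with
one de-novo pair.  Requested kinds that are infeasible in the current state
fall back along attach → de-novo → internal, so valid configurations never
fail; in particular, when the vertex pool is exhausted late in a long
sequence, attachment requests degrade to internal edges.

**Level-aware wiring.**  Nested sampling gives subject `s` (0-based) the
threshold `t_s = ceil((s+1)·E/N)` and the edges with age below it, so the
support of age `a` is `#{s : t_s > a}`.  With more events than subjects,
consecutive events share a support level and appear atomically at the same
`k`; an attach edge whose target only became connected within the same level
would then be undirectable, and the sweep could not replay the truth exactly.
The generator therefore wires attach and internal events only to vertices
connected in **strictly earlier support levels** (a stricter subset of
"currently connected"; with at most one event per level the two coincide).
This makes nested-mode direction recovery exact by construction — the
strongest available closed-loop check — at the cost of slightly less
within-level mixing than a fully online growth process would have.

Bernoulli sampling instead includes each edge independently with probability
`p(age)`, linear from `p_max = 0.95` down to `p_min = 0.30`; support is then
Binomial(`N`, `p(age)`), strongly anticorrelated with age but no longer
deterministic, which exercises the partial-recovery paths.

Defaults: 96 subjects, 200-vertex ROI-labeled pool (`lh_region_i` /
`rh_region_i`), 300 events with fractions 0.8/0.1/0.1
(attach/de-novo/internal), nested mode.  These are a desk-scale stand-in for
a ~hundred-subject cohort over a ~1000-ROI parcellation; the full
1015-vertex / 418-subject size also runs in seconds and is covered by a test.
Note that 300 events on a 200-vertex pool exhaust the fresh vertices late in
the sequence, so the realized attach fraction is below the nominal 0.8; the
fallback edges are internal and leave all closed-loop guarantees intact.

What the generator does **not** emulate: spatial embedding, hemispheric
symmetry, fiber-count or length weights (all weights are 1.0), measurement
noise in edge detection under nested mode, and subject-level vertex dropout.
Passing tests therefore show the algorithms are correct under the stated
growth model, not that real cohorts follow it.

## Numerical and degenerate-input choices

- All randomness flows through seeded `numpy.random.default_rng`; derived
  streams use seed sequences like `(seed, rep)`, never arithmetic on seeds.
- Internal-pair sampling uses rejection sampling (cap 200 tries) with a
  deterministic full scan as fallback, so it is exact at any density.
- An edgeless population yields an all-zero trajectory, an empty tree, and an
  empty orientation partition rather than errors; a null comparison with zero
  final SD reports z = 0 when the difference is zero, ±inf otherwise.
- Writers sort records canonically and emit LF line endings, so identical
  inputs produce byte-identical outputs; floats are written with `repr` for
  lossless round trips.

## Limitations

- The orientation rule covers only `iso_conn` edges; no heuristic is applied
  to the rest, by design.
- CSV edge lists cannot carry isolated vertices; the population vertex set is
  the union of subject labels, and a vertex isolated in every subject is
  invisible to CSV-based pipelines (GraphML preserves it).
- The null model's vertex count defaults to the population's; populations
  whose unused parcels are invisible (see above) therefore get a slightly
  smaller null universe than a fixed-parcellation run would.
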