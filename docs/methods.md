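# Methods

## The graph model

A reaction network is a bipartite directed multigraph G = (V, E).  Nodes
are *physical entities* or *events*; each carries a stable identifier (the
node's identity — compartment-specific occurrences of one molecule arrive
as distinct identifiers from the curated source), a display name, a set of
cellular-component accessions, and an opaque schema-category string used
only for grouping in summaries.  Edges are typed; the type forces the
orientation (`input`, `catalyst`, `positive_regulation`,
`negative_regulation`: entity → event; `output`: event → entity), which
makes bipartiteness an insertion-time invariant and self-loops impossible.
Parallel edges are preserved: a molecule consumed *and* catalysing the same
reaction contributes two edges.  The graph is qualitative — no
stoichiometry, no rate laws.

Two degree semantics coexist deliberately.  d±(v) counts edges (parallel
edges separately, all five types by default; every degree-consuming
function accepts an `edge_types` filter), while N±(v) is a set of distinct
nodes.  The centrality formulas below sum over N±(v) but use edge-count
degrees inside the sums; keeping both semantics explicit in the model layer
avoids silent disagreement between measures.

## Import semantics

The importer targets a labelled-property-graph schema (pinned naming:
version 73 of the upstream schema; other versions are accepted with a
warning).  For a species code S it retains every `ReactionLikeEvent` whose
`species` relationship points at S **or** whose identifier matches the
generic pattern `R-(ALL|NUL)-.*` — generic reactions belong to every
species and may carry no species link at all.  Entities enter the graph
only through relationships of retained events: `input` and `output` rows
map to edges directly; catalysts are reached through
`catalystActivity` → `physicalEntity` chains; regulators through
`regulatedBy` → `regulator` chains, signed by the regulation node's
`PositiveRegulation`/`NegativeRegulation` class (an unsigned regulation is
a schema error, reported as such).  `referenceEntity` supplies identity
metadata (fallback display names) and never creates edges.  Events with no
surviving entity relationship are kept as isolated nodes: small and
single-node weak components are real features of these networks and
dropping them would bias every component census.  Each relationship row
becomes one edge, so a duplicated row is a parallel edge — multiplicity is
data, not noise.

The query layer is written against a three-method store interface
(`node_ids_with_label`, `node_properties`, `related`); the package ships a
JSON-dump backend, and a live graph-database client can be plugged in by
implementing the same interface.

## Centrality measures

All five measures come in in/out variants (degree also total); an
in-measure on G equals the corresponding out-measure on the edge-reversed
graph, which the test suite checks measure by measure.

- **DC±(v) = d±(v)**.
- **HC±(v)**: the largest h such that at least h of v's in-(out-)neighbours
  have in-(out-)degree ≥ h.  The neighbour degree is taken in the *same*
  direction as the measure, by analogy with the Laplacian formula where the
  direction is explicit; a `neighbor_degree_direction` option switches the
  reading.  h = 0 is always feasible, so sinks/sources score 0.
- **LAPC±(v) = d±(v)² + d±(v) + 2 Σ_{u∈N±(v)} d±(u)**, the drop in
  Laplacian energy on removing v; the sum runs over distinct neighbours.
- **LC±(v) = (1/d±(v)) Σ_{u∈N±(v)} (d±(v) − d±(u)) / (d±(v) + d±(u))**.
  A node of degree 0 scores 0 (the formula divides by d±(v), and 0 is the
  natural information-free value); a neighbour of degree 0 contributes a
  term of exactly +1, no guard needed since d±(v) > 0 whenever the
  neighbourhood is nonempty.
- **CC(v) = n / Σ_u d_G(u, v)** with unweighted shortest directed distances
  *into* v, computed by BFS from v on the reversed simple projection
  (parallel edges cannot change a distance).  Reaction networks are never
  strongly connected, so the literal formula is degenerate: some distance
  is infinite for every node outside a terminal SCC.  The default
  `reachable` mode therefore restricts the numerator and the sum to the set
  of nodes that reach v (which contains v itself at distance 0); the
  `strict` mode applies the formula literally and returns 0 whenever any
  node fails to reach v.  The two agree exactly on strongly connected
  graphs.  Scores may exceed 1 because the numerator is n, not n − 1.  An
  `out` direction (distances from v) is provided as a convenience; the
  canonical definition is the `in` variant.

## Connectivity structure

SCC/WCC decomposition and condensation are delegated to networkx; the
module adds the domain bookkeeping.  The condensation is a simple DAG
(parallel crossings between two components merge — multiplicity carries no
information at this level).  *Diameter* of the condensation means the
longest finite shortest path over ordered reachable pairs: the condensation
is disconnected in practice, so the all-pairs textbook diameter would be
infinite, and the reachable-pairs maximum is the only reading that yields a
single finite number.  An undirected variant is exposed for comparison.
The census (`condensation_report`) reports condensed node/edge counts,
sources and the compartments their member nodes touch, the largest SCC's
size and compartment coverage, the fraction of original nodes in singleton
components, weak-component counts (sizes measured in condensed nodes), and
the diameter.

## Compartment hierarchy

The cellular-component ontology is read from OBO; `is_a` and `part_of` are
treated as containment by default (configurable — upstream annotation
practice does not distinguish them consistently).  Construction: (1) add a
dummy root with exactly two children, the cell term (GO:0005623) and the
extracellular region term (GO:0005576), which are kept as structural
anchors whether or not they host reactions; (2) discard every compartment
annotating zero *event* nodes — entities alone do not rescue a compartment;
(3) re-link each orphaned retained term to the lowest non-discarded
ancestor along *each* ancestral path, deduplicated.  Containment is a DAG,
not a forest, so the lowest retained ancestor can be plural; linking to all
of them preserves the DAG shape instead of forcing an arbitrary tree.
Accessions present in the graph but missing from the ontology are kept,
with a warning, as leaves under the dummy root.

Per-compartment statistics use the node-induced subgraph on direct labels;
a node annotated with several compartments belongs to each subgraph.  An
`aggregate_descendants` mode unions labels down the hierarchy instead,
since annotations sit at mixed abstraction levels and either convention is
defensible; direct labels are the default because they are
assumption-free.  Every row satisfies n_wcc ≤ n_scc ≤ n_nodes.

## Distribution summaries

Scores on these networks live on small discrete supports, so the PDF is
the empirical probability mass function over distinct observed values and
the CDF its running sum (monotone, ending at 1); no binning or smoothing.
Frequency histograms (exact counts) are provided for integer measures with
tiny supports, such as the H-index, and reject non-integral input.

## Synthetic fixtures: what they emulate and what they do not

`FixtureSpec` defaults model the curated human network at 1:35 scale,
fixed a priori from its published global shape: 1,000 nodes split
62.4% entities / 37.6% events; 1,507 randomly drawn edges typed i.i.d. from
the observed global mix (47.4% input, 37.9% output, 10.8% catalyst, 2.6%
positive and 1.3% negative regulation); 111 compartments in a depth-5
containment DAG (about 15% of terms get a second parent); and one planted
alternating entity→event cycle spanning 324 nodes (32.4% of the graph),
emulating the giant strongly connected component — uniformly random
bipartite digraphs at this density essentially never produce one, which is
why cycles are planted explicitly.  Bipartite alternating cycles have even
node counts, so odd requested sizes round up.  Random-edge endpoints are
drawn with Zipf-like weights (exponent 0.7 over a shuffled node ranking) to
give heavy-tailed degree distributions; the first edges cycle through every
entity so that each entity is attached whenever n_edges ≥ n_entities,
which also makes the schema-dump round trip exact.  Everything is
deterministic in the seed, down to byte-identical serialized files.

Random input/output edges around the planted cycle merge additional nodes
into the giant SCC, so its realized share (~0.55) exceeds the planted
32.4%; the planted size is a lower bound by construction, not a calibrated
target.  Not emulated: the real network's exact degree sequence, the heavy
concentration of nodes in a few compartments (fixture labels are uniform),
biologically meaningful stoichiometry, and reaction semantics generally.
Passing tests therefore certify the graph machinery and the measure
implementations, not biological conclusions about any particular network.

## Numerical conventions and edge cases

- Integer-valued measures (DC, HC, LAPC) are compared exactly in tests;
  real-valued ones (LC, CC) to 1e-9, since neighbour summation order is
  unspecified.
- Empty graph: every centrality returns an empty score map; the category
  summary returns an empty table; `empirical_distribution` rejects empty
  input.
- Degenerate closeness (nothing reaches v, or a single-node graph) scores
  0 in both modes.
- Edge keys only disambiguate parallel edges; graph equality and the
  save/load round trip compare the typed-edge multiset, so keys may be
  relabelled within a parallel bundle.
- Serialization is deterministic (sorted keys) and outputs carry no
  timestamps, making byte-level reproducibility testable.

## Problem sizes

The test suite sweeps 200 seeded random fixtures of at most 50 nodes for
the oracle-equivalence and duality checks (brute-force oracles are O(n³)),
60 fixtures for condensation properties, and 40 random DAGs of at most 30
nodes for the diameter oracle.  The acceptance script runs the default
1,000-node fixture; the full analysis including all-nodes closeness takes
a few seconds on one CPU.
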