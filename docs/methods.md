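# Methods

## The star value

The local subnetwork of a vertex `v` is `v` (the hub) plus its adjacent
vertices (the spokes).  If the spokes are pairwise connected the
neighbourhood is a clique and the hub mediates nothing; if no two spokes
are connected it is a star and every spoke pair communicates through the
hub.  The *workload* of an undirected hub with spoke set `C` and `m`
edges among the spokes is

    L(v) = |C| (|C| - 1) / 2 - m,

the number of spoke pairs whose shortest path runs through the hub
(assuming shortest-hop routing and crediting the hub even when parallel
two-hop paths exist).  The *star value*

    SV(v) = 2 L / |C|^2 = 1 - (2 m + |C|) / |C|^2

is 0 for any clique hub and `1 - 1/k` for a pure `k`-spoke star, so it
approaches 1 for large stars.  Unlike the clustering coefficient, SV is
sensitive to neighbourhood size: a 50-spoke star imposes far more
mediation work than a 3-spoke star, and SV reflects that.

### Directed neighbourhoods

A directed neighbourhood is modelled as a tripartite flow: spokes with an
arc *into* the hub only form the source-only set `S`, spokes with an arc
*from* the hub only form the target-only set `T`, and reciprocal spokes
form `C`.  The source side `S + C` communicates with the target side
`T + C` through the hub; `m` counts the direct source-to-target arcs that
relieve it.  Then

    L(v)  = |S| (|T| + |C|) + |C| (|T| + (|C| - 1)/2) - m
    SV(v) = L / ( |S| (|T| + |C| + 2)/2 + |T| (|C| + 1) + |C|^2 / 2 ).

Two numerical conventions are deliberate design choices:

- **Intra-`C` arc weight.**  An arc between two reciprocal spokes counts
  1/2 toward `m`, so a fully reciprocal spoke pair contributes one unit —
  exactly the single unordered pair it serves in the workload term
  `|C| (|C| - 1)/2`.  Counting such arcs at full weight would drive `L`
  negative on reciprocal cliques and break the identity with the
  undirected formula; the halved weight guarantees `L >= 0`, clique
  hubs at 0, and *exact* vertexwise agreement between the directed
  measure on a fully reciprocal digraph and the undirected measure on
  its symmetrization (both are asserted in the test suite).
- **Normalizer parse (`denom="P1"`).**  The normalizer above is the
  unique reading of the directed normalization that collapses to
  `|C|^2 / 2` when `S = T = {}` and hence reduces the directed SV to the
  undirected one.  For very asymmetric neighbourhoods it can marginally
  exceed the workload ceiling, so directed SV can slightly exceed 1;
  values are reported raw and clipped only when binned into the `[0, 1]`
  histogram (clip counts are logged).  An alternative `denom="MAX"`
  normalizes by the workload of the arc-free partition, bounding SV in
  `[0, 1]` by construction, for sensitivity comparisons.

Degree-0 vertices (and directed vertices with empty neighbourhoods) have
no defined SV; they are excluded from tables, means and histograms, with
the exclusion count logged.

## Attribute measures

Vertices carry an integer group code in `1..K` (e.g. the eight brain
super-areas — basal ganglia, diencephalon, and the six cortical lobes —
of a cortical parcellation).  Codes are integers at least 1; a declared
group may be uninhabited, which keeps fixtures with sparse code usage
valid.

**Disparity** of a hub is the number of distinct spoke group codes that
differ from the hub's own code: 0 for a homogeneous neighbourhood, at
most `K - 1`.  The disparity profile reports, per disparity value, the
mean hub SV, mean hub degree, and the fraction of local subnetworks.

**Workload closure coefficient (WCC)** of a group `g`: consider all
unordered pairs of group-`g` vertices that are non-adjacent yet share at
least one common neighbour anywhere in the network (the *open pairs*; the
common hub may have any attribute).  A pair is *closed* if at least one
common hub is itself in `g`.  WCC = closed / open.  A group with no open
pairs is vacuously closed and reported as WCC 1.0 with a `degenerate`
flag, since the ratio is 0/0 there.  The per-group record also carries
the intra-group edge density and the mean clustering coefficient of the
induced subgraph, the two companion measures that determine how many
open pairs exist in the first place.  Disparity and WCC are defined on
undirected networks.

## Brokerage census

On a digraph, vertex `b` brokers the ordered pair `(s, t)` when arcs
`s -> b` and `b -> t` exist and the direct arc `s -> t` does not; the
reverse arc `t -> s` does not disqualify (directional non-adjacency, the
Gould–Fernandez convention).  Each brokered pair is classified by the
group equality pattern of `(A(s), A(b), A(t))` into coordinator,
gatekeeper, representative, consultant or liaison; the five cases
partition all triples, so the role counts of a vertex sum to its open
directed two-path count.  Counts are unnormalized and every broker of a
pair gets full credit.  The census reports per-role top-`k` vertices
(ties broken lexicographically) and a per-role best-broker matrix over
group pairs; because the matrix orientation is a convention, it is
recorded in the output header (`source-target` default: rows are the
source's group, columns the role's complementary group — the
broker/target group for gatekeeper, the target group for representative,
the broker group for consultant, the target group for liaison).

## Null models

- **ISO** permutes vertex labels uniformly.  Every topological invariant
  (degree distribution, SV multiset, path lengths) is preserved exactly,
  while which attribute sits on which topological position is
  randomized.
- **MS** applies Maslov–Sneppen double-edge swaps
  `(a,b), (c,d) -> (a,d), (c,b)`, rejecting proposals that create
  self-loops or parallel edges.  Undirected swaps preserve each degree;
  directed arc swaps preserve in- and out-degrees separately.  The
  budget is 10 successful swaps per edge (a common randomization
  choice), giving up after 100 proposals per edge with a logged warning;
  both multipliers are configurable.
- **B-MS** runs the same swaps independently inside each attribute
  block — the edge set joining one unordered pair of groups or lying
  within one group — with bipartite-safe swaps in inter-group blocks
  (each endpoint stays on its group's side) and, for digraphs, arcs
  grouped by ordered group pair.  This preserves the full block
  edge-count matrix and in fact every vertex's per-block degree, on top
  of the MS invariants.

These are practical randomizations of the switching-chain family, not
exact-uniform samplers of their respective ensembles.

## Generators and what the synthetic data does (not) emulate

`erdos_renyi`, `barabasi_albert` and `watts_strogatz` delegate to the
standard networkx generators and relabel to string vertex ids.  The ER
default `p = 10194 / (351 * 350)` reproduces the reference calibration:
a 351-vertex graph whose ~5097 undirected edges are counted once per
direction (the symmetric-arc convention used throughout, reported next
to the unique count in every summary).  At this density the ensemble's
mean clustering equals `p` (~0.083), its diameter is 3, its
characteristic path length ~2.0 and its grand mean SV ~0.884, consistent
with the closed-form ER limit `1 - p + (p - 1)/(n p)` (~0.885).  The
WS (`k = 29` lattice neighbours, rewiring 0.4) and BA (15 edges per
step) defaults only approximate the same edge budget and are
demonstration settings, not calibrated replications.

`planted_neighborhood(k, m)` builds a hub with `k` spokes and exactly
`m` uniformly-placed intra-spoke edges, so the hub's SV is
`1 - (2m + k)/k^2` by construction — the oracle for the SV formulas.
`attributed_block_graph` draws independent Bernoulli edges at separate
intra-/inter-group densities.  These fixtures emulate block structure
and planted star/clique motifs; they do not emulate spatial embedding,
hierarchical parcellation depth, reciprocity correlations or degree
heterogeneity of real cortical networks, so tests passing on them
validate the *measures and invariants*, not any biological claim.

## Numerical and procedural choices

- SV histograms use 20 equal bins on `[0, 1]`, half-open except the last;
  moment statistics (population skewness, excess kurtosis) default to raw
  values, with an option to weight bin midpoints by frequencies.
- Summary statistics are computed on the largest component — strong for
  digraphs, connected otherwise — with ties broken by the smallest member
  vertex; path lengths respect arc direction, clustering uses the
  undirected view.
- All iteration is in lexicographic vertex order and every stochastic
  operation takes an explicit seed; ensembles of `R` replicates use seeds
  `seed .. seed+R-1`, so identical invocations are byte-reproducible.
- Degenerate inputs fail loudly: empty edge lists, vertices without
  attributes, zero-variance moment inputs and isolated hubs raise,
  rather than returning silent placeholders.

## Problem sizes

The test suite and the reproduction script run 20-replicate ensembles at
n = 351 (the reference calibration), brute-force oracle comparisons on
hundreds of graphs of at most 12 vertices, and 1000-trial randomized
property checks — sizes chosen so the full suite completes in well under
a minute while still exercising every code path at the calibrated study
scale.

## Known limitations

- The directed SV under `P1` is not hard-bounded in `[0, 1]`; see above.
- WCC enumerates group pairs in `O(|g|^2)` with a common-neighbour scan
  per pair — fine for hundreds of vertices per group, not for very large
  groups.
- MS/B-MS provide switching-chain randomization, not exact-uniform
  degree-sequence sampling; very constrained blocks (e.g. a star) may
  admit few or no swaps, which is reported via the attempt-cap warning.
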