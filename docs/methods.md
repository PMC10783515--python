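# Methods

## The multiplex model

The package models the joint structure of cell signaling and transcriptional
regulation as a multiplex network: a fixed gene universe indexed 0..N−1 with
13 layers, each an N×N signed sparse adjacency.  The signaling side
contributes 11 interaction-specific layers (S = 1..11: activation,
binding/association, compound, dephosphorylation, dissociation, indirect
effect, inhibition, phosphorylation, PPI, state change, ubiquitination) and
one collapsed `KEGGPPI` layer; the regulatory side contributes one directed
TF → target layer (GRN).  The multiplex contract — every layer shares the
same index space, isolated nodes included — is what makes multilink counting
a per-position operation.

Construction rules, in order:

1. **KGML parsing.** Each pathway document yields a directed graph of
   entries and typed relations.  Entries naming several gene identifiers are
   expanded; a relation between multi-gene entries becomes the Cartesian
   product of edges; a relation with several subtype children yields one
   record per subtype.  Group entries (protein complexes) are disaggregated
   into complete graphs of their member genes, annotated `within_group` and
   undirected.  Binding/association and dissociation are undirected; all
   other subtypes, including compound-mediated relations, follow the
   relation's entry1 → entry2 orientation (KGML does not flag directedness
   explicitly; this is the conventional reading).  Unrecognized subtypes are
   flagged `unknown`.
2. **Merging.** The per-pathway graphs are aggregated into a directed
   heterogeneous multigraph; parallel records differing in type or pathway
   are kept, since the same physical edge can mean different things in
   different pathways (edge multiplicity and type-conflict fractions are
   reported).
3. **Refinement.** Non-gene nodes (compounds, maps, orthologs), unknown-type
   records, self-loops and GErel (expression/repression) records are
   removed; GErel duplicates what the GRN layer represents.  PPI edges are
   then merged in as undirected `ppi` records, but only on node pairs not
   already covered by a signaling record — a curated signaling interaction
   supersedes the context-free PPI edge.  The gene universe is the union of
   signaling and PPI genes; the GRN is pruned to it.
4. **Matrix fill.** A directed edge i→j is stored as +1 at (i, j) and −1 at
   (j, i); undirected edges as +1 at both positions.  The negative mirror is
   bookkeeping that lets the counting step read the relative direction of
   overlapping edges straight off the stacked matrices.  Reciprocal directed
   edges of one type collapse to the +1/+1 form (the sign trick cannot
   represent both arcs; presence is preserved and entries stay in
   {−1, 0, +1}).  Within one typed layer a directed typed edge wins over a
   coincident undirected edge; in the collapsed KEGGPPI layer any undirected
   record makes the pair traversable both ways, since that layer feeds the
   shortest-path search.
5. **Layer assembly.** Every typed layer S also carries all PPI edges,
   enlarging the rewiring space of its null model; `within_group` records
   are folded into binding/association (S = 2), reading complex
   co-membership as a physical-association statement (configurable through
   `type_index`).

## Multilink statistics

A multilink (S, R) describes one node pair jointly: S the signaling edge
type (0 = none), R ∈ {−1, 0, 1} the regulatory edge relative to the
signaling edge's direction — 36 types.  Counting conventions:

- A directed signaling edge contributes one count, with R read relative to
  its orientation; a GRN edge in each direction contributes (S, +1) and
  (S, −1) respectively.
- An undirected signaling edge has no reference direction: with any GRN
  overlap it contributes one count to (S, +1) *and* one to (S, −1) (so the
  two tallies are exactly equal on undirected-only layers); without overlap
  it is corrected for double counting and tallied once under (S, 0).
- (0, R) types are counted on the collapsed KEGGPPI layer only, so a GRN
  edge missing from the signaling layer is not multiply counted across the
  11 typed layers.  The (0, +1)/(0, −1) pair is indistinguishable and kept
  once as (0, 1).  (0, 0) is computed arithmetically from the number of
  ordered positions minus occupied ones — the dense complement is never
  materialized.

Counting operates on the layers' edge sets (hash-set membership), not on
dense arrays; the test suite checks it against an independent O(N²) dense
matrix scan on randomized toys.

Significance is ensemble-based only.  For actual count c_a and null counts
c_r over N_rand draws: z = (c_a − ⟨c_r⟩)/σ(c_r) with the population σ, and
the empirical p is the tail fraction #{c_r ≥ c_a}/N_rand for z > 0
(respectively ≤ for z < 0).  The raw fraction is reported — no 1/N_rand
floor — so p = 0 means "beyond every null draw" and is displayed as
< 1/N_rand in output text.  Degenerate nulls (σ = 0) leave z undefined when
c_a equals every draw (p = 1, never significant) or ±∞ otherwise, flagged
for the score's σ = 0 branch.  N_rand defaults to 100.

## Null model

Layers are randomized independently by pairwise edge rewiring: directed
swaps (a→b, c→d) → (a→d, c→b) on the arc set, double-edge swaps on the
undirected set, each rejecting self-loops, duplicates, and any swap that
would doubly occupy an unordered pair (which would break the signed fill).
The budget is Q×|E| *attempted* swaps per edge class with Q = 10 by default
— a standard burn-in for this family of null models; counting attempts
rather than acceptances guarantees termination on swap-poor graphs (a star
admits no legal swap and returns unchanged).  In- and out-degree sequences,
undirected degrees, edge counts and the directed/undirected character of
every edge are preserved exactly.

Instances are precomputed (500 per layer in a full run, giving 250 000
unique signaling×GRN pairings per layer pair) and drawn deterministically:
the k-th draw for a context is ((h+k) mod n, ((h+k) div n) mod n) with h a
CRC32 hash of (layer pair, context key).  Consecutive offsets within a
window of n² are distinct modulo n², so draws never collide within one
context, and everything is a pure function of the master seed.  Child seeds
per (master seed, layer, instance) keep layers independent.

## Crosstalk inference

For an ordered pair (A, B) the mutually exclusive node sets exA = A∖B,
exB = B∖A define the candidate positions; common genes are excluded so that
only edges genuinely *between* the pathways are read.

- **between**: all ordered positions exA×exB plus transposes.
- **shortest**: one BFS shortest path per (a ∈ exA, b ∈ exB) on the directed
  KEGGPPI layer (undirected edges traversable both ways; path reconstruction
  is deterministic by smallest-predecessor choice).  A path is kept only if
  every internal node lies outside A∪B — these are the intermediary nodes —
  and, given an `sp` threshold, if it has at most that many intermediaries
  (sp = 1 means a→x→b; direct a→b edges have zero intermediaries and pass
  any threshold).  Positions are the union of edges over retained paths.
  Shortest paths are computed on the *directed* layer to preserve the
  ordered-pair semantics of A → B crosstalk.

Null draws for the shortest method re-derive the subset on the randomized
KEGGPPI instance sharing the signaling layer's instance index, so each draw
sees one coherent randomized multilayer.

Proxy types are (S, ±1) for S = 1..11 plus (0, 1) — a statistically
over-represented pure regulatory edge between pathways is itself evidence of
transcriptional crosstalk (`include_zero=False` restricts to signaling-borne
types).  A pair is *detected* when at least one proxy type has a nonzero
actual count; n_sig counts proxies with p_emp ≤ 0.05 and z > 0 (the
boundary p = 0.05 counts).  p̃ is the minimum p over proxies with c_a > 0
and z̃ the maximum finite z; the two extrema may come from different types.
Ties at the minimum p are broken toward the highest *finite* z: a degenerate
null leaves z undefined, which cannot serve a highest-z ranking key, so the
σ = 0 score branch applies only when every type attaining p̃ is degenerate.
The score 1000·n_sig − log10(p̃+0.001)·z̃ encodes the three-key order
(n_sig, then p̃, then z̃) as long as |log10(p̃+0.001)·z̃| < 1000, i.e.
z̃ < 333.  Detected pairs are ranked by score descending with lexicographic
tie-break; undetected pairs are listed after, unranked.  Mediators — the
concrete edge positions realizing each significant type — are reported for
inspection and export.

Leave-one-layer-out excludes the *significant* multilink types on one layer
and re-scores: a layer with no significant multilinks anywhere is an exact
no-op, and a pair whose entire significance sat on the excluded layer drops
out of the ranking.  The PPI layer cannot be excluded — it is the connective
tissue of the collapsed layer that the shortest-path subsets are built on.

## Baselines and evaluation

Node and edge overlap use two-tailed Fisher exact tests (scipy) with
Benjamini–Hochberg correction (statsmodels), ranked by FDR ascending; the
edge-overlap universe is N·(N−1) ordered positions over the union gene set,
matching the directed multigraph (unordered available as an option).
Overlap tests are symmetric, so both orderings of a pair receive the same
value.  Direct edges between exclusive sets are scored with the same
ensemble machinery, over-represented pairs first.  The receptor → TF
baseline extracts K shortest paths with Yen's algorithm
(networkx `shortest_simple_paths`, ties resolved by length then
lexicographic order) and applies a plug-in statistic χ over the path set;
the shipped default, the path count, is a documented stand-in, not the
published χ closed form, which users can supply as `chi_fn`.

Evaluation is deliberately two-mode because every method has undetectable
pairs.  Deterministic: ROC/PR over detected labeled pairs only.  Stochastic:
all labeled pairs, with undetected ones given random distinct ranks strictly
below the last detected rank, re-shuffled per iteration (1000 by default);
AUCs are reported as mean ± sd over shuffles, and with zero undetected pairs
the mode short-circuits to the deterministic value with sd = 0 exactly.
AUROC comes from scikit-learn on negated ranks (equal to the normalized
Mann–Whitney statistic, which the tests assert); AUPRC is the average
precision estimator.

## Synthetic data

The generator emulates the statistical shape of the real inputs at desk
scale, and its defaults are the package's study conditions: 200 genes, 5
pathways of 14–26 genes with 15% overlap between adjacent pathways
(pathways share genes, as real ones do), per-type signaling densities
mirroring the empirical type abundances (activation and phosphorylation
common, ubiquitination and state change rare), pathway subgraphs built as
random recursive trees plus density-driven extra edges (connected and
sparse, density well under 0.1), a G(n, p) PPI scaffold at p = 0.01, and a
bipartite GRN with 10% of genes as TFs at 1% density.  Everything is a pure
function of (spec, seed).  A spec whose expected edge count for a requested
nonzero layer is below one is rejected as infeasible.

Planting adds n coincident (signaling type S, GRN direction R) edge pairs
between the pathways' exclusive node sets (between mode) or through fresh
intermediary genes (shortest mode).  Planted endpoints are restricted to
genes private to the pair: an endpoint shared with a third pathway would
leak the signal into that pathway's between-subsets, and locality — all
other pairs' subsets unchanged — is part of the planting contract and is
tested.  Planted PPI edges propagate to every typed layer, mirroring the
layer-assembly rule, so a single planted (9, ±1) signal saturates n_sig
across layers; discrimination between competing pairs then rests on z̃,
which is why the score's z term matters.

What the generator does **not** emulate: empirical degree distributions
(hubs), the modular structure of real interactomes, correlated placement of
regulatory and signaling edges, or biological identifiers.  Passing the
power and calibration studies therefore shows that the statistical machinery
is correct and well-calibrated under the stated toy conditions, not that the
inferences on real KEGG/PPI/GRN data are biologically validated.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline at the
default conditions — 200 genes, 5 pathways, N_rand = 100 null draws, Q = 10,
20 seeded replicates for the power and calibration studies — sizes chosen so
a complete run takes minutes on one CPU while the ensembles remain large
enough for stable tail estimates at the 0.05 level.  Other choices: the
ensemble σ is the population standard deviation; empirical p-values are raw
tail fractions; ranking ties anywhere are broken lexicographically by
pathway id for determinism; allocation hashes use CRC32 for stability across
platforms and sessions.

## Known limitations

- The ±1 sign trick cannot represent reciprocal directed edges of one type;
  they are stored as undirected, losing the two-arc distinction.
- One shortest path is taken per node pair; equally short alternative paths
  that avoid pathway members are not searched, so a path discarded for
  touching A∪B may hide a valid alternative (the discard-then-filter order
  is intrinsic to the subset definition).
- n_sig is highly dependent across types because PPI edges live in every
  typed layer; it should be read as a saturating evidence indicator, not as
  22 independent discoveries.
- The empirical p resolution is 1/N_rand; at N_rand = 100 nothing between 0
  and 0.01 is representable, and p = 0 only means "beyond the ensemble".
- The χ baseline's default statistic is a path count, not the published χ
  formula; conclusions about that baseline transfer only to the supplied
  plug-in.
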