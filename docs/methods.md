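# Methods

This note documents the models, conventions and numerical choices behind
`proximap`, in the order the pipeline applies them, together with what the
synthetic data do and do not emulate.

## The relationship graph and the jump metric

A condition map is an undirected simple graph over protein accessions.
Edges carry a nonempty set of relation types — `interactome` (physical
interaction), `metabolome` (shared substrates/products/cofactors of
reactions), `signaling_other` (signaling, homology, miscellaneous curated
links) — plus a free-text provenance tag. Ingest rules, applied uniformly
by every reader and constructor:

- self-loops are dropped with a logged warning (they cannot affect any
  shortest path);
- parallel records for the same unordered pair are merged, taking the
  union of their type sets;
- every edge endpoint is materialised as a node; node ids are
  case-preserved, nonempty, unique.

All distances are **jumps**: unweighted shortest-path edge counts.
Although some source databases are directional, distances are computed on
the undirected view: the set-to-set statistics below symmetrise over both
directions anyway, and physical interactions have no natural orientation.
Relation types never weight a jump — no principled type weighting exists
for mixed interaction/metabolic/signaling edges, so each edge counts 1.

Analyses that need a connected metric space (set distances, nulls, the
embedding) restrict to the largest connected component first; equal-size
ties are broken toward the component containing the lexicographically
smallest node id, so the choice is deterministic. Proteins outside the
component are *dropped and counted* (`n_dropped`, `component_note`), never
assigned an infinite or penalty distance — an unreachable protein simply
has no defined jump distance, and inventing one would let the penalty
constant dominate the statistic.

## Map construction

`build_map(seeds, store, depth)` returns the induced subgraph of the
universe on all proteins within `depth` jumps of any seed — *induced*
meaning every universe edge between included proteins is kept, not just a
BFS tree, since the local wiring density is exactly what the downstream
statistics measure. Seeds missing from the universe are retained as
isolated, flagged nodes so presence statistics against the original seed
list stay well-defined. `depth` defaults to 1; real curated universes are
dense enough that one expansion step grows a few hundred seeds by roughly
an order of magnitude, and `expansion_profile` tabulates node/edge counts
per depth so users can calibrate the radius to their universe rather than
trust a fixed constant.

## Presence

`presence(effectors, map)` = |effectors ∩ map| / |effectors|, reported as
an **integer floor percent**: `pct = floor(100·k/n)`. Floor, not
round-half: presence is a containment claim, and quoting 19/52 as 37%
would overstate it. Motive-level presence is the same operation applied to
the motive's effector subset.

## Set-to-set distance (modified Hausdorff)

For sets A, B (after component restriction) each protein contributes its
*directed minimum*: the jump count to the nearest member of the opposite
set. Reported fields:

- `pooled_mean` — mean of all |A|+|B| directed minima; the default
  headline statistic (one pool, so larger sets carry more weight);
- `mean_of_means` — (mean over A + mean over B)/2; equal set weighting;
- `min_pairwise` — smallest directed minimum (an integer);
- `hausdorff_max` — the classical max-min Hausdorff distance, carried as
  a diagnostic only: a single peripheral protein dominates it, which is
  the opposite of what a set-level proximity question wants;
- `forward_mean` / `reverse_mean`, `n_a`, `n_b`, `n_dropped`.

Both averaging conventions are always computed because the pooled and
equal-weight readings are both defensible; every report labels which one
it used. Implementation: one multi-source BFS per set gives every node's
distance to that set, so a pair costs two BFS traversals and the all-pairs
sweep over k conditions costs k traversals, not k².

## Nulls and percentiles

Two empirical references are provided, and they answer different
questions:

- **All-pairs null** (`null_distribution`): the statistic over all
  C(k, 2) unordered pairs of usable conditions (those with ≥ 1 in-map
  effector; others are skipped with a warning). This is the reference for
  "how close are two conditions, as condition pairs go".
- **Anchored null** (`anchored_null`): the distances from one fixed
  anchor set (a seed list, a pathway) to every condition. This is the
  calibrated reference for "how close is *this particular* set to
  condition X": when every comparison shares an anchor, the conditional
  distribution of distance-to-that-anchor differs from the all-pairs
  mixture — empirically, random conditions' percentiles against the
  all-pairs null are visibly non-uniform (the anchor's own centrality
  shifts them all), while against the anchored reference they are uniform
  by construction. The planted-signal recovery test asserts significance
  under *both* references; the anchored one is the statistically clean
  claim.

`percentile_of(null, d)` is the ECDF with the closed comparison
P(value ≤ d). A normal fit to the null's (mean, sd — sample moments,
ddof = 1) is reported alongside for descriptive comparison only; nothing
downstream depends on normality. Distances measured between a seed set and
conditions should be computed on the universe graph, not on the
seed-expanded map, when the question is "is this condition unusually
close": a depth-d map puts *every* node within d jumps of a seed and so
biases all distances-to-seeds low by construction.

## 2D projection

`geodesic_mds` computes all-pairs jump distances on the largest component
(sparse Dijkstra with unit weights) and applies classical (Torgerson) MDS:
double-centre the squared distance matrix, take the top-2 eigenpairs,
scale eigenvectors by √λ (negative eigenvalues clipped to 0). Classical
MDS was chosen over stress majorisation because it is deterministic and
has no initialisation; the remaining per-axis sign ambiguity is fixed by
flipping each axis, if needed, so the lexicographically smallest embedded
id has nonnegative coordinates. Embeddings are therefore bit-reproducible.
Coordinates are centred at the origin; the `stress` diagnostic is the
normalised residual √(Σ(d_emb − d_geo)²/Σd_geo²) over all embedded pairs.
A metric-SMACOF variant (scikit-learn, fixed seed) and a landmark/Nyström
approximation (`n_landmarks`, for maps too large for a dense matrix) exist
behind flags and are documented as approximations. `distance_preservation`
reports the Spearman correlation between jump and embedded Euclidean
distance over sampled pairs; embedded distances are rounded to 9 decimals
before ranking so that pair ties present in exact arithmetic (e.g. equal
geodesics on a path) are not broken by eigensolver noise.

## Density grids and peak regions

`density_grid` rasterises an embedded subset in one of two modes:

- `count`: each protein falls in exactly one half-open cell (the closing
  edges of the final cells are closed so boundary points are binned);
  values are proteins per cell and sum exactly to the subset size;
- `kde`: an isotropic Gaussian kernel evaluated at cell centres,
  normalised as a probability density (integrates to ≈ 1 when the extent
  pads the data by ≥ 3 bandwidths). Bandwidth defaults to Scott's rule
  for two dimensions, h = n^(−1/6)·√((var_x+var_y)/2). Points are summed
  in coordinate order, not id order, so grids are invariant to protein
  relabeling at the bit level.

Grids default to the *full* embedding's bounding box padded 5%, whatever
the subset, so background and overlay grids share coordinates cell for
cell (`cluster_overlay` returns both on the common extent). Default
resolution is 256×256; both choices are recorded in grid metadata.
`peak_regions` thresholds at a quantile of the positive cell values and
returns 4-connected components, sorted by contained mass, ties by top-left
cell index. Rendering is a thin optional matplotlib layer; all analysis
operates on the numeric grids.

## Protein-level links

`direct_links` enumerates every map edge with one endpoint among the
effectors and the other among the seeds; a protein belonging to both sets
participates from either side, and an edge whose two endpoints are each in
both sets is recorded once, oriented with the smaller id as the effector.
`k_jump_links` generalises to effector–seed pairs within k jumps
(self-pairs at distance 0 are excluded — a relationship needs at least one
jump), with k defaulting to 2 and always reported, since "relationship
count" is meaningless without its radius. `motive_breakdown` splits direct
links by the motive of the effector involved; an effector in several
motives counts once per motive and is flagged, and percentages are floors
of 100·count/n_direct for consistency with presence.

## Synthetic data: what it emulates, and what it does not

The generators stand in for two resources that cannot be redistributed: a
curated protein-relationship universe and a condition database with
effector annotations.

- **Universe**: Barabási–Albert preferential attachment (default), because
  curated interactomes have heavy-tailed degree distributions; an
  Erdős–Rényi variant exists for tests whose oracles are simpler there.
  Edge types are i.i.d. draws from a configurable mix
  (0.5/0.3/0.2 interactome/metabolome/signaling_other by default).
- **Seeds**: a uniform draw of protein ids (real seed lists are
  pathway-correlated; uniformity is the conservative neutral choice for
  testing the machinery).
- **Conditions**: effector sets drawn uniformly without replacement, sizes
  uniform on a configurable range (default 20–60, i.e. tens of proteins),
  split round-robin over 1–3 motives; ~160 conditions by default. The
  optional **planted** condition draws its effectors from the seeds'
  one-jump neighbourhood (preferring strict neighbours over seeds
  themselves, so the presence and distance signals stay distinguishable);
  infeasible plantings fail loudly with the shortfall.
- **Scales**: `small` (300-protein universe, 25 seeds, 20 conditions) for
  fast tests; `paper_like` (16,000 proteins, attachment 5, 447 seeds, 161
  conditions, effector sizes 20–60), calibrated once so that a depth-1
  build yields a map of roughly 3,000–4,000 proteins — the size regime
  the workflow is meant for.

Everything is bit-reproducible from (spec, seed). What the synthetic data
do **not** reproduce: the biology. Real universes have correlated,
pathway-structured edges, type-dependent topology, annotation biases and
false negatives; real condition databases have overlapping, curated
effector sets of very uneven quality. Passing tests therefore demonstrate
that the *machinery* is correct and calibrated (oracle-exact distances,
valid ECDFs, recoverable planted signals, conserved density mass,
deterministic runs) — not that any particular biological conclusion drawn
from real data is right.

## Pipeline and determinism

`run_analysis` chains build → presence → distance/null → embed → density →
links from one YAML config in which every under-determined choice (depth,
statistic, k, MDS variant, grid resolution/bandwidth/mode) is explicit.
Each stage writes its artifact and downstream stages re-read from disk, so
any stage can be rerun in isolation. Floats are serialised via `repr`
(shortest round-trip form) and grids via a fixed `%.17g` format; manifests
contain no timestamps; consequently two runs on the same inputs are
byte-identical, which the test suite asserts at paper-like scale.

## Known limitations

- No edge confidence scores or weighted shortest paths; all edges count 1
  jump regardless of evidence strength.
- Directionality of signaling edges is preserved as metadata but unused.
- The classical-MDS projection of a small-world graph is necessarily
  lossy (stress ~0.7 at paper-like scale); it is a visualisation aid, and
  all significance statements are made on the graph metric, never on the
  2D projection.
- Degree-preserving randomisation nulls (z-score-style proximity) are out
  of scope; the implemented nulls are the all-pairs and anchored
  empirical distributions described above.
- The KDE integral check holds only when the grid extent pads the data
  adequately; with the default 5% padding, mass outside the grid is
  simply not represented.
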