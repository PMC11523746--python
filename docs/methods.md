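# Methods

## The detection problem

A square-grid arrangement is a subnetwork that tiles into 4-cycles the way
a rectangular lattice does. The minimal unit is the cycle graph C₄; a
lattice-like structure repeats it. The detector does not search for
subgraph isomorphisms — populations of neurons at lattice vertices and
missing links make the idealized pattern rare — but for *metric
signatures*: neighborhoods whose topology is statistically lattice-like.
The search is deliberately non-conservative (inclusive band endpoints,
permissive thresholds) and relies on a contiguity requirement — flagged
windows must overlap — to separate structure from isolated coincidence.

## Graph model

Networks are undirected simple graphs over opaque string node IDs.
Connectome records (directed synapses, possibly repeated, possibly
self-referential, possibly weighted) are collapsed: direction, weights,
duplicates and self-loops are dropped, with counts logged. All five
metrics are defined on undirected simple graphs, so nothing downstream
can consume the discarded detail. The unit of analysis is the connected
component; path-based quantities are computed on the largest component.

## Metrics

* **Transitivity** `T = 3·#triangles / #triads`, with `T = 0` when there
  are no triads. The zero convention matters: a square lattice must pass
  the `T ≤ 0.20` filter exactly, not vacuously fail on 0/0.
* **Square clustering** (Lind et al.): for node v and each neighbor pair
  (u, w), `q` counts common neighbors of u and w other than v (realized
  squares), and the denominator adds the squares u and w could still form
  given their remaining degree. `C₄(v) = Σq / Σ(q + a)`, 0 when the
  denominator vanishes. Graph-level value = unweighted node mean.
* **Spectral bipartivity** `b_s = Σ cosh λⱼ / Σ exp λⱼ` over adjacency
  eigenvalues: the even-closed-walk fraction of total closed-walk weight.
  Computed by dense symmetric eigendecomposition (`eigvalsh`), which is
  comfortable at the scales analyzed here (windows and components well
  below ~10³ nodes). The ratio is evaluated in log space
  (`logsumexp`) so large spectral radii cannot overflow, and clamped at
  1.0: `b_s ≤ 1` holds by theory, and without the clamp eigensolver
  rounding (≈1 + 2·10⁻¹⁶) would push bipartite windows off the inclusive
  band endpoint.
* **Average shortest path length**: BFS all-pairs mean over unordered
  pairs. Disconnected input is an error instructing the caller to pass a
  component — silently averaging within components would silently change
  sigma.
* **Sigma** `σ = (C/C_rand)/(L/L_rand)` with `C` the mean local triangle
  clustering and `L` the mean path length; `C_rand`, `L_rand` are means
  over `n_rand = 10` degree-preserving references with `5·|E|` accepted
  double-edge swaps each. Conventions:
  - `σ ≡ 0` when `C = 0`. For triangle-free graphs the ratio is a 0/0
    form (references are typically triangle-free too); pinning σ to 0
    makes the metric a clean lattice-exclusion filter and matches the
    calibration value of 0.0 for square grids of every size.
  - A complete graph admits no legal swap, so references equal the input
    and `σ = 1` exactly.
  - If every reference loses every triangle while the graph has some,
    `σ = +∞` (an unbounded clustering excess), which fails any finite
    band.
  - σ is undefined (None) for graphs of fewer than 4 nodes.

## Randomization

References use Maslov–Sneppen double-edge swaps: pick edges (a,b), (c,d),
rewire to (a,d), (c,b); reject swaps creating self-loops or parallel
edges. The degree sequence is preserved exactly. Connectivity is *not*
checked per swap — profiling showed the per-swap BFS dominating the whole
calibration sweep by an order of magnitude — and is instead enforced by
resampling: sigma draws up to 10× the needed references from derived
seeds and discards disconnected ones. For the dense small graphs swept
here, disconnection is rare, so resampling almost never triggers.

All randomness flows from one user seed through `numpy` `SeedSequence`
derivation: generator seeds, per-reference seeds, and per-window sigma
seeds (keyed by the window center's rank in sorted node order, so results
are independent of node insertion order). Same seed → byte-identical
outputs.

## Calibration sweep

Six model families, metrics computed per graph, ranges pooled per family:

| family | grid | why it is in the sweep |
|---|---|---|
| square lattice | n×n, n = 3…9 (9–81 nodes) | the target pattern |
| triangular lattice | equal sides 3…9 (10–55 nodes) | the confusable grid |
| complete | every n in 9…27 | maximal density control |
| Erdős–Rényi | n ∈ {9, 18, 27}, p ∈ {0.4, 0.5} | unstructured control |
| Barabási–Albert | n ∈ {9, 18, 27}, M ∈ 3…6 | hub-dominated control |
| Watts–Strogatz | n ∈ {9, 18, 27}, k ∈ {4, 6}, p ∈ {0.1, 0.5} | small-world control |

Design choices where the design was genuinely open:

- **Lattice dimensions.** Square lattices are swept as perfect squares
  3×3…9×9. Triangular lattices use the equal-side family of the standard
  triangular row lattice, sides 3…9; the dimensions are a config list
  (`TRIANGULAR_LATTICE_DIMS`), and the equal-side choice is the natural
  analogue of the square sweep.
- **Replicates.** Stochastic cells run 20 derived seeds each; (min, max)
  pools replicates and cells. Three sizes {9, 18, 27} span the non-grid
  size band; deterministic families are swept at every size since they
  cost nothing.
- **Small-world k.** The ring construction joins k/2 neighbors per side,
  so k must be even; the sweep uses {4, 6} and the generator rejects odd
  k outright rather than rounding.
- **ER connectivity.** Low-p random graphs may be disconnected; they are
  kept and measured on their largest component, which is why the random
  row's node range can dip below 9.

`derive_criteria` turns the sweep into a validated band set: it returns
transitivity [0, 0.20], bipartivity [0.80, 1.0], sigma [0, 0.50], minimum
component 36 nodes — and raises unless the square-grid row passes every
band while the complete and triangular rows each fail at least one.

The triangular row's clustering range measures 0.13–0.20 and its sigma
range is broad (≈1.3–4.9 across seeds): a triangle-rich lattice looks
small-world to sigma, which is exactly why sigma works as an exclusion
band.

## The sliding-window scan

A window is the closed 2-hop neighborhood of a node: the node, its
neighbors, and their neighbors. Its induced subgraph is connected by
construction. Every node of the accepted component seeds one window.
A window is flagged when all three bands admit it **and** it has at least
`min_window_nodes = 4` nodes — a window smaller than C₄ cannot contain a
square, and windows below 4 nodes have no sigma at all (unflaggable, not
an error).

Flagged windows sharing ≥ 1 node are chained into clusters (connected
components of the overlap relation). Sharing one node is the weakest
contiguity notion and therefore consistent with the non-conservative
design; it is a formalization choice — "overlap" admits stricter
definitions (shared edges, minimum Jaccard) that would trade recall for
precision. Single flagged windows are reported separately as weak
evidence and do not enter the score. The component's square-grid-ness
score is |∪ cluster node sets| / |component nodes|, displayed as a whole
percentage.

The 36-node component floor is a practical sample-size cutoff below which
the metric suite is unreliable; it applies to components, not windows
(flagged windows with fewer than 20 nodes are normal and expected).

## Planted-lattice benchmark

`gridscan.benchmark` plants a 5×5 square lattice in an ER(40, 0.15)
background with 2 bridge edges and scans the hybrid; per trial it reports
**recovery** (planted nodes inside the recovered union) and
**contamination** (background nodes swept in). Across 20 derived seeds,
recovery is complete (every trial recovers 100% of planted nodes), while
contamination is bimodal: most trials sweep in ~5% of the background, but
a substantial minority exceed 20%, because sparse near-bipartite ER
neighborhoods (T ≈ 0.05–0.1, b_s ≈ 0.8–0.93, σ ≈ 0.2–0.5) genuinely
satisfy the bands and their 2-hop windows are large. Cross-checking those
windows against networkx's independent small-world sigma confirms the
values; the contamination is the method's real false-positive behavior
under its non-conservative bands, not an artifact of this implementation.

What the synthetic benchmark does *not* emulate about real connectome
data: heavy-tailed degree distributions, spatial correlation of
connectivity, neuron populations at lattice vertices, and annotation
noise. Passing it shows the pipeline recovers an idealized planted
pattern and bounds its behavior on a generic background — not that
region-level scores on a real connectome are unbiased.

## Degenerate inputs and tie-breaks

- Empty graph: components → empty list; metrics that average over nodes
  raise.
- Component ties in size break by smallest member ID, so reports are
  deterministic.
- Equal-size clusters order by largest node union, then lexicographic
  first window center.
- Band membership is inclusive at both endpoints everywhere.

## Known limitations

- Sigma is noisy at `n_rand = 10`; windows near the σ = 0.5 boundary can
  flip between seeds. The per-window seeds make any single report exactly
  reproducible, but borderline flags should be read as borderline.
- Full eigendecomposition makes bipartivity O(n³) per window; fine at
  connectome-region scale, not intended for 10⁵-node components.
- The scan flags *metric* lattice-likeness; it never verifies an actual
  grid embedding. GraphML export exists so a human can inspect flagged
  regions.
- Only square-grid detection is implemented; triangular or hexagonal
  modes would need different bands and a different clustering metric.
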