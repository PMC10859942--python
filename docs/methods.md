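# Methods

## Model and procedure

`looa` treats an aggregate interactome as a simple undirected graph:
proteins are vertices, crosslink-detected interactions are edges. Direction
is discarded (a crosslink is symmetric), self-loops (intra-protein
crosslinks) are dropped, and reciprocal/duplicate rows are collapsed so a
pair of proteins contributes one interaction to the degree count.

Influence is defined operationally: remove one element, recompute the
graph-level profile of five network properties, and take the difference
ΔNP = NP_initial − NP_after. LOVO iterates over vertices (the removed
vertex takes its incident edges with it), LOEO over edges (the vertex set
is unchanged). Both scans recompute profiles exactly rather than
incrementally: at the intended scale (≤ ~5k vertices / ~50k edges) the
O(|elements| · V·E) cost of exact Brandes-style recomputation is minutes,
and exactness removes a whole class of update-maintenance bugs. Deltas are
reported as raw differences; `influence_ratio` (CLI `--ratio`) optionally
rescales each column by the initial profile to read influence as a
fractional reduction, but the difference form is the primary definition.

## The five network properties

* **DC (degree aggregate).** Default mode `sum`: Σ deg(v) = 2|E|, the
  network's total complexity. Under LOVO the delta is exactly 2·deg(v);
  under LOEO it is exactly 2 for every edge, i.e. constant — which is why a
  `centralization` mode (Freeman degree centralization,
  Σ(deg_max − deg(v)) / ((n−1)(n−2))) exists as a variance-bearing
  alternative. Default stays `sum`, the literal total-complexity reading.
* **EC.** Dominant eigenvector of the adjacency matrix, computed by power
  iteration on A + I (the +I shift has the same eigenvectors but converges
  on bipartite components) from a uniform positive start, tolerance 1e-10,
  cap 1000 iterations. Each connected component is solved and max-scaled
  independently: a whole-graph iteration on a disconnected graph puts all
  mass on one component and zeroes the rest, which would make knockout
  deltas jump discontinuously the moment a removal splits the graph.
  Single-vertex components have no interactions and score 0.
* **BC.** Shortest-path betweenness (each unordered pair counted once,
  equal-length paths splitting credit equally), normalized by (n−1)(n−2)/2;
  identically 0 for n < 3.
* **CC.** Harmonic closeness, (1/(n−1)) Σ 1/d(v,u) with 1/∞ = 0. The
  harmonic form is used precisely because knockout intermediates are often
  disconnected; classic closeness would be undefined there.
* **GCC.** Transitivity: 3 × triangles / connected triplets, defined as 0
  when no connected triplet exists.

Graph-level aggregation: DC per its mode; EC/BC/CC as arithmetic means over
all surviving vertices (the least surprising scalar that stays comparable
as n changes by one); GCC is already graph-level. Note one consequence:
LOVO ΔCC can be negative, because deleting a peripheral vertex shrinks the
averaging set and can raise the survivors' mean even though every
individual closeness is monotone under deletion. LOEO ΔCC is provably
non-negative (fixed vertex set), and the tests assert exactly that split.

BC, CC and GCC are evaluated through igraph's C routines for speed inside
the knockout loops; the test suite checks them against hand-rolled
exhaustive oracles (explicit shortest-path enumeration, BFS distance maps,
neighbour-pair triplet counting) and dense eigendecomposition on hundreds
of small graphs. EC is implemented directly because the per-component
max-scaling convention above is not a library default.

## Scoring

The delta matrix is column-standardized (mean 0, sd 1, ddof = 1) and the
Pearson correlation matrix eigendecomposed — correlation PCA, not
covariance PCA, because Kaiser's eigenvalue ≥ 1 rule presumes unit-variance
variables and the delta columns live on incommensurate scales (edge counts
vs quantities in [0, 1]). Constant columns are dropped first with a
warning; %variance uses the post-drop column count as denominator so the
scree always totals 100. Eigenvalues are clipped at 0 to absorb −1e-16
round-off from the symmetric eigensolver.

Component signs are arbitrary in any PCA, so they are anchored to a delta
whose sign is known by construction: the loading on dDC is made
non-negative; if dDC was dropped (LOEO in sum mode) the anchor falls back
to dCC — the only other delta that cannot be negative under deletion — and
only then to the largest-magnitude loading. Anchoring to a sign-guaranteed
axis keeps "higher composite = removal costs the network more" true even
when the dominant loading happens to sit on a descriptor (like EC) whose
delta runs opposite to disruption.

Selection keeps the leading components satisfying eigenvalue ≥ 1 OR
variance ≥ 10% (both thresholds user-tunable); since eigenvalues are
sorted, the kept set is a prefix. At least one component is always kept —
an empty selection would silently rank everything equal. The composite
score is the eigenvalue-weighted sum of the selected component scores
(weights normalized to 1), which collapses to PC1 exactly when one
component is selected. Ranks are 1-based positions after sorting by
descending score with lexicographic identifier tie-break.

Degenerate inputs degrade explicitly rather than failing: with exactly one
non-constant column the composite score is that column's z-score; with none
(e.g. LOVO on a clique, where symmetry makes every row identical) all
elements tie at 0 and the ranking is identifier order. `fit_pca` itself
still refuses < 2 usable columns; the graceful path lives in the
`score_influence` pipeline the CLI uses.

Cos² (squared variable coordinate, loading² = eigenvalue · eigenvector
entry²) quantifies how well each delta column is represented by each
component; rows sum to 1 over all components.

## Synthetic interactomes

No aggregate interactome ships with the package, so `fixtures` generates
networks that emulate one topologically: growth by preferential attachment
(each arriving vertex attaches to m = 3 existing vertices with probability
∝ (deg+1)^α; the +1 smoothing lets the earliest vertices be chosen; default
α = 1), followed by hub planting (chosen vertices receive random edges
until their degree hits a target drawn from the requested band — planting
after growth makes hub degree directly controllable, matching the
mega/major/midi/mini degree-bin framing), followed by uniform noise edges.
Everything is a deterministic function of the spec including its seed.

The reference study conditions used by tests and the acceptance script are
n = 200 proteins, 10 planted hubs in the major band (50–99 interactions),
α = 1, 100 noise edges — large enough for a real hub hierarchy (the census
also contains organic midi- and mini-hubs), small enough that a full
LOVO + LOEO run takes seconds per graph. What passing these tests shows is
that the pipeline recovers *topologically planted* anchors; real
crosslinking data additionally carries detection noise, abundance bias and
false-positive interactions that the generator deliberately does not model,
so recovery rates here are an upper bound on biological performance.

## Numerical choices and edge cases

* Power iteration: tol 1e-10 on the max-scaled sup-norm change, max 1000
  iterations, error (never a silent partial result) on non-convergence.
* Constant-column detection: sample sd ≤ 1e-12 × max(1, mean |column|);
  exact-arithmetic constants (the LOEO dDC column) are caught exactly,
  near-machine-noise columns are treated as constant rather than being
  standardized into amplified noise.
* Ties: all orderings (delta rows, rankings, serialized edge lists) are
  lexicographic in element identifiers, so outputs are byte-reproducible.
* Graphs below the minimum size for an analysis (3 vertices for LOVO,
  2 edges for LOEO, 3 rows for any PCA) raise typed errors; the CLI maps
  them to non-zero exits and removes partial outputs.

## Limitations

* Influence is purely structural; no edge weights, abundances or confidence
  scores are used (the input format carries none).
* Single-element knockouts only; synergistic pair/group effects are out of
  scope.
* The graph-level collapse of per-vertex centralities (arithmetic mean) is
  one defensible choice among several (sum, max); rankings can differ under
  another collapse.
* Composite scores are in standardized-PC units: comparable within one run,
  not across datasets — only ranks travel.
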