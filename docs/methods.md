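# Methods

## Morphological similarity networks

A subject's network has one node per cortical parcel and edge weights that
quantify how similar two parcels' *distributions* of vertex-wise cortical
thickness are. For a pair of parcels the two thickness vectors are binned
into 30 equal-width bins spanning the pooled min–max of the pair; the edge
weight is the absolute Pearson correlation of the two 30-bin frequency
vectors. Conventions, and why:

- **Shared bin support per pair.** The bin-wise correlation only compares
  like with like if both histograms use the same edges; the pooled range is
  the smallest support containing both samples. A corollary (tested): adding
  a constant to both parcels of a pair shifts the edges but not the
  similarity.
- **Counts, not proportions.** Pearson correlation is invariant to
  rescaling either frequency vector, so the choice is immaterial; counts
  keep the conservation property Σfreq = vertex count.
- **Absolute value after correlation.** Negative correlations (anti-phase
  distribution curves) are a small minority in this kind of data and enter
  by magnitude; the fraction of negative raw correlations is logged per
  subject. |r| is taken on the signed frequency correlation, never on the
  inputs.
- **Diagonal fixed at 0.** Self-similarity carries no information and
  self-loops are excluded from all topology.
- **Degenerate pairs** (zero pooled range, or a zero-variance frequency
  vector) get similarity 0 with a warning — a flat histogram carries no
  shape information. More than 10 % degenerate pairs aborts the subject as a
  data pathology.

Parcels with fewer than 50 vertices are excluded up front (strictly
less-than: a 50-vertex parcel survives). The bundled atlas table lists the
32 Yeo-7 parcels that survive this filter, with their vertex counts; its row
order is the canonical node order everywhere.

## OMST sparsification

Similarity matrices are dense; topology is computed on a sparse binary
graph chosen threshold-free by orthogonal minimal spanning trees:

1. Map weights to distances, d = 1/w (absent where w = 0). The reciprocal
   transform is the common choice in the OMST literature; 1 − w is available
   behind a flag for sensitivity analysis.
2. Extract successive minimum spanning trees, each round excluding all
   previously selected edges (rounds are therefore pairwise edge-disjoint;
   if exclusion disconnects the graph a round is a minimum spanning forest).
   Kruskal construction with a lexicographic (distance, i, j) tie-break
   makes the decomposition fully deterministic, even under exact ties.
3. After each round, evaluate the cumulative selection's global cost
   efficiency: GCE = E_glob(weighted selected subgraph, shortest paths on
   the transformed distances, efficiency = mean reciprocal shortest
   distance) − cost, where cost is the selected fraction of total edge
   weight. Keep the aggregation with maximal GCE (first maximum on ties).
4. Binarize the selected edges. The first tree guarantees the result is
   connected with between N−1 and m·(N−1) edges for m selected rounds.

The GCE efficiency term is computed on the *weighted* selected subgraph
(the original formulation); only the final selection is binarized. Round
extraction defaults to at most N−1 rounds with an early stop after the GCE
curve declines for 3 consecutive rounds — in practice the maximum sits at
2–3 rounds (graph density ~10–20 %) and the early stop never moves it; the
exhaustive-prefix acceptance test disables the early stop entirely.

## Topology

Seven measures on the binary network. Numerical conventions:

- Unreachable ordered pairs contribute 0 to efficiency sums (1/∞ = 0).
- E_glob = mean over ordered pairs of 1/L_ij; E_nodal(i) the same restricted
  to pairs from i; E_local(i) = E_glob of the subgraph induced by i's
  neighbours, defined as 0 when i has fewer than two neighbours.
  E_glob equals the node average of E_nodal (asserted as an invariant).
- Betweenness sums σ_kj(i)/σ_kj over *ordered* pairs k ≠ j, both ≠ i, with
  no halving and no normalisation — the centre of a 3-path scores 2, twice
  the networkx unordered convention (tested against it explicitly).
  Shortest-path counts come from a level-synchronous BFS recursion.
- Eigenvector centrality is the leading eigenvector of the adjacency
  (dense symmetric eigendecomposition), unit Euclidean norm, Perron
  (nonnegative) orientation; the defining residual must be below 1e−10.
- Pagerank solves r = (1−d)·1 + d·A·D⁻¹·r as a dense linear system
  (N = 32; no power iteration needed), d = 0.85; r sums to N and equals 1
  on every regular graph; residual below 1e−12 is enforced.

Every measure is checked against naive brute-force reimplementations
(triple-loop Floyd–Warshall, explicit shortest-path enumeration, full
eigendecomposition, fixed-point iteration) on *every* connected graph with
up to 7 nodes (the complete graph atlas, 995 graphs) and 200 random 8-node
graphs, to 1e−9.

## Behavior scoring

The MHC-SF has 14 items on a 6-point frequency scale. Numeric coding is
0–5 ("never" = 0), which yields the conventional subscale maxima — 15
(emotional, 3 items), 25 (social, 5 items), 30 (psychological, 6 items),
70 total; instruments coded 1–6 are rescored via `item_offset=1`. The
item→subscale map defaults to the standard ordering (1–3 emotional, 4–8
social, 9–14 psychological) and is configurable, since translations vary.
Cronbach's α uses the sample (n−1) variance convention. Missing or
out-of-range items are errors, never imputed.

## GLM association

For each parcel, node metric and well-being dimension, ordinary least
squares of the score on age, sex (0/1), education, intracranial volume,
mean cortical thickness (vertex-weighted mean over reserved parcels, a
parcel-weighted variant behind a flag) and the metric, plus intercept.
The effect size is the partial correlation of metric and outcome given the
covariates, recovered from the t statistic: r = sign(t)·√(t²/(t²+df)),
df = n − 7; the identity r²(t²+df) = t² is asserted on every fit. A
zero-order correlation is available behind a flag. Covariates are left
unstandardized (OLS inference is invariant to affine rescaling).

Families for Benjamini–Hochberg FDR (q < 0.05) are the 32 parcels within
one (metric × dimension) combination; pooling across metrics is available
behind a flag. Global efficiency, one value per subject, is tested per
dimension without the parcel loop and without FDR. For any (parcel, metric)
significant on the total score, the per-dimension effect sizes are the
partial correlations of the three component dimensions at that same parcel
and metric.

The family loop is vectorised with the Frisch–Waugh–Lovell decomposition
(residualize outcome and metrics on the covariates once per family), which
is algebraically identical to the full fit and is tested against the
single-fit path. A metric column with no residual variance (constant, or
collinear with covariates) carries no evidence and is reported as r = 0,
p = 1 — conservative by construction.

## Synthetic cohorts

The generator emulates the analysis inputs at the vertex level; it does not
simulate images, surfaces or preprocessing.

- **Thickness.** Each parcel draws its vertices from a balanced
  two-component Gaussian location mixture around a 2.5 mm baseline
  (components ±sep/2, spread ≈ 0.3 mm) — values squarely in the plausible
  2–4 mm cortical range. Background parcels get subject-stable shape
  parameters (mean jitter sd 0.06 mm, spread multiplier 0.85–1.15,
  separation ≤ 0.12 mm) plus a small per-subject jitter (0.02 mm). These
  defaults keep the cohort's similarity matrices dense and heterogeneous
  enough that the GCE optimum sits at ≥ 2 OMST rounds for almost all
  subjects, matching the density regime the topology stage expects. No
  distributional facts about vertex-level thickness are available for this
  design, so these are conventional choices, not data-derived ones.
- **Covariates.** Age (37.3 ± 13.1 y), education (15.4 ± 3.2 y) and ICV
  (1.45 ± 0.15 × 10⁶ mm³) from correlated normals (target age–education
  correlation −0.401); sex an independent Bernoulli draw. Negative SDs are
  rejected; zero SDs legitimately produce constant columns.
- **Items.** A standard-normal latent well-being factor plus per-item noise
  (sd 1.0) is thresholded at five equally spaced ordered cut points
  (centre −1.1, spacing 0.75 on the latent scale), chosen so the default
  cohort's totals land near the upper-middle of the 0–70 range
  (mean ≈ 52, sd ≈ 14, α ≈ 0.93) — the right-skewed profile typical of
  healthy-community well-being data.
- **Planted effect.** One effect parcel, its neighbour set (default: the
  parcels sharing its hemisphere and Yeo network), and two "gate" anchor
  parcels (default: the two largest background parcels). The cluster is
  strongly bimodal (separation 0.8 mm, component sd 0.15 mm) at the shared
  baseline; the gates are narrow unimodal distributions at the extreme peak
  positions (baseline ± 0.75 mm, sd 0.10 mm). The effect parcel's
  separation slides with the subject's latent factor between
  gate-aligned (low latent: its strongest similarities are the two mutually
  dissimilar gates, so its network neighbours are unconnected and local
  efficiency collapses) and cluster-aligned (high latent: a triangle-rich
  neighbourhood, local efficiency near 1). `effect_size` is the *target*
  partial correlation between the planted parcel's local efficiency and the
  total score; the internal latent-gain mapping is linear with a constant
  calibrated once by pilot simulation at the design's operating point
  (|r| = 0.4, n = 65: realized mean partial r 0.42, sd 0.10 across seeds).
  The mapping is approximate away from that operating point.
- **Randomness.** One global seed feeds a hierarchical `SeedSequence`
  stream per subject (covariates / behavior / thickness substreams), so
  identical configs are bitwise-reproducible and enlarging the cohort never
  changes already-generated subjects.

What the generator does *not* emulate: spatial vertex autocorrelation
within a parcel, scanner/site effects, age-related thinning gradients,
hemispheric asymmetries, or any real anatomical similarity structure
between specific parcel pairs. Passing tests therefore demonstrate that the
*pipeline machinery* is correct and calibrated under a faithful synthetic
regime — not that any particular real-data finding replicates.

## Monte-Carlo studies

- **Null calibration** (1000 replicates, n = 65). Under the null the
  networks are generated independently of behavior and covariates, so the
  study crosses 50 fully regenerated network cohorts with 20 fresh
  behavior/covariate draws each — conditional on the design this is
  distribution-identical for the metric-term test and fits desk-scale
  runtimes. Checks: Kolmogorov–Smirnov uniformity of the reference p-value
  on a continuous metric channel (eigenvector centrality), tail calibration
  P(p ≤ 0.05) on both the EC and Elocal channels, and the BH family
  false-positive rate ≤ q within a 99 % binomial margin. Local efficiency
  itself is a strongly discrete statistic on a ~2-round OMST graph, which
  makes its null p-value distribution slightly lumpy in the middle at
  1000-replicate KS resolution while its 0.05-tail and the family FPR stay
  correctly calibrated (≈ 0.045–0.05) — the quantities FDR control actually
  rests on.
- **Planted recovery** (100 seeds). With a planted Elocal effect of target
  partial r = 0.4 at one parcel, n = 65: the planted parcel is its family's
  top hit and FDR-significant in a majority of seeds, with the realized
  partial correlation near the target (the single-seed sampling sd of a
  partial correlation at n = 65 is ≈ 0.1, so individual seeds scatter
  around it).

## Problem sizes and runtimes

The study design itself is small (65 × 32, ~13.7k vertices per subject;
one full pipeline run takes ~2 s). The simulation studies use 1000 null
replicates and 100 recovery seeds; the exhaustive graph-oracle sweep covers
995 atlas graphs plus 200 random 8-node graphs. The full test suite runs in
roughly ten minutes on one CPU.

## Known limitations

- The OMST GCE selection can sit on a near-tie between m and m+1 rounds;
  which side wins is then decided by tiny weight differences. This is a
  property of the method, not of the implementation — it is why local
  efficiency on OMST graphs is a noisy per-subject statistic at n = 65.
- The reported "r" is the covariate-adjusted partial correlation; zero-order
  correlations can differ when covariates correlate with the metric.
- The binarized-network convention discards edge-weight information
  downstream of OMST by design; no weighted-metric variants are provided.
- `effect_size` calibration is anchored at |r| = 0.4 with the default
  32-parcel layout; other layouts or magnitudes may realize a somewhat
  different partial correlation.
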