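# Methods

## Model and procedure

The pipeline operates on a single pre-computed co-expression module: a
genes × subjects matrix of (log-intensity) expression values containing a
designated target gene. Subjects may first be filtered on metadata; the
quality rule keeps RNA integrity numbers strictly greater than the cutoff
(default 7.0) and, optionally, restricts to listed ancestry groups. Genes
constant across subjects are dropped (Pearson correlation is undefined for
them) with a warning.

Similarity is the absolute Pearson correlation of expression profiles,
`s_ij = |cor(x_i, x_j)|`, so positively and negatively co-regulated pairs
are treated alike; only the strength of the relationship matters. A hard
threshold `t` turns the weighted network into a simple graph (`edge iff
s_ij ≥ t`; ties at exactly `t` are edges; isolated nodes are retained so
per-node normalizations stay well defined). Scanning `t` over a grid
(default 0.30–0.60, step 0.01; the study-scale analyses shipped here use 0.05)
produces the threshold profiles everything else is built on.

### Topology

Degree, strength (weighted degree), Freeman betweenness (unordered pairs,
endpoints excluded, unnormalized), geodesic distances, diameter and
eccentricity. High thresholds disconnect the graph, so diameter and
eccentricity are taken over finite distances only and an isolated node has
eccentricity 0; without this convention the threshold profiles would be
dominated by infinities. Averages are over all nodes, isolated ones
included. The thresholds at which the three non-monotonic properties (mean
betweenness, diameter, mean eccentricity) peak bracket the **optimal
range**: below it the dense network carries mostly noise correlations,
above it too much information is lost. Degree decreases monotonically and
carries no peak information.

### Community detection

Four detectors, all delegated to igraph behind one deterministic contract:
fast greedy and Louvain (modularity optimization), walktrap (random-walk
similarity, dendrogram cut at maximum modularity, 4-step walks), infomap
(map equation, 10 trials, best kept). Louvain's result depends on node
order, so the wrapper runs 10 seeded restarts and keeps the
highest-modularity partition — the same "several trials, report best"
convention as infomap. The igraph RNG is re-seeded on every call, making
`detect_communities(graph, method, seed)` a pure function. Edgeless graphs
yield all-singleton partitions; isolated nodes are singleton communities.

A target community must have at least `min_size` genes (default 3 — fewer
is not a community) and at most a `max_size_frac` fraction of the network
(default one half — a "community" absorbing most of the network is a
detection failure, not a community; empirically the map equation returns
the whole connected graph as one module at dense thresholds). Scan cells
violating the band are flagged, not dropped, and flagged cells exclude
their threshold from the selection step below.

### Pivotal Module Index

`PMI = (k_tc · b_tc) / (D_tc · N_tc)`, with mean degree `k_tc` and mean
betweenness `b_tc` computed on the subgraph induced by the target
community (a `scope="global"` switch measures them in the whole thresholded
network instead; the induced form measures internal cohesion and is the
default), `D_tc` the induced diameter (per-component maximum when
disconnected; zero diameter, i.e. an edgeless induced subgraph, makes the
index undefined) and `N_tc` the community size. A clique community has
zero internal betweenness and hence PMI 0: the index rewards communities
that are dense *and* internally strategic, not saturated ones.

The **chosen threshold** is the argmax of the cross-method mean PMI over
thresholds where every method yields a valid community, restricted to the
optimal range from the topology scan (falling back to the whole grid if the
range holds no fully valid threshold); ties break toward the lower, more
inclusive threshold.

Error bands: subjects (columns) are resampled with replacement `n_boot`
times (default 1000); each replicate rebuilds the network, re-detects and
recomputes the PMI; the 25th–75th percentile range of the replicate
distribution is the statistical error. Replicates whose community falls
outside the size band contribute nothing.

Trend test: the per-threshold cross-method mean PMI, weighted by the
bootstrap half-band (cross-method spread when no bands exist), is fit with
a straight line (weighted least squares via statsmodels); the reduced χ²
is reported and a threshold is flagged as an excess when its PMI lies above
the upper 95% confidence band of the fit and more than 1.96 of its own
errors above the fitted value.

### Betweenness entropy

The betweenness vector is rescaled to a probability mass
`p_i = b_i / Σ b` before applying Shannon's formula
`H = −Σ p_i log2 p_i`, and `H` is divided by the node count so networks
and communities of different sizes are comparable. Feeding raw betweenness
into the logarithm is not a proper entropy (it can be negative and is not
scale-invariant); a `literal=True` switch computes that raw variant for
comparison. All-zero betweenness (e.g. complete graphs) gives entropy 0 by
the `0·log 0 := 0` convention. The entropy argmax over the optimal range
serves as an independent confirmation of the PMI threshold; on
disagreement beyond one grid step the PMI wins and the event is logged.

### Validation

*Dice concordance*: overlap of each method's community with the reference
method's (fast greedy) at the chosen threshold, with bootstrap
interquartile spreads on community sizes. *Dice stability*: the reference
community at the chosen threshold compared against the communities at
every other grid threshold. *Embeddedness*: the target's strength per node
(sum of unthresholded |r| to the other set members, divided by set size)
in the community versus the whole module versus a null of `n_reps`
(default 1000) random communities of the same size — target plus
`size − 1` genes drawn without replacement from the module. *Hubs*: genes
with scaled strength (strength / maximum strength) strictly above 0.70,
and the fraction of them inside the detected community.

## Synthetic data

The generator plants a known pivotal community: a module of `module_genes`
(default 85) containing a core of `core_genes` (default 28, the target is
core member 0), observed on `n_subjects` (default 199) i.i.d. multivariate
normal subjects. Pairwise correlations follow a block factor model: core
gene `i` has loading `l_i ~ U(√r_core ± δ)`, other module genes
`m_j ~ U(√r_module ± δ)`, giving `corr = l_i l_j` within the core,
`m_i m_j` within the rest, and `α l_i m_j` across with `α` fixed so the
cross-block mean is exactly `r_module`. Block means therefore equal the
design values (defaults `r_core = 0.6`, `r_module = 0.35`) while
individual pairs spread around them.

The spread δ (default 0.05) matters. A perfectly equicorrelated core
becomes a complete clique at every threshold below `r_core`, so exactly
where it is recoverable it has zero internal betweenness and no
pivotality signal — the index the pipeline exists to compute would be
degenerate by construction. δ = 0.05 is the largest spread that keeps the
three planted correlation classes separated by about two sampling-noise
standard deviations at n = 199 (core pairs ≥ 0.52 versus everything else
≤ 0.41); `loading_spread=0` recovers the plain equicorrelated design.
Optional independent measurement noise (`noise_sd`) attenuates all
correlations uniformly, and an optional per-gene affine transform
emulates log-intensity ranges without affecting correlations.

What the generator does **not** emulate: periphery substructure (real
modules contain further sub-clusters; the synthetic periphery is one
homogeneous block), heavy-tailed or age-dependent expression, batch
effects, and strength heterogeneity — synthetic gene strengths are nearly
uniform, so almost every gene clears the 0.70 hub cutoff and the hub
overlap is close to the community fraction of the module, unlike real
data where hubs are few. Passing tests therefore demonstrate the
machinery recovers a planted block-structured community under realistic
noise, not that any particular biological dataset will behave as cleanly.

Two documented detector behaviors surface on this synthetic family and are
worth knowing about: modularity optimizers can split, or orphan single
members of, a community that holds nearly all of the network's edges (the
degree-based null model makes a dominant community unjustifiable), and the
map equation absorbs an unstructured sparse periphery into the adjacent
dense community. The size band and the optimal-range restriction keep the
threshold choice away from the worst of both regimes.

## Numerical choices

- Correlations are clipped to [0, 1] after the |·| to absorb rounding;
  the diagonal is defined as 0.
- The planted correlation matrix is Cholesky-factorized; if indefinite it
  is repaired by eigenvalue clipping with the unit diagonal restored.
- Threshold grids are built from rounded multiples of the step so grid
  values compare exactly across stages.
- One global seed expands through `numpy.random.SeedSequence` into
  per-stage seeds (detection, bootstrap, null); reruns with the same
  configuration are byte-identical, and float summations iterate in
  network order so results do not depend on set iteration order.
- Degenerate inputs are flagged rather than fatal wherever the scan must
  continue (empty-edge thresholds, undersized communities, collapsed
  bootstrap replicates); they are errors where a single value is requested
  (PMI of a singleton, Dice of two empty sets, modularity of an edgeless
  graph).

## Scale of the shipped analyses

The packaged tests and examples run the study-scale design (199 × 85) on a
0.05-step grid with 100 bootstrap replicates and a 1000-draw strength
null, which completes in well under a minute; the finer 0.01 grid and
1000-replicate bootstrap are the library defaults and scale linearly.

## Known limitations

- The PMI compares communities of different sizes through a single ratio;
  its absolute scale is not calibrated, only its argmax is used.
- Betweenness is recomputed per threshold from scratch; very large modules
  (thousands of genes) would need incremental or sampled betweenness.
- The entropy normalization choice (probability mass vs raw betweenness)
  changes curve heights; conclusions are drawn from argmax locations only.
- Covariate adjustment of expression (age, pH, post-mortem interval) is
  out of scope; the matrix is consumed as given.
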