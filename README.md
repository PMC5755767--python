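# pivotalnet

Detect a **pivotal community** of genes around a target gene inside a
co-expression module.

Weighted gene co-expression network analysis (WGCNA) clusters genes into
modules, but those modules often hold far too many genes to interpret.
`pivotalnet` takes one such module — a genes × subjects expression matrix
containing a target gene of interest (e.g. *DRD2*) — and fractionates it by
scanning a hard threshold over the absolute-Pearson similarity network,
looking for the tight, strategically connected sub-community the target
really belongs to.

## Method

1. **Network.** Pairwise similarity `s_ij = |cor(x_i, x_j)|` across
   subjects (the sign of co-expression is deliberately discarded). A hard
   threshold `t` binarizes it: edge iff `s_ij ≥ t`.
2. **Topology scan.** Mean degree, mean betweenness, diameter and mean
   eccentricity per threshold; the range where the three non-monotonic
   properties peak brackets the candidate thresholds.
3. **Community detection.** Four detectors spanning the main algorithm
   families — fast greedy and Louvain (modularity), walktrap (random-walk
   similarity), infomap (map equation) — each extracting the community
   containing the target.
4. **Pivotal Module Index.** For the target community at threshold `t`,

   ```
   PMI = (k_tc · b_tc) / (D_tc · N_tc)
   ```

   with `k_tc`/`b_tc` the mean degree and mean (Freeman) betweenness of the
   community's nodes, `D_tc` its diameter and `N_tc` its size. High degree
   and betweenness flag intense, strategic connectivity; small diameter and
   size reward cohesion. The chosen threshold is the argmax of the
   cross-method mean PMI within the topology-selected range; subject
   bootstrap (resample subjects with replacement, 25th–75th percentile of
   the PMI distribution) supplies error bands, and a weighted linear fit
   flags thresholds significantly above the overall trend.
5. **Entropy confirmation.** Shannon entropy of the normalized betweenness
   distribution per node, for the network and the community; its argmax
   should coincide with the PMI choice.
6. **Validation.** Dice overlap `2|A∩B|/(|A|+|B|)` measures cross-method
   concordance and stability across neighboring thresholds; the target's
   strength per node (mean |r| to community members) is compared against
   1000 random communities of the same size; hub genes (scaled strength
   > 0.70) are checked for membership in the detected community.

## Worked example

Simulate a study-scale module (199 subjects, 85 genes, a planted 28-gene
core at |r| ≈ 0.6 inside a |r| ≈ 0.35 module) and run the full pipeline:

```sh
pivotalnet simulate --out expr.tsv --truth core.txt --seed 0
# wrote 85 genes x 199 subjects to expr.tsv

cat > run.yaml <<'YAML'
expression: expr.tsv
target: DRD2
grid_start: 0.30
grid_stop: 0.60
grid_step: 0.05
n_boot: 100
null_reps: 1000
seed: 0
out_dir: out
YAML

pivotalnet run --config run.yaml
# best threshold 0.500 (entropy argmax 0.450, confirmed); community of 28 genes; outputs in out
```

The run selects threshold 0.50 — inside the planted separation band between
the module correlation (0.35) and the core correlation (0.6) — and the
entropy argmax (0.45) confirms it to within one grid step. All four
detectors return exactly the same 28-gene community (`out/concordance.tsv`):

```
method       size  size_q25  size_q75  dice_vs_reference
fast_greedy  28    28.0      31.0      1.0
louvain      28    28.0      29.0      1.0
walktrap     28    29.0      33.0      1.0
infomap      28    29.0      31.0      1.0
```

and that community is precisely the planted core (Dice = 1.0 against
`core.txt`). `out/summary.json` reports the embeddedness check: the
target's strength per node is 0.551 inside the community versus 0.385 in
the whole module and 0.376 ± 0.021 across 1000 random same-size
communities — the detected community is far more than a random slice of
the module.

Each stage is also available separately (`pivotalnet topo`, `pmi`,
`entropy`, `stability`, `communities`, `embed`, `net`) and as library
functions (`pivotalnet.pmi_scan`, `pivotalnet.dice_scan`, ...).

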