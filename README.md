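# fcgraph

Graph-theoretic analysis of longitudinal (pre/post-treatment) resting-state
functional connectivity over a small ROI parcellation.

`fcgraph` is for researchers who have ROI-level BOLD time series from two
sessions per subject (for example before and after a drug intervention) and
want to know **which network properties of which regions changed**. It
implements the full chain:

1. **Connectivity** — per session, the 14 × 14 (or N × N) Pearson
   correlation matrix of the ROI time courses (optionally Fisher
   r-to-z transformed).
2. **Proportional thresholding** — binarize at a connection density *k* by
   keeping the E = round(k·N(N−1)/2) strongest edges, sweeping
   k = 5%…40% in 5% steps so all subjects are compared at equal densities.
3. **Graph indexes** — per node: degree, clustering coefficient *C*,
   average path length, local efficiency, global efficiency, betweenness
   centrality (Brandes, exact); per network: characteristic path length *L*.
4. **Small-worldness** — against a degree-matched random null built by
   Maslov–Sneppen double-edge swaps (1000 rewires per edge by default):
   s(k) = g(k)/l(k) with g = C_real/C_rand and l = L_real/L_rand;
   s > 1 indicates small-world organization.
5. **Paired statistics** — two-sided Wilcoxon signed-rank test of every
   ROI × metric cell (post vs pre), exact small-sample p-values by
   enumeration of the signed-rank distribution, plus a post/pre median
   "radar" normalization of the significant indexes.

The built-in parcellation is a 14-region pain + default-mode-network (DMN)
set: bilateral Brodmann areas 1, 2, 3, 13 and 32 (pain network) plus mPFC,
PCC and bilateral lateral parietal cortex (DMN). Any ROI set can be
supplied as a CSV.

Because raw clinical rs-fMRI is rarely shareable, the package ships a
**synthetic cohort generator**: paired multivariate-Gaussian ROI series
with a controllable correlation structure, AR(1) temporal smoothness,
per-subject heterogeneity, and injectable post-session connectivity
effects — so the entire pipeline is testable and its statistical behavior
(type-I error, power) measurable without any data download.

## Worked example

Simulate an 8-subject paired cohort (150 volumes/session, TR 3 s) with a
known post-session effect — the correlation between the left lateral
parietal cortex and the six somatosensory ROIs raised by +0.35 — then run
the default analysis:

```bash
fcgraph simulate --out demo/cohort --seed 42 \
    --effect-roi LateralParietal_L \
    --effect-partners BA1_L,BA1_R,BA2_L,BA2_R,BA3_L,BA3_R \
    --effect-delta 0.35
fcgraph run --manifest demo/cohort/manifest.json --out demo/results --seed 42
```

Output (about 7 s):

```
comparison rows: 92; significant at alpha=0.05: 10
  LateralParietal_L    betweenness_centrality   density=0.25 p=0.0078 increase
  LateralParietal_L    clustering_coefficient   density=0.25 p=0.0312 decrease
  LateralParietal_L    degree                   density=0.25 p=0.0115 increase
  BA1_R                global_efficiency        density=0.25 p=0.0391 increase
  LateralParietal_L    global_efficiency        density=0.25 p=0.0078 increase
  LateralParietal_L    local_efficiency         density=0.25 p=0.0391 decrease
  network              small_worldness          density=0.25 p=0.0078 decrease
  network              small_worldness          density=0.3  p=0.0078 decrease
  network              small_worldness          density=0.35 p=0.0078 decrease
  network              small_worldness          density=0.4  p=0.0078 decrease
results written to demo/results
```

The 92 rows are the 14 ROIs × 6 nodal indexes compared at the 25%
reference density, plus one small-worldness comparison per density in the
sweep. Reading the flagged rows: the injected correlation increase gives
the target node more supra-threshold edges (degree ↑, p = 0.0115) and
routes more shortest paths through it (betweenness ↑, p = 0.0078 — the
smallest two-sided p attainable with 8 untied pairs, 2/2⁸); its new
neighbors are mostly unconnected to each other, so its clustering
coefficient and local efficiency drop; and the extra cross-network edges
displace triangle-closing within-network edges at fixed density, lowering
whole-network small-worldness. Each significant cell's post/pre median
ratio is written to `radar.csv` (e.g. degree 2.17, clustering 0.27), and
`demo/results/` also contains the per-session connectivity matrices,
the long-format nodal metric table, the density sweep, and a
`node_annotations.csv` marking each significant ROI with its direction of
change. Add `--figures` to get per-cell pre/post boxplots and the radar
chart as PNGs.

Per-node indexes of a single session are available directly:

```bash
fcgraph metrics --timeseries demo/cohort/sub-01_pre.csv --density 0.25
```

```
                   degree  clustering_coefficient  average_path_length  local_efficiency  global_efficiency  betweenness_centrality
roi
BA1_L                   3                  0.3333               1.8889            0.3333             0.4359                  2.1667
BA1_R                   5                  0.5000               1.4444            0.7500             0.5385                  3.7500
...
edges: 23 (realized density 0.2527)
```

All of this is equally available as a library (`fcgraph.generate_cohort`,
`fcgraph.run_pipeline`, …), and the per-stage transforms are exposed as
scikit-learn transformers (`ConnectivityTransformer`, `DensityThreshold`,
`GraphMetricsExtractor`) that compose with `sklearn.pipeline.Pipeline`.

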