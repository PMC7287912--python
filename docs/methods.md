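# Methods

## The analysis model

The pipeline treats each subject-session as an undirected, unweighted
functional brain graph. Nodes are ROIs whose averaged BOLD signals are
given as a (volumes × ROIs) matrix; edges are defined by thresholding the
pairwise Pearson correlation matrix at a fixed **connection density**
rather than at a fixed correlation value, so that every graph entering the
group comparison has the same number of edges and differences in graph
indexes cannot be driven by overall correlation level. The comparison of
interest is strictly within-subject: each index is computed per session
and the pre/post difference is tested across subjects with a paired
nonparametric test.

Assumptions this implies:

- the ROI signals are stationary enough over a session for a single
  correlation matrix to be meaningful;
- edge *presence* (the rank order of correlations), not edge weight,
  carries the signal of interest — all indexes are computed on binary
  graphs;
- subjects are exchangeable under the null of no session effect, which is
  exactly the condition the signed-rank test requires.

## Stages and their numerical choices

**Connectivity.** Pearson correlation per ROI pair, diagonal forced to
zero, symmetry enforced. A Fisher r-to-z option exists but is off by
default: density thresholding depends only on the edge *ranking*, which
any strictly monotone transform preserves, so z-transforming changes
nothing downstream (this is asserted by a test).

**Proportional thresholding.** At density k, the top
E = round-half-up(k · N(N−1)/2) node pairs (minimum 1) become edges.
Ranking is by signed correlation descending — strongest positive
couplings first, the common resting-state convention — with
ranking-by-magnitude available as an option. Ties at the cutoff are
broken lexicographically on the (i, j) index pair, making the ranking a
deterministic total order; a consequence used by the tests is that edge
sets are exactly nested across densities. At N = 14 the default sweep
5%–40% in 5% steps yields 5, 9, 14, 18, 23, 27, 32, 36 edges.

**Graph indexes.** Degree; clustering coefficient 2tᵢ/(kᵢ(kᵢ−1)) (0 when
kᵢ < 2); all-pairs BFS hop distances; nodal average path length (mean
distance to *reachable* peers; NaN for an isolated node, excluded from
group statistics with a warning); characteristic path length (mean over
reachable unordered pairs); nodal global efficiency (mean of 1/d with
1/∞ = 0, so disconnection penalizes rather than poisons the index); local
efficiency (global efficiency of the neighbor-induced subgraph, node
excluded; 0 below two neighbors); betweenness centrality by Brandes'
exact accumulation, unnormalized by default ((N−1)(N−2)/2 normalization
behind a flag). The reachable-pairs/1-over-infinity conventions are the
standard connectome treatment of the disconnected graphs that are
inevitable at 5% density on 14 nodes, and they are applied identically to
real and null graphs.

**Null model and small-worldness.** The reference network is generated by
Maslov–Sneppen degree-preserving rewiring: R × E attempted double-edge
swaps (R = `rewires_per_edge`, default 1000), each accepted only if it
creates neither a self-loop nor a multi-edge. "Rewiring each edge R
times" is implemented as attempted swaps rather than accepted swaps; at
the default depth the chain is mixed far beyond what distinguishes the
two. `ensemble_size` controls how many independent null graphs C_rand and
L_rand are averaged over; the default of 1 mirrors the single-reference
convention of small clinical studies, but ≥ 20 is recommended (a test
verifies the variance reduction). If the null ensemble is triangle-free
(possible at the lowest densities), C_rand = 0 and s(k) is recorded as
NaN and excluded pairwise from the group test rather than propagated.

**Paired statistics.** Two-sided Wilcoxon signed-rank per ROI × metric
cell. Differences of zero are dropped before ranking (Wilcoxon's original
convention; Pratt's is available). For m ≤ 12 retained untied differences
the p-value is exact, from the full signed-rank distribution computed by
dynamic programming over rank sums (equivalent to enumerating all 2^m
sign assignments; the distribution is cached per rank multiset, which is
what makes the Monte-Carlo calibration below affordable). Forced-exact
mode also handles mid-ranks. Otherwise a normal approximation with tie
correction (variance Σrᵢ²/4) is used, with optional continuity
correction. No multiple-comparison correction is applied by default —
the procedure reports uncorrected per-cell p < α across 14 ROIs × 6
indexes, so roughly α of the cells will be flagged under the global null
and single-cell findings should be read as candidate markers, not
confirmatory results; Benjamini–Hochberg is available via
`correction="fdr_bh"`.

**Density mode.** The paper-style report compares nodal indexes at one
**reference density** (default 25%, the density at which small-worldness
is singled out) — this is the default `density_mode="reference"`.
`"per_density"` tests every density (multiplying the number of tests
8-fold) and `"aggregate"` tests the per-subject mean over the sweep.
Small-worldness is always compared per density.

## The synthetic cohort generator

Each subject-session is a zero-mean multivariate Gaussian series with a
target correlation matrix, optionally AR(1)-filtered in time
(xₜ = φxₜ₋₁ + √(1−φ²)·εₜ with εₜ ~ N(0, Σ) and a stationary start, so the
cross-ROI correlation target Σ is preserved exactly and the lag-1
autocorrelation is φ). Defaults encode the study conditions the package
targets: 8 subjects, 150 volumes (7 min 30 s at TR = 3 s), the 14-region
parcellation.

- **Base correlation structure** (chosen once as a plausible resting-state
  block pattern): within-pain 0.25, within-DMN 0.35, homotopic L/R pairs
  of the same area 0.45, cross-network 0.05; PSD-repaired at
  construction.
- **Subject heterogeneity**: i.i.d. Gaussian jitter (s.d.
  `subject_jitter`, default 0.05) added to the off-diagonal entries, then
  eigenvalue-clipped at 1e-8 and re-normalized to unit diagonal (a
  congruence transform, so positive semi-definiteness is exact). The
  jittered matrix is shared between a subject's two sessions — this
  within-subject correlation is what gives the paired design its power.
- **Effects**: a signed increment δ on chosen (target, partner)
  correlation entries of the post session, clipped to ±0.99 and
  PSD-repaired. The canonical validation effect is δ = +0.35 between
  LateralParietal_L and the six somatosensory ROIs, which reliably raises
  the target's degree at the 25% density.
- **Autocorrelation**: default φ = 0.3, a mild temporal smoothness
  plausible at a 3-second TR. It widens the sampling variability of the
  correlation estimates but does not affect the validity of the paired
  test.
- **Seeding**: one master seed; every (subject, purpose) stream is an
  independent `SeedSequence(seed, spawn_key=(subject, stream))`, so
  output is bit-identical regardless of generation order.

What the generator does *not* emulate: hemodynamics, scanner drift and
physiological noise spectra, motion artifacts, spatial (voxel-level)
structure, non-Gaussian tails, and session-level global signal changes.
Passing calibration on this generator therefore demonstrates that the
*procedure* is valid when its exchangeability assumptions hold — not that
real fMRI preprocessing leaves those assumptions intact.

## Measured statistical behavior

The calibration study (`fcgraph.calibration`, run by both the acceptance
suite and `scripts/acceptance.py`) generates no-effect cohorts and
analyzes them with the real pipeline at the reference density. The
per-cell rejection rate at α = 0.05 lands near 0.04 rather than 0.05:
with 8 pairs the exact signed-rank distribution is discrete (the
attainable two-sided levels below 0.05 sum to 5/128 ≈ 0.039), and
integer-valued cells such as degree produce ties and zero differences
that make individual tests conservative. The power study injects the
canonical effect and requires the targeted (LateralParietal_L, degree)
cell to be flagged with direction "increase"; at δ = +0.35 against
jitter 0.05 this detection is essentially certain.

Problem sizes used by the validation runs — 500 oracle graphs of 5–8
nodes, 1000 rewiring trials at 10 rewires/edge (plus a batch at the full
1000), 20 seeds per reference topology, 1000 type-I replicates and 100
power replicates — were chosen to make Monte-Carlo error small relative
to the acceptance bands while keeping a full run in the minutes range on
one CPU.

## Known limitations

- Only binary-graph indexes; no weighted variants, modularity, or
  rich-club coefficients.
- The connectivity estimator is plain Pearson (no partial correlation,
  no nuisance regression); upstream preprocessing is out of scope.
- Small-worldness uses the classical random-reference ratio s = g/l
  only; lattice-referenced variants (ω, SWP) are not implemented.
- With `ensemble_size=1` the null estimates C_rand and L_rand are noisy;
  the default is kept for fidelity to common practice in small clinical
  studies, not because it is statistically advisable.
- The exact Wilcoxon enumeration caps at m = 20 (forced mode); beyond
  that only the normal approximation is offered.
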