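# Methods

This note documents the models, the numerical choices, and the limits of
what the synthetic experiments can show. It is the design record for the
package; the README covers usage.

## 1. Synthetic cohort

### What is emulated

Two groups of subjects (11 healthy-like, 10 AD-like by default) with
region-wise signal matrices (90 regions × 240 timepoints, i.e. 8 min at a
2 s sampling interval). The planted group differences mirror the
degeneration pattern the analysis is built to detect: the AD-like group has
fewer edges overall, fewer long-distance (> 75 mm) edges, and consequently
lower global efficiency, clustering, and transitivity at every threshold in
the 0.50–0.60 sweep.

### Planted graphs are spatially modular — and must be

`plant_group_adjacency` partitions the regions into spatially compact
communities (capacity-constrained k-means on the synthetic coordinates),
connects each community internally, and spends the remaining edge budget on
distance-penalized cross-community edges (weight `exp(-D/75 mm)`, multiplied
by `long_range_retention` for pairs beyond 75 mm, per-node cross-degree cap
2, exact total edge count by Gumbel top-k sampling).

Modularity is not an aesthetic choice. A correlation matrix that equals
0.6 on the edges of a graph and ~0 elsewhere only exists for very sparse
graphs: the row of a unit-diagonal PSD matrix is a unit-norm direction, so
a node whose neighbours are mutually uncorrelated supports at most
⌊1/0.6²⌋ = 2 neighbours at r = 0.6. Any generator that plants r = 0.6 on an
Erdős–Rényi-like graph of realistic density therefore cannot deliver that
correlation — whatever repair makes the matrix PSD destroys the planted
value. Compound-symmetric blocks (cliques at r = 0.6) are PSD at any size,
so a modular graph carries the target correlation essentially exactly,
with only the sparse cross edges slightly attenuated. Brain functional
networks are strongly modular, so the synthetic structure is also the
realistic choice.

Group defaults (frozen once, exposed in `SyntheticCohortConfig`):

| parameter | healthy | AD-like | why |
|---|---|---|---|
| edges | 480 | 330 | density deficit (the edge-count contrast) |
| blocks | auto (11–12 nodes) | 9 nodes, 10 % of internal pairs removed | smaller, "holey" modules lower clustering/transitivity structurally, not by sampling noise |
| cross edges | 18 | 6 | AD keeps fewer long bridges; bridges raise hop-count efficiency, so the AD deficit in global efficiency requires AD to have fewer of them |
| long-range retention | 1.0 | 0.3 | > 75 mm candidate pairs down-weighted for AD |

Per-subject variability: `subject_jitter` (default 0.02) resamples that
fraction of edges (drop k random edges, add k fresh distance-penalized
pairs), keeping the edge count exact.

### Covariance construction

The subject covariance starts from `I + r·A` (r = 0.6 on the jittered
subject adjacency) and is projected to the nearest correlation matrix by
Higham alternating projections with an eigenvalue floor (default 0.01),
followed by a few rounds of per-edge recalibration so the realized on-edge
values converge to the target. Uniform diagonal loading was rejected: it
rescales every off-diagonal entry by the same factor, and with
λ_min(I + 0.6A) ≈ 1 − 1.2√(mean degree) the planted correlation would land
near 0.16 at these densities. The projection concentrates the (small)
repair where the structure demands it; measured on the defaults, mean
on-edge correlation is 0.60 ± 0.02 and the 99th percentile of non-edge
entries stays below 0.45, which is what makes the τ = 0.5 recovery property
hold (sensitivity ≥ 0.92, specificity 1.0 per subject at T = 5000).

Signals are `L·Z` with `L` the Cholesky factor and `Z` i.i.d. standard
normal — stationary, white in time. No hemodynamics, autocorrelation,
band-pass filtering, motion or scanner drift is modelled: sample Pearson
correlation is invariant to per-region affine rescaling and, in
expectation, to temporal filtering of stationary signals, so these
omissions do not move the quantities the pipeline consumes. What passing
tests show is therefore that the *graph machinery* behaves as claimed on
data with known truth; they do not validate preprocessing of real scanner
data, which is out of scope.

## 2. Network construction

Pearson correlation of every region pair (zero-variance regions are
rejected with the offending index; T ≥ 3 required), then binarization at
each τ in the inclusive grid 0.50:0.01:0.60 (11 values, built by integer
index to avoid float accumulation). Edges use the signed correlation with
an inclusive cut (r ≥ τ); negative-edge handling and partial correlation
are non-goals. Covariate regression is omitted: the synthetic signals have
no nuisance structure to regress.

## 3. Topology metrics

All metrics are computed directly on the adjacency matrix (level-synchronous
matrix-product BFS; Brandes-style betweenness vectorized over sources) and
are tested against naive Floyd–Warshall / path-enumeration /
neighbour-counting oracles on 200 random graphs plus hand-computed fixtures,
and against networkx. Conventions: disconnected pairs contribute 0 to
global efficiency; degree-<2 nodes count as 0 in the clustering average
(keeping N fixed across thresholds); transitivity is 0 when no connected
triples exist; the long-distance cutoff is strict (> 75 mm); betweenness is
unnormalized fractional-credit — the evolution rule renormalizes the scale
away, so the convention is observationally irrelevant downstream.

## 4. Evolution rule

Per step: draw a fresh symmetric `R ~ U(0,1)`; synchronously over unordered
pairs, add non-edges with `CP ≥ 0.5` and `R ≤ 0.03`, remove edges with
`DP ≥ 0.5` and `R ≤ 0.03`; recompute betweenness, CP and DP from the new
network; stop after 100 steps. Raw weights are
`w_cp = (K_i+K_j)/D²` and `w_dp = (K_i+K_j)·D²`.

The proportionalities fix the rule only up to a normalization, and the
choice of normalization *is* the dynamics:

* **DP: frozen scale.** `DP = min(w_dp / s₀, 1)` with
  `s₀ = 2 × quantile₀.₇₀(w_dp over the initial edges)`. Betweenness and
  distance are positively coupled (long bridges carry shortest paths), so
  `w_dp` is heavy-tailed; against a *per-step maximum* the `DP ≥ 0.5` band
  holds only a handful of pairs and the network essentially never rewires.
  Against a frozen scale, removing bridges concentrates betweenness on the
  survivors, DP rises (the disconnection pressure is increasing by design),
  the cascade spreads into the module interiors, and it extinguishes itself
  once the modules decouple and internal betweenness collapses — the
  trajectories stabilize well before step 100.
* **CP: per-step candidate scale.** `CP = min(w_cp / c_t, 1)` with
  `c_t = 2 × quantile₀.₉₉₂₅(w_cp over current non-edges)`. A per-step scale
  keeps additions sparse and self-limiting (a frozen CP scale diverges: the
  same betweenness concentration that drives removals would compound
  additions). Additions land on short-range pairs around high-betweenness
  hubs; attaching spokes to hubs grows connected triples faster than
  triangles, which is how the evolved networks lose transitivity — the
  signature of degeneration the transitivity classifier keys on.

The two quantiles are the only free constants; they were calibrated once on
the default cohort so that the evolved trajectories show the qualitative
behaviour the protocol requires — decline of all four parameters toward the
AD-like group and stabilization within 100 steps — and then frozen. The
update is synchronous (no pair-order dependence); a pair can never satisfy
both rules (it is either an edge or not). Per-subject randomness comes from
substreams derived from the master seed and subject order, so group runs
are reproducible as a whole and per subject.

## 5. Classification

Per feature and threshold: z-score the 21 training values (11 healthy, 10
AD-like) on their own mean/sd, fit `SVC(kernel="linear", C=1)`, transform
the 11 evolved values with the stored scaler, and report the fraction
assigned to the AD class. Kernel, regularization and scaling are the
smallest-assumption choices for a 21-sample one-dimensional problem; the
boundary tie goes to AD (deterministic). The 11×4 table plus per-feature
averages is written as percentages. Cross-validated accuracy on the
training groups is deliberately out of scope — the protocol measures where
the evolved networks land, not generalization error.

## 6. Numerical and degenerate-input choices

* Nearest-correlation projection: ≤ 80 Dykstra-corrected iterations,
  eigenvalue floor on the PSD projection, final symmetric renormalization;
  non-PD results raise rather than clip.
* Empty networks: betweenness, CP and DP are identically zero, so an empty
  network is a fixed point of the evolution.
* A zero DP scale (no edges, or an all-zero betweenness as in a disjoint
  union of cliques) disables removals rather than dividing by zero.
* Matrix/atlas/profile files are plain text at full round-trip precision;
  parse errors carry file, line and column.

## 7. Problem sizes

Defaults reproduce the study geometry: 90 regions, 240 timepoints, 21
subjects, 11 thresholds, 100 evolution steps (11 × 11 = 121 traces, each
recomputing betweenness per step). The full experiment runs in ~2 minutes
on one CPU; the recovery check uses T = 5000. The test suite scales some
substrates down (e.g. a 40-node state for the 10,000-replicate flip-rate
check) purely because the contract being tested is size-independent.

## 8. Known limitations

* The synthetic cohort has block-modular truth; metrics behave differently
  on degree-heterogeneous (hub-dominated) real connectomes, and nothing
  here validates the pipeline against scanner noise, motion or atlas
  misregistration.
* The evolution rule's algebraic normalization is a modelling choice fixed
  by behaviour (decline + stabilization), not by a closed-form derivation.
* Group contrasts are point comparisons of group means; no significance
  testing is performed (none is part of the protocol).
* With 21 training samples, SVM accuracies are quantized in steps of 1/11
  and sensitive to the planted effect sizes; the defaults produce strong
  separation by construction.
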