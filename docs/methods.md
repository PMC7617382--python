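# Methods

## Model

The package models an N-dimensional binary activity vector σ (regions on or
off) with the pairwise maximum-entropy distribution

    P(σ) = Z⁻¹ e^{−E(σ)/T},   E(σ) = −Σᵢ hᵢσᵢ − ½ Σ_{i,j≠i} Jᵢⱼσᵢσⱼ,

the unique maximum-entropy distribution matching first moments ⟨σᵢ⟩ and
second moments ⟨σᵢσⱼ⟩.  J is symmetric with zero diagonal; T = 1 at the
fitted scale and is varied only in the thermodynamics module.  Both the
spin convention σᵢ ∈ {−1, +1} and the occupation convention σᵢ ∈ {0, 1}
are supported throughout.  `convert_convention` maps (h, J) between them
exactly (J₀₁ = 4J±, h₀₁ = 2h± − 2J±·1, state map s = 2σ − 1, constant
absorbed by Z), so any quantity that depends only on the distribution is
convention-invariant; this is asserted in the tests.  The specific heat is
convention-invariant; the susceptibility rescales by exactly 1/4 from ±1 to
0/1 because M is affine in the state.

Enumeration-based operations (exact fitting, state probabilities, entropy,
landscape, exact thermodynamics) require N ≤ 20 (2²⁰ states); the state
index uses region 0 as the least significant bit.

## Fitting

**Exact (likelihood) fit, N ≤ 15 by default.**  Gradient descent on the
moment mismatch: h ← h + ε(⟨σᵢ⟩_data − ⟨σᵢ⟩_model), and likewise for J
against exactly enumerated model moments; this is the likelihood gradient.
Convergence is declared when the largest absolute moment discrepancy falls
below `tolerance` (default 1e-4).  The step size starts at 0.1, shrinks by
half whenever the error increases (oscillation), and otherwise grows by 2%
up to 10× its initial value; this acceleration changes only the path, not
the fixed point, which is verified directly (`model_moments` of the result
matches the target within tolerance).  Target moments on the boundary of
the attainable polytope (a region always on/off, a perfectly (anti)coupled
pair — checked via the exact pairwise cell probabilities) are rejected with
an error naming the offending moment, since the maximiser is then infinite;
the message suggests lowering the binarization threshold or merging
clusters.

**Pseudo-likelihood fit, any N.**  Gradient ascent on the product of
single-region conditionals.  The conditional mean of region i given the
rest is tanh(hᵢ + Σⱼ Jᵢⱼσⱼ) in ±1 and the logistic function of the same
field in 0/1 — both forms are implemented per convention and verified
against each other through `convert_convention`, since they follow from
the same single-site Boltzmann conditional.  Updates mirror the exact fit
with the conditional statistics in place of model moments; sufficient
statistics are accumulated on the unique raster rows (weighted), which
makes the per-iteration cost independent of T beyond the first pass.  The
per-row (directed) coupling estimates are averaged into a symmetric J
after convergence.  Pseudo-likelihood is consistent: on 10⁵ samples at
N = 12 its couplings correlate with the exact fit's at r > 0.999.

The `PairwiseMaxEnt` estimator selects the route automatically (exact up
to `exact_max_n` = 15, pseudo-likelihood beyond), exposes `h_`, `J_`,
`converged_`, and composes with scikit-learn tooling.

## Preprocessing

Spatial parcellation is k-means (k-means++ init, 10 restarts, fixed seed)
on neuron x/y/z; ROI traces are unweighted member means.  Functional
clustering is agglomerative with average linkage on 1 − Pearson
correlation of ROI traces — correlation rather than covariance so trace
scale does not dominate — cut at N clusters; cluster traces are member-ROI
means.  Binarization z-scores each cluster trace over time and applies a
strict threshold (z > Z is "on"; the boundary sample is "off"), making the
Z = 0 case reproducible.  Zero-variance traces are an error naming the
trace.  Multi-recording data are concatenated along time after per-cluster,
per-recording z-scoring, with no further cross-recording normalization.

## Evaluation

Multi-information: S₁ (independent-model entropy from marginals), S₂
(fitted pairwise model entropy, enumeration), S_N (plug-in entropy of
empirical state frequencies); I₂ = S₁ − S₂, I_N = S₁ − S_N, r = I₂/I_N.
Entropies are computed in nats and reported in bits.  The plug-in S_N is
biased downward at small T; a warning is attached when T < 10·2^N.
Because plug-in joint entropy is subadditive, I_N is strictly positive for
any finite sample, so "independent data" cannot be flagged by I_N ≤ 0;
instead r is reported undefined whenever I_N is below a chi-square bias
floor, (k_obs − 1 − N)/T nats (about twice the expected plug-in I_N under
exact independence, where k_obs is the number of observed states).
Genuinely coupled data sit orders of magnitude above this floor.

Structure–function: correlations and ROC/AUC are computed on the
off-diagonal upper triangle, with |Jᵢⱼ| as the score — structural fiber
counts are nonnegative, so coupling magnitude is the comparable quantity;
raw-J correlations are reported alongside.  AUC uses the rank-sum identity
(tie-robust); structural edges are binarized at fractions of the matrix
maximum (defaults 1% and 30%).  In resolution scans the structural matrix
is aggregated to a cluster partition by summing fiber counts between
member regions (regions mapped to clusters by majority vote of their
neurons); degenerate grid cells (e.g. overclustering duplicates a region
and drives a pair moment to the boundary) are reported as undefined cells
with the error message rather than aborting the scan.

## Energy landscape

States are nodes of the N-hypercube (Hamming-1 adjacency).  Local minima
are states strictly below all N neighbors.  Basins are assigned by
steepest descent to the lowest-energy neighbor, ties broken by smallest
state index; states processed in increasing (energy, index) order so the
assignment is a single pass.  Ties are measure-zero for continuous
parameters; plateau states (possible in symmetric fixtures) are attached
deterministically to their lexicographically smallest neighbor's basin,
counted, and warned about.  Saddle states between minima follow the
deletion definition — remove states in decreasing energy order (ties:
larger index first) until a pair of minima disconnects; the remover is
their saddle — implemented as the equivalent union-find sweep in
increasing energy order, recording pairwise saddle energies and the
disconnectivity merge tree.  Asymmetric barriers are saddle energy minus
each minimum's energy; the symmetric barrier is the smaller of the two.
The implementation is checked against an independent minimax-Hamming-path
oracle (max edge on the minimum spanning tree with edge weight
max(E_u, E_v)) on randomized instances at N ≤ 8.

## Dynamics

Metropolis–Hastings single-flip walks: propose one of N neighbors
uniformly, accept with min[1, e^{(E(σ)−E(σ′))/T}]; per step the flip index
is drawn before the acceptance uniform from one seeded generator, so
chains are bit-reproducible.  Burn-in defaults to 30 000 steps.  A basin
transition is counted only when the basin label changes (rejected
proposals and within-basin moves are not transitions); dwell times are run
lengths of constant label.  Empirical and simulated series are compared at
the basin level: simulated counts are rescaled to the empirical total and
the off-diagonal counts regressed (flagged unreliable below 3 nonzero
pairs).  Comparison walks are unthinned — thinning would distort dwell
times.  The size–dwell relation regresses log mean dwell on basin-size
fraction.

## Thermodynamics and virtual resection

Exact engine: enumeration under P ∝ e^{−E/T}; C = varE/T², χ = varM/T with
M = Σᵢσᵢ (unnormalized; divide χ by N² for the per-region form).  The MCMC
engine anneals from the highest temperature down (default grid 2.0 → 0.05,
step 0.05; T = 0 excluded with a warning), seeding each chain with the
previous temperature's final state; C and χ come from variances of thinned
samples (defaults 103 000 steps, 3 000 burn-in, thin 500 per temperature —
one tenth of the full-scale chain, restorable via config).  Reported
Monte-Carlo standard errors use the delta-method variance of a sample
variance (empirical fourth moment) inflated by the lag-1 autocorrelation
factor; oracle comparisons in the tests use 1 000 thinned samples per
temperature so that the SE estimate itself is stable.  T_c is the grid
argmax of C refined by a 3-point quadratic when interior (flagged when on
the boundary); FWHM interpolates the two half-maximum crossings linearly
and is flagged undefined when a crossing falls outside the grid.

Virtual resection zeroes row and column `region` of J.  The resected
region is excluded from the E and M sums (equivalently, the curve is
computed on the (N−1)-region submodel — exact, since a decoupled spin
factorises out): a decoupled spin with nonzero h would otherwise add an
independent-spin Schottky term to C that is pure bias when comparing
regions.  This is switchable (`exclude_resected=False` keeps the full
state space).  Region strength is the intact row sum Σⱼ J_region,j.
Thermal analyses default to the 0/1 convention, whose low-temperature
phenotype (episodes of global activation and inactivity) matches the
bistability seen in data; fitting defaults to ±1.  Both are supported
everywhere.

## Synthetic data

The generator defines the study conditions: couplings are Gaussian
(scale = `coupling_scale`, default 0.3) on an Erdős–Rényi support of
density 0.4 — producing both strongly and weakly coupled nodes so
structure–function and resection analyses have contrast; fields are
uniform in [−1, 0] (±1 convention) so the all-off state dominates,
mirroring sparse activation; the structural matrix is
gain·|J| + half-normal noise (`structure_noise`), clipped at zero, exactly
proportional to |J| at zero noise.  Boltzmann sampling is i.i.d. via
enumeration (N ≤ 20) or a burned-in, thinned Metropolis chain (any N).
Calcium emulation is a two-level step signal (on = 1, off = 0) plus white
noise of SD 1/snr on each of `neurons_per_region` neurons per region,
positioned in Gaussian blobs around well-separated centers; no indicator
kinetics, motion artifacts, or atlas registration are modelled, because
the pipeline consumes only z-scored thresholded cluster averages.  Passing
tests therefore demonstrate correctness of the inference and analysis
chain under the model's own assumptions — not robustness to slow calcium
decay, drift, or registration error in real recordings.  All stochastic
operations take an explicit integer seed; there is no global RNG state.

## Problem sizes

Default analyses run at N = 8–12 regions with 10⁴–10⁵ samples, 10⁶-step
comparison walks, and 10³ thinned draws per temperature for MCMC
thermodynamic oracles; these sizes give estimator errors well inside the
assertion margins used in the tests while keeping any single analysis in
the seconds-to-minutes range on one CPU.

## Known limitations

- Enumeration-bound operations stop at N = 20; no approximate landscape
  exploration for larger N.
- No regularized (L1/L2) inverse Ising, mean-field/TAP inversions, or
  higher-order (triplet) models.
- The plug-in entropy estimator is used without bias correction; r at
  small T is optimistic and flagged, not corrected.
- The disconnectivity merge tree is exported as JSON; no dendrogram
  rendering.
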