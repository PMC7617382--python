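# memscape

Pairwise maximum-entropy modelling and energy-landscape analysis of
coarse-grained neural activity.

## What this is for

Whole-brain calcium imaging yields tens of thousands of single-neuron
traces.  After coarse-graining to N functional clusters and binarizing
(on/off per time point), the joint statistics of the N-dimensional binary
state can be captured by the *pairwise maximum-entropy model* (MEM) — the
least-structured distribution matching the observed activation rates
⟨σᵢ⟩ and coactivation rates ⟨σᵢσⱼ⟩.  That distribution is the Ising model

    P(σ) = Z⁻¹ exp(−E(σ)/T),    E(σ) = −Σᵢ hᵢσᵢ − ½ Σ_{i≠j} Jᵢⱼ σᵢσⱼ,

with activation biases hᵢ and pairwise functional couplings Jᵢⱼ.  memscape
implements the full analysis chain a systems-neuroscience practitioner
needs around that model:

- **synthetic** — ground-truth models, Boltzmann-sampled rasters,
  calcium-like traces with spatially blobbed neurons, and a structural
  ("fiber count") matrix correlated with |J|, so every downstream stage is
  testable without external data;
- **preprocess** — spatial k-means parcellation, functional clustering of
  ROI traces on 1 − correlation, per-cluster z-score binarization at
  threshold z (in {−1,+1} or {0,1} conventions);
- **model** — `PairwiseMaxEnt`, a scikit-learn estimator fitting (h, J)
  either by exact moment-matching gradient descent (enumeration, N ≤ 15 by
  default) or by pseudo-likelihood maximisation (any N);
- **evaluation** — state-probability comparison, multi-information fraction
  r = I₂/I_N, structure–function correlation and ROC/AUC, split-half
  robustness, resolution scans over (N, z);
- **landscape** — local energy minima (attractor states), steepest-descent
  basins, saddle states by the deletion algorithm, disconnectivity merge
  tree, asymmetric/symmetric energy barriers;
- **dynamics** — empirical basin dwell times and transition matrices versus
  Metropolis–Hastings random walks on the fitted landscape;
- **thermo** — specific heat C(T) = varE/T² and susceptibility
  χ(T) = varM/T by exact enumeration or annealed MCMC, critical temperature
  T_c, FWHM of the C curve, and *virtual resection* (zeroing one region's
  couplings) to rank regions by their influence on critical behavior.

## Worked example

```python
import numpy as np
from memscape import (make_ground_truth, sample_states, fit_exact, moments_from_states,
                      assign_basins, multi_information, convert_convention, exact_curve)
from memscape.model import PM1
from memscape.preprocess import BinaryRaster
from memscape.landscape import landscape_summary

gt = make_ground_truth(n_regions=8, coupling_scale=0.5, structure_noise=0.05, seed=5)
X = sample_states(gt, 50_000, method="exact_enumeration", seed=1)
report = fit_exact(moments_from_states(X, PM1), convention=PM1)
print(f"converged in {report.iterations} iterations, "
      f"max moment error {report.max_moment_error:.2e}")
iu = np.triu_indices(8, 1)
print(f"coupling recovery: r = {np.corrcoef(report.params.J[iu], gt.J_true[iu])[0,1]:.3f}")

fq = multi_information(BinaryRaster(X, 0.0, PM1), report.params)
print(f"multi-information captured: r = {fq.r:.3f}  "
      f"(S1 = {fq.S1:.3f}, S2 = {fq.S2:.3f}, SN = {fq.SN:.3f} bits)")

decomp = assign_basins(report.params)
print(landscape_summary(decomp).to_string(
    index=False, columns=["state_index", "state_bits", "energy", "basin_size"]))

curve = exact_curve(convert_convention(report.params, "zero_one"))
print(f"Tc = {curve.Tc:.3f}, C peak = {curve.C_peak:.2f}, FWHM = {curve.fwhm:.3f}")
```

Output:

```
converged in 243 iterations, max moment error 9.91e-05
coupling recovery: r = 1.000
multi-information captured: r = 0.997  (S1 = 7.381, S2 = 6.407, SN = 6.404 bits)
 state_index state_bits    energy  basin_size
          72   00010010 -4.704093    0.273438
          28   00111000 -4.065051    0.250000
          96   00000110 -3.316520    0.101562
          54   01101100 -2.944508    0.375000
Tc = 0.481, C peak = 3.20, FWHM = 0.825
```

Reading it: the fitted couplings recover the planted ones essentially
perfectly from 5×10⁴ samples; the pairwise model accounts for 99.7% of the
multi-information (S1 − S2 versus S1 − SN); the fitted landscape has four
attractor states (bit strings list region 0 first) whose basins partition
all 256 states; and the 0/1-convention thermodynamics locate the specific
heat peak at T_c ≈ 0.48 with a ≈ 0.83-wide critical window.

## Command line

Every stage is also a subcommand over a single JSON config:

```bash
memscape demo --seed 7 --out-dir out          # simulate ... resect, end to end
memscape simulate --config my.json
memscape validate --config my.json            # echo the normalized config
```

Artifacts land under `out/<stage>/` with a `manifest.json` recording every
parameter used, the seed, and input checksums.  Identical config + seed
gives byte-identical CSV/JSON outputs.

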