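"""Model-fit quality and structure-function coupling.

Goodness of fit of the pairwise model is the fraction of the
multi-information it captures:

    S1 = entropy of the independent (first-order) model,
    S2 = entropy of the fitted pairwise model,
    SN = plug-in entropy of the empirical state distribution,
    I2 = S1 - S2,  IN = S1 - SN,  r = I2 / IN  (0 <= r <= 1 in expectation).

Structure-function coupling correlates coupling magnitudes |J_ij| with a
structural (fiber-count) matrix and scores the detection of binarized
structural edges by |J_ij| via ROC/AUC.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .model import (
    BoundaryMomentError,
    MEMParams,
    MomentSet,
    enumerate_distribution,
    fit_exact,
    fit_pseudolikelihood,
    moments_from_states,
    states_to_index,
)
from .preprocess import (
    BinaryRaster,
    binarize,
    empirical_moments,
    functional_clusters,
    spatial_kmeans,
)

LN2 = np.log(2.0)


def _raster_states(raster) -> tuple[np.ndarray, str]:
    if isinstance(raster, BinaryRaster):
        return raster.states, raster.convention
    raise TypeError("expected a BinaryRaster")


@dataclasses.dataclass
class FitQuality:
    """Entropies (bits) and the captured multi-information fraction."""

    S1: float
    S2: float
    SN: float
    I2: float
    IN: float
    r: float  # nan when undefined
    r_defined: bool
    units: str = "bits"
    warnings: list = dataclasses.field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def state_probability_comparison(raster: BinaryRaster, params: MEMParams) -> pd.DataFrame:
    """Empirical vs model probability for every state (both columns sum to 1)."""
    states, conv = _raster_states(raster)
    n = params.n_regions
    idx = states_to_index(states, conv)
    emp = np.bincount(idx, minlength=2**n) / idx.size
    model = enumerate_distribution(params)
    n_active = np.array([bin(i).count("1") for i in range(2**n)])
    return pd.DataFrame(
        {
            "state": np.arange(2**n),
            "empirical_p": emp,
            "model_p": model,
            "n_active": n_active,
        }
    )


def multi_information(raster: BinaryRaster, params: MEMParams) -> FitQuality:
    """Multi-information decomposition of model fit (reported in bits).

    SN uses the plug-in (maximum-likelihood) entropy estimator, which is
    biased downward at small T; a warning is attached when T < 10 * 2^N.
    r is flagged undefined when IN does not exceed the chi-square bias floor
    of the plug-in estimator under independence (approximately
    (k_observed - 1 - N) / T nats), so that truly independent data are not
    assigned a fabricated fraction.
    """
    states, conv = _raster_states(raster)
    T, n = states.shape
    warns: list[str] = []
    if T < 10 * 2**n:
        warns.append(
            f"T={T} < 10*2^N: plug-in entropy SN is biased downward; r is optimistic"
        )
        warnings.warn(warns[-1], stacklevel=2)
    # S1: independent model from per-region marginals
    p_on = (states > 0).mean(axis=0) if conv == "plus_minus_one" else states.mean(axis=0)
    p_on = np.clip(p_on, 1e-15, 1 - 1e-15)
    s1 = float(-(p_on * np.log(p_on) + (1 - p_on) * np.log(1 - p_on)).sum())
    # SN: plug-in from empirical state frequencies
    idx = states_to_index(states, conv)
    counts = np.bincount(idx, minlength=2**n)
    freq = counts[counts > 0] / T
    sn = float(-(freq * np.log(freq)).sum())
    # S2: fitted pairwise model entropy
    p_model = enumerate_distribution(params)
    p_model = p_model[p_model > 0]
    s2 = float(-(p_model * np.log(p_model)).sum())

    i2 = s1 - s2
    i_n = s1 - sn
    k_obs = int((counts > 0).sum())
    bias_floor = max(k_obs - 1 - n, 1) / T  # ~2x the chi-square mean of plug-in IN
    defined = i_n > bias_floor
    if not defined:
        warns.append(
            f"IN={i_n:.3g} nats is within the plug-in bias floor {bias_floor:.3g}; "
            "r undefined (data indistinguishable from independent)"
        )
    r = float(i2 / i_n) if defined else np.nan
    return FitQuality(
        S1=s1 / LN2, S2=s2 / LN2, SN=sn / LN2, I2=i2 / LN2, IN=i_n / LN2,
        r=r, r_defined=bool(defined), warnings=warns,
    )


@dataclasses.dataclass
class StructureFunctionReport:
    correlation: float  # Pearson of |J| vs structural, off-diagonal upper triangle
    pearson_abs: float
    spearman_abs: float
    pearson_raw: float
    spearman_raw: float
    auc_by_threshold: dict  # threshold fraction -> AUC (nan when undefined)
    roc_curves: dict  # threshold fraction -> (fpr, tpr) arrays
    flags: list


def structure_function(
    params: MEMParams | np.ndarray,
    structural: np.ndarray,
    thresholds: tuple = (0.01, 0.30),
) -> StructureFunctionReport:
    """Correlation and edge-detection AUC of couplings against structure.

    For each threshold fraction f the structural matrix is binarized at
    f * max(structural) and |J_ij| is used as the classifier score; the AUC
    is the rank-sum (Mann-Whitney) statistic, exact and tie-robust.
    """
    J = params.J if isinstance(params, MEMParams) else np.asarray(params)
    structural = np.asarray(structural, dtype=float)
    if structural.shape != J.shape:
        raise ValueError("structural matrix shape does not match J")
    if not np.allclose(structural, structural.T):
        raise ValueError("structural matrix must be symmetric")
    iu = np.triu_indices(J.shape[0], k=1)
    j_raw = J[iu]
    j_abs = np.abs(j_raw)
    s = structural[iu]
    flags: list[str] = []

    def _corr(fn, a, b):
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return np.nan
        return float(fn(a, b).statistic)

    pearson_abs = _corr(stats.pearsonr, j_abs, s)
    spearman_abs = _corr(stats.spearmanr, j_abs, s)
    pearson_raw = _corr(stats.pearsonr, j_raw, s)
    spearman_raw = _corr(stats.spearmanr, j_raw, s)

    auc_by_threshold: dict = {}
    roc_curves: dict = {}
    smax = s.max() if s.size else 0.0
    for f in thresholds:
        labels = s > f * smax
        if labels.all() or not labels.any():
            auc_by_threshold[f] = np.nan
            roc_curves[f] = (np.array([]), np.array([]))
            flags.append(f"threshold {f}: single-class structural labels; AUC undefined")
            continue
        auc_by_threshold[f] = float(roc_auc_score(labels, j_abs))
        fpr, tpr, _ = roc_curve(labels, j_abs)
        roc_curves[f] = (fpr, tpr)
    return StructureFunctionReport(
        pearson_abs, pearson_abs, spearman_abs, pearson_raw, spearman_raw,
        auc_by_threshold, roc_curves, flags,
    )


@dataclasses.dataclass
class SplitHalfReport:
    corr_J: float
    corr_h: float
    corr_state_p: float
    params_a: MEMParams
    params_b: MEMParams


def split_half(
    raster: BinaryRaster,
    fit_config: dict | None = None,
    seed: int = 0,
    shuffle: bool = True,
) -> SplitHalfReport:
    """Fit two random halves of the time samples independently and compare.

    Returns Pearson correlations of the two J estimates (off-diagonal upper
    triangle), the two h estimates, and the two model state-probability
    vectors.  ``shuffle=False`` splits into first/second half deterministically.
    """
    states, conv = _raster_states(raster)
    T, n = states.shape
    if T < 4:
        raise ValueError("need at least 4 time samples")
    cfg = dict(learning_rate=0.1, tolerance=1e-4, max_iter=200_000, exact_max_n=15)
    cfg.update(fit_config or {})
    exact_max_n = cfg.pop("exact_max_n")
    order = np.random.default_rng(seed).permutation(T) if shuffle else np.arange(T)
    halves = [states[order[: T // 2]], states[order[T // 2 :]]]
    fitted = []
    for name, half in zip("AB", halves):
        const = np.flatnonzero(half.std(axis=0) == 0)
        if const.size:
            raise ValueError(f"cluster(s) {const.tolist()} constant in half {name}")
        if n <= exact_max_n:
            rep = fit_exact(moments_from_states(half, conv), convention=conv, **cfg)
        else:
            rep = fit_pseudolikelihood(half, convention=conv, **cfg)
        fitted.append(rep.params)
    pa, pb = fitted
    iu = np.triu_indices(n, k=1)
    corr_j = float(stats.pearsonr(pa.J[iu], pb.J[iu]).statistic)
    corr_h = float(stats.pearsonr(pa.h, pb.h).statistic)
    corr_p = float(
        stats.pearsonr(enumerate_distribution(pa), enumerate_distribution(pb)).statistic
    )
    return SplitHalfReport(corr_j, corr_h, corr_p, pa, pb)


def aggregate_structural(
    structural: np.ndarray, region_to_cluster: np.ndarray, n_clusters: int
) -> np.ndarray:
    """Sum pairwise fiber counts between the member regions of each cluster."""
    structural = np.asarray(structural, dtype=float)
    out = np.zeros((n_clusters, n_clusters))
    for a in range(n_clusters):
        ia = np.flatnonzero(region_to_cluster == a)
        for b in range(a + 1, n_clusters):
            ib = np.flatnonzero(region_to_cluster == b)
            out[a, b] = out[b, a] = structural[np.ix_(ia, ib)].sum()
    return out


def majority_region_to_cluster(
    region_of_neuron: np.ndarray, cluster_of_neuron: np.ndarray
) -> np.ndarray:
    """Map each ground-truth region to the functional cluster holding most of its neurons."""
    regions = np.unique(region_of_neuron)
    mapping = np.empty(regions.size, dtype=np.int64)
    for r in regions:
        labels, counts = np.unique(cluster_of_neuron[region_of_neuron == r], return_counts=True)
        mapping[r] = labels[np.argmax(counts)]
    return mapping


def scan_resolutions(
    recording,
    cluster_numbers: list,
    thresholds_z: list,
    structural: np.ndarray,
    *,
    n_rois: int | None = None,
    threshold_fracs: tuple = (0.01,),
    convention: str = "plus_minus_one",
    seed: int = 0,
    fit_config: dict | None = None,
) -> pd.DataFrame:
    """Grid of structure-function AUC / correlation over (N clusters, z).

    For each cluster number the neuron traces are spatially parcellated,
    functionally clustered, binarized at each z, fitted, and scored against
    the structural matrix aggregated to the cluster partition (sum of fiber
    counts between member regions).  The returned frame carries one row per
    (N, z) cell; the maximizing cell is the row with the largest AUC.
    """
    from .model import EXACT_FIT_LIMIT

    cfg = dict(learning_rate=0.1, tolerance=1e-4, max_iter=200_000)
    cfg.update(fit_config or {})
    n_neurons = recording.traces.shape[0]
    n_rois = n_rois or min(8 * max(cluster_numbers), n_neurons)
    rois = spatial_kmeans(recording.neuron_positions, recording.traces, n_rois, seed=seed)
    rows = []
    for n_clusters in cluster_numbers:
        clusters = functional_clusters(rois, n_clusters)
        cluster_of_neuron = clusters.cluster_of_roi[rois.roi_of_neuron]
        mapping = majority_region_to_cluster(recording.region_of_neuron, cluster_of_neuron)
        agg = aggregate_structural(structural, mapping, n_clusters)
        for z in thresholds_z:
            row = {"n_clusters": n_clusters, "threshold_z": z, "auc": np.nan,
                   "pearson": np.nan, "spearman": np.nan, "error": ""}
            try:
                raster = binarize(clusters, threshold_z=z, convention=convention)
                moments = empirical_moments(raster)
                if n_clusters <= EXACT_FIT_LIMIT:
                    rep = fit_exact(moments, convention=convention, **cfg)
                else:
                    rep = fit_pseudolikelihood(raster.states, convention=convention, **cfg)
            except (BoundaryMomentError, ValueError) as exc:
                # degenerate cell (e.g. overclustering duplicates a region, a
                # cluster saturates at high z): report it, keep scanning
                row["error"] = str(exc)
                rows.append(row)
                continue
            sf = structure_function(rep.params, agg, thresholds=threshold_fracs)
            aucs = [v for v in sf.auc_by_threshold.values() if np.isfinite(v)]
            row.update(
                auc=float(np.mean(aucs)) if aucs else np.nan,
                pearson=sf.pearson_abs,
                spearman=sf.spearman_abs,
            )
            rows.append(row)
    return pd.DataFrame(rows)
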