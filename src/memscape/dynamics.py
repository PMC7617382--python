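"""Basin-level dynamics: empirical transitions vs Metropolis random walks.

The observed raster is mapped to a basin-label time series via the landscape
decomposition; transition counts, in/out transition probabilities and dwell
times are tabulated; and the same statistics are computed for a
Metropolis-Hastings random walk on the fitted landscape (single-flip
proposals, acceptance min[1, e^{(E(s)-E(s'))/T}]).  Only changes of basin
label count as transitions — rejected proposals and within-basin moves do
not.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from . import _mcmc
from .landscape import LandscapeDecomposition, landscape_energies
from .model import MEMParams, states_to_index
from .preprocess import BinaryRaster


@dataclasses.dataclass
class TransitionStats:
    freq: np.ndarray  # (k, k) integer counts of basin switches, zero diagonal
    p_out: np.ndarray  # row-normalized (nan rows flagged in `empty_rows`)
    p_in: np.ndarray  # column-normalized
    dwell_mean: np.ndarray  # mean run length per basin (nan if never visited)
    visits: np.ndarray  # number of runs per basin
    total_dwell: np.ndarray  # total samples per basin
    empty_rows: np.ndarray  # basins with no outgoing transitions
    empty_cols: np.ndarray  # basins with no incoming transitions
    n_basins: int


@dataclasses.dataclass
class WalkConfig:
    n_steps: int = 1_000_000
    burn_in: int = 30_000
    seed: int = 0
    temperature: float = 1.0

    def __post_init__(self) -> None:
        if self.n_steps <= 0:
            raise ValueError("n_steps must be positive")
        if self.burn_in < 0:
            raise ValueError("burn_in must be nonnegative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def basin_trajectory(raster: BinaryRaster | np.ndarray, decomp: LandscapeDecomposition,
                     convention: str | None = None) -> np.ndarray:
    """Basin label (index into decomp.minima) for every time point."""
    if isinstance(raster, BinaryRaster):
        states, convention = raster.states, raster.convention
    else:
        states = np.asarray(raster)
        if convention is None:
            raise ValueError("convention required for a bare state array")
    idx = states_to_index(states, convention)
    return decomp.basin_label[idx]


def transition_stats(labels: np.ndarray, n_basins: int | None = None) -> TransitionStats:
    """Count basin-to-basin switches and dwell (run-length) statistics."""
    labels = np.asarray(labels, dtype=np.int64).ravel()
    if labels.size < 2:
        raise ValueError("need a label series of length >= 2")
    k = int(labels.max()) + 1 if n_basins is None else n_basins
    freq = np.zeros((k, k), dtype=np.int64)
    change = np.flatnonzero(labels[1:] != labels[:-1])
    np.add.at(freq, (labels[change], labels[change + 1]), 1)

    # run lengths
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [labels.size]))
    run_labels = labels[starts]
    run_lengths = ends - starts
    visits = np.bincount(run_labels, minlength=k)
    total_dwell = np.bincount(run_labels, weights=run_lengths, minlength=k).astype(np.int64)
    with np.errstate(invalid="ignore"):
        dwell_mean = np.where(visits > 0, total_dwell / np.maximum(visits, 1), np.nan)

    row = freq.sum(axis=1)
    col = freq.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_out = np.where(row[:, None] > 0, freq / np.maximum(row[:, None], 1), np.nan)
        p_in = np.where(col[None, :] > 0, freq / np.maximum(col[None, :], 1), np.nan)
    return TransitionStats(
        freq=freq,
        p_out=p_out,
        p_in=p_in,
        dwell_mean=dwell_mean,
        visits=visits,
        total_dwell=total_dwell,
        empty_rows=np.flatnonzero(row == 0),
        empty_cols=np.flatnonzero(col == 0),
        n_basins=k,
    )


def mcmc_walk(params: MEMParams, cfg: WalkConfig) -> np.ndarray:
    """Metropolis-Hastings walk over state indices (burn-in discarded, unthinned)."""
    e = landscape_energies(params)
    n = params.n_regions
    rng = np.random.default_rng(cfg.seed)
    start = int(rng.integers(0, e.size))
    chain_seed = int(np.random.SeedSequence(cfg.seed).generate_state(1)[0] % (2**31))
    path = _mcmc.metropolis_bits(
        e, n, cfg.burn_in + cfg.n_steps, start, 1.0 / cfg.temperature, chain_seed
    )
    return path[cfg.burn_in:]


def walk_basin_labels(params: MEMParams, decomp: LandscapeDecomposition, cfg: WalkConfig) -> np.ndarray:
    return decomp.basin_label[mcmc_walk(params, cfg)]


@dataclasses.dataclass
class TransitionComparison:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    scatter: pd.DataFrame
    reliable: bool


def compare_transitions(empirical: TransitionStats, simulated: TransitionStats) -> TransitionComparison:
    """Regress empirical on (rescaled) simulated off-diagonal transition counts."""
    if empirical.n_basins != simulated.n_basins:
        raise ValueError("basin sets differ between the two series")
    k = empirical.n_basins
    off = ~np.eye(k, dtype=bool)
    x = simulated.freq[off].astype(float)
    y = empirical.freq[off].astype(float)
    if x.sum() > 0:
        x = x * (y.sum() / x.sum())  # rescale simulated counts to empirical total
    pairs = np.argwhere(off)
    scatter = pd.DataFrame(
        {"from": pairs[:, 0], "to": pairs[:, 1], "simulated": x, "empirical": y}
    )
    nonzero = (x > 0) | (y > 0)
    reliable = int(nonzero.sum()) >= 3
    if reliable and np.ptp(x) > 0:
        res = stats.linregress(x, y)
        return TransitionComparison(
            res.slope, res.intercept, res.rvalue**2, res.pvalue, scatter, True
        )
    return TransitionComparison(np.nan, np.nan, np.nan, np.nan, scatter, False)


@dataclasses.dataclass
class DwellSizeFit:
    slope: float
    intercept: float
    r_squared: float
    n_basins_used: int
    reliable: bool


def dwell_size_relation(tstats: TransitionStats, decomp: LandscapeDecomposition) -> DwellSizeFit:
    """Exponential size-dwell law: regress log mean dwell on basin-size fraction."""
    use = (tstats.visits > 0) & np.isfinite(tstats.dwell_mean)
    if use.sum() < 3:
        return DwellSizeFit(np.nan, np.nan, np.nan, int(use.sum()), False)
    x = decomp.basin_sizes[use]
    y = np.log(tstats.dwell_mean[use])
    res = stats.linregress(x, y)
    return DwellSizeFit(res.slope, res.intercept, res.rvalue**2, int(use.sum()), True)
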