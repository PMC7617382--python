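"""Synthetic ground truth: models, rasters, calcium-like traces, structure.

Everything downstream (preprocessing, fitting, landscape, dynamics,
thermodynamics) is exercised on recordings produced here, so every stage is
testable without external imaging data.  The generator emulates:

* a ground-truth pairwise model (h, J) over N regions, with couplings drawn
  as Gaussian weights on an Erdos-Renyi support (density ~0.4) so the model
  has both strongly and weakly connected nodes, and negative-biased fields
  (uniform in [-1, 0] in the +-1 convention) so the all-off state dominates,
  mirroring sparse activation;
* binary state time series sampled from the model's Boltzmann distribution
  (exact enumeration for N <= 20, Metropolis otherwise);
* continuous calcium-like traces (two-level step signal plus white noise —
  no indicator kinetics, since the pipeline only consumes z-scored
  thresholded traces) whose binarization recovers the states;
* neuron positions forming spatial blobs per region;
* a structural "fiber count" matrix  a*|J| + noise, clipped at zero, so the
  structure-function analysis has a tunable ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np

from . import _mcmc
from .model import (
    PM1,
    CapabilityError,
    ENUMERATION_LIMIT,
    MEMParams,
    _check_convention,
    enumerate_distribution,
    state_table,
)


@dataclasses.dataclass
class GroundTruth:
    """A generative pairwise model plus a matched structural matrix."""

    n_regions: int
    h_true: np.ndarray
    J_true: np.ndarray
    convention: str
    structural: np.ndarray
    seed: int

    @property
    def params(self) -> MEMParams:
        return MEMParams(h=self.h_true, J=self.J_true, convention=self.convention)


@dataclasses.dataclass
class SyntheticRecording:
    """Neuron-level synthetic recording with its generating ground truth."""

    neuron_positions: np.ndarray  # (n_neurons, 3)
    traces: np.ndarray  # (n_neurons, T)
    region_of_neuron: np.ndarray  # (n_neurons,)
    states_true: np.ndarray  # (T, N)
    ground_truth: GroundTruth | None = None
    threshold_z: float = 0.0  # binarization threshold that recovers states_true


def make_ground_truth(
    n_regions: int,
    coupling_scale: float = 0.3,
    structure_noise: float = 0.1,
    seed: int = 0,
    *,
    density: float = 0.4,
    convention: str = PM1,
    h_low: float = -1.0,
    h_high: float = 0.0,
    structure_gain: float = 1.0,
) -> GroundTruth:
    """Draw a random ground-truth model and a correlated structural matrix.

    structural = structure_gain * |J| + structure_noise * (half-normal noise),
    symmetrised, clipped at zero, zero diagonal.  With structure_noise = 0 the
    structural matrix is exactly proportional to |J|.
    """
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    if coupling_scale <= 0:
        raise ValueError("coupling_scale must be positive")
    if structure_noise < 0:
        raise ValueError("structure_noise must be nonnegative")
    _check_convention(convention)
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n_regions, k=1)
    support = rng.random(len(iu[0])) < density
    if not support.any():  # guarantee at least one coupling
        support[rng.integers(len(support))] = True
    w = np.where(support, rng.normal(0.0, coupling_scale, len(support)), 0.0)
    J = np.zeros((n_regions, n_regions))
    J[iu] = w
    J = J + J.T
    h = rng.uniform(h_low, h_high, n_regions)

    noise = structure_noise * rng.normal(size=len(iu[0]))
    s_upper = np.clip(structure_gain * np.abs(w) + noise, 0.0, None)
    structural = np.zeros_like(J)
    structural[iu] = s_upper
    structural = structural + structural.T
    return GroundTruth(n_regions, h, J, convention, structural, seed)


def _as_params(model) -> MEMParams:
    return model.params if isinstance(model, GroundTruth) else model


def sample_states(
    model,
    n_samples: int,
    temperature: float = 1.0,
    method: str = "exact_enumeration",
    seed: int = 0,
    *,
    burn_in: int | None = None,
    thin: int | None = None,
) -> np.ndarray:
    """Sample binary states from the model's Boltzmann distribution.

    ``exact_enumeration`` draws i.i.d. samples from the enumerated
    distribution (N <= 20); ``metropolis`` returns a burned-in, thinned
    single-flip chain and works for any N.
    """
    params = _as_params(model)
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    n = params.n_regions
    if n_samples == 0:
        return np.empty((0, n))
    if method == "exact_enumeration":
        if n > ENUMERATION_LIMIT:
            raise CapabilityError(
                f"exact enumeration requires N <= {ENUMERATION_LIMIT}; use metropolis"
            )
        rng = np.random.default_rng(seed)
        p = enumerate_distribution(params, temperature)
        idx = rng.choice(p.size, size=n_samples, p=p)
        return state_table(n, params.convention)[idx]
    if method == "metropolis":
        burn_in = 200 * n if burn_in is None else burn_in
        thin = 10 * n if thin is None else thin
        rng = np.random.default_rng(seed)
        off = -1.0 if params.convention == PM1 else 0.0
        state0 = np.where(rng.random(n) < 0.5, 1.0, off)
        chain_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
        return _mcmc.metropolis_spins(
            params.h,
            params.J,
            state0,
            burn_in + thin * n_samples,
            burn_in,
            thin,
            1.0 / temperature,
            params.convention == PM1,
            chain_seed,
        )
    raise ValueError(f"unknown sampling method {method!r}")


def _region_centers(n_regions: int, rng: np.random.Generator, arena: float, min_dist: float) -> np.ndarray:
    centers = []
    for _ in range(10_000):
        c = rng.uniform(0.0, arena, 3)
        if all(np.linalg.norm(c - prev) >= min_dist for prev in centers):
            centers.append(c)
            if len(centers) == n_regions:
                return np.array(centers)
    raise RuntimeError("could not place well-separated region centers; enlarge arena")


def states_to_traces(
    states: np.ndarray,
    neurons_per_region: int = 20,
    snr: float = 5.0,
    seed: int = 0,
    *,
    ground_truth: GroundTruth | None = None,
    arena: float = 100.0,
    blob_scale: float = 2.0,
) -> SyntheticRecording:
    """Emulate a calcium recording from a binary state raster.

    Each neuron's trace is its region's on/off level (1/0) plus Gaussian
    noise of standard deviation 1/snr; positions are Gaussian blobs around
    well-separated region centers.  The region-average trace, z-scored and
    thresholded strictly above z = 0, recovers the generating states with
    error rate -> 0 as snr -> infinity.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    states = np.atleast_2d(np.asarray(states, dtype=float))
    T, n_regions = states.shape
    rng = np.random.default_rng(seed)
    on = states > 0.5 if states.min() >= 0 else states > 0
    level = on.astype(float).T  # (N, T)

    centers = _region_centers(n_regions, rng, arena, 8.0 * blob_scale)
    region_of_neuron = np.repeat(np.arange(n_regions), neurons_per_region)
    positions = centers[region_of_neuron] + rng.normal(
        0.0, blob_scale, (n_regions * neurons_per_region, 3)
    )
    traces = level[region_of_neuron] + rng.normal(
        0.0, 1.0 / snr, (n_regions * neurons_per_region, T)
    )
    return SyntheticRecording(
        neuron_positions=positions,
        traces=traces,
        region_of_neuron=region_of_neuron,
        states_true=states,
        ground_truth=ground_truth,
        threshold_z=0.0,
    )


# ---------------------------------------------------------------------------
# I/O: HDF5 for arrays, CSV for the structural matrix, JSON for parameters


def write_recording(rec: SyntheticRecording, path) -> None:
    """Write a recording to ``path`` (an existing directory).

    Layout: recording.h5 with /traces (n_neurons x T), /positions
    (n_neurons x 3), /region_of_neuron, /states_true; structural.csv with
    region labels as header; ground_truth.json with full-precision h, J.
    """
    path = Path(path)
    if not path.is_dir():
        raise IOError(f"not a writable directory: {path}")
    with h5py.File(path / "recording.h5", "w", track_order=True) as f:
        f.create_dataset("traces", data=rec.traces, track_times=False)
        f.create_dataset("positions", data=rec.neuron_positions, track_times=False)
        f.create_dataset(
            "region_of_neuron", data=rec.region_of_neuron.astype(np.int64), track_times=False
        )
        f.create_dataset("states_true", data=rec.states_true, track_times=False)
        f.attrs["threshold_z"] = rec.threshold_z
    if rec.ground_truth is not None:
        gt = rec.ground_truth
        import pandas as pd

        labels = [f"region_{i}" for i in range(gt.n_regions)]
        pd.DataFrame(gt.structural, index=labels, columns=labels).to_csv(
            path / "structural.csv", float_format="%.17g"
        )
        (path / "ground_truth.json").write_text(
            json.dumps(
                {
                    "convention": "pm1" if gt.convention == PM1 else "01",
                    "h": gt.h_true.tolist(),
                    "J": gt.J_true.tolist(),
                    "seed": gt.seed,
                }
            )
        )


def read_recording(path) -> SyntheticRecording:
    """Read back a recording written by :func:`write_recording`."""
    path = Path(path)
    with h5py.File(path / "recording.h5", "r") as f:
        traces = f["traces"][()]
        positions = f["positions"][()]
        region = f["region_of_neuron"][()]
        states = f["states_true"][()]
        threshold_z = float(f.attrs["threshold_z"])
    gt = None
    gt_path = path / "ground_truth.json"
    if gt_path.exists():
        import pandas as pd

        d = json.loads(gt_path.read_text())
        structural = pd.read_csv(
            path / "structural.csv", index_col=0, float_precision="round_trip"
        ).to_numpy()
        h = np.array(d["h"])
        gt = GroundTruth(
            n_regions=h.size,
            h_true=h,
            J_true=np.array(d["J"]),
            convention=PM1 if d["convention"] == "pm1" else "zero_one",
            structural=structural,
            seed=int(d["seed"]),
        )
    return SyntheticRecording(positions, traces, region, states, gt, threshold_z)
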