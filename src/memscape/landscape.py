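"""Energy landscape over the 2^N binary states of a fitted pairwise model.

States are nodes of the N-dimensional hypercube (neighbors are one Hamming
distance apart).  The module finds local minima (attractor states), assigns
every state to a basin by steepest descent, and locates saddle states by the
deletion procedure: remove states in decreasing energy order and record, for
each pair of minima, the energy of the state whose removal first disconnects
them.  Implemented equivalently (and efficiently) as a union-find sweep in
increasing energy order.

Conventions for degenerate energies (ties are measure-zero for continuous
parameters but arise in symmetric fixtures):

* a state tied with a neighbor is not a local minimum (strict inequality);
* steepest descent moves to the lowest-energy neighbor, ties broken by
  smallest state index; plateau sinks (no strictly lower neighbor, not a
  minimum) are attached to their lexicographically smallest neighbor's basin
  and counted in ``n_plateau_states``;
* the deletion order breaks energy ties by removing the larger state index
  first.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .model import MEMParams, energy, state_table


@dataclasses.dataclass
class LandscapeDecomposition:
    energies: np.ndarray  # (2^N,)
    minima: np.ndarray  # state indices, sorted by energy
    basin_label: np.ndarray  # (2^N,) index into `minima`
    basin_sizes: np.ndarray  # fraction of states per minimum
    n_spins: int
    n_plateau_states: int = 0

    @property
    def basin_of_state(self) -> np.ndarray:
        """Minimum state index for every state."""
        return self.minima[self.basin_label]


@dataclasses.dataclass
class DisconnectivityGraph:
    minima: np.ndarray
    minima_energies: np.ndarray
    saddle_energy: np.ndarray  # (k, k), nan on diagonal
    barrier_asym: np.ndarray  # [i, j] = E_saddle(i,j) - E(min_i)
    barrier_sym: np.ndarray  # min of the two asymmetric barriers
    merge_tree: dict  # nested {energy, children} / {minimum, energy} nodes


def landscape_energies(params: MEMParams, temperature: float = 1.0) -> np.ndarray:
    """Energies of all 2^N states (temperature does not rescale energies)."""
    return energy(params, state_table(params.n_regions, params.convention))


def _neighbor_indices(n_spins: int) -> np.ndarray:
    idx = np.arange(2**n_spins, dtype=np.int64)
    return idx[:, None] ^ (1 << np.arange(n_spins, dtype=np.int64))


def find_minima(params: MEMParams, temperature: float = 1.0) -> np.ndarray:
    """State indices whose energy is strictly below all N Hamming-1 neighbors."""
    e = landscape_energies(params, temperature)
    nbr = _neighbor_indices(params.n_regions)
    is_min = (e[:, None] < e[nbr]).all(axis=1)
    minima = np.flatnonzero(is_min)
    if minima.size == 0:
        warnings.warn("landscape has no strict local minima (flat or fully tied)", stacklevel=2)
    return minima[np.argsort(e[minima], kind="stable")]


def assign_basins(params: MEMParams, minima: np.ndarray | None = None) -> LandscapeDecomposition:
    """Steepest-descent basin decomposition of the full state space."""
    if minima is None:
        minima = find_minima(params)
    minima = np.asarray(minima, dtype=np.int64)
    if minima.size == 0:
        raise ValueError("no minima: basin decomposition undefined on a flat landscape")
    n = params.n_regions
    e = landscape_energies(params)
    nbr = _neighbor_indices(n)
    label = np.full(e.size, -1, dtype=np.int64)
    min_rank = {int(s): k for k, s in enumerate(minima)}

    # lowest-energy neighbor, ties by smallest state index
    nbr_sorted_by_idx = np.sort(nbr, axis=1)
    best = nbr_sorted_by_idx[np.arange(e.size), np.argmin(e[nbr_sorted_by_idx], axis=1)]

    order = np.lexsort((np.arange(e.size), e))  # energy asc, index asc
    n_plateau = 0
    for s in order:
        if s in min_rank:
            label[s] = min_rank[s]
            continue
        t = best[s]
        if e[t] < e[s] or (e[t] == e[s] and label[t] >= 0):
            if e[t] == e[s]:
                n_plateau += 1
            label[s] = label[t]
        else:
            # plateau sink: tied neighborhood processed later; attach to the
            # lowest labeled neighbor, else to the global minimum basin
            n_plateau += 1
            labeled = [t for t in nbr[s] if label[t] >= 0]
            label[s] = label[min(labeled, key=lambda t: (e[t], t))] if labeled else 0
    if n_plateau:
        warnings.warn(f"{n_plateau} plateau state(s) assigned by the tie rule", stacklevel=2)
    sizes = np.bincount(label, minlength=minima.size) / e.size
    return LandscapeDecomposition(e, minima, label, sizes, n, n_plateau)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = np.arange(n, dtype=np.int64)

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        self.parent[self.find(a)] = self.find(b)


def find_saddles(params: MEMParams, minima: np.ndarray | None = None) -> DisconnectivityGraph:
    """Saddle energies and barriers between every pair of local minima.

    Dual of the deletion procedure: states are added in increasing energy
    order (ties: smaller index first, i.e. deleted later) and merged with
    already-present neighbors; the state whose addition first joins the
    components of two minima is their saddle, and its energy their saddle
    energy.  The merge tree nests minima groupings by saddle energy level.
    """
    if minima is None:
        minima = find_minima(params)
    minima = np.asarray(minima, dtype=np.int64)
    k = minima.size
    e = landscape_energies(params)
    e_min = e[minima]
    saddle = np.full((k, k), np.nan)
    np.fill_diagonal(saddle, np.nan)
    if k < 2:
        return DisconnectivityGraph(
            minima, e_min, saddle, np.full((k, k), np.nan), np.full((k, k), np.nan),
            {"minimum": int(minima[0]), "energy": float(e_min[0])} if k == 1 else {},
        )
    nbr = _neighbor_indices(params.n_regions)
    order = np.lexsort((np.arange(e.size), e))
    uf = _UnionFind(e.size)
    present = np.zeros(e.size, dtype=bool)
    rank_of_min = {int(s): i for i, s in enumerate(minima)}
    # per-root bookkeeping: minima ranks and merge-tree node per component
    comp_minima: dict[int, list[int]] = {}
    comp_node: dict[int, dict] = {}

    for s in order:
        s = int(s)
        present[s] = True
        roots = {uf.find(s)}
        for t in nbr[s]:
            t = int(t)
            if present[t]:
                roots.add(uf.find(t))
        groups = []
        for r in roots:
            if r in comp_minima:
                groups.append((comp_minima.pop(r), comp_node.pop(r)))
        if s in rank_of_min:
            groups.append(([rank_of_min[s]], {"minimum": s, "energy": float(e[s])}))
        # merge union-find components
        for t in nbr[s]:
            t = int(t)
            if present[t]:
                uf.union(s, t)
        root = uf.find(s)
        if len(groups) >= 2:
            ranks_flat = [m for g, _ in groups for m in g]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a in groups[gi][0]:
                        for b in groups[gj][0]:
                            if np.isnan(saddle[a, b]):
                                saddle[a, b] = saddle[b, a] = e[s]
            node = {"energy": float(e[s]), "children": [g[1] for g in groups]}
            comp_minima[root] = ranks_flat
            comp_node[root] = node
        elif len(groups) == 1:
            comp_minima[root] = groups[0][0]
            comp_node[root] = groups[0][1]
        if len(comp_minima) == 1 and sum(len(v) for v in comp_minima.values()) == k:
            if not np.isnan(saddle[~np.eye(k, dtype=bool)]).any():
                break
    merge_tree = next(iter(comp_node.values())) if comp_node else {}
    barrier_asym = saddle - e_min[:, None]
    barrier_sym = np.minimum(barrier_asym, barrier_asym.T)
    return DisconnectivityGraph(minima, e_min, saddle, barrier_asym, barrier_sym, merge_tree)


def landscape_summary(
    decomp: LandscapeDecomposition, dg: DisconnectivityGraph | None = None
) -> pd.DataFrame:
    """One row per minimum: state index, bit pattern, energy, basin size, barriers."""
    bits = [
        format(int(s), f"0{decomp.n_spins}b")[::-1]  # region 0 first
        for s in decomp.minima
    ]
    df = pd.DataFrame(
        {
            "state_index": decomp.minima,
            "state_bits": bits,
            "energy": decomp.energies[decomp.minima],
            "basin_size": decomp.basin_sizes,
        }
    )
    if dg is not None and dg.minima.size == decomp.minima.size:
        for j in range(dg.minima.size):
            df[f"barrier_sym_to_{int(dg.minima[j])}"] = dg.barrier_sym[:, j]
    return df


def export_decomposition(decomp: LandscapeDecomposition, path) -> None:
    """CSV export: one row per state (index, bits, energy, basin label)."""
    n_states = decomp.energies.size
    bits = [format(i, f"0{decomp.n_spins}b")[::-1] for i in range(n_states)]
    pd.DataFrame(
        {
            "state_index": np.arange(n_states),
            "state_bits": bits,
            "energy": decomp.energies,
            "basin_minimum": decomp.basin_of_state,
        }
    ).to_csv(path, index=False)
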