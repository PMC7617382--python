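"""Numba Metropolis kernels.

Two chain representations:

* bit chain — states are integer indices into a precomputed 2^N energy
  table; a proposal flips one bit (XOR).  Used wherever the state space is
  enumerable (N <= 20).
* spin chain — states are explicit spin vectors; the energy change of a
  single flip is computed from (h, J) in O(N).  Works for any N.

Both draw, per step, first the flip index and then the acceptance uniform,
from numba's seeded legacy RNG, so chains are bit-reproducible for a given
integer seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def metropolis_bits(energies, n_spins, n_steps, start_state, beta, seed):
    """Single-flip Metropolis walk over state indices; returns the full path.

    Acceptance probability min[1, exp(-beta * (E' - E))].
    """
    np.random.seed(seed)
    path = np.empty(n_steps, dtype=np.int64)
    s = start_state
    e = energies[s]
    for t in range(n_steps):
        k = np.random.randint(0, n_spins)
        prop = s ^ (1 << k)
        de = energies[prop] - e
        if de <= 0.0 or np.random.random() < np.exp(-beta * de):
            s = prop
            e = energies[prop]
        path[t] = s
    return path


@njit(cache=True)
def metropolis_spins(h, J, state0, n_steps, burn_in, thin, beta, pm1, seed):
    """Single-flip Metropolis over explicit spin vectors; thinned samples.

    ``state0`` is modified in place and holds the final state on return.
    Returns an (n_kept, N) array of recorded states.
    """
    np.random.seed(seed)
    n = h.size
    s = state0
    n_kept = (n_steps - burn_in) // thin
    out = np.empty((n_kept, n), dtype=np.float64)
    kept = 0
    for t in range(n_steps):
        k = np.random.randint(0, n)
        v = s[k]
        vnew = -v if pm1 else 1.0 - v
        field = h[k]
        for j in range(n):
            field += J[k, j] * s[j]
        de = -(vnew - v) * field
        if de <= 0.0 or np.random.random() < np.exp(-beta * de):
            s[k] = vnew
        if t >= burn_in and (t - burn_in) % thin == thin - 1 and kept < n_kept:
            out[kept] = s
            kept += 1
    return out[:kept]
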