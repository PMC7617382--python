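"""Pairwise maximum-entropy (Ising) model: representation, enumeration and fitting.

The model assigns every binary activity pattern sigma an energy

    E(sigma) = - sum_i h_i sigma_i - 1/2 sum_{i != j} J_ij sigma_i sigma_j

and probability P(sigma) = exp(-E/T) / Z.  ``h_i`` is the activation bias of
region i and ``J_ij`` the symmetric pairwise functional interaction.  Two
state conventions are supported: spins in {-1, +1} (``plus_minus_one``) and
occupation variables in {0, 1} (``zero_one``); :func:`convert_convention`
maps parameters between them without changing the distribution.

Fitting comes in two flavours:

* :func:`fit_exact` — likelihood maximisation by moment matching against the
  exactly enumerated Boltzmann distribution (feasible for N <= 20, intended
  for N <= 15);
* :func:`fit_pseudolikelihood` — gradient ascent on the pseudo-likelihood
  (product of single-region conditionals), which converges to the maximum
  likelihood estimate as the number of samples grows and scales to larger N.

:class:`PairwiseMaxEnt` wraps both behind a scikit-learn estimator interface.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
from scipy.special import expit, logsumexp
from sklearn.base import BaseEstimator

PM1 = "plus_minus_one"
ZO = "zero_one"
CONVENTIONS = (PM1, ZO)

#: largest N for which the 2^N state space is enumerated
ENUMERATION_LIMIT = 20
#: default switchover between exact and pseudo-likelihood fitting
EXACT_FIT_LIMIT = 15


class CapabilityError(ValueError):
    """Requested an exact computation beyond the enumerable state-space size."""


class BoundaryMomentError(ValueError):
    """Target moments on the boundary of the moment polytope (infinite parameters)."""


class ConvergenceError(RuntimeError):
    """A fit diverged (non-finite parameters)."""


def _check_convention(convention: str) -> str:
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; expected one of {CONVENTIONS}")
    return convention


@dataclasses.dataclass
class MEMParams:
    """Parameters (h, J) of a pairwise maximum-entropy model.

    Attributes
    ----------
    h : (N,) array
        Activation biases.
    J : (N, N) array
        Symmetric couplings with zero diagonal.
    convention : {"plus_minus_one", "zero_one"}
        The binary alphabet the states live in.
    """

    h: np.ndarray
    J: np.ndarray
    convention: str = PM1

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float).ravel()
        self.J = np.asarray(self.J, dtype=float)
        _check_convention(self.convention)
        n = self.h.size
        if self.J.shape != (n, n):
            raise ValueError(f"J must be {(n, n)}, got {self.J.shape}")
        if not (np.isfinite(self.h).all() and np.isfinite(self.J).all()):
            raise ValueError("h and J must be finite")
        if not np.allclose(self.J, self.J.T, atol=1e-10):
            raise ValueError("J must be symmetric")
        if np.abs(np.diag(self.J)).max(initial=0.0) > 1e-12:
            raise ValueError("J must have zero diagonal")
        # normalise exactly
        self.J = (self.J + self.J.T) / 2.0
        np.fill_diagonal(self.J, 0.0)

    @property
    def n_regions(self) -> int:
        return self.h.size

    def to_dict(self) -> dict:
        return {
            "convention": self.convention,
            "h": self.h.tolist(),
            "J": self.J.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MEMParams":
        return cls(h=np.array(d["h"]), J=np.array(d["J"]), convention=d["convention"])

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "MEMParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclasses.dataclass
class MomentSet:
    """First and second moments <sigma_i>, <sigma_i sigma_j> of a binary raster."""

    means: np.ndarray
    second_moments: np.ndarray
    n_samples: int = 0

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float).ravel()
        self.second_moments = np.asarray(self.second_moments, dtype=float)


@dataclasses.dataclass
class FitReport:
    params: MEMParams
    iterations: int
    max_moment_error: float
    converged: bool
    method: str
    error_history: list = dataclasses.field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "iterations": self.iterations,
            "max_moment_error": self.max_moment_error,
            "converged": self.converged,
            "method": self.method,
            "error_history": list(self.error_history),
        }


# ---------------------------------------------------------------------------
# state-space utilities


def state_table(n_regions: int, convention: str = PM1) -> np.ndarray:
    """All 2^N states as a (2^N, N) array.

    Region 0 is the least significant bit of the state index, so state index
    ``s`` has region i on iff ``(s >> i) & 1``.
    """
    _check_convention(convention)
    if n_regions > ENUMERATION_LIMIT:
        raise CapabilityError(
            f"enumeration requires N <= {ENUMERATION_LIMIT}, got {n_regions}"
        )
    idx = np.arange(2**n_regions, dtype=np.int64)
    bits = ((idx[:, None] >> np.arange(n_regions)) & 1).astype(float)
    return 2.0 * bits - 1.0 if convention == PM1 else bits


def states_to_index(states: np.ndarray, convention: str = PM1) -> np.ndarray:
    """Map states (rows) to their enumeration indices (region 0 = LSB)."""
    states = np.atleast_2d(np.asarray(states))
    on = states > 0 if convention == PM1 else states > 0.5
    weights = (1 << np.arange(states.shape[1])).astype(np.int64)
    return on.astype(np.int64) @ weights


def validate_states(states: np.ndarray, convention: str) -> np.ndarray:
    """Check that all entries belong to the convention's alphabet."""
    _check_convention(convention)
    states = np.asarray(states, dtype=float)
    lo, hi = (-1.0, 1.0) if convention == PM1 else (0.0, 1.0)
    vals = np.unique(states)
    if not np.all(np.isin(vals, [lo, hi])):
        raise ValueError(
            f"states contain values {vals} outside the {convention} alphabet {{{lo}, {hi}}}"
        )
    return states


def energy(params: MEMParams, states: np.ndarray) -> np.ndarray:
    """Energy E(sigma) of one state (shape (N,)) or a stack of states (T, N)."""
    states = np.asarray(states, dtype=float)
    single = states.ndim == 1
    s = np.atleast_2d(states)
    if s.shape[1] != params.n_regions:
        raise ValueError("state dimension does not match params")
    validate_states(s, params.convention)
    e = -s @ params.h - 0.5 * np.einsum("ti,ij,tj->t", s, params.J, s)
    return float(e[0]) if single else e


def enumerate_distribution(params: MEMParams, temperature: float = 1.0) -> np.ndarray:
    """Boltzmann probabilities over all 2^N states (log-sum-exp stabilised)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    S = state_table(params.n_regions, params.convention)
    logw = -energy(params, S) / temperature
    return np.exp(logw - logsumexp(logw))


def model_moments(params: MEMParams, temperature: float = 1.0) -> MomentSet:
    """Exact <sigma_i> and <sigma_i sigma_j> under the Boltzmann distribution."""
    S = state_table(params.n_regions, params.convention)
    p = enumerate_distribution(params, temperature)
    means = p @ S
    second = S.T @ (p[:, None] * S)
    return MomentSet(means=means, second_moments=second, n_samples=0)


def moments_from_states(states: np.ndarray, convention: str = PM1) -> MomentSet:
    """Empirical moments of a T x N binary raster."""
    s = validate_states(np.atleast_2d(states), convention)
    T = s.shape[0]
    if T < 1:
        raise ValueError("need at least one sample")
    return MomentSet(means=s.mean(axis=0), second_moments=s.T @ s / T, n_samples=T)


# ---------------------------------------------------------------------------
# convention conversion


def convert_convention(params: MEMParams, to: str) -> MEMParams:
    """Re-express (h, J) in the other binary alphabet, same distribution.

    Under the affine map s = 2*sigma - 1 the energies of corresponding states
    differ only by a state-independent constant absorbed by Z, with
    J01 = 4*Jpm and h01 = 2*hpm - 2*Jpm.sum(axis=1).
    """
    _check_convention(to)
    if to == params.convention:
        return MEMParams(params.h.copy(), params.J.copy(), params.convention)
    if params.convention == PM1:  # pm1 -> 01
        J = 4.0 * params.J
        h = 2.0 * params.h - 2.0 * params.J.sum(axis=1)
    else:  # 01 -> pm1
        J = params.J / 4.0
        h = params.h / 2.0 + params.J.sum(axis=1) / 4.0
    return MEMParams(h=h, J=J, convention=to)


# ---------------------------------------------------------------------------
# fitting


def _check_interior_moments(target: MomentSet, convention: str, eps: float = 1e-9) -> None:
    """Reject moments on the boundary of the attainable polytope.

    Uses the exact pairwise cell probabilities: for every pair (i, j) the four
    joint on/off frequencies implied by (means, second moments) must be
    strictly positive, otherwise the maximising parameters are infinite.
    """
    m = target.means
    q = target.second_moments
    n = m.size
    if convention == PM1:
        if np.any(np.abs(m) >= 1 - eps):
            i = int(np.argmax(np.abs(m)))
            raise BoundaryMomentError(
                f"mean of region {i} is at the boundary (<sigma_{i}> = {m[i]:.6g}); "
                "lower the binarization threshold or merge clusters"
            )
        for i in range(n):
            for j in range(i + 1, n):
                cells = np.array(
                    [
                        1 + m[i] + m[j] + q[i, j],
                        1 + m[i] - m[j] - q[i, j],
                        1 - m[i] + m[j] - q[i, j],
                        1 - m[i] - m[j] + q[i, j],
                    ]
                ) / 4.0
                if cells.min() < eps:
                    raise BoundaryMomentError(
                        f"pair moment ({i},{j}) is at the boundary "
                        f"(<sigma_i sigma_j> = {q[i, j]:.6g}); "
                        "lower the binarization threshold or merge clusters"
                    )
    else:
        if np.any(m <= eps) or np.any(m >= 1 - eps):
            i = int(np.argmin(np.minimum(m, 1 - m)))
            raise BoundaryMomentError(
                f"mean of region {i} is at the boundary (<sigma_{i}> = {m[i]:.6g})"
            )
        for i in range(n):
            for j in range(i + 1, n):
                cells = np.array(
                    [q[i, j], m[i] - q[i, j], m[j] - q[i, j], 1 - m[i] - m[j] + q[i, j]]
                )
                if cells.min() < eps:
                    raise BoundaryMomentError(
                        f"pair moment ({i},{j}) is at the boundary "
                        f"(<sigma_i sigma_j> = {q[i, j]:.6g})"
                    )


def _moment_error(target: MomentSet, model: MomentSet) -> float:
    dh = np.abs(target.means - model.means).max()
    dq = np.abs(target.second_moments - model.second_moments)
    np.fill_diagonal(dq, 0.0)
    return float(max(dh, dq.max()))


def fit_exact(
    target: MomentSet,
    convention: str = PM1,
    init: MEMParams | None = None,
    learning_rate: float = 0.1,
    tolerance: float = 1e-4,
    max_iter: int = 200_000,
) -> FitReport:
    """Maximum-likelihood fit by moment-matching gradient descent.

    Iterates h <- h + eps*(<sigma_i>_data - <sigma_i>_model) and similarly for
    J against exactly enumerated model moments, until the largest absolute
    moment discrepancy falls below ``tolerance``.  The step size decays
    geometrically when the error oscillates and grows slowly otherwise.
    """
    _check_convention(convention)
    n = target.means.size
    if n > ENUMERATION_LIMIT:
        raise CapabilityError(f"exact fit requires N <= {ENUMERATION_LIMIT}")
    _check_interior_moments(target, convention)

    if init is not None:
        h = init.h.copy()
        J = init.J.copy()
    else:
        h = np.zeros(n)
        J = np.zeros((n, n))
    S = state_table(n, convention)
    q_target = target.second_moments.copy()
    q_target = (q_target + q_target.T) / 2.0

    lr = learning_rate
    prev_err = np.inf
    err = np.inf
    history: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        logw = S @ h + 0.5 * np.einsum("ti,ij,tj->t", S, J, S)
        p = np.exp(logw - logsumexp(logw))
        m_model = p @ S
        q_model = S.T @ (p[:, None] * S)
        gh = target.means - m_model
        gq = q_target - q_model
        np.fill_diagonal(gq, 0.0)
        err = float(max(np.abs(gh).max(), np.abs(gq).max()))
        if it <= 50 or it % 50 == 0:
            history.append(err)
        if err <= tolerance:
            break
        if err > prev_err:
            lr = max(lr * 0.5, learning_rate * 1e-4)
        else:
            lr = min(lr * 1.02, learning_rate * 10)
        prev_err = err
        h += lr * gh
        J += lr * gq
    converged = err <= tolerance
    params = MEMParams(h=h, J=J, convention=convention)
    return FitReport(params, it, err, converged, "exact_gradient", history)


def _conditional_means(h: np.ndarray, J: np.ndarray, X: np.ndarray, convention: str) -> np.ndarray:
    """E[sigma_i | rest] for every sample row, per convention.

    tanh(h_i + sum_j J_ij sigma_j) for {-1,+1}; the logistic form
    1/(1+exp(-(h_i + sum_j J_ij sigma_j))) for {0,1}.  Both follow from the
    single-site Boltzmann conditional; the diagonal of J is zero, so the sum
    may run over all j.
    """
    field = X @ J.T + h
    return np.tanh(field) if convention == PM1 else expit(field)


def fit_pseudolikelihood(
    states: np.ndarray,
    convention: str = PM1,
    learning_rate: float = 0.1,
    tolerance: float = 1e-4,
    max_iter: int = 50_000,
) -> FitReport:
    """Pseudo-likelihood maximisation by gradient ascent.

    Ascends the product of single-region conditional likelihoods with the
    update rules h_i += eps*(<sigma_i>_emp - <sigma_i>_cond) and
    J_ij += eps*(<sigma_i sigma_j>_emp - <sigma_j(t) E[sigma_i|rest]>_t).
    The per-row (directed) estimates are averaged into a symmetric J after
    convergence.  Consistent: converges to the MLE as T grows.
    """
    X = validate_states(np.atleast_2d(states), convention)
    T, n = X.shape
    if T < 2:
        raise ValueError("need at least two samples")
    const = np.flatnonzero(X.std(axis=0) == 0)
    if const.size:
        raise BoundaryMomentError(
            f"region(s) {const.tolist()} are constant over time; cannot fit"
        )
    # sufficient statistics live on unique rows: collapse for speed
    Xu, counts = np.unique(X, axis=0, return_counts=True)
    w = counts / T
    emp = moments_from_states(X, convention)
    q_emp = emp.second_moments

    h = np.zeros(n)
    J = np.zeros((n, n))
    lr = learning_rate
    prev_err = np.inf
    err = np.inf
    history: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        cond = _conditional_means(h, J, Xu, convention)  # (U, n)
        m_model = w @ cond
        # <sigma_j(t) * E[sigma_i | rest_t]>_t  (directed, row i)
        q_model = cond.T @ (w[:, None] * Xu)
        gh = emp.means - m_model
        gq = q_emp - q_model
        np.fill_diagonal(gq, 0.0)
        err = float(max(np.abs(gh).max(), np.abs(gq).max()))
        if it <= 50 or it % 50 == 0:
            history.append(err)
        if err <= tolerance:
            break
        if err > prev_err:
            lr = max(lr * 0.5, learning_rate * 1e-4)
        else:
            lr = min(lr * 1.02, learning_rate * 10)
        prev_err = err
        h += lr * gh
        J += lr * gq
        if not (np.isfinite(h).all() and np.isfinite(J).all()):
            raise ConvergenceError(
                "pseudo-likelihood ascent diverged; try a smaller learning rate"
            )
    J = (J + J.T) / 2.0
    np.fill_diagonal(J, 0.0)
    params = MEMParams(h=h, J=J, convention=convention)
    return FitReport(params, it, err, err <= tolerance, "pseudo_likelihood", history)


# ---------------------------------------------------------------------------
# scikit-learn estimator


class PairwiseMaxEnt(BaseEstimator):
    """Pairwise maximum-entropy (Ising) model as a scikit-learn estimator.

    Parameters
    ----------
    method : {"auto", "exact", "pseudolikelihood"}
        Fitting route.  "auto" uses the exact likelihood fit up to
        ``exact_max_n`` regions and pseudo-likelihood beyond.
    convention : {"plus_minus_one", "zero_one"}
        Alphabet of the input raster.
    learning_rate, tol, max_iter
        Gradient-scheme controls shared by both fitters.
    exact_max_n : int
        Switchover dimension for "auto".

    Attributes
    ----------
    h_ : (N,) ndarray of fitted activation biases.
    J_ : (N, N) ndarray of fitted symmetric couplings.
    n_iter_ : iterations used.
    converged_ : whether the tolerance was reached.
    report_ : full :class:`FitReport`.

    Examples
    --------
    >>> import numpy as np
    >>> from memscape.model import PairwiseMaxEnt
    >>> rng = np.random.default_rng(0)
    >>> X = rng.choice([-1.0, 1.0], size=(5000, 4))
    >>> est = PairwiseMaxEnt().fit(X)
    >>> est.J_.shape
    (4, 4)
    """

    def __init__(
        self,
        method: str = "auto",
        convention: str = PM1,
        learning_rate: float = 0.1,
        tol: float = 1e-4,
        max_iter: int = 200_000,
        exact_max_n: int = EXACT_FIT_LIMIT,
        random_state: int | None = None,
    ):
        self.method = method
        self.convention = convention
        self.learning_rate = learning_rate
        self.tol = tol
        self.max_iter = max_iter
        self.exact_max_n = exact_max_n
        self.random_state = random_state

    def fit(self, X, y=None):
        X = validate_states(np.atleast_2d(np.asarray(X, dtype=float)), self.convention)
        n = X.shape[1]
        method = self.method
        if method == "auto":
            method = "exact" if n <= self.exact_max_n else "pseudolikelihood"
        if method == "exact":
            report = fit_exact(
                moments_from_states(X, self.convention),
                convention=self.convention,
                learning_rate=self.learning_rate,
                tolerance=self.tol,
                max_iter=self.max_iter,
            )
        elif method == "pseudolikelihood":
            report = fit_pseudolikelihood(
                X,
                convention=self.convention,
                learning_rate=self.learning_rate,
                tolerance=self.tol,
                max_iter=self.max_iter,
            )
        else:
            raise ValueError(f"unknown method {self.method!r}")
        if not report.converged:
            warnings.warn(
                f"fit did not reach tolerance {self.tol} in {report.iterations} "
                f"iterations (max moment error {report.max_moment_error:.3g})",
                stacklevel=2,
            )
        self.report_ = report
        self.h_ = report.params.h
        self.J_ = report.params.J
        self.convention_ = self.convention
        self.n_features_in_ = n
        self.n_iter_ = report.iterations
        self.converged_ = report.converged
        return self

    @property
    def params_(self) -> MEMParams:
        return MEMParams(h=self.h_, J=self.J_, convention=self.convention_)

    def energy(self, X) -> np.ndarray:
        return energy(self.params_, X)

    def log_prob(self, X) -> np.ndarray:
        """Exact log P(sigma) per row (requires N <= 20)."""
        p = enumerate_distribution(self.params_)
        idx = states_to_index(np.atleast_2d(X), self.convention_)
        return np.log(p[idx])

    def score(self, X, y=None) -> float:
        """Mean log-likelihood per sample (exact, N <= 20)."""
        return float(np.mean(self.log_prob(X)))

    def sample(self, n_samples: int, temperature: float = 1.0, method: str = "metropolis", seed: int | None = None):
        from .synthetic import sample_states  # local import to avoid cycle

        seed = self.random_state if seed is None else seed
        return sample_states(
            self.params_, n_samples, temperature=temperature, method=method, seed=seed or 0
        )
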