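"""Unit and property tests for the pairwise model core."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.base import clone

from memscape.model import (
    PM1,
    ZO,
    BoundaryMomentError,
    CapabilityError,
    MEMParams,
    MomentSet,
    PairwiseMaxEnt,
    convert_convention,
    energy,
    enumerate_distribution,
    fit_exact,
    fit_pseudolikelihood,
    model_moments,
    moments_from_states,
    state_table,
    states_to_index,
)
from memscape.synthetic import sample_states


def test_energy_hand_values():
    p = MEMParams(h=np.array([1.0, -1.0]), J=np.array([[0, 0.5], [0.5, 0]]))
    assert energy(p, np.array([1.0, 1.0])) == pytest.approx(-0.5)
    p0 = MEMParams(h=np.zeros(3), J=np.zeros((3, 3)))
    S = state_table(3, PM1)
    assert np.allclose(energy(p0, S), 0.0)


def test_energy_spin_flip_symmetry(random_params):
    p = random_params(5, seed=3)
    p = MEMParams(h=np.zeros(5), J=p.J)  # h = 0
    S = state_table(5, PM1)
    assert np.allclose(energy(p, S), energy(p, -S))


def test_energy_rejects_wrong_alphabet():
    p = MEMParams(h=np.zeros(2), J=np.zeros((2, 2)), convention=PM1)
    with pytest.raises(ValueError, match="alphabet"):
        energy(p, np.array([0.0, 1.0]))


def test_params_validation():
    with pytest.raises(ValueError, match="symmetric"):
        MEMParams(h=np.zeros(2), J=np.array([[0, 1.0], [0.5, 0]]))
    with pytest.raises(ValueError, match="diagonal"):
        MEMParams(h=np.zeros(2), J=np.array([[1.0, 0], [0, 1.0]]))


def test_enumeration_closed_forms():
    # h = 0, J = 0 -> uniform
    p0 = MEMParams(h=np.zeros(4), J=np.zeros((4, 4)))
    assert np.allclose(enumerate_distribution(p0), 1 / 16)
    # single +-1 spin, h = 1: P(+1) = e / (e + 1/e)
    p1 = MEMParams(h=np.array([1.0]), J=np.zeros((1, 1)))
    d = enumerate_distribution(p1)
    assert d[1] == pytest.approx(np.e / (np.e + np.exp(-1)), abs=1e-12)
    # T -> infinity: uniform limit
    d_hot = enumerate_distribution(p1, temperature=1e6)
    assert np.abs(d_hot - 0.5).max() < 1e-5


def test_enumeration_capability_limit():
    n = 21
    with pytest.raises(CapabilityError):
        enumerate_distribution(MEMParams(h=np.zeros(n), J=np.zeros((n, n))))


def test_model_moments_two_spin_ferromagnet():
    p = MEMParams(h=np.zeros(2), J=np.array([[0, 1.0], [1.0, 0]]))
    m = model_moments(p)
    assert m.second_moments[0, 1] == pytest.approx(np.tanh(1.0), abs=1e-12)
    assert np.allclose(m.means, 0.0, atol=1e-12)
    # internal consistency with the enumerated distribution
    S = state_table(2, PM1)
    d = enumerate_distribution(p)
    assert np.allclose(m.means, d @ S)


def test_states_to_index_lsb_convention():
    # region 0 is the least significant bit
    s = np.array([[1.0, -1.0, -1.0], [-1.0, -1.0, 1.0]])
    assert states_to_index(s, PM1).tolist() == [1, 4]


class TestFitExact:
    def test_parameter_recovery(self, random_params):
        p0 = random_params(6, scale=0.3, seed=11)
        rep = fit_exact(model_moments(p0), convention=PM1, tolerance=1e-6)
        assert rep.converged
        assert np.abs(rep.params.h - p0.h).max() < 1e-3
        assert np.abs(rep.params.J - p0.J).max() < 1e-3

    def test_independent_spins_give_zero_couplings(self):
        rng = np.random.default_rng(0)
        means = rng.uniform(-0.5, 0.5, 5)
        q = np.outer(means, means)
        np.fill_diagonal(q, 1.0)
        rep = fit_exact(MomentSet(means, q), convention=PM1, tolerance=1e-5)
        assert np.abs(rep.params.J).max() < 1e-4

    def test_uniform_target_gives_zero_params(self):
        target = MomentSet(np.zeros(4), np.eye(4))
        rep = fit_exact(target, convention=PM1)
        assert np.abs(rep.params.h).max() <= 1e-4
        assert np.abs(rep.params.J).max() <= 1e-4

    def test_fixed_point_moments_match(self, random_params):
        p0 = random_params(5, seed=2)
        target = model_moments(p0)
        rep = fit_exact(target, convention=PM1, tolerance=1e-5)
        got = model_moments(rep.params)
        assert np.abs(got.means - target.means).max() <= 1e-5
        off = ~np.eye(5, dtype=bool)
        assert np.abs((got.second_moments - target.second_moments)[off]).max() <= 1e-5

    def test_boundary_moments_rejected(self):
        means = np.array([1.0, 0.0])  # always-on region
        q = np.eye(2)
        with pytest.raises(BoundaryMomentError, match="region 0"):
            fit_exact(MomentSet(means, q), convention=PM1)
        # perfectly correlated pair
        q = np.ones((2, 2))
        with pytest.raises(BoundaryMomentError, match="pair"):
            fit_exact(MomentSet(np.zeros(2), q), convention=PM1)


class TestFitPseudolikelihood:
    def test_consistency_with_truth(self, gt12):
        X = sample_states(gt12, 100_000, method="exact_enumeration", seed=1)
        rep = fit_pseudolikelihood(X, convention=PM1)
        iu = np.triu_indices(12, k=1)
        assert np.corrcoef(rep.params.J[iu], gt12.J_true[iu])[0, 1] >= 0.95
        assert np.corrcoef(rep.params.h, gt12.h_true)[0, 1] >= 0.9

    def test_agreement_with_exact_fit(self, random_params):
        p0 = random_params(10, scale=0.25, seed=4)
        X = sample_states(p0, 100_000, method="exact_enumeration", seed=2)
        pl = fit_pseudolikelihood(X, convention=PM1)
        ex = fit_exact(moments_from_states(X, PM1), convention=PM1)
        iu = np.triu_indices(10, k=1)
        assert np.corrcoef(pl.params.J[iu], ex.params.J[iu])[0, 1] >= 0.98
        assert np.abs(pl.params.J - ex.params.J).max() < 0.05

    def test_independent_raster_shrinks_couplings(self):
        rng = np.random.default_rng(3)
        X = np.where(rng.random((50_000, 6)) < 0.4, 1.0, -1.0)
        rep = fit_pseudolikelihood(X, convention=PM1)
        assert np.abs(rep.params.J).max() < 0.03

    def test_constant_cluster_rejected(self):
        X = np.ones((100, 3))
        X[:, 1] = np.where(np.arange(100) % 2, 1.0, -1.0)
        with pytest.raises(BoundaryMomentError, match="constant"):
            fit_pseudolikelihood(X, convention=PM1)

    def test_01_convention_conditional_agrees_with_pm1(self, random_params):
        # fitting the same data in either alphabet must give the same model
        p0 = random_params(6, scale=0.3, seed=9)
        X = sample_states(p0, 40_000, method="exact_enumeration", seed=5)
        rep_pm = fit_pseudolikelihood(X, convention=PM1)
        rep_01 = fit_pseudolikelihood((X + 1) / 2, convention=ZO)
        back = convert_convention(rep_01.params, PM1)
        assert np.abs(back.J - rep_pm.params.J).max() < 0.05
        assert np.abs(back.h - rep_pm.params.h).max() < 0.05


class TestConvertConvention:
    @given(st.integers(0, 1000))
    def test_round_trip_and_distribution_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        iu = np.triu_indices(n, k=1)
        J = np.zeros((n, n))
        J[iu] = rng.normal(0, 0.4, len(iu[0]))
        p = MEMParams(h=rng.normal(0, 0.5, n), J=J + J.T, convention=PM1)
        q = convert_convention(p, ZO)
        back = convert_convention(q, PM1)
        assert np.allclose(back.h, p.h, atol=1e-12)
        assert np.allclose(back.J, p.J, atol=1e-12)
        # same on-bit index ordering => direct comparison of probabilities
        tv = 0.5 * np.abs(enumerate_distribution(p) - enumerate_distribution(q)).sum()
        assert tv <= 1e-12

    def test_zero_params_stay_uniform(self):
        p = MEMParams(h=np.zeros(3), J=np.zeros((3, 3)), convention=PM1)
        q = convert_convention(p, ZO)
        assert np.allclose(enumerate_distribution(q), 1 / 8)


def test_maximum_entropy_among_moment_matched_distributions(random_params):
    """Perturbing the fitted distribution within the moment constraints
    can only lower the entropy."""
    p0 = random_params(3, seed=8)
    rep = fit_exact(model_moments(p0), convention=PM1, tolerance=1e-8)
    d = enumerate_distribution(rep.params)
    S = state_table(3, PM1)
    # constraint matrix: normalization, means, pairwise second moments
    rows = [np.ones(8)]
    rows += [S[:, i] for i in range(3)]
    rows += [S[:, i] * S[:, j] for i in range(3) for j in range(i + 1, 3)]
    A = np.vstack(rows)
    _, _, vt = np.linalg.svd(A)
    null = vt[np.linalg.matrix_rank(A):]
    ent = -(d * np.log(d)).sum()
    rng = np.random.default_rng(0)
    for _ in range(50):
        direction = null.T @ rng.normal(size=null.shape[0])
        for eps in (1e-3, 1e-2):
            d2 = d + eps * direction
            if (d2 <= 0).any():
                continue
            assert -(d2 * np.log(d2)).sum() <= ent + 1e-12


class TestPairwiseMaxEnt:
    def test_sklearn_api(self, gt8):
        est = PairwiseMaxEnt(tol=1e-3)
        assert clone(est).get_params()["tol"] == 1e-3
        X = sample_states(gt8, 20_000, method="exact_enumeration", seed=1)
        est.fit(X)
        assert est.J_.shape == (8, 8)
        assert est.converged_
        assert np.allclose(est.J_, est.J_.T)
        iu = np.triu_indices(8, k=1)
        assert np.corrcoef(est.J_[iu], gt8.J_true[iu])[0, 1] > 0.9

    def test_auto_switchover_uses_pseudolikelihood(self):
        rng = np.random.default_rng(0)
        X = np.where(rng.random((500, 4)) < 0.5, 1.0, -1.0)
        est = PairwiseMaxEnt(method="auto", exact_max_n=3, tol=1e-3).fit(X)
        assert est.report_.method == "pseudo_likelihood"

    def test_score_is_mean_log_likelihood(self, gt8):
        X = sample_states(gt8, 5_000, method="exact_enumeration", seed=3)
        est = PairwiseMaxEnt(tol=1e-3).fit(X)
        d = enumerate_distribution(est.params_)
        idx = states_to_index(X, PM1)
        assert est.score(X) == pytest.approx(np.log(d[idx]).mean())
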