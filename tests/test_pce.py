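import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oxymap.params import ParameterSet, UncertainParameter
from oxymap.pce import (
    basis_eval,
    build_design,
    ensemble_moments,
    fit_pce,
    hermite,
    multi_indices,
    sobol_decompose,
)

from .oracles import gauss_hermite_nodes_via_jacobi, mc_projection

# Frozen 1-D 5-point standardized Gauss-Hermite nodes (eigenvalues of
# the probabilists' Jacobi matrix, recomputed by the oracle below).
NODES_5 = [-2.856970013872806, -1.355626179974266, 0.0, 1.355626179974266, 2.856970013872806]


@pytest.mark.parametrize(
    "n, x, expected",
    [(0, 7.3, 1.0), (1, 2.0, 2.0), (2, 2.0, 3.0), (3, 2.0, 2.0)],
)
def test_hermite_closed_forms(n, x, expected):
    assert hermite(n, x) == pytest.approx(expected)


@given(n=st.integers(0, 10), x=st.floats(-5.0, 5.0))
def test_hermite_matches_numpy_hermite_e(n, x):
    from numpy.polynomial import hermite_e

    c = np.zeros(n + 1)
    c[n] = 1.0
    assert hermite(n, x) == pytest.approx(float(hermite_e.hermeval(x, c)), rel=1e-10, abs=1e-10)


@pytest.mark.parametrize(
    "alpha, xi, expected",
    [
        ((0, 0, 0), (3.7, -1.2, 0.4), 1.0),
        ((2, 0, 0), (2.0, 0.0, 0.0), 3.0 / math.sqrt(2.0)),
        ((1, 1, 1), (1.0, 1.0, 1.0), 1.0),
    ],
)
def test_basis_eval_orthonormal_normalization(alpha, xi, expected):
    assert basis_eval(alpha, np.array(xi)) == pytest.approx(expected)


def test_multi_index_basis_has_twenty_members_and_constant_first():
    basis = multi_indices(max_order=3, ndim=3)
    assert len(basis) == 20
    assert basis[0] == (0, 0, 0)
    assert all(sum(a) <= 3 for a in basis)
    assert len(set(basis)) == 20


class TestBuildDesign:
    def test_default_design_has_125_runs(self, design):
        assert design.n_runs == 125
        assert design.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(design.weights > 0)

    def test_single_point_rule_sits_at_the_means(self, params):
        d = build_design(params, points_per_dim=1)
        assert d.n_runs == 1
        assert d.nodes_std[0] == pytest.approx([0.0, 0.0, 0.0])
        assert d.nodes_phys[0] == pytest.approx(params.means)
        assert d.weights[0] == pytest.approx(1.0)

    def test_five_point_nodes_match_jacobi_eigenvalue_oracle(self, design):
        got = np.sort(np.unique(np.round(design.nodes_std[:, 0], 12)))
        oracle = gauss_hermite_nodes_via_jacobi(5)
        assert got == pytest.approx(oracle, abs=1e-10)
        assert got == pytest.approx(NODES_5, abs=1e-12)

    def test_nodes_symmetric_about_zero(self, design):
        for dim in range(3):
            vals = np.sort(np.unique(np.round(design.nodes_std[:, dim], 12)))
            assert vals == pytest.approx(-vals[::-1])

    def test_physical_nodes_respect_floor(self, design, params):
        for dim, p in enumerate(params):
            assert design.nodes_phys[:, dim].min() >= p.floor - 1e-15
        # with 50% relative sd the lowest node (-2.857 sd) would be
        # negative untruncated, so the clip engages for w and kappa
        for dim, p in [(0, params["w"]), (1, params["kappa"])]:
            assert (1 + p.rel_sd * design.nodes_std[:, dim].min()) * p.mean < p.floor

    def test_rejects_nonpositive_resolution(self, params):
        with pytest.raises(ValueError):
            build_design(params, points_per_dim=0)


def test_quadrature_orthonormality(design):
    """sum_q w_q psi_a psi_b = delta_ab for all pairs the 5-point rule
    integrates exactly (per-dimension degree sums <= 9)."""
    basis = [a for a in __import__("itertools").product(range(5), repeat=3)]
    psi = np.stack([basis_eval(a, design.nodes_std) for a in basis])
    gram = (psi * design.weights) @ psi.T
    # keep only pairs within the exactness degree of the rule
    for i, a in enumerate(basis):
        for j, b in enumerate(basis):
            if all(ai + bi <= 9 for ai, bi in zip(a, b)):
                expected = 1.0 if a == b else 0.0
                assert abs(gram[i, j] - expected) < 1e-10, (a, b)


class TestFitPCE:
    def test_constant_output_gives_constant_expansion(self, design):
        pce = fit_pce(design, np.full(design.n_runs, 9.5))
        assert pce.coeffs[0, 0] == pytest.approx(9.5)
        assert np.all(np.abs(pce.coeffs[1:]) < 1e-10)

    def test_linear_output_projects_onto_first_order_term(self, design):
        pce = fit_pce(design, design.nodes_std[:, 0])
        idx = pce.basis.index((1, 0, 0))
        assert pce.coeffs[idx, 0] == pytest.approx(1.0, abs=1e-12)
        others = np.delete(pce.coeffs[:, 0], idx)
        assert np.all(np.abs(others) < 1e-12)

    def test_mixed_quadratic_matches_symbolic_and_mc_oracle(self, design, rng):
        # Y = xi_w^2 * xi_kappa = (He2(xi_w) + 1) He1(xi_kappa):
        # coefficients sqrt(2) on (2,1,0) and 1 on (0,1,0).
        f = lambda xi: xi[..., 0] ** 2 * xi[..., 1]
        pce = fit_pce(design, f(design.nodes_std))
        c = {a: pce.coeffs[i, 0] for i, a in enumerate(pce.basis)}
        assert c[(2, 1, 0)] == pytest.approx(math.sqrt(2.0), abs=1e-12)
        assert c[(0, 1, 0)] == pytest.approx(1.0, abs=1e-12)
        for a, v in c.items():
            if a not in {(2, 1, 0), (0, 1, 0)}:
                assert abs(v) < 1e-12
        # independent Monte-Carlo projection, n = 1e6
        mc = mc_projection(lambda x: x[:, 0] ** 2 * x[:, 1], (2, 1, 0), 10**6, rng)
        assert mc == pytest.approx(math.sqrt(2.0), abs=0.02)

    def test_exact_reconstruction_of_cubic_polynomials(self, design, rng):
        from .oracles import random_cubic

        for _ in range(5):
            f = random_cubic(rng)
            y = f(design.nodes_std)
            pce = fit_pce(design, y)
            y_hat = pce.evaluate(design.nodes_std)[:, 0]
            assert y_hat == pytest.approx(y, rel=1e-9, abs=1e-9)

    def test_shape_mismatch_raises(self, design):
        with pytest.raises(ValueError):
            fit_pce(design, np.zeros(design.n_runs - 1))


class TestSobolDecompose:
    def test_additive_linear_split(self, design):
        y = 3.0 * design.nodes_std[:, 0] + 4.0 * design.nodes_std[:, 2]
        s = sobol_decompose(fit_pce(design, y))
        assert s.fractions["S_w"][0] == pytest.approx(36.0, abs=1e-8)
        assert s.fractions["S_a"][0] == pytest.approx(64.0, abs=1e-8)
        for k in ("S_kappa", "S_w_kappa", "S_w_a", "S_kappa_a", "S_w_kappa_a"):
            assert abs(s.fractions[k][0]) < 1e-8

    def test_pure_pairwise_interaction(self, design):
        y = design.nodes_std[:, 0] * design.nodes_std[:, 1]
        s = sobol_decompose(fit_pce(design, y))
        assert s.fractions["S_w_kappa"][0] == pytest.approx(100.0, abs=1e-8)
        for k in ("S_w", "S_kappa", "S_a"):
            assert abs(s.fractions[k][0]) < 1e-8

    def test_odd_univariate_terms_pool_into_one_main_effect(self, design, rng):
        from .oracles import saltelli_sobol

        y = design.nodes_std[:, 0] + design.nodes_std[:, 0] ** 3
        s = sobol_decompose(fit_pce(design, y))
        assert s.fractions["S_w"][0] == pytest.approx(100.0, abs=1e-8)
        est, se = saltelli_sobol(lambda x: x[:, 0] + x[:, 0] ** 3, 10**5, rng)
        assert abs(est["S_w"] - 100.0) <= 3 * max(se["S_w"], 0.5)

    def test_zero_variance_reported_as_missing_not_zero(self, design):
        s = sobol_decompose(fit_pce(design, np.full(design.n_runs, 5.0)))
        assert s.total_variance[0] == pytest.approx(0.0, abs=1e-20)
        assert all(np.isnan(v[0]) for v in s.fractions.values())
        assert not s.defined[0]

    def test_completeness_on_random_cubics(self, design, rng):
        from .oracles import random_cubic

        for _ in range(5):
            y = random_cubic(rng)(design.nodes_std)
            s = sobol_decompose(fit_pce(design, y))
            total = sum(s.fractions[k][0] for k in s.fractions)
            assert total == pytest.approx(100.0, rel=1e-6)


def test_truncation_floor_barely_perturbs_sobol_indices():
    """Clipping nodes at 5% of the mean moves smooth-function Sobol
    indices by under one percentage point versus no truncation."""

    def make(floor_frac):
        return ParameterSet(
            tuple(
                UncertainParameter(n, m, r, floor_frac * m)
                for n, m, r in (("w", 15.0, 0.5), ("kappa", 3e-5, 0.5), ("a", 0.6, 0.25))
            )
        )

    f = lambda nodes: nodes[:, 0] / 15.0 + (nodes[:, 1] / 3e-5) ** 2 + 3.0 * nodes[:, 2]
    results = []
    for floor_frac in (0.05, 0.0):
        ps = make(floor_frac) if floor_frac else ParameterSet(
            tuple(UncertainParameter(n, m, r, 0.0) for n, m, r in
                  (("w", 15.0, 0.5), ("kappa", 3e-5, 0.5), ("a", 0.6, 0.25)))
        )
        d = build_design(ps, 5)
        s = sobol_decompose(fit_pce(d, f(d.nodes_phys)))
        results.append({k: v[0] for k, v in s.fractions.items()})
    for k in results[0]:
        assert abs(results[0][k] - results[1][k]) < 1.0


class TestEnsembleMoments:
    def test_constant(self, design):
        mean, sd = ensemble_moments(design, np.full(design.n_runs, 9.5))
        assert mean == pytest.approx(9.5)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_standard_normal_moments_integrated_exactly(self, design):
        mean, sd = ensemble_moments(design, design.nodes_std[:, 0])
        assert mean == pytest.approx(0.0, abs=1e-10)
        assert sd == pytest.approx(1.0, abs=1e-10)

    def test_variance_equals_sum_of_squared_coefficients(self, design, rng):
        from .oracles import random_cubic

        y = random_cubic(rng)(design.nodes_std)
        _, sd = ensemble_moments(design, y)
        pce = fit_pce(design, y)
        assert sd**2 == pytest.approx(float(pce.variance[0]), rel=1e-9)
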