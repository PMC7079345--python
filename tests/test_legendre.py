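import math

import numpy as np
import pytest
from scipy.special import eval_legendre

from dtilearn.legendre import (
    LegendreOrderConfig,
    LegendreMomentTransformer,
    LMDescriptor,
    featurize_protein,
    legendre_moments,
    legendre_polynomial,
    sample_grid,
)
from dtilearn.pssm import PSSM


def naive_legendre_moments(g, a_max, b_max):
    """Independent brute-force double sum over the defining formula."""
    g = np.asarray(g, dtype=float)
    K, L = g.shape
    x = [(2 * i - K - 1) / K for i in range(1, K + 1)]
    y = [(2 * j - L - 1) / L for j in range(1, L + 1)]
    out = np.empty((a_max + 1, b_max + 1))
    for a in range(a_max + 1):
        for b in range(b_max + 1):
            s = 0.0
            for i in range(K):
                for j in range(L):
                    s += eval_legendre(a, x[i]) * eval_legendre(b, y[j]) * g[i, j]
            out[a, b] = (2 * a + 1) * (2 * b + 1) / (K * L) * s
    return out.ravel()


class TestPolynomial:
    def test_p0_is_one(self):
        for x in (-1.0, -0.3, 0.0, 0.8, 1.0):
            assert legendre_polynomial(0, x) == 1.0

    def test_p1_is_identity(self):
        assert legendre_polynomial(1, 0.5) == 0.5

    def test_p3_hand_value(self):
        # (5x^3 - 3x)/2 at x = 0.5
        assert legendre_polynomial(3, 0.5) == pytest.approx(-0.4375, abs=1e-15)

    @pytest.mark.parametrize("a", range(31))
    def test_value_one_at_one(self, a):
        assert legendre_polynomial(a, 1.0) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("a", range(7))
    def test_recurrence_matches_rodrigues_expansion(self, a, rng):
        # Rodrigues form: P_a(x) = 2^-a sum_k (-1)^k C(a,k) C(2a-2k,a) x^(a-2k)
        for x in rng.uniform(-1, 1, size=10):
            direct = sum(
                (-1) ** k * math.comb(a, k) * math.comb(2 * a - 2 * k, a) * x ** (a - 2 * k)
                for k in range(a // 2 + 1)
            ) / 2**a
            assert legendre_polynomial(a, x) == pytest.approx(direct, rel=1e-12, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            legendre_polynomial(-1, 0.0)
        with pytest.raises(ValueError):
            legendre_polynomial(2, 1.5)


class TestGrid:
    def test_two_cells(self):
        x, _ = sample_grid(2, 1)
        np.testing.assert_allclose(x, [-0.5, 0.5])

    def test_single_cell(self):
        x, _ = sample_grid(1, 1)
        np.testing.assert_allclose(x, [0.0])

    def test_five_cells_formula_and_symmetry(self):
        x, _ = sample_grid(5, 1)
        np.testing.assert_allclose(x, [-0.8, -0.4, 0.0, 0.4, 0.8])
        assert x.sum() == pytest.approx(0.0, abs=1e-15)

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            sample_grid(0, 5)

    def test_discrete_near_orthogonality(self):
        # (1/K) sum P_a P_b -> delta_ab / (2a+1) as K grows
        K = 200
        x, _ = sample_grid(K, 1)
        for a in range(11):
            for b in range(11):
                inner = np.mean(legendre_polynomial(a, x) * legendre_polynomial(b, x))
                target = 1.0 / (2 * a + 1) if a == b else 0.0
                assert inner == pytest.approx(target, abs=2.0 / K)


class TestMoments:
    def test_constant_matrix_l00(self):
        c = 3.25
        d = legendre_moments(np.full((10, 20), c), LegendreOrderConfig(0, 0))
        assert d.values[0] == pytest.approx(c, rel=1e-12)

    def test_linearity(self, rng):
        g1 = rng.normal(size=(6, 20))
        g2 = rng.normal(size=(6, 20))
        cfg = LegendreOrderConfig(4, 4)
        alpha, beta = 0.7, -1.3
        lhs = legendre_moments(alpha * g1 + beta * g2, cfg).values
        rhs = alpha * legendre_moments(g1, cfg).values + beta * legendre_moments(g2, cfg).values
        np.testing.assert_allclose(lhs, rhs, rtol=1e-10, atol=1e-12)

    @pytest.mark.parametrize("shape", [(1, 1), (3, 5), (5, 20), (8, 20)])
    def test_matches_naive_oracle(self, shape, rng):
        g = rng.normal(size=shape)
        cfg = LegendreOrderConfig(5, 5)
        ours = legendre_moments(g, cfg).values
        oracle = naive_legendre_moments(g, 5, 5)
        np.testing.assert_allclose(ours, oracle, rtol=1e-10, atol=1e-12)

    def test_default_descriptor_length_961(self, rng):
        d = legendre_moments(rng.normal(size=(13, 20)))
        assert d.values.size == 961

    def test_constant_matrix_odd_moments_zero(self):
        d = legendre_moments(np.full((6, 20), 2.0), LegendreOrderConfig(5, 5))
        vals = d.values.reshape(6, 6)
        for a in range(6):
            for b in range(6):
                if (a + b) % 2 == 1:
                    assert vals[a, b] == pytest.approx(0.0, abs=1e-12)

    def test_determinism(self, rng):
        g = rng.normal(size=(9, 20))
        v1 = legendre_moments(g).values
        v2 = legendre_moments(g.copy()).values
        assert (v1 == v2).all()

    def test_empty_and_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            legendre_moments(np.empty((0, 20)))
        bad = np.zeros((2, 20))
        bad[1, 3] = np.inf
        with pytest.raises(ValueError):
            legendre_moments(bad)


class TestFeaturize:
    def test_fixed_length_across_protein_sizes(self, rng):
        for n in (50, 700):
            pssm = PSSM("p", rng.integers(-10, 12, size=(n, 20)).astype(float))
            assert featurize_protein(pssm).values.size == 961

    def test_row_reversal_changes_odd_moments(self, rng):
        scores = rng.integers(-10, 12, size=(30, 20)).astype(float)
        cfg = LegendreOrderConfig(3, 3)
        fwd = featurize_protein(PSSM("p", scores), cfg).values.reshape(4, 4)
        rev = featurize_protein(PSSM("p", scores[::-1]), cfg).values.reshape(4, 4)
        odd_a = [abs(fwd[a, b] - rev[a, b]) for a in (1, 3) for b in range(4)]
        assert max(odd_a) > 1e-8
        # even-a moments are invariant under row reversal
        np.testing.assert_allclose(fwd[0], rev[0], atol=1e-12)

    def test_single_residue_protein(self):
        pssm = PSSM("p", np.arange(20, dtype=float).reshape(1, 20))
        d = featurize_protein(pssm)
        assert np.isfinite(d.values).all()


class TestTransformer:
    def test_transform_matrix_shape(self, rng):
        pssms = [PSSM(f"p{i}", rng.integers(-5, 5, size=(10 + i, 20)).astype(float))
                 for i in range(3)]
        t = LegendreMomentTransformer(a_max=4, b_max=4)
        M = t.fit_transform(pssms)
        assert M.shape == (3, 25)

    def test_get_set_params_roundtrip(self):
        t = LegendreMomentTransformer()
        t.set_params(a_max=2, b_max=3)
        assert t.get_params()["a_max"] == 2
        assert t.fit().n_features_out_ == 12
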