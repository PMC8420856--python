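import numpy as np
import pytest

from serotensor import (FitConfig, KruskalFactors, SimSpec, censored_lstsq,
                        compute_r2x, fit_cmtf, generate_coupled,
                        initialize_factors, khatri_rao, reconstruct,
                        standardize_components, unfold)
from serotensor.cmtf import factor_congruence

from conftest import make_dataset


def normal_equations_oracle(B, x):
    return np.linalg.pinv(B.T @ B) @ B.T @ x


class TestCensoredLstsq:
    def test_square_invertible_exact(self, rng):
        B = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        X = rng.standard_normal((3, 2))
        sol = censored_lstsq(B, X)
        np.testing.assert_allclose(B @ sol.T, X, atol=1e-10)

    def test_full_mask_matches_normal_equations(self, rng):
        B = rng.standard_normal((20, 4))
        X = rng.standard_normal((20, 5))
        sol = censored_lstsq(B, X, np.ones_like(X, bool))
        for j in range(5):
            np.testing.assert_allclose(sol[j], normal_equations_oracle(B, X[:, j]),
                                       atol=1e-8)

    def test_partial_mask_per_column_oracle(self, rng):
        B = rng.standard_normal((15, 3))
        X = rng.standard_normal((15, 4))
        mask = np.ones_like(X, bool)
        mask[4, 1] = False
        sol = censored_lstsq(B, X, mask)
        for j in range(4):
            rows = mask[:, j]
            np.testing.assert_allclose(
                sol[j], normal_equations_oracle(B[rows], X[rows, j]), atol=1e-8)

    def test_zero_observed_column_gives_zeros(self, rng):
        B = rng.standard_normal((6, 2))
        X = rng.standard_normal((6, 3))
        mask = np.ones_like(X, bool)
        mask[:, 2] = False
        sol = censored_lstsq(B, X, mask)
        assert not sol[2].any()
        assert sol[:2].any()

    def test_rank_deficient_minimum_norm(self):
        B = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])  # rank 1
        x = np.array([[5.0], [10.0], [15.0]])
        mask = np.array([[True], [True], [False]])
        sol = censored_lstsq(B, x, mask)[0]
        expect = np.linalg.pinv(B[:2]) @ x[:2, 0]  # min-norm solution
        np.testing.assert_allclose(sol, expect, atol=1e-8)


class TestInitialization:
    def test_complete_data_equals_plain_svd(self, small_coupled):
        d, _ = small_coupled
        f = initialize_factors(d, FitConfig(R=2))
        x1 = unfold(d.tensor.values, 1)
        U = np.linalg.svd(x1, full_matrices=False)[0][:, :2]
        # compare up to per-column sign
        for r in range(2):
            assert min(np.linalg.norm(f.B[:, r] - U[:, r]),
                       np.linalg.norm(f.B[:, r] + U[:, r])) < 1e-8

    def test_rank1_noiseless_recovered_before_als(self):
        d, truth, _ = generate_coupled(SimSpec(
            n_subjects=12, n_receptors=4, n_antigens=5, n_glycans=None,
            R_true=1, seed=3))
        f = initialize_factors(d, FitConfig(R=1))
        # rank-1 SVD init already reconstructs up to component scale
        cong = factor_congruence(truth, f)
        assert cong[0] >= 0.999

    def test_zero_padding_when_r_exceeds_mode(self):
        d, _, _ = generate_coupled(SimSpec(
            n_subjects=10, n_receptors=3, n_antigens=4, n_glycans=None,
            R_true=2, seed=0))
        f = initialize_factors(d, FitConfig(R=5))
        assert f.B.shape == (3, 5)
        assert not f.B[:, 3:].any()


class TestFit:
    def test_exact_rank2_coupled_recovery(self, small_coupled):
        d, truth = small_coupled
        res = fit_cmtf(d, FitConfig(R=2))
        assert res.r2x >= 0.999
        assert factor_congruence(truth, res.factors).min() >= 0.99

    def test_r2x_monotone_in_components(self, masked_coupled):
        d, _ = masked_coupled
        r2xs = [fit_cmtf(d, FitConfig(R=R)).r2x for R in (1, 2, 3)]
        assert r2xs[0] <= r2xs[1] + 1e-9 <= r2xs[2] + 2e-9

    def test_trace_monotone_within_fit(self, masked_coupled):
        d, _ = masked_coupled
        res = fit_cmtf(d, FitConfig(R=2))
        vals = [v for _, v in res.r2x_trace]
        assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:]))

    def test_final_trace_matches_returned_factors(self, masked_coupled):
        d, _ = masked_coupled
        res = fit_cmtf(d, FitConfig(R=2))
        assert compute_r2x(d, res.factors)[0] == pytest.approx(res.r2x, abs=1e-12)

    def test_tensor_only_mode(self):
        d, truth, _ = generate_coupled(SimSpec(
            n_subjects=15, n_receptors=4, n_antigens=5, n_glycans=None,
            R_true=2, seed=9))
        res = fit_cmtf(d, FitConfig(R=2))
        assert res.factors.D is None
        assert res.r2x >= 0.999

    def test_rank1_multistart_oracle_3x3x3(self, rng):
        """Best rank-1 fit agrees with exhaustive multi-start dense ALS."""
        t = rng.standard_normal((3, 3, 3))
        d = make_dataset(t)
        ours = fit_cmtf(d, FitConfig(R=1)).r2x

        def dense_rank1_als(a, b, c, iters=500):
            for _ in range(iters):
                a = unfold(t, 0) @ khatri_rao([c[:, None], b[:, None]])[:, 0]
                a /= np.linalg.norm(a)
                b = unfold(t, 1) @ khatri_rao([c[:, None], a[:, None]])[:, 0]
                b /= np.linalg.norm(b)
                kr = khatri_rao([b[:, None], a[:, None]])[:, 0]
                c = unfold(t, 2) @ kr / (kr @ kr)
            resid = t - np.einsum("i,j,k->ijk", a, b, c)
            return 1 - np.sum(resid**2) / np.sum(t**2)

        best = max(dense_rank1_als(*np.random.default_rng(s).standard_normal((3, 3)))
                   for s in range(8))
        assert ours >= best - 1e-3

    def test_multistart_deterministic_and_no_worse(self, masked_coupled):
        d, _ = masked_coupled
        single = fit_cmtf(d, FitConfig(R=3))
        multi1 = fit_cmtf(d, FitConfig(R=3, n_starts=3, seed=5))
        multi2 = fit_cmtf(d, FitConfig(R=3, n_starts=3, seed=5))
        assert multi1.r2x >= single.r2x - 1e-12
        np.testing.assert_array_equal(multi1.factors.A, multi2.factors.A)

    def test_r_exceeding_all_modes_errors(self, small_coupled):
        d, _ = small_coupled
        with pytest.raises(ValueError):
            fit_cmtf(d, FitConfig(R=100))


class TestComputeR2X:
    def test_exact_reconstruction_gives_one(self, small_coupled):
        d, truth = small_coupled
        overall, tx, mx = compute_r2x(d, truth)
        assert overall == pytest.approx(1.0, abs=1e-12)
        assert tx == pytest.approx(1.0, abs=1e-12)
        assert mx == pytest.approx(1.0, abs=1e-12)

    def test_zero_factors_give_zero(self, small_coupled):
        d, truth = small_coupled
        f = KruskalFactors(np.zeros_like(truth.A), np.zeros_like(truth.B),
                           np.zeros_like(truth.C), np.zeros_like(truth.D))
        assert compute_r2x(d, f)[0] == pytest.approx(0.0)

    def test_scalar_example(self):
        d = make_dataset(np.full((1, 1, 1), 2.0))
        f = KruskalFactors(np.array([[1.0]]), np.array([[1.0]]), np.array([[1.0]]))
        assert compute_r2x(d, f)[0] == pytest.approx(0.75)


class TestStandardize:
    def test_reconstruction_invariant(self, masked_coupled):
        d, _ = masked_coupled
        f = fit_cmtf(d, FitConfig(R=3)).factors
        x0, y0 = reconstruct(f)
        x1, y1 = reconstruct(standardize_components(f))
        np.testing.assert_allclose(x1, x0, atol=1e-12)
        np.testing.assert_allclose(y1, y0, atol=1e-12)

    def test_sign_rule_flips_negative_receptor_column(self, rng):
        A = rng.standard_normal((6, 1))
        B = -np.abs(rng.standard_normal((4, 1)))  # all negative
        C = np.abs(rng.standard_normal((5, 1)))
        f = standardize_components(KruskalFactors(A.copy(), B.copy(), C.copy()))
        assert np.mean(f.B[:, 0]) >= 0
        assert np.mean(f.C[:, 0]) >= 0
        # A flipped along with B
        assert np.sign(f.A[0, 0]) == -np.sign(A[0, 0])

    def test_components_ordered_by_variance(self, rng):
        A = rng.standard_normal((8, 2))
        B = rng.standard_normal((5, 2))
        C = rng.standard_normal((6, 2))
        f = KruskalFactors(A, B, C)
        out = standardize_components(f)
        var = []
        for r in range(2):
            term = np.einsum("i,j,k->ijk", out.scale[r] * out.A[:, r],
                             out.B[:, r], out.C[:, r])
            var.append(np.sum(term**2))
        assert var[0] >= var[1]

    def test_factor_ranges_and_scale(self, masked_coupled):
        d, _ = masked_coupled
        f = standardize_components(fit_cmtf(d, FitConfig(R=3)).factors)
        for M in (f.A, f.B, f.C):
            assert np.max(np.abs(M), axis=0) == pytest.approx(1.0)
        assert (f.scale > 0).all()

    def test_nonnegative_mean_receptor_antigen(self, masked_coupled):
        d, _ = masked_coupled
        f = standardize_components(fit_cmtf(d, FitConfig(R=3)).factors)
        assert (f.B.mean(axis=0) >= -1e-12).all()
        assert (f.C.mean(axis=0) >= -1e-12).all()


def test_factor_congruence_identity_under_rescaling(rng):
    A, B, C = (rng.standard_normal((n, 3)) for n in (6, 5, 4))
    truth = KruskalFactors(A, B, C)
    perm = [2, 0, 1]
    est = KruskalFactors(-2.0 * A[:, perm], B[:, perm] * 0.5, C[:, perm])
    assert factor_congruence(truth, est).min() >= 1 - 1e-12
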