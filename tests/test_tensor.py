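"""Unfoldings, SVD bases, rank-k reconstruction, numerical rank."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import prefmode as pm
from prefmode import DegenerateDataError, InvalidInputError, PopulationTensor
from conftest import loop_unfold


def _indexed_tensor():
    """2×3×4 tensor with X[n,c,t] = 100n + 10c + t (1-based indices)."""
    n, c, t = 2, 3, 4
    vals = np.zeros((n, c, t))
    for i in range(n):
        for j in range(c):
            for tt in range(t):
                vals[i, j, tt] = 100 * (i + 1) + 10 * (j + 1) + (tt + 1)
    return PopulationTensor.from_values(vals)


class TestUnfold:
    def test_time_major_column_bookkeeping(self):
        tensor = _indexed_tensor()
        unf = pm.unfold(tensor, "neuron")
        assert unf.values.shape == (2, 12)
        # row n=1, column for (t=3, c=2): 0-based col (3-1)*3 + (2-1) = 7
        assert unf.values[0, 7] == 123
        unf2 = pm.unfold(tensor, "condition")
        assert unf2.values.shape == (3, 8)
        # row c=2, column for (t=3, n=1): 0-based col (3-1)*2 + 0 = 4
        assert unf2.values[1, 4] == 123

    @pytest.mark.parametrize("mode", ["neuron", "condition"])
    def test_matches_loop_oracle(self, rng, mode):
        vals = rng.standard_normal((3, 5, 4))
        tensor = PopulationTensor.from_values(vals)
        np.testing.assert_array_equal(
            pm.unfold(tensor, mode).values, loop_unfold(vals, mode)
        )

    @pytest.mark.parametrize("mode", ["neuron", "condition"])
    def test_rank_one_outer_product(self, rng, mode):
        a, b, c = rng.standard_normal(4), rng.standard_normal(5), rng.standard_normal(6)
        tensor = PopulationTensor.from_values(np.einsum("i,j,k->ijk", a, b, c))
        assert np.linalg.matrix_rank(pm.unfold(tensor, mode).values) == 1

    @pytest.mark.parametrize("mode", ["neuron", "condition"])
    def test_frobenius_norm_preserved(self, rng, mode):
        tensor = PopulationTensor.from_values(rng.standard_normal((4, 4, 4)))
        norm_t = np.linalg.norm(tensor.values)
        norm_u = np.linalg.norm(pm.unfold(tensor, mode).values)
        assert abs(norm_u - norm_t) <= 1e-12 * norm_t

    def test_fold_inverts_unfold(self, random_tensor):
        for mode in ("neuron", "condition"):
            unf = pm.unfold(random_tensor, mode)
            np.testing.assert_array_equal(
                pm.fold(unf.values, mode, random_tensor.shape), random_tensor.values
            )

    def test_degenerate_tensor_rejected(self):
        with pytest.raises(InvalidInputError):
            PopulationTensor.from_values(np.empty((0, 3, 2)))

    def test_bad_mode_rejected(self, random_tensor):
        with pytest.raises(InvalidInputError):
            pm.unfold(random_tensor, "timex")


class TestModeBasis:
    def test_constructed_rank_two_tensor(self, rng):
        # tensor = weighted sum of 2 fixed orthonormal C×T patterns per neuron
        c, t, n = 4, 5, 6
        q, _ = np.linalg.qr(rng.standard_normal((c * t, 2)))
        patterns = q.T.reshape(2, c, t)
        weights = rng.standard_normal((n, 2))
        vals = np.einsum("nk,kct->nct", weights, patterns)
        tensor = PopulationTensor.from_values(vals)
        basis = pm.mode_basis(tensor, "neuron", 2)
        s = basis.singular_values
        assert np.all(s[2:] < 1e-10 * s[0])
        err = pm.reconstruct_rank_k(tensor, "neuron", 2).total_error
        assert err < 1e-12

    @pytest.mark.parametrize("mode", ["neuron", "condition"])
    def test_elements_orthonormal(self, random_tensor, mode):
        basis = pm.mode_basis(random_tensor, mode, 3)
        flat = basis.elements.reshape(3, -1)
        gram = flat @ flat.T
        assert np.abs(gram - np.eye(3)).max() < 1e-8

    def test_singular_values_match_gram_eigensolver(self, rng):
        vals = rng.standard_normal((3, 3, 2))
        tensor = PopulationTensor.from_values(vals)
        for mode in ("neuron", "condition"):
            unf = loop_unfold(vals, mode)
            eigs = np.sort(np.linalg.eigvalsh(unf @ unf.T))[::-1]
            s2 = pm.mode_basis(tensor, mode, 1).singular_values ** 2
            np.testing.assert_allclose(s2, eigs, rtol=1e-9, atol=1e-12)

    def test_coefficients_reproduce_truncation(self, random_tensor):
        k = 2
        basis = pm.mode_basis(random_tensor, "neuron", k)
        approx = np.einsum("nk,kct->nct", basis.coefficients, basis.elements)
        # must equal the refolded rank-k truncation of the unfolding
        unf = pm.unfold(random_tensor, "neuron").values
        u, s, vt = np.linalg.svd(unf, full_matrices=False)
        trunc = pm.fold((u[:, :k] * s[:k]) @ vt[:k], "neuron", random_tensor.shape)
        np.testing.assert_allclose(approx, trunc, atol=1e-10)

    def test_k_out_of_range_names_interval(self, random_tensor):
        with pytest.raises(InvalidInputError, match=r"\[1, 5\]"):
            pm.mode_basis(random_tensor, "neuron", 6)
        with pytest.raises(InvalidInputError):
            pm.mode_basis(random_tensor, "neuron", 0)


class TestReconstruction:
    def test_full_rank_reconstruction_is_exact(self, rng):
        tensor = PopulationTensor.from_values(rng.standard_normal((4, 5, 3)))
        assert pm.reconstruct_rank_k(tensor, "neuron", 4).total_error < 1e-12

    def test_rank_one_tensor_k1_exact(self, rng):
        a, b, c = rng.standard_normal(4), rng.standard_normal(4), rng.standard_normal(5)
        tensor = PopulationTensor.from_values(np.einsum("i,j,k->ijk", a, b, c))
        for mode in ("neuron", "condition"):
            assert pm.reconstruct_rank_k(tensor, mode, 1).total_error < 1e-12

    def test_error_matches_singular_value_oracle(self, rng):
        vals = rng.standard_normal((5, 5, 3))
        tensor = PopulationTensor.from_values(vals)
        unf = loop_unfold(vals, "condition")
        s = np.linalg.svd(unf, compute_uv=False)
        expected = 1.0 - np.sum(s[:2] ** 2) / np.sum(s**2)
        got = pm.reconstruct_rank_k(tensor, "condition", 2).total_error
        assert abs(got - expected) < 1e-10

    def test_error_monotone_in_k(self, rng):
        tensor = PopulationTensor.from_values(rng.standard_normal((6, 5, 4)))
        for mode in ("neuron", "condition"):
            errs = [pm.reconstruct_rank_k(tensor, mode, k).total_error for k in range(1, 6)]
            assert np.all(np.diff(errs) <= 1e-12)

    def test_single_timepoint_mode_symmetry(self, rng):
        tensor = PopulationTensor.from_values(rng.standard_normal((6, 6, 1)))
        for k in (1, 3, 6):
            en = pm.reconstruct_rank_k(tensor, "neuron", k).total_error
            ec = pm.reconstruct_rank_k(tensor, "condition", k).total_error
            assert abs(en - ec) < 1e-10

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        scale=st.floats(-100.0, 100.0).filter(lambda x: abs(x) > 1e-3),
        k=st.integers(1, 4),
        mode=st.sampled_from(["neuron", "condition"]),
    )
    def test_permutation_and_scale_invariance(self, seed, scale, k, mode):
        rng = np.random.default_rng(seed)
        vals = rng.standard_normal((4, 5, 3))
        base = pm.reconstruct_rank_k(
            PopulationTensor.from_values(vals), mode, k
        ).total_error
        perm_n = rng.permutation(4)
        perm_c = rng.permutation(5)
        permuted = PopulationTensor.from_values(vals[perm_n][:, perm_c] * scale)
        got = pm.reconstruct_rank_k(permuted, mode, k).total_error
        assert abs(got - base) < 1e-9

    def test_all_zero_tensor_raises(self):
        tensor = PopulationTensor.from_values(np.zeros((3, 3, 3)))
        with pytest.raises(DegenerateDataError):
            pm.reconstruct_rank_k(tensor, "neuron", 1)


class TestNumericalRank:
    def test_threshold_behaviour(self):
        assert pm.numerical_rank(np.diag([1.0, 1e-12])) == 1
        assert pm.numerical_rank(np.eye(5)) == 5
        assert pm.numerical_rank(np.zeros((4, 4))) == 0

    def test_tolerance_is_relative(self):
        assert pm.numerical_rank(1e6 * np.diag([1.0, 1e-12])) == 1
        assert pm.numerical_rank(np.diag([1.0, 1e-12]), rel_tol=1e-13) == 2

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidInputError):
            pm.numerical_rank(np.array([[np.nan, 0.0], [0.0, 1.0]]))
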