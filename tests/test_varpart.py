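"""Transforms, PCNM, RDA, forward selection and variance partitioning."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import steppediv as sd
from steppediv.varpart import morans_i, drop_collinear


def grid_coords(rows, cols, q=0.5):
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.column_stack([(cc.ravel() + 0.5) * q, (rr.ravel() + 0.5) * q])


class TestTransforms:
    @pytest.mark.parametrize(
        "row, expected",
        [([4, 0], [1.0, 0.0]), ([1, 1, 1, 1], [0.5, 0.5, 0.5, 0.5])],
    )
    def test_hellinger_rows(self, row, expected):
        np.testing.assert_allclose(sd.hellinger_transform([row])[0], expected)

    def test_hellinger_rows_have_unit_sum_of_squares(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(2.0, size=(30, 8)) + np.eye(30, 8, dtype=int)  # no zero rows
        H = sd.hellinger_transform(X)
        np.testing.assert_allclose((H**2).sum(axis=1), 1.0, rtol=1e-12)

    def test_hellinger_zero_rows_warn_and_stay_zero(self):
        with pytest.warns(UserWarning, match="all-zero"):
            H = sd.hellinger_transform([[0, 0], [1, 3]])
        assert np.all(H[0] == 0)

    def test_hellinger_negative_rejected(self):
        with pytest.raises(ValueError):
            sd.hellinger_transform([[-1, 2]])

    def test_standardize_column(self):
        z = sd.standardize(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(z.ravel(), [-1, 0, 1])

    def test_standardize_drops_constant_and_is_idempotent(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            z = sd.standardize(X)
        assert list(z.columns) == ["a"]
        np.testing.assert_allclose(sd.standardize(z).to_numpy(), z.to_numpy(), atol=1e-12)

    def test_drop_collinear_removes_duplicated_variable(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=50)
        env = pd.DataFrame({"a": a, "dup": a * 2 + 0.01 * rng.normal(size=50),
                            "c": rng.normal(size=50)})
        kept = drop_collinear(env, threshold=0.8)
        assert len(kept.columns) == 2 and "c" in kept.columns


class TestPCNM:
    def test_collinear_points_truncation_is_spacing(self):
        coords = np.array([[0.0, 0], [1.0, 0], [2.0, 0], [3.0, 0]])
        basis = sd.pcnm(coords)
        assert basis.truncation == pytest.approx(1.0)

    def test_matches_dense_eigendecomposition_oracle(self):
        # independent oracle: eigendecompose the doubly centred truncated
        # matrix with numpy.linalg.eig, compare axis-by-axis up to sign
        rng = np.random.default_rng(4)
        coords = rng.uniform(0, 3, size=(9, 2))
        basis = sd.pcnm(coords)
        from scipy.spatial.distance import pdist, squareform
        from scipy.sparse.csgraph import minimum_spanning_tree

        D = squareform(pdist(coords))
        t = minimum_spanning_tree(D).data.max()
        Dt = np.where(D > t, 4 * t, D)
        np.fill_diagonal(Dt, 0.0)
        n = len(D)
        J = np.eye(n) - 1 / n
        B = J @ (-0.5 * Dt**2) @ J
        w, v = np.linalg.eig(B)
        w, v = np.real(w), np.real(v)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        keep = w > 1e-10 * w[0]
        np.testing.assert_allclose(basis.eigenvalues, w[keep], rtol=1e-8)
        for i in range(keep.sum()):
            dot = abs(basis.vectors[:, i] @ v[:, i])
            assert dot == pytest.approx(1.0, abs=1e-6)

    def test_eigenvectors_orthonormal_and_centred(self):
        basis = sd.pcnm(grid_coords(6, 6))
        V = basis.vectors
        np.testing.assert_allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-8)
        np.testing.assert_allclose(V.mean(axis=0), 0.0, atol=1e-8)
        assert np.all(basis.eigenvalues > 0)

    def test_leading_axis_is_broad_scale(self):
        basis = sd.pcnm(grid_coords(10, 10))
        i_first = morans_i(basis.vectors[:, 0], basis.coords, threshold=0.75)
        i_last = morans_i(basis.vectors[:, -1], basis.coords, threshold=0.75)
        assert i_first > i_last

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            sd.pcnm(np.array([[0.0, 0], [0.0, 0], [1.0, 1]]))


class TestRDA:
    def test_adjusted_r2_values(self):
        assert sd.adjusted_r2(1.0, 50, 3) == 1.0
        assert sd.adjusted_r2(0.0, 100, 1) == pytest.approx(-1 / 98)
        assert sd.adjusted_r2(0.37, 50, 0) == 0.37
        with pytest.raises(ValueError):
            sd.adjusted_r2(0.5, 4, 3)

    def test_response_equal_to_predictor_gives_one(self):
        x = np.arange(10.0)
        assert sd.rda_r2(x, x) == pytest.approx(1.0)

    def test_equals_squared_pearson_for_univariate(self):
        rng = np.random.default_rng(5)
        x, e = rng.normal(size=100), rng.normal(size=100)
        y = 2 * x + e
        r = stats.pearsonr(x, y).statistic
        assert sd.rda_r2(y, x) == pytest.approx(r**2, rel=1e-10)

    def test_orthonormal_predictors_r2_additive(self):
        rng = np.random.default_rng(6)
        X, _ = np.linalg.qr(rng.normal(size=(40, 3)))
        X = X - X.mean(axis=0)
        X, _ = np.linalg.qr(X)
        Y = rng.normal(size=(40, 2))
        total = sd.rda_r2(Y, X)
        parts = sum(sd.rda_r2(Y, X[:, [j]]) for j in range(3))
        assert total == pytest.approx(parts, rel=1e-8)

    def test_noise_r2_near_zero(self):
        rng = np.random.default_rng(7)
        assert sd.rda_r2(rng.normal(size=1000), rng.normal(size=1000)) < 0.01

    def test_collinear_columns_dropped_with_warning(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=30)
        X = np.column_stack([x, 2 * x])
        with pytest.warns(UserWarning, match="collinear"):
            r2 = sd.rda_r2(rng.normal(size=30), X)
        assert 0 <= r2 <= 1


class TestForwardSelect:
    def test_signal_candidate_selected_first_with_minimal_p(self):
        rng = np.random.default_rng(9)
        n, n_perm = 60, 199
        signal = rng.normal(size=n)
        X = np.column_stack([signal] + [rng.normal(size=n) for _ in range(9)])
        y = signal + 0.1 * rng.normal(size=n)
        res = sd.forward_select(y, X, n_perm=n_perm, seed=1)
        assert res.selected[0] == 0
        assert res.steps[0].p_value == pytest.approx(1 / (n_perm + 1))

    def test_selection_deterministic_under_seed(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(50, 6))
        y = X[:, 2] + 0.5 * rng.normal(size=50)
        r1 = sd.forward_select(y, X, n_perm=99, seed=3)
        r2 = sd.forward_select(y, X, n_perm=99, seed=3)
        assert r1.selected == r2.selected
        assert [s.p_value for s in r1.steps] == [s.p_value for s in r2.steps]

    def test_double_stopping_caps_at_global_adjusted_r2(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(40, 8))
        y = X[:, 0] + X[:, 1] + 0.3 * rng.normal(size=40)
        res = sd.forward_select(y, X, n_perm=99, seed=0)
        for step in res.steps:
            assert step.cum_adj_r2 <= res.global_adj_r2 + 1e-9

    def test_type_one_error_rate_near_alpha(self):
        # all-noise candidates: P(select anything) should track alpha = 0.05
        rng = np.random.default_rng(12)
        n, k, reps = 30, 8, 500
        false_positives = 0
        for rep in range(reps):
            X = rng.normal(size=(n, k))
            y = rng.normal(size=n)
            res = sd.forward_select(y, X, alpha=0.05, n_perm=99, seed=rep)
            false_positives += bool(res.selected)
        # binomial 99% band around 0.05 for 500 replicates
        band = 2.576 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(false_positives / reps - 0.05) <= band + 1e-12

    def test_global_p_uniform_under_null(self):
        # permutation p-values of the global test under H0 ~ Uniform(0,1)
        rng = np.random.default_rng(13)
        pvals = []
        for rep in range(200):
            X = rng.normal(size=(25, 4))
            y = rng.normal(size=25)
            res = sd.forward_select(y, X, alpha=-1.0, n_perm=99, seed=1000 + rep)
            pvals.append(res.global_p)
        stat = stats.kstest(pvals, "uniform").statistic
        assert stat < 1.63 / np.sqrt(200) + 0.005  # alpha = 0.01 KS band + grid bias


class TestPartition:
    def _construct(self, seed=0, n=100, coupled=False):
        rng = np.random.default_rng(seed)
        env = rng.normal(size=(n, 2))
        space = rng.normal(size=(n, 2))
        y = env @ [1.0, 0.5] + 0.5 * rng.normal(size=n)
        if coupled:
            y = y + space @ [0.8, 0.0]
        return y, env, space

    def test_fractions_sum_to_hundred_percent(self):
        y, env, space = self._construct(coupled=True)
        part = sd.partition(y, env, space, n_perm=49, seed=0)
        pct = part.percentages()
        assert sum(pct.values()) == pytest.approx(100.0, abs=1e-9)

    def test_orthogonal_env_space_gives_small_b(self):
        bs = [
            sd.partition(*self._construct(seed=s), n_perm=0, seed=0).b
            for s in range(20)
        ]
        assert abs(np.mean(bs)) < 0.02

    def test_env_only_signal_gives_small_c(self):
        cs, as_ = [], []
        for s in range(10):
            y, env, space = self._construct(seed=100 + s)
            p = sd.partition(y, env, space, n_perm=0, seed=0)
            cs.append(p.c)
            as_.append(p.a)
        assert abs(np.mean(cs)) < 0.02
        assert np.mean(as_) > 0.5

    def test_empty_space_selection_collapses_exactly(self):
        y, env, _ = self._construct()
        part = sd.partition(y, env, None, n_perm=49, seed=0)
        ab = sd.adjusted_r2(sd.rda_r2(y, env), len(y), env.shape[1])
        assert part.b == 0 and part.c == 0
        assert part.a == pytest.approx(ab, abs=1e-12)
        assert part.p_c is None

    def test_invariant_to_predictor_column_order(self):
        y, env, space = self._construct(coupled=True)
        p1 = sd.partition(y, env, space, n_perm=0, seed=0)
        p2 = sd.partition(y, env[:, ::-1], space[:, ::-1], n_perm=0, seed=0)
        for attr in "abcd":
            assert getattr(p1, attr) == pytest.approx(getattr(p2, attr), abs=1e-10)

    def test_partial_tests_detect_true_effects(self):
        y, env, space = self._construct(coupled=True, n=150)
        part = sd.partition(y, env, space, n_perm=199, seed=2)
        assert part.p_a <= 0.01
        assert part.p_c <= 0.01
        assert part.p_total <= 0.01

    def test_too_many_predictors_rejected(self):
        rng = np.random.default_rng(14)
        with pytest.raises(ValueError, match="too small"):
            sd.partition(rng.normal(size=10), rng.normal(size=(10, 6)),
                         rng.normal(size=(10, 6)), n_perm=0, seed=0)

    def test_hellinger_community_matrix_response_supported(self):
        rng = np.random.default_rng(15)
        comm = rng.poisson(3.0, size=(60, 10)) + np.eye(60, 10, dtype=int)
        H = sd.hellinger_transform(comm)
        env = rng.normal(size=(60, 3))
        space = rng.normal(size=(60, 2))
        part = sd.partition(H, env, space, n_perm=49, seed=1)
        assert sum(part.percentages().values()) == pytest.approx(100.0, abs=1e-9)
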