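"""Environmental association: preprocessing, distances, variance
partitioning recovery and aliasing, Mantel calibration."""

import numpy as np
import pandas as pd
import pytest

from magpop.counts import ParameterError
from magpop.env import (
    euclidean_distance_matrix,
    mantel_test,
    pair_kernel,
    preprocess_env,
    variance_partition,
)


def env_table(n=6, seed=0):
    rng = np.random.default_rng(seed)
    cols = [
        "temperature", "salinity", "oxygen", "ammonium", "iron",
        "nitrate", "nitrite", "phosphate", "silicate",
    ]
    return pd.DataFrame(
        rng.random((n, len(cols))) + 1.0, columns=cols,
        index=[f"s{i}" for i in range(n)],
    )


class TestPreprocess:
    def test_zscore_example(self):
        df = pd.DataFrame({"temperature": [2.0, 4.0, 6.0], "salinity": [1.0, 2.0, 4.0]})
        out, _rep = preprocess_env(df)
        np.testing.assert_allclose(
            out["temperature"], [-1.2247, 0.0, 1.2247], atol=1e-4
        )

    def test_nitrate_nitrite_merge(self):
        df = env_table()
        df["nitrate"] = [1, 2, 3, 4, 5, 6.0]
        df["nitrite"] = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        out, _rep = preprocess_env(df)
        assert "nitrate_nitrite" in out.columns
        assert "nitrate" not in out.columns and "nitrite" not in out.columns
        merged = np.array([1.1, 2.2, 3.3, 4.4, 5.5, 6.6])
        expected = (merged - merged.mean()) / merged.std()
        np.testing.assert_allclose(out["nitrate_nitrite"], expected, atol=1e-12)

    def test_ammonium_dropped(self):
        out, _rep = preprocess_env(env_table())
        assert "ammonium" not in out.columns

    def test_duplicated_variable_flagged_by_vif_but_retained(self):
        df = env_table(n=8, seed=1)
        df["silicate"] = df["phosphate"] * 1.0  # exact collinearity
        out, rep = preprocess_env(df)
        assert "silicate" in out.columns and "phosphate" in out.columns
        assert "silicate" in rep["high_vif"] or "phosphate" in rep["high_vif"]

    def test_constant_variable_dropped_with_warning(self):
        df = env_table()
        df["iron"] = 3.0
        with pytest.warns(UserWarning, match="iron"):
            out, _rep = preprocess_env(df)
        assert "iron" not in out.columns

    def test_all_retained_variables_standardised(self):
        out, _rep = preprocess_env(env_table(n=10, seed=2))
        np.testing.assert_allclose(out.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(ddof=0), 1.0, atol=1e-12)


class TestDistances:
    def test_scalar_and_pythagorean_cases(self):
        assert euclidean_distance_matrix(np.array([1.0, 4.0]))[0, 1] == 3.0
        d = euclidean_distance_matrix(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert d[0, 1] == 5.0

    def test_identical_samples_distance_zero_and_symmetry(self):
        x = np.array([2.0, 2.0, 5.0])
        d = euclidean_distance_matrix(x)
        assert d[0, 1] == 0.0
        np.testing.assert_allclose(d, d.T)
        assert np.all(np.diag(d) == 0)

    def test_missing_value_names_sample(self):
        s = pd.Series([1.0, np.nan, 2.0], index=["a", "b", "c"])
        with pytest.raises(ParameterError, match="b"):
            euclidean_distance_matrix(s)


def _simulate_response(kernel, share, m, rng):
    cov = share * kernel + (1.0 - share) * np.eye(m)
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(m))
    return chol @ rng.normal(size=m)


def _as_fst_matrix(y, n):
    m = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    m[iu] = y
    return pd.DataFrame(m + m.T)


class TestVariancePartition:
    def test_single_kernel_recovery_at_moderate_scale(self):
        rng = np.random.default_rng(3)
        n = 12
        m = n * (n - 1) // 2
        props = []
        for _rep in range(10):
            x = rng.normal(size=n)
            dist = euclidean_distance_matrix(x)
            y = _simulate_response(pair_kernel(dist), 0.8, m, rng)
            vp = variance_partition(
                _as_fst_matrix(y, n), {"v": dist}, mantel_permutations=49, seed=0
            )
            props.append(vp.proportions["v"])
        assert np.mean(props) == pytest.approx(0.8, abs=0.15)

    def test_pure_noise_gives_small_env_shares(self):
        rng = np.random.default_rng(4)
        n = 10
        m = n * (n - 1) // 2
        shares = []
        for _rep in range(10):
            dists = {k: euclidean_distance_matrix(rng.normal(size=n)) for k in ("a", "b", "c")}
            y = rng.normal(size=m)
            vp = variance_partition(
                _as_fst_matrix(y, n), dists, mantel_permutations=49, seed=0
            )
            shares.append(max(vp.proportions[k] for k in ("a", "b", "c")))
        assert np.mean(shares) < 0.15

    def test_identical_kernels_alias_but_their_sum_is_stable(self):
        rng = np.random.default_rng(5)
        n = 12
        m = n * (n - 1) // 2
        x = rng.normal(size=n)
        dist = euclidean_distance_matrix(x)
        y = _simulate_response(pair_kernel(dist), 0.6, m, rng)
        single = variance_partition(
            _as_fst_matrix(y, n), {"v": dist}, mantel_permutations=49, seed=0
        )
        double = variance_partition(
            _as_fst_matrix(y, n), {"v1": dist, "v2": dist.copy()}, mantel_permutations=49, seed=0
        )
        summed = double.proportions["v1"] + double.proportions["v2"]
        assert summed == pytest.approx(single.proportions["v"], abs=0.05)

    def test_proportions_sum_to_one_and_lie_in_unit_interval(self):
        rng = np.random.default_rng(6)
        n = 8
        dists = {k: euclidean_distance_matrix(rng.normal(size=n)) for k in ("a", "b")}
        y = rng.normal(size=n * (n - 1) // 2)
        vp = variance_partition(_as_fst_matrix(y, n), dists, mantel_permutations=49, seed=0)
        assert sum(vp.proportions.values()) == pytest.approx(1.0, abs=1e-6)
        assert all(0.0 <= v <= 1.0 for v in vp.proportions.values())

    def test_sample_relabelling_invariance(self):
        rng = np.random.default_rng(7)
        n = 9
        x = rng.normal(size=n)
        dist = euclidean_distance_matrix(x)
        y = _simulate_response(pair_kernel(dist), 0.5, n * (n - 1) // 2, rng)
        fst_m = _as_fst_matrix(y, n)
        vp1 = variance_partition(fst_m, {"v": dist}, mantel_permutations=49, seed=0)
        perm = rng.permutation(n)
        fst_p = pd.DataFrame(fst_m.to_numpy()[np.ix_(perm, perm)])
        vp2 = variance_partition(
            fst_p, {"v": dist[np.ix_(perm, perm)]}, mantel_permutations=49, seed=0
        )
        assert vp1.proportions["v"] == pytest.approx(vp2.proportions["v"], abs=1e-6)

    def test_tiny_problems_fall_back_to_method_of_moments(self):
        rng = np.random.default_rng(8)
        n = 3  # 3 pairs < 6
        dist = euclidean_distance_matrix(rng.normal(size=n))
        y = rng.normal(size=3)
        vp = variance_partition(_as_fst_matrix(y, n), {"v": dist}, mantel_permutations=49, seed=0)
        assert any("method-of-moments" in w for w in vp.warnings)

    def test_high_residual_share_raises_diagnostic(self):
        rng = np.random.default_rng(9)
        n = 10
        dist = euclidean_distance_matrix(rng.normal(size=n))
        y = rng.normal(size=n * (n - 1) // 2)  # pure noise -> residual ~ 1
        vp = variance_partition(_as_fst_matrix(y, n), {"v": dist}, mantel_permutations=49, seed=0)
        assert any("residual share" in w for w in vp.warnings)


class TestMantel:
    def test_identical_matrices_maximal_r_minimal_p(self):
        rng = np.random.default_rng(0)
        a = euclidean_distance_matrix(rng.normal(size=8))
        r, p = mantel_test(a, a, n_perm=999, seed=1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1.0 / 1000.0)

    def test_negated_matrix_one_sided_p_near_one(self):
        rng = np.random.default_rng(1)
        a = euclidean_distance_matrix(rng.normal(size=8))
        r, p = mantel_test(a, -a, n_perm=499, seed=1)
        assert r == pytest.approx(-1.0)
        assert p > 0.95

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(2)
        a = euclidean_distance_matrix(rng.normal(size=7))
        b = euclidean_distance_matrix(rng.normal(size=7))
        assert mantel_test(a, b, n_perm=299, seed=5) == mantel_test(a, b, n_perm=299, seed=5)

    def test_constant_matrix_rejected(self):
        a = np.zeros((5, 5))
        with pytest.raises(ParameterError):
            mantel_test(a, a)

    def test_type_one_error_calibration_small(self):
        rng = np.random.default_rng(3)
        rejections = 0
        trials = 200
        for i in range(trials):
            a = euclidean_distance_matrix(rng.normal(size=7))
            b = euclidean_distance_matrix(rng.normal(size=7))
            _r, p = mantel_test(a, b, n_perm=99, seed=i)
            rejections += p <= 0.05
        assert rejections / trials == pytest.approx(0.05, abs=0.035)
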