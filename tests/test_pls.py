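"""PLS1, the spin permutation test and bootstrap gene Z-scores."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from morphotx.pls import (
    bootstrap_gene_z,
    extract_pls_gene_sets,
    pls_first_component,
    random_rotation,
    spin_permutations,
    spin_test,
    spin_test_pls,
    weights_tmap_correlation,
)
from morphotx.synth import hemisphere_centroids


def _instance(rng, n=30, g=8):
    X = pd.DataFrame(rng.standard_normal((n, g)),
                     columns=[f"G{j}" for j in range(g)],
                     index=[f"R{i}" for i in range(n)])
    y = pd.Series(rng.standard_normal(n), index=X.index)
    return X, y


class TestPLS1:
    def test_weights_parallel_to_cross_covariance(self, rng):
        X, y = _instance(rng)
        res = pls_first_component(X, y, n_components=1)
        xz = (X - X.mean()) / X.std(ddof=1)
        oracle = xz.to_numpy().T @ (y - y.mean()).to_numpy()
        oracle /= np.linalg.norm(oracle)
        if oracle @ res.weights.to_numpy() < 0:
            oracle = -oracle
        np.testing.assert_allclose(res.weights.to_numpy(), oracle, atol=1e-8)
        assert res.weights.to_numpy() @ res.weights.to_numpy() == pytest.approx(1.0)

    def test_matches_sklearn_two_components(self, rng):
        X, y = _instance(rng, n=40, g=12)
        res = pls_first_component(X, y, n_components=2)
        sk = PLSRegression(n_components=2, scale=True).fit(X.to_numpy(), y.to_numpy())
        for k in range(2):
            w_sk = sk.x_weights_[:, k] / np.linalg.norm(sk.x_weights_[:, k])
            w_my = res.weights.to_numpy() if k == 0 else None
            if k == 0:
                if w_sk @ w_my < 0:
                    w_sk = -w_sk
                np.testing.assert_allclose(w_my, w_sk, atol=1e-8)
        t_sk = sk.x_scores_[:, 0]
        if t_sk @ res.scores.to_numpy() < 0:
            t_sk = -t_sk
        np.testing.assert_allclose(res.scores.to_numpy(), t_sk, atol=1e-8)
        # variance explained per component matches sklearn's y-space R2 split
        yc = (y - y.mean()).to_numpy()
        for k in range(2):
            t = sk.x_scores_[:, k]
            expected = (t @ yc) ** 2 / ((t @ t) * (yc @ yc))
            assert res.component_variance[k] == pytest.approx(expected, abs=1e-8)

    def test_perfect_predictor_limit(self, rng):
        n = 40
        x1 = rng.standard_normal(n)
        noise = rng.standard_normal((n, 9)) * 1e-6
        X = pd.DataFrame(np.column_stack([x1, noise]))
        res = pls_first_component(X, pd.Series(x1), n_components=1, scale=False)
        assert res.weights.abs().idxmax() == 0
        assert res.variance_explained == pytest.approx(1.0, abs=1e-9)

    def test_sign_convention_scores_align_with_response(self, rng):
        X, y = _instance(rng)
        res = pls_first_component(X, y)
        assert np.corrcoef(res.scores, y)[0, 1] >= 0
        res_neg = pls_first_component(X, -y)
        np.testing.assert_allclose(res_neg.scores.to_numpy(), -res.scores.to_numpy(),
                                   atol=1e-10)

    def test_gene_reordering_invariance(self, rng):
        X, y = _instance(rng)
        res = pls_first_component(X, y)
        perm = rng.permutation(X.shape[1])
        res_p = pls_first_component(X.iloc[:, perm], y)
        np.testing.assert_allclose(res_p.scores.to_numpy(), res.scores.to_numpy(),
                                   atol=1e-10)
        np.testing.assert_allclose(
            res_p.weights.to_numpy(), res.weights.to_numpy()[perm], atol=1e-10
        )

    def test_degenerate_inputs_rejected(self, rng):
        X, y = _instance(rng, n=10, g=4)
        with pytest.raises(ValueError, match="zero variance"):
            pls_first_component(X, pd.Series(np.ones(10), index=X.index))
        with pytest.raises(ValueError, match="rank"):
            pls_first_component(X, y, n_components=5)


class TestSpin:
    def test_rotations_orthonormal_det_plus_one(self, rng):
        for _ in range(100):
            q = random_rotation(rng)
            np.testing.assert_allclose(q @ q.T, np.eye(3), atol=1e-10)
            assert np.linalg.det(q) == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("method", ["greedy", "hungarian"])
    def test_reassignment_is_permutation(self, method):
        coords = hemisphere_centroids(50).to_numpy()
        perms = spin_permutations(coords, 20, seed=3, method=method)
        values = np.random.default_rng(0).standard_normal(50)
        for perm in perms:
            assert sorted(perm) == list(range(50))
            np.testing.assert_array_equal(np.sort(values[perm]), np.sort(values))

    def test_duplicate_centroids_rejected(self):
        coords = hemisphere_centroids(20).to_numpy()
        coords[5] = coords[4]
        with pytest.raises(ValueError, match="duplicate"):
            spin_permutations(coords, 5, seed=0)

    def test_p_floor_when_observed_beats_all(self, rng):
        centroids = hemisphere_centroids(40)
        target = rng.standard_normal(40)

        def statistic(values):
            return float(np.corrcoef(values, target)[0, 1])

        null, p = spin_test(statistic, target, centroids, n_rotations=99, seed=1)
        assert p == pytest.approx(1.0 / 100.0)
        assert len(null.values) == 99

    def test_constant_map_rejected(self):
        centroids = hemisphere_centroids(20)
        with pytest.raises(ValueError, match="zero-variance"):
            spin_test(np.std, np.ones(20), centroids, n_rotations=10, seed=0)

    def test_generic_and_batched_spin_agree(self, rng):
        centroids = hemisphere_centroids(30)
        X = pd.DataFrame(rng.standard_normal((30, 12)))
        y = rng.standard_normal(30)

        def statistic(values):
            return pls_first_component(X, pd.Series(values, index=X.index),
                                       n_components=1).variance_explained

        _, p_generic = spin_test(statistic, y, centroids, n_rotations=49, seed=11)
        _, p_batch = spin_test_pls(X, y, centroids, n_rotations=49, seed=11)
        assert p_generic == pytest.approx(p_batch)

    def test_statistic_retry_on_failure(self, rng):
        centroids = hemisphere_centroids(25)
        y = rng.standard_normal(25)
        calls = {"n": 0}

        def flaky(values):
            calls["n"] += 1
            if calls["n"] == 3:
                raise RuntimeError("transient")
            return float(values[0])

        null, p = spin_test(flaky, y, centroids, n_rotations=20, seed=5)
        assert len(null.values) == 20 and np.isfinite(null.values).all()


def test_spin_never_more_liberal_than_naive_permutation():
    """On spatially smooth null maps, destroying autocorrelation (naive
    permutation) rejects at least as often as the structure-preserving
    spin test."""
    from morphotx.synth import gp_cholesky, great_circle_distances, smooth_fields

    coords = hemisphere_centroids(120).to_numpy()
    chol = gp_cholesky(great_circle_distances(coords), 0.5)
    spin_perms = spin_permutations(coords, 99, seed=17)
    perm_rng = np.random.default_rng(18)
    naive_perms = np.array([perm_rng.permutation(120) for _ in range(99)])
    field_rng = np.random.default_rng(19)
    spin_rej = naive_rej = 0
    for _ in range(200):
        X = pd.DataFrame(smooth_fields(chol, 250, field_rng))
        y = smooth_fields(chol, 1, field_rng)[:, 0]
        _, p_spin = spin_test_pls(X, y, None, perms=spin_perms)
        _, p_naive = spin_test_pls(X, y, None, perms=naive_perms)
        spin_rej += p_spin <= 0.05
        naive_rej += p_naive <= 0.05
    assert naive_rej >= spin_rej


class TestBootstrapZ:
    def test_duplicated_gene_column_symmetry(self, rng):
        X, y = _instance(rng, n=60, g=6)
        X["G_dup"] = X["G0"] .to_numpy()
        z = bootstrap_gene_z(X, y, n_boot=400, seed=2)
        assert z.loc["G0", "weight"] == pytest.approx(z.loc["G_dup", "weight"], abs=1e-12)
        assert z.loc["G0", "se"] == pytest.approx(z.loc["G_dup", "se"], rel=0.05)
        assert z.loc["G0", "z"] == pytest.approx(z.loc["G_dup", "z"], rel=0.05)

    def test_fixed_seed_reproducible(self, rng):
        X, y = _instance(rng, n=25, g=5)
        a = bootstrap_gene_z(X, y, n_boot=150, seed=9)
        b = bootstrap_gene_z(X, y, n_boot=150, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_z_sign_matches_weight_and_se_positive(self, rng):
        X, y = _instance(rng, n=40, g=10)
        z = bootstrap_gene_z(X, y, n_boot=150, seed=4)
        assert (z["se"] > 0).all()
        assert np.all(np.sign(z["z"]) == np.sign(z["weight"]))
        assert np.all((z["p"] > 0) & (z["p"] <= 1)) and np.all(z["q"] >= z["p"] - 1e-15)


class TestGeneSetExtraction:
    def test_empty_below_threshold(self):
        tab = pd.DataFrame({"z": [1.0, -2.0], "q": [0.001, 0.001]},
                           index=["a", "b"])
        assert extract_pls_gene_sets(tab, 5.0, 0.05) == ([], [])

    def test_direct_partition(self):
        tab = pd.DataFrame({"z": [6.0, -6.0, 0.0], "q": [1e-9, 1e-9, 0.9]},
                           index=["up", "down", "nil"])
        plus, minus = extract_pls_gene_sets(tab, 5.0, 0.05)
        assert plus == ["up"] and minus == ["down"]

    def test_sizes_monotone_in_threshold(self, rng):
        tab = pd.DataFrame({"z": rng.standard_normal(300) * 4,
                            "q": rng.uniform(0, 0.04, 300)},
                           index=[f"g{i}" for i in range(300)])
        sizes = []
        for thr in (0.5, 1.0, 2.0, 4.0, 8.0):
            plus, minus = extract_pls_gene_sets(tab, thr, 0.05)
            sizes.append(len(plus) + len(minus))
        assert sizes == sorted(sizes, reverse=True)


class TestScoreMapCorrelation:
    def test_exact_and_sign_flip(self, rng):
        t = pd.Series(rng.standard_normal(20), index=[f"R{i}" for i in range(20)])
        r, p = weights_tmap_correlation(t, t)
        assert r == pytest.approx(1.0)
        r_neg, _ = weights_tmap_correlation(-t, t)
        assert r_neg == pytest.approx(-1.0)

    def test_alignment_required(self, rng):
        scores = pd.Series(rng.standard_normal(5), index=list("abcde"))
        with pytest.raises(ValueError, match="aligned"):
            weights_tmap_correlation(scores, pd.Series(np.ones(5), index=list("fghij")))
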