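import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from scipy.spatial import procrustes
from skbio import DistanceMatrix
import skbio.stats.distance as skd
import skbio.stats.ordination as sko

from ecoturn.multivariate import anosim, distlm, mantel, pcoa, permanova


def euclid_dm(points, ids=None):
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 1:
        points = points.T
    ids = ids or [f"s{i}" for i in range(points.shape[0])]
    return DistanceMatrix(squareform(pdist(points)), ids=ids)


class TestPcoa:
    def test_unit_square_eigenvalues(self):
        dm = euclid_dm([[0, 0], [1, 0], [1, 1], [0, 1]])
        res = pcoa(dm)
        assert abs(res.eigenvalues[0] - 1.0) < 1e-8
        assert abs(res.eigenvalues[1] - 1.0) < 1e-8
        assert np.all(np.abs(res.eigenvalues[2:]) < 1e-8)

    def test_collinear_points_single_axis(self):
        res = pcoa(euclid_dm([0.0, 1.0, 2.0]))
        assert res.eigenvalues[0] > 1e-6
        assert abs(res.eigenvalues[1]) < 1e-10

    def test_equidistant_points_equal_eigenvalues(self):
        n = 5
        d = np.ones((n, n)) - np.eye(n)
        res = pcoa(DistanceMatrix(d, ids=[f"s{i}" for i in range(n)]))
        # regular simplex: n-1 equal positive eigenvalues
        np.testing.assert_allclose(res.eigenvalues[:n - 1],
                                   res.eigenvalues[0], rtol=1e-10)

    def test_euclidean_round_trip_procrustes(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(12, 3))
        res = pcoa(euclid_dm(pts))
        _, _, disparity = procrustes(pts, res.coordinates.to_numpy()[:, :3])
        assert disparity < 1e-8

    def test_matches_skbio(self):
        rng = np.random.default_rng(6)
        dm = euclid_dm(rng.normal(size=(9, 4)))
        mine = pcoa(dm)
        ref = sko.pcoa(dm)
        np.testing.assert_allclose(mine.eigenvalues[:5],
                                   np.asarray(ref.eigvals)[:5], atol=1e-8)

    def test_asymmetric_input_rejected(self):
        bad = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError):
            pcoa(bad)


class TestPermanova:
    def test_two_cluster_fixture_closed_form(self):
        """1-D points {0,1} vs {10,11}: SS partition, F and the exact
        enumerated p-value have closed forms."""
        dm = euclid_dm([0.0, 1.0, 10.0, 11.0], ids=list("abcd"))
        factors = pd.DataFrame({"g": ["A", "A", "B", "B"]}, index=list("abcd"))
        res = permanova(dm, factors, "g", exact=True)
        row = res.table.loc["g"]
        assert row["sum_sq"] == pytest.approx(100.0)
        assert res.table.loc["Total", "sum_sq"] == pytest.approx(101.0)
        assert row["pseudo_F"] == pytest.approx(200.0)
        assert row["R2"] == pytest.approx(100 / 101)
        assert row["p"] == pytest.approx(1 / 3)

    def test_equals_classical_anova_on_euclidean_1d(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            y = rng.normal(size=12)
            g = np.array(["A"] * 6 + ["B"] * 6)
            res = permanova(euclid_dm(y), pd.DataFrame({"g": g}), "g",
                            n_perm=99, seed=1)
            f_ref = stats.f_oneway(y[:6], y[6:]).statistic
            assert res.table.loc["g", "pseudo_F"] == pytest.approx(f_ref)

    def test_matches_skbio_one_way(self):
        rng = np.random.default_rng(3)
        dm = euclid_dm(rng.normal(size=(10, 3)))
        g = ["A"] * 5 + ["B"] * 5
        mine = permanova(dm, pd.DataFrame({"g": g}, index=dm.ids), "g",
                         n_perm=99, seed=0)
        ref = skd.permanova(dm, g, permutations=99)
        assert mine.table.loc["g", "pseudo_F"] == pytest.approx(
            ref["test statistic"])

    def test_crossed_design_r2_sums_to_one(self, tiny_sim):
        from ecoturn.dissimilarity import distance_matrix
        table, meta, _ = tiny_sim
        res = permanova(distance_matrix(table), meta,
                        "site + season + site:season", n_perm=99, seed=0)
        assert res.table["R2"].drop("Total").sum() == pytest.approx(1.0)
        assert (res.table["df"].drop("Total").sum()) == table.n_samples - 1

    def test_no_group_structure_gives_tiny_r2(self):
        # identical duplicate of every sample in both groups
        pts = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
        g = ["A"] * 3 + ["B"] * 3
        res = permanova(euclid_dm(pts), pd.DataFrame({"g": g}), "g",
                        n_perm=99, seed=0)
        assert res.table.loc["g", "R2"] == pytest.approx(0.0, abs=1e-10)

    def test_sampled_p_matches_exact_within_binomial_error(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=6)
        g = ["A"] * 3 + ["B"] * 3
        fac = pd.DataFrame({"g": g})
        p_exact = permanova(euclid_dm(y), fac, "g", exact=True).table.loc["g", "p"]
        n_perm = 999
        p_mc = permanova(euclid_dm(y), fac, "g", n_perm=n_perm,
                         seed=4).table.loc["g", "p"]
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(p_mc - p_exact) < 3 * se + 2 / n_perm

    def test_single_level_factor_rejected(self):
        dm = euclid_dm([0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="levels"):
            permanova(dm, pd.DataFrame({"g": ["A", "A", "A"]}), "g", n_perm=99)

    def test_confounded_terms_reported(self):
        dm = euclid_dm([0.0, 1.0, 2.0, 3.0])
        fac = pd.DataFrame({"a": ["x", "x", "y", "y"],
                            "b": ["u", "u", "v", "v"]})
        with pytest.raises(ValueError, match="confounded"):
            permanova(dm, fac, "a + b", n_perm=99)


class TestAnosim:
    def test_perfect_separation_r_is_one(self):
        dm = euclid_dm([0.0, 0.1, 0.2, 0.3, 10.0, 10.1, 10.2, 10.3])
        res = anosim(dm, np.array(["A"] * 4 + ["B"] * 4), n_perm=199, seed=0)
        assert res["R"] == pytest.approx(1.0)
        assert res["p"] <= 0.05  # only label-preserving permutations reach R=1

    def test_matches_skbio(self):
        rng = np.random.default_rng(8)
        dm = euclid_dm(rng.normal(size=(12, 2)))
        g = ["A"] * 6 + ["B"] * 6
        mine = anosim(dm, np.array(g), n_perm=99, seed=0)
        ref = skd.anosim(dm, g, permutations=99)
        assert mine["R"] == pytest.approx(ref["test statistic"])

    def test_singleton_group_rejected(self):
        dm = euclid_dm([0.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            anosim(dm, np.array(["A", "A", "B"]), n_perm=99)


class TestMantel:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(2)
        d = squareform(pdist(rng.normal(size=(8, 2))))
        assert mantel(d, d, n_perm=99, seed=0)["r"] == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        d = squareform(pdist(rng.normal(size=(8, 2))))
        d2 = 0.3 + 2.0 * d
        np.fill_diagonal(d2, 0)
        assert mantel(d, d2, n_perm=99, seed=0)["r"] == pytest.approx(1.0)

    def test_matches_skbio(self):
        rng = np.random.default_rng(4)
        a = DistanceMatrix(squareform(pdist(rng.normal(size=(9, 2)))))
        b = DistanceMatrix(squareform(pdist(rng.normal(size=(9, 2)))))
        mine = mantel(a, b, n_perm=99, seed=0)
        r_ref = skd.mantel(a, b, permutations=0)[0]
        assert mine["r"] == pytest.approx(r_ref)

    def test_spearman_rank_based(self):
        rng = np.random.default_rng(5)
        d = squareform(pdist(rng.normal(size=(8, 2))))
        d2 = d ** 3  # monotone transform
        assert mantel(d, d2, method="spearman",
                      n_perm=99, seed=0)["r"] == pytest.approx(1.0)

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError):
            mantel(np.zeros((3, 3)), np.zeros((4, 4)), n_perm=99)


class TestDistlm:
    def test_single_variable_explains_everything(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=10)
        env = pd.DataFrame({"y": y})
        res = distlm(euclid_dm(y), env, n_perm=99, seed=0)
        assert res.marginal.loc[0, "pct_variation"] == pytest.approx(100.0)

    def test_orthogonal_variables_partition_exactly(self):
        """With x1 orthogonal to x2 and D Euclidean on (x1, x2), the
        conditional share of each variable equals its marginal share and
        the cumulative reaches 100%."""
        n = 8
        x1 = np.cos(2 * np.pi * np.arange(n) / n)
        x2 = np.sin(2 * np.pi * np.arange(n) / n)
        env = pd.DataFrame({"x1": x1, "x2": x2})
        dm = euclid_dm(np.column_stack([2 * x1, x2]))
        res = distlm(dm, env, n_perm=999, seed=0, selection_alpha=1.0)
        marg = res.marginal.set_index("variable")["pct_variation"]
        seq = res.sequential.set_index("variable")
        assert seq["pct_cumulative"].iloc[-1] == pytest.approx(100.0, abs=1e-6)
        for v in ("x1", "x2"):
            assert seq.loc[v, "pct_added"] == pytest.approx(marg[v], abs=1e-6)

    def test_pure_noise_selects_nothing(self):
        rng = np.random.default_rng(7)
        # structureless distances, unrelated noise predictors
        dm = euclid_dm(rng.normal(size=(14, 6)))
        env = pd.DataFrame({f"n{i}": rng.normal(size=14) for i in range(3)})
        res = distlm(dm, env, n_perm=199, seed=1, selection_alpha=0.01)
        assert len(res.sequential) == 0
        assert "did not improve" in res.stop_reason

    def test_constant_variable_excluded_with_warning(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=8)
        env = pd.DataFrame({"y": y, "const": np.ones(8)})
        with pytest.warns(UserWarning, match="constant"):
            res = distlm(euclid_dm(y), env, n_perm=99, seed=0)
        assert list(res.marginal["variable"]) == ["y"]

    def test_cumulative_is_nondecreasing_and_bounded(self, tiny_sim):
        from ecoturn.dissimilarity import distance_matrix
        table, meta, env = tiny_sim
        res = distlm(distance_matrix(table), env, n_perm=99, seed=0,
                     selection_alpha=1.0)
        cum = res.sequential["pct_cumulative"].to_numpy()
        assert np.all(np.diff(cum) >= -1e-9)
        assert cum[-1] <= 100 + 1e-9
        assert res.marginal["pct_variation"].between(0, 100).all()
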