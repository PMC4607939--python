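import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from ecoturn.dissimilarity import distance_matrix
from ecoturn.simulate import SimConfig, generate_dataset
from ecoturn.turnover import (compare_slopes, similarity_lag_pairs,
                              slope_test_zero, tdr_fit,
                              within_group_similarity)


def power_law_pairs(lags, w=0.1, c=0.5):
    """Exact power-law similarity s = c * lag^-w, one pair per lag."""
    rows = []
    for i, lag in enumerate(lags):
        rows.append({"sample_i": f"a{i}", "sample_j": f"b{i}",
                     "day_i": 0.0, "day_j": float(lag),
                     "lag_days": float(lag), "similarity": c * lag ** (-w)})
    return pd.DataFrame(rows)


def meta_frame(sites, days, reps):
    rows, ids = [], []
    for s in sites:
        for d in days:
            for r in range(reps):
                ids.append(f"{s}_d{d}_r{r}")
                rows.append({"site": s, "day": d, "replicate": r})
    return pd.DataFrame(rows, index=ids)


class TestSimilarityLagPairs:
    def test_pair_counting_two_timepoints(self):
        meta = meta_frame(["site1"], [1, 6], 2)
        d = DistanceMatrix(1 - np.eye(4), ids=list(meta.index))
        pairs = similarity_lag_pairs(d, meta, group="site1")
        assert (pairs["lag_days"] == 0).sum() == 2
        assert (pairs["lag_days"] == 5).sum() == 4

    def test_identical_samples_full_similarity(self):
        meta = meta_frame(["site1"], [1, 6], 1)
        d = DistanceMatrix(np.zeros((2, 2)), ids=list(meta.index))
        pairs = similarity_lag_pairs(d, meta, group="site1")
        assert pairs["similarity"].iloc[0] == 1.0

    def test_lag_arithmetic(self):
        meta = meta_frame(["site1"], [1, 6, 60], 1)
        d = DistanceMatrix(1 - np.eye(3), ids=list(meta.index))
        pairs = similarity_lag_pairs(d, meta, group="site1")
        assert sorted(pairs["lag_days"]) == [5, 54, 59]

    def test_single_timepoint_rejected(self):
        meta = meta_frame(["site1"], [3], 2)
        d = DistanceMatrix(np.zeros((2, 2)), ids=list(meta.index))
        with pytest.raises(ValueError, match="single time point"):
            similarity_lag_pairs(d, meta, group="site1")


class TestTdrFit:
    def test_exact_power_law_recovered(self):
        pairs = power_law_pairs([5, 54, 59, 88, 142, 147], w=0.1)
        fit = tdr_fit(pairs)
        assert fit.slope == pytest.approx(-0.1, abs=1e-10)
        assert fit.w == pytest.approx(0.1, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_constant_similarity_zero_slope(self):
        pairs = power_law_pairs([5, 54, 59], w=0.0)
        fit = tdr_fit(pairs)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.w == -fit.slope

    def test_lag_rescaling_only_moves_intercept(self):
        pairs = power_law_pairs([5, 50, 100, 140], w=0.2, c=0.4)
        scaled = pairs.assign(lag_days=pairs["lag_days"] * 7.0)
        f1, f2 = tdr_fit(pairs), tdr_fit(scaled)
        assert f2.slope == pytest.approx(f1.slope, abs=1e-12)
        assert f2.intercept != pytest.approx(f1.intercept)

    def test_mean_per_lag_aggregation(self):
        # two pairs at one lag average before the log transform
        pairs = pd.concat([power_law_pairs([5, 50, 100]),
                           power_law_pairs([5])], ignore_index=True)
        pairs.loc[3, "similarity"] = 0.9
        fit = tdr_fit(pairs)
        expected_s5 = (0.5 * 5 ** -0.1 + 0.9) / 2
        assert 10 ** fit.predict([5])[0] > 0  # smoke: prediction defined
        assert fit.n_lags == 3
        # all-pairs mode keeps both points
        assert tdr_fit(pairs, aggregation="all-pairs").n_pairs == 4
        del expected_s5

    def test_zero_similarity_lags_dropped_with_warning(self):
        pairs = power_law_pairs([5, 50, 100, 140])
        pairs.loc[1, "similarity"] = 0.0
        with pytest.warns(UserWarning, match="zero similarity"):
            fit = tdr_fit(pairs)
        assert fit.n_lags == 3

    def test_too_few_lags_rejected(self):
        with pytest.raises(ValueError, match="3 usable"):
            tdr_fit(power_law_pairs([5, 10]))

    def test_turnover_rate_orders_with_theta(self):
        """Communities with faster latent mean reversion show a steeper
        fitted decay over matched seeds."""
        wins = 0
        for seed in range(20):
            ws = []
            for theta in (0.004, 0.03):
                cfg = SimConfig(n_sites=1, n_otus_pool=80, reads_per_sample=400,
                                n_replicates=2, turnover_theta=theta,
                                filter_strength=0.0, site_effect=0.0, seed=seed)
                table, meta, _ = generate_dataset(cfg)
                pairs = similarity_lag_pairs(distance_matrix(table), meta,
                                             group="site1")
                ws.append(tdr_fit(pairs).w)
            wins += ws[1] > ws[0]
        assert wins >= 19


class TestSlopeTests:
    def test_constant_similarity_not_significant(self):
        pairs = power_law_pairs([5, 54, 59, 88, 142, 147], w=0.0)
        fit = tdr_fit(pairs)
        res = slope_test_zero(fit, pairs, n_perm=99, n_boot=100, seed=0)
        assert res["p"] > 0.5

    def test_strong_decay_hits_grid_minimum(self):
        meta = meta_frame(["site1"], [1, 6, 60, 66, 148, 153], 2)
        days = meta["day"].to_numpy(dtype=float)
        # similarity decays exactly with lag: distances from a power law
        lag = np.maximum(np.abs(days[:, None] - days[None, :]), 1.0)
        sim = 0.8 * lag ** -0.15
        d = 1 - sim
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix((d + d.T) / 2, ids=list(meta.index))
        pairs = similarity_lag_pairs(dm, meta, group="site1")
        fit = tdr_fit(pairs)
        res = slope_test_zero(fit, pairs, n_perm=199, n_boot=100, seed=0)
        assert res["p"] == pytest.approx(1 / 200)

    def test_boot_slope_count_and_ci(self):
        pairs = power_law_pairs([5, 54, 59, 88, 142, 147], w=0.1)
        fit = tdr_fit(pairs)
        res = slope_test_zero(fit, pairs, n_perm=99, n_boot=150, seed=1)
        assert len(res["boot_slopes"]) == 150
        lo, hi = res["boot_ci"]
        assert lo <= hi

    def test_small_boot_rejected(self):
        pairs = power_law_pairs([5, 54, 59])
        fit = tdr_fit(pairs)
        with pytest.raises(ValueError, match="n_boot"):
            slope_test_zero(fit, pairs, n_boot=10, seed=0)


class TestCompareSlopes:
    def _dm_meta(self, seed, theta_by_site):
        tables = []
        metas = []
        for i, (site, theta) in enumerate(theta_by_site.items()):
            cfg = SimConfig(n_sites=1, n_otus_pool=80, reads_per_sample=400,
                            n_replicates=2, turnover_theta=theta,
                            filter_strength=0.0, site_effect=0.0,
                            seed=seed + 1000 * i)
            t, m, _ = generate_dataset(cfg)
            t.data.columns = [c.replace("site1", site) for c in t.data.columns]
            m.index = [c.replace("site1", site) for c in m.index]
            m["site"] = site
            tables.append(t.data)
            metas.append(m)
        combined = pd.concat(tables, axis=1)
        from ecoturn.tables import CommunityTable
        return (distance_matrix(CommunityTable(combined)),
                pd.concat(metas))

    def test_identical_group_zero_delta(self):
        meta = meta_frame(["a", "b"], [1, 6, 60, 66], 1)
        n = len(meta)
        rng = np.random.default_rng(0)
        block = rng.uniform(0.2, 0.8, size=(4, 4))
        d = np.zeros((n, n))
        # same distance structure duplicated in both groups
        d[:4, :4] = (block + block.T) / 2
        d[4:, 4:] = (block + block.T) / 2
        d[:4, 4:] = 0.5
        d[4:, :4] = 0.5
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(d, ids=list(meta.index))
        res = compare_slopes(dm, meta, ("a", "b"), n_perm=99, seed=0)
        assert res["delta_w"] == pytest.approx(0.0, abs=1e-12)

    def test_detects_turnover_difference(self):
        res_ps = []
        for seed in range(5):
            dm, meta = self._dm_meta(seed, {"fast": 0.03, "slow": 0.002})
            res = compare_slopes(dm, meta, ("fast", "slow"), n_perm=99,
                                 seed=seed)
            res_ps.append((res["delta_w"], res["p"]))
        deltas = [d for d, _ in res_ps]
        assert np.mean([d > 0 for d in deltas]) >= 0.8


class TestWithinGroupSimilarity:
    def test_identical_samples(self):
        meta = meta_frame(["g"], [1, 6], 2)
        dm = DistanceMatrix(np.zeros((4, 4)), ids=list(meta.index))
        res = within_group_similarity(dm, meta, group_col="site")
        rec = res["groups"]["g"]
        assert rec["mean"] == 1.0 and rec["sd"] == 0.0

    def test_pair_count_for_group_of_four(self):
        meta = meta_frame(["g"], [1, 6], 2)
        dm = DistanceMatrix(1 - np.eye(4), ids=list(meta.index))
        assert within_group_similarity(dm, meta)["groups"]["g"]["n"] == 6

    def test_two_group_difference_reported(self, tiny_sim):
        table, meta, _ = tiny_sim
        res = within_group_similarity(distance_matrix(table), meta,
                                      n_perm=99, seed=0)
        assert set(res["groups"]) == {"site1", "site2"}
        assert 0 <= res["difference"]["p"] <= 1
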