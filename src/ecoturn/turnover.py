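"""Time-decay of community similarity (temporal turnover).

Community similarity ``s = 1 - d`` between pairs of samples from one site is
regressed on the time interval separating them in log-log space:

    log10(s) = intercept + slope * log10(lag_days),

and the turnover rate is ``w = -slope`` (positive when similarity decays).
By default similarities are first averaged within each distinct lag
("mean-per-lag"), the convention of time-decay analyses that plot one point
per sampling-interval class; an all-pairs regression is available.

Inference
---------
* :func:`slope_test_zero` tests ``slope = 0``.  The primary p-value comes
  from a permutation null that relabels *samples* (rows/columns of the
  within-group similarity matrix are permuted jointly, lags fixed), which
  respects the dependence among pairs that share a sample.  A pair-level
  shuffle of similarities across lags is available as an option.  A
  bootstrap distribution of the slope — resampling samples with
  replacement and recomputing all pairs — is reported alongside, together
  with the legacy one-sample t-test of the observed rate against the
  bootstrap mean.
* :func:`compare_slopes` tests the difference in turnover rate between two
  groups by reassigning samples to groups at random and recomputing both
  fits per permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

__all__ = [
    "similarity_lag_pairs",
    "tdr_fit",
    "TdrFit",
    "slope_test_zero",
    "compare_slopes",
    "within_group_similarity",
]


def similarity_lag_pairs(d: DistanceMatrix, meta: pd.DataFrame,
                         group: str | None = None, group_col: str = "site",
                         day_col: str = "day") -> pd.DataFrame:
    """All unordered within-group sample pairs with their time lag.

    Returns a frame with columns ``sample_i``, ``sample_j``, ``lag_days``,
    ``similarity``; lag-0 (replicate) pairs are included with ``lag_days = 0``
    so callers can use them for within-group similarity contrasts (the
    regression itself drops them).
    """
    ids = list(d.ids)
    meta = meta.loc[ids]
    if group is not None:
        mask = meta[group_col] == group
        ids = [s for s, m in zip(ids, mask) if m]
        if not ids:
            raise ValueError(f"no samples in group {group!r}")
        meta = meta.loc[ids]
        d = d.filter(ids)
    days = meta[day_col].to_numpy(dtype=float)
    if len(np.unique(days)) < 2:
        raise ValueError("group has a single time point; no lags to regress on")
    sim = 1.0 - d.data
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    return pd.DataFrame({
        "sample_i": [ids[i] for i in iu[0]],
        "sample_j": [ids[j] for j in iu[1]],
        "day_i": days[iu[0]],
        "day_j": days[iu[1]],
        "lag_days": np.abs(days[iu[1]] - days[iu[0]]),
        "similarity": sim[iu],
    })


@dataclass
class TdrFit:
    """A fitted time-decay-of-similarity regression."""

    slope: float
    intercept: float
    r_squared: float
    n_lags: int
    n_pairs: int
    aggregation: str
    dropped_lags: list

    @property
    def w(self) -> float:
        """Turnover rate, the negated slope."""
        return -self.slope

    def predict(self, lags) -> np.ndarray:
        """Predicted similarity at the given lags (days)."""
        lags = np.asarray(lags, dtype=float)
        return 10.0 ** (self.intercept + self.slope * np.log10(lags))

    def summary(self) -> str:
        return ("Time-decay fit (log10 similarity ~ log10 lag)\n"
                f"  slope     {self.slope: .5f}   (w = {self.w:.5f})\n"
                f"  intercept {self.intercept: .5f}\n"
                f"  R^2       {self.r_squared: .5f}\n"
                f"  lags used {self.n_lags} ({self.n_pairs} pairs, "
                f"{self.aggregation})")


def _regression_points(pairs: pd.DataFrame, aggregation: str):
    pos = pairs[pairs["lag_days"] > 0]
    if aggregation == "mean-per-lag":
        grouped = pos.groupby("lag_days")["similarity"].mean()
        lags = grouped.index.to_numpy(dtype=float)
        sims = grouped.to_numpy(dtype=float)
    elif aggregation == "all-pairs":
        lags = pos["lag_days"].to_numpy(dtype=float)
        sims = pos["similarity"].to_numpy(dtype=float)
    else:
        raise ValueError("aggregation must be 'mean-per-lag' or 'all-pairs'")
    ok = sims > 0
    dropped = sorted(set(lags[~ok]))
    return lags[ok], sims[ok], dropped, len(pos)


def tdr_fit(pairs: pd.DataFrame, aggregation: str = "mean-per-lag") -> TdrFit:
    """Ordinary least squares of log10(similarity) on log10(lag).

    Lags whose (aggregated) similarity is 0 are dropped with a warning
    (their log is undefined); at least 3 usable distinct lags are required.
    """
    lags, sims, dropped, n_pairs = _regression_points(pairs, aggregation)
    if dropped:
        warnings.warn(f"dropped lags with zero similarity: {dropped}",
                      UserWarning, stacklevel=2)
    if len(np.unique(lags)) < 3:
        raise ValueError("fewer than 3 usable distinct lags")
    x, y = np.log10(lags), np.log10(sims)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = intercept + slope * x
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res < 1e-20 else 0.0)
    return TdrFit(float(slope), float(intercept), float(r2),
                  int(len(np.unique(lags))), n_pairs, aggregation, dropped)


def _slope_arrays(lags: np.ndarray, sims: np.ndarray, aggregation: str) -> float:
    """Closed-form log-log OLS slope from raw pair arrays (NaN if degenerate).

    Pairs with unknown (NaN) similarity are ignored."""
    known = np.isfinite(sims)
    lags, sims = lags[known], sims[known]
    if aggregation == "mean-per-lag":
        uniq, inv = np.unique(lags, return_inverse=True)
        sims = np.bincount(inv, weights=sims) / np.bincount(inv)
        lags = uniq
    ok = (lags > 0) & (sims > 0)
    lags, sims = lags[ok], sims[ok]
    if len(np.unique(lags)) < 3:
        return np.nan
    x, y = np.log10(lags), np.log10(sims)
    xc = x - x.mean()
    return float(np.dot(xc, y) / np.dot(xc, xc))


def slope_test_zero(fit: TdrFit, pairs: pd.DataFrame, n_perm: int = 999,
                    n_boot: int = 1000, seed: int | None = None,
                    method: str = "samples") -> dict:
    """Test the fitted slope against zero.

    Returns a dict with the permutation p-value (primary), the bootstrap
    slope distribution with its percentile CI (secondary), and the legacy
    one-sample t-test of the observed slope against the bootstrap mean.

    ``method='samples'`` (default) permutes sample identities over the
    similarity matrix while keeping the lag structure — valid when samples,
    not pairs, are the exchangeable units.  ``method='pairs'`` shuffles the
    similarity values across lag pairs.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    rng = np.random.default_rng(seed)
    slope_obs = fit.slope

    if "day_i" not in pairs.columns or "day_j" not in pairs.columns:
        raise ValueError("pairs frame must carry day_i/day_j columns "
                         "(as produced by similarity_lag_pairs)")
    samples = sorted(set(pairs["sample_i"]) | set(pairs["sample_j"]))
    idx_of = {s: i for i, s in enumerate(samples)}
    si = pairs["sample_i"].map(idx_of).to_numpy()
    sj = pairs["sample_j"].map(idx_of).to_numpy()
    sims = pairs["similarity"].to_numpy(dtype=float)
    days = np.zeros(len(samples))
    days[si] = pairs["day_i"].to_numpy(dtype=float)
    days[sj] = pairs["day_j"].to_numpy(dtype=float)
    lags_obs = pairs["lag_days"].to_numpy(dtype=float)

    count = 0
    if method == "samples":
        # permute which sample sits at which day (lag structure kept, pair
        # dependence respected), i.e. relabel samples at random
        for _ in range(n_perm):
            dp = days[rng.permutation(len(samples))]
            sp = _slope_arrays(np.abs(dp[si] - dp[sj]), sims, fit.aggregation)
            if np.isfinite(sp) and abs(sp) >= abs(slope_obs) - 1e-12:
                count += 1
    elif method == "pairs":
        for _ in range(n_perm):
            sp = _slope_arrays(lags_obs, rng.permutation(sims), fit.aggregation)
            if np.isfinite(sp) and abs(sp) >= abs(slope_obs) - 1e-12:
                count += 1
    else:
        raise ValueError("method must be 'samples' or 'pairs'")
    p_perm = (count + 1) / (n_perm + 1)

    # full similarity lookup for the sample-level bootstrap
    n_s = len(samples)
    sim_mat = np.full((n_s, n_s), np.nan)
    sim_mat[si, sj] = sims
    sim_mat[sj, si] = sims
    boot = []
    attempts = 0
    while len(boot) < n_boot and attempts < 20 * n_boot:
        attempts += 1
        take = rng.integers(0, n_s, size=n_s)
        ii, jj = np.triu_indices(n_s, k=1)
        a, b = take[ii], take[jj]
        distinct = a != b
        a, b = a[distinct], b[distinct]
        sb = _slope_arrays(np.abs(days[a] - days[b]), sim_mat[a, b],
                           fit.aggregation)
        if np.isfinite(sb):
            boot.append(sb)
    boot = np.asarray(boot)
    if len(boot) == 0:
        raise ValueError("bootstrap failed: no resample produced a fit")
    ci = tuple(np.percentile(boot, [2.5, 97.5]))
    t_stat, t_p = stats.ttest_1samp(boot, popmean=slope_obs)
    return {
        "p": p_perm,
        "method": method,
        "n_permutations": n_perm,
        "boot_slopes": boot,
        "boot_ci": ci,
        "t_boot": float(t_stat),
        "t_boot_p": float(t_p),
        "seed": seed,
    }


def compare_slopes(d: DistanceMatrix, meta: pd.DataFrame,
                   groups: tuple[str, str], group_col: str = "site",
                   day_col: str = "day", n_perm: int = 1000,
                   seed: int | None = None,
                   aggregation: str = "mean-per-lag") -> dict:
    """Two-sided permutation test of the difference in turnover rate.

    ``delta_w = w_A - w_B``; the null reassigns samples to the two groups at
    random (sample-level relabelling), recomputes within-group pairs and
    refits both regressions per permutation.
    """
    ga, gb = groups
    meta = meta.loc[list(d.ids)]
    members = {g: [s for s in d.ids if meta.loc[s, group_col] == g] for g in groups}
    for g, mem in members.items():
        if len(mem) < 4:
            raise ValueError(f"group {g!r} has too few samples to fit a decay curve")
    pool = members[ga] + members[gb]
    n_a = len(members[ga])
    sub = d.filter(pool)
    sim = 1.0 - sub.data
    days = meta.loc[pool, day_col].to_numpy(dtype=float)
    idx_of = {s: i for i, s in enumerate(pool)}

    def slope_for(indices: np.ndarray) -> float:
        ii, jj = np.triu_indices(len(indices), k=1)
        a_idx, b_idx = indices[ii], indices[jj]
        return _slope_arrays(np.abs(days[a_idx] - days[b_idx]),
                             sim[a_idx, b_idx], aggregation)

    all_idx = np.arange(len(pool))
    obs_a = slope_for(np.array([idx_of[s] for s in members[ga]]))
    obs_b = slope_for(np.array([idx_of[s] for s in members[gb]]))
    if not (np.isfinite(obs_a) and np.isfinite(obs_b)):
        raise ValueError("degenerate group: could not fit a decay curve")
    delta_obs = (-obs_a) - (-obs_b)

    rng = np.random.default_rng(seed)
    count, used = 0, 0
    for _ in range(n_perm):
        perm = rng.permutation(all_idx)
        sa = slope_for(np.sort(perm[:n_a]))
        sb = slope_for(np.sort(perm[n_a:]))
        if not (np.isfinite(sa) and np.isfinite(sb)):
            continue
        used += 1
        if abs((-sa) - (-sb)) >= abs(delta_obs) - 1e-12:
            count += 1
    return {"delta_w": delta_obs, "w": {ga: -obs_a, gb: -obs_b},
            "p": (count + 1) / (used + 1), "n_permutations": used, "seed": seed}


def within_group_similarity(d: DistanceMatrix, meta: pd.DataFrame,
                            group_col: str = "site", n_perm: int = 999,
                            seed: int | None = None) -> dict:
    """Within-group pairwise similarities (all lags pooled, lag 0 included).

    Returns per-group mean, sd and pair count; for exactly two groups, a
    permutation p-value for the difference of group means (samples
    relabelled across groups).
    """
    ids = list(d.ids)
    meta = meta.loc[ids]
    groups = meta[group_col].to_numpy()
    labels, counts = np.unique(groups, return_counts=True)
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 samples")
    sim = 1.0 - d.data
    iu = np.triu_indices(len(ids), k=1)
    pair_groups = np.where(groups[iu[0]] == groups[iu[1]], groups[iu[0]], None)
    sims = sim[iu]

    def summaries(pg):
        out = {}
        for lab in labels:
            vals = sims[pg == lab]
            out[lab] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1))
                        if len(vals) > 1 else 0.0, "n": int(len(vals))}
        return out

    result = {"groups": summaries(pair_groups)}
    if len(labels) == 2:
        def diff(pg):
            a = sims[pg == labels[0]].mean()
            b = sims[pg == labels[1]].mean()
            return a - b
        obs = diff(pair_groups)
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            gp = groups[rng.permutation(len(ids))]
            pg = np.where(gp[iu[0]] == gp[iu[1]], gp[iu[0]], None)
            if abs(diff(pg)) >= abs(obs) - 1e-12:
                count += 1
        result["difference"] = {"delta_mean": float(obs),
                                "p": (count + 1) / (n_perm + 1),
                                "n_permutations": n_perm, "seed": seed}
    return result
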