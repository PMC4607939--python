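"""Null-model partitioning of community assembly into deterministic and
stochastic components.

For every within-group sample pair the observed similarity ``s_obs`` is
compared with the similarity expected when community membership is random
under fixed constraints.  The per-pair determinism fraction is

    f = (s_obs - s_null_mean) / s_obs,

positive when communities are more similar than chance (deterministic
convergence), negative when less similar (deterministic divergence), and
near zero when the observed structure is indistinguishable from the null.

Null model
----------
Each randomized table preserves, per sample, the observed richness and total
count.  Taxon identities are drawn without replacement with probability
proportional to each taxon's occurrence frequency across the whole table
(the regional pool), and the sample's observed abundance values are then
randomly permuted across the drawn taxa — a Raup-Crick-style null extended
to abundances.  An unweighted-draw variant (all pool taxa equally likely) is
available for sensitivity analyses.

Aggregation
-----------
Per group of pairs, four summaries are reported:

* ``determinism_pct``     = 100 * mean(max(f, 0))    — deterministic convergence;
* ``divergence_pct``      = 100 * mean(max(-f, 0))   — deterministic divergence;
* ``stochasticity_pct``   = 100 * mean(1 - |f|)      — the complement;
* ``mean_fraction_pct``   = 100 * mean(f)            — signed mean of ratios;
* ``pooled_fraction_pct`` = 100 * (mean(s_obs) - mean(s_null)) / mean(s_obs).

``determinism_pct + divergence_pct + stochasticity_pct = 100``; the first and
third alone generally sum to less than 100 (the asymmetric convention of
published determinacy/stochasticity percentages).  The mean of per-pair
ratios carries a Jensen bias of roughly ``-cv(s_obs)**2`` even for data that
truly follow the null; the pooled (ratio-of-means) variant is unbiased there
and is the quantity to use for neutrality calibration.  Per-pair fractions
are clipped to ``[-1, 1]`` before aggregation; raw values are kept in the
per-pair records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.spatial import distance as ssd
from skbio import DistanceMatrix

from .tables import CommunityTable

__all__ = [
    "null_communities",
    "partition",
    "NullPartition",
    "determinism_contrast",
    "within_group_pairs",
]


def occurrence_weights(table: CommunityTable) -> np.ndarray:
    """Per-taxon occurrence frequency across samples (the draw weights)."""
    return (table.data.to_numpy() > 0).sum(axis=1).astype(float)


def null_communities(table: CommunityTable, n_null: int, seed: int,
                     weighted: bool = True,
                     weights: np.ndarray | None = None) -> Iterator[np.ndarray]:
    """Yield ``n_null`` randomized count matrices (OTUs x samples).

    Every randomization preserves each sample's richness and total count;
    taxon identities are drawn with probability proportional to occurrence
    frequency (or uniformly if ``weighted`` is False, or to explicit
    ``weights``), and observed abundance values are permuted across the
    drawn taxa.  Randomizations are independent given the seed.
    """
    if n_null < 100:
        raise ValueError("n_null must be at least 100")
    counts = table.data.to_numpy()
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("null model requires an integer count table")
    counts = np.round(counts).astype(np.int64)
    n_otus, n_samples = counts.shape
    if weights is None:
        w = occurrence_weights(table) if weighted else np.ones(n_otus)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n_otus,):
            raise ValueError("weights length must equal the number of taxa")
    pool = np.flatnonzero(w > 0)
    p = w[pool] / w[pool].sum()
    sample_abund = [counts[counts[:, j] > 0, j] for j in range(n_samples)]
    richness = np.array([len(a) for a in sample_abund])
    if (richness > len(pool)).any():
        raise ValueError("sample richness exceeds the available taxon pool")
    rng = np.random.default_rng(seed)
    for _ in range(n_null):
        null = np.zeros_like(counts)
        for j in range(n_samples):
            r = richness[j]
            if r == 0:
                continue
            taxa = pool[_weighted_sample_without_replacement(rng, p, r)]
            null[taxa, j] = rng.permutation(sample_abund[j])
        yield null


def _weighted_sample_without_replacement(rng: np.random.Generator,
                                         p: np.ndarray, size: int) -> np.ndarray:
    if size == len(p):
        return np.arange(len(p))
    # Efraimidis-Spirakis exponential-sort trick: O(n) per draw, exact
    keys = rng.exponential(size=len(p)) / p
    return np.argpartition(keys, size)[:size]


def within_group_pairs(meta: pd.DataFrame, group_col: str = "site",
                       season_col: str | None = "season") -> pd.DataFrame:
    """All unordered sample pairs sharing a group label (and, if a season
    column is given, sharing the season), labelled for the partition."""
    rows = []
    ids = list(meta.index)
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            sa, sb = ids[a], ids[b]
            if meta.loc[sa, group_col] != meta.loc[sb, group_col]:
                continue
            row = {"sample_i": sa, "sample_j": sb,
                   "group": meta.loc[sa, group_col]}
            if season_col is not None and season_col in meta.columns:
                if meta.loc[sa, season_col] != meta.loc[sb, season_col]:
                    continue
                row["season"] = meta.loc[sa, season_col]
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class NullPartition:
    """Per-pair determinism fractions and group-level summaries."""

    pairs: pd.DataFrame
    summary: pd.DataFrame
    n_null: int
    seed: int
    metric: str

    def group_summary(self, group) -> pd.Series:
        return self.summary.loc[group]


def _pair_metric(metric: str):
    if metric == "bray_curtis":
        return lambda x, y: ssd.braycurtis(x, y)
    if metric == "sorensen":
        return lambda x, y: ssd.dice(x > 0, y > 0)
    raise ValueError("metric must be 'bray_curtis' or 'sorensen'")


def partition(table: CommunityTable, d_obs: DistanceMatrix, pairs: pd.DataFrame,
              n_null: int = 999, seed: int = 0, metric: str = "bray_curtis",
              weighted: bool = True,
              weights: np.ndarray | None = None) -> NullPartition:
    """Partition within-group pair similarities against the null expectation.

    ``d_obs`` must come from the same ``metric`` applied to ``table``.
    Pairs with zero observed similarity are excluded with a warning.  The
    per-pair Monte-Carlo standard error of ``s_null_mean`` is reported as
    ``s_null_se``.
    """
    dist = _pair_metric(metric)
    ids = list(d_obs.ids)
    idx = {s: i for i, s in enumerate(ids)}
    col = {s: j for j, s in enumerate(table.sample_ids)}
    missing = [s for s in pd.concat([pairs["sample_i"], pairs["sample_j"]]).unique()
               if s not in idx or s not in col]
    if missing:
        raise ValueError(f"pair samples absent from table/distances: {missing[:5]}")

    s_obs = np.array([1.0 - d_obs.data[idx[a], idx[b]]
                      for a, b in zip(pairs["sample_i"], pairs["sample_j"])])
    usable = s_obs > 0
    if (~usable).any():
        warnings.warn(f"excluded {int((~usable).sum())} pair(s) with zero "
                      "observed similarity", UserWarning, stacklevel=2)
    pairs = pairs.loc[usable].reset_index(drop=True)
    s_obs = s_obs[usable]

    ai = pairs["sample_i"].map(col).to_numpy()
    bi = pairs["sample_j"].map(col).to_numpy()
    acc = np.zeros(len(pairs))
    acc2 = np.zeros(len(pairs))
    for null in null_communities(table, n_null, seed, weighted=weighted,
                                 weights=weights):
        s = np.array([1.0 - dist(null[:, a], null[:, b]) for a, b in zip(ai, bi)])
        acc += s
        acc2 += s * s
    s_null_mean = acc / n_null
    s_null_var = np.maximum(acc2 / n_null - s_null_mean ** 2, 0.0)
    s_null_se = np.sqrt(s_null_var / n_null)

    frac = (s_obs - s_null_mean) / s_obs
    clipped = np.clip(frac, -1.0, 1.0)
    records = pairs.copy()
    records["s_obs"] = s_obs
    records["s_null_mean"] = s_null_mean
    records["s_null_sd"] = np.sqrt(s_null_var)
    records["s_null_se"] = s_null_se
    records["determinism_fraction"] = frac

    rows = {}
    for group, sub in records.groupby("group"):
        f = np.clip(sub["determinism_fraction"].to_numpy(), -1.0, 1.0)
        so = sub["s_obs"].to_numpy()
        sn = sub["s_null_mean"].to_numpy()
        rows[group] = {
            "n_pairs": len(f),
            "determinism_pct": 100.0 * np.maximum(f, 0).mean(),
            "divergence_pct": 100.0 * np.maximum(-f, 0).mean(),
            "stochasticity_pct": 100.0 * (1.0 - np.abs(f)).mean(),
            "mean_fraction_pct": 100.0 * f.mean(),
            "pooled_fraction_pct": 100.0 * (so.mean() - sn.mean()) / so.mean(),
        }
    summary = pd.DataFrame(rows).T
    summary.index.name = "group"
    return NullPartition(records, summary, n_null, seed, metric)


def determinism_contrast(part_a: NullPartition, part_b: NullPartition,
                         season_col: str = "season") -> dict:
    """Relative change in determinism between two partitions.

    ``pct_increase = 100 * (det_A - det_B) / det_B`` on the truncated
    determinism percentages, overall (pair-weighted across groups) and per
    season label present in both inputs.
    """
    def overall(part: NullPartition) -> float:
        f = np.clip(part.pairs["determinism_fraction"].to_numpy(), -1, 1)
        return 100.0 * np.maximum(f, 0).mean()

    det_a, det_b = overall(part_a), overall(part_b)
    if det_b == 0:
        raise ValueError("reference determinism is zero; contrast undefined")
    out = {"det_a": det_a, "det_b": det_b,
           "pct_increase": 100.0 * (det_a - det_b) / det_b}
    if season_col in part_a.pairs.columns and season_col in part_b.pairs.columns:
        rows = []
        shared = sorted(set(part_a.pairs[season_col]) & set(part_b.pairs[season_col]))
        for season in shared:
            fa = np.clip(part_a.pairs.loc[part_a.pairs[season_col] == season,
                                          "determinism_fraction"], -1, 1)
            fb = np.clip(part_b.pairs.loc[part_b.pairs[season_col] == season,
                                          "determinism_fraction"], -1, 1)
            da = 100.0 * np.maximum(fa, 0).mean()
            db = 100.0 * np.maximum(fb, 0).mean()
            rows.append({"season": season, "det_a": da, "det_b": db,
                         "pct_increase": np.nan if db == 0
                         else 100.0 * (da - db) / db})
        out["per_season"] = pd.DataFrame(rows).set_index("season")
    return out
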