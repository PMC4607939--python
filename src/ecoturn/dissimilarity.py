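"""Alpha diversity and pairwise community dissimilarity.

Distances are Bray-Curtis (abundance-based) and Sørensen (incidence-based);
similarity used throughout the package is ``1 - dissimilarity``.  Distance
matrices are held in :class:`skbio.DistanceMatrix`, whose tab-delimited
square serialization interoperates with the usual ecology tooling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import distance as ssd
from skbio import DistanceMatrix

from .tables import CommunityTable

__all__ = [
    "bray_curtis",
    "sorensen",
    "distance_matrix",
    "alpha_diversity",
    "similarity",
]

_METRICS = ("bray_curtis", "sorensen")


def _check_pair(x, y, name):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"{name}: vectors must be 1-D with equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError(f"{name}: abundances must be nonnegative")
    if x.sum() == 0 or y.sum() == 0:
        raise ValueError(f"{name}: all-zero abundance vector")
    return x, y


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity, ``1 - 2 * sum(min(x, y)) / (sum(x) + sum(y))``."""
    x, y = _check_pair(x, y, "bray_curtis")
    return float(ssd.braycurtis(x, y))


def sorensen(x, y) -> float:
    """Sørensen (Dice) incidence dissimilarity on presence/absence at count > 0."""
    x, y = _check_pair(x, y, "sorensen")
    return float(ssd.dice(x > 0, y > 0))


def distance_matrix(table: CommunityTable, metric: str = "bray_curtis") -> DistanceMatrix:
    """All pairwise distances between samples of a community table."""
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}, got {metric!r}")
    data = table.data.to_numpy(dtype=float).T  # samples x OTUs
    zero = np.flatnonzero(data.sum(axis=1) == 0)
    if len(zero):
        bad = [table.sample_ids[i] for i in zero]
        raise ValueError(f"all-zero sample(s): {bad}")
    if metric == "bray_curtis":
        condensed = ssd.pdist(data, metric="braycurtis")
    else:
        condensed = ssd.pdist(data > 0, metric="dice")
    return DistanceMatrix(ssd.squareform(condensed), ids=table.sample_ids)


def similarity(dm: DistanceMatrix) -> pd.DataFrame:
    """Similarity matrix ``1 - d`` as a labelled DataFrame."""
    return pd.DataFrame(1.0 - dm.data, index=list(dm.ids), columns=list(dm.ids))


def alpha_diversity(table: CommunityTable, base: float = np.e) -> pd.DataFrame:
    """Per-sample richness, Shannon H' and Pielou evenness.

    ``H' = -sum(p * log p)`` over positive proportions (natural log by
    default); evenness ``J = H' / log(richness)``, defined as 1 for a
    single-taxon sample.
    """
    data = table.data.to_numpy(dtype=float)
    sums = data.sum(axis=0)
    if (sums == 0).any():
        bad = [s for s, t in zip(table.sample_ids, sums) if t == 0]
        raise ValueError(f"empty sample(s): {bad}")
    p = data / sums
    logb = np.log(base)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p) / logb, 0.0)
    shannon = -plogp.sum(axis=0)
    richness = (data > 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        evenness = np.where(richness > 1, shannon / (np.log(richness) / logb), 1.0)
    return pd.DataFrame(
        {"richness": richness, "shannon": shannon, "evenness": evenness},
        index=table.sample_ids,
    )
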