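"""Co-occurrence ("molecular ecological") networks over core OTUs.

The workflow follows the random-matrix-theory (RMT) network approach: compute
pairwise correlations between taxon abundance profiles, scan similarity
thresholds ``st`` and pick the smallest one at which the nearest-neighbour
spacing distribution (NNSD) of the thresholded matrix's unfolded eigenvalues
becomes Poisson (``exp(-d)``) — the signature of uncorrelated, modular
structure — while the unthresholded spectrum is not.  Edges are pairs with
``|r| >= st``; topology metrics (average degree, clustering, path length,
fast-greedy modularity, degree-distribution power-law fit) are reported next
to degree-preserving rewired baselines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .tables import CommunityTable, relative_abundance

__all__ = [
    "correlation_matrix",
    "rmt_threshold",
    "RmtScan",
    "build_network",
    "EcoNetwork",
    "topology",
    "random_baseline",
    "positive_edge_fraction",
]


def correlation_matrix(core_table: CommunityTable, method: str = "pearson",
                       transform: str = "log1p") -> pd.DataFrame:
    """Pairwise correlation of per-OTU abundance profiles.

    Profiles are relative abundances, ``log(x + 1)``-transformed by default
    (``transform='none'`` skips it); zero-variance OTUs are excluded with a
    warning.
    """
    if core_table.n_samples < 4:
        raise ValueError("need at least 4 samples for meaningful correlations")
    rel = relative_abundance(core_table)
    x = rel.data.to_numpy(dtype=float)
    if transform == "log1p":
        x = np.log1p(x)
    elif transform != "none":
        raise ValueError("transform must be 'log1p' or 'none'")
    sd = x.std(axis=1)
    keep = sd > 0
    if (~keep).any():
        bad = [o for o, k in zip(core_table.otu_ids, keep) if not k]
        warnings.warn(f"excluding {len(bad)} zero-variance OTU(s)",
                      UserWarning, stacklevel=2)
    x = x[keep]
    ids = [o for o, k in zip(core_table.otu_ids, keep) if k]
    if method == "pearson":
        r = np.corrcoef(x)
    elif method == "spearman":
        ranks = np.apply_along_axis(stats.rankdata, 1, x)
        r = np.corrcoef(ranks)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=ids, columns=ids)


# --------------------------------------------------------------------------
# RMT threshold selection
# --------------------------------------------------------------------------

def _nnsd_poisson_p(eigvals: np.ndarray, poly_degree: int = 5,
                    edge_trim: float = 0.05) -> float:
    """Goodness-of-fit p of the unfolded NNSD against the Poisson form e^-d.

    The spectrum edges (``edge_trim`` of the levels at each end, at least
    one) are discarded before unfolding — edge/outlier eigenvalues (e.g.
    large factor eigenvalues of a correlation matrix) otherwise wreck the
    smooth fit to the cumulative spectral density.  Unfolding fits a
    low-order polynomial to the empirical cumulative density; spacings of
    the unfolded levels are binned into ``ceil(sqrt(m))`` equal-probability
    exponential bins and tested by chi-square.
    """
    vals = np.sort(eigvals)
    m = len(vals)
    if m < 10:
        return np.nan
    cut = max(1, int(np.floor(edge_trim * m)))
    vals = vals[cut:m - cut]
    m = len(vals)
    if m < 10 or np.ptp(vals) < 1e-12:  # too few or fully degenerate levels
        return np.nan
    # empirical cumulative density, fitted smoothly
    cdf = (np.arange(1, m + 1) - 0.5) / m
    deg = min(poly_degree, m - 2)
    coef = np.polyfit(vals, cdf, deg)
    unfolded = m * np.polyval(coef, vals)
    spacings = np.diff(np.sort(unfolded))
    spacings = spacings[np.isfinite(spacings)]
    if len(spacings) < 8:
        return np.nan
    mean = spacings.mean()
    if mean <= 0:
        return np.nan
    spacings = spacings / mean  # normalize to unit mean
    k = max(int(np.ceil(np.sqrt(len(spacings)))), 4)
    edges = np.append(-np.log(1.0 - np.arange(k) / k), np.inf)  # Exp(1) bins
    observed, _ = np.histogram(spacings, bins=edges)
    expected = np.full(k, len(spacings) / k)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    dof = k - 2  # bins minus one, minus the fitted mean
    return float(stats.chi2.sf(chi2, dof))


@dataclass
class RmtScan:
    """Result of the threshold scan: chosen ``st`` (None on failure) and
    per-threshold NNSD Poisson-fit p-values."""

    st: float | None
    diagnostics: pd.DataFrame
    p_unthresholded: float
    alpha: float

    @property
    def failed(self) -> bool:
        return self.st is None


def rmt_threshold(corr: pd.DataFrame, scan=None, alpha: float = 0.05,
                  poly_degree: int = 5) -> RmtScan:
    """Scan similarity thresholds and pick the smallest RMT-consistent one.

    For each candidate ``st`` the correlation matrix is hard-thresholded
    (off-diagonal ``|r| < st`` set to 0, rows/columns left with no
    off-diagonal entry dropped) and the NNSD of its unfolded eigenvalues is
    tested against the Poisson form.  The chosen ``st`` is the smallest
    candidate with Poisson-consistent NNSD (p > alpha); the scan fails (st
    None) if no candidate qualifies.  If the unthresholded NNSD is already
    Poisson-consistent a warning is issued (threshold choice is then weakly
    identified).
    """
    r = corr.to_numpy(dtype=float)
    n = r.shape[0]
    if n < 30:
        raise ValueError("need at least 30 OTUs for a meaningful spectrum")
    if scan is None:
        scan = np.round(np.arange(0.30, 1.00, 0.01), 2)
    p_full = _nnsd_poisson_p(np.linalg.eigvalsh(r), poly_degree)
    if np.isfinite(p_full) and p_full > alpha:
        warnings.warn("unthresholded spectrum already has Poisson NNSD; "
                      "threshold is weakly identified", UserWarning, stacklevel=2)
    rows = []
    chosen = None
    for st in scan:
        m = r.copy()
        off = np.abs(m) < st
        np.fill_diagonal(off, False)
        m[off] = 0.0
        connected = (np.abs(m) > 0).sum(axis=1) > 1  # beyond the diagonal
        mm = m[np.ix_(connected, connected)]
        p = _nnsd_poisson_p(np.linalg.eigvalsh(mm), poly_degree) \
            if mm.shape[0] >= 10 else np.nan
        rows.append({"st": float(st), "n_connected": int(connected.sum()),
                     "p_poisson": p})
        if chosen is None and np.isfinite(p) and p > alpha:
            chosen = float(st)
    diagnostics = pd.DataFrame(rows).set_index("st")
    return RmtScan(chosen, diagnostics, p_full, alpha)


# --------------------------------------------------------------------------
# network construction and metrics
# --------------------------------------------------------------------------

@dataclass
class EcoNetwork:
    """A signed co-occurrence network over core OTUs."""

    graph: nx.Graph
    st: float

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def edges(self) -> pd.DataFrame:
        rows = [{"otu_a": a, "otu_b": b, "r": d["r"], "sign": d["sign"]}
                for a, b, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["otu_a", "otu_b", "r", "sign"])

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_links(self) -> int:
        return self.graph.number_of_edges()


def build_network(corr: pd.DataFrame, st: float) -> EcoNetwork:
    """Graph with an edge wherever ``|r| >= st`` (isolated nodes dropped,
    matching the convention of reporting the connected network size)."""
    if not (0 < st < 1):
        raise ValueError("st must lie in (0, 1)")
    r = corr.to_numpy(dtype=float)
    ids = list(corr.index)
    g = nx.Graph()
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    hits = np.abs(r[iu]) >= st
    if not hits.any():
        raise ValueError(f"no edges at st = {st}")
    for i, j in zip(iu[0][hits], iu[1][hits]):
        g.add_edge(ids[i], ids[j], r=float(r[i, j]),
                   sign=1 if r[i, j] > 0 else -1)
    return EcoNetwork(g, float(st))


def _power_law_r2(graph: nx.Graph) -> float:
    degrees = np.array([d for _, d in graph.degree()])
    values, freq = np.unique(degrees, return_counts=True)
    ok = values > 0
    values, freq = values[ok], freq[ok]
    if len(values) < 3:
        return np.nan
    x, y = np.log(values.astype(float)), np.log(freq.astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ss_tot = np.sum((y - y.mean()) ** 2)
    return float(1.0 - np.sum(resid ** 2) / ss_tot) if ss_tot > 0 else np.nan


def _mean_path_within_components(graph: nx.Graph) -> float:
    total, pairs = 0.0, 0
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        if sub.number_of_nodes() < 2:
            continue
        for _, lengths in nx.all_pairs_shortest_path_length(sub):
            total += sum(lengths.values())
            pairs += len(lengths) - 1
    return total / pairs if pairs else np.nan


def topology(net: EcoNetwork) -> dict:
    """Topology metrics of a built network.

    avgK = 2L/n; avgCC = mean local clustering (degree < 2 contributes 0);
    GD = mean shortest-path length over connected pairs within components;
    M = modularity of the Clauset-Newman-Moore fast-greedy partition;
    powerlaw_r2 = R^2 of log(frequency) on log(degree).
    """
    g = net.graph
    if g.number_of_edges() == 0:
        raise ValueError("empty network")
    n, l = g.number_of_nodes(), g.number_of_edges()
    communities = list(nx.community.greedy_modularity_communities(g))
    # stable module numbering: by size (desc), then by smallest member
    communities = sorted((sorted(c) for c in communities),
                         key=lambda c: (-len(c), c[0]))
    signs = np.array([d["sign"] for _, _, d in g.edges(data=True)])
    return {
        "n_nodes": n,
        "n_links": l,
        "avgK": 2.0 * l / n,
        "avgCC": float(np.mean(list(nx.clustering(g).values()))),
        "GD": _mean_path_within_components(g),
        "modularity": float(nx.community.modularity(g, communities)),
        "n_modules": len(communities),
        "powerlaw_r2": _power_law_r2(g),
        "positive_edge_fraction": float((signs > 0).mean()),
        "modules": {node: m for m, comm in enumerate(communities) for node in comm},
    }


def positive_edge_fraction(net: EcoNetwork) -> float:
    """Fraction of edges with a positive correlation sign."""
    if net.n_links == 0:
        raise ValueError("network has no edges")
    signs = np.array([d["sign"] for _, _, d in net.graph.edges(data=True)])
    return float((signs > 0).mean())


def _rewire(graph: nx.Graph, rng: np.random.Generator,
            target_swaps: int, max_tries: int) -> tuple[nx.Graph, int]:
    """Degree-preserving double-edge swaps; returns (graph, successful swaps)."""
    g = graph.copy()
    edges = list(g.edges())
    done = tries = 0
    while done < target_swaps and tries < max_tries:
        tries += 1
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        if g.has_edge(a, d) or g.has_edge(c, b):
            continue
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(a, d)
        g.add_edge(c, b)
        edges[i] = (a, d)
        edges[j] = (c, b)
        done += 1
    return g, done


def random_baseline(net: EcoNetwork, n_rand: int = 100,
                    seed: int | None = None) -> dict:
    """Degree-preserving rewired baselines: mean +/- sd of GD, avgCC, M.

    Each rewire targets ``10 * L`` successful double-edge swaps (self-loops
    and multi-edges rejected).  Graphs too rigid to rewire (e.g. cliques)
    are reported with ``degenerate=True`` and zero spread.
    """
    if net.n_links < 2:
        raise ValueError("need at least 2 edges to rewire")
    rng = np.random.default_rng(seed)
    target = 10 * net.n_links
    gds, ccs, mods, swap_counts = [], [], [], []
    for _ in range(n_rand):
        g, swaps = _rewire(net.graph, rng, target, max_tries=100 * net.n_links)
        swap_counts.append(swaps)
        gds.append(_mean_path_within_components(g))
        ccs.append(float(np.mean(list(nx.clustering(g).values()))))
        comms = list(nx.community.greedy_modularity_communities(g))
        mods.append(float(nx.community.modularity(g, comms)))
    def ms(v):
        v = np.asarray(v, dtype=float)
        return {"mean": float(np.nanmean(v)), "sd": float(np.nanstd(v, ddof=1))}
    degenerate = max(swap_counts) == 0
    if degenerate:
        warnings.warn("graph could not be rewired (rigid wiring); baseline is "
                      "degenerate", UserWarning, stacklevel=2)
    return {"GD": ms(gds), "avgCC": ms(ccs), "modularity": ms(mods),
            "n_rand": n_rand, "mean_swaps": float(np.mean(swap_counts)),
            "degenerate": degenerate, "seed": seed}
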