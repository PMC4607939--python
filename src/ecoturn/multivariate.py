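"""Ordination and permutation statistics on distance matrices.

Implements the distance-based multivariate toolkit of community ecology:

* :func:`pcoa` — principal coordinates analysis via Gower double centering,
  with negative eigenvalues reported rather than corrected;
* :func:`permanova` — permutational multivariate ANOVA (``adonis``-style)
  with crossed factors, sequential (Type-I) sums of squares in formula order
  and free permutation of sample labels;
* :func:`anosim` — rank-based between/within group statistic R;
* :func:`mantel` — matrix correlation with joint row/column permutation;
* :func:`distlm` — distance-based linear model: marginal tests per
  environmental variable and forward selection with conditional tests.

All sums of squares come from the Gower-centered matrix
``G = -(1/2) * C A C`` with ``A = d**2`` and ``C`` the centering matrix;
``SS_total = trace(G) = sum_{i<j} d_ij**2 / n``, and the portion explained
by a design matrix ``X`` is ``trace(H G)`` with ``H`` the hat matrix of
``X`` (McArdle-Anderson).  Permutation p-values use the ``+1`` convention
(the observed statistic counts in both numerator and denominator).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.stats import rankdata
from skbio import DistanceMatrix

__all__ = [
    "pcoa", "PcoaResult",
    "permanova", "PermanovaResult",
    "anosim", "mantel",
    "distlm", "DistlmResult",
]


# --------------------------------------------------------------------------
# shared linear algebra
# --------------------------------------------------------------------------

def gower_center(d: np.ndarray) -> np.ndarray:
    """Gower-centered matrix ``G = -0.5 * C d^2 C``."""
    a = -0.5 * d.astype(float) ** 2
    row = a.mean(axis=1, keepdims=True)
    return a - row - row.T + a.mean()


def _hat(x: np.ndarray) -> np.ndarray:
    """Hat (projection) matrix of a design matrix, robust to rank deficiency."""
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return q @ q.T


def _rank(x: np.ndarray) -> int:
    return int(np.linalg.matrix_rank(x, tol=1e-10))


def _as_square(d) -> tuple[np.ndarray, list[str]]:
    if isinstance(d, DistanceMatrix):
        return d.data.astype(float), list(d.ids)
    arr = np.asarray(d, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("distance input must be square")
    if not np.allclose(arr, arr.T, atol=1e-8):
        raise ValueError("distance matrix is not symmetric")
    return arr, [str(i) for i in range(arr.shape[0])]


# --------------------------------------------------------------------------
# PCoA
# --------------------------------------------------------------------------

@dataclass
class PcoaResult:
    """Principal coordinates: eigenvalues (descending, negatives included),
    sample coordinates on the positive axes (scaled by sqrt eigenvalue) and
    the proportion of positive-eigenvalue variation per axis."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray

    def summary(self) -> pd.DataFrame:
        k = self.coordinates.shape[1]
        return pd.DataFrame({
            "eigenvalue": self.eigenvalues[:k],
            "proportion_explained": self.proportion_explained[:k],
        }, index=[f"PCo{i + 1}" for i in range(k)])


def pcoa(d) -> PcoaResult:
    """Principal coordinates analysis of a distance matrix.

    Negative eigenvalues (from non-Euclidean distances) are reported as-is
    and excluded from the ``proportion_explained`` denominator; no Lingoes/
    Cailliez correction is applied.
    """
    dist, ids = _as_square(d)
    n = dist.shape[0]
    if n < 3:
        raise ValueError("pcoa needs at least 3 samples")
    g = gower_center(dist)
    vals, vecs = eigh((g + g.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10 * max(1.0, abs(vals[0]))
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    total_pos = vals[pos].sum()
    prop = np.where(vals > 0, vals / total_pos, 0.0) if total_pos > 0 else np.zeros(n)
    frame = pd.DataFrame(coords, index=ids,
                         columns=[f"PCo{i + 1}" for i in range(coords.shape[1])])
    return PcoaResult(frame, vals, prop)


# --------------------------------------------------------------------------
# PERMANOVA
# --------------------------------------------------------------------------

def _parse_formula(formula: str) -> list[str]:
    terms = [t.strip() for t in formula.split("+")]
    if any(not t for t in terms):
        raise ValueError(f"malformed formula {formula!r}")
    return terms


def _term_columns(term: str, factors: pd.DataFrame) -> np.ndarray:
    """Full-rank (treatment-coded, no intercept column) design columns of a
    term; interactions given as ``a:b`` use products of main-effect codings."""
    parts = term.split(":")
    blocks = []
    for p in parts:
        p = p.strip()
        if p not in factors.columns:
            raise KeyError(f"unknown factor {p!r} in formula")
        col = factors[p]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > len(col) // 2:
            # continuous covariate
            blocks.append(col.to_numpy(dtype=float)[:, None])
            continue
        levels = pd.unique(col)
        if len(levels) < 2:
            raise ValueError(f"factor {p!r} has fewer than 2 levels")
        dummies = pd.get_dummies(col.astype(str), drop_first=True)
        blocks.append(dummies.to_numpy(dtype=float))
    out = blocks[0]
    for b in blocks[1:]:
        out = np.einsum("ij,ik->ijk", out, b).reshape(out.shape[0], -1)
    return out


@dataclass
class PermanovaResult:
    """adonis-style table: one row per term plus residual and total."""

    table: pd.DataFrame
    n_permutations: int | None
    seed: int | None
    formula: str

    def summary(self) -> pd.DataFrame:
        return self.table

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PERMANOVA ({self.formula})\n{self.table.to_string()}"


def permanova(d, factors: pd.DataFrame, formula: str, n_perm: int = 999,
              seed: int | None = None, exact: bool = False) -> PermanovaResult:
    """Permutational multivariate ANOVA with sequential sums of squares.

    Parameters
    ----------
    d : skbio.DistanceMatrix or square array
    factors : DataFrame indexed (or ordered) like the samples of ``d``.
    formula : e.g. ``"site + time + site:time"``; terms enter in this order
        (Type-I, matching the adonis default).
    n_perm : number of free permutations of sample labels (ignored if
        ``exact``); must be >= 99.
    exact : enumerate all ``n!`` permutations (feasible for n <= 8); the
        p-value is then the exact fraction of permutations with
        ``F_perm >= F_obs``.
    """
    dist, ids = _as_square(d)
    n = dist.shape[0]
    if isinstance(factors.index, pd.Index) and set(ids) <= set(map(str, factors.index)):
        factors = factors.loc[ids]
    if len(factors) != n:
        raise ValueError("factors frame does not match the distance matrix samples")
    if not exact and n_perm < 99:
        raise ValueError("n_perm must be at least 99")

    terms = _parse_formula(formula)
    g = gower_center(dist)
    ss_total = float(np.trace(g))

    # nested sequence of hat matrices (intercept first)
    x = np.ones((n, 1))
    hats, dfs = [_hat(x)], []
    rank_prev = 1
    for term in terms:
        cols = _term_columns(term, factors)
        x = np.hstack([x, cols])
        rank_new = _rank(x)
        if rank_new == rank_prev:
            raise ValueError(f"term {term!r} is confounded with earlier terms "
                             "(singular design)")
        dfs.append(rank_new - rank_prev)
        rank_prev = rank_new
        hats.append(_hat(x))
    df_resid = n - rank_prev
    if df_resid <= 0:
        raise ValueError("saturated design: no residual degrees of freedom")
    resid_proj = np.eye(n) - hats[-1]
    diffs = [hats[i + 1] - hats[i] for i in range(len(terms))]

    def stats_for(gm: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
        ss_terms = np.array([float(np.sum(dm * gm)) for dm in diffs])
        ss_res = float(np.sum(resid_proj * gm))
        fs = (ss_terms / np.array(dfs)) / (ss_res / df_resid)
        return ss_terms, ss_res, fs

    ss_terms, ss_res, f_obs = stats_for(g)

    if exact:
        if n > 9:
            raise ValueError("exact enumeration is limited to n <= 9")
        count = np.zeros(len(terms))
        total = 0
        for perm in itertools.permutations(range(n)):
            idx = np.array(perm)
            _, _, fp = stats_for(g[np.ix_(idx, idx)])
            count += fp >= f_obs - 1e-12
            total += 1
        pvals = count / total
        n_perm_used = total - 1
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(len(terms))
        for _ in range(n_perm):
            idx = rng.permutation(n)
            _, _, fp = stats_for(g[np.ix_(idx, idx)])
            count += fp >= f_obs - 1e-12
        pvals = (count + 1) / (n_perm + 1)
        n_perm_used = n_perm

    rows = []
    for i, term in enumerate(terms):
        rows.append({"term": term, "df": dfs[i], "sum_sq": ss_terms[i],
                     "pseudo_F": f_obs[i], "R2": ss_terms[i] / ss_total,
                     "p": pvals[i]})
    rows.append({"term": "Residual", "df": df_resid, "sum_sq": ss_res,
                 "pseudo_F": np.nan, "R2": ss_res / ss_total, "p": np.nan})
    rows.append({"term": "Total", "df": n - 1, "sum_sq": ss_total,
                 "pseudo_F": np.nan, "R2": 1.0, "p": np.nan})
    table = pd.DataFrame(rows).set_index("term")
    return PermanovaResult(table, n_perm_used, seed, formula)


# --------------------------------------------------------------------------
# ANOSIM & Mantel
# --------------------------------------------------------------------------

def _anosim_r(ranks: np.ndarray, within: np.ndarray, n: int) -> float:
    return float((ranks[~within].mean() - ranks[within].mean()) / (n * (n - 1) / 4.0))


def anosim(d, grouping, n_perm: int = 999, seed: int | None = None) -> dict:
    """ANOSIM R statistic and permutation p-value.

    ``R = (mean between-group rank - mean within-group rank) / (n(n-1)/4)``
    over the ranked pairwise distances (average ranks at ties).
    """
    dist, ids = _as_square(d)
    n = dist.shape[0]
    groups = np.asarray(pd.Series(grouping).loc[ids] if isinstance(grouping, pd.Series)
                        and set(ids) <= set(map(str, grouping.index)) else grouping)
    if len(groups) != n:
        raise ValueError("grouping length does not match the distance matrix")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("anosim needs at least 2 groups")
    if (counts < 2).any():
        raise ValueError("anosim groups must each contain at least 2 samples")
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(dist[iu])
    within = groups[iu[0]] == groups[iu[1]]
    r_obs = _anosim_r(ranks, within, n)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        gp = groups[rng.permutation(n)]
        count += _anosim_r(ranks, gp[iu[0]] == gp[iu[1]], n) >= r_obs - 1e-12
    return {"R": r_obs, "p": (count + 1) / (n_perm + 1),
            "n_permutations": n_perm, "seed": seed}


def mantel(d1, d2, method: str = "pearson", n_perm: int = 999,
           seed: int | None = None) -> dict:
    """Mantel correlation between two distance matrices over lower triangles,
    with p by jointly permuting one matrix's rows and columns."""
    a, ids1 = _as_square(d1)
    b, ids2 = _as_square(d2)
    if a.shape != b.shape:
        raise ValueError("matrices differ in size")
    if isinstance(d1, DistanceMatrix) and isinstance(d2, DistanceMatrix):
        if ids1 != ids2:
            if set(ids1) != set(ids2):
                raise ValueError("matrices have different sample IDs")
            b = DistanceMatrix(b, ids2).filter(ids1).data
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    va = a[iu]
    if method == "spearman":
        va = rankdata(va)

    def corr_with(bm: np.ndarray) -> float:
        vb = bm[iu]
        if method == "spearman":
            vb = rankdata(vb)
        return float(np.corrcoef(va, vb)[0, 1])

    r_obs = corr_with(b)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        count += abs(corr_with(b[np.ix_(idx, idx)])) >= abs(r_obs) - 1e-12
    return {"r": r_obs, "p": (count + 1) / (n_perm + 1),
            "method": method, "n_permutations": n_perm, "seed": seed}


# --------------------------------------------------------------------------
# DistLM
# --------------------------------------------------------------------------

@dataclass
class DistlmResult:
    """Marginal tests (each variable alone) and the sequential forward-
    selection table of a distance-based linear model."""

    marginal: pd.DataFrame
    sequential: pd.DataFrame
    stop_reason: str
    selection_alpha: float
    n_permutations: int
    seed: int | None

    def summary(self) -> str:
        lines = ["DistLM marginal tests", self.marginal.to_string(),
                 "", "DistLM sequential (forward selection)",
                 self.sequential.to_string() if len(self.sequential) else "(no variable selected)",
                 f"stop reason: {self.stop_reason}"]
        return "\n".join(lines)


def distlm(d, env: pd.DataFrame, n_perm: int = 999, seed: int | None = None,
           selection_alpha: float = 0.05) -> DistlmResult:
    """Distance-based linear model with marginal and forward-sequential tests.

    Marginal: each variable fitted alone; % variation = 100 * tr(H_v G) /
    tr(G), pseudo-F with 1 and n-2 df, p by permutation of the
    Gower-centered matrix.  Sequential: forward selection adds, at each
    step, the candidate with the largest conditional gain whose conditional
    permutation p <= ``selection_alpha``; stops when no candidate qualifies.
    Constant (zero-variance) variables are excluded with a warning.
    """
    dist, ids = _as_square(d)
    n = dist.shape[0]
    if isinstance(env.index, pd.Index) and set(ids) <= set(map(str, env.index)):
        env = env.loc[ids]
    if len(env) != n:
        raise ValueError("environment table does not match the distance matrix")
    env = env.apply(pd.to_numeric)
    keep = []
    for c in env.columns:
        if np.std(env[c].to_numpy(dtype=float)) == 0:
            warnings.warn(f"excluding constant variable {c!r}", UserWarning,
                          stacklevel=2)
        else:
            keep.append(c)
    env = env[keep]
    if env.shape[1] == 0:
        raise ValueError("no usable (non-constant) environmental variables")

    g = gower_center(dist)
    ss_total = float(np.trace(g))
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(n) for _ in range(n_perm)]
    ones = np.ones((n, 1))

    def explained(hat: np.ndarray, gm: np.ndarray) -> float:
        return float(np.sum(hat * gm))

    # ---- marginal tests
    rows = []
    for c in env.columns:
        h = _hat(np.hstack([ones, env[[c]].to_numpy(dtype=float)]))
        ss = explained(h, g)
        f_obs = ss / ((ss_total - ss) / (n - 2))
        count = 0
        for idx in perms:
            gp = g[np.ix_(idx, idx)]
            ssp = explained(h, gp)
            count += ssp / ((ss_total - ssp) / (n - 2)) >= f_obs - 1e-12
        rows.append({"variable": c, "pseudo_F": f_obs,
                     "p": (count + 1) / (n_perm + 1),
                     "pct_variation": 100.0 * ss / ss_total})
    marginal = (pd.DataFrame(rows).sort_values("pct_variation", ascending=False)
                .reset_index(drop=True))

    # ---- forward selection
    selected: list[str] = []
    seq_rows = []
    x_sel = ones
    h_sel = _hat(ones)
    ss_sel = 0.0
    stop_reason = ""
    candidates = list(env.columns)
    while candidates:
        best = None
        for c in candidates:
            x_c = np.hstack([x_sel, env[[c]].to_numpy(dtype=float)])
            if _rank(x_c) == _rank(x_sel):
                continue  # collinear with already-selected variables
            h_c = _hat(x_c)
            gain = explained(h_c, g) - ss_sel
            if best is None or gain > best[1]:
                best = (c, gain, x_c, h_c)
        if best is None:
            stop_reason = "remaining variables are collinear with the selected set"
            break
        c, gain, x_c, h_c = best
        k = x_c.shape[1]
        df2 = n - k
        if df2 <= 0:
            stop_reason = "design saturated before all variables entered"
            break
        f_obs = gain / ((ss_total - ss_sel - gain) / df2)
        count = 0
        for idx in perms:
            gp = g[np.ix_(idx, idx)]
            ss_c = explained(h_c, gp)
            gain_p = ss_c - explained(h_sel, gp)
            count += gain_p / ((ss_total - ss_c) / df2) >= f_obs - 1e-12
        p = (count + 1) / (n_perm + 1)
        if p > selection_alpha:
            stop_reason = ("stopped: best remaining variable "
                           f"({c!r}, conditional p = {p:.3g}) did not improve the "
                           "model in the conditional test")
            break
        selected.append(c)
        candidates.remove(c)
        x_sel, h_sel, ss_sel = x_c, h_c, ss_sel + gain
        seq_rows.append({"variable": c, "pseudo_F": f_obs, "p": p,
                         "pct_added": 100.0 * gain / ss_total,
                         "pct_cumulative": 100.0 * ss_sel / ss_total})
    else:
        stop_reason = "all variables entered the model"
    sequential = pd.DataFrame(seq_rows, columns=["variable", "pseudo_F", "p",
                                                 "pct_added", "pct_cumulative"])
    return DistlmResult(marginal, sequential, stop_reason, selection_alpha,
                        n_perm, seed)
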