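"""Synthetic bacterioplankton community time series with known ground truth.

The generator emulates a processed 16S survey of the kind produced by a
two-site (e.g. disturbed vs. reference), multi-season water-sampling design:
a fixed number of replicate samples per site per sampling day, every sample
rarefied to an even read depth, lognormal-ish abundance distributions, and
community composition that decorrelates with time lag so that downstream
similarity decays with increasing sampling interval.

Model
-----
Each taxon ``k`` at site ``s`` carries a latent log-abundance ``z[s, t, k]``
following a stationary discrete-time Ornstein–Uhlenbeck process with mean 0,
stationary standard deviation ``latent_sigma`` and mean-reversion rate
``turnover_theta`` (per day): between sampling days ``t`` and ``t + dt``,

    z[t + dt] = z[t] * exp(-theta * dt) + sigma * sqrt(1 - exp(-2 theta dt)) * eps.

Taxon latents are mutually independent (optionally, planted blocks share a
common OU component to create correlated taxa for network analyses).  Sampling
probabilities combine the latent state with a Gaussian environmental-filtering
kernel on one latent environmental axis ``e(s, t)``:

    p[k] ∝ exp( z[s,t,k] + b[s,k] + eta[k] - filter_strength * (u[k] - e(s,t))**2 )

where ``u[k]`` is the taxon's environmental optimum, ``b[s,k]`` a persistent
site-specific offset with standard deviation ``site_effect``, and ``eta`` an
independent per-sample "patchiness" perturbation with standard deviation
``replicate_sigma`` — water samples taken side by side do not share exactly
the same community, and this noise floor keeps replicate similarity well
below 1 as observed in real surveys.  Each sample is a multinomial draw of
``reads_per_sample`` reads from its own ``p``, i.e. tables come out
pre-rarefied to even depth.

With ``filter_strength = 0`` and ``site_effect = 0`` all taxa are
exchangeable and the two sites are independent draws from one process.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .tables import CommunityTable

__all__ = ["SimConfig", "generate_dataset", "generate_blocked_taxa"]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic community generator.

    Defaults mirror a two-site, six-time-point, four-replicate seasonal
    survey rarefied to 3,870 reads, with within-season day pairs a few days
    apart and seasons roughly two months apart.
    """

    n_otus_pool: int = 300
    n_sites: int = 2
    n_timepoints: int = 6
    n_replicates: int = 4
    reads_per_sample: int = 3870
    sampling_days: tuple[int, ...] = (1, 6, 60, 66, 148, 153)
    turnover_theta: float = 0.005    # per-day mean reversion of the latent OU
    latent_sigma: float = 1.5        # stationary sd of latent log abundance
    replicate_sigma: float = 1.5     # sd of per-sample (patchiness) noise
    filter_strength: float = 0.5     # weight of environmental matching
    site_effect: float = 0.3         # sd of persistent per-site taxon offsets
    n_corr_blocks: int = 0
    block_size: int = 0
    block_rho: float = 0.8
    seed: int = 0

    def __post_init__(self):
        for name in ("n_otus_pool", "n_sites", "n_timepoints", "n_replicates",
                     "reads_per_sample"):
            v = getattr(self, name)
            if int(v) != v or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        days = tuple(int(d) for d in self.sampling_days)
        if len(days) != self.n_timepoints:
            raise ValueError("sampling_days length must equal n_timepoints")
        if any(d <= 0 for d in days) or any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("sampling_days must be strictly increasing positive integers")
        for name in ("turnover_theta", "latent_sigma", "replicate_sigma",
                     "filter_strength", "site_effect"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (0 <= self.block_rho <= 1):
            raise ValueError("block_rho must lie in [0, 1]")
        if self.n_corr_blocks * self.block_size > self.n_otus_pool:
            raise ValueError("correlation blocks exceed the taxon pool")
        object.__setattr__(self, "sampling_days", days)

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


def _season_labels(days: Sequence[int], gap: int = 30) -> list[str]:
    """Group sampling days into seasons at gaps longer than ``gap`` days."""
    labels, season = [], 1
    for i, d in enumerate(days):
        if i > 0 and d - days[i - 1] > gap:
            season += 1
        labels.append(f"season{season}")
    return labels


def _ou_path(rng: np.random.Generator, days: Sequence[int], n_series: int,
             theta: float, sigma: float) -> np.ndarray:
    """Stationary OU sample paths at irregular times; shape (len(days), n_series)."""
    z = np.empty((len(days), n_series))
    z[0] = sigma * rng.standard_normal(n_series)
    for t in range(1, len(days)):
        dt = days[t] - days[t - 1]
        rho = np.exp(-theta * dt)
        z[t] = rho * z[t - 1] + sigma * np.sqrt(max(1.0 - rho * rho, 0.0)) \
            * rng.standard_normal(n_series)
    return z


def generate_dataset(config: SimConfig) -> tuple[CommunityTable, pd.DataFrame, pd.DataFrame]:
    """Generate an OTU table, a sample-metadata frame and an environment table.

    Returns
    -------
    table : CommunityTable
        Counts, every column summing exactly to ``reads_per_sample``.
    meta : pandas.DataFrame
        One row per sample: ``site``, ``season``, ``day``, ``replicate``.
    env : pandas.DataFrame
        One row per sample with >= 4 numeric variables; ``temperature`` is a
        deterministic function of the latent environmental axis, ``noise`` is
        pure noise uncorrelated with the communities.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_latent, rng_counts, rng_env, rng_pool = \
        [np.random.default_rng(s) for s in ss.spawn(4)]

    days = np.asarray(cfg.sampling_days, dtype=float)
    seasons = _season_labels(cfg.sampling_days)
    n_k = cfg.n_otus_pool

    # taxon environmental optima, shared across sites
    optima = rng_pool.uniform(-1.2, 1.2, size=n_k)
    # block membership for planted taxon correlations
    block_of = np.full(n_k, -1)
    for b in range(cfg.n_corr_blocks):
        block_of[b * cfg.block_size:(b + 1) * cfg.block_size] = b

    # latent environmental axis: a monotone seasonal drift (temperature-like)
    span = days[-1] - days[0] if len(days) > 1 else 1.0
    env_axis = 1.0 - 2.0 * (days - days[0]) / span  # declines 1 -> -1

    otu_ids = [f"OTU{i + 1:04d}" for i in range(n_k)]
    sample_ids, meta_rows, env_rows, columns = [], [], [], []

    for s in range(cfg.n_sites):
        site = f"site{s + 1}"
        z = _ou_path(rng_latent, cfg.sampling_days, n_k,
                     cfg.turnover_theta, cfg.latent_sigma)
        if cfg.n_corr_blocks:
            zb = _ou_path(rng_latent, cfg.sampling_days, cfg.n_corr_blocks,
                          cfg.turnover_theta, cfg.latent_sigma)
            r = np.sqrt(cfg.block_rho)
            for k in range(n_k):
                if block_of[k] >= 0:
                    z[:, k] = r * zb[:, block_of[k]] + np.sqrt(1 - cfg.block_rho) * z[:, k]
        b_site = cfg.site_effect * rng_latent.standard_normal(n_k)
        for t in range(cfg.n_timepoints):
            logw = z[t] + b_site - cfg.filter_strength * (optima - env_axis[t]) ** 2
            temperature = 15.0 + 10.0 * env_axis[t]
            for r_i in range(cfg.n_replicates):
                sid = f"{site}_d{cfg.sampling_days[t]}_r{r_i + 1}"
                sample_ids.append(sid)
                # per-sample patchiness noise on top of the site-time latent
                eta = cfg.replicate_sigma * rng_counts.standard_normal(n_k)
                logw_r = logw + eta
                p_r = np.exp(logw_r - logw_r.max())
                p_r /= p_r.sum()
                columns.append(rng_counts.multinomial(cfg.reads_per_sample, p_r))
                meta_rows.append({"site": site, "season": seasons[t],
                                  "day": cfg.sampling_days[t], "replicate": r_i + 1})
                env_rows.append({
                    "temperature": temperature,
                    "dissolved_oxygen": 8.0 - 2.0 * env_axis[t]
                    + 0.2 * rng_env.standard_normal(),
                    "din": 8.0 + 2.0 * cfg.site_effect * s
                    + 0.5 * rng_env.standard_normal(),
                    "chl_a": float(np.exp(rng_env.normal(0.5, 0.4))),
                    "noise": float(rng_env.standard_normal()),
                })

    counts = pd.DataFrame(np.column_stack(columns), index=otu_ids, columns=sample_ids)
    meta = pd.DataFrame(meta_rows, index=sample_ids)
    env = pd.DataFrame(env_rows, index=sample_ids)
    return CommunityTable(counts), meta, env


def generate_blocked_taxa(n_otus: int, n_samples: int, n_blocks: int,
                          block_size: int, block_rho: float, seed: int,
                          scale: float = 0.5, base: float = 50.0) -> CommunityTable:
    """Abundance table with planted blocks of correlated taxa.

    The first ``n_blocks * block_size`` taxa form blocks: within a block every
    taxon's latent value is ``sqrt(rho) * shared + sqrt(1 - rho) * own`` so the
    latent within-block correlation is exactly ``block_rho`` (identical taxa at
    ``block_rho = 1``).  Remaining taxa are independent background.  Counts are
    ``floor(base * exp(scale * latent))`` per sample, a monotone lognormal-type
    transform that approximately preserves the planted correlations.
    """
    if not (0 <= block_rho <= 1):
        raise ValueError("block_rho must lie in [0, 1]")
    if n_blocks * block_size > n_otus:
        raise ValueError("blocks exceed the taxon pool")
    rng = np.random.default_rng(seed)
    shared = rng.standard_normal((n_blocks, n_samples))
    latent = rng.standard_normal((n_otus, n_samples))
    for b in range(n_blocks):
        rows = slice(b * block_size, (b + 1) * block_size)
        latent[rows] = (np.sqrt(block_rho) * shared[b]
                        + np.sqrt(1.0 - block_rho) * latent[rows])
    counts = np.floor(base * np.exp(scale * latent)).astype(np.int64)
    otu_ids = [f"OTU{i + 1:04d}" for i in range(n_otus)]
    sample_ids = [f"sample{j + 1}" for j in range(n_samples)]
    return CommunityTable(pd.DataFrame(counts, index=otu_ids, columns=sample_ids))
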