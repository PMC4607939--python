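# ecoturn

Temporal turnover, community-assembly partitioning and co-occurrence
networks for microbial community time series.

`ecoturn` is aimed at microbial ecologists asking how a bacterial (or any
taxon-count) community changes through time and what that implies about the
processes structuring it — for example, whether a habitat under long-term
(press) disturbance shows flattened temporal turnover, a larger
deterministic component of assembly, and tighter species-to-species
association networks than an undisturbed reference. It takes a classic
tab-delimited OTU table plus sample metadata and environmental variables,
and provides the full statistical stack such a study needs, end to end,
with every stochastic step seed-controlled.

## What it computes

* **Tables** — classic OTU-table I/O, rarefaction to even depth (uniform
  subsampling without replacement), relative abundance, taxonomic
  aggregation, dominant-family (>1% mean relative abundance) and core-OTU
  (detected in >50% of samples) screens.
* **Dissimilarity** — Bray-Curtis and Sørensen distance matrices
  (similarity `s = 1 − d`), richness / Shannon `H' = −Σ p ln p` / Pielou
  evenness.
* **Multivariate** — PCoA (Gower double centering, negative eigenvalues
  reported), PERMANOVA with crossed factors and sequential sums of squares
  (`adonis`-style: `R² = SS_term / SS_total` from the Gower-centered
  matrix), ANOSIM, Mantel, and a distance-based linear model (DistLM) with
  marginal tests and forward selection under conditional permutation tests.
* **Turnover** — the time-decay of similarity relationship: OLS of
  `log10(similarity)` on `log10(time lag)`, turnover rate `w = −slope`,
  permutation test of `w = 0`, bootstrap CIs, two-group slope comparison,
  and within-group similarity contrasts.
* **Assembly** — a Raup-Crick-style null model (richness, totals and
  abundance multisets preserved; occurrence-frequency-weighted taxon
  draws) partitioning each pair's similarity into deterministic vs
  stochastic components via `f = (s_obs − s_null)/s_obs`, with per-season
  group summaries and between-habitat contrasts.
* **Networks** — core-OTU correlation networks thresholded by the
  random-matrix-theory criterion (smallest threshold whose unfolded
  eigenvalue spacings become Poisson), topology metrics (avgK, avgCC, GD,
  fast-greedy modularity, degree power-law R², positive-edge fraction) and
  degree-preserving rewired baselines.
* **Simulation** — a generator with known ground truth (latent
  Ornstein-Uhlenbeck log abundances, tunable turnover rate, environmental
  filtering strength, site effects, planted correlation blocks) so every
  statistic above can be validated against a recoverable truth.

## Worked example

```python
from ecoturn.simulate import SimConfig, generate_dataset
from ecoturn.dissimilarity import distance_matrix
from ecoturn.multivariate import permanova
from ecoturn.turnover import similarity_lag_pairs, tdr_fit, slope_test_zero

cfg = SimConfig(seed=42)          # 2 sites x 6 days x 4 replicates, 3,870 reads
table, meta, env = generate_dataset(cfg)
dm = distance_matrix(table)       # Bray-Curtis

res = permanova(dm, meta.assign(day=meta["day"].astype(str)),
                "day + site + day:site", n_perm=999, seed=0)
print(res.table.round(3))

pairs = similarity_lag_pairs(dm, meta, group="site1")
fit = tdr_fit(pairs)
print(fit.summary())
test = slope_test_zero(fit, pairs, n_perm=999, seed=0)
print(f"  p (slope = 0): {test['p']:.3f}")
```

prints

```
          df  sum_sq  pseudo_F     R2      p
term
day        5   2.659     2.132  0.162  0.001
site       1   2.523    10.114  0.154  0.001
day:site   5   2.237     1.793  0.136  0.001
Residual  36   8.980       NaN  0.548    NaN
Total     47  16.398       NaN  1.000    NaN

Time-decay fit (log10 similarity ~ log10 lag)
  slope     -0.19011   (w = 0.19011)
  intercept -0.34248
  R^2        0.60108
  lags used 13 (240 pairs, mean-per-lag)
  p (slope = 0): 0.001
```

Sampling day explains 16.2% of community variance and habitat 15.4% (both
p = 0.001, the grid minimum at 999 permutations), and within site 1 the
community similarity decays as a power of the time lag with turnover rate
w ≈ 0.19 per log10-day, significantly different from zero — the community
keeps turning over across the three simulated seasons.

The same analyses run from the shell:

```bash
ecoturn simulate --seed 42 --out demo/
ecoturn dist demo/otu_table.tsv --out demo/d.tsv
ecoturn permanova demo/d.tsv demo/metadata.tsv --formula "site + season"
ecoturn tdr demo/d.tsv demo/metadata.tsv --group site1
ecoturn run-all --config run.yaml     # full pipeline -> report bundle
```

`run-all` writes the complete report bundle (distance matrix, PCoA,
PERMANOVA and DistLM tables, per-site turnover fits and slope comparison,
null-model determinism summaries and habitat contrast, per-site network
metrics with random baselines, dominant-taxon table) plus a manifest of
seeds and stage timings; a run is byte-for-byte reproducible from its
config.

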