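# Methods

`ecoturn` analyses temporal turnover, assembly processes and co-occurrence
structure in microbial community time series. This note records the models,
the numerical choices and the limits of what the test suite demonstrates.

## Synthetic communities (`ecoturn.simulate`)

The generator emulates the processed level of a two-site seasonal
bacterioplankton survey: 2 sites x 6 sampling days x 4 replicates, every
sample rarefied to an even depth of 3,870 reads, with within-season day
pairs a few days apart and seasons roughly two months apart
(`sampling_days = (1, 6, 60, 66, 148, 153)`).

Each taxon `k` at site `s` has a latent log abundance `z[s, t, k]` following
a stationary Ornstein-Uhlenbeck process with mean 0, stationary standard
deviation `latent_sigma` (default 1.5 — a lognormal-ish abundance
distribution; no published abundance model exists for these communities, so
the lognormal choice is a modelling decision) and mean-reversion rate
`turnover_theta` per day. Between-sample latent correlation decays as
`exp(-theta * lag)`, which after the Bray-Curtis transform produces a
monotone, approximately power-law-looking similarity decay over the study's
lag range; the decay shape is always *measured* by the turnover module, not
assumed. The default `turnover_theta = 0.005` puts the fitted turnover rate
near 0.1 per log10-day, the regime reported for coastal bacterioplankton.

Sampling probabilities are

    p[k] ∝ exp( z[s,t,k] + b[s,k] + eta[k] − filter_strength · (u[k] − e(s,t))² )

* `u[k]` — taxon environmental optimum, uniform on [−1.2, 1.2];
* `e(s,t)` — one latent environmental axis drifting monotonically over the
  season sequence (temperature-like); the emitted `temperature` variable is
  a deterministic function of it, `dissolved_oxygen` is tied to it with
  noise, `noise` is pure noise;
* `b[s,k]` — persistent site offsets with sd `site_effect` (default 0.3),
  giving the PERMANOVA/ANOSIM site signal;
* `eta[k]` — independent per-sample "patchiness" noise with sd
  `replicate_sigma` (default 1.5). Water replicates drawn metres apart do
  not share an identical community; without this term replicate similarity
  is ~0.9 and every similarity-based statistic sits far from the field
  regime (~0.2–0.3 replicate similarity with it).

Counts are one multinomial draw of `reads_per_sample` per sample, i.e.
tables are emitted pre-rarefied; deeper tables can be generated and passed
through `tables.rarefy` to exercise rarefaction itself. With
`filter_strength = 0` and `site_effect = 0` all taxa are exchangeable and
the two sites are independent draws from one process.

What the generator does **not** emulate: sequencing error, chimeras,
taxonomy errors, true species-abundance mega-diversity (pool default 300
taxa), phylogenetic structure, or negative (inhibitory) taxon
interactions — which is why simulated co-occurrence networks come out with
essentially all-positive edges. Passing tests therefore demonstrate the
statistical machinery recovers planted structure of these kinds, not that
real surveys satisfy the model.

## Tables (`ecoturn.tables`)

Rarefaction is a single multivariate-hypergeometric draw per sample
(uniform subsampling without replacement), seed-controlled; samples below
depth are dropped and reported. Dominance (mean relative abundance
strictly > 1%) and core-OTU prevalence (detected in strictly more than 50%
of samples) both use strict inequalities — one consistent reading of
"more than". Dominance is computed across all samples by default; group-wise
screening is available by subsetting samples first.

## Dissimilarity (`ecoturn.dissimilarity`)

Bray-Curtis on abundances and Sørensen on presence/absence; similarity is
uniformly `1 − dissimilarity`. Shannon diversity uses the natural log
(base-2 available); evenness is `H'/ln(richness)`, defined as 1 for a
single-taxon sample. UniFrac metrics are out of scope (no phylogeny);
every downstream statistic here runs on Bray-Curtis (Sørensen for
sensitivity), an explicit substitution relative to tree-based ordinations.

## Multivariate statistics (`ecoturn.multivariate`)

All partitioning uses the Gower-centered matrix `G = −½ C D² C`;
`SS_total = tr(G)`, and the part explained by a design matrix `X` is
`tr(H G)` with `H` the hat matrix (McArdle–Anderson). PERMANOVA uses
sequential (Type-I) sums of squares in formula order — the `adonis`
default — with free permutation of sample labels and the `+1` p-value
convention; complete enumeration is available for n ≤ 9. PCoA reports
negative eigenvalues unchanged and excludes them from the
proportion-explained denominator (no Lingoes/Cailliez correction).
DistLM marginal tests fit each variable alone; forward selection adds the
largest conditional gain subject to conditional permutation p ≤ α
(default 0.05; the selection criterion of the original DistLM software is
not published, so this is pinned here), permuting the raw centered matrix
as `adonis` does. ANOSIM and Spearman statistics use average ranks at ties.

## Turnover (`ecoturn.turnover`)

The time-decay regression fits `log10(similarity)` on `log10(lag)`;
`w = −slope`. Similarities are averaged within each distinct lag before
fitting (mean-per-lag; all-pairs available). Lag-0 (replicate) pairs are
excluded from the regression — their log lag is undefined — but included in
the within-group similarity contrast. Zero-similarity lags are dropped with
a warning.

Inference on the slope: pairs that share a sample are statistically
dependent, so the primary permutation null relabels *samples* (joint
row/column permutation of the within-group similarity matrix, lag structure
fixed); its type-I error is verified at the nominal rate in the acceptance
suite. A pair-level similarity shuffle is kept as an option
(`method="pairs"`). A sample-level bootstrap of the slope is reported with
a percentile CI, together with the older one-sample t-test of the observed
rate against the bootstrap mean — retained for comparability, not as the
primary test, since testing a statistic against the centre of its own
resampling distribution has no clear null. Slope comparison between two
groups permutes group membership at the sample level and refits both
regressions per permutation.

## Assembly partition (`ecoturn.assembly`)

The null model preserves each sample's richness and total count, draws
taxon identities without replacement weighted by occurrence frequency
across the table (Raup-Crick-style, extended to abundances by permuting
the sample's observed abundance vector over the drawn taxa); an
unweighted-draw variant is provided. The per-pair determinism fraction is
`f = (s_obs − s_null_mean)/s_obs`.

Aggregation choices, made explicit because published determinacy and
stochasticity percentages frequently do not sum to 100:

* `determinism_pct = 100·mean(max(f,0))` (deterministic convergence),
  `divergence_pct = 100·mean(max(−f,0))`, `stochasticity_pct =
  100·mean(1−|f|)`; the three sum to 100, and determinism + stochasticity
  alone sum to less — the asymmetric convention.
* `mean_fraction_pct = 100·mean(f)` — the signed mean of per-pair ratios.
  This statistic carries a Jensen bias of about `−cv(s_obs)²` even for
  data generated by the null itself (mean of ratios), so it is *not* used
  for calibration.
* `pooled_fraction_pct = 100·(mean s_obs − mean s_null)/mean s_obs` — the
  ratio of means, unbiased under the null; this is the quantity the
  self-consistency and neutrality checks assert on.

Known property, documented rather than hidden: any shared structure between
samples — including mass effects (replicates drawn from the same water
mass) and temporal autocorrelation — registers as "determinism" in this
family of null models. Neutrality calibration therefore holds for pairs
separated beyond the latent autocorrelation time, and under the
unweighted-draw variant (occurrence-frequency weighting recycles stochastic
occupancy fluctuations into the null and biases the pooled fraction
negative by a few percent on neutral data). Per-pair Monte-Carlo standard
errors of `s_null_mean` are reported; fractions are clipped to [−1, 1] for
aggregation with raw values kept in the per-pair records.

## Networks (`ecoturn.network`)

Correlations are Pearson (Spearman available) between per-OTU
`log(x+1)`-transformed relative-abundance profiles of core OTUs; absent
taxa contribute the pseudocount, not a missing value. The RMT threshold
scan hard-thresholds the correlation matrix over st ∈ {0.30, …, 0.99},
drops rows left without off-diagonal entries, trims 5% of eigenvalues at
each spectrum edge (outlier factor eigenvalues otherwise wreck the
unfolding), unfolds via a degree-5 polynomial fit to the cumulative
spectral density, and chi-square-tests the nearest-neighbour spacings
against `exp(−d)` with `ceil(sqrt(m))` equal-probability bins. The chosen
st is the smallest Poisson-consistent threshold; exhaustion is reported as
failure with per-st diagnostics so the caller can set st manually.

Topology: `avgK = 2L/n`; clustering coefficient averages local values with
degree-<2 nodes contributing 0; `GD` averages shortest paths over connected
pairs within components; modularity uses Clauset-Newman-Moore fast-greedy
agglomeration (module numbering normalized by size then lexicographic
member for reproducibility); the degree-distribution fit is ordinary least
squares of log frequency on log degree. Random baselines use
degree-preserving double-edge swaps targeting 10·L successful swaps with
rejection of self-loops/multi-edges; rigid graphs (e.g. cliques) are
reported as degenerate with zero spread. Isolated nodes are excluded from
the reported network size, matching the convention of reporting the
connected network.

## Pipeline and problem sizes

`pipeline.run_all` derives every stage seed deterministically from one run
seed, so a config reproduces its output directory byte-for-byte. Default
problem sizes (999 permutations, 1,000 bootstrap resamples, 199 null
tables, 50 rewires, full 0.30–0.99 threshold scan on the standard 48-sample
survey) complete in about a minute on a single core; the acceptance script
uses the same sizes. These sizes give permutation p-value grids of 1/1000
and Monte-Carlo SEs comfortably below the effects the package is built to
detect; they are the package's defaults, not upper limits.

## Known limitations

* The null-model "determinism" conflates selection with any source of
  shared structure (dispersal, mass effects, autocorrelation); interpret
  contrasts between matched designs, not absolute percentages.
* The RMT scan needs a dense enough spectrum (≥ ~30 correlated taxa) and
  loses discrimination on very sparse thresholded matrices, where the
  chi-square test has little power; diagnostics expose the full p-value
  profile per threshold.
* Simulated co-occurrence networks carry essentially no negative edges;
  positive-edge fractions near 1 are a property of the generator, not of
  the metrics.
* All-pairs TDR regression treats dependent pairs as independent points;
  the mean-per-lag default and sample-level permutation mitigate but do
  not remove this.
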