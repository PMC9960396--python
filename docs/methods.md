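# Methods

This note documents the models, numerical choices and limitations behind
`phagedyn`. Thresholds quoted here are package defaults; all are
configurable through `PipelineConfig`.

## Synthetic community generator

The generator (`phagedyn.synthetic`) emulates a five-year monthly
metagenomic survey of a T4-like cyanophage community and its
picocyanobacterial hosts. Its defaults are the package's reference study
conditions: 200 species (50 per dynamic archetype), 60 monthly samples,
viral-fraction libraries of 10⁵ mapped reads against 2×10⁴ for the cellular
fraction (the ~5× mapped-depth gap that motivates the downsampling
robustness check), 10% of months missing completely at random, and eight
host taxa coupled to seasonal phages at strength 0.8.

Latent per-species abundance is lognormal. Each species draws a baseline
log-abundance offset from N(0, 1) (`species_log_sd`), which produces the
long-tailed, mostly-rare rank-abundance structure typical of these
communities: at the defaults ~94% of species sit below 2% mean relative
abundance with a ~30× spread between the top species and the median.
Month-to-month lognormal noise has SD 0.5 in log units.

The four archetypes are generative mirrors of the dynamic classes the
analysis assigns:

* **seasonal** — a raised-cosine window of width 8 months centred on the
  peak month; inside the window log-abundance is
  `baseline + amplitude·bump + noise` (default amplitude 1.5, i.e. 3× the
  noise SD), outside it the species is exactly absent. The hard window is a
  deliberate choice: seasonal phages in these systems drop below detection
  for months at a time before recurring, and without true off-season
  absence every seasonal species would be detected year-round and the
  persistent rule (which takes precedence) would swallow the seasonal
  class. Peak months alternate between a warm (May–August) and a cool
  (November–February) group, giving the two host-linked seasonal guilds.
* **persistent** — lognormal around the baseline, present every month.
* **occasional / sporadic** — present in a Bernoulli subset of months
  (occurrence probability 0.4 and 0.08 respectively), lognormal when
  present.

Read counts are multinomial draws per month from the latent relative
abundances, so library sizes are conserved exactly. The cellular fraction
draws from the same latent abundances distorted by independent per-cell
lognormal noise (SD 0.3, optional lag), making the two fractions strongly
positively correlated, as observed. Marker coverage and depth are derived
from counts by the Lander–Waterman expectation (`1 − e^{−depth}`, rounded
to exactly 1.0 once the expected number of uncovered bases falls below half
a base), so the 100%-coverage/2×-depth retention rule is exercised
realistically. Host taxa are scaled, noisy copies of their linked phage
group's seasonal signal on a persistent background; environmental
covariates are two seasonal drivers (temperature, mixed-layer depth), a
deterministic photoperiod and two pure-noise series.

All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawning, with one child stream per species, so
any trajectory is reproducible in isolation.

What the generator does **not** emulate: read-level errors and mapping
ambiguity, sequence evolution, within-species variant turnover,
compositional interactions between species beyond the shared multinomial
budget, autocorrelated environmental forcing, and informatively missing
months. Passing recovery tests on this generator therefore demonstrates
correctness of the statistical machinery under the stated model, not
robustness to those real-data complications.

## Species clustering

Pairwise marker identity is global (end-gap-free) alignment identity:
matches divided by aligned columns after trimming terminal indel columns
from a Needleman–Wunsch alignment (edlib). Arguments are put in a canonical
order before aligning so the score is exactly symmetric despite co-optimal
alignment paths. The ambiguity code N mismatches everything, including
another N (conservative and deterministic). A lineage-specific insertion
can be excised via `mask_intervals` rather than hard-coded coordinates.
Clustering collapses exact duplicates, then processes unique sequences in
decreasing length order (ties broken lexicographically by id), joining the
first centroid matched at ≥98% identity — deterministic greedy centroid
clustering in the style of length-sorted tools.

## Dynamic-class inference

Each retained species' RPKM series is modelled as

    y(t) = β₀ + f(month of year) + g(elapsed months) + ε

with `f` a cyclic cubic regression spline (k = 8, knots evenly spaced on
the 12-month circle, value/first/second derivative continuous across the
year wrap, penalty = integrated squared second derivative) and `g` a cubic
B-spline (k = 10) for interannual trend; both smooths carry sum-to-zero
constraints. RPKM is untransformed with Gaussian error by default.

Two fits serve two purposes. *Inference*: `seasonal_p` (and `trend_p`) come
from the exact F-test between the nested **unpenalized** regression-spline
fits, computed via rank-revealing SVD projections — under a Gaussian null
this test is exactly calibrated (measured 5.4% rejections at α = 0.05 over
2000 null series), and with monthly data and moderate k it loses little
power (simulated power 1.0 at amplitude/noise = 2). *Curve estimation*: the
reported seasonal curve and its peak month come from the penalized fit with
smoothing parameters chosen by GCV on a 7×7 log-spaced grid (a small 10⁻⁸
ridge keeps the normal equations well conditioned). An edf-based F-test
between GCV-selected penalized fits was evaluated and rejected for
inference: its adaptivity inflated the type-I error to ~12% at α = 0.05.

Classification applies, in order: persistent if detected (RPKM > 0) in more
than 85% of non-missing samples — persistence deliberately overrides
seasonality; seasonal if the raw seasonal p < 0.05; sporadic if detected in
fewer than 15%; otherwise occasional. Boundaries are strict inequalities;
both the precedence and strictness are configurable, and q-values
(Storey π₀ at λ = 0.5 with a BH fallback when fewer than 20 usable
p-values or an unstable estimate; p = 1 entries excluded and assigned
q = 1) are reported alongside for FDR-aware filtering. All-zero series are
flagged with p = 1 by convention.

The downsampling robustness procedure divides counts by 5, zeroes values
below 1 (fractional values ≥ 1 are kept), recomputes RPKM against the
reduced library sizes, refits and reclassifies, and compares class
compositions by Pearson chi-squared (zero-margin categories dropped with a
warning and df adjusted).

## Community statistics

Richness uses the bias-corrected incidence-based Chao estimator with the
matching variance (formulas in the `community` module docstring); the
estimator is deliberately the bias-corrected form, which stays finite when
no species occurs in exactly two samples. Rarefaction is the exact
hypergeometric expectation computed with log-gamma arithmetic. The
time-decay analysis bins all pairwise Bray–Curtis similarities by integer
calendar-month lag (dates truncated to months — the design is monthly), and
fits similarity on `sin(2πlag/12)` and `cos(2πlag/12)` with intercept by
OLS over lags 3–36 (short lags are excluded because 1–2-month similarities
sit far above the rest); the p-value is the F-test of both harmonic
coefficients jointly. The fit uses per-lag mean similarities — matching the
plotted curve — with a `per_pair` option for fitting every pair. The period
is fixed at 12 months: the hypothesis is annual seasonality, and fitting
the period would change the test. No linear lag term is included by
default.

## Local similarity networks

Series are rank-normalised (normal quantiles of mid-ranks, then centred and
scaled); constant series are excluded. The local similarity score is the
maximum absolute partial sum of the pointwise product over contiguous
aligned segments with shift up to 3 months, divided by series length —
a Kadane scan along each alignment diagonal, with positive and negative run
matrices. Missing observations contribute zero to a run: they neither
extend nor reset it, the closest simple analogue of NA-tolerant local
similarity without introducing breakpoints at every data gap.

Significance: seeded permutation of one series' observed values (add-one
correction) is the reference method and is verified uniform under the null.
The theoretical alternative maps `√n · LS` to the distribution of
`max|W(t)|` of a standard Brownian motion (theta-function series) raised to
the power 2D+1 for the 2D+1 quasi-independent delay offsets; on simulated
nulls it tracks permutation p-values within roughly a factor of two in the
p ∈ [0.001, 0.1] range. `build_network` defaults to the theoretical method
because all-pairs permutation over hundreds of nodes (tens of thousands of
edges × thousands of permutations) is impractical; per-edge permutation
remains available.

Edges must pass p < 0.0015, Q < 0.05 (BH/Storey over all computed edges)
and |Spearman ρ| ≥ 0.6 simultaneously; ρ is computed on the simultaneous
(delay-0) overlap of non-missing months, separate from the LS delay. The
absolute-value reading of the ρ filter is the default, with a
positive-only switch. Connected components smaller than five nodes are
pruned, and edges are tallied by role pair (host–virus by fraction,
virus–virus, host–host, environment). Filtering is monotone: tightening
any threshold can only remove edges.

## Variance partitioning

Host community matrices (samples × taxa) are Hellinger-transformed;
environmental covariates standardized to zero mean, unit variance. RDA is
ordinary least squares of the centred response on centred predictors with
`r² = ‖Ŷ‖²/‖Y‖²` and the Ezekiel adjustment; rank-deficient predictor
blocks use the least-norm solution, with ranks from SVD. Partial RDA
residualises on the conditioning block and reports the conditional fit as
a *difference of projections* (fit on [X Z] minus fit on Z), which is
numerically exact when X lies inside span(Z); its adjusted R² is
`adjR²(X∪Z) − adjR²(Z)`, the decomposition used by two-block variance
partitioning. The two-block partition reports unique, shared and
unexplained adjusted fractions, which sum to one by construction; small
negative adjusted fractions are reported as computed and clipped only for
display.

Forward selection operates on principal-component axes of each predictor
block: the axis adding the most explained variance is tested by permuting
current-model residuals (Freedman–Lane), kept if p < 0.1, and the loop
stops at the first failure. Under a null response the expected number of
selected axes is approximately α × (number of candidates) (measured
0.097 per candidate at α = 0.1). Significance of unique fractions uses the
same Freedman–Lane scheme on the partial-RDA pseudo-F with free row
permutation (≤200 permutations by default). Free permutation ignores
temporal autocorrelation; with strongly autocorrelated monthly series the
permutation p-values for the unique fractions will be somewhat liberal.

## Phylogenetic traits

Trait transitions are counted by Hartigan's generalisation of Fitch
parsimony (majority-state sets at each node), which is exactly minimal on
multifurcations and reduces to classic intersection/union Fitch on binary
nodes; unlabeled leaves are pruned first, and the count is invariant to
child order. Per-state monophyly asks whether the MRCA of a state's leaves
subtends exactly those leaves. The null distribution shuffles labels across
leaves (seeded), yielding a z-score and a one-sided p-value for
phylogenetic clustering of the dynamic phenotype. Trees are consumed, not
inferred; rooting on a designated outgroup is supported.

## Pipeline

Stages (simulate → cluster → quantify → stats → dynamics → network →
varpart → phylo) exchange plain TSV files; a run directory carries the full
config (YAML), a provenance manifest (config hash, seed, package version)
and a parameter-echoing log, and completed stages are skipped when their
hash marker matches the current config. Reruns with identical config and
seed are byte-identical. When no tree is supplied, the phylo stage draws a
seeded random birth–death topology over the analysed species — labeled
synthetic in its output name — so the trait statistics can be exercised
end-to-end; with a random topology the observed transition count is
expected to sit inside the permutation null, and it does.

Problem sizes in the test-suite and acceptance runs (200-species default
community; a 24-species, 36-month community for pipeline-level checks;
500–1000 replicates for calibration simulations) were chosen as the
smallest sizes at which the recovery and calibration margins are stable
across seeds.

## Known limitations

* The seasonal test assumes Gaussian errors on (possibly log1p) RPKM;
  heavy-tailed count noise at very low abundance is only partially
  absorbed by the rank-based network statistics downstream.
* The theoretical LSA p-value is an asymptotic approximation; at n < 30 or
  for p > 0.2 it deviates noticeably from permutation, and the network
  q-values inherit that approximation when the theoretical method is used.
* Free permutation in RDA/varpart and in LSA ignores temporal
  autocorrelation (no restricted/cyclic-shift schemes).
* Greedy centroid clustering depends on processing order by design;
  equivalence with exhaustive best-centroid assignment is only guaranteed
  under the documented ordering rule.
* Chao richness on the synthetic default is essentially equal to observed
  richness because the generator's 200 species are nearly all detected —
  the estimator's unseen-species correction is exercised in unit tests, not
  by the default community.
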