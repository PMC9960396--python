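# phagedyn

Species-level analysis of marine T4-like cyanophage community time series.

Monthly metagenomic surveys of ocean surface waters capture two views of the
phage community: the **viral fraction** (<0.2 µm, free virions) and the
**cellular fraction** (0.2–1.2 µm, cells with phages replicating inside
them). `phagedyn` implements the full analysis chain used to characterise
T4-like cyanophage species and their picocyanobacterial hosts
(*Prochlorococcus*, *Synechococcus*) from such surveys:

* **Species delineation** — marker-gene (DNA polymerase amplicon) sequences
  are dereplicated and greedily clustered at 98% nucleotide identity, a
  threshold that falls inside the empirical gap between intra-population
  (marker identity >99%, core-gene ANI >97%) and inter-population (<90%,
  <88%) comparisons of isolate genomes. `benchmark_threshold` recomputes
  that gap from marker-vs-ANI pairs.
* **Abundance** — RPKM (reads per kilobase of gene per million library
  reads); species are retained only with 100% marker base coverage at ≥2×
  depth in at least one sample.
* **Community statistics** — bias-corrected incidence-based Chao richness
  `S_obs + ((N−1)/N)·q₁(q₁−1)/(2(q₂+1))`, exact hypergeometric rarefaction,
  rank abundance, and Bray–Curtis similarity `1 − Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ)` binned
  by month lag with an annual-harmonic OLS fit over lags 3–36 months.
* **Dynamic classes** — each species' series is fit with
  `y = β₀ + f_cyclic(month) + g(elapsed time)` (cyclic cubic regression
  spline + trend spline) and assigned one of four classes: *persistent*
  (detected in >85% of samples), *seasonal* (cyclic term p < 0.05),
  *sporadic* (detected in <15%), else *occasional*; with Storey/BH q-values,
  a divide-by-five downsampling robustness check and chi-squared
  class-composition comparisons.
* **Networks** — delay-aware local similarity analysis (max delay 3 months)
  across phage species in both fractions, host ASVs/ecotypes and
  environmental covariates, filtered to p < 0.0015, Q < 0.05, |ρ| ≥ 0.6,
  with sub-networks of fewer than five nodes pruned.
* **Variance partitioning** — Hellinger-transformed host community
  composition decomposed by RDA/partial RDA into fractions uniquely
  explained by phage community composition versus environment, with
  forward selection of principal-component axes (permutation p < 0.1) and
  permutation ANOVA.
* **Phylogenetic traits** — Fitch/Hartigan parsimony transition counts and
  per-state monophyly of dynamic classes on a species tree, against a
  label-permutation null.
* **Synthetic communities** — a fully labeled generator reproducing the
  survey's structure (lognormal rank-abundance tail, four dynamic
  archetypes, two correlated size fractions, host coupling, missing months)
  so every stage is testable without any sequencing data.

## Worked example

```python
import pandas as pd
from phagedyn.synthetic import SimulationConfig, simulate_dataset
from phagedyn import dynamics as dyn, community as cs, abundance as ab

cfg = SimulationConfig(n_seasonal=10, n_persistent=10, n_occasional=10,
                       n_sporadic=10, n_months=48)
ds = simulate_dataset(cfg, seed=42)
dates = pd.PeriodIndex(list(ds.counts_viral.samples), freq="M")

cls = dyn.classify_table(ds.counts_viral, dates)
print("class counts:", dyn.class_counts(cls))
joined = cls.join(ds.truth["archetype"])
print("recovery: %.1f%%" % (100 * (joined["class"] == joined["archetype"]).mean()))

rich = cs.chao_incidence(ds.counts_viral.counts.to_numpy() > 0)
print("chao: %.1f +/- %.1f (observed %d)" % (rich.chao, rich.chao_se, rich.s_obs))

at = ab.abundance_table(ds.counts_viral)
fit = cs.fit_lag_sine(cs.similarity_vs_lag(at.rel_abund, dates))
print("sine fit p = %.3g, r2 = %.3f" % (fit.p_value, fit.r2))
```

prints

```
class counts: {'seasonal': 10, 'persistent': 10, 'occasional': 10, 'sporadic': 10}
recovery: 100.0%
chao: 40.0 +/- 0.0 (observed 40)
sine fit p = 8.29e-29, r2 = 0.985
```

Every one of the 40 simulated species is assigned its generating dynamic
class; the Chao estimate equals observed richness because all species were
seen more than twice; and community similarity oscillates with a 12-month
period (maxima at lags 12/24/36, minima at 6/18/30), the hallmark of a
seasonally recurring community.

The same analyses run from the shell:

```bash
phagedyn run-all --seed 1 --out runs/demo         # simulate -> ... -> phylo
phagedyn cluster --config cfg.yaml --out runs/c   # single stage
```

Each run directory carries a `config.yaml`, a provenance `manifest.json`
(config hash, seed, version) and per-stage TSV outputs; rerunning with the
same config and seed reproduces every file byte-identically.

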