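# amitrace

Tracing somatic assortment of alleles in amitotic polyploid nuclei.

In ciliates such as *Paramecium tetraurelia*, the somatic macronucleus holds
~860 genome copies and divides by amitosis: copies partition randomly between
daughter nuclei, with no spindle. A locus carrying two forms — here a
retained internal eliminated sequence (IES⁺) alongside the normally excised
form (IES⁻) — therefore drifts across asexual generations. The IES retention
score (IRS), the fraction of somatic copies retaining the IES, is a
phenotype-free molecular marker of that drift, measurable by single-cell
DNA sequencing. `amitrace` implements the computational machinery for this
approach, for researchers studying amitosis, polyploid drift, or single-cell
WGA data from AT-rich genomes:

* **assortment models** (`amitrace.assort`) — exact Markov propagation of
  the IES⁺ copy-number distribution under three macronuclear architectures:
  *haploid* whole-genome subunits (`m' ~ Hypergeom(2k, 2m, k)`, variance
  constant `c = 1/(2k−1)`), *chromosomal* with co-segregating sister
  chromatids (`c = 1/(k−1)`), and *diploid* bundles (`c = 0`); the closed
  form `σ²(p₀, g) = p₀(1−p₀)(1−(1−c)^g)`; heterozygosity loss, phenotypic
  switch probabilities, and Monte-Carlo simulation of daily re-isolation and
  mass-culture regimes;
* **WGA bias quantification** (`amitrace.bias`) — GC-bias and terminal-bias
  slopes of normalized coverage (per 10% GC / per 10 kb from chromosome
  ends) and the depth-compensation arithmetic;
* **dropout accounting** (`amitrace.dropout`) — dropout calls at the
  ≤20-read threshold, decomposition into terminal / GC / residual
  components, count correction and z-scores;
* **retention scoring** (`amitrace.retention`) — IRS and per-boundary scores
  from MIRET-dialect support tables, the four-rule filter cascade, exact
  binomial boundary-discordance testing with Benjamini–Hochberg adjustment,
  and the CV-based measurement-error model;
* **drift tracking** (`amitrace.track`) — track-set selection, model-based
  95% confidence bands `IRS₀ ± 2σ(IRS₀, Δgen)`, within-band fractions, and
  rank-based dispersion comparisons;
* **synthetic data** (`amitrace.synth`) — toy AT-rich genomes, biased
  coverage, binomial read-support tables and multi-timepoint cohorts evolved
  under a known model, so the full pipeline is testable without sequencing
  data.

## Worked example

```python
import numpy as np
import amitrace as at

# 1) how fast do retained IESs assort in a ~860C nucleus?
haploid = at.build_model("haploid", ploidy_k=860)
dist = at.propagate(haploid, irs0=0.5, generations=200)
print(f"sigma after 200 divisions : {dist.sigma():.4f}")
print(f"heterozygous cells        : {at.heterozygosity(dist):.4f}")
print(f"phenotypic switch (>=0.85): {100 * at.switch_fraction(dist):.2f}%")
print(f"50 heterozygous loci      : {at.multilocus_switch(at.switch_fraction(dist), 50):.3f}")

# 2) can extra depth compensate single-cell WGA biases?
print(f"10 kb from a terminus, 1.5x depth: {at.compensated_coverage(0.321, 2, 1.5):.3f}")
print(f"20% GC below the mean, 1.5x depth: {at.compensated_coverage(0.163, 2, 1.5):.3f}")

# 3) track a synthetic cohort against the model's 95% band
rng = np.random.default_rng(0)
cohort = at.evolve_cohort(haploid, rng.uniform(0.2, 0.8, 200),
                          schedule=[0, 31], n_replicates=8,
                          depth_model=2000, seed=0)
ts = at.select_track_set(cohort)
cis = at.construct_ci(ts, haploid, delta_generations=31)
frac, _ = at.within_ci_fraction(cohort, cis, cohort.timepoints()[1])
print(f"track set n={len(ts.locus_ids)}, within-CI fraction: {frac:.3f}")
```

Output:

```
sigma after 200 divisions : 0.1657
heterozygous cells        : 0.9999
phenotypic switch (>=0.85): 1.42%
50 heterozygous loci      : 0.511
10 kb from a terminus, 1.5x depth: 0.537
20% GC below the mean, 1.5x depth: 1.011
track set n=199, within-CI fraction: 0.946
```

Reading: even after a full ~200-division clonal cycle, a locus starting at
IRS₀ = 0.5 drifts only mildly (σ ≈ 0.17); essentially every cell still
carries both forms, and only ~1.4% of cells would cross the 0.85 phenotypic
switch threshold at a single locus (~51% if 50 such loci segregate
independently). A 1.5× depth increase rescues GC-poor sequence
(normalized coverage ≈ 1.01) but not chromosome termini (≈ 0.54). On a
cohort evolved and scored under the same haploid model, ~95% of later
observations fall inside the 2σ band, as they should.

A command-line interface mirrors the library
(`amitrace synth|bias|dropout|irs|assort|track`, see `amitrace --help`);
all formats are plain TSV/BED/FASTA/JSON.

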