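# Methods

## The segregation model

Amitosis partitions macronuclear DNA between daughter nuclei without a
spindle. We model one biallelic locus — an IES locus carrying IES⁺
(retained) and IES⁻ (excised) forms — in a nucleus of ploidy `k` (default
860, the somatic ploidy of *P. tetraurelia*). The state is the integer
number `m` of IES⁺ copies in G1; the retention level is `m/k`.

A division is modelled as: replicate every subunit, then draw a daughter's
complement without replacement. What the subunit is distinguishes the three
architectures:

| model | segregating subunit | single-division kernel | variance constant c |
|---|---|---|---|
| haploid | whole haploid genome set | `m' ~ Hypergeom(2k, 2m, k)` | `1/(2k−1)` |
| chromosomal | chromosome, sister chromatids co-segregating | `m' = 2j`, `j ~ Hypergeom(k, m, k/2)` | `1/(k−1)` |
| diploid | heterozygous diploid bundle | identity | 0 |

Every kernel is a martingale (`E[m'] = m`) with absorbing boundaries at 0
and `k`. The conditional variance of the fraction is `c·p(1−p)` per
division, giving the recursion `Var_{g+1} = Var_g(1−c) + c·p₀(1−p₀)` and
the closed form

    σ²(p₀, g) = p₀(1−p₀) · (1 − (1−c)^g).

Exact propagation (dense `(k+1)×(k+1)` row-stochastic matrix applied to a
point mass at `round(p₀·k)`) reproduces this variance to ~1e−14 and
conserves probability to <1e−12 per step; the test suite also verifies the
kernels against brute-force enumeration of all partitions at k ∈ {2, 4, 8}.

Notes on the chromosomal kernel: free segregation of `2k` independent
chromosome copies would collapse, for a single locus, onto the haploid
kernel. Treating replicated sister chromatids as co-segregating pairs
(partition the `k` G1 copies, then re-replicate) doubles the per-division
variance relative to the haploid model (`c = 1/(k−1)` vs `1/(2k−1)`) and
reproduces the characteristic contrast between the two models' 200-division
switch probabilities (~1.4% vs ~6–7% from IRS₀ = 0.5 at the 0.85
threshold). The kernel's state is renormalised to `k` after re-replication;
aneuploidy of the focal chromosome's total copy number is not modelled.

Derived summaries: heterozygosity `H = 1 − P(0) − P(k)` (both forms still
present); phenotypic switch `P(m ≥ ceil(0.85·k))` — under incomplete
dominance a locus switches phenotype once IES⁺ copies exceed 85% of the
ploidy (`ceil` resolves the tie; 731 copies at k = 860); multi-locus switch
`1 − (1−p)^n` for `n` independent heterozygous loci; and the assortment
rate `dσ/dg`, analytically or by finite difference. `σ` is symmetric in
`p₀ ↔ 1−p₀` and the rate is maximal at `p₀ = 0.5`.

## Culture-regime Monte Carlo

Two regimes are simulated with integer states (equivalent to the classic
bit-vector formulation, without materialising bits):

* **daily re-isolation** — each line divides `div_per_day` times (default
  4) and a single random survivor continues. Since the two daughters of a
  division are exchangeable, a uniformly random leaf of the daily 16-cell
  tree has the law of a single random daughter path, so one path per line
  is tracked. Defaults: 1024 replicate lines.
* **mass culture** — all cells divide (both complementary daughters `m'`
  and `2m−m'` kept), then a bottleneck of `founders` random cells (default
  1024) without replacement seeds the next day.

The across-line σ trajectory of many isolation lines converges on the
analytic σ (verified within 3 Monte-Carlo SE at generations 40/120/200),
and the empirical state distribution of ≥10⁴ lineages matches the exact
propagated distribution with Kolmogorov–Smirnov distance < 0.02 at
generations 40 and 200.

## Retention scoring and the error model

A support row (MIRET dialect) carries retention reads per boundary
(SUPPORT_LEFT/RIGHT) and excision reads. Real MIRET tables expose one
shared SUPPORT_MAC count — a read crossing the excised junction supports
excision at both boundaries — which is then the denominator partner of both
boundary scores. The synthetic generator additionally emits per-boundary
excision counts (SUPPORT_MAC_LEFT/RIGHT), which are used when present.
Scores: pooled `IRS = (L+R)/(L+R+M_L+M_R)`; boundary scores
`L/(L+M_L)` and `R/(R+M_R)`; `bIRS` their mean; `SD_bIRS = |l−r|/√2`
(two-value sample SD, n−1 denominator); `CV = SD_bIRS / bIRS`, the relative
random error of a single sample's estimate. The pooled IRS always lies
between the two boundary scores.

The error-set filter cascade removes, in order-independent set fashion for
the first three rules: (1) coverage (sum of the three MIRET columns) below
20 reads — below this the estimate is unreliable across most of the IRS
range; (2) both boundary scores below 0.1 — background excision noise;
(3) exactly identical boundary scores — short IESs whose two junctions are
spanned by the same reads contribute no boundary-level replication;
(4) significantly discordant boundaries. Discordance is tested per locus
with an exact binomial test of the left boundary's retention reads against
the right boundary score as fixed success probability (roles swap when the
right score is degenerate; both degenerate → untestable), BH-adjusted
across tested loci at α = 0.05. The choice of conditioning side is a
convention; the test is applied to loci surviving rules 1–3, mirroring the
order in which the cascade is described for real data. Under concordant
boundaries, the post-BH flag rate stays below α.

Delta-method check of the error model: at boundary depth `d_b` and score
`s`, the median CV is `z₀.₅(|N|)·√((1−s)/(s·d_b))` with the folded-normal
median factor 0.6745; the synthetic generator reproduces this within a few
percent, and doubling depth shrinks the median CV by √2.

## Bias estimators and dropout accounting

**GC bias.** Window coverage is binned by integer GC percent (floor),
normalized by the genome-wide length-weighted mean base coverage, and the
slope of an unweighted OLS of normalized coverage on GC percent over the
9–50% range (the genome's composition span) is reported per 10% GC. Bins
with fewer than 10 windows are excluded from the fit to limit leverage of
sparse composition extremes. The estimator recovers injected slopes in
{0, 0.05, 0.163, 0.3} within ±0.02 on ≥10⁴-window genomes and is invariant
to coverage rescaling.

**Terminal bias.** For each end of each telomere-capped scaffold (≥100 kb;
shorter ones are skipped with a warning), 49 sliding windows of 2 kb at
1-kb steps span the outermost 50 kb; each contributes its median base
coverage, normalized by the genome-wide (length-weighted) median. The OLS
slope of these points on distance from the nearer terminus, restricted to
≤30 kb where the recovery plateaus, is reported per 10 kb. Both ends are
pooled. The true relationship is parabolic; the linear slope is the
conventional summary. For the reference single-cell profile (14% of plateau
coverage at 1 kb, plateau at 30 kb) the parabola-implied OLS slope is
≈0.30 per 10 kb, consistent with the ~0.32 reported for real single-cell
libraries.

**Depth compensation.** `(1 − n_units·slope) · depth_fold` gives the
expected normalized coverage `n_units` slope-units from the reference point
when sequencing at `depth_fold` extra depth — e.g. 1.5× depth yields ≈1.01
for DNA 20% GC below the mean (b_GC = 0.163) but only ≈0.54 at 10 kb from
a terminus (b_Ter = 0.321).

**Dropout.** A locus drops out when its coverage is ≤20 reads (inclusive).
Total dropout decomposes as `total = terminal + gc + residual`: the
terminal fraction is measured on loci within 30 kb of either scaffold end
(matching the bias fit range); the residual component scales a bulk
reference's residual dropout by the single-cell/bulk mapped-read-pair
ratio; the GC component is the remainder, clamped at 0 (components are
fractions of loci). Counts are corrected as `n/(1 − total dropout)` and
compared via z-scores.

## Synthetic-data generator

The generator defines the study conditions for all tests:

* **genome** — window GC is Beta-distributed, re-parameterised by mean 0.28
  and SD 0.06 and truncated to [0.05, 0.55] by rejection; this reproduces
  16th/84th window-GC percentiles of ~22%/34% without modelling real
  sequence. Scaffolds (default 1-kb windows) are telomere-capped unless
  requested otherwise.
* **coverage** — expected normalized coverage is
  `(1 + b_GC·(gc−gc̄)/0.10) · terminal_factor(d)` with multiplicative Gamma
  noise of unit mean (default CV 0.05); the terminal factor is the parabola
  described above, applied at window centres of capped scaffolds.
* **support counts** — per-boundary read totals are Poisson around half the
  locus depth (so dropout arises naturally from the bias parameters via the
  window coverage at the locus position); retention reads are binomial at
  the true retention level, optionally offset by ±discordance/2 per
  boundary to exercise the discordance filter. Observed IRS is an unbiased
  estimator of the truth.
* **cohorts** — replicate lineages iterate the chosen model's division
  kernel continuously through a generation schedule (a replicate's later
  timepoints continue from its own earlier truth, as in a daily
  re-isolation time course); support tables are drawn at each observation
  and the hidden truth is retained. Truth trajectories are martingales;
  across-replicate truth SD matches the analytic σ, and the
  chromosomal/haploid SD ratio is ≈√2 at matched settings.

What the generator does **not** emulate: read-level artifacts (chimeras,
duplicates, mappability), MDA branching structure, correlated biases along
a scaffold, aneuploidy of total copy number, or selection. Passing tests
therefore demonstrate correctness of the estimators and models under the
stated sampling assumptions, not robustness to every artifact of real
single-cell libraries.

All randomness derives from one root seed via fixed SeedSequence spawn
keys, one per operation family, so results are reproducible and adding
draws to one operation does not perturb another.

## Drift tracking and calibration

The track set keeps loci with IRS > 0.1 and coverage > 20 reads (both
strict) in *every* sample of the cohort; IRS₀ is the replicate-mean pooled
IRS at the first timepoint. The 95% band is `IRS₀ ± 2σ(IRS₀, Δgen)`,
clamped to [0, 1], with σ from the closed form — at high ploidy the
propagated distribution is close to normal over ≲50 generations for
0.1 < IRS₀ < 0.9. Default Δgen values follow the 3.5-divisions/day mapping
of the emulated design (day 5 ≈ gen 17; day 10 − day 5 ≈ 17; day 14 −
day 5 ≈ 31). Measurement error is deliberately not folded into the band: it
is quantified separately by the retention error model, so an empirical
within-band fraction below 95% is itself informative about extra-model
variation.

Calibration is assessed on a cohort generated and scored under the same
model, with the first timepoint at generation 0 and 2000-read depth: the
within-band fraction is then 0.95 ± 0.03 (the band covers drift only, and
this design keeps baseline noise from confounding the check). With a
drifted baseline (e.g. first observation at generation 17) the same band
necessarily undercovers somewhat, since baseline drift and its estimation
error sit outside the band; this is the expected behaviour, not a defect.

Dispersion statistics use the n−1 sample SD across replicates per locus and
timepoint; SD ratios are computed pairwise (later/earlier) on loci with
nonzero denominators. Comparisons use one-sided rank tests — Wilcoxon
signed-rank on aligned loci when paired, Mann–Whitney rank-sum otherwise
(e.g. observed dispersion at n = 75 loci vs an error distribution at
n = 1196, which cannot be aligned) — with normal-approximation effect size
`r = |Z|/√N` and BH adjustment across the comparisons performed. All-zero
difference vectors return p = 1, r = 0 rather than an error.

## Numerical choices and problem sizes

* Kernel construction uses vectorised hypergeometric PMFs; the 861-state
  kernel builds in seconds and is cached per (kind, k).
* Switch thresholds use `ceil(threshold·k)` with a 1e−9 guard against
  binary-representation noise (0.85·860 must give 731, not 732).
* Probability conservation is asserted at every propagation step (1e−12).
* The test suite runs its simulations at deliberately modest sizes —
  12,000-window genomes, cohorts of a few hundred loci with 4–10
  replicates, 10⁴ Monte-Carlo lineages, 1024 isolation lines over 200
  generations — chosen so the full suite completes in well under a minute
  of compute while keeping Monte-Carlo standard errors far below the
  tolerances tested.

## Known limitations

* The boundary-discordance test conditions on one side's score as a fixed
  probability; a symmetric two-proportion test would be a reasonable
  alternative and would differ slightly at low counts.
* The chromosomal model's paired-chromatid reading is one of several
  mechanisms compatible with "chromosomes segregate individually"; it is
  chosen because free segregation of independent copies is
  indistinguishable from the haploid model at a single locus.
* Real-data quantities that depend on the original sequencing libraries
  (dropout levels of particular samples, observed dispersion shifts,
  within-band fractions of the empirical track set) are outside the scope
  of the synthetic pipeline; the package reproduces their arithmetic and
  their qualitative structure, not their values.
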