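# Methods

## Seasonal model and inference

Methylation beta values β ∈ [0, 1] are transformed to M-values
M = log2(β / (1 − β)); values at the boundary are clamped to 1e-6
before the logit so M is always finite. All modelling is on the M
scale, where array noise is closer to homoscedastic. The inverse
transform 2^M / (1 + 2^M) round-trips to at least 12 significant
digits and is used to report effects on the percent-methylation scale.

The conception date of each individual is mapped to an angle
θ = 2π · (days elapsed since 1 January) / (days in that year), so
1 January = 0 and 31 December is just under 2π. When conception date
must be derived from birth date, the package subtracts 280 days (the
average gestation length in the study populations this design
emulates); the offset is a parameter.

Per CpG, ordinary least squares fits

M = α₀ + Σ α_k x_k + Σ_r [β_r sin(rθ) + γ_r cos(rθ)] + ε,

with one Fourier pair by default (`n_pairs=1`); higher-order pairs are
available behind the same parameter but are not the default because a
single pair already captures a free-phase annual sinusoid. Seasonal
significance is the likelihood-ratio statistic
2(ll_full − ll_reduced) = n·log(RSS_reduced / RSS_full) under the
Gaussian likelihood, referred to χ² with 2 df per pair. This is the
convention of standard linear-model LRT routines. Its exact-F
finite-sample equivalent rejects slightly above nominal (about 5.4%
at α = 5% with n = 250 and seven design columns); this is a property
of the convention, not of the implementation, and vanishes as n grows.

Multiple testing uses Benjamini–Hochberg step-up with an overridable
test count m: by default m is the number of p-values supplied, and a
larger m reproduces the convention of adjusting a CpG subset against a
fixed array background.

### Amplitude and phase

The fitted seasonal curve is evaluated on a 365-point daily grid at a
covariate reference point (means for continuous covariates, the modal
level for binary indicators — a "typical individual" rather than an
impossible fractional one), back-transformed to the beta scale, and
summarised as amplitude = (max − min) × 100 with the argmax/argmin
days. The grid is authoritative because it extends unchanged to
multi-pair models; for the single-pair model it agrees with the closed
form (acrophase atan2(β₁, γ₁), M-scale amplitude 2√(β₁² + γ₁²)) to
within one grid step, which the test-suite verifies. When both
seasonal coefficients are exactly zero the amplitude is 0 and the peak
day is reported as missing. Because the back-transform is monotone,
peak and nadir days are identical on the M and beta scales, and for
the single-pair model they are half a year apart.

### Outlier rule

Per CpG, beta values more than 3×IQR beyond the 25th/75th percentiles
are masked before fitting. Quartiles use linear (type-7)
interpolation — stated explicitly because the masked set depends on
the convention — and are computed once on the unmasked vector (single
pass; no re-iteration after masking). The rule is applied on the beta
scale, the plain reading of "methylation values". Masking requires at
least 4 non-missing values.

### Covariates and PCs

`compute_pcs` returns the first k scores of an unsupervised PCA of the
centred M-value matrix, variance-ordered, with the sign convention
that each component's largest-magnitude loading is positive (making
scores reproducible across equivalent decompositions). A caveat worth
knowing: regressing on PCs estimated from the same matrix absorbs a
little of each CpG's own noise when the CpG panel is small. At the
desk scale used in the tests (2000 CpGs, 250 samples, 6 PCs) this
inflates the null rejection rate by roughly one percentage point
(λ ≈ 1.05–1.1); the effect shrinks as the panel grows toward real
array size (hundreds of thousands of CpGs), where the practice is
standard. The engine-calibration checks therefore run without
data-derived PCs, while the FDR/power checks run the full standard
adjustment.

`preadjust_covariate` implements the sensitivity-analysis scheme of
regressing a single covariate out of every CpG before the main model,
restoring the per-CpG mean.

## Hit selection, controls, replication

Hits are a pure filter: q < 0.05 and amplitude ≥ 4% (both thresholds
are parameters and are recorded in the output's provenance). Matched
controls are drawn greedily, one per hit, in seeded shuffled order
from the background (excluding hits and any supplied exclusion sets):
the first candidate whose beta distribution is indistinguishable from
the hit's by a two-sided two-sample Kolmogorov–Smirnov test at
p > 0.1 is accepted and removed from the pool. Greedy one-to-one
assignment in shuffled order was an open design choice; reuse of
controls is not allowed, and every accepted pair is re-checkable post
hoc. Random controls are a uniform sample without replacement.

Replication between two EWAS tables is summarised over shared CpGs by
(i) the Spearman correlation of peak days on linear day-of-year
values, with a circular (Fisher–Lee) correlation available because the
linear statistic is sensitive to where the 1 January cut falls; (ii)
paired amplitude deltas tested two-sided by Wilcoxon signed-rank with
Pratt zero handling (all-zero deltas report p = 1); (iii) the count of
CpGs significant in the second table.

## Genomic context

CpG clusters are single-linkage chains of CpGs whose nearest neighbour
is within 5 kbp (inclusive at exactly 5 kbp). De-clustering samples
one member per cluster (always keeping singletons), seeded. Enrichment
of a CpG set against an annotation track (BED-style 0-based half-open
intervals, or an explicit CpG-id set) uses the fold
(set_overlap/set_total) / (bg_overlap/bg_total) over the full
background and a two-sided Fisher exact test on set vs
background-minus-set; the test choice was the package's (a fold and p
were required but no test was named). With zero background overlap the
fold is undefined (NaN) and the Fisher p is still reported.
Cluster-adjusted enrichment de-clusters set and background together —
each background cluster contributes one representative, preferring a
set member for clusters that contain one — and reports the median fold
and p over 100 seeded draws, so a single unlucky within-cluster sample
cannot drive the result. Proximity is measured from the CpG position
to the nearest interval edge (0 inside an interval); proximity curves
report, per distance, the proportion of the de-clustered set within
that distance, with percentile 95% CIs from 1000 bootstrap resamples
of the CpG set.

Gametic methylation status per CpG: oocyte-methylated germline DMR
(oo-gDMR) when sperm < 25% and oocyte > 75%; the symmetric sperm-gDMR
when oocyte < 25% and sperm > 75%; sperm-hypomethylated-only when
sperm ≤ 25% without oocyte hypermethylation. The ≤/< asymmetry at the
25% sperm boundary is deliberate, preserving the source definitions of
the two categories verbatim; a CpG at exactly 25% sperm methylation
can be sperm-hypo but never oo-gDMR.

## Genetic analyses

SNPs enter as allelic dosages (0/1/2). Filters: empirical MAF must
exceed 10% and at least 10 homozygous carriers are required (rare
homozygotes exert undue leverage in linear models). mQTL mapping is
two-step to maximise power: a cis screen (same chromosome, within
1 Mb inclusive) with BH-FDR within the pooled cis family, then a trans
screen over all SNPs with BH-FDR over the full family. Effects are
estimated by Frisch–Waugh partialling (methylation and dosage both
residualised on the covariates), which is exactly the joint-OLS
estimate; cis/trans labels are a pure function of coordinates.
Variance explained per CpG is ΔadjR² = adjR²(covariates + all its
significant mQTL) − adjR²(covariates only) on identical samples;
adjusted R² prevents CpGs with many mQTL from being mechanically
favoured, and small negative deltas are possible.

Gene-by-season interaction per CpG tests M ~ covs + f(θ) + G + G·f(θ)
where f is sin or cos, whichever was the more significant marginal
Fourier term in the main seasonal fit (ties fall to sin). The
season-genotype confounding check regresses dosage on sin θ + cos θ
with a joint F-test (default), or — when rainy/dry day-of-year windows
are supplied — compares allele counts between season groups with a
2×2 chi-square without continuity correction, mirroring the behaviour
of standard allelic-association tools that require a discrete
phenotype. Both FDR and a Bonferroni-style threshold are reported.

## The synthetic-cohort generator

The generator produces the statistical structure the analysis assumes,
so every downstream stage can be exercised without controlled-access
cohort data. Defaults describe the study conditions the package is
designed for and were fixed once:

- **n_samples = 250**: the scale of the child cohorts this design
  emulates (233–289).
- **Conception dates**: von Mises on the day-of-year circle;
  concentration 0 (the default) gives year-round uniform conceptions,
  as in a prospective design; years drawn from a two-year window.
- **Seasonal signal**: injected on the M-value scale as
  A·sin(θ − θ_peak + π/2), so methylation peaks at `peak_day`
  (default 244, early September — the rainy-season peak) and bottoms
  half a year later. A = 0.1735 by default, sized so the beta-scale
  amplitude at an intermediate baseline (0.5) is ~6%, the scale of
  reported seasonal effects; `logit_amplitude_for_beta_amplitude`
  computes A for any target. Because the signal lives on the logit
  scale, beta-scale amplitude is baseline-dependent; the truth table
  stores both.
- **Baselines**: hit CpGs are intermediately methylated
  (0.35–0.65) — the hotspot signature — while background CpGs follow
  a low/high/intermediate mixture typical of arrays.
- **noise_sd_logit = 0.3**: residual M-value SD typical of
  intermediately methylated array CpGs.
- **Latent structure**: probe-specific batch offsets (SD 0.15, two
  batches) and 5 Gaussian cell-composition factors with N(0, 0.1)
  loadings. Together these span six strong latent dimensions, which
  the standard six-PC adjustment is designed to capture; covariate
  effects (e.g. sex, +0.1 on the M scale) are additive and uniform
  across CpGs. No interactions are generated unless a GxE effect is
  explicitly configured.
- **Genotypes**: Hardy–Weinberg binomial dosages at MAF drawn from
  (0.15, 0.5); SNPs failing the empirical MAF/homozygote filters are
  re-drawn so every emitted SNP passes at the configured n. Spiked
  cis-mQTL (default at half the hit CpGs) add 0.146 per dose on the M
  scale — sized to explain ~9% of methylation variance at MAF 0.3 —
  and are placed 10 kb from their target CpG.
- **Coordinates and tracks**: CpGs are spread over four chromosomes
  with large gaps; a configurable fraction of hits is placed within
  5 kbp of a neighbour to create clusters. The annotation track
  covers hits at a rate calibrated so the fold enrichment over the
  full background equals the requested fold in expectation (5%
  background coverage).
- `simulate_followup` re-measures the same individuals with the
  seasonal amplitude scaled (default halved) and fresh
  batch/cell/noise draws, emulating attenuation of the effect with
  age in a longitudinal design.

All randomness flows through one seeded generator: the same
configuration and seed reproduce the cohort bit-for-bit, and the
pipeline's text outputs are byte-identical across runs.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: array chemistry and probe artefacts
(IDAT-level noise, dye bias, cross-hybridisation), realistic LD
between SNPs (SNPs are independent apart from the configured
SNP–CpG coupling), heavy-tailed or bimodal residuals, genuine cell
mixtures with simplex constraints, correlated methylation *within*
clusters (cluster members share coordinates, not signal), and
population structure or relatedness.

## Sizes used by the test-suite and acceptance script

The statistical checks run at the sizes the properties are stated for:
null calibration on one 250 × 2000 null cohort; FDR/power on mixed
cohorts of 5000 CpGs with 10% hits (20 replicates in the test-suite, 8
in the reporting script); parameter recovery over 200 (script: 150)
single-CpG replicates at n = 250; mQTL recovery over 100 (script: 60)
replicates at n = 284. Everything completes in well under a minute per
block on one CPU.

## Known limitations

- No mixed models, robust/sandwich errors, or surrogate-variable
  estimation beyond PCA; no meta-analysis across cohorts (deliberate,
  since effects attenuate with age and pooling would dilute them).
- The mQTL scan materialises its test matrix densely; it is meant for
  a hit set times a pruned SNP panel, not a genome-wide scan.
- IDAT preprocessing, normalisation, probe QC, cell-count estimation,
  imputation/phasing/LD pruning and chromatin-state prediction are
  upstream of this package and out of scope.
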