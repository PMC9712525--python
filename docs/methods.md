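# Methods

## The analysis problem

The toolkit implements a transgenerational epigenome-wide association
study (EWAS) design: does a grandmother's smoking during the pregnancy of
a parent associate with DNA methylation in the grandchild?  The exposure
is binary and comes on two lines — maternal grandmother (MGM) and
paternal grandmother (PGM) — and because germline exposure effects are
often sex-specific, each line is analysed in all individuals, in females,
and in males: six EWAS per dataset.  The design assumes two methylation
arrays with partially overlapping probe content (an EPIC-like discovery
array and a 450k-like replication array) and up to three sampling
timepoints (birth, age 7, adolescence).

Because the motivating cohort data are access-restricted, the package
ships a first-class synthetic cohort generator that reproduces the
*structure* of such data, so that every downstream stage — QC,
exclusions, deconvolution, association, replication, meta-analysis,
enrichment — is exercised and tested end to end on data with known
ground truth.

## Per-CpG model

For probe *j* and sample *i* with methylation beta value
`y_ij ∈ [0, 1]`:

    y_ij = b0_j + b1_j x_i + g_j' z_i + e_ij

where `x_i` is the binary grandmaternal-smoking exposure and `z_i` the
covariates: age at sampling (gestational age at birth), sex (both-sex
stratum only), batch as fixed-effect dummies, sample type (birth and
age-7 datasets, where collection differed), and estimated cell-type
proportions with the last column dropped (the proportions sum to one, so
the full set is collinear with the intercept).  `b1_j` — the beta-scale
methylation difference associated with exposure — is the effect size;
inference uses ordinary least squares with two-sided p-values from the
Student t distribution on the residual degrees of freedom (strata can be
a few hundred samples, so the normal approximation is not assumed).
The fit is vectorised across probes through one shared design matrix;
probes with missing values are refitted individually on their complete
cases.  Rank-deficient per-probe designs yield a row of missing
statistics plus a warning count rather than a silent drop; a constant
exposure aborts the analysis with a diagnostic.

Genome-wide significance uses the array-specific conventions 9e-8
(EPIC-like) and 2.4e-7 (450k-like).  Bonferroni thresholds for candidate
lookups are computed as `alpha / n_tested` from the probes actually
tested, reported rounded to a configurable number of significant figures
and compared at full precision.

### Probe and sample filtering

Detection-p QC removes samples whose fraction of probes with detection
p > 0.01 strictly exceeds 10% (a sample at exactly 10% passes).  Study
exclusions then apply, in order: restriction to the dataset
(timepoint × array); non-white or missing ethnicity (discovery array
only — the rule models a cohort whose replication arm was ethnically
homogeneous); children of mothers who smoked during the pregnancy; own
smokers; samples missing the analysed line's exposure; the sex stratum.
Only *reported* smokers are excluded — missing maternal- or own-smoking
status is retained.  Each stage is logged (before/removed/after), making
any order-dependence visible.  Probe filtering: both-sex analyses keep
autosomes only; single-sex analyses keep autosomes + X; Y is always
removed.  Cross-reactive and SNP-flagged probes are never dropped, only
annotated, so hits can be checked against the flags afterwards.

### Cell composition

Blood methylation is a mixture over cell types, and cell composition can
confound exposure associations.  Proportions are estimated per sample by
constrained projection on a reference panel (Houseman-style): minimise
`||b - R'w||²` subject to `w ≥ 0, Σw = 1` over the probes shared between
sample and reference.  The simplex constraint is enforced by augmenting
the least-squares system with a sum-to-one row weighted 1000:1 and
solving with non-negative least squares, then renormalising; on
unit-scale problems the residual sum deviation is below 1e-9, the
solution is deterministic, and noiseless mixtures are recovered to
machine precision.  A rank-deficient reference triggers a warning and a
pseudo-inverse fallback.

### Surrogate-variable sensitivity check

To check that the known covariates capture the substantial sources of
variation, the engine refits each EWAS with surrogate variables appended
and reports the Pearson correlation of the two effect-size vectors.  The
surrogates are the leading principal components of the residuals after
regressing every probe on the known covariates *excluding the exposure*.
This exclusion is essential, not cosmetic: principal components of
full-model residuals are exactly orthogonal to the design, and appending
regressors orthogonal to the design provably leaves the exposure
coefficient unchanged — the concordance would be identically 1 and the
check vacuous.  Leaving the exposure out lets unmodelled structure that
co-varies with the exposure surface in the surrogates, which is
precisely what the sensitivity analysis is meant to detect.  This is a
residual-PCA construction, lighter than the full iteratively reweighted
surrogate variable algorithm; it serves as a concordance check, not as
the primary adjustment.

## Replication battery

No single statistic captures replication of top hits, so three
complementary views are computed for each discovery/replication pair,
restricted to probes present on both arrays:

1. **Lookup** — the top 25 discovery sites tested in the replication
   dataset at p < 0.05/25, with a stricter family-adjusted flag at
   p < 0.05/(6·25) = 0.0003 for the six EWAS families.
2. **Effect-size correlation** — Pearson r (p via the t transform on
   n − 2 df) between paired effects over the top 10/25/50/100/200 sites.
3. **Sign binomial** — count the top-K sites with replication p < 0.05
   *and* concordant effect direction; exact one-sided binomial test
   against null success probability p0 = 0.025 (the joint chance of
   p < 0.05 and a coin-flip sign agreement).  The alternative convention
   p0 = 0.05 (direction-agnostic) is available by argument.

Top-K selection is fully deterministic: ascending p, ties broken by
larger |effect|, then probe id.  The same machinery serves cross-sex
agreement (female vs male strata) and cross-timepoint replication in
both directions, where lookups use the three-timepoint convention
alpha/3.

## Meta-analysis

Fixed-effects inverse-variance pooling of per-probe summary statistics
across datasets (the METAL scheme): `w_s = 1/se_s²`,
`effect = Σ w_s e_s / Σ w_s`, `se = (Σ w_s)^{-1/2}`, two-sided normal
p on z = effect/se.  Datasets are treated as independent (no sample
overlap by design).  Probes present in fewer than all studies are
flagged via `n_studies` and can be dropped with `common_only`.  The SE
contracts exactly as k^{-1/2} for k identical studies — one of the
frozen closed-form checks.

## Enrichment statistics

**A-priori region lookups.**  X-chromosome sites (per sex), germline
demethylation-escapee regions, and imprinting control regions (ICRs) are
biologically privileged locations for transgenerational signal.  Each
lookup recomputes its own Bonferroni threshold from the number of
tested probes in the mask rather than hard-coding a published count.

**Locus overlap (LOLA-style).**  Each probe contributes a 201 bp window
(100 bp on either side of the 1-based CpG coordinate, i.e. the 0-based
half-open interval `[pos−101, pos+100)`).  Within the ranked top set,
later windows overlapping an earlier one are removed to prevent double
counting; the better-ranked (smaller p) site is kept, and removed sites
are excluded from both margins of the table.  The universe windows are
not deduplicated (the margin-inflation concern applies to the small top
set).  For each region set a 2×2 table of window-overlap counts feeds a
one-sided Fisher exact test for over-representation; the log odds ratio
is natural-log with a Haldane–Anscombe 0.5 correction when any cell is
zero.  Strand is ignored throughout — array CpG coordinates are
strandless.

**Candidate-set inflation.**  For a candidate CpG list (e.g. sites known
to respond to prenatal or own smoking), p-values are converted to 1-df
chi-square quantiles and lambda is their median over 0.4549 (the
chi-square(1) median).  The standard error is a site-level bootstrap
(default 1000 resamples, seeded).  QQ coordinates use the midpoint
plotting positions `(i − 0.5)/n`.  A one-sided Wilcoxon rank-sum test
asks whether candidate p-values are stochastically smaller than the rest
of the tested probes' — exact enumeration when both groups have ≤ 10
members and no ties, otherwise the normal approximation with tie
correction.

A note on sampling variability: the lambda of a *random* 500-site subset
of a 5000-probe null EWAS has sampling SD ≈ 0.10 (the subset median is
noisy), so calibration statements about random candidate sets are made
about the mean lambda over many seeded draws, not about a single draw.

## Synthetic cohort generator

The generator produces, from one integer seed: per-timepoint beta
matrices, a sample sheet, a probe annotation table, the cell-type
reference used for mixing, a detection-p matrix, genomic region sets,
candidate lists, and a table of injected true effects.  The generative
model per sample and probe is

    beta = clamp01( Σ_t w_t μ_tj + batch(b, j) + s_j (age − mean age)
                    + δ_j · exposed · sexmatch + ε ),  ε ~ N(0, σ)

with cell weights w ~ Dirichlet(α) (default 7 cell types, α = 2, a
blood-like "complete" panel size), reference profiles μ drawn around a
per-probe baseline Uniform(0.10, 0.90) with cell-type offsets of SD
0.08, per-(batch, probe) offsets of SD 0.01 over 4 batch levels,
per-probe age slopes of SD 0.0005/year, and noise SD 0.02 on the beta
scale.  Noise is additive Gaussian with clamping rather than
logit-scale — adequate at desk scale, and the clamp keeps every emitted
value in [0, 1] (property-tested).

Cohort structure: exposure prevalences default to 0.31 (MGM) and 0.38
(PGM) with 20% missingness; maternal smoking in pregnancy is drawn at
0.4 given grandmaternal smoking vs 0.15 otherwise, so the
maternal-smoking exclusion is correlated with the exposure and
non-trivially exercised (these conditional rates are generator defaults
chosen to make the exclusion logic consequential; the true empirical
correlation in any real cohort is unknown to us).  Own smoking (5%)
applies at adolescence only.  Ethnicity is 86% white / 10% non-white /
4% missing.  About 60% of individuals are on the EPIC-like array
(measured at adolescence only); 450k-like individuals are measured at
all configured timepoints.  90% of probes are shared between arrays, at
least one probe is deliberately EPIC-only (mirroring content absent from
the older array), and probes carry X/Y, ICR, escapee, cross-reactive and
SNP flags at configurable rates.  Detection-p matrices are constructed
so that exactly the requested number of samples fail the 10% rule and
every other sample stays below it.

What the generator does *not* emulate: raw intensity/IDAT artefacts,
probe chemistry (Type I/II), normalisation residue, spatially correlated
methylation (neighbouring CpGs are independent here), logit-scale
heteroscedasticity, and genetic relatedness.  Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
generative model, not robustness to every artefact of real arrays.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run at desk scale, chosen as
the smallest sizes at which each property is statistically decisive:
null calibration at 200 samples × 5000 probes; effect recovery at
n = 700 with 50 injected 0.05 effects; sign-test type-I error over 1000
paired null replicates of 25 probes × 100 samples; replication power
over 20 replicates at n = 700 with 20 shared causal probes.  Other
choices: p-values are floored at the smallest positive double rather
than reported as 0; the last cell-type column is always the one dropped
(deterministic); top-K tie-breaks are total-ordered; bootstrap and all
simulation randomness flow from explicit seeds, with the pipeline
fanning one global seed into fixed per-stage child seeds so stages are
independently replayable.

## Known limitations

- The deconvolution reference is simulated, not a laboratory-sorted
  panel; probe-signature selection is by variance, not by the published
  signature of any specific reference.
- The surrogate-variable check is residual PCA, not the full SVA
  algorithm, and is intended only as a concordance diagnostic.
- Fixed-effects meta-analysis only; no heterogeneity statistics.
- The exclusion order (ethnicity → maternal smoking → own smoking) is
  one defensible ordering; the per-stage log exists precisely so that
  order-dependence can be audited.
- Pipeline TSV outputs carry 6 significant digits; byte-identical
  reruns are guaranteed for a fixed config and seed.
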