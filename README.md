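# transewas

Transgenerational EWAS toolkit: does grandmaternal smoking during a
parent's gestation associate with DNA methylation in the grandchild?

`transewas` is a Python library (with a thin CLI) for running this
study design end to end: per-CpG linear-model association of methylation
beta values with a binary grandmaternal-smoking exposure on two lines
(maternal and paternal grandmother), stratified by sex, across two
partially overlapping arrays (EPIC-like discovery, 450k-like
replication) and up to three timepoints.  Around the association engine
it provides detection-p sample QC, study-exclusion rules, reference-based
cell-composition estimation, a three-pronged replication battery,
inverse-variance fixed-effects meta-analysis, a-priori region lookups
(X chromosome per sex, demethylation-escapee regions, imprinting control
regions), LOLA-style locus-overlap enrichment, and candidate-CpG-set
inflation/enrichment statistics.

Because cohort methylation data of this kind are access-restricted, the
package includes a seeded synthetic cohort generator that reproduces the
statistical structure of such data (cell-mixture variation, batch
effects, correlated maternal smoking, sex-restricted injected effects,
two-array probe content, detection p-values), so every stage is testable
with known ground truth and no downloads.  It is aimed at epigenetic
epidemiologists who want a transparent, fully tested re-implementation
of this analysis design, and at methodologists who want a sandbox with
plantable effects.

## The model

For probe *j*, sample *i*:

    y_ij = β0_j + β1_j·x_i + γ_j'z_i + ε_ij,   y in [0, 1]

with exposure `x ∈ {0, 1}` and covariates `z`: age (gestational age at
birth), sex (both-sex stratum only), batch dummies, sample type where
collection differed, and estimated cell proportions (last column
dropped).  `β1_j` is the beta-scale effect size; p-values come from the
Student t distribution on the residual degrees of freedom.  Array-level
significance uses 9e-8 (EPIC-like) and 2.4e-7 (450k-like); candidate
lookups use `α/n_tested` Bonferroni thresholds computed from the probes
actually tested.  Replication of top-K discovery sites is assessed by
lookup at `0.05/K` (family-adjusted `0.05/(6K)`), Pearson correlation of
effect sizes, and an exact one-sided binomial test of directional
replication (null success probability 0.025).  Meta-analysis pools
per-probe effects with weights `1/se²`.  Candidate-set inflation is
`λ = median(χ²)/0.4549` with a bootstrap SE.  See `docs/methods.md` for
assumptions, defaults and limitations.

## Worked example

```python
import transewas as tw

cfg = tw.SimulationConfig(
    n_samples=300, n_probes=1000, seed=7,
    causal_probes=[("cg0000042", 0.05, "MGM", "all")],
)
cohort = tw.simulate_cohort(cfg)

spec = tw.AnalysisSpec("MGM", "all", "adolescent", "epic_like")
kept, log = tw.apply_study_exclusions(cohort.samples, spec)
probes, _ = tw.filter_probes_for_analysis(cohort.probes, spec)
cells = tw.estimate_cell_proportions(cohort.betas["adolescent"],
                                     cohort.reference)

model = tw.EwasModel(
    cohort.betas["adolescent"].subset(kept, probes),
    cohort.samples, spec, cellcounts=cells,
)
results = model.fit()
print(results.summary(top=3))
```

```
EWAS Results
============================================================
Exposure line:      MGM grandmaternal smoking
Stratum:            all
Timepoint / array:  adolescent / epic_like
Samples:            97
Probes tested:      950
Covariates:         age_years, sex_M, batch_batch1, batch_batch2, batch_batch3, cell0, cell1, cell2, cell3, cell4, cell5
GW threshold:       9e-08
Probes below GW:    1
------------------------------------------------------------
Top 3 associations:
 probe_id   effect       se  tstat    pvalue  n
cg0000042  0.04591 0.005444  8.432 8.234e-13 97
cg0000828 -0.01359  0.00397 -3.423 0.0009589 97
cg0000676 -0.01693 0.005043 -3.357  0.001187 97
```

Of 300 simulated individuals, 97 remain in this analysis cell after the
exclusion chain (EPIC-like array, white ethnicity, no maternal smoking
in pregnancy, no own smoking, MGM exposure observed); 950 of 1000 probes
survive the autosomes-only rule.  The one probe below the genome-wide
threshold is the injected effect: the true beta-scale difference of 0.05
is estimated at 0.046 (SE 0.0054).  The stratified specs, the
replication battery (`tw.replication_report`), meta-analysis
(`tw.fixed_effects_meta`) and the enrichment statistics all consume
these `EwasResults` objects.

The full design — simulate → QC → exclusions → deconvolution → 24 EWAS →
replication → meta-analysis → lookups and enrichment → JSON report — is
one command:

```bash
transgen-ewas all --seed 11 --out demo_out -v
```

(optionally `--config pipeline.yaml` to override simulation sizes,
thresholds or injected effects), with replayable per-stage subcommands
(`simulate`, `qc`, `cellcounts`, `ewas`, `replicate`, `meta`, `enrich`,
`report`).

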