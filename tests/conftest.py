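"""Shared fixtures: small seeded cohorts and pre-fitted EWAS results."""

import numpy as np
import pandas as pd
import pytest

import transewas as tw


def clean_config(**kw) -> tw.SimulationConfig:
    """A config with every exclusion pathway switched off, so the analysis
    sample equals the simulated sample (used for calibration checks)."""
    base = dict(
        exposure_missing_rate=0.0,
        maternal_smoking_given_gm=0.0,
        maternal_smoking_given_no_gm=0.0,
        own_smoking_rate=0.0,
        ethnicity_nonwhite_rate=0.0,
        ethnicity_missing_rate=0.0,
        frac_epic_samples=1.0,
        timepoints=("adolescent",),
    )
    base.update(kw)
    return tw.SimulationConfig(**base)


def fit_spec(cohort, spec, cellcounts=None):
    """Exclusions + probe filter + model fit for one analysis cell."""
    kept, _ = tw.apply_study_exclusions(cohort.samples, spec)
    pids, _ = tw.filter_probes_for_analysis(cohort.probes, spec)
    mat = cohort.betas[spec.timepoint].subset(samples=kept, probes=pids)
    model = tw.EwasModel(mat, cohort.samples, spec, cellcounts=cellcounts)
    return model, model.fit()


@pytest.fixture(scope="session")
def small_cohort():
    """120 samples x 300 probes, one injected MGM effect, all timepoints."""
    cfg = tw.SimulationConfig(
        n_samples=120, n_probes=300, seed=3,
        causal_probes=[("cg0000010", 0.05, "MGM", "all")],
    )
    return tw.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_ewas():
    """Null calibration dataset: 200 samples x 5000 probes, no injected
    effects, no exclusions; EWAS adjusted for batch and estimated cells."""
    cfg = clean_config(n_samples=200, n_probes=5000, seed=42)
    cohort = tw.simulate_cohort(cfg)
    cc = tw.estimate_cell_proportions(cohort.betas["adolescent"],
                                      cohort.reference)
    spec = tw.AnalysisSpec("MGM", "all", "adolescent", "epic_like")
    _, res = fit_spec(cohort, spec, cellcounts=cc)
    return cohort, res


def make_result(probe_ids, effects, pvalues, ses=None, n=100) -> pd.DataFrame:
    """Bare EWAS result table for replication/enrichment unit tests."""
    effects = np.asarray(effects, dtype=float)
    ses = np.abs(effects) / 2 + 0.01 if ses is None else np.asarray(ses)
    return pd.DataFrame(
        {"probe_id": list(probe_ids), "effect": effects, "se": ses,
         "tstat": effects / ses, "pvalue": np.asarray(pvalues, dtype=float),
         "n": n}
    )
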