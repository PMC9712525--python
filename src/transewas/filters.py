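"""Sample QC, study-exclusion and probe-filtering rules.

Three rule families, applied in a declared order and logged stage by stage:

* detection-p sample QC — drop samples where more than 10% of probes have
  detection p > 0.01;
* study exclusions — ethnicity (discovery array only), mothers who smoked
  in pregnancy, own smokers, missing grandmaternal-smoking status for the
  analysed line, then restriction to the sex stratum;
* probe filtering — both-sex analyses keep autosomes only; single-sex
  analyses keep autosomes + X (Y always removed).  Cross-reactive and
  SNP-flagged probes are never dropped, only carried as annotation.

All functions are pure: input tables are not mutated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

AUTOSOMES = {str(c) for c in range(1, 23)}


@dataclass(frozen=True)
class AnalysisSpec:
    """One EWAS cell of the study design: line x stratum x timepoint x array."""

    line: str  # MGM | PGM
    stratum: str  # all | F | M
    timepoint: str  # birth | child7 | adolescent
    array: str  # epic_like | k450_like

    def __post_init__(self):
        if self.line not in ("MGM", "PGM"):
            raise ValueError(f"unknown line {self.line!r}")
        if self.stratum not in ("all", "F", "M"):
            raise ValueError(f"unknown stratum {self.stratum!r}")
        if self.timepoint not in ("birth", "child7", "adolescent"):
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        if self.array not in ("epic_like", "k450_like"):
            raise ValueError(f"unknown array {self.array!r}")

    @property
    def exposure_column(self) -> str:
        return "mgm_smoked" if self.line == "MGM" else "pgm_smoked"

    @property
    def label(self) -> str:
        return f"{self.line}_{self.stratum}_{self.timepoint}_{self.array}"


def six_specs(timepoint: str, array: str) -> list[AnalysisSpec]:
    """The six (line x stratum) analyses run per dataset."""
    return [
        AnalysisSpec(line, stratum, timepoint, array)
        for line in ("MGM", "PGM")
        for stratum in ("all", "F", "M")
    ]


@dataclass
class ExclusionLog:
    """Ordered record of filtering stages (counts before/removed/after)."""

    stages: list[dict] = field(default_factory=list)

    def add(self, stage: str, n_before: int, n_after: int, reason: str) -> None:
        n_removed = n_before - n_after
        if n_after < 0 or n_removed < 0:
            raise ValueError("inconsistent exclusion counts")
        self.stages.append(
            {"stage": stage, "n_before": n_before, "n_removed": n_removed,
             "n_after": n_after, "reason": reason}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.stages,
            columns=["stage", "n_before", "n_removed", "n_after", "reason"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def qc_detection_filter(
    detection_p: pd.DataFrame,
    probe_alpha: float = 0.01,
    sample_fraction: float = 0.10,
) -> tuple[list[str], ExclusionLog]:
    """Remove samples whose fraction of undetected probes exceeds the cutoff.

    A probe is undetected when its detection p-value exceeds ``probe_alpha``;
    a sample is removed when its undetected fraction *strictly* exceeds
    ``sample_fraction`` (a sample at exactly the cutoff passes).
    """
    if detection_p.size == 0:
        raise ValueError("empty detection p-value matrix")
    vals = detection_p.to_numpy()
    if (vals < 0).any() or (vals > 1).any():
        raise ValueError("detection p-values must lie in [0, 1]")
    frac = (vals > probe_alpha).mean(axis=1)
    keep = frac <= sample_fraction
    kept = [s for s, k in zip(detection_p.index, keep) if k]
    log = ExclusionLog()
    log.add(
        "detection_qc", len(detection_p), len(kept),
        f"fraction of probes with detection p > {probe_alpha} "
        f"exceeds {sample_fraction:.0%}",
    )
    return kept, log


def apply_study_exclusions(
    samples: pd.DataFrame,
    spec: AnalysisSpec,
    ethnicity_rule: bool = True,
) -> tuple[list[str], ExclusionLog]:
    """Apply the study-exclusion chain for one analysis spec.

    Order: select the (timepoint, array) cohort; drop non-white/missing
    ethnicity (discovery array only, when the rule is on); drop children of
    mothers who smoked in pregnancy; drop own smokers; drop samples missing
    the grandmaternal-smoking status for the analysed line; restrict to the
    sex stratum.  Samples with missing maternal- or own-smoking status are
    retained (only reported smokers are excluded).
    """
    if spec.exposure_column not in samples.columns:
        raise ValueError(f"missing exposure column {spec.exposure_column}")
    log = ExclusionLog()
    df = samples[
        (samples["timepoint"] == spec.timepoint) & (samples["array"] == spec.array)
    ]
    log.add("cohort", len(samples), len(df),
            f"restrict to {spec.timepoint}/{spec.array}")

    if ethnicity_rule and spec.array == "epic_like":
        n0 = len(df)
        df = df[df["ethnicity"] == "white"]
        log.add("ethnicity", n0, len(df), "non-white or missing ethnicity")

    n0 = len(df)
    df = df[df["maternal_smoked_pregnancy"] != "yes"]
    log.add("maternal_smoking", n0, len(df), "mother reported smoking in pregnancy")

    n0 = len(df)
    df = df[df["own_smoker"] != "yes"]
    log.add("own_smoking", n0, len(df), "participant reported smoking")

    n0 = len(df)
    df = df[df[spec.exposure_column].isin(["yes", "no"])]
    log.add("missing_exposure", n0, len(df),
            f"missing {spec.line} grandmaternal smoking status")

    if spec.stratum != "all":
        n0 = len(df)
        df = df[df["sex"] == spec.stratum]
        log.add("sex_stratum", n0, len(df), f"restrict to sex = {spec.stratum}")

    kept = list(df["sample_id"])
    if not kept:
        warnings.warn(f"no samples remain after exclusions for {spec.label}")
    return kept, log


def filter_probes_for_analysis(
    probes: pd.DataFrame,
    spec: AnalysisSpec,
) -> tuple[list[str], pd.DataFrame]:
    """Probe set for one analysis, with flag annotation carried along.

    Both-sex analyses keep autosomes only; single-sex analyses keep
    autosomes plus X.  Y is always removed.  Probes flagged cross-reactive
    or SNP-affected are kept and returned as annotation, never dropped.
    """
    if "chrom" not in probes.columns:
        raise ValueError("probe table lacks a chrom column")
    array_col = "on_epic" if spec.array == "epic_like" else "on_450k"
    df = probes[probes[array_col]]
    chrom = df["chrom"].astype(str)
    if spec.stratum == "all":
        keep = chrom.isin(AUTOSOMES)
    else:
        keep = chrom.isin(AUTOSOMES | {"X"})
    kept = df[keep]
    ann_cols = ["probe_id", "chrom", "pos", "in_icr", "in_escapee",
                "flagged_cross_reactive", "flagged_snp"]
    ann = kept[[c for c in ann_cols if c in kept.columns]].reset_index(drop=True)
    return list(kept["probe_id"]), ann
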