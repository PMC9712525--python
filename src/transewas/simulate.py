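"""Seeded synthetic methylation cohorts for transgenerational EWAS.

Emulates the data structure of a two-array blood-methylation study:
an EPIC-like discovery array and a 450k-like replication array with
partially overlapping probe sets, measurements at up to three timepoints
(birth, age 7, adolescence), Dirichlet cell-composition variation,
categorical batch effects, grandmaternal-smoking exposures on the
maternal (MGM) and paternal (PGM) lines with optional sex-restricted
injected effects, correlated maternal smoking (for exclusion testing),
and a detection p-value matrix for sample QC.

The generative model for sample i at probe j is

    beta_ij = clamp01( sum_t w_it mu_tj + batch(b_i, j)
                       + s_j (age_i - mean age) + delta_j x_i m_i + eps_ij )

with cell weights w_i ~ Dirichlet(alpha), cell reference mu, per-probe
batch offsets, per-probe age slopes s_j, injected exposure effects
delta_j for exposed (x_i = 1) sex-matching (m_i = 1) individuals, and
Gaussian noise eps ~ N(0, noise_sd).  Everything is driven by a single
integer seed; identical configs and seeds give bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TIMEPOINTS = ("birth", "child7", "adolescent")
ARRAYS = ("epic_like", "k450_like")

#: mean chronological ages (years) / gestational age (weeks) used for centring
_TIMEPOINT_AGE = {"birth": 39.5, "child7": 7.5, "adolescent": 17.8}
_TIMEPOINT_AGE_SD = {"birth": 1.5, "child7": 0.3, "adolescent": 0.4}
_SAMPLE_TYPES = {
    "birth": ("blood_spot", "white_cells"),
    "child7": ("white_cells", "whole_blood"),
    "adolescent": ("peripheral_blood",),
}


class ConfigurationError(ValueError):
    """Raised when a simulation config violates its invariants."""


@dataclass(frozen=True)
class CausalProbe:
    """An injected exposure effect at one probe.

    delta is a beta-scale mean shift applied to exposed individuals on the
    given grandmaternal line; sex_restriction limits it to one sex.
    """

    probe_id: str
    delta: float
    line: str = "MGM"  # MGM | PGM
    sex_restriction: str = "all"  # all | F | M

    def __post_init__(self) -> None:
        if self.line not in ("MGM", "PGM"):
            raise ConfigurationError(f"unknown exposure line {self.line!r}")
        if self.sex_restriction not in ("all", "F", "M"):
            raise ConfigurationError(
                f"unknown sex restriction {self.sex_restriction!r}"
            )


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Defaults are desk-scale but structurally faithful: two arrays, three
    timepoints, seven blood cell types, batch effects and exposure
    prevalences in the range reported for ancestral-smoking cohorts.
    """

    n_samples: int = 400
    n_probes: int = 2000
    n_cell_types: int = 7
    dirichlet_alpha: tuple[float, ...] | None = None  # default: flat-ish
    batch_levels: int = 4
    batch_sd: float = 0.01
    noise_sd: float = 0.02
    cell_type_sd: float = 0.08
    age_slope_sd: float = 0.0005
    exposure_prevalence_mgm: float = 0.31
    exposure_prevalence_pgm: float = 0.38
    exposure_missing_rate: float = 0.2
    maternal_smoking_given_gm: float = 0.4
    maternal_smoking_given_no_gm: float = 0.15
    own_smoking_rate: float = 0.05
    ethnicity_nonwhite_rate: float = 0.10
    ethnicity_missing_rate: float = 0.04
    causal_probes: tuple[CausalProbe, ...] = ()
    frac_x_probes: float = 0.04
    frac_y_probes: float = 0.01
    frac_icr_probes: float = 0.02
    frac_escapee_probes: float = 0.05
    frac_flagged_cross_reactive: float = 0.02
    frac_flagged_snp: float = 0.02
    probe_overlap_both_arrays: float = 0.9
    frac_epic_samples: float = 0.6
    timepoints: tuple[str, ...] = TIMEPOINTS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dirichlet_alpha is None:
            self.dirichlet_alpha = tuple([2.0] * self.n_cell_types)
        self.causal_probes = tuple(
            cp if isinstance(cp, CausalProbe)
            else CausalProbe(**cp) if isinstance(cp, dict)
            else CausalProbe(*cp)
            for cp in self.causal_probes
        )
        self.validate()

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_probes < 1:
            raise ConfigurationError("n_samples and n_probes must be positive")
        if len(self.dirichlet_alpha) != self.n_cell_types:
            raise ConfigurationError(
                "dirichlet_alpha length must equal n_cell_types"
            )
        if any(a <= 0 for a in self.dirichlet_alpha):
            raise ConfigurationError("dirichlet_alpha must be strictly positive")
        for name in (
            "exposure_prevalence_mgm",
            "exposure_prevalence_pgm",
            "exposure_missing_rate",
            "maternal_smoking_given_gm",
            "maternal_smoking_given_no_gm",
            "own_smoking_rate",
            "ethnicity_nonwhite_rate",
            "ethnicity_missing_rate",
            "frac_x_probes",
            "frac_y_probes",
            "frac_icr_probes",
            "frac_escapee_probes",
            "frac_flagged_cross_reactive",
            "frac_flagged_snp",
            "probe_overlap_both_arrays",
            "frac_epic_samples",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        unknown = set(self.timepoints) - set(TIMEPOINTS)
        if unknown:
            raise ConfigurationError(f"unknown timepoints {sorted(unknown)}")
        if not self.timepoints:
            raise ConfigurationError("at least one timepoint required")
        known_ids = set(probe_ids(self.n_probes))
        for cp in self.causal_probes:
            if cp.probe_id not in known_ids:
                raise ConfigurationError(
                    f"causal probe {cp.probe_id} not among generated probes"
                )

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


def probe_ids(n_probes: int) -> list[str]:
    """Deterministic synthetic probe identifiers (array-manifest style)."""
    return [f"cg{i:07d}" for i in range(n_probes)]


@dataclass
class CellReference:
    """Mean methylation profile of each reference cell type.

    mean_beta is (cell types x probes), every entry in [0, 1].
    """

    cell_type_names: list[str]
    mean_beta: pd.DataFrame  # index: cell type, columns: probe_id

    def __post_init__(self) -> None:
        vals = self.mean_beta.to_numpy()
        if np.isnan(vals).any():
            raise ValueError("cell reference contains missing values")
        if (vals < 0).any() or (vals > 1).any():
            raise ValueError("cell reference values must lie in [0, 1]")

    def to_tsv(self, path: str | Path) -> None:
        self.mean_beta.to_csv(path, sep="\t", index_label="cell_type")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CellReference":
        df = pd.read_csv(path, sep="\t", index_col="cell_type")
        return cls(list(df.index), df)


@dataclass
class MethylationMatrix:
    """Beta values (samples x probes) with optional missingness as NaN."""

    beta: pd.DataFrame  # index: sample_id, columns: probe_id

    def __post_init__(self) -> None:
        if self.beta.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.beta.columns.has_duplicates:
            raise ValueError("duplicate probe ids")
        vals = self.beta.to_numpy()
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.beta.columns)

    def subset(self, samples=None, probes=None) -> "MethylationMatrix":
        df = self.beta
        if samples is not None:
            df = df.loc[[s for s in samples if s in df.index]]
        if probes is not None:
            probes = [p for p in probes if p in df.columns]
            df = df[probes]
        return MethylationMatrix(df)

    def to_tsv(self, path: str | Path) -> None:
        self.beta.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MethylationMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="sample_id"))


@dataclass
class SimulatedCohort:
    """Everything one simulation run produces."""

    config: SimulationConfig
    betas: dict[str, MethylationMatrix]  # keyed by timepoint
    samples: pd.DataFrame
    probes: pd.DataFrame
    reference: CellReference
    true_effects: pd.DataFrame
    cell_weights: dict[str, pd.DataFrame]  # true mixing weights per timepoint

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for tp, mat in self.betas.items():
            mat.to_tsv(outdir / f"beta_{tp}.tsv")
        self.samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
        self.probes.to_csv(outdir / "probes.tsv", sep="\t", index=False)
        self.reference.to_tsv(outdir / "cell_reference.tsv")
        self.true_effects.to_csv(outdir / "true_effects.tsv", sep="\t", index=False)


def _make_probe_table(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    ids = probe_ids(cfg.n_probes)
    n = cfg.n_probes
    n_x = int(round(cfg.frac_x_probes * n))
    n_y = int(round(cfg.frac_y_probes * n))
    chroms = np.array(
        [str(c) for c in rng.integers(1, 23, size=n)], dtype=object
    )
    sex_idx = rng.choice(n, size=n_x + n_y, replace=False)
    chroms[sex_idx[:n_x]] = "X"
    chroms[sex_idx[n_x:]] = "Y"
    # unique 1-based coordinates within each chromosome
    pos = np.zeros(n, dtype=int)
    for c in np.unique(chroms):
        m = chroms == c
        pos[m] = np.sort(
            rng.choice(np.arange(1, 50_000_000, 1000), size=m.sum(), replace=False)
        ) + rng.integers(0, 1000, size=m.sum())
    on_450k = rng.random(n) < cfg.probe_overlap_both_arrays
    if on_450k.all():
        on_450k[0] = False  # keep one designated probe EPIC-only
    frac = {
        "in_icr": cfg.frac_icr_probes,
        "in_escapee": cfg.frac_escapee_probes,
        "flagged_cross_reactive": cfg.frac_flagged_cross_reactive,
        "flagged_snp": cfg.frac_flagged_snp,
    }
    cols = {k: rng.random(n) < v for k, v in frac.items()}
    return pd.DataFrame(
        {
            "probe_id": ids,
            "chrom": chroms,
            "pos": pos,
            "on_epic": True,
            "on_450k": on_450k,
            **cols,
        }
    )


def _make_reference(cfg: SimulationConfig, probe_ids_: list[str],
                    rng: np.random.Generator) -> CellReference:
    baseline = rng.uniform(0.10, 0.90, size=cfg.n_probes)
    offsets = rng.normal(0.0, cfg.cell_type_sd, size=(cfg.n_cell_types, cfg.n_probes))
    mu = np.clip(baseline[None, :] + offsets, 0.0, 1.0)
    names = [f"cell{t}" for t in range(cfg.n_cell_types)]
    return CellReference(names, pd.DataFrame(mu, index=names, columns=probe_ids_))


def _draw_exposures(cfg: SimulationConfig, n: int, rng: np.random.Generator):
    def gm(prev):
        status = np.where(rng.random(n) < prev, "yes", "no").astype(object)
        status[rng.random(n) < cfg.exposure_missing_rate] = "missing"
        return status

    mgm = gm(cfg.exposure_prevalence_mgm)
    pgm = gm(cfg.exposure_prevalence_pgm)
    # maternal smoking correlates with MGM smoking (same maternal line)
    p_mat = np.where(
        mgm == "yes", cfg.maternal_smoking_given_gm, cfg.maternal_smoking_given_no_gm
    )
    maternal = np.where(rng.random(n) < p_mat, "yes", "no")
    return mgm, pgm, maternal


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate one full synthetic cohort.

    Returns per-timepoint beta matrices, a sample sheet (one row per
    measurement), a probe annotation table, the cell-type reference used
    for mixing, and the table of injected true effects.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    probes = _make_probe_table(cfg, rng)
    pids = list(probes["probe_id"])
    reference = _make_reference(cfg, pids, rng)
    mu = reference.mean_beta.to_numpy()  # K x P

    n = cfg.n_samples
    individual = np.array([f"S{i:05d}" for i in range(n)], dtype=object)
    sex = np.where(rng.random(n) < 0.5, "F", "M").astype(object)
    eth = np.full(n, "white", dtype=object)
    u = rng.random(n)
    eth[u < cfg.ethnicity_nonwhite_rate] = "nonwhite"
    eth[(u >= cfg.ethnicity_nonwhite_rate)
        & (u < cfg.ethnicity_nonwhite_rate + cfg.ethnicity_missing_rate)] = "missing"
    array = np.where(
        rng.random(n) < cfg.frac_epic_samples, "epic_like", "k450_like"
    ).astype(object)
    mgm, pgm, maternal = _draw_exposures(cfg, n, rng)
    own = np.where(rng.random(n) < cfg.own_smoking_rate, "yes", "no").astype(object)

    batch_off = rng.normal(0.0, cfg.batch_sd, size=(cfg.batch_levels, cfg.n_probes))
    age_slope = rng.normal(0.0, cfg.age_slope_sd, size=cfg.n_probes)

    # injected effect vector per (line, sex_restriction) combination
    delta = {}
    eff_rows = []
    for cp in cfg.causal_probes:
        j = pids.index(cp.probe_id)
        key = (cp.line, cp.sex_restriction)
        delta.setdefault(key, np.zeros(cfg.n_probes))[j] += cp.delta
        eff_rows.append(
            {"probe_id": cp.probe_id, "delta": cp.delta,
             "line": cp.line, "sex_restriction": cp.sex_restriction}
        )
    true_effects = pd.DataFrame(
        eff_rows, columns=["probe_id", "delta", "line", "sex_restriction"]
    )

    betas: dict[str, MethylationMatrix] = {}
    weights: dict[str, pd.DataFrame] = {}
    sheet_rows = []
    on_450k = probes["on_450k"].to_numpy()

    for tp in [t for t in TIMEPOINTS if t in cfg.timepoints]:
        # EPIC-like individuals are measured at adolescence only
        measured = (array == "k450_like") | (tp == "adolescent")
        idx = np.flatnonzero(measured)
        m = idx.size
        if m == 0:
            continue
        sample_id = np.array([f"{individual[i]}_{tp}" for i in idx], dtype=object)
        w = rng.dirichlet(cfg.dirichlet_alpha, size=m)
        batch = rng.integers(0, cfg.batch_levels, size=m)
        stypes = _SAMPLE_TYPES[tp]
        stype = np.array([stypes[k] for k in rng.integers(0, len(stypes), size=m)],
                         dtype=object)
        age = rng.normal(_TIMEPOINT_AGE[tp], _TIMEPOINT_AGE_SD[tp], size=m)

        signal = w @ mu + batch_off[batch]
        signal += np.outer(age - _TIMEPOINT_AGE[tp], age_slope)
        for (line, restr), dvec in delta.items():
            exposed = (mgm[idx] if line == "MGM" else pgm[idx]) == "yes"
            if restr != "all":
                exposed = exposed & (sex[idx] == restr)
            signal += np.outer(exposed.astype(float), dvec)
        if cfg.noise_sd > 0:
            signal += rng.normal(0.0, cfg.noise_sd, size=signal.shape)
        beta = np.clip(signal, 0.0, 1.0)
        # probes absent from a sample's array are missing by design
        k450_rows = array[idx] == "k450_like"
        beta[np.ix_(k450_rows, ~on_450k)] = np.nan

        betas[tp] = MethylationMatrix(
            pd.DataFrame(beta, index=sample_id, columns=pids)
        )
        weights[tp] = pd.DataFrame(
            w, index=sample_id, columns=reference.cell_type_names
        )
        for k, i in enumerate(idx):
            sheet_rows.append(
                {
                    "sample_id": sample_id[k],
                    "individual_id": individual[i],
                    "sex": sex[i],
                    "age_years": round(float(age[k]), 3) if tp != "birth" else np.nan,
                    "gestational_age_weeks": (
                        round(float(age[k]), 3) if tp == "birth" else np.nan
                    ),
                    "ethnicity": eth[i],
                    "mgm_smoked": mgm[i],
                    "pgm_smoked": pgm[i],
                    "maternal_smoked_pregnancy": maternal[i],
                    "own_smoker": own[i] if tp == "adolescent" else "no",
                    "batch_id": f"batch{batch[k]}",
                    "sample_type": stype[k],
                    "timepoint": tp,
                    "array": array[i],
                }
            )

    samples = pd.DataFrame(sheet_rows)
    return SimulatedCohort(cfg, betas, samples, probes, reference, true_effects, weights)


def simulate_detection_pvalues(
    config: SimulationConfig,
    n_failing_samples: int,
    failing_fraction: float,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Detection p-value matrix with a constructed set of failing samples.

    Exactly ``n_failing_samples`` rows have a fraction >= failing_fraction
    of probes with detection p > 0.01; every other row stays below the 10%
    QC threshold.
    """
    if failing_fraction <= 0.10:
        raise ConfigurationError(
            "failing_fraction must exceed 0.10 or the sample would pass QC"
        )
    n = config.n_samples if sample_ids is None else len(sample_ids)
    if n_failing_samples > n:
        raise ConfigurationError("n_failing_samples exceeds n_samples")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xDE7EC7]))
    p = rng.uniform(0.0, 0.009, size=(n, config.n_probes))
    # passing samples: a small (<10%) fraction of undetected probes
    n_bad_pass = int(0.02 * config.n_probes)
    n_bad_fail = int(np.ceil(failing_fraction * config.n_probes))
    failing = rng.choice(n, size=n_failing_samples, replace=False)
    for i in range(n):
        k = n_bad_fail if i in failing else n_bad_pass
        if k:
            cols = rng.choice(config.n_probes, size=k, replace=False)
            p[i, cols] = rng.uniform(0.02, 1.0, size=k)
    ids = sample_ids if sample_ids is not None else [
        f"S{i:05d}_adolescent" for i in range(n)
    ]
    return pd.DataFrame(p, index=ids, columns=probe_ids(config.n_probes))


def make_region_sets(
    probe_table: pd.DataFrame,
    n_sets: int,
    enriched_set_probes: list[str] | None = None,
    seed: int = 0,
    n_intervals: int = 50,
    interval_len: int = 500,
    window_bp: int = 100,
):
    """Random genomic interval sets over the simulated genome (BED semantics).

    If ``enriched_set_probes`` is given, the first set ("planted_set") is
    built from windows around those probes — a planted enrichment for the
    locus-overlap test.
    """
    from .enrichment import RegionSet  # local import avoids a cycle

    if probe_table.empty:
        raise ValueError("empty probe table")
    rng = np.random.default_rng(seed)
    tbl = probe_table.set_index("probe_id")
    chroms = sorted(probe_table["chrom"].unique())
    sets = []
    if enriched_set_probes is not None:
        rows = []
        for pid in enriched_set_probes:
            c, pos = tbl.at[pid, "chrom"], int(tbl.at[pid, "pos"])
            rows.append((c, max(0, pos - window_bp - 1), pos + window_bp))
        sets.append(RegionSet("planted_set",
                              pd.DataFrame(rows, columns=["chrom", "start", "end"])))
    while len(sets) < n_sets:
        rows = []
        for _ in range(n_intervals):
            c = chroms[rng.integers(0, len(chroms))]
            start = int(rng.integers(0, 50_000_000))
            rows.append((c, start, start + interval_len))
        sets.append(RegionSet(f"random_set_{len(sets)}",
                              pd.DataFrame(rows, columns=["chrom", "start", "end"])))
    return sets
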