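"""Per-CpG linear-model association engine.

The central object is :class:`EwasModel`: methylation beta values for one
analysis cell (line x stratum x timepoint x array) regressed, probe by
probe, on a binary grandmaternal-smoking exposure plus covariates.
``fit()`` returns an :class:`EwasResults` carrying per-probe effect sizes,
standard errors, t statistics, two-sided p-values (Student t on the
residual degrees of freedom) and sample counts, together with the
array-specific genome-wide significance threshold.

Covariates follow the timepoint plan: gestational age and sample type at
birth; age and sample type at age 7; age in adolescence; sex only in the
both-sex stratum; batch as fixed-effect dummies; estimated cell-type
proportions with the last (compositionally redundant) column dropped.

A residual-PCA surrogate-variable sensitivity check
(:func:`surrogate_sensitivity`) reports the concordance of effect sizes
between the known-covariate model and the surrogate-augmented model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .filters import AnalysisSpec
from .simulate import MethylationMatrix

#: genome-wide significance defaults per array flavour
GENOME_WIDE_THRESHOLDS = {"epic_like": 9e-8, "k450_like": 2.4e-7}


def round_sigfigs(x: float, sigfigs: int) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sigfigs - 1))


@dataclass(frozen=True)
class BonferroniThreshold:
    """Family-wise threshold alpha / n_tests.

    ``value`` is the full-precision threshold used in comparisons;
    ``reported`` is the value rounded to the requested significant figures,
    the form quoted in text.
    """

    alpha: float
    n_tests: int
    value: float
    reported: float

    def __float__(self) -> float:
        return self.value


def bonferroni_threshold(
    alpha: float, n_tests: int, sigfigs: int = 2
) -> BonferroniThreshold:
    """Per-test threshold for a family of ``n_tests`` tests at level alpha."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    value = alpha / n_tests
    return BonferroniThreshold(alpha, n_tests, value, round_sigfigs(value, sigfigs))


def _dummies(series: pd.Series, prefix: str) -> pd.DataFrame:
    d = pd.get_dummies(series.astype(str), prefix=prefix, drop_first=True)
    return d.astype(float)


class EwasModel:
    """Per-probe OLS of methylation on a binary exposure plus covariates.

    Parameters
    ----------
    beta
        Beta matrix restricted to the analysis samples and probes
        (NaN entries are dropped per probe).
    samples
        Sample sheet rows for the same samples (one row each), carrying
        the exposure and covariate columns.
    spec
        The analysis cell being fitted.
    cellcounts
        Estimated cell-type proportions (samples x cell types); the last
        column is dropped to break compositional collinearity.
    threshold
        Genome-wide significance cutoff; defaults to the array-specific
        constant (9e-8 EPIC-like, 2.4e-7 450k-like).
    """

    def __init__(
        self,
        beta: MethylationMatrix | pd.DataFrame,
        samples: pd.DataFrame,
        spec: AnalysisSpec,
        cellcounts: pd.DataFrame | None = None,
        threshold: float | None = None,
    ):
        df = beta.beta if isinstance(beta, MethylationMatrix) else beta
        samples = samples.set_index("sample_id") if "sample_id" in samples.columns \
            else samples
        common = [s for s in df.index if s in samples.index]
        if not common:
            raise ValueError("no overlap between beta matrix and sample sheet")
        self.beta = df.loc[common]
        self.samples = samples.loc[common]
        self.spec = spec
        self.cellcounts = None if cellcounts is None else cellcounts.loc[common]
        self.threshold = (
            GENOME_WIDE_THRESHOLDS[spec.array] if threshold is None else threshold
        )
        self.exog, self.exog_names = self._build_design()

    @classmethod
    def from_cohort(
        cls,
        cohort,
        spec: AnalysisSpec,
        cellcounts: pd.DataFrame | None = None,
        ethnicity_rule: bool = True,
        qc_keep: list[str] | None = None,
        threshold: float | None = None,
    ) -> "EwasModel":
        """Build a model from a simulated cohort, applying the standard
        exclusion and probe-filtering rules for ``spec``."""
        from .filters import apply_study_exclusions, filter_probes_for_analysis

        kept, _ = apply_study_exclusions(cohort.samples, spec, ethnicity_rule)
        if qc_keep is not None:
            qc = set(qc_keep)
            kept = [s for s in kept if s in qc]
        probes, _ = filter_probes_for_analysis(cohort.probes, spec)
        mat = cohort.betas[spec.timepoint].subset(samples=kept, probes=probes)
        cc = None if cellcounts is None else cellcounts
        return cls(mat, cohort.samples, spec, cellcounts=cc, threshold=threshold)

    # -- design ---------------------------------------------------------
    def _build_design(self) -> tuple[np.ndarray, list[str]]:
        s = self.samples
        spec = self.spec
        expo = s[spec.exposure_column].map({"yes": 1.0, "no": 0.0})
        if expo.isna().any():
            bad = s.index[expo.isna()][:3].tolist()
            raise ValueError(
                f"exposure {spec.exposure_column} not binary for samples {bad}; "
                "apply study exclusions first"
            )
        if expo.nunique() < 2:
            raise ValueError(
                f"exposure constant within stratum for {spec.label}; "
                "analysis aborted"
            )
        cols: dict[str, pd.Series | pd.DataFrame] = {}
        if spec.timepoint == "birth":
            cols["gestational_age_weeks"] = s["gestational_age_weeks"].astype(float)
            cols["sample_type"] = _dummies(s["sample_type"], "stype")
        elif spec.timepoint == "child7":
            cols["age_years"] = s["age_years"].astype(float)
            cols["sample_type"] = _dummies(s["sample_type"], "stype")
        else:
            cols["age_years"] = s["age_years"].astype(float)
        if spec.stratum == "all":
            cols["sex"] = (s["sex"] == "M").astype(float).rename("sex_M")
        cols["batch"] = _dummies(s["batch_id"], "batch")
        if self.cellcounts is not None:
            cols["cells"] = self.cellcounts.iloc[:, :-1].astype(float)

        parts = [pd.Series(1.0, index=s.index, name="intercept"),
                 expo.rename("exposure")]
        for v in cols.values():
            parts.append(v)
        X = pd.concat(parts, axis=1)
        # drop covariate columns with no variation (single batch level etc.)
        keep = ["intercept", "exposure"] + [
            c for c in X.columns[2:] if X[c].nunique() > 1
        ]
        X = X[keep]
        arr = X.to_numpy(dtype=float)
        if np.linalg.matrix_rank(arr) < arr.shape[1]:
            raise ValueError(
                f"design matrix rank-deficient for {spec.label}: "
                f"columns {list(X.columns)}"
            )
        return arr, list(X.columns)

    # -- fitting --------------------------------------------------------
    @property
    def nobs(self) -> int:
        return self.exog.shape[0]

    def fit(self, extra_exog: np.ndarray | None = None) -> "EwasResults":
        """Fit the per-probe regressions (vectorised OLS).

        extra_exog appends columns to the design (used by the surrogate
        sensitivity check).
        """
        X = self.exog
        names = list(self.exog_names)
        if extra_exog is not None:
            X = np.column_stack([X, extra_exog])
            names += [f"sv{i}" for i in range(extra_exog.shape[1])]
        n, k = X.shape
        if n <= k:
            raise ValueError("fewer observations than design columns")
        Y = self.beta.to_numpy(dtype=float)
        m = Y.shape[1]
        effect = np.full(m, np.nan)
        se = np.full(m, np.nan)
        tstat = np.full(m, np.nan)
        pval = np.full(m, np.nan)
        nper = np.full(m, 0, dtype=int)
        n_warn = 0

        XtX = X.T @ X
        XtX_inv = np.linalg.inv(XtX)
        complete = ~np.isnan(Y).any(axis=0)
        if complete.any():
            Yc = Y[:, complete]
            coef = XtX_inv @ (X.T @ Yc)
            resid = Yc - X @ coef
            dof = n - k
            sigma2 = (resid ** 2).sum(axis=0) / dof
            se_c = np.sqrt(np.maximum(sigma2, 0.0) * XtX_inv[1, 1])
            eff_c = coef[1]
            with np.errstate(divide="ignore", invalid="ignore"):
                t_c = np.where(se_c > 0, eff_c / se_c, np.nan)
            p_c = 2.0 * stats.t.sf(np.abs(t_c), dof)
            idx = np.flatnonzero(complete)
            effect[idx], se[idx], tstat[idx] = eff_c, se_c, t_c
            pval[idx] = np.clip(p_c, np.finfo(float).tiny, 1.0)
            nper[idx] = n
        for j in np.flatnonzero(~complete):
            y = Y[:, j]
            mask = np.isfinite(y)
            Xj = X[mask]
            nj = int(mask.sum())
            nper[j] = nj
            if nj <= k or np.linalg.matrix_rank(Xj) < k:
                n_warn += 1
                continue
            XtXj_inv = np.linalg.inv(Xj.T @ Xj)
            cj = XtXj_inv @ (Xj.T @ y[mask])
            rj = y[mask] - Xj @ cj
            s2 = (rj ** 2).sum() / (nj - k)
            sej = math.sqrt(max(s2, 0.0) * XtXj_inv[1, 1])
            effect[j] = cj[1]
            se[j] = sej
            if sej > 0:
                tstat[j] = cj[1] / sej
                pval[j] = max(2.0 * stats.t.sf(abs(tstat[j]), nj - k),
                              np.finfo(float).tiny)
        if n_warn:
            warnings.warn(f"{n_warn} probes dropped for rank deficiency")

        table = pd.DataFrame(
            {
                "probe_id": self.beta.columns,
                "effect": effect,
                "se": se,
                "tstat": tstat,
                "pvalue": pval,
                "n": nper,
            }
        )
        return EwasResults(self, table, names, n_rank_warnings=n_warn)


class EwasResults:
    """Results of one EWAS: per-probe estimates and significance summary."""

    def __init__(self, model: EwasModel | None, table: pd.DataFrame,
                 exog_names: list[str] | None = None, n_rank_warnings: int = 0):
        self.model = model
        self.table = table.reset_index(drop=True)
        self.exog_names = exog_names or []
        self.n_rank_warnings = n_rank_warnings

    @property
    def spec(self) -> AnalysisSpec | None:
        return self.model.spec if self.model is not None else self._spec

    @property
    def threshold(self) -> float:
        return self.model.threshold if self.model is not None else self._threshold

    def ranked(self) -> pd.DataFrame:
        """Rows sorted by ascending p; ties by larger |effect|, then probe id."""
        t = self.table.copy()
        t["_abs"] = -t["effect"].abs()
        t = t.sort_values(["pvalue", "_abs", "probe_id"], kind="mergesort")
        return t.drop(columns="_abs").reset_index(drop=True)

    def significant(self, threshold: float | None = None) -> pd.DataFrame:
        thr = self.threshold if threshold is None else threshold
        return self.ranked().query("pvalue < @thr")

    def summary(self, top: int = 10) -> str:
        spec = self.spec
        lines = [
            "EWAS Results",
            "=" * 60,
            f"Exposure line:      {spec.line} grandmaternal smoking",
            f"Stratum:            {spec.stratum}",
            f"Timepoint / array:  {spec.timepoint} / {spec.array}",
            f"Samples:            {int(self.table['n'].max()) if len(self.table) else 0}",
            f"Probes tested:      {len(self.table)}",
            f"Covariates:         {', '.join(self.exog_names[2:]) or 'none'}",
            f"GW threshold:       {self.threshold:g}",
            f"Probes below GW:    {int((self.table['pvalue'] < self.threshold).sum())}",
            "-" * 60,
            f"Top {top} associations:",
            self.ranked().head(top).to_string(
                index=False, float_format=lambda v: f"{v:.4g}"
            ),
        ]
        return "\n".join(lines)

    def qq_data(self) -> pd.DataFrame:
        p = np.sort(self.table["pvalue"].dropna().to_numpy())
        n = p.size
        exp = -np.log10((np.arange(1, n + 1) - 0.5) / n)
        return pd.DataFrame({"expected": exp, "observed": -np.log10(p)})

    def plot_qq(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d = self.qq_data()
        ax.plot(d["expected"], d["observed"], ".", ms=3)
        lim = max(d["expected"].max(), d["observed"].max())
        ax.plot([0, lim], [0, lim], "k--", lw=1)
        ax.set_xlabel("expected -log10 p")
        ax.set_ylabel("observed -log10 p")
        return ax

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, spec: AnalysisSpec | None = None,
                 threshold: float = 0.05) -> "EwasResults":
        res = cls(None, pd.read_csv(path, sep="\t"))
        res._spec = spec
        res._threshold = threshold
        return res


@dataclass(frozen=True)
class SurrogateCheck:
    """Concordance between known-covariate and surrogate-augmented fits."""

    n_surrogates: int
    effect_correlation: float


def surrogate_variables(model: EwasModel, k_sv: int) -> np.ndarray:
    """Top-k principal components of the covariate-adjusted residuals.

    A light surrogate-variable construction: regress every probe on the
    known covariates *excluding the exposure* (so unmodelled structure that
    co-varies with the exposure remains visible), centre the residual
    matrix, and take the leading left singular vectors as per-sample
    surrogate scores.
    """
    X = model.exog
    n, k = X.shape
    if not 1 <= k_sv < n - k:
        raise ValueError("k_sv must be >= 1 and below residual degrees of freedom")
    X0 = np.delete(X, 1, axis=1)  # drop the exposure column
    Y = model.beta.to_numpy(dtype=float)
    Y = np.where(np.isfinite(Y), Y, np.nanmean(Y, axis=0, keepdims=True))
    coef = np.linalg.lstsq(X0, Y, rcond=None)[0]
    R = Y - X0 @ coef
    R = R - R.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(R, full_matrices=False)
    return U[:, :k_sv] * S[:k_sv]


def surrogate_sensitivity(model: EwasModel, k_sv: int = 5) -> SurrogateCheck:
    """Pearson correlation of effect sizes with vs without surrogates."""
    base = model.fit()
    sv = surrogate_variables(model, k_sv)
    if np.allclose(sv, 0.0):
        return SurrogateCheck(k_sv, 1.0)
    aug = model.fit(extra_exog=sv)
    a = base.table["effect"].to_numpy()
    b = aug.table["effect"].to_numpy()
    ok = np.isfinite(a) & np.isfinite(b)
    r = float(stats.pearsonr(a[ok], b[ok]).statistic)
    return SurrogateCheck(k_sv, r)
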