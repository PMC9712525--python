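"""Candidate-set and region-based enrichment statistics.

* a-priori region lookups (X chromosome per sex, germline-demethylation
  escapee regions, imprinting control regions) at the Bonferroni threshold
  of the looked-up set;
* locus-overlap (LOLA-style) enrichment of the top EWAS sites against
  named genomic interval sets, using 100 bp windows on either side of each
  CpG, overlap-deduplication of the top windows, and a one-sided Fisher
  exact test;
* genomic inflation (lambda with bootstrap SE and QQ coordinates) of a
  candidate CpG set, and a one-sided Wilcoxon rank-sum test of whether
  candidate sites have systematically smaller p-values than the rest of
  the tested probes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .ewas import bonferroni_threshold
from .replication import _table

#: median of the chi-square(1) distribution
CHI2_NULL_MEDIAN = 0.4549364231195724


@dataclass
class RegionSet:
    """Named genomic intervals with BED semantics (0-based, half-open)."""

    name: str
    intervals: pd.DataFrame  # columns chrom, start, end
    source_tissue: str | None = None

    def __post_init__(self) -> None:
        iv = self.intervals
        if not {"chrom", "start", "end"}.issubset(iv.columns):
            raise ValueError("intervals need chrom/start/end columns")
        if (iv["start"] >= iv["end"]).any():
            raise ValueError("intervals must satisfy start < end")

    def merged(self) -> dict[str, np.ndarray]:
        """Per-chromosome merged intervals as (n, 2) arrays."""
        out: dict[str, np.ndarray] = {}
        for chrom, grp in self.intervals.groupby("chrom"):
            iv = grp[["start", "end"]].sort_values("start").to_numpy()
            merged = [list(iv[0])]
            for s, e in iv[1:]:
                if s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            out[str(chrom)] = np.asarray(merged)
        return out

    def to_bed(self, path: str | Path) -> None:
        iv = self.intervals.copy()
        iv["name"] = self.name
        iv.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path: str | Path, name: str | None = None) -> "RegionSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3]
        df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
        set_name = name or (str(df["name"].iloc[0]) if "name" in df else Path(path).stem)
        return cls(set_name, df[["chrom", "start", "end"]].astype(
            {"start": int, "end": int}))


def candidate_region_lookup(
    result, probe_mask, alpha: float = 0.05
) -> tuple[pd.DataFrame, "object"]:
    """Flag probes in an a-priori region set at its own Bonferroni threshold.

    The threshold is alpha divided by the number of *tested* probes in the
    mask, so it adapts to the analysis rather than being hard-coded.
    """
    t = _table(result)
    mask = set(probe_mask)
    tested = t[t["probe_id"].isin(mask) & t["pvalue"].notna()]
    if tested.empty:
        raise ValueError("probe mask does not intersect tested probes")
    thr = bonferroni_threshold(alpha, len(tested))
    flags = tested[["probe_id", "effect", "pvalue"]].copy()
    flags["significant"] = flags["pvalue"] < thr.value
    return flags.reset_index(drop=True), thr


def _probe_windows(
    probe_ids: list[str], probes: pd.DataFrame, window_bp: int
) -> pd.DataFrame:
    """100 bp-style windows: 1-based CpG position pos becomes the 0-based
    half-open interval [pos - window - 1, pos + window), a (2w+1) bp span."""
    tbl = probes.set_index("probe_id")
    rows = []
    for pid in probe_ids:
        pos = int(tbl.at[pid, "pos"])
        rows.append((pid, str(tbl.at[pid, "chrom"]),
                     max(0, pos - window_bp - 1), pos + window_bp))
    return pd.DataFrame(rows, columns=["probe_id", "chrom", "start", "end"])


def _dedup_windows(win: pd.DataFrame) -> pd.DataFrame:
    """Remove later-ranked windows overlapping an earlier kept window."""
    kept: list[int] = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for i, row in win.iterrows():
        ivs = by_chrom.setdefault(row["chrom"], [])
        if any(row["start"] < e and s < row["end"] for s, e in ivs):
            continue
        ivs.append((row["start"], row["end"]))
        kept.append(i)
    return win.loc[kept]


def _overlaps_any(win: pd.DataFrame, merged: dict[str, np.ndarray]) -> np.ndarray:
    # merged intervals are disjoint and sorted, so the last interval
    # starting before the window's end is the only overlap candidate
    out = np.zeros(len(win), dtype=bool)
    for k, (_, row) in enumerate(win.iterrows()):
        iv = merged.get(row["chrom"])
        if iv is None:
            continue
        j = int(np.searchsorted(iv[:, 0], row["end"]))
        out[k] = j > 0 and iv[j - 1, 1] > row["start"]
    return out


def fisher_enrichment(
    a: int, b: int, c: int, d: int, two_sided: bool = False
) -> tuple[float, float]:
    """Odds-ratio summary of one 2x2 overlap table.

    Returns (natural-log odds ratio, Fisher exact p).  The p-value is
    one-sided for over-representation by default; log OR uses the
    Haldane-Anscombe 0.5 correction when any cell is zero.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("contingency counts must be non-negative")
    alt = "two-sided" if two_sided else "greater"
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative=alt).pvalue)
    if min(a, b, c, d) == 0:
        log_or = float(np.log(((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))))
    else:
        log_or = float(np.log((a * d) / (b * c)))
    return log_or, p


def locus_overlap_enrichment(
    top_sites: list[str],
    universe: list[str],
    probes: pd.DataFrame,
    region_sets: list[RegionSet],
    window_bp: int = 100,
    two_sided: bool = False,
) -> pd.DataFrame:
    """LOLA-style Fisher enrichment of top-site windows in region sets.

    Each probe contributes a (2*window_bp + 1) bp window around its CpG.
    Within the ranked top set, later windows overlapping an earlier one are
    removed (the better-ranked site is kept) to prevent inflation; removed
    top sites are excluded from both margins.  For every region set a 2x2
    table (a = top windows overlapping, b = top windows not overlapping,
    c/d likewise over universe-minus-top) feeds a one-sided Fisher exact
    test for over-representation; log_or is the natural-log odds ratio with
    a Haldane-Anscombe 0.5 correction when any cell is zero.
    """
    top_set = set(top_sites)
    if not top_set.issubset(set(universe)):
        raise ValueError("top_sites must be a subset of the universe")
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    known_chroms = set(probes["chrom"].astype(str))
    top_win = _dedup_windows(_probe_windows(list(top_sites), probes, window_bp))
    rest = [p for p in universe if p not in top_set]
    rest_win = _probe_windows(rest, probes, window_bp)
    rows = []
    for rs in region_sets:
        merged = rs.merged()
        stray = set(merged) - known_chroms
        if stray:
            warnings.warn(
                f"region set {rs.name}: chromosomes {sorted(stray)} absent "
                "from the probe annotation; counted as non-overlap"
            )
        a = int(_overlaps_any(top_win, merged).sum())
        b = len(top_win) - a
        c = int(_overlaps_any(rest_win, merged).sum())
        d = len(rest_win) - c
        log_or, p = fisher_enrichment(a, b, c, d, two_sided=two_sided)
        rows.append({"set_name": rs.name, "a": a, "b": b, "c": c, "d": d,
                     "log_or": log_or, "pvalue": p})
    return pd.DataFrame(rows)


@dataclass
class InflationResult:
    """Genomic inflation of a candidate CpG set within an EWAS."""

    lambda_: float
    lambda_se: float
    qq_points: pd.DataFrame  # expected / observed -log10 p quantiles
    n_sites: int

    def plot_qq(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.qq_points["expected"], self.qq_points["observed"], ".", ms=3)
        lim = float(self.qq_points.max().max())
        ax.plot([0, lim], [0, lim], "k--", lw=1)
        ax.set_xlabel("expected -log10 p")
        ax.set_ylabel("observed -log10 p")
        ax.set_title(f"lambda = {self.lambda_:.2f} ± {self.lambda_se:.2f}")
        return ax


def candidate_set_inflation(
    result, candidate_ids, n_boot: int = 1000, seed: int | None = None
) -> InflationResult:
    """Lambda (median chi-square ratio) of a candidate set, with bootstrap SE.

    p-values are converted to 1-df chi-square quantiles; lambda is their
    median over the chi-square(1) null median 0.4549.  The SE is the
    standard deviation of lambda over seeded bootstrap resamples of the
    candidate sites.
    """
    t = _table(result).set_index("probe_id")
    ids = [c for c in candidate_ids if c in t.index]
    p = t.loc[ids, "pvalue"].to_numpy(dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 10:
        raise ValueError("need >= 10 candidate sites with finite p-values")
    chi2 = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi2) / CHI2_NULL_MEDIAN)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = np.median(rng.choice(chi2, size=chi2.size, replace=True))
    boots /= CHI2_NULL_MEDIAN
    se = float(boots.std(ddof=1))
    if np.ptp(p) == 0:
        warnings.warn("all candidate p-values identical; lambda SE is 0")
        se = 0.0
    ps = np.sort(p)
    exp = -np.log10((np.arange(1, ps.size + 1) - 0.5) / ps.size)
    qq = pd.DataFrame({"expected": exp, "observed": -np.log10(ps)})
    return InflationResult(lam, se, qq, int(p.size))


def wilcoxon_enrichment(result, candidate_ids) -> tuple[float, float]:
    """One-sided Wilcoxon rank-sum: are candidate p-values smaller than the
    rest of the tested probes'?

    Exact enumeration when both groups have <= 10 members (and no ties);
    otherwise the normal approximation with tie correction.
    Returns (rank-sum statistic, one-sided p).
    """
    t = _table(result)
    t = t[t["pvalue"].notna()]
    cand_mask = t["probe_id"].isin(set(candidate_ids))
    cand = t.loc[cand_mask, "pvalue"].to_numpy(dtype=float)
    other = t.loc[~cand_mask, "pvalue"].to_numpy(dtype=float)
    if cand.size == 0:
        raise ValueError("no candidate probes among tested probes")
    if other.size == 0:
        raise ValueError("candidate set equals the tested universe")
    exact = (cand.size <= 10 and other.size <= 10
             and np.unique(np.concatenate([cand, other])).size
             == cand.size + other.size)
    res = stats.mannwhitneyu(
        cand, other, alternative="less",
        method="exact" if exact else "asymptotic",
    )
    return float(res.statistic), float(res.pvalue)
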