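"""Replication battery and fixed-effects meta-analysis for EWAS summary stats.

Three complementary replication checks of the top discovery hits, run on
the probes present on both arrays:

1. lookup — the top-K discovery sites tested in the replication dataset at
   p < alpha/K, with a stricter family-adjusted flag at
   p < alpha/(n_families * K);
2. effect-size correlation — Pearson r between discovery and replication
   effects over the top 10/25/50/100/200 sites;
3. sign binomial — an exact one-sided binomial test of how many top sites
   replicate at p < alpha with the same direction of effect, against a
   null success probability p0 (default 0.025 = joint chance of p < 0.05
   and a coin-flip sign agreement).

The same machinery serves cross-sex and cross-timepoint agreement
analyses (where lookups use the alpha/3 convention for three timepoints),
and a METAL-style inverse-variance fixed-effects meta-analysis pools
effect sizes across datasets.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_KS = (10, 25, 50, 100, 200)


def _table(result) -> pd.DataFrame:
    """Accept an EwasResults or a bare result table."""
    return result.table if hasattr(result, "table") else result


def _ranked(result) -> pd.DataFrame:
    if hasattr(result, "ranked"):
        return result.ranked()
    t = _table(result).copy()
    t["_abs"] = -t["effect"].abs()
    t = t.sort_values(["pvalue", "_abs", "probe_id"], kind="mergesort")
    return t.drop(columns="_abs").reset_index(drop=True)


def top_k_select(result, k: int, restrict_to=None) -> list[str]:
    """Top-k probes by ascending p (ties: larger |effect|, then probe id).

    ``restrict_to`` filters the ranking before truncation (e.g. to probes
    present on the replication array).  If fewer than k remain, all are
    returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    t = _ranked(result)
    t = t[t["pvalue"].notna()]
    if restrict_to is not None:
        allowed = set(restrict_to)
        t = t[t["probe_id"].isin(allowed)]
    ids = list(t["probe_id"].head(k))
    if len(ids) < k:
        warnings.warn(f"only {len(ids)} probes available for top-{k} selection")
    return ids


def lookup_replication(
    discovery,
    replication,
    k: int = 25,
    alpha: float = 0.05,
    n_ewas_families: int = 6,
    lookup_alpha: float | None = None,
) -> pd.DataFrame:
    """Test the top-k discovery sites in the replication dataset.

    replicated  <=> replication p < lookup threshold (default alpha/k)
    survives_family <=> replication p < alpha/(n_ewas_families * k)
    """
    rep = _table(replication).set_index("probe_id")
    shared = set(_table(discovery)["probe_id"]) & set(rep.index)
    if not shared:
        raise ValueError("discovery and replication share no probes")
    top = top_k_select(discovery, k, restrict_to=shared)
    thr = (alpha / k) if lookup_alpha is None else lookup_alpha
    thr_family = alpha / (n_ewas_families * k)
    disc = _ranked(discovery).set_index("probe_id")
    rows = []
    for rank, pid in enumerate(top, start=1):
        p_rep = float(rep.at[pid, "pvalue"])
        rows.append(
            {
                "probe_id": pid,
                "discovery_rank": rank,
                "discovery_p": float(disc.at[pid, "pvalue"]),
                "replication_p": p_rep,
                "replicated": bool(p_rep < thr),
                "survives_family": bool(p_rep < thr_family),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["threshold"] = thr
    out.attrs["family_threshold"] = thr_family
    return out


def effectsize_correlation(
    discovery, replication, ks=DEFAULT_KS
) -> pd.DataFrame:
    """Pearson correlation of paired effect sizes over the top-K sites."""
    rep = _table(replication).set_index("probe_id")
    shared = set(_table(discovery)["probe_id"]) & set(rep.index)
    rows = []
    for k in ks:
        top = top_k_select(discovery, k, restrict_to=shared)
        disc = _ranked(discovery).set_index("probe_id")
        a = disc.loc[top, "effect"].to_numpy(dtype=float)
        b = rep.loc[top, "effect"].to_numpy(dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        a, b = a[ok], b[ok]
        if a.size < 3:
            rows.append({"k": k, "pearson_r": np.nan, "pearson_p": np.nan,
                         "n_used": int(a.size)})
            continue
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            warnings.warn(f"constant effect vector at k={k}; r undefined")
            rows.append({"k": k, "pearson_r": np.nan, "pearson_p": np.nan,
                         "n_used": int(a.size)})
            continue
        r = stats.pearsonr(a, b)
        rows.append({"k": k, "pearson_r": float(r.statistic),
                     "pearson_p": float(r.pvalue), "n_used": int(a.size)})
    return pd.DataFrame(rows)


def sign_binomial_test(
    discovery,
    replication,
    ks=DEFAULT_KS,
    alpha: float = 0.05,
    p0: float = 0.025,
) -> pd.DataFrame:
    """Exact one-sided binomial test of directional replication of top sites.

    A site is a success when its replication p < alpha and the replication
    effect has the same sign as the discovery effect.  ``p0`` is the null
    success probability; 0.025 treats the sign as a coin flip given
    p < 0.05, while 0.05 ignores direction (one-sided convention) —
    selectable by argument.
    """
    rep = _table(replication).set_index("probe_id")
    shared = set(_table(discovery)["probe_id"]) & set(rep.index)
    disc = _ranked(discovery).set_index("probe_id")
    rows = []
    for k in ks:
        top = top_k_select(discovery, k, restrict_to=shared)
        succ = trials = 0
        for pid in top:
            e_d = float(disc.at[pid, "effect"])
            if e_d == 0 or not np.isfinite(e_d):
                warnings.warn(f"zero discovery effect at {pid}; excluded")
                continue
            e_r = float(rep.at[pid, "effect"])
            p_r = float(rep.at[pid, "pvalue"])
            trials += 1
            if p_r < alpha and np.sign(e_r) == np.sign(e_d):
                succ += 1
        p = stats.binomtest(succ, trials, p0, alternative="greater").pvalue \
            if trials else np.nan
        rows.append({"k": k, "n_success": succ, "n_trials": trials,
                     "binomial_p": float(p)})
    return pd.DataFrame(rows)


@dataclass
class ReplicationReport:
    """The three replication sections for one (discovery, replication) pair."""

    discovery_label: str
    replication_label: str
    lookup: pd.DataFrame
    correlations: pd.DataFrame
    sign_tests: pd.DataFrame
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "discovery": self.discovery_label,
            "replication": self.replication_label,
            "params": self.params,
            "lookup": self.lookup.to_dict(orient="records"),
            "correlations": self.correlations.to_dict(orient="records"),
            "sign_tests": self.sign_tests.to_dict(orient="records"),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def n_replicated(self) -> int:
        return int(self.lookup["replicated"].sum())


def replication_report(
    discovery,
    replication,
    ks=DEFAULT_KS,
    k_lookup: int = 25,
    alpha: float = 0.05,
    n_ewas_families: int = 6,
    lookup_alpha: float | None = None,
    p0: float = 0.025,
    discovery_label: str = "discovery",
    replication_label: str = "replication",
) -> ReplicationReport:
    """Run all three replication approaches for one result pair."""
    return ReplicationReport(
        discovery_label,
        replication_label,
        lookup=lookup_replication(
            discovery, replication, k=k_lookup, alpha=alpha,
            n_ewas_families=n_ewas_families, lookup_alpha=lookup_alpha,
        ),
        correlations=effectsize_correlation(discovery, replication, ks),
        sign_tests=sign_binomial_test(discovery, replication, ks,
                                      alpha=alpha, p0=p0),
        params={"ks": list(ks), "k_lookup": k_lookup, "alpha": alpha,
                "n_ewas_families": n_ewas_families, "p0": p0,
                "lookup_alpha": lookup_alpha},
    )


def cross_group_agreement(
    result_a,
    result_b,
    ks=DEFAULT_KS,
    timepoint_lookup: bool = False,
    alpha: float = 0.05,
    timepoint_divisor: int = 3,
    label_a: str = "a",
    label_b: str = "b",
) -> ReplicationReport:
    """Agreement between two arbitrary analyses (e.g. male vs female strata,
    or adolescent vs earlier-life timepoints).

    With ``timepoint_lookup`` the lookup threshold is alpha/timepoint_divisor
    (the three-timepoint convention) instead of alpha/K.
    """
    lookup_alpha = alpha / timepoint_divisor if timepoint_lookup else None
    return replication_report(
        result_a, result_b, ks=ks, alpha=alpha, lookup_alpha=lookup_alpha,
        discovery_label=label_a, replication_label=label_b,
    )


def fixed_effects_meta(results: list, common_only: bool = False) -> pd.DataFrame:
    """Inverse-variance-weighted fixed-effects meta-analysis.

    Per probe: weights w_s = 1/se_s^2, pooled effect = sum(w e)/sum(w),
    pooled SE = (sum w)^{-1/2}, z = effect/SE, two-sided normal p.
    Probes contributing fewer than all studies are flagged via
    ``n_studies`` (and dropped when ``common_only``).
    """
    if len(results) < 2:
        raise ValueError("meta-analysis needs >= 2 result sets")
    tabs = []
    for i, r in enumerate(results):
        t = _table(r)[["probe_id", "effect", "se"]].copy()
        t = t[np.isfinite(t["effect"]) & (t["se"] > 0)]
        t["study"] = i
        tabs.append(t)
    longf = pd.concat(tabs, ignore_index=True)
    w = 1.0 / longf["se"] ** 2
    longf["w"] = w
    longf["we"] = w * longf["effect"]
    g = longf.groupby("probe_id", sort=True).agg(
        sw=("w", "sum"), swe=("we", "sum"), n_studies=("study", "size")
    )
    effect = g["swe"] / g["sw"]
    se = 1.0 / np.sqrt(g["sw"])
    z = effect / se
    out = pd.DataFrame(
        {
            "probe_id": g.index,
            "effect_meta": effect.to_numpy(),
            "se_meta": se.to_numpy(),
            "z": z.to_numpy(),
            "pvalue": np.clip(2.0 * stats.norm.sf(np.abs(z.to_numpy())),
                              np.finfo(float).tiny, 1.0),
            "n_studies": g["n_studies"].to_numpy(),
        }
    ).reset_index(drop=True)
    if common_only:
        out = out[out["n_studies"] == len(results)].reset_index(drop=True)
    return out
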