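"""Config-driven orchestration of the full study design.

simulate -> detection-p QC -> study exclusions -> cell-count deconvolution
-> six EWAS per timepoint/array -> replication battery -> meta-analysis ->
a-priori region lookups and enrichment statistics -> JSON report.

Every stage reads its inputs from, and writes its outputs to, a single
workspace directory, so the stages can be run individually (they compose
to the same outputs as a single end-to-end run) and any stage can be
replayed.  One global seed is fanned out to per-stage child seeds by a
fixed derivation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cellcomp, enrichment, replication
from .ewas import EwasModel, EwasResults, GENOME_WIDE_THRESHOLDS, \
    bonferroni_threshold, surrogate_sensitivity
from .filters import AnalysisSpec, apply_study_exclusions, \
    filter_probes_for_analysis, qc_detection_filter, six_specs
from .simulate import CellReference, MethylationMatrix, SimulationConfig, \
    make_region_sets, simulate_cohort, simulate_detection_pvalues

log = logging.getLogger("transewas")

_STAGE_IDS = {"simulate": 1, "qc": 2, "cellcounts": 3, "ewas": 4,
              "replicate": 5, "meta": 6, "enrich": 7, "report": 8}
_FLOAT_FMT = "%.6g"


@dataclass
class Thresholds:
    epic_gw: float = GENOME_WIDE_THRESHOLDS["epic_like"]
    k450_gw: float = GENOME_WIDE_THRESHOLDS["k450_like"]
    alpha: float = 0.05
    replication_k: int = 25
    family_count: int = 6
    timepoint_divisor: int = 3


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    output_dir: str = "transewas_out"
    seed: int = 0
    n_failing_qc: int = 2
    failing_fraction: float = 0.2
    n_region_sets: int = 5
    ks: tuple[int, ...] = replication.DEFAULT_KS
    datasets: tuple[tuple[str, str], ...] = (
        ("adolescent", "epic_like"),
        ("adolescent", "k450_like"),
        ("birth", "k450_like"),
        ("child7", "k450_like"),
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        thr = Thresholds(**raw.pop("thresholds", {}))
        if "causal_probes" in raw:
            raise ValueError("causal_probes belongs under simulation:")
        cfg = cls(simulation=sim, thresholds=thr, **raw)
        return cfg

    def to_yaml(self) -> str:
        d = json.loads(json.dumps(asdict(self)))  # tuples -> lists
        return yaml.safe_dump(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence([int(self.seed), _STAGE_IDS[stage]])
        return int(ss.generate_state(1)[0] % (2 ** 31))

    def analysis_specs(self) -> list[AnalysisSpec]:
        out = []
        for tp, array in self.datasets:
            out.extend(six_specs(tp, array))
        return out

    def gw_threshold(self, array: str) -> float:
        return self.thresholds.epic_gw if array == "epic_like" \
            else self.thresholds.k450_gw


def _outdir(cfg: PipelineConfig) -> Path:
    p = Path(cfg.output_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, **kw)


# ---------------------------------------------------------------- stages

def stage_simulate(cfg: PipelineConfig) -> dict:
    out = _outdir(cfg)
    sim = cfg.simulation.replace(seed=cfg.stage_seed("simulate"))
    cohort = simulate_cohort(sim)
    cohort.write(out)
    dp = simulate_detection_pvalues(
        sim, cfg.n_failing_qc, cfg.failing_fraction,
        sample_ids=list(cohort.samples["sample_id"]),
    )
    dp.to_csv(out / "detection_p.tsv", sep="\t", index_label="sample_id",
              float_format=_FLOAT_FMT)
    planted = list(cohort.true_effects["probe_id"].unique())
    sets = make_region_sets(
        cohort.probes, cfg.n_region_sets,
        enriched_set_probes=planted or None, seed=cfg.stage_seed("simulate"),
    )
    (out / "region_sets").mkdir(exist_ok=True)
    for rs in sets:
        rs.to_bed(out / "region_sets" / f"{rs.name}.bed")
    # candidate lists: a random draw and the injected probes padded randomly
    rng = np.random.default_rng(cfg.stage_seed("simulate") + 1)
    pids = list(cohort.probes["probe_id"])
    random_list = sorted(rng.choice(pids, size=min(500, max(10, len(pids) // 5)),
                                    replace=False))
    causal_list = sorted(set(planted) | set(
        rng.choice(pids, size=min(100, max(10, len(pids) // 8)),
                   replace=False)))
    (out / "candidates").mkdir(exist_ok=True)
    Path(out / "candidates" / "random_sites.txt").write_text(
        "\n".join(map(str, random_list)) + "\n")
    Path(out / "candidates" / "planted_sites.txt").write_text(
        "\n".join(map(str, causal_list)) + "\n")
    info = {
        "n_samples": int(cfg.simulation.n_samples),
        "n_measurements": int(len(cohort.samples)),
        "n_probes": int(cfg.simulation.n_probes),
        "n_causal": int(len(cohort.true_effects)),
        "timepoints": sorted(cohort.betas.keys()),
    }
    log.info("simulate: %s", info)
    return info


def stage_qc(cfg: PipelineConfig) -> dict:
    out = _outdir(cfg)
    dp = pd.read_csv(out / "detection_p.tsv", sep="\t", index_col="sample_id")
    kept, xlog = qc_detection_filter(dp)
    Path(out / "qc_kept_samples.txt").write_text("\n".join(kept) + "\n")
    xlog.to_tsv(out / "qc_exclusion_log.tsv")
    info = {"n_before": int(len(dp)), "n_kept": len(kept)}
    log.info("qc: %s", info)
    return info


def stage_cellcounts(cfg: PipelineConfig) -> dict:
    out = _outdir(cfg)
    ref = CellReference.from_tsv(out / "cell_reference.tsv")
    info = {}
    for beta_path in sorted(out.glob("beta_*.tsv")):
        tp = beta_path.stem.replace("beta_", "")
        mat = MethylationMatrix.from_tsv(beta_path)
        cc = cellcomp.estimate_cell_proportions(mat, ref)
        cc.to_csv(out / f"cellcounts_{tp}.tsv", sep="\t",
                  index_label="sample_id", float_format=_FLOAT_FMT)
        info[tp] = int(len(cc))
    log.info("cellcounts: %s", info)
    return info


def _load_inputs(out: Path):
    samples = pd.read_csv(out / "samples.tsv", sep="\t")
    probes = pd.read_csv(out / "probes.tsv", sep="\t")
    qc_keep = Path(out / "qc_kept_samples.txt").read_text().split()
    return samples, probes, qc_keep


def stage_ewas(cfg: PipelineConfig) -> dict:
    out = _outdir(cfg)
    samples, probes, qc_keep = _load_inputs(out)
    qc = set(qc_keep)
    info: dict = {"specs": {}}
    mats: dict[str, MethylationMatrix] = {}
    ccs: dict[str, pd.DataFrame] = {}
    for spec in cfg.analysis_specs():
        tp = spec.timepoint
        if tp not in mats:
            mats[tp] = MethylationMatrix.from_tsv(out / f"beta_{tp}.tsv")
            ccs[tp] = pd.read_csv(out / f"cellcounts_{tp}.tsv", sep="\t",
                                  index_col="sample_id")
        kept, xlog = apply_study_exclusions(samples, spec)
        kept = [s for s in kept if s in qc]
        pids, _ = filter_probes_for_analysis(probes, spec)
        mat = mats[tp].subset(samples=kept, probes=pids)
        model = EwasModel(mat, samples, spec, cellcounts=ccs[tp],
                          threshold=cfg.gw_threshold(spec.array))
        res = model.fit()
        res.to_tsv(out / f"{spec.label}.ewas.tsv")
        xlog.to_tsv(out / f"{spec.label}.exclusions.tsv")
        entry = {
            "n_samples": int(model.nobs),
            "n_probes": int(len(res.table)),
            "min_p": float(res.table["pvalue"].min()),
            "n_genomewide": int((res.table["pvalue"] < model.threshold).sum()),
        }
        if spec.array == "epic_like" and spec.stratum == "all" \
                and spec.timepoint == "adolescent":
            chk = surrogate_sensitivity(model, k_sv=5)
            entry["sv_effect_correlation"] = round(chk.effect_correlation, 6)
        info["specs"][spec.label] = entry
        log.info("ewas %s: %s", spec.label, entry)
    return info


def _load_result(out: Path, spec: AnalysisSpec, cfg: PipelineConfig) -> EwasResults:
    return EwasResults.from_tsv(out / f"{spec.label}.ewas.tsv", spec=spec,
                                threshold=cfg.gw_threshold(spec.array))


def stage_replicate(cfg: PipelineConfig) -> dict:
    out = _outdir(cfg)
    thr = cfg.thresholds
    info: dict = {"discovery_vs_450k": {}, "cross_sex": {}, "timepoints": {}}
    (out / "replication").mkdir(exist_ok=True)
    for line in ("MGM", "PGM"):
        for stratum in ("all", "F", "M"):
            disc = _load_result(out, AnalysisSpec(line, stratum, "adolescent",
                                                  "epic_like"), cfg)
            rep = _load_result(out, AnalysisSpec(line, stratum, "adolescent",
                                                 "k450_like"), cfg)
            report = replication.replication_report(
                disc, rep, ks=cfg.ks, k_lookup=thr.replication_k,
                alpha=thr.alpha, n_ewas_families=thr.family_count,
                discovery_label=disc.spec.label, replication_label=rep.spec.label,
            )
            report.to_json(out / "replication" / f"{line}_{stratum}.json")
            info["discovery_vs_450k"][f"{line}_{stratum}"] = {
                "n_replicated": report.n_replicated(),
                "n_survive_family": int(report.lookup["survives_family"].sum()),
            }
        # cross-sex agreement within the discovery dataset
        f = _load_result(out, AnalysisSpec(line, "F", "adolescent", "epic_like"), cfg)
        m = _load_result(out, AnalysisSpec(line, "M", "adolescent", "epic_like"), cfg)
        rep_fm = replication.cross_group_agreement(
            f, m, ks=cfg.ks, label_a=f.spec.label, label_b=m.spec.label)
        rep_fm.to_json(out / "replication" / f"{line}_cross_sex.json")
        info["cross_sex"][line] = {
            "r_at_25": _corr_at(rep_fm.correlations, 25)}
        # earlier-life replication, both directions, alpha/3 convention
        adol = _load_result(out, AnalysisSpec(line, "all", "adolescent",
                                              "k450_like"), cfg)
        for tp in ("birth", "child7"):
            if not (out / f"{line}_all_{tp}_k450_like.ewas.tsv").exists():
                continue
            early = _load_result(out, AnalysisSpec(line, "all", tp,
                                                   "k450_like"), cfg)
            fwd = replication.cross_group_agreement(
                adol, early, ks=cfg.ks, timepoint_lookup=True,
                timepoint_divisor=thr.timepoint_divisor, alpha=thr.alpha,
                label_a=adol.spec.label, label_b=early.spec.label)
            back = replication.cross_group_agreement(
                early, adol, ks=cfg.ks, timepoint_lookup=True,
                timepoint_divisor=thr.timepoint_divisor, alpha=thr.alpha,
                label_a=early.spec.label, label_b=adol.spec.label)
            fwd.to_json(out / "replication" / f"{line}_adolescent_to_{tp}.json")
            back.to_json(out / "replication" / f"{line}_{tp}_to_adolescent.json")
            info["timepoints"][f"{line}_{tp}"] = {
                "n_forward": fwd.n_replicated(),
                "n_backward": back.n_replicated(),
            }
    log.info("replicate: %s", info)
    return info


def _corr_at(corr: pd.DataFrame, k: int) -> float | None:
    row = corr[corr["k"] == k]
    return None if row.empty else round(float(row["pearson_r"].iloc[0]), 6)


def stage_meta(cfg: PipelineConfig) -> dict:
    out = _outdir(cfg)
    info = {}
    for line in ("MGM", "PGM"):
        for stratum in ("all", "F", "M"):
            epic = _load_result(out, AnalysisSpec(line, stratum, "adolescent",
                                                  "epic_like"), cfg)
            k450 = _load_result(out, AnalysisSpec(line, stratum, "adolescent",
                                                  "k450_like"), cfg)
            meta = replication.fixed_effects_meta([epic, k450])
            _write(meta, out / f"meta_{line}_{stratum}.tsv")
            common = meta[meta["n_studies"] == 2]
            info[f"{line}_{stratum}"] = {
                "n_common": int(len(common)),
                "min_p": float(common["pvalue"].min()),
                "n_significant": int(
                    (common["pvalue"] < cfg.thresholds.k450_gw).sum()),
            }
    log.info("meta: %s", info)
    return info


def stage_enrich(cfg: PipelineConfig) -> dict:
    out = _outdir(cfg)
    _, probes, _ = _load_inputs(out)
    thr = cfg.thresholds
    info: dict = {"lookups": {}, "tfbs": {}, "candidates": {}}
    # a-priori lookups in the discovery dataset
    masks = {
        "icr": probes.loc[probes["in_icr"], "probe_id"],
        "escapee": probes.loc[probes["in_escapee"], "probe_id"],
    }
    lookup_rows = []
    for line in ("MGM", "PGM"):
        res_all = _load_result(out, AnalysisSpec(line, "all", "adolescent",
                                                 "epic_like"), cfg)
        for name, mask in masks.items():
            try:
                flags, bthr = enrichment.candidate_region_lookup(
                    res_all, mask, alpha=thr.alpha)
            except ValueError:
                continue
            info["lookups"][f"{line}_{name}"] = {
                "n_tested": bthr.n_tests,
                "threshold": bthr.reported,
                "n_significant": int(flags["significant"].sum()),
            }
            flags["lookup"] = f"{line}_{name}"
            lookup_rows.append(flags)
        # X chromosome, per sex
        xmask = probes.loc[probes["chrom"].astype(str) == "X", "probe_id"]
        for stratum in ("F", "M"):
            res_s = _load_result(out, AnalysisSpec(line, stratum, "adolescent",
                                                   "epic_like"), cfg)
            try:
                flags, bthr = enrichment.candidate_region_lookup(
                    res_s, xmask, alpha=thr.alpha)
            except ValueError:
                continue
            info["lookups"][f"{line}_X_{stratum}"] = {
                "n_tested": bthr.n_tests,
                "threshold": bthr.reported,
                "n_significant": int(flags["significant"].sum()),
            }
            flags["lookup"] = f"{line}_X_{stratum}"
            lookup_rows.append(flags)
    if lookup_rows:
        _write(pd.concat(lookup_rows, ignore_index=True),
               out / "region_lookups.tsv")

    # TFBS-style locus overlap enrichment of the top 25 discovery sites
    region_sets = [enrichment.RegionSet.from_bed(p)
                   for p in sorted((out / "region_sets").glob("*.bed"))]
    heat = {}
    enr_all = []
    for line in ("MGM", "PGM"):
        for stratum in ("all", "F", "M"):
            res = _load_result(out, AnalysisSpec(line, stratum, "adolescent",
                                                 "epic_like"), cfg)
            universe = list(res.table.loc[res.table["pvalue"].notna(),
                                          "probe_id"])
            top = replication.top_k_select(res, thr.replication_k)
            enr = enrichment.locus_overlap_enrichment(
                top, universe, probes, region_sets)
            enr["analysis"] = f"{line}_{stratum}"
            enr_all.append(enr)
            heat[f"{line}_{stratum}"] = dict(zip(enr["set_name"], enr["log_or"]))
    enr_tab = pd.concat(enr_all, ignore_index=True)
    _write(enr_tab, out / "tfbs_enrichment.tsv")
    _write(pd.DataFrame(heat).rename_axis("set_name").reset_index(),
           out / "tfbs_log_or_matrix.tsv")
    best = enr_tab.sort_values("pvalue").iloc[0]
    info["tfbs"] = {"n_sets": len(region_sets),
                    "best_set": str(best["set_name"]),
                    "best_log_or": round(float(best["log_or"]), 4),
                    "best_p": float(best["pvalue"])}

    # candidate-set inflation and rank-sum enrichment
    seed = cfg.stage_seed("enrich")
    qq_rows = []
    for lst in sorted((out / "candidates").glob("*.txt")):
        ids = lst.read_text().split()
        for line in ("MGM", "PGM"):
            res = _load_result(out, AnalysisSpec(line, "all", "adolescent",
                                                 "epic_like"), cfg)
            infl = enrichment.candidate_set_inflation(res, ids, seed=seed)
            _, wp = enrichment.wilcoxon_enrichment(res, ids)
            key = f"{line}_{lst.stem}"
            info["candidates"][key] = {
                "lambda": round(infl.lambda_, 4),
                "lambda_se": round(infl.lambda_se, 4),
                "wilcoxon_p": float(wp),
                "n_sites": infl.n_sites,
            }
            qq = infl.qq_points.copy()
            qq["candidate_set"] = key
            qq_rows.append(qq)
    _write(pd.concat(qq_rows, ignore_index=True), out / "qq_points.tsv")
    log.info("enrich: %s", info)
    return info


def stage_report(cfg: PipelineConfig) -> dict:
    """Assemble the JSON summary from the per-stage info files on disk."""
    out = _outdir(cfg)
    stages = {}
    for name in STAGES:
        p = out / "stage_info" / f"{name}.json"
        if p.exists():
            stages[name] = json.loads(p.read_text())
    report = {
        "seed": int(cfg.seed),
        "config_hash": cfg.config_hash(),
        "stages": stages,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


STAGES = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "cellcounts": stage_cellcounts,
    "ewas": stage_ewas,
    "replicate": stage_replicate,
    "meta": stage_meta,
    "enrich": stage_enrich,
}


def run_stage(cfg: PipelineConfig, name: str) -> dict:
    """Run one stage and persist its headline numbers for the report."""
    if name == "report":
        return stage_report(cfg)
    out = _outdir(cfg)
    try:
        info = STAGES[name](cfg)
    except Exception as err:  # abort with a replayable pointer
        raise RuntimeError(
            f"stage {name!r} failed ({err}); replay with "
            f"`transgen-ewas {name} --config <file>`"
        ) from err
    (out / "stage_info").mkdir(exist_ok=True)
    with open(out / "stage_info" / f"{name}.json", "w") as fh:
        json.dump(info, fh, indent=2, sort_keys=True)
    return info


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage in order; returns the JSON report dict."""
    for name in STAGES:
        log.info("=== stage %s ===", name)
        run_stage(cfg, name)
    return stage_report(cfg)
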