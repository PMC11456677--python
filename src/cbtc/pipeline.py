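"""End-to-end orchestration: simulate/load -> segment -> fc -> compare -> classify -> predict.

A run is configured by a flat :class:`RunConfig` (mirrors the CLI flags,
loadable from YAML), executes the enabled stages in order, writes each
stage's tabular outputs plus a machine-readable ``summary.json``, and logs
one structured line per stage.  All randomness flows from named seeds
recorded in the summary, so an identical config reproduces a byte-identical
summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import cpm as _cpm
from . import fc as _fc
from . import parcellation as _parc
from . import stats as _stats
from .regions import (
    LoopManifest,
    default_manifest,
    load_loop_manifest,
    load_phenotype,
    save_phenotype,
    subjects_to_frame,
)
from .simulate import SimulationConfig, SyntheticDataset, simulate_cohort

log = logging.getLogger("cbtc")

STAGES = ("segment", "fc", "compare", "classify", "predict")


@dataclass
class RunConfig:
    """One pipeline run.  Exactly one input mode: ``simulate`` or ``load``."""

    mode: str = "simulate"
    out_dir: str = "cbtc_run"
    manifest_path: str | None = None
    # load mode
    phenotype_path: str | None = None
    series_dir: str | None = None
    # simulate mode
    n_patients: int = 64
    n_controls: int = 64
    n_timepoints: int = 200
    rho0: float = 0.4
    delta: float = 0.15
    behavior_noise_sd: float = 4.0
    profile_concentration: float = 50.0
    voxels_per_subdivision: int = 40
    # stage toggles
    stages: tuple[str, ...] = STAGES
    # analysis parameters
    scheme: str = "loops"
    tau: float = 0.01
    tie_rule: str = "first-target"
    ttest_variant: str = "welch"
    svm_C: float = 1.0
    ranking_scope: str = "fold"
    k_max: int | None = None
    n_perm_classify: int = 0
    n_perm_cpm: int = 0
    cpm_p_sel: float = 0.05
    cpm_corr: str = "pearson"
    cpm_combined: str = "two-predictor"
    cpm_min_frac: float = 1.0
    save_series: bool = False
    # named seeds
    seed: int = 0
    classify_perm_seed: int | None = None
    cpm_perm_seed: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (output location excluded)."""
        payload = asdict(self)
        payload.pop("out_dir", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def save_series(dataset: SyntheticDataset, series_dir) -> None:
    """Write one regions x time TSV per subject."""
    d = Path(series_dir)
    d.mkdir(parents=True, exist_ok=True)
    for sid, mat in dataset.series.items():
        mat.to_csv(d / f"{sid}.tsv", sep="\t", float_format="%.8g")


def save_profiles(dataset: SyntheticDataset, profiles_dir) -> None:
    """Write one voxel-profile TSV per subcortical structure.

    Columns: ``voxel_id``, one ``p_<target>`` per cortical target, and the
    planted ``true_target`` (synthetic ground truth, absent for real data).
    """
    d = Path(profiles_dir)
    d.mkdir(parents=True, exist_ok=True)
    for key, prof in sorted(dataset.profiles.items()):
        df = pd.DataFrame(prof.probs, columns=[f"p_{t}" for t in prof.targets])
        df.insert(0, "voxel_id", np.arange(len(df)))
        df["true_target"] = [prof.targets[i] for i in prof.true_labels]
        df.to_csv(d / f"{key.replace(':', '_')}.tsv", sep="\t", index=False,
                  float_format="%.8g")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _round(obj, nd=10):
    if isinstance(obj, float):
        return round(obj, nd)
    if isinstance(obj, dict):
        return {str(k): _round(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v, nd) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), nd)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    summary: dict = {
        "config_hash": config.config_hash(),
        "seeds": {
            "simulate": config.seed,
            "classify_perm": config.classify_perm_seed
            if config.classify_perm_seed is not None else config.seed + 1,
            "cpm_perm": config.cpm_perm_seed
            if config.cpm_perm_seed is not None else config.seed + 2,
        },
        "stages": {},
    }
    try:
        manifest = (load_loop_manifest(config.manifest_path)
                    if config.manifest_path else default_manifest())
        dataset = _stage_input(config, manifest, out, summary)
        if "segment" in config.stages and dataset.profiles:
            _stage_segment(config, dataset, out, summary)
        fc_tables = None
        if "fc" in config.stages:
            fc_tables = _stage_fc(config, dataset, manifest, out, summary)
        if fc_tables is not None:
            pheno = subjects_to_frame(dataset.subjects)
            if "compare" in config.stages:
                _stage_compare(config, fc_tables, pheno, out, summary)
            if "classify" in config.stages:
                _stage_classify(config, fc_tables, pheno, out, summary, manifest)
            if "predict" in config.stages:
                _stage_predict(config, fc_tables, pheno, out, summary)
    except StageError:
        (out / "FAILED").write_text(json.dumps(summary, indent=2, sort_keys=True))
        raise
    summary["wall_time_s"] = None  # kept out of the reproducibility contract
    blob = json.dumps(_round(summary), indent=2, sort_keys=True)
    (out / "summary.json").write_text(blob + "\n")
    log.info("pipeline done in %.1fs -> %s", time.time() - t0, out / "summary.json")
    return summary


def _log_stage(name: str, out: Path, t_start: float, **info) -> None:
    log.info("stage=%s wall=%.2fs out=%s %s", name, time.time() - t_start, out,
             " ".join(f"{k}={v}" for k, v in info.items()))


def _stage_input(config: RunConfig, manifest: LoopManifest, out: Path,
                 summary: dict) -> SyntheticDataset:
    t = time.time()
    try:
        if config.mode == "simulate":
            sim = SimulationConfig(
                n_patients=config.n_patients, n_controls=config.n_controls,
                n_timepoints=config.n_timepoints, rho0=config.rho0,
                delta=config.delta, behavior_noise_sd=config.behavior_noise_sd,
                profile_concentration=config.profile_concentration,
                voxels_per_subdivision=config.voxels_per_subdivision,
                seed=config.seed)
            dataset = simulate_cohort(sim, manifest)
            save_phenotype(dataset.subjects, out / "phenotype.tsv")
            if config.save_series:
                save_series(dataset, out / "series")
                save_profiles(dataset, out / "profiles")
            truth = asdict(sim)
            truth["behavior_edges"] = [list(x) for x in truth["behavior_edges"]]
            (out / "truth.json").write_text(json.dumps(_round(truth), indent=2,
                                                       sort_keys=True, default=list))
            summary["stages"]["simulate"] = {
                "n_patients": sim.n_patients, "n_controls": sim.n_controls,
                "n_timepoints": sim.n_timepoints,
                "psd_repair_perturbation": dataset.repair_perturbation,
            }
        elif config.mode == "load":
            if not config.phenotype_path or not Path(config.phenotype_path).exists():
                raise FileNotFoundError(f"phenotype file not found: {config.phenotype_path}")
            subjects = load_phenotype(config.phenotype_path)
            series = {}
            sdir = Path(config.series_dir or "")
            for s in subjects:
                p = sdir / f"{s.id}.tsv"
                if not p.exists():
                    raise FileNotFoundError(f"series file not found: {p}")
                series[s.id] = pd.read_csv(p, sep="\t", index_col=0)
            dataset = SyntheticDataset(subjects, series, {}, SimulationConfig())
            summary["stages"]["load"] = {"n_subjects": len(subjects)}
        else:
            raise ValueError(f"unknown input mode {config.mode!r}")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(config.mode, exc) from exc
    _log_stage(config.mode, out, t)
    return dataset


def _stage_segment(config: RunConfig, dataset: SyntheticDataset, out: Path,
                   summary: dict) -> None:
    t = time.time()
    try:
        rows, dice_summary = [], {}
        for key, prof in sorted(dataset.profiles.items()):
            pm = _parc.winner_take_all(prof.probs, prof.targets, prof.structure,
                                       tau=config.tau, tie_rule=config.tie_rule)
            d = _parc.recovery_dice(pm, prof.true_labels)
            dice_summary[key] = float(np.mean(list(d.values())))
            for tag, val in d.items():
                rows.append({"structure": key, "tag": tag, "dice": val,
                             "n_voxels": int((pm.assignments == prof.targets.index(tag)).sum())})
        pd.DataFrame(rows).to_csv(out / "parcellation_recovery.tsv", sep="\t",
                                  index=False, float_format="%.6g")
        summary["stages"]["segment"] = {"mean_recovery_dice": dice_summary,
                                        "tau": config.tau}
    except Exception as exc:
        raise StageError("segment", exc) from exc
    _log_stage("segment", out, t)


def _stage_fc(config: RunConfig, dataset: SyntheticDataset, manifest: LoopManifest,
              out: Path, summary: dict) -> dict[str, pd.DataFrame]:
    t = time.time()
    try:
        tables = {}
        for scheme in ("loops", "atlas"):
            fc = _fc.extract_fc_vector(dataset.series, manifest, scheme)
            _fc.save_fc_table(fc, out / f"fc_{scheme}.tsv")
            tables[scheme] = fc
        summary["stages"]["fc"] = {
            "edges_per_subject": {s: int(tables[s].shape[1]) for s in tables},
            "n_subjects": int(len(tables["loops"])),
        }
    except Exception as exc:
        raise StageError("fc", exc) from exc
    _log_stage("fc", out, t)
    return tables


def _stage_compare(config: RunConfig, fc_tables, pheno: pd.DataFrame, out: Path,
                   summary: dict) -> None:
    t = time.time()
    try:
        demo = _stats.demographic_stats(pheno)
        comp_summary = {"demographics": {
            "chi2": demo.chi2, "chi2_p": demo.chi2_p,
            "mw_z": demo.mw_z, "mw_p": demo.mw_p,
        }}
        labels = pheno.set_index("id")["group"]
        for scheme, fc in fc_tables.items():
            table = _stats.compare_groups(fc, labels.loc[fc.index].to_numpy(),
                                          variant=config.ttest_variant)
            _stats.save_edge_stats(table, out / f"group_stats_{scheme}.tsv")
            sig = table[table["significant"]]
            comp_summary[scheme] = {
                "n_edges": int(len(table)),
                "n_significant": int(len(sig)),
                "significant_edges": sorted(sig["edge"].tolist()),
            }
        summary["stages"]["compare"] = comp_summary
    except Exception as exc:
        raise StageError("compare", exc) from exc
    _log_stage("compare", out, t)


def _labels_pm1(pheno: pd.DataFrame, index) -> np.ndarray:
    groups = pheno.set_index("id")["group"].loc[index]
    return np.where(groups == "patient", 1, -1)


def _stage_classify(config: RunConfig, fc_tables, pheno: pd.DataFrame, out: Path,
                    summary: dict, manifest: LoopManifest) -> None:
    t = time.time()
    try:
        cls_summary = {}
        for scheme, fc in fc_tables.items():
            y = _labels_pm1(pheno, fc.index)
            res = _classify.accuracy_curve(fc.to_numpy(), y,
                                           ranking_scope=config.ranking_scope,
                                           C=config.svm_C, k_max=config.k_max)
            pd.DataFrame({"k": list(res.accuracy_by_k),
                          "accuracy": list(res.accuracy_by_k.values())}
                         ).to_csv(out / f"accuracy_curve_{scheme}.tsv", sep="\t",
                                  index=False, float_format="%.6g")
            pd.DataFrame({"fpr": res.roc[0], "tpr": res.roc[1]}).to_csv(
                out / f"roc_{scheme}.tsv", sep="\t", index=False, float_format="%.6g")
            entry = {
                "best_k": res.best_k, "accuracy": res.accuracy,
                "sensitivity": res.sensitivity, "specificity": res.specificity,
                "auc": res.auc, "ranking_scope": res.ranking_scope, "C": res.C,
            }
            if config.n_perm_classify > 0:
                p, _ = _classify.permutation_test_auc(
                    fc.to_numpy(), y, k=res.best_k,
                    n_perm=config.n_perm_classify,
                    seed=summary["seeds"]["classify_perm"],
                    ranking_scope=config.ranking_scope, C=config.svm_C)
                entry["permutation_p"] = p
                entry["n_permutations"] = config.n_perm_classify
            cls_summary[scheme] = entry
        summary["stages"]["classify"] = cls_summary
    except Exception as exc:
        raise StageError("classify", exc) from exc
    _log_stage("classify", out, t)


def _stage_predict(config: RunConfig, fc_tables, pheno: pd.DataFrame, out: Path,
                   summary: dict) -> None:
    t = time.time()
    try:
        pheno_i = pheno.set_index("id")
        pred_summary = {}
        for scheme, fc in fc_tables.items():
            patients = [i for i in fc.index if pheno_i.loc[i, "group"] == "patient"]
            behavior = pheno_i.loc[patients, "ue_fma"].astype(float).to_numpy()
            fc_pat = fc.loc[patients]
            results = _cpm.run_cpm(
                fc_pat, behavior, p_sel=config.cpm_p_sel, corr_type=config.cpm_corr,
                combined=config.cpm_combined, n_perm=config.n_perm_cpm,
                seed=summary["seeds"]["cpm_perm"], min_frac=config.cpm_min_frac)
            rows = []
            for mode, res in results.items():
                for sid, p_val, o in zip(patients, res.predicted, res.observed):
                    rows.append({"id": sid, "mode": mode,
                                 "predicted": p_val, "observed": o})
            pd.DataFrame(rows).to_csv(out / f"cpm_predictions_{scheme}.tsv",
                                      sep="\t", index=False, float_format="%.6g")
            stab = [{"mode": m, "edge": e, "sign": s}
                    for m, res in results.items()
                    for e, s in sorted(res.well_represented.items())]
            pd.DataFrame(stab, columns=["mode", "edge", "sign"]).to_csv(
                out / f"cpm_stability_{scheme}.tsv", sep="\t", index=False)
            pred_summary[scheme] = {
                m: {"spearman_r": res.spearman_r,
                    "permutation_p": res.permutation_p,
                    "empty_folds": res.empty_folds,
                    "well_represented": dict(sorted(res.well_represented.items()))}
                for m, res in results.items()
            }
        summary["stages"]["predict"] = pred_summary
    except Exception as exc:
        raise StageError("predict", exc) from exc
    _log_stage("predict", out, t)
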