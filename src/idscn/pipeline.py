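"""Configuration-driven orchestration: simulate (or load) -> build IDSCN ->
edgewise stats -> NBS -> prediction -> classification.

Every stage draws its seed deterministically from the master seed and the
stage name, so re-running a config reproduces all numeric outputs exactly
and reordering stages cannot silently change results.  Outputs land under a
single run directory together with a machine-readable JSON run report whose
headline numbers are copied from the stage results (never recomputed).

Two presets ship with the pipeline: ``paper`` mirrors the study-scale
analysis parameters (FDR q < .001, Bonferroni family of 3, NBS alpha .05
with 10,000 permutations, selection p < .01, weight thresholds .8/.9, grid
steps 5), and ``desk`` keeps the same thresholds but reduces permutation
counts to interactive scale.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import atlas as atlas_mod
from . import classification as cls_mod
from . import nbs as nbs_mod
from . import prediction as pred_mod
from . import stats as stats_mod
from .atlas import CorticalThicknessTable, dk_atlas, edge_enumeration
from .network import build_idscn_cohort
from .synthetic import CohortConfig, generate_cohort

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "stage_seed", "PRESETS"]

log = logging.getLogger("idscn.pipeline")

PRESETS: dict[str, dict] = {
    "paper": {
        "fdr_q": 0.001,
        "bonferroni_factor": 3,
        "nbs_alpha": 0.05,
        "nbs_permutations": 10_000,
        "selection_p": 0.01,
        "weight_thresholds": (0.8, 0.9),
        "grid_steps": 5,
        "prediction_permutations": 10_000,
        "outer_folds": 10,
        "repeats": 10,
        "svm_C": 1.0,
    },
    "desk": {
        "fdr_q": 0.001,
        "bonferroni_factor": 3,
        "nbs_alpha": 0.05,
        "nbs_permutations": 1_000,
        "selection_p": 0.01,
        "weight_thresholds": (0.8, 0.9),
        "grid_steps": 5,
        "prediction_permutations": 200,
        "outer_folds": 10,
        "repeats": 10,
        "svm_C": 1.0,
    },
}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    out_dir: str = "idscn_run"
    seed: int = 0
    preset: str = "desk"
    input_table: str | None = None  # CSV/TSV path; None -> synthetic cohort
    control_group: str = "CONTROL"
    cohort: CohortConfig | None = None  # synthetic spec when input_table is None
    fdr_q: float | None = None  # per-field overrides of the preset
    bonferroni_factor: int | None = None
    nbs_alpha: float | None = None
    nbs_permutations: int | None = None
    selection_p: float | None = None
    weight_thresholds: tuple[float, float] | None = None
    grid_steps: int | None = None
    prediction_permutations: int | None = None
    outer_folds: int | None = None
    repeats: int | None = None
    svm_C: float | None = None
    classifier_features: int = 30  # top-F fallback size when no edge is significant

    def resolved(self) -> dict:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        params = dict(PRESETS[self.preset])
        for key in params:
            override = getattr(self, key)
            if override is not None:
                params[key] = override
        for bound_key, lo, hi in (
            ("fdr_q", 0, 1), ("nbs_alpha", 0, 1), ("selection_p", 0, 1),
        ):
            if not lo < params[bound_key] < hi:
                raise ValueError(f"{bound_key} must lie in ({lo}, {hi})")
        return params

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        cohort = raw.pop("cohort", None)
        cfg = cls(**raw)
        if cohort is not None:
            cfg.cohort = CohortConfig(**cohort)
        return cfg


@dataclass
class RunReport:
    config: dict
    stages: dict = field(default_factory=dict)
    headline: dict = field(default_factory=dict)
    manifest: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    failed_stage: str | None = None

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        return json.dumps(dataclasses.asdict(self), indent=2, default=default)


def _write(report: RunReport, path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(text)
    report.manifest.append(str(path))


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis; returns (and writes) the run report."""
    params = config.resolved()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas = dk_atlas()
    edges = edge_enumeration(atlas, "unique_pairs")
    report = RunReport(
        config={**{k: v for k, v in dataclasses.asdict(config).items() if k != "cohort"},
                "resolved": params}
    )
    t0 = time.time()
    stage = "simulate"
    try:
        # --- stage 1: obtain the cohort table ------------------------------
        truth = None
        if config.input_table:
            table = atlas_mod.load_ct_table(config.input_table, atlas)
        else:
            cc = config.cohort or CohortConfig()
            cc = dataclasses.replace(cc, seed=stage_seed(config.seed, "simulate"))
            cohort = generate_cohort(cc, atlas)
            table = cohort.table
            truth = cohort.truth
            atlas_mod.save_ct_table(table, out / "cohort.csv")
            report.manifest.append(str(out / "cohort.csv"))
            _write(report, out / "truth.json", json.dumps(truth, indent=2, sort_keys=True))
        groups = table.group_labels()
        if config.control_group not in groups:
            raise ValueError(f"control group {config.control_group!r} not in table")
        report.stages["simulate"] = {
            "n_subjects": table.n_subjects,
            "groups": {g: int((table.group == g).sum()) for g in groups},
            "seed": stage_seed(config.seed, "simulate"),
        }
        log.info("cohort ready: %s subjects", table.n_subjects)

        # --- stage 2: IDSCN ------------------------------------------------
        stage = "build_idscn"
        controls = table.by_group(config.control_group)
        gamers = table.subset(table.group != config.control_group)
        stack_g = build_idscn_cohort(controls, gamers, mode="add_in")
        stack_c = build_idscn_cohort(controls, controls, mode="leave_one_out")
        z_by_group = {}
        for g in groups:
            src = stack_c if g == config.control_group else stack_g
            z_by_group[g] = edges.extract(src.z)[src.group == g]
        long = []
        for src in (stack_g, stack_c):
            flat = edges.extract(src.z)
            for si, sid in enumerate(src.subject_ids):
                long.append(pd.DataFrame({
                    "subject_id": sid,
                    "edge": np.arange(edges.n_edges),
                    "z": flat[si],
                }))
        idscn_path = out / "idscn_long.csv"
        pd.concat(long).to_csv(idscn_path, index=False, float_format="%.10g")
        report.manifest.append(str(idscn_path))
        report.stages["build_idscn"] = {
            "mode": {"gamers": "add_in", "controls": "leave_one_out"},
            "reference_n": int(controls.n_subjects),
        }

        # --- stage 3: edgewise statistics ---------------------------------
        stage = "stats"
        anova = stats_mod.edgewise_anova(z_by_group, q_threshold=params["fdr_q"])
        sig = anova.significant_edges()
        posthoc = stats_mod.posthoc_pairwise(
            z_by_group, sig, bonferroni_factor=params["bonferroni_factor"]
        )
        tidy = stats_mod.tidy_edge_report(anova, posthoc, edges, atlas)
        _write(report, out / "edge_stats.csv", tidy.to_csv(index=False))
        report.stages["stats"] = {
            "significant_edges": int(sig.size),
            "df": [anova.df1, anova.df2],
            "excluded_edges": int(anova.excluded.sum()),
        }

        # --- stage 4: NBS --------------------------------------------------
        stage = "nbs"
        f_thresh = nbs_mod.f_threshold_from_anova(anova)
        nbs_res = nbs_mod.nbs_permutation_test(
            z_by_group,
            stat_threshold=f_thresh,
            n_regions=atlas.n_regions,
            n_permutations=params["nbs_permutations"],
            alpha=params["nbs_alpha"],
            seed=stage_seed(config.seed, "nbs"),
        )
        _write(report, out / "nbs.json", json.dumps({
            "stat_threshold": nbs_res.stat_threshold,
            "alpha": nbs_res.alpha,
            "n_permutations": nbs_res.n_permutations,
            "seed": nbs_res.seed,
            "components": [
                {"size": c.size, "p": c.p_value, "edges": c.edges}
                for c in nbs_res.observed_components
            ],
        }, indent=2))
        _write(report, out / "nbs_null_max_sizes.csv",
               "\n".join(map(str, nbs_res.null_max_sizes.tolist())) + "\n")
        report.stages["nbs"] = {
            "stat_threshold": f_thresh,
            "n_components": len(nbs_res.observed_components),
            "min_p": nbs_res.min_p,
        }

        # --- stage 5: prediction of weekly hours ---------------------------
        stage = "predict"
        pred_summary = {}
        gamer_groups = [g for g in groups if g != config.control_group]
        for g in gamer_groups:
            mask = gamers.group == g
            hours = gamers.weekly_hours[mask] if gamers.weekly_hours is not None else None
            if hours is None or np.all(~np.isfinite(hours)):
                pred_summary[g] = {"skipped": "no weekly_hours"}
                continue
            X = edges.extract(stack_g.z)[mask]
            cv = pred_mod.CVConfig(
                outer_folds=params["outer_folds"],
                repeats=params["repeats"],
                selection_p=params["selection_p"],
                n_permutations=params["prediction_permutations"],
                grid_steps=params["grid_steps"],
                seed=stage_seed(config.seed, f"predict:{g}"),
            )
            res = pred_mod.nbs_predict_cv(X, hours, cv, atlas.n_regions)
            entry = {
                "r_mean": res.r_mean,
                "r_ci": list(res.r_ci),
                "permutation_p": res.permutation_p,
                "empty_folds": res.empty_folds,
            }
            wdf = pd.DataFrame({"edge": np.arange(edges.n_edges), "weight": res.weights})
            _write(report, out / f"prediction_weights_{g}.csv", wdf.to_csv(index=False))
            for thr in params["weight_thresholds"]:
                wm = pred_mod.threshold_edge_weights(res.weights, thr, atlas.n_regions)
                entry[f"positive_edges@{thr}"] = len(wm.positive_edges)
                entry[f"negative_edges@{thr}"] = len(wm.negative_edges)
                deg = pd.DataFrame({
                    "region": atlas.short_names,
                    "degree_positive": wm.nodal_degree_positive,
                    "degree_negative": wm.nodal_degree_negative,
                })
                _write(report, out / f"nodal_degree_{g}_w{thr}.csv", deg.to_csv(index=False))
            pred_summary[g] = entry
        report.stages["predict"] = pred_summary

        # --- stage 6: pairwise classification -------------------------------
        stage = "classify"
        if sig.size:
            feat_edges, feat_rule = sig, f"significant edges (q<{params['fdr_q']:g})"
        else:
            order = np.argsort(-np.nan_to_num(anova.F, nan=-np.inf), kind="stable")
            feat_edges = order[: config.classifier_features]
            feat_rule = f"top {config.classifier_features} edges by F (no significant edge)"
        cls_summary = {"features": int(feat_edges.size), "feature_rule": feat_rule}
        pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1 :]]
        for a, b in pairs:
            Xa, Xb = z_by_group[a][:, feat_edges], z_by_group[b][:, feat_edges]
            X = np.vstack([Xa, Xb])
            y = np.array([a] * len(Xa) + [b] * len(Xb), dtype=object)
            res = cls_mod.loocv_linear_svm(X, y, positive_class=a, C=params["svm_C"])
            cls_summary[f"{a}_vs_{b}"] = {
                "auc": res.auc,
                "accuracy": res.accuracy,
                "sensitivity": res.sensitivity,
                "specificity": res.specificity,
            }
            roc = pd.DataFrame(res.roc_points, columns=["fpr", "tpr"])
            _write(report, out / f"roc_{a}_vs_{b}.csv", roc.to_csv(index=False))
        report.stages["classify"] = cls_summary

        # --- headline -------------------------------------------------------
        report.headline = {
            "significant_edge_count": int(sig.size),
            "nbs_min_component_p": nbs_res.min_p,
            "prediction_r": {
                g: pred_summary[g].get("r_mean") for g in gamer_groups
            },
            "classification_auc": {
                f"{a}_vs_{b}": cls_summary[f"{a}_vs_{b}"]["auc"] for a, b in pairs
            },
        }
    except Exception as exc:
        report.failed_stage = stage
        report.warnings.append(f"stage {stage} failed: {exc}")
        (out / "run_report.json").write_text(report.to_json())
        raise
    report.stages["elapsed_s"] = round(time.time() - t0, 2)
    (out / "run_report.json").write_text(report.to_json())
    report.manifest.append(str(out / "run_report.json"))
    return report
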