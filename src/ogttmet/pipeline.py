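"""End-to-end orchestration: cohort -> filters -> AUC -> selection -> report.

Stage order follows the analysis design: preprocessing (QC-RSD and blank
filters, log-scale imputation), windowed AUC features, the two-step
univariate selection, timepoint-discriminant PLS-DA feeding fuzzy temporal
clustering, per-window chemical enrichment, network export, and the
group-discriminant PLS-DA on AUC features + clinical index feeding the
correlation comparison. Every stage writes TSV/JSON artifacts and the run
manifest records config, seed, and SHA-256 checksums so a rerun with the
same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .auc import CANONICAL_WINDOWS, build_auc_table
from .clustering import cluster_composition, estimate_fuzzifier, fuzzy_cmeans
from .config import PipelineConfig, SimConfig
from .correlation import compare_group_correlations
from .data import GROUPS, ROLE_STUDY, TimeCourseDataset
from .enrichment import enrichment_by_window
from .network import build_network, export_graph
from .plsda import fit_plsda, prune_by_vip, lv_repeated_measures, select_by_loading
from .preprocessing import (
    apply_filters,
    filter_blank,
    filter_qc_rsd,
    impute_missing,
    log10_autoscale,
    timecourse_zscores,
)
from .sim import generate_blank_qc, generate_cohort, write_cohort
from .univariate import group_effects_all_windows, time_effect_screen

log = logging.getLogger("ogttmet")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": json.loads(config.model_dump_json()),
        "version": __version__,
        "stages": [],
        "warnings": [],
        "complete": False,
    }
    t_start = time.time()
    stage_name = "load"
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")

            # -- load or simulate ------------------------------------------
            truth = None
            if config.sim is not None:
                dataset, truth = generate_cohort(config.sim)
                dataset = generate_blank_qc(config.sim, dataset)
                write_cohort(dataset, truth, out / "input")
            else:
                dataset = TimeCourseDataset.from_dir(config.input_dir)
            _record(manifest, out, "load", [])

            # -- preprocessing ---------------------------------------------
            stage_name = "preprocessing"
            reports = []
            if (dataset.samples["role"] == "qc").sum() >= 2:
                reports.append(filter_qc_rsd(dataset, config.qc_rsd_threshold))
            if (dataset.samples["role"] == "blank").sum() >= 3:
                reports.append(filter_blank(dataset, config.blank_alpha))
            for r in reports:
                r.to_tsv(out / f"filter_{r.filter_name}.tsv")
            dataset = apply_filters(dataset, reports)
            study = dataset.matrix(ROLE_STUDY)
            if study.isna().any().any():
                filled = 10.0 ** impute_missing(np.log10(study), seed=config.seed)
                dataset.intensities.loc[filled.index, filled.columns] = filled
                study = dataset.matrix(ROLE_STUDY)
            _record(manifest, out, "preprocessing",
                    [out / f"filter_{r.filter_name}.tsv" for r in reports])

            # -- AUC features ----------------------------------------------
            stage_name = "auc_features"
            auc_feats = build_auc_table(dataset, CANONICAL_WINDOWS, log10=config.auc_on_log10)
            auc_feats.to_tsv(out / "auc_features.tsv")
            _record(manifest, out, "auc_features", [out / "auc_features.tsv"])

            # -- two-step univariate ---------------------------------------
            stage_name = "univariate"
            screen = time_effect_screen(dataset, fdr_level=config.fdr_level)
            screen.to_csv(out / "time_effect_screen.tsv", sep="\t")
            selected = list(screen.index[screen["selected"]])
            window_stats = group_effects_all_windows(auc_feats, metabolites=selected or None)
            window_stats.to_csv(out / "group_effects.tsv", sep="\t", index=False)
            _record(manifest, out, "univariate",
                    [out / "time_effect_screen.tsv", out / "group_effects.tsv"])

            # -- timepoint PLS-DA + temporal clustering ---------------------
            stage_name = "plsda_time"
            scaled = log10_autoscale(study.loc[:, dataset.metabolites])
            meta = dataset.study_meta()
            tp_labels = [f"t{int(t)}" for t in meta.loc[scaled.index, "timepoint_min"]]
            model_t = prune_by_vip(
                scaled.to_numpy(), tp_labels, threshold=config.vip_threshold,
                max_components=config.max_components, variables=list(scaled.columns),
            )
            rm = lv_repeated_measures(
                model_t.T[:, 0],
                meta.loc[scaled.index, "subject_id"].to_numpy(),
                meta.loc[scaled.index, "timepoint_min"].to_numpy(),
            )
            model_t.loadings.to_csv(out / "plsda_time_loadings.tsv", sep="\t")
            pd.DataFrame({"variable": model_t.variables, "vip": model_t.vip}).to_csv(
                out / "plsda_time_vip.tsv", sep="\t", index=False
            )
            (out / "plsda_time_rm.json").write_text(json.dumps(rm, indent=2))
            _record(manifest, out, "plsda_time",
                    [out / "plsda_time_loadings.tsv", out / "plsda_time_vip.tsv",
                     out / "plsda_time_rm.json"])

            stage_name = "clustering"
            z = timecourse_zscores(dataset.restrict(model_t.variables))
            m_fuzz = config.fuzzifier or estimate_fuzzifier(len(z), z.shape[1])
            clus = fuzzy_cmeans(z, c=config.n_clusters, m=m_fuzz, seed=config.seed)
            clus.membership.to_csv(out / "cluster_membership.tsv", sep="\t")
            clus.centroids.to_csv(out / "cluster_centroids.tsv", sep="\t")
            pd.DataFrame(
                {"cluster": clus.assignment,
                 "max_membership": clus.membership.max(axis=1)}
            ).to_csv(out / "cluster_assignment.tsv", sep="\t")
            if dataset.annotations is not None:
                comp = cluster_composition(
                    clus, dataset.annotations["chem_class"].to_dict()
                )
                comp.to_csv(out / "cluster_composition.tsv", sep="\t")
            _record(manifest, out, "clustering",
                    [out / "cluster_membership.tsv", out / "cluster_centroids.tsv",
                     out / "cluster_assignment.tsv"])

            # -- enrichment per window --------------------------------------
            stage_name = "enrichment"
            enr = pd.DataFrame()
            if dataset.annotations is not None:
                enr = enrichment_by_window(
                    window_stats,
                    dataset.annotations["chem_class"].to_dict(),
                    min_size=config.enrichment_min_size,
                    alpha=config.alpha,
                )
                enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            _record(manifest, out, "enrichment", [out / "enrichment.tsv"] if len(enr) else [])

            # -- network -----------------------------------------------------
            stage_name = "network"
            graph_files = []
            if dataset.annotations is not None:
                G = build_network(
                    window_stats, dataset.annotations, dataset.kegg_pairs,
                    tanimoto_min=config.tanimoto_min, g_floor=config.g_floor,
                    alpha=config.alpha, exclude_classes=config.network_exclude_classes,
                )
                graph_files = [
                    export_graph(G, out / "network.graphml", "graphml"),
                    export_graph(G, out / "network.sif", "sif"),
                ]
            _record(manifest, out, "network", graph_files)

            # -- group PLS-DA + correlations --------------------------------
            stage_name = "correlation"
            corr_files = []
            if dataset.clinical is not None:
                full = f"{dataset.timepoints[0]:g}-{dataset.timepoints[-1]:g}"
                wide = auc_feats.wide(full)
                feats = wide.copy()
                subj_groups = dataset.subjects()["group"]
                mi = dataset.clinical["matsuda"]
                feats["matsuda"] = mi.loc[feats.index]
                # AUC features are already on the log scale when
                # auc_on_log10 is set; autoscale without re-logging then.
                if config.auc_on_log10:
                    sd = feats.std(ddof=1)
                    scaled_g = ((feats - feats.mean()) / sd).loc[:, sd > 0]
                else:
                    scaled_g = log10_autoscale(feats)
                model_g = prune_by_vip(
                    scaled_g.to_numpy(), list(subj_groups.loc[scaled_g.index]),
                    threshold=config.vip_threshold,
                    max_components=config.max_components,
                    variables=list(scaled_g.columns),
                )
                sel_vars = [v for v in select_by_loading(model_g, config.loading_k_sd)
                            if v != "matsuda"]
                corr = compare_group_correlations(
                    wide, mi, subj_groups, variables=sel_vars or None
                )
                corr.to_csv(out / "mi_correlations.tsv", sep="\t")
                pd.DataFrame(
                    {"variable": model_g.variables, "vip": model_g.vip}
                ).to_csv(out / "plsda_group_vip.tsv", sep="\t", index=False)
                corr_files = [out / "mi_correlations.tsv", out / "plsda_group_vip.tsv"]
            _record(manifest, out, "correlation", corr_files)

            # -- recovery report vs ground truth ----------------------------
            if truth is not None:
                stage_name = "recovery"
                rec = _recovery_report(truth, window_stats, config)
                (out / "recovery.json").write_text(json.dumps(rec, indent=2))
                _record(manifest, out, "recovery", [out / "recovery.json"])

            manifest["warnings"] = sorted({str(w.message) for w in caught})
    except Exception as exc:  # pragma: no cover - error path
        manifest["failed_stage"] = stage_name
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise RuntimeError(f"pipeline stage {stage_name!r} failed: {exc}") from exc

    manifest["complete"] = True
    manifest["runtime_s"] = round(time.time() - t_start, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _record(manifest: dict, out: Path, stage: str, files: list[Path]) -> None:
    manifest["stages"].append(
        {
            "name": stage,
            "outputs": {f.name: _sha256(f) for f in files if Path(f).exists()},
        }
    )
    log.info("stage %s done (%d outputs)", stage, len(files))


def _recovery_report(truth, window_stats: pd.DataFrame, config: PipelineConfig) -> dict:
    """Sensitivity/FDR of the group contrast against planted truth."""
    full = window_stats[window_stats["window"] == "0-120"]
    hits = set(full.loc[full["pvalue"] < config.alpha, "metabolite"])
    planted = set(truth.affected)
    tp = len(hits & planted)
    return {
        "n_planted": len(planted),
        "n_detected": len(hits),
        "sensitivity": tp / len(planted) if planted else None,
        "false_discovery_rate": (len(hits) - tp) / len(hits) if hits else None,
    }


def regenerate_fixtures(seed: int, out_dir) -> Path:
    """Write the small deterministic fixtures used by the test-suite helpers."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(
        n_per_group=5, n_metabolites=12, n_affected=2, enriched_class_size=2,
        n_classes=3, n_high_rsd=1, n_blank_artifacts=1, qc_replicates=4,
        n_blanks=4, missing_rate=0.0, seed=seed,
    )
    dataset, truth = generate_cohort(cfg)
    dataset = generate_blank_qc(cfg, dataset)
    write_cohort(dataset, truth, out)
    toy = pd.DataFrame(
        {"time_min": [0, 15, 30, 60, 120], "value": [2.0, 4.0, 3.0, 5.0, 1.0]}
    )
    toy.to_csv(out / "toy_trajectory.tsv", sep="\t", index=False)
    return out
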