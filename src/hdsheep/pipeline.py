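"""End-to-end orchestration: QC -> phase alignment -> screening -> panel.

``run_pipeline`` drives the stages from a single config and writes the
report bundle (exclusions, normalized table, DLMO table, screen table,
class summary, urea-cycle ratio screen, panel models, ROC, per-bin AUC)
plus a manifest of seeds, thresholds and file checksums, so a rerun with
the same config is bit-identical.  ``hierarchical_cluster_order`` supplies
the metabolite ordering used for profile heat maps (Ward linkage on
Euclidean distances between per-metabolite group-mean phase profiles,
z-scored per metabolite).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from . import __version__
from .circadian import (
    align_to_dlmo,
    compute_dlmo,
    melatonin_profiles_from_frame,
    phase_bin,
)
from .data_model import (
    ConcentrationTable,
    ValidationError,
    read_concentration_table,
    write_results_table,
)
from .diffstats import UREA_CYCLE_RATIOS, compute_ratio_series, fit_metabolite_anova, \
    screen_metabolites, summarize_significance, bh_fdr
from .panel import (
    MarkerFilterCriteria,
    auc_by_timepoint,
    losocv_predictions,
    pooled_cv_auc,
    preselect_markers,
    roc_curve,
    sensitivity_at_specificity,
    sheep_level_predictions,
    stepwise_build_panels,
)
from .qc import QCThresholds, exclude_metabolites, qc2_normalize
from .synthetic import generate_cohort, paperlike_config


@dataclasses.dataclass
class PipelineConfig:
    """Inputs, thresholds and seeds for a full run.

    Either point ``concentrations_path``/``annotation_path``/
    ``melatonin_path`` at CSV files, or set ``synthetic_seed`` to run on a
    freshly generated paperlike cohort.
    """

    out_dir: str | Path
    concentrations_path: str | Path | None = None
    annotation_path: str | Path | None = None
    melatonin_path: str | Path | None = None
    synthetic_seed: int | None = None
    qc_thresholds: QCThresholds = dataclasses.field(default_factory=QCThresholds)
    dlmo_threshold: float = 0.25
    alpha: float = 0.05
    criteria: MarkerFilterCriteria = dataclasses.field(default_factory=MarkerFilterCriteria)
    panel_max_size: int = 12
    target_specificity: float = 0.90

    def __post_init__(self) -> None:
        file_mode = self.concentrations_path is not None
        if file_mode == (self.synthetic_seed is not None):
            raise ValidationError("set either input paths or synthetic_seed, not both")
        if file_mode:
            for p in (self.concentrations_path, self.annotation_path, self.melatonin_path):
                if p is None or not Path(p).exists():
                    raise ValidationError(f"input file missing: {p}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns it in memory."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.synthetic_seed is not None:
        cohort = generate_cohort(paperlike_config(config.synthetic_seed))
        table, profiles = cohort.concentrations, cohort.melatonin
        inputs = {"synthetic_seed": config.synthetic_seed}
    else:
        table = read_concentration_table(config.concentrations_path, config.annotation_path)
        profiles = melatonin_profiles_from_frame(pd.read_csv(config.melatonin_path))
        inputs = {
            str(p): _sha256(Path(p))
            for p in (config.concentrations_path, config.annotation_path, config.melatonin_path)
        }

    # 1. QC: exclusion then between-plate normalization
    report = exclude_metabolites(table, config.qc_thresholds)
    write_results_table(report.as_frame(), out_dir / "exclusions.csv")
    retained = table.subset_metabolites(report.retained)
    normalized, factors = qc2_normalize(retained)
    write_results_table(
        factors.reset_index(), out_dir / "qc2_factors.csv"
    )

    # 2. circadian phase alignment
    dlmo = {p.sheep_id: compute_dlmo(p, config.dlmo_threshold) for p in profiles}
    write_results_table(
        pd.DataFrame({"sheep_id": list(dlmo), "dlmo_clock_time": list(dlmo.values())}),
        out_dir / "dlmo.csv",
    )
    aligned = align_to_dlmo(normalized, dlmo)

    # 3. per-metabolite screen, tabulation, urea-cycle ratios
    screen = screen_metabolites(aligned, alpha=config.alpha)
    write_results_table(screen, out_dir / "anova.csv")
    summary = summarize_significance(screen, alpha=config.alpha)
    write_results_table(summary, out_dir / "summary.csv")
    ratio_rows = []
    study = aligned.study_samples()
    design = pd.DataFrame(
        {
            "genotype": study["genotype"].to_numpy(),
            "time": study["sampling_index"].to_numpy(),
            "sheep_id": study["sheep_id"].to_numpy(),
        }
    )
    for ratio in UREA_CYCLE_RATIOS:
        try:
            series = compute_ratio_series(aligned, ratio)
        except ValidationError:
            continue  # a component was excluded by QC
        y = series.loc[study["sample_id"]].to_numpy()
        pg, pt, pi = fit_metabolite_anova(y, design)
        ratio_rows.append(
            {
                "ratio": ratio.name,
                "interpretation": ratio.interpretation,
                "p_genotype": pg,
                "p_time": pt,
                "p_interaction": pi,
                "control_mean": float(np.nanmean(y[(study["genotype"] == "control").to_numpy()])),
                "hd_mean": float(np.nanmean(y[(study["genotype"] == "HD").to_numpy()])),
            }
        )
    if ratio_rows:
        ratios = pd.DataFrame(ratio_rows)
        for term in ("genotype", "time", "interaction"):
            ratios[f"fdr_{term}"] = bh_fdr(ratios[f"p_{term}"].to_numpy())
        write_results_table(ratios, out_dir / "ratios.csv")

    # 4. marker pre-selection and stepwise panel building
    verdicts = preselect_markers(screen, aligned, config.criteria)
    write_results_table(verdicts, out_dir / "preselection.csv")
    candidates = verdicts.loc[verdicts["selected"], "abbreviation"].tolist()
    bundle: dict = {
        "table": aligned,
        "exclusions": report,
        "dlmo": dlmo,
        "screen": screen,
        "summary": summary,
        "preselection": verdicts,
    }
    if candidates:
        fdr_map = dict(zip(screen["abbreviation"], screen["fdr_genotype"]))
        models = stepwise_build_panels(
            aligned, candidates, max_size=config.panel_max_size, fdr_by_marker=fdr_map
        )
        final = models[-1]
        preds = losocv_predictions(aligned, final.markers)
        sens, thr = sensitivity_at_specificity(preds, config.target_specificity)
        curve = roc_curve(
            preds["predicted_probability"].to_numpy(),
            (preds["genotype"] == "HD").astype(int).to_numpy(),
        )
        bins = auc_by_timepoint(preds)
        sheep_preds = sheep_level_predictions(preds)
        sheep_pos = sheep_preds["predicted_probability"] >= thr
        hd_mask = sheep_preds["genotype"] == "HD"
        panel_json = {
            "models": [
                {
                    "markers": m.markers,
                    "coefficients": [float(c) for c in m.coefficients],
                    "step_auc": [float(a) for a in m.step_auc],
                    "final_auc": float(m.final_auc),
                }
                for m in models
            ],
            "final_pooled_cv_auc": float(pooled_cv_auc(preds)),
            "sensitivity_at_target_specificity": float(sens),
            "probability_threshold": float(thr),
            "target_specificity": config.target_specificity,
            "sheep_level_detection_rate": float(sheep_pos[hd_mask].mean()),
            "sheep_level_false_positive_rate": float(sheep_pos[~hd_mask].mean()),
        }
        (out_dir / "panel.json").write_text(json.dumps(panel_json, indent=2))
        write_results_table(
            pd.DataFrame(
                {
                    "threshold": curve.thresholds,
                    "sensitivity": curve.sensitivity,
                    "specificity": curve.specificity,
                }
            ),
            out_dir / "roc.csv",
        )
        write_results_table(bins, out_dir / "bin_auc.csv")
        bundle.update(panel=panel_json, predictions=preds, bin_auc=bins)

    # 5. clustering order for the profile heat map
    profiles_mat = genotype_phase_profiles(aligned)
    if len(profiles_mat) >= 2:
        order, merges = hierarchical_cluster_order(profiles_mat)
        write_results_table(
            pd.DataFrame(
                {"leaf_rank": np.arange(len(order)), "abbreviation": profiles_mat.index[order]}
            ),
            out_dir / "cluster_order.csv",
        )
        bundle["cluster_order"] = profiles_mat.index[order].tolist()

    manifest = {
        "package_version": __version__,
        "inputs": inputs,
        "qc_thresholds": dataclasses.asdict(config.qc_thresholds),
        "dlmo_threshold": config.dlmo_threshold,
        "alpha": config.alpha,
        "criteria": dataclasses.asdict(config.criteria),
        "panel_max_size": config.panel_max_size,
        "target_specificity": config.target_specificity,
        "artifacts": {},
    }
    for f in sorted(out_dir.iterdir()):
        if f.name != "manifest.json":
            manifest["artifacts"][f.name] = _sha256(f)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = manifest
    return bundle


def genotype_phase_profiles(
    table: ConcentrationTable, standardize: bool = True
) -> pd.DataFrame:
    """Metabolite x (genotype, phase-bin) group-mean matrix for clustering.

    Values are per-genotype means within 2 h DLMO-relative phase bins,
    z-scored per metabolite by default (profile-shape clustering across
    classes whose absolute concentrations differ by orders of magnitude).
    """
    study = table.study_samples()
    if "phase_offset" not in study.columns:
        raise ValidationError("table lacks a phase_offset column; align to DLMO first")
    bins = phase_bin(study["phase_offset"].to_numpy())
    vals = table.study_values().reset_index(drop=True)
    vals["_genotype"] = study["genotype"].to_numpy()
    vals["_bin"] = bins
    means = vals.groupby(["_genotype", "_bin"]).mean()
    mat = means.T  # metabolite x (genotype, bin)
    mat = mat.dropna(axis=1, how="all")
    # sparse edge bins can leave isolated gaps; fill with the profile mean
    mat = mat.apply(lambda row: row.fillna(row.mean()), axis=1)
    if standardize:
        centred = mat.sub(mat.mean(axis=1), axis=0)
        sd = mat.std(axis=1, ddof=0).replace(0.0, 1.0)
        mat = centred.div(sd, axis=0)
    return mat


def hierarchical_cluster_order(matrix: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Ward-linkage agglomerative clustering of row profiles.

    Returns (leaf order, merge tree in scipy linkage form).  Rows must be
    complete; impute upstream before clustering.
    """
    if len(matrix) < 2:
        raise ValidationError("need at least 2 rows to cluster")
    arr = np.asarray(matrix, dtype=float)
    if np.isnan(arr).any():
        raise ValidationError("matrix has missing cells; impute upstream first")
    merges = linkage(arr, method="ward", metric="euclidean")
    return leaves_list(merges), merges
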