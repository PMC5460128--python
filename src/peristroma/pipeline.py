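"""End-to-end pipeline: simulate/load -> ADC -> regions -> features ->
graphs -> classification, with a reproducibility manifest.

Every random stage derives its seed deterministically from the pipeline
seed, so two runs with identical configuration produce byte-identical
feature tables and reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adc import BValuePair, compute_adc
from .classify import (
    EAConfig,
    REDUCED_EA,
    ea_feature_pool,
    loocv_evaluate,
    roc_points,
    univariate_screen,
)
from .features import (
    RegionStatistics,
    build_feature_table,
    feature_matrix,
    feature_names,
    region_statistics,
)
from .graph import anova_across_regions, anova_between_groups, build_region_graph, degree_summary
from .segmentation import FCMConfig, build_regions, segment_fibroglandular
from .synthetic import CohortConfig, SyntheticCase, generate_cohort, load_nifti, read_manifest

log = logging.getLogger("peristroma")

FLOAT_FORMAT = "%.10g"  # 10 significant digits in every CSV


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full run.

    Either ``manifest`` points at an on-disk cohort (CSV with case_id,
    ki67_label and NIfTI paths) or ``simulate`` is true and ``cohort``
    parameterises the synthetic generator.
    """

    out_dir: str = "peristroma_out"
    simulate: bool = True
    manifest: str | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    fcm: FCMConfig = field(default_factory=FCMConfig)
    ea: EAConfig = field(default_factory=lambda: EAConfig(**REDUCED_EA))
    shell_px: int = 4
    boundary_halfwidth_px: int = 2
    b0: float = 50.0
    b1: float = 1000.0
    seed: int = 0


def extract_case_statistics(
    s0: np.ndarray,
    s1: np.ndarray,
    tumour_mask: np.ndarray,
    b0: float,
    b1: float,
    fcm: FCMConfig,
    shell_px: int = 4,
    boundary_halfwidth_px: int = 2,
    pixel_spacing_mm: float = 1.45,
) -> RegionStatistics:
    """ADC map + fibroglandular segmentation + regions + statistics for one case."""
    adc = compute_adc(BValuePair(s0, s1, b0, b1))
    fibro = segment_fibroglandular(s0, fcm)
    regions = build_regions(
        tumour_mask,
        fibro,
        shell_px=shell_px,
        boundary_halfwidth_px=boundary_halfwidth_px,
        pixel_spacing_mm=pixel_spacing_mm,
    )
    return region_statistics(adc, regions)


def _load_cases(config: PipelineConfig) -> list[SyntheticCase]:
    if config.simulate:
        log.info("simulating cohort: n=%d seed=%d", config.cohort.n_cases, config.cohort.seed)
        return generate_cohort(config.cohort)
    if not config.manifest:
        raise ValueError("either simulate=True or a manifest path is required")
    table = read_manifest(config.manifest)
    cases = []
    for row in table.itertuples(index=False):
        cases.append(
            SyntheticCase(
                case_id=str(row.case_id),
                ki67_label=str(row.ki67_label),
                s0_image=load_nifti(row.s0_path),
                s1_image=load_nifti(row.s1_path),
                tumour_mask=load_nifti(row.mask_path) > 0.5,
                ground_truth_region_means=np.full(6, np.nan),
                ground_truth_adc=np.full((1, 1), np.nan),
                fibroglandular_truth=np.zeros((1, 1), dtype=bool),
            )
        )
    return cases


def compute_feature_table(config: PipelineConfig) -> pd.DataFrame:
    """Stages simulate/load through feature extraction."""
    cases = _load_cases(config)
    triples = []
    for i, case in enumerate(cases):
        fcm = FCMConfig(
            n_clusters=config.fcm.n_clusters,
            fuzzifier=config.fcm.fuzzifier,
            tolerance=config.fcm.tolerance,
            max_iterations=config.fcm.max_iterations,
            seed=(config.fcm.seed * 1009 + i) % (2**31 - 1),
        )
        stats = extract_case_statistics(
            case.s0_image,
            case.s1_image,
            case.tumour_mask,
            config.b0,
            config.b1,
            fcm,
            config.shell_px,
            config.boundary_halfwidth_px,
            config.cohort.pixel_spacing_mm,
        )
        triples.append((case.case_id, case.ki67_label, stats))
    log.info("extracted features for %d cases", len(triples))
    return build_feature_table(triples)


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write all outputs under ``out_dir``.

    Returns a result bundle with the feature table, both region graphs, the
    ANOVA summaries, the classifier report and the manifest.  Any stage
    failure propagates with its stage logged; outputs written before the
    failure are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_outputs: dict[str, str] = {}

    log.info("stage features: start")
    table = compute_feature_table(config)
    features_csv = out / "features.csv"
    table.to_csv(features_csv, index=False, float_format=FLOAT_FORMAT)
    stage_outputs["features"] = str(features_csv)
    log.info("stage features: done (%d cases, %d feature columns)",
             len(table), len(feature_names()))

    log.info("stage graph: start")
    graphs = {}
    edge_frames, degree_frames = [], []
    for group in ("high", "low"):
        rg = build_region_graph(table, group)
        graphs[group] = rg
        edges = rg.pair_stats.copy()
        edges.insert(0, "group", group)
        edge_frames.append(edges)
        deg = degree_summary(rg)
        deg.insert(0, "group", group)
        degree_frames.append(deg)
    edges_csv = out / "region_graph_edges.csv"
    pd.concat(edge_frames).to_csv(edges_csv, index=False, float_format=FLOAT_FORMAT)
    degrees_csv = out / "region_graph_degrees.csv"
    pd.concat(degree_frames).to_csv(degrees_csv, index=False)
    stage_outputs["graph_edges"] = str(edges_csv)
    stage_outputs["graph_degrees"] = str(degrees_csv)
    log.info(
        "stage graph: done (total degree high=%d low=%d)",
        graphs["high"].total_degree,
        graphs["low"].total_degree,
    )

    log.info("stage anova: start")
    anova = {
        "mean_adc_across_regions": anova_across_regions(table),
        "tumour_mean_adc_by_ki67": anova_between_groups(table),
    }
    anova_json = out / "anova.json"
    anova_json.write_text(json.dumps(anova, indent=2))
    stage_outputs["anova"] = str(anova_json)

    log.info("stage classify: start (EA pop=%d gens=%d)",
             config.ea.population_size, config.ea.max_generations)
    X, y, names = feature_matrix(table)
    screen = univariate_screen(X, y, names, seed=config.seed)
    screen_csv = out / "univariate_screen.csv"
    screen.to_csv(screen_csv, index=False, float_format=FLOAT_FORMAT)
    stage_outputs["univariate_screen"] = str(screen_csv)

    ea = ea_feature_pool(X, y, config.ea)
    report = loocv_evaluate(X, y, names, ea.mask, seed=config.seed)
    log.info("stage classify: done (LOOCV AUC=%.3f)", report.auc)

    report_json = out / "classifier_report.json"
    report_json.write_text(json.dumps(report.to_dict(), indent=2))
    predictions_csv = out / "loocv_predictions.csv"
    pd.DataFrame(
        {
            "case_id": table["case_id"],
            "ki67_label": table["ki67_label"],
            "score": report.scores,
        }
    ).to_csv(predictions_csv, index=False, float_format=FLOAT_FORMAT)
    freq_csv = out / "selection_frequency.csv"
    report.selection_frequency.rename("frequency").rename_axis("feature").to_csv(
        freq_csv, float_format=FLOAT_FORMAT
    )
    roc_csv = out / "roc_points.csv"
    roc_points(y, report.scores).to_csv(roc_csv, index=False, float_format=FLOAT_FORMAT)
    stage_outputs.update(
        classifier_report=str(report_json),
        loocv_predictions=str(predictions_csv),
        selection_frequency=str(freq_csv),
        roc_points=str(roc_csv),
    )

    manifest = {
        "package_version": __version__,
        "config": _config_dict(config),
        "config_hash": config_hash(config),
        "seed": config.seed,
        "n_cases": int(len(table)),
        "stage_outputs": stage_outputs,
    }
    manifest_path = out / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    log.info("run complete: %s", manifest_path)

    return {
        "feature_table": table,
        "graphs": graphs,
        "anova": anova,
        "univariate": screen,
        "ea": ea,
        "report": report,
        "manifest": manifest,
    }


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    for key in ("region_corr_low", "region_corr_high"):
        d["cohort"][key] = np.asarray(d["cohort"][key]).tolist()
    return d


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(_config_dict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
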