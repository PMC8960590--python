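"""Pipeline orchestration: simulated cohorts and paired-frame nano analysis.

Two workflows tie the stages together:

``mapping``
    Simulate (or load) a two-genotype cohort of hemisection fields,
    detect the three channels, classify synapses, aggregate per-lamina
    statistics, build percent-of-control heat maps and run the
    genotype × region ANOVA.

``nano``
    Render paired confocal/STED frames of the PSD95 channel, detect PSDs
    and nanoclusters, assign NCs to PSDs and summarise subtype
    frequencies.

Both are deterministic given a configuration and seed, and both are thin
compositions of the library modules — everything they do can be done by
calling the modules directly.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .coloc import classify_synapses, records_to_dataframe
from .detection import DetectionParams, PunctaSet, detect_puncta
from .image import ImagePlane
from .io import DETECTION_PROFILES, RunConfig, write_image, write_table
from .nanostructure import assign_nanoclusters, nc_metrics, subtype_distribution
from .regional import (
    compute_region_stats,
    contact_loss_correlation,
    percent_difference,
    synapse_table,
)
from .stats import chi_squared, two_way_anova
from .synthetic import (
    GroundTruthScene,
    OpticsModel,
    RegionAtlas,
    SceneParams,
    build_region_atlas,
    inject_aggregates,
    remove_tripartite,
    render,
    sample_scene,
)

__all__ = [
    "subject_seeds",
    "simulate_subject",
    "analyse_subject",
    "run_mapping_cohort",
    "nano_field",
    "run_nano_study",
    "run_pipeline",
]

log = logging.getLogger("synaptomap")

_CHANNELS = ("psd95", "vglut2", "pap")


def subject_seeds(base_seed: int, n: int) -> list[int]:
    """Derive n reproducible per-subject seeds (< 2**31) from one seed."""
    state = np.random.SeedSequence(int(base_seed)).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def simulate_subject(
    params: SceneParams,
    atlas: RegionAtlas,
    optics: OpticsModel,
    tripartite_loss: float | Mapping[str, float] = 0.0,
    with_aggregates: bool = False,
    channels: Sequence[str] = _CHANNELS,
) -> tuple[GroundTruthScene, dict[str, ImagePlane]]:
    """Sample one subject's scene and render its channels.

    ``tripartite_loss`` > 0 models the case genotype: that fraction of
    ground-truth tripartite entities is removed before rendering.
    """
    scene = sample_scene(params, atlas)
    if isinstance(tripartite_loss, Mapping) or tripartite_loss:
        scene = remove_tripartite(scene, tripartite_loss, seed=params.seed)
    images = {ch: render(scene, ch, optics) for ch in channels}
    if with_aggregates:
        images = {ch: inject_aggregates(img, scene) for ch, img in images.items()}
    return scene, images


def analyse_subject(
    images: Mapping[str, ImagePlane],
    atlas: RegionAtlas,
    det_params: Mapping[str, DetectionParams],
    mode: str = "triple",
    subject: str = "s1",
    genotype: str = "control",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detect, classify and aggregate one subject's field.

    Returns (per-synapse table, per-region long-format statistics).
    """
    puncta: dict[str, PunctaSet] = {}
    for ch, img in images.items():
        puncta[ch] = detect_puncta(img, det_params.get(ch, DETECTION_PROFILES["mapping"]))
    records = classify_synapses(
        puncta["psd95"],
        puncta.get("vglut2"),
        puncta["pap"],
        mode=mode,
    )
    table = synapse_table(records, puncta["psd95"], atlas)
    stats = compute_region_stats(table, atlas, subject=subject, genotype=genotype)
    return table, stats


def run_mapping_cohort(
    base_params: SceneParams,
    atlas: RegionAtlas,
    optics: OpticsModel,
    det_params: Mapping[str, DetectionParams],
    n_control: int = 5,
    n_case: int = 5,
    tripartite_loss: float | Mapping[str, float] = 0.4,
    mode: str = "triple",
    seed: int = 0,
) -> dict:
    """Simulate and analyse a control-vs-case cohort end to end.

    Each subject gets an independent scene (derived seed) on the shared
    atlas; case subjects lose ``tripartite_loss`` of their ground-truth
    tripartite synapses.  Returns the pooled region statistics, heat-map
    tables for tripartite and non-tripartite density, the two-way
    genotype × region ANOVA per measure, and the contact-vs-loss
    correlation.
    """
    seeds = subject_seeds(seed, n_control + n_case)
    all_stats = []
    for i in range(n_control + n_case):
        is_case = i >= n_control
        params = dataclasses.replace(base_params, seed=seeds[i])
        _, images = simulate_subject(
            params,
            atlas,
            optics,
            tripartite_loss=tripartite_loss if is_case else 0.0,
        )
        genotype = "case" if is_case else "control"
        _, stats = analyse_subject(
            images,
            atlas,
            det_params,
            mode=mode,
            subject=f"{genotype}_{i + 1}",
            genotype=genotype,
        )
        all_stats.append(stats)
        log.info("subject %d/%d (%s) analysed", i + 1, n_control + n_case, genotype)
    stats = pd.concat(all_stats, ignore_index=True)
    control = stats[stats["genotype"] == "control"]
    case = stats[stats["genotype"] == "case"]

    heatmaps = {
        m: percent_difference(case, control, m)
        for m in ("tripartite_density", "non_tripartite_density", "density")
    }
    anova = {}
    for m, (cls, col) in {
        "tripartite_density": ("tripartite", "density_per_100um2"),
        "non_tripartite_density": ("non_tripartite", "density_per_100um2"),
        "density": ("all", "density_per_100um2"),
    }.items():
        sub = stats[stats["synapse_class"] == cls]
        anova[m] = two_way_anova(sub, col, "genotype", "region")
    try:
        r, p, corr_table = contact_loss_correlation(case, control)
        correlation = {"r": r, "p": p, "table": corr_table}
    except ValueError:
        correlation = None
    return {
        "region_stats": stats,
        "heatmaps": heatmaps,
        "anova": anova,
        "correlation": correlation,
        "seeds": seeds,
    }


def nano_field(
    params: SceneParams,
    det_confocal: DetectionParams,
    det_sted: DetectionParams,
    confocal_optics: Optional[OpticsModel] = None,
    sted_optics: Optional[OpticsModel] = None,
    atlas: Optional[RegionAtlas] = None,
) -> dict:
    """One paired confocal/STED field of the PSD95 channel, analysed.

    Returns the scene, both punctum sets, the NC→PSD assignment, the
    per-NC / per-PSD metric tables and the subtype distribution.
    """
    if atlas is None:
        atlas = build_region_atlas(params.field_size_px, params.pixel_size_nm)
    confocal_optics = confocal_optics or OpticsModel.confocal()
    sted_optics = sted_optics or OpticsModel.sted()
    scene = sample_scene(params, atlas)
    img_conf = render(scene, "psd95", confocal_optics)
    img_sted = render(scene, "psd95", sted_optics)
    psd_set = detect_puncta(img_conf, det_confocal)
    nc_set = detect_puncta(img_sted, det_sted)
    assignment = assign_nanoclusters(psd_set, nc_set)
    nc_table, psd_summary = nc_metrics(assignment)
    dist = subtype_distribution(assignment)
    return {
        "scene": scene,
        "psd_set": psd_set,
        "nc_set": nc_set,
        "assignment": assignment,
        "nc_table": nc_table,
        "psd_summary": psd_summary,
        "subtypes": dist,
    }


def run_nano_study(
    base_params: SceneParams,
    det_confocal: DetectionParams,
    det_sted: DetectionParams,
    n_fields: int = 4,
    seed: int = 0,
    case_nc_distribution: Optional[tuple[float, ...]] = None,
) -> dict:
    """Paired-frame study over several fields, optionally two genotypes.

    With ``case_nc_distribution`` set, half of a second cohort of fields
    is rendered with that NC-count distribution (the case genotype) and a
    chi-squared test compares subtype counts between cohorts.
    """
    seeds = subject_seeds(seed, 2 * n_fields)

    def collect(dist: Optional[tuple[float, ...]], field_seeds: list[int]) -> dict:
        frames = []
        counts = {"1": 0, "2": 0, "3+": 0}
        for s in field_seeds:
            params = dataclasses.replace(
                base_params,
                seed=s,
                **(
                    {"nc_count_distribution": dist}
                    if dist is not None
                    else {}
                ),
            )
            res = nano_field(params, det_confocal, det_sted)
            frames.append(res)
            for k, v in subtype_distribution(res["assignment"]).counts.items():
                counts[k] += v
        return {"fields": frames, "counts": counts}

    control = collect(None, seeds[:n_fields])
    out = {"control": control}
    if case_nc_distribution is not None:
        case = collect(tuple(case_nc_distribution), seeds[n_fields:])
        table = np.array(
            [
                [control["counts"][k] for k in ("1", "2", "3+")],
                [case["counts"][k] for k in ("1", "2", "3+")],
            ]
        )
        out["case"] = case
        out["chi_squared"] = chi_squared(table)
    return out


def _scene_params_from_config(cfg: RunConfig) -> SceneParams:
    return SceneParams(**cfg.scene, seed=cfg.seed) if "seed" not in cfg.scene else SceneParams(**cfg.scene)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the configured workflow and write its outputs.

    Every table is written as CSV with a provenance header carrying the
    config hash and seed; images and the atlas as TIFF.  Outputs of
    completed stages survive a later-stage failure.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    h = cfg.hash()
    params = _scene_params_from_config(cfg)
    if cfg.workflow == "simulate":
        atlas = build_region_atlas(
            params.field_size_px, params.pixel_size_nm, cfg.atlas_layout
        )
        optics = OpticsModel.confocal(**cfg.optics) if cfg.optics.get(
            "modality", "confocal"
        ) == "confocal" else OpticsModel.sted(**{k: v for k, v in cfg.optics.items() if k != "modality"})
        scene, images = simulate_subject(params, atlas, optics, with_aggregates=params.aggregate_count > 0)
        for ch, img in images.items():
            write_image(img, out / f"{ch}.tif")
        write_image(
            ImagePlane(
                pixels=atlas.label_image.astype(float),
                pixel_size_nm=atlas.pixel_size_nm,
                channel="atlas",
                bit_depth=16,
            ),
            out / "atlas.tif",
        )
        write_table(scene.to_dataframe(), out / "ground_truth.csv", seed=cfg.seed, cfg_hash=h)
        write_table(atlas.to_dataframe(), out / "atlas_regions.csv", seed=cfg.seed, cfg_hash=h)
        import yaml as _yaml

        (out / "params.yaml").write_text(
            _yaml.safe_dump(dataclasses.asdict(params), sort_keys=True)
        )
    elif cfg.workflow == "mapping":
        atlas = build_region_atlas(
            params.field_size_px, params.pixel_size_nm, cfg.atlas_layout
        )
        optics = OpticsModel.confocal(**{k: v for k, v in cfg.optics.items() if k != "modality"})
        det = {ch: cfg.detection_params(ch if ch in cfg.detection else "mapping") for ch in _CHANNELS}
        cohort = cfg.cohort or {}
        result = run_mapping_cohort(
            params,
            atlas,
            optics,
            det,
            n_control=int(cohort.get("n_control", 5)),
            n_case=int(cohort.get("n_case", 5)),
            tripartite_loss=cohort.get("tripartite_loss", 0.4),
            mode=cfg.mode,
            seed=cfg.seed,
        )
        write_table(result["region_stats"], out / "region_stats.csv", seed=cfg.seed, cfg_hash=h)
        for m, tab in result["heatmaps"].items():
            write_table(tab, out / f"heatmap_{m}.csv", seed=cfg.seed, cfg_hash=h)
        report = []
        for m, res in result["anova"].items():
            for effect, sr in res.items():
                report.append(
                    {
                        "measure": m,
                        "effect": effect,
                        "F": sr.statistic,
                        "df1": sr.df[0],
                        "df2": sr.df[1],
                        "p": sr.p_value,
                    }
                )
        write_table(pd.DataFrame(report), out / "anova.csv", seed=cfg.seed, cfg_hash=h)
        if result["correlation"] is not None:
            write_table(
                result["correlation"]["table"].assign(
                    r=result["correlation"]["r"], p=result["correlation"]["p"]
                ),
                out / "contact_loss_correlation.csv",
                seed=cfg.seed,
                cfg_hash=h,
            )
    elif cfg.workflow == "nano":
        nano_cfg = cfg.nano or {}
        det_c = cfg.detection_params("confocal")
        det_s = cfg.detection_params("sted")
        result = run_nano_study(
            params,
            det_c,
            det_s,
            n_fields=int(nano_cfg.get("n_fields", 2)),
            seed=cfg.seed,
            case_nc_distribution=(
                tuple(nano_cfg["case_nc_distribution"])
                if "case_nc_distribution" in nano_cfg
                else None
            ),
        )
        rows = []
        for cohort_name in ("control", "case"):
            if cohort_name not in result:
                continue
            for i, f in enumerate(result[cohort_name]["fields"]):
                d = f["subtypes"]
                rows.append(
                    {
                        "cohort": cohort_name,
                        "field": i,
                        "n_psd": d.n_psd_with_nc,
                        "mean_nc_per_psd": d.mean_nc_per_psd,
                        "freq_1": d.frequencies["1"],
                        "freq_2": d.frequencies["2"],
                        "freq_3plus": d.frequencies["3+"],
                    }
                )
        write_table(pd.DataFrame(rows), out / "subtypes.csv", seed=cfg.seed, cfg_hash=h)
        nc_tables = pd.concat(
            [f["nc_table"].assign(field=i) for i, f in enumerate(result["control"]["fields"])],
            ignore_index=True,
        )
        write_table(nc_tables, out / "nanoclusters.csv", seed=cfg.seed, cfg_hash=h)
        if "chi_squared" in result:
            sr = result["chi_squared"]
            write_table(
                pd.DataFrame(
                    [{"chi2": sr.statistic, "df": sr.df[0], "p": sr.p_value}]
                ),
                out / "subtype_chi_squared.csv",
                seed=cfg.seed,
                cfg_hash=h,
            )
    return out
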