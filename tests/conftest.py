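"""Shared fixtures and ground-truth matching helpers."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from scipy.spatial import cKDTree

from synaptomap import (
    OpticsModel,
    SceneParams,
    build_region_atlas,
    sample_scene,
)
from synaptomap.io import DETECTION_PROFILES


def noise_free_confocal(background: float = 20.0) -> OpticsModel:
    return OpticsModel.confocal(
        background_level=background, poisson_scale=0.0, read_noise_sd=0.0
    )


def noise_free_sted(background: float = 20.0) -> OpticsModel:
    return OpticsModel.sted(
        background_level=background, poisson_scale=0.0, read_noise_sd=0.0
    )


def snr_confocal(snr: float, peak: float = 600.0, background: float = 50.0) -> OpticsModel:
    """Confocal optics whose background noise sd gives the requested peak SNR.

    Poisson noise at the background level plus read noise combine to
    sd = peak / snr; the Poisson part is fixed by the background, the
    read-noise term absorbs the remainder.
    """
    poisson_var = background  # poisson_scale = 1
    target_var = (peak / snr) ** 2
    read_sd = float(np.sqrt(max(target_var - poisson_var, 0.0)))
    return OpticsModel.confocal(
        background_level=background, poisson_scale=1.0, read_noise_sd=read_sd
    )


def sparse_scene_params(
    n_target: int = 100,
    field_px: int = 512,
    pixel_size_nm: float = 100.0,
    seed: int = 0,
    **overrides,
) -> SceneParams:
    """Params for well-separated entities: density set for ~n_target entities."""
    area_100um2 = (field_px * pixel_size_nm / 1000.0) ** 2 / 100.0
    defaults = dict(
        field_size_px=(field_px, field_px),
        pixel_size_nm=pixel_size_nm,
        psd_density=n_target / area_100um2,
        tripartite_fraction=0.3,
        min_psd_spacing_nm=1500.0,
        intensity_cv=0.1,
        aggregate_count=0,
        seed=seed,
    )
    defaults.update(overrides)
    return SceneParams(**defaults)


def match_centroids(
    truth_nm: np.ndarray,
    detected_px: np.ndarray,
    pixel_size_nm: float,
    tol_px: float = 1.0,
) -> tuple[float, float, np.ndarray]:
    """(recall, precision, per-truth NN distance in px) with a distance cutoff."""
    if len(detected_px) == 0:
        return 0.0, 0.0, np.full(len(truth_nm), np.inf)
    truth_px = truth_nm / pixel_size_nm - 0.5
    d_truth, _ = cKDTree(detected_px).query(truth_px)
    recall = float((d_truth <= tol_px).mean()) if len(truth_px) else 1.0
    d_det, _ = cKDTree(truth_px).query(detected_px)
    precision = float((d_det <= tol_px).mean())
    return recall, precision, d_truth


def scene_truth_px(scene, pixel_size_nm: float) -> np.ndarray:
    return np.array(
        [
            [e.psd_centre_nm[0], e.psd_centre_nm[1]]
            for e in scene.entities
        ]
    )


@pytest.fixture(scope="session")
def mapping_profile():
    return DETECTION_PROFILES["mapping"]


@pytest.fixture(scope="session")
def small_atlas():
    return build_region_atlas((64, 64), 100.0, "bands")
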