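"""Ground-truthed synthetic micrograph generation.

Forward model for the measurement chain the analysis inverts: excitatory
postsynaptic densities (PSDs) are placed across a laminar region atlas at
region-dependent densities, each PSD is composed of 1-4 PSD95 nanoclusters
(NCs) of ~140 nm diameter, a configurable fraction of PSDs carry an
apposed presynaptic (VGLUT2-like) punctum and an overlapping perisynaptic
astrocytic process (PAP) punctum — the tripartite synapses.  Scenes are
rendered under confocal-like (320 nm FWHM) or STED-like (70 nm FWHM)
point-spread functions with background plus Poisson shot noise and
Gaussian read noise, and may be contaminated with large saturating
lipofuscin-like aggregates.

Every stochastic step is driven by the scene seed, so identical parameters
reproduce byte-identical ground truth and images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .image import ImagePlane

__all__ = [
    "REGION_NAMES",
    "DEFAULT_REGION_DENSITY",
    "DEFAULT_CONTACT_FRACTION",
    "OpticsModel",
    "SceneParams",
    "SynapseEntity",
    "Aggregate",
    "GroundTruthScene",
    "RegionAtlas",
    "build_region_atlas",
    "sample_scene",
    "render",
    "inject_aggregates",
    "remove_tripartite",
]

#: Rexed laminae groupings used for hemisection maps, dorsal to ventral.
REGION_NAMES: tuple[str, ...] = (
    "I-II",
    "III-IV",
    "V",
    "VI",
    "VII",
    "VIII",
    "IX",
    "X",
)

#: Default per-region PSD densities (puncta per 100 µm²).  Chosen for
#: plausibility — denser dorsal sensory laminae, sparser ventral motor
#: laminae — since per-lamina densities are not published.
DEFAULT_REGION_DENSITY: dict[str, float] = {
    "I-II": 40.0,
    "III-IV": 36.0,
    "V": 32.0,
    "VI": 28.0,
    "VII": 24.0,
    "VIII": 22.0,
    "IX": 20.0,
    "X": 26.0,
}

#: Default per-region fraction of synapses contacted by a PAP
#: (tripartite fraction): highest dorsally (~28%), lowest in lamina VII
#: (~17%), matching the reported range of astrocytic contact percentages.
DEFAULT_CONTACT_FRACTION: dict[str, float] = {
    "I-II": 0.28,
    "III-IV": 0.26,
    "V": 0.24,
    "VI": 0.22,
    "VII": 0.17,
    "VIII": 0.19,
    "IX": 0.20,
    "X": 0.21,
}

_CHANNELS = ("psd95", "vglut2", "pap")


@dataclass(frozen=True)
class OpticsModel:
    """Imaging modality: PSF width plus the noise model.

    The PSF is an isotropic Gaussian of the stated full width at half
    maximum.  Noise is Poisson on (signal + background), scaled by
    ``poisson_scale`` photons per intensity unit, followed by additive
    Gaussian read noise; either term can be switched off (set to 0) for
    noise-free oracle renderings.
    """

    modality: str
    psf_fwhm_nm: float
    background_level: float = 50.0
    poisson_scale: float = 1.0
    read_noise_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.modality not in ("confocal", "sted"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.psf_fwhm_nm <= 0:
            raise ValueError("psf_fwhm_nm must be positive")
        if self.background_level < 0 or self.read_noise_sd < 0:
            raise ValueError("background_level and read_noise_sd must be >= 0")
        if self.poisson_scale < 0:
            raise ValueError("poisson_scale must be >= 0")

    @classmethod
    def confocal(cls, psf_fwhm_nm: float = 320.0, **kwargs) -> "OpticsModel":
        return cls(modality="confocal", psf_fwhm_nm=psf_fwhm_nm, **kwargs)

    @classmethod
    def sted(cls, psf_fwhm_nm: float = 70.0, **kwargs) -> "OpticsModel":
        return cls(modality="sted", psf_fwhm_nm=psf_fwhm_nm, **kwargs)

    @property
    def noise_free(self) -> bool:
        return self.poisson_scale == 0 and self.read_noise_sd == 0


RegionValue = Union[float, Mapping[str, float]]


@dataclass(frozen=True)
class SceneParams:
    """Everything that defines one synthetic field of view.

    Lengths in nm, densities in puncta per 100 µm², probabilities in [0, 1].
    """

    field_size_px: tuple[int, int] = (512, 512)
    pixel_size_nm: float = 100.0
    psd_density: RegionValue = field(
        default_factory=lambda: dict(DEFAULT_REGION_DENSITY)
    )
    tripartite_fraction: RegionValue = field(
        default_factory=lambda: dict(DEFAULT_CONTACT_FRACTION)
    )
    presyn_fraction: float = 1.0
    presyn_offset_nm: float = 200.0
    pap_overlap_nm: float = 100.0
    nc_count_distribution: tuple[float, ...] = (0.45, 0.32, 0.15, 0.08)
    nc_diameter_nm: float = 140.0
    nc_spacing_nm: float = 150.0
    min_psd_spacing_nm: float = 700.0
    punctum_peak_intensity: float = 600.0
    intensity_cv: float = 0.15
    presyn_diameter_nm: float = 300.0
    pap_diameter_nm: float = 300.0
    aggregate_count: int = 3
    aggregate_diameter_um: tuple[float, float] = (3.0, 6.0)
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.field_size_px
        if h < 1 or w < 1:
            raise ValueError("field_size_px must be positive")
        for name in (
            "pixel_size_nm",
            "presyn_offset_nm",
            "pap_overlap_nm",
            "nc_diameter_nm",
            "nc_spacing_nm",
            "min_psd_spacing_nm",
            "presyn_diameter_nm",
            "pap_diameter_nm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        dist = self.nc_count_distribution
        if any(p < 0 for p in dist) or not math.isclose(sum(dist), 1.0, abs_tol=1e-9):
            raise ValueError("nc_count_distribution must be non-negative and sum to 1")
        for prob in self._region_values(self.tripartite_fraction).values():
            if not 0.0 <= prob <= 1.0:
                raise ValueError("tripartite_fraction must be in [0, 1]")
        if not 0.0 <= self.presyn_fraction <= 1.0:
            raise ValueError("presyn_fraction must be in [0, 1]")
        for dens in self._region_values(self.psd_density).values():
            if dens < 0:
                raise ValueError("psd_density must be >= 0")
        if self.aggregate_count < 0:
            raise ValueError("aggregate_count must be >= 0")

    @staticmethod
    def _region_values(value: RegionValue) -> dict[str, float]:
        if isinstance(value, Mapping):
            return dict(value)
        return {name: float(value) for name in REGION_NAMES}

    def density_for(self, region: str) -> float:
        return self._region_values(self.psd_density).get(region, 0.0)

    def tripartite_for(self, region: str) -> float:
        return self._region_values(self.tripartite_fraction).get(region, 0.0)

    @property
    def field_size_nm(self) -> tuple[float, float]:
        h, w = self.field_size_px
        return (h * self.pixel_size_nm, w * self.pixel_size_nm)


@dataclass
class SynapseEntity:
    """Ground truth for one synapse: a PSD and its partners.

    Coordinates are physical (y, x) positions in nm from the image origin.
    ``has_pap`` is the ground-truth tripartite flag.
    """

    id: int
    psd_centre_nm: tuple[float, float]
    nc_centres_nm: list[tuple[float, float]]
    region: str
    has_presyn: bool = True
    presyn_centre_nm: Optional[tuple[float, float]] = None
    has_pap: bool = False
    pap_centre_nm: Optional[tuple[float, float]] = None
    peak_intensity: float = 600.0

    @property
    def nc_count(self) -> int:
        return len(self.nc_centres_nm)

    @property
    def is_tripartite(self) -> bool:
        return self.has_pap


@dataclass
class Aggregate:
    """Footprint of one injected lipofuscin-like artifact."""

    centre_nm: tuple[float, float]
    diameter_um: float


@dataclass
class RegionAtlas:
    """Label image delineating the laminae of one hemisection field.

    ``label_image`` holds integers 0..n where 0 means "outside" and label
    ``i`` corresponds to ``region_names[i - 1]``.
    """

    label_image: np.ndarray
    region_names: tuple[str, ...]
    pixel_size_nm: float

    def __post_init__(self) -> None:
        self.label_image = np.asarray(self.label_image, dtype=np.int32)
        if self.label_image.ndim != 2:
            raise ValueError("label_image must be 2-D")
        if self.label_image.max(initial=0) > len(self.region_names):
            raise ValueError("label exceeds number of region names")

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_image.shape  # type: ignore[return-value]

    def region_area_um2(self) -> dict[str, float]:
        pixel_area = (self.pixel_size_nm / 1000.0) ** 2
        counts = np.bincount(
            self.label_image.ravel(), minlength=len(self.region_names) + 1
        )
        return {
            name: float(counts[i + 1] * pixel_area)
            for i, name in enumerate(self.region_names)
        }

    def region_of_pixel(self, row: int, col: int) -> str:
        label = int(self.label_image[row, col])
        return "outside" if label == 0 else self.region_names[label - 1]

    def to_dataframe(self):
        import pandas as pd

        areas = self.region_area_um2()
        return pd.DataFrame(
            {
                "label": np.arange(1, len(self.region_names) + 1),
                "region": list(self.region_names),
                "area_um2": [areas[name] for name in self.region_names],
            }
        )


@dataclass
class GroundTruthScene:
    """A sampled scene: entities, the atlas they live on, and provenance."""

    entities: list[SynapseEntity]
    atlas: RegionAtlas
    params: SceneParams
    artifacts: list[Aggregate] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entities)

    @property
    def tripartite_fraction_observed(self) -> float:
        if not self.entities:
            return float("nan")
        return sum(e.has_pap for e in self.entities) / len(self.entities)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "id": [e.id for e in self.entities],
                "y_nm": [e.psd_centre_nm[0] for e in self.entities],
                "x_nm": [e.psd_centre_nm[1] for e in self.entities],
                "region": [e.region for e in self.entities],
                "nc_count": [e.nc_count for e in self.entities],
                "has_presyn": [e.has_presyn for e in self.entities],
                "has_pap": [e.has_pap for e in self.entities],
            }
        )


def build_region_atlas(
    field_size_px: tuple[int, int],
    pixel_size_nm: float,
    layout: str = "bands",
    region_names: Sequence[str] = REGION_NAMES,
) -> RegionAtlas:
    """Partition a field into contiguous laminar regions.

    ``bands`` slices the field into horizontal bands of (near-)equal
    height, dorsal at the top; ``wedges`` into angular sectors around the
    field centre.  Stands in for the hand-drawn laminae delineation of
    real hemisection maps.
    """
    h, w = field_size_px
    n = len(region_names)
    if pixel_size_nm <= 0:
        raise ValueError("pixel_size_nm must be positive")
    labels = np.zeros((h, w), dtype=np.int32)
    if layout == "bands":
        if h < n:
            raise ValueError(
                f"field of {h} rows cannot hold {n} one-row bands"
            )
        edges = np.linspace(0, h, n + 1).round().astype(int)
        for i in range(n):
            labels[edges[i] : edges[i + 1], :] = i + 1
    elif layout == "wedges":
        if h * w < n:
            raise ValueError(f"field of {h * w} px cannot hold {n} wedges")
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        rows, cols = np.mgrid[0:h, 0:w]
        angle = np.arctan2(rows - cy, cols - cx)  # [-pi, pi)
        sector = np.floor((angle + np.pi) / (2 * np.pi) * n).astype(np.int32)
        labels = np.clip(sector, 0, n - 1) + 1
        counts = np.bincount(labels.ravel(), minlength=n + 1)
        if np.any(counts[1:] == 0):
            raise ValueError("field too small: some wedge regions are empty")
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return RegionAtlas(
        label_image=labels,
        region_names=tuple(region_names),
        pixel_size_nm=pixel_size_nm,
    )


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    theta = rng.uniform(0.0, 2.0 * np.pi)
    return np.array([np.sin(theta), np.cos(theta)])


def _place_nanoclusters(
    centre: np.ndarray, k: int, spacing_nm: float, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Place k NC centres around the PSD centre with pairwise spacing.

    For k >= 2 the centres sit on a randomly rotated regular k-gon whose
    side equals ``spacing_nm`` (circumradius jittered upward by up to 8%),
    so the minimum pairwise distance is guaranteed by construction.
    """
    if k == 1:
        return [tuple(centre)]
    circumradius = spacing_nm / (2.0 * np.sin(np.pi / k))
    circumradius *= rng.uniform(1.0, 1.08)
    theta0 = rng.uniform(0.0, 2.0 * np.pi)
    out = []
    for j in range(k):
        theta = theta0 + 2.0 * np.pi * j / k
        out.append(
            (
                float(centre[0] + circumradius * np.sin(theta)),
                float(centre[1] + circumradius * np.cos(theta)),
            )
        )
    return out


def sample_scene(params: SceneParams, atlas: RegionAtlas) -> GroundTruthScene:
    """Sample ground-truth synapses onto the atlas.

    PSD counts per region follow a homogeneous spatial Poisson process at
    the region's density; PSD centres respect a hard minimum spacing so
    neighbouring PSDs stay resolvable at mapping resolution.  Each entity
    is independently tripartite with the (per-region) tripartite fraction
    and its NC count is drawn from ``nc_count_distribution``.
    """
    if atlas.shape != tuple(params.field_size_px):
        raise ValueError(
            f"atlas shape {atlas.shape} != field_size_px {tuple(params.field_size_px)}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 0]))
    px = params.pixel_size_nm
    field_h_nm, field_w_nm = params.field_size_nm
    # keep every centre (PSD, NC, partners) strictly inside the field
    margin_nm = max(
        params.presyn_offset_nm,
        params.pap_overlap_nm,
        params.nc_spacing_nm,
        params.pap_diameter_nm / 2,
    ) + px
    entities: list[SynapseEntity] = []
    accepted: list[np.ndarray] = []
    pixel_area_100um2 = (px / 1000.0) ** 2 / 100.0  # pixel area in 100 µm² units
    for label, region in enumerate(atlas.region_names, start=1):
        density = params.density_for(region)
        if density <= 0:
            continue
        region_pixels = np.argwhere(atlas.label_image == label)
        if len(region_pixels) == 0:
            continue
        expected = density * len(region_pixels) * pixel_area_100um2
        n = int(rng.poisson(expected))
        placed = 0
        attempts = 0
        max_attempts = 200 * max(n, 1)
        while placed < n:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"could not place {n} PSDs in region {region!r} at the "
                    f"requested density with min_psd_spacing_nm="
                    f"{params.min_psd_spacing_nm}; lower the density or spacing"
                )
            idx = rng.integers(0, len(region_pixels))
            row, col = region_pixels[idx]
            centre = np.array(
                [(row + rng.random()) * px, (col + rng.random()) * px]
            )
            if (
                centre[0] < margin_nm
                or centre[1] < margin_nm
                or centre[0] > field_h_nm - margin_nm
                or centre[1] > field_w_nm - margin_nm
            ):
                continue
            if accepted:
                dists = np.linalg.norm(np.asarray(accepted) - centre, axis=1)
                if dists.min() < params.min_psd_spacing_nm:
                    continue
            accepted.append(centre)
            placed += 1
            k = 1 + int(
                rng.choice(len(params.nc_count_distribution), p=params.nc_count_distribution)
            )
            nc_centres = _place_nanoclusters(centre, k, params.nc_spacing_nm, rng)
            has_presyn = bool(rng.random() < params.presyn_fraction)
            presyn_centre = None
            if has_presyn:
                offset = _unit_vector(rng) * params.presyn_offset_nm
                presyn_centre = (
                    float(centre[0] + offset[0]),
                    float(centre[1] + offset[1]),
                )
            has_pap = bool(rng.random() < params.tripartite_for(region))
            pap_centre = None
            if has_pap:
                offset = _unit_vector(rng) * params.pap_overlap_nm
                pap_centre = (
                    float(centre[0] + offset[0]),
                    float(centre[1] + offset[1]),
                )
            peak = params.punctum_peak_intensity * max(
                0.2, 1.0 + params.intensity_cv * rng.standard_normal()
            )
            entities.append(
                SynapseEntity(
                    id=len(entities) + 1,
                    psd_centre_nm=(float(centre[0]), float(centre[1])),
                    nc_centres_nm=nc_centres,
                    region=region,
                    has_presyn=has_presyn,
                    presyn_centre_nm=presyn_centre,
                    has_pap=has_pap,
                    pap_centre_nm=pap_centre,
                    peak_intensity=float(peak),
                )
            )
    return GroundTruthScene(entities=entities, atlas=atlas, params=params)


def _channel_sites(
    scene: GroundTruthScene, channel: str
) -> tuple[np.ndarray, np.ndarray, float]:
    """(centres_nm, peak_intensities, structure_diameter_nm) for a channel."""
    params = scene.params
    centres: list[tuple[float, float]] = []
    peaks: list[float] = []
    if channel == "psd95":
        for e in scene.entities:
            centres.extend(e.nc_centres_nm)
            peaks.extend([e.peak_intensity] * e.nc_count)
        structure = params.nc_diameter_nm
    elif channel == "vglut2":
        for e in scene.entities:
            if e.has_presyn and e.presyn_centre_nm is not None:
                centres.append(e.presyn_centre_nm)
                peaks.append(e.peak_intensity)
        structure = params.presyn_diameter_nm
    elif channel == "pap":
        for e in scene.entities:
            if e.has_pap and e.pap_centre_nm is not None:
                centres.append(e.pap_centre_nm)
                peaks.append(e.peak_intensity)
        structure = params.pap_diameter_nm
    else:
        raise ValueError(
            f"unknown channel {channel!r}; expected one of {_CHANNELS}"
        )
    return (
        np.asarray(centres, dtype=float).reshape(-1, 2),
        np.asarray(peaks, dtype=float),
        structure,
    )


def render(
    scene: GroundTruthScene,
    channel: str,
    optics: OpticsModel,
    pixel_size_nm: Optional[float] = None,
) -> ImagePlane:
    """Render one channel of a scene under the given optics.

    Each fluorophore site (NC centres for psd95, partner centres for the
    other channels) becomes a Gaussian spot whose FWHM is the larger of
    the PSF width and the physical structure size, at its planted peak
    intensity.  Constant background is added, then Poisson shot noise and
    Gaussian read noise (each skipped when its parameter is 0).  Output
    intensities are quantised to the 16-bit range, as a camera would.

    ``pixel_size_nm`` overrides the scene pixel size (e.g. 20 nm/px for
    STED frames of a scene defined on a 100 nm mapping grid); the field of
    view in nm is unchanged, so ground-truth coordinates stay valid.
    """
    params = scene.params
    px = pixel_size_nm if pixel_size_nm is not None else params.pixel_size_nm
    field_h_nm, field_w_nm = params.field_size_nm
    h = int(round(field_h_nm / px))
    w = int(round(field_w_nm / px))
    centres, peaks, structure = _channel_sites(scene, channel)
    fwhm_nm = max(optics.psf_fwhm_nm, structure)
    sigma_px = fwhm_nm / 2.354820045 / px
    img = np.zeros((h, w), dtype=np.float64)
    half = max(1, int(math.ceil(4.0 * sigma_px)))
    for (cy, cx), peak in zip(centres, peaks):
        r0 = cy / px - 0.5  # centre in pixel-index coordinates
        c0 = cx / px - 0.5
        rmin = max(0, int(math.floor(r0)) - half)
        rmax = min(h, int(math.ceil(r0)) + half + 1)
        cmin = max(0, int(math.floor(c0)) - half)
        cmax = min(w, int(math.ceil(c0)) + half + 1)
        if rmin >= rmax or cmin >= cmax:
            continue
        rr = np.arange(rmin, rmax, dtype=float) - r0
        cc = np.arange(cmin, cmax, dtype=float) - c0
        img[rmin:rmax, cmin:cmax] += peak * np.exp(
            -(rr[:, None] ** 2 + cc[None, :] ** 2) / (2.0 * sigma_px**2)
        )
    img += optics.background_level
    channel_idx = _CHANNELS.index(channel)
    modality_idx = 0 if optics.modality == "confocal" else 1
    rng = np.random.default_rng(
        np.random.SeedSequence([int(params.seed), 1, channel_idx, modality_idx])
    )
    if optics.poisson_scale > 0:
        img = rng.poisson(img * optics.poisson_scale) / optics.poisson_scale
    if optics.read_noise_sd > 0:
        img = img + rng.normal(0.0, optics.read_noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 65535)
    return ImagePlane(
        pixels=img, pixel_size_nm=px, channel=channel, bit_depth=16
    )


def inject_aggregates(image: ImagePlane, scene: GroundTruthScene) -> ImagePlane:
    """Add bright saturating lipofuscin-like discs and record their footprints.

    Disc count and diameter range come from the scene parameters; the
    footprints are appended to ``scene.artifacts`` so downstream tests can
    verify the maximum-size filter rejects them.  Zero count is a no-op.
    """
    params = scene.params
    if params.aggregate_count == 0:
        return image
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 2]))
    px = image.pixel_size_nm
    h, w = image.shape
    pixels = image.pixels.copy()
    lo, hi = params.aggregate_diameter_um
    rows, cols = np.mgrid[0:h, 0:w]
    for _ in range(params.aggregate_count):
        diameter_um = float(rng.uniform(lo, hi))
        radius_px = diameter_um * 1000.0 / 2.0 / px
        cy = rng.uniform(radius_px, h - radius_px)
        cx = rng.uniform(radius_px, w - radius_px)
        disc = (rows - cy) ** 2 + (cols - cx) ** 2 <= radius_px**2
        pixels[disc] = image.max_value
        scene.artifacts.append(
            Aggregate(
                centre_nm=((cy + 0.5) * px, (cx + 0.5) * px),
                diameter_um=diameter_um,
            )
        )
    return image.with_pixels(pixels)


def remove_tripartite(
    scene: GroundTruthScene,
    loss_fraction: RegionValue,
    seed: int,
) -> GroundTruthScene:
    """Delete a fraction of the ground-truth tripartite entities.

    Models a selective tripartite-synapse loss: non-tripartite entities
    are untouched.  ``loss_fraction`` may be a scalar or a per-region
    mapping.  Entity ids are renumbered; the atlas and params are shared
    with the source scene.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    if isinstance(loss_fraction, Mapping):
        loss = dict(loss_fraction)
    else:
        loss = {name: float(loss_fraction) for name in scene.atlas.region_names}
    kept: list[SynapseEntity] = []
    for e in scene.entities:
        if e.has_pap and rng.random() < loss.get(e.region, 0.0):
            continue
        kept.append(replace(e, id=len(kept) + 1))
    return GroundTruthScene(
        entities=kept, atlas=scene.atlas, params=scene.params, artifacts=list(scene.artifacts)
    )
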