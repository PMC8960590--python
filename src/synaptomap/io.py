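"""File formats and run configuration.

Images travel as single-plane 8/16-bit TIFF with the pixel size recorded
in the resolution tags (ImageJ-compatible, µm units); tables as CSV with
a provenance header (software version, config hash, seed) in ``#``
comment lines; configuration as YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .detection import DetectionParams
from .image import ImagePlane

__all__ = [
    "read_image",
    "write_image",
    "write_table",
    "read_table",
    "RunConfig",
    "load_config",
    "config_hash",
    "DETECTION_PROFILES",
]

#: Built-in detection profiles: ``mapping`` for 100 nm/px hemisection maps,
#: ``confocal``/``sted`` for 20 nm/px paired nanostructure frames.
DETECTION_PROFILES: dict[str, DetectionParams] = {
    "mapping": DetectionParams(
        background_radius_px=50.0,
        smooth_sigma_px=1.0,
        threshold_mode="moments",
        min_area_um2=0.04,
        max_area_um2=2.0,
    ),
    "confocal": DetectionParams(
        background_radius_px=50.0,
        smooth_sigma_px=1.5,
        threshold_mode="moments",
        min_area_um2=0.02,
        max_area_um2=2.0,
    ),
    # STED nanocluster detection thresholds at half the nominal punctum peak:
    # the equivalent diameter of a thresholded Gaussian spot is unbiased at
    # the half-maximum level, which is what NC size estimates need.
    "sted": DetectionParams(
        background_radius_px=25.0,
        smooth_sigma_px=1.0,
        threshold_mode="manual",
        manual_threshold=300.0,
        min_area_um2=0.005,
        max_area_um2=0.2,
    ),
}


def write_image(plane: ImagePlane, path) -> None:
    """Write a single-plane TIFF with the pixel size in resolution tags."""
    path = Path(path)
    dtype = np.uint8 if plane.bit_depth == 8 else np.uint16
    data = np.clip(np.round(plane.pixels), 0, plane.max_value).astype(dtype)
    px_um = plane.pixel_size_nm / 1000.0
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / px_um, 1.0 / px_um),
        metadata={"unit": "um", "Channel": plane.channel},
    )


def read_image(path, pixel_size_nm: Optional[float] = None, channel: str = "") -> ImagePlane:
    """Read a single-plane 8/16-bit TIFF into an :class:`ImagePlane`.

    The pixel size is taken from the TIFF resolution tags; pass
    ``pixel_size_nm`` to override or to supply it when the file has no
    calibration.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        if data.ndim != 2:
            raise ValueError(f"{path}: expected a single-plane 2-D TIFF")
        if data.dtype == np.uint8:
            bit_depth = 8
        elif data.dtype == np.uint16:
            bit_depth = 16
        else:
            raise ValueError(f"{path}: unsupported dtype {data.dtype}; need uint8/uint16")
        if pixel_size_nm is None:
            res = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            ij_unit = (tif.imagej_metadata or {}).get("unit") if tif.is_imagej else None
            if res is None or res.value[0] == 0:
                raise ValueError(
                    f"{path}: no pixel size in TIFF metadata; pass pixel_size_nm "
                    "explicitly or set it in the run config"
                )
            px_per_unit = res.value[0] / res.value[1]
            if ij_unit == "um" or ij_unit == "micron":
                pixel_size_nm = 1000.0 / px_per_unit
            elif unit is not None and getattr(unit.value, "name", "") == "CENTIMETER":
                pixel_size_nm = 1e7 / px_per_unit
            elif unit is not None and getattr(unit.value, "name", "") == "INCH":
                pixel_size_nm = 2.54e7 / px_per_unit
            else:
                raise ValueError(
                    f"{path}: cannot interpret resolution unit; pass pixel_size_nm"
                )
    return ImagePlane(
        pixels=data.astype(np.float64),
        pixel_size_nm=float(pixel_size_nm),
        channel=channel,
        bit_depth=bit_depth,
    )


def config_hash(obj: Any) -> str:
    """Stable short hash of any JSON-serialisable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_table(
    df: pd.DataFrame,
    path,
    seed: Optional[int] = None,
    cfg_hash: Optional[str] = None,
) -> None:
    """Write a CSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# synaptomap {__version__}\n")
        if cfg_hash is not None:
            fh.write(f"# config_hash={cfg_hash}\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run.

    ``workflow`` selects the orchestration: ``mapping`` (simulate a
    two-genotype cohort, detect three channels, classify, map, test) or
    ``nano`` (paired confocal/STED fields, NC assignment, subtype
    frequencies).  ``scene``/``optics`` blocks are keyword arguments for
    :class:`~synaptomap.synthetic.SceneParams` and
    :class:`~synaptomap.synthetic.OpticsModel`; ``detection`` maps channel
    or profile names onto :class:`~synaptomap.detection.DetectionParams`
    overrides.
    """

    workflow: str = "mapping"
    seed: int = 0
    out_dir: str = "synaptomap_out"
    scene: dict = field(default_factory=dict)
    optics: dict = field(default_factory=dict)
    detection: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)
    nano: dict = field(default_factory=dict)
    mode: str = "triple"
    atlas_layout: str = "bands"
    pixel_size_nm: Optional[float] = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.workflow not in ("mapping", "nano", "simulate"):
            raise ValueError(f"unknown workflow {self.workflow!r}")
        if self.mode not in ("triple", "psd_pap"):
            raise ValueError(f"unknown classification mode {self.mode!r}")

    def detection_params(self, profile: str) -> DetectionParams:
        base = DETECTION_PROFILES.get(profile, DETECTION_PROFILES["mapping"])
        overrides = dict(self.detection.get(profile, {}))
        if overrides:
            return DetectionParams(**{**asdict(base), **overrides})
        return base

    def hash(self) -> str:
        """Hash of the analysis configuration (output location and logging
        verbosity excluded: they do not affect results)."""
        payload = asdict(self)
        payload.pop("out_dir", None)
        payload.pop("log_level", None)
        return config_hash(payload)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise ValueError(f"{path}: config must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "scene" in raw and "field_size_px" in raw["scene"]:
        raw["scene"]["field_size_px"] = tuple(raw["scene"]["field_size_px"])
    return RunConfig(**raw)
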