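"""Serial-section image stacks: spatial data model and file I/O.

An :class:`ImageStack` is a single-channel voxel grid indexed
``(section, row, col)`` with physical voxel dimensions carried by a
:class:`VoxelGeometry`.  A :class:`RegionOfInterest` groups the channels
imaged at one location (typically SYP / PSD95 / OC on 15-30 sequential
70 nm sections).  Stacks round-trip losslessly through multi-page
grayscale TIFF; a YAML sidecar manifest maps channels to files and records
geometry and provenance, and quantification results serialize to CSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, TYPE_CHECKING

import numpy as np
import pandas as pd
import tifffile
import yaml

if TYPE_CHECKING:  # pragma: no cover
    from .quantify import QuantResult

#: Section-count range of the standard acquisition protocol; inputs outside
#: it are accepted with a warning.
SECTION_RANGE = (15, 30)


class StackIOError(ValueError):
    """Raised for unreadable or structurally inconsistent stack files."""


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical voxel dimensions in micrometres.

    ``dz`` defaults to 0.070 um, the thickness of ultrathin serial
    sections; ``dx``/``dy`` default to 0.1 um, typical for a 63x/1.4 NA
    system, and are always configurable because the camera pixel pitch is
    acquisition-specific.
    """

    dx: float = 0.1
    dy: float = 0.1
    dz: float = 0.070

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0 and self.dz > 0):
            raise ValueError(f"voxel dimensions must be strictly positive, got {self}")

    @property
    def voxel_volume_um3(self) -> float:
        return self.dx * self.dy * self.dz

    def to_dict(self) -> dict:
        return {"dx": self.dx, "dy": self.dy, "dz": self.dz}

    @classmethod
    def from_dict(cls, d: Mapping) -> "VoxelGeometry":
        return cls(dx=float(d["dx"]), dy=float(d["dy"]), dz=float(d["dz"]))


@dataclass
class ImageStack:
    """Single-channel serial-section voxel grid.

    ``voxels`` is indexed ``(section, row, col)`` and must be non-negative;
    integer input is preserved as written, processing stages promote to
    floating point.
    """

    voxels: np.ndarray
    geometry: VoxelGeometry
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D (section, row, col), got shape {self.voxels.shape}")
        if self.voxels.size and self.voxels.min() < 0:
            raise ValueError("voxel intensities must be non-negative")
        lo, hi = SECTION_RANGE
        if not lo <= self.n_sections <= hi:
            warnings.warn(
                f"stack {self.channel_name!r} has {self.n_sections} sections, outside "
                f"the standard {lo}-{hi} section acquisition range",
                UserWarning,
                stacklevel=2,
            )

    @property
    def n_sections(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def with_voxels(self, voxels: np.ndarray) -> "ImageStack":
        """Copy of this stack with new voxel data (geometry/name kept)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            return replace(self, voxels=voxels)


@dataclass
class RegionOfInterest:
    """The channels imaged at one location of one slice.

    All member stacks share shape and geometry; ``treatment_label`` follows
    the study design (control / phosphoramidon / bace1i / ab_pos / ab_neg /
    other).
    """

    case_id: str
    treatment_label: str
    roi_index: int
    channels: dict[str, ImageStack] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {s.shape for s in self.channels.values()}
        geoms = {s.geometry for s in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"ROI channels have inconsistent shapes: {shapes}")
        if len(geoms) > 1:
            raise ValueError(f"ROI channels have inconsistent geometries: {geoms}")

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    @property
    def geometry(self) -> VoxelGeometry:
        return next(iter(self.channels.values())).geometry

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    def map_channels(self, fn) -> "RegionOfInterest":
        """Apply ``fn(ImageStack) -> ImageStack`` to every channel."""
        return replace(self, channels={name: fn(stack) for name, stack in self.channels.items()})


def read_stack(path: str | Path, geometry: VoxelGeometry, channel_name: str = "") -> ImageStack:
    """Read a multi-page grayscale TIFF into an :class:`ImageStack`.

    Page count becomes ``n_sections``; intensities are preserved losslessly.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            pages = [p.asarray() for p in tif.pages]
    except (OSError, tifffile.TiffFileError) as exc:
        raise StackIOError(f"cannot read TIFF {path}: {exc}") from exc
    if not pages:
        raise StackIOError(f"TIFF {path} contains no pages")
    shapes = {p.shape for p in pages}
    if len(shapes) > 1:
        raise StackIOError(f"TIFF {path} pages have inconsistent shapes: {shapes}")
    return ImageStack(np.stack(pages), geometry=geometry, channel_name=channel_name)


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as a multi-page grayscale TIFF (lossless for integer dtypes)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(stack.voxels))
    return path


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a binary mask as an 8-bit multi-page TIFF (0/255)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))
    return path


def read_roi(manifest_path: str | Path) -> RegionOfInterest:
    """Load an ROI from its YAML sidecar manifest.

    The manifest records case/treatment identity, geometry, and a
    channel -> TIFF-file map (paths relative to the manifest).
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        man = yaml.safe_load(fh)
    geometry = VoxelGeometry.from_dict(man["geometry"])
    channels = {
        name: read_stack(manifest_path.parent / rel, geometry, channel_name=name)
        for name, rel in man["channels"].items()
    }
    return RegionOfInterest(
        case_id=str(man["case_id"]),
        treatment_label=str(man.get("treatment", "other")),
        roi_index=int(man.get("roi_index", 0)),
        channels=channels,
    )


def write_roi(roi: RegionOfInterest, out_dir: str | Path, dtype=None) -> Path:
    """Write every channel as a TIFF plus the YAML sidecar manifest.

    Returns the manifest path.  ``dtype`` optionally casts voxel data on
    write (e.g. ``np.uint16`` for simulator float output).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    channel_files = {}
    for name, stack in roi.channels.items():
        fname = f"{name}.tif"
        data = stack.voxels if dtype is None else np.clip(np.round(stack.voxels), 0, np.iinfo(dtype).max).astype(dtype)
        tifffile.imwrite(out_dir / fname, data)
        channel_files[name] = fname
    manifest = {
        "case_id": roi.case_id,
        "treatment": roi.treatment_label,
        "roi_index": roi.roi_index,
        "geometry": roi.geometry.to_dict(),
        "channels": channel_files,
    }
    manifest_path = out_dir / "roi.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest_path


def write_quant_table(results: "Iterable[QuantResult]", path: str | Path) -> Path:
    """Write quantification results as a tidy CSV.

    One row per (ROI, channel or channel pair, metric) with a deterministic
    column and row order so identical runs are byte-identical; values
    round-trip through :func:`read_quant_table` at full precision.
    """
    results = list(results)
    if not results:
        raise ValueError("no results to write")
    rows: list[dict] = []
    for res in results:
        rows.extend(res.to_rows())
    df = pd.DataFrame(rows, columns=["case_id", "treatment", "roi_index", "subject", "metric", "value"])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_quant_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
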