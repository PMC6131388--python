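"""Volume, landmark, mask and report I/O.

All in-memory geometry uses one fixed anatomical frame:

* ``X`` increases toward the subject's **left**,
* ``Y`` increases toward **anterior**,
* ``Z`` increases toward **superior**,

with world coordinates in millimetres.  Voxel ``(i, j, k)`` of a
:class:`Volume3D` sits at ``origin + index * spacing`` (0-based indices).
Format readers normalise whatever orientation is stored on disk into this
frame, so downstream code never needs to reason about header conventions.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import SimpleITK as sitk

__all__ = [
    "Volume3D",
    "Image2D",
    "BinaryVolume3D",
    "LandmarkSet",
    "SplineRecord",
    "AnalysisReport",
    "LANDMARK_NAMES",
    "FormatError",
    "MetadataError",
    "SchemaError",
    "BoundsError",
    "load_volume",
    "save_volume",
    "load_landmarks",
    "save_landmarks",
    "load_mask2d",
    "save_mask2d",
    "load_report",
    "save_report",
]


class FormatError(ValueError):
    """File could not be read as any supported volume/image format."""


class MetadataError(ValueError):
    """Required header metadata (e.g. voxel spacing) is missing or invalid."""


class SchemaError(ValueError):
    """A structured file (landmarks, report) violates its schema."""


class BoundsError(ValueError):
    """A point lies outside the stated volume bounds."""


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

def _as_tuple3(v) -> tuple[float, float, float]:
    t = tuple(float(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected 3 components, got {len(t)}")
    return t


@dataclass
class Volume3D:
    """A 3-D scalar grid in the package's anatomical frame.

    ``data`` is indexed ``[i, j, k]`` along (X, Y, Z).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("Volume3D data must be 3-dimensional")
        if any(n < 2 for n in self.data.shape):
            raise ValueError("Volume3D needs at least 2 voxels per axis")
        self.spacing = _as_tuple3(self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise MetadataError("voxel spacing components must be > 0")
        self.origin = _as_tuple3(self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centres along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.data.shape[axis])

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.asarray(self.origin, float)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return lo, hi

    def contains_point(self, p: Sequence[float]) -> bool:
        lo, hi = self.world_bounds()
        p = np.asarray(p, float)
        return bool(np.all(p >= lo - 1e-9) and np.all(p <= hi + 1e-9))

    def index_of(self, p: Sequence[float]) -> tuple[int, int, int]:
        """Nearest voxel index of a world point."""
        idx = np.round((np.asarray(p, float) - np.asarray(self.origin)) / np.asarray(self.spacing))
        return tuple(int(v) for v in idx)

    def copy_with(self, data: np.ndarray) -> "Volume3D":
        return Volume3D(data, self.spacing, self.origin)


@dataclass
class BinaryVolume3D:
    """Boolean companion of :class:`Volume3D` (same frame and geometry)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        self.spacing = _as_tuple3(self.spacing)
        self.origin = _as_tuple3(self.origin)

    @property
    def shape(self):
        return self.data.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.data.shape[axis])


@dataclass
class Image2D:
    """A 2-D image with pixel spacing and origin in mm.

    ``axes`` names the two world axes the image rows/columns run along,
    e.g. ``("X", "Y")`` for an axial projection.
    """

    data: np.ndarray
    spacing: tuple[float, float]
    origin: tuple[float, float] = (0.0, 0.0)
    axes: tuple[str, str] = ("X", "Y")

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("Image2D data must be 2-dimensional")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self):
        return self.data.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.data.shape[axis])

    def pixel_area(self) -> float:
        return self.spacing[0] * self.spacing[1]


LANDMARK_NAMES = (
    "frankfort_orbit",
    "frankfort_meatus",
    "coronal_right",
    "coronal_left",
    "occlusal_anterior",
    "occlusal_posterior",
    "condyle_a",
    "condyle_b",
    "canine_right",
    "canine_left",
)


@dataclass
class LandmarkSet:
    """The ten operator-selected points, in world mm.

    Frankfort orbit/meatus drive reorientation; the coronal and occlusal
    pairs define the two half-plane removals; the condyle pair positions
    the condyle-cap ellipses; the canine pair is the distal-contact
    reference of the dental arch.
    """

    points: dict[str, np.ndarray]

    def __post_init__(self):
        missing = [k for k in LANDMARK_NAMES if k not in self.points]
        if missing:
            raise SchemaError(f"landmark set missing keys: {missing}")
        extra = [k for k in self.points if k not in LANDMARK_NAMES]
        if extra:
            raise SchemaError(f"landmark set has unknown keys: {extra}")
        self.points = {k: np.asarray(self.points[k], float).reshape(3) for k in LANDMARK_NAMES}
        if not self.points["canine_right"][0] < self.points["canine_left"][0]:
            raise SchemaError(
                "canine_right must lie at smaller X than canine_left "
                "(X increases toward the subject's left)"
            )

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def transformed(self, fn) -> "LandmarkSet":
        """Apply a point transform (world mm -> world mm) to every landmark."""
        return LandmarkSet({k: np.asarray(fn(v), float) for k, v in self.points.items()})

    def check_bounds(self, vol: Volume3D) -> None:
        for name, p in self.points.items():
            if not vol.contains_point(p):
                raise BoundsError(f"landmark {name!r} at {p.tolist()} is outside the volume bounds")


@dataclass
class SplineRecord:
    """Serializable piecewise-cubic description of one fitted coordinate."""

    name: str
    breaks: list[float]
    coefficients: list[list[float]]  # one inner list of 4 per cubic piece

    def __post_init__(self):
        self.breaks = [float(b) for b in self.breaks]
        self.coefficients = [[float(c) for c in row] for row in self.coefficients]
        for row in self.coefficients:
            if len(row) != 4:
                raise SchemaError("each spline piece must carry exactly 4 coefficients")
        if self.breaks and len(self.coefficients) != len(self.breaks) - 1:
            raise SchemaError("number of pieces must be len(breaks) - 1")


@dataclass
class AnalysisReport:
    """End-of-pipeline summary of the average arch and its focal trough."""

    threshold: float
    mean_individual_area_mm2: float
    average_arch_area_mm2: float
    anterior_min_thickness_mm: float
    posterior_min_thickness_mm: float
    transition_lateral_mm: float
    transition_posterior_mm: float
    transition_slope_deg: float
    splines: list[SplineRecord] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisReport":
        try:
            splines = [SplineRecord(**s) for s in d.get("splines", [])]
            kwargs = {
                k: d[k]
                for k in (
                    "threshold",
                    "mean_individual_area_mm2",
                    "average_arch_area_mm2",
                    "anterior_min_thickness_mm",
                    "posterior_min_thickness_mm",
                    "transition_lateral_mm",
                    "transition_posterior_mm",
                    "transition_slope_deg",
                )
            }
        except KeyError as exc:
            raise SchemaError(f"report missing field {exc}") from exc
        return cls(splines=splines, metadata=d.get("metadata", {}), **kwargs)


# --------------------------------------------------------------------------
# volumes
# --------------------------------------------------------------------------

# SimpleITK's world frame is LPS.  Our frame is LAS, so the Y world
# coordinate flips sign and the in-memory array (z, y, x) is transposed.
_LAS = "LAS"


def _sitk_to_volume(img: sitk.Image) -> Volume3D:
    if img.GetDimension() != 3:
        raise FormatError("expected a 3-D image")
    img = sitk.DICOMOrient(img, _LAS)
    arr = sitk.GetArrayFromImage(img)  # (k, j, i)
    data = np.ascontiguousarray(arr.transpose(2, 1, 0))
    spacing = img.GetSpacing()
    if any(s <= 0 for s in spacing):
        raise MetadataError("header reports non-positive voxel spacing")
    ox, oy, oz = img.GetOrigin()  # LPS mm
    origin = (ox, -oy, oz)
    return Volume3D(data, spacing, origin)


def _volume_to_sitk(vol: Volume3D) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(vol.spacing))
    ox, oy, oz = vol.origin
    img.SetOrigin((ox, -oy, oz))
    img.SetDirection((1.0, 0.0, 0.0, 0.0, -1.0, 0.0, 0.0, 0.0, 1.0))
    return img


def load_volume(path: str | Path) -> Volume3D:
    """Read a DICOM series directory, NIfTI file or MetaImage file.

    The returned volume is reoriented into the package frame; spacing and
    origin come from the header.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file or directory: {path}")
    try:
        if path.is_dir():
            reader = sitk.ImageSeriesReader()
            series = reader.GetGDCMSeriesFileNames(str(path))
            if not series:
                raise FormatError(f"no DICOM series found in directory {path}")
            reader.SetFileNames(series)
            img = reader.Execute()
        else:
            img = sitk.ReadImage(str(path))
    except FormatError:
        raise
    except Exception as exc:  # pragma: no cover - message depends on ITK
        raise FormatError(f"could not read volume from {path}: {exc}") from exc
    return _sitk_to_volume(img)


def save_volume(vol: Volume3D, path: str | Path) -> None:
    """Write a volume as NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd)."""
    try:
        sitk.WriteImage(_volume_to_sitk(vol), str(path))
    except Exception as exc:
        raise OSError(f"could not write volume to {path}: {exc}") from exc


# --------------------------------------------------------------------------
# landmarks
# --------------------------------------------------------------------------

def load_landmarks(path: str | Path, volume: Volume3D | None = None) -> LandmarkSet:
    """Read a flat JSON object ``{name: [x, y, z]}`` of the 10 points (mm).

    If ``volume`` is given, every point is checked against its bounds.
    """
    try:
        with open(path) as fh:
            raw = json.load(fh)
    except OSError as exc:
        raise FormatError(f"could not read landmark file {path}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise SchemaError(f"landmark file {path} is not valid JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise SchemaError("landmark file must be a JSON object {name: [x,y,z]}")
    for name, xyz in raw.items():
        if not (isinstance(xyz, (list, tuple)) and len(xyz) == 3):
            raise SchemaError(f"landmark {name!r} must be a 3-element [x, y, z] list")
    lm = LandmarkSet({k: np.asarray(v, float) for k, v in raw.items()})
    if volume is not None:
        lm.check_bounds(volume)
    return lm


def save_landmarks(lm: LandmarkSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({k: list(map(float, v)) for k, v in lm.points.items()}, fh, indent=2)


# --------------------------------------------------------------------------
# 2-D masks
# --------------------------------------------------------------------------

def save_mask2d(img: Image2D, path: str | Path) -> None:
    """Write a binary 2-D mask as PNG/TIFF plus a JSON geometry sidecar."""
    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(path, (np.asarray(img.data, bool).T.astype(np.uint8) * 255))
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump(
            {"spacing": list(img.spacing), "origin": list(img.origin), "axes": list(img.axes)},
            fh,
        )


def load_mask2d(path: str | Path) -> Image2D:
    import imageio.v3 as iio

    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise FormatError(f"could not read mask image {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[..., 0]
    data = (arr.T > 0)
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
        return Image2D(data, tuple(meta["spacing"]), tuple(meta["origin"]), tuple(meta["axes"]))
    return Image2D(data, (1.0, 1.0))


# --------------------------------------------------------------------------
# reports
# --------------------------------------------------------------------------

def save_report(report: AnalysisReport, path: str | Path) -> None:
    try:
        with open(path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
    except OSError as exc:
        raise OSError(f"could not write report to {path}: {exc}") from exc


def load_report(path: str | Path) -> AnalysisReport:
    try:
        with open(path) as fh:
            raw = json.load(fh)
    except OSError as exc:
        raise FormatError(f"could not read report {path}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise SchemaError(f"report file {path} is not valid JSON: {exc}") from exc
    return AnalysisReport.from_dict(raw)
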