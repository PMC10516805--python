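"""Reading and writing of micrographs, label rasters, HDF5 containers and CSV reports.

Micrographs are reflective-light colour images of TRAP-stained osteoclast
cultures on dentine.  All pixel data is 8-bit; spatial calibration (physical
edge length of one pixel, in micrometres) travels with the image rather than
being re-entered downstream.  The default calibration of 2.031 µm/pixel
corresponds to a ×5 objective on the acquisition setup the pipeline was
designed around.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import DomainError, FormatError

#: Physical edge length of one pixel at ×5 magnification, µm.
DEFAULT_CALIBRATION_UM = 2.031

#: Minimum area for a connected purple object to count as a mature osteoclast, µm².
DEFAULT_MIN_OSTEOCLAST_AREA_UM2 = 825.0


@dataclass(frozen=True)
class ClassEntry:
    id: int
    name: str
    display_colour: tuple[int, int, int]


@dataclass(frozen=True)
class ClassTable:
    """Ordered semantic classes with display colours for exported segmentations."""

    entries: tuple[ClassEntry, ...]

    def __post_init__(self):
        ids = [e.id for e in self.entries]
        if ids != list(range(1, len(ids) + 1)):
            raise DomainError(f"class ids must be contiguous from 1, got {ids}")
        colours = {e.display_colour for e in self.entries}
        if len(colours) != len(self.entries):
            raise DomainError("display colours must be pairwise distinct")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(e.id for e in self.entries)

    def name_of(self, class_id: int) -> str:
        for e in self.entries:
            if e.id == class_id:
                return e.name
        raise DomainError(f"unknown class id {class_id}")

    def colour_of(self, class_id: int) -> tuple[int, int, int]:
        for e in self.entries:
            if e.id == class_id:
                return e.display_colour
        raise DomainError(f"unknown class id {class_id}")


def default_class_table() -> ClassTable:
    """The canonical four-class table with the published LUT colours.

    Dentine is blue, pre-osteoclasts green, resorption pits yellow and mature
    osteoclasts red in exported segmentation overlays.
    """
    return ClassTable(
        (
            ClassEntry(1, "dentine", (0, 0, 255)),
            ClassEntry(2, "pre-osteoclast", (0, 255, 0)),
            ClassEntry(3, "resorption", (255, 255, 0)),
            ClassEntry(4, "osteoclast", (255, 0, 0)),
        )
    )


@dataclass
class RasterImage:
    """A calibrated 3-channel 8-bit micrograph."""

    pixels: np.ndarray  # (H, W, 3) uint8
    calibration_um: float = DEFAULT_CALIBRATION_UM
    source_path: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise FormatError(f"expected (H, W, 3) pixel grid, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise FormatError("zero-area image")
        if px.dtype != np.uint8:
            raise FormatError(f"expected 8-bit channels, got dtype {px.dtype}")
        if not self.calibration_um > 0:
            raise DomainError("calibration must be positive")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    @property
    def pixel_area_um2(self) -> float:
        return self.calibration_um**2


@dataclass
class AnnotationMap:
    """Sparse brushstroke-style training labels (0 = unlabeled, k = class id)."""

    labels: np.ndarray  # (H, W) small non-negative ints
    class_table: ClassTable = field(default_factory=default_class_table)

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise DomainError(f"labels must be 2D, got shape {lab.shape}")
        present = set(np.unique(lab).tolist()) - {0}
        valid = set(self.class_table.ids)
        if not present <= valid:
            raise DomainError(f"labels contain unknown class ids {sorted(present - valid)}")
        self.labels = lab.astype(np.uint8)

    def pixels_per_class(self) -> dict[int, int]:
        return {cid: int(np.sum(self.labels == cid)) for cid in self.class_table.ids}


def _promote_to_rgb(arr: np.ndarray, path: str) -> np.ndarray:
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"{path}: unsupported channel layout {arr.shape}")
    if arr.dtype != np.uint8:
        raise FormatError(f"{path}: unsupported bit depth {arr.dtype}, only 8-bit supported")
    if arr.shape[0] == 0 or arr.shape[1] == 0:
        raise FormatError(f"{path}: zero-area image")
    return arr


def read_image(path: str, calibration_um: float = DEFAULT_CALIBRATION_UM) -> RasterImage:
    """Read a TIFF, PNG or HDF5 micrograph with the stated spatial calibration.

    Grayscale inputs are promoted to three identical channels; pixel values are
    preserved bit-exact.  Bit depths above 8 per channel are rejected rather
    than rescaled because the classifier's features are defined on 8-bit
    statistics.
    """
    if not os.path.exists(path):
        raise IOError(f"image file not found: {path}")
    ext = os.path.splitext(path)[1].lower()
    if ext in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "data" not in f:
                raise FormatError(f"{path}: HDF5 file lacks a 'data' dataset")
            ds = f["data"]
            arr = ds[...]
            stored = ds.attrs.get("calibration_um")
            if stored is not None:
                calibration_um = float(stored)
    elif ext in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif ext == ".png":
        arr = iio.imread(path)
    else:
        raise FormatError(f"{path}: unsupported extension {ext!r}")
    return RasterImage(_promote_to_rgb(np.asarray(arr), path), calibration_um, source_path=path)


def write_image(image: RasterImage, path: str) -> str:
    """Write a RasterImage as TIFF or PNG (chosen by extension)."""
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        tifffile.imwrite(path, image.pixels)
    elif ext == ".png":
        iio.imwrite(path, image.pixels)
    else:
        raise FormatError(f"{path}: unsupported extension {ext!r}")
    return path


def convert_to_hdf5(image: RasterImage, path: str) -> str:
    """Write the pixel grid into an HDF5 container.

    Layout: one gzip-compressed dataset named ``data`` with axis order
    (y, x, c); the calibration is stored as the ``calibration_um`` attribute.
    ``read_image`` on the result reproduces the image bit-exact.
    """
    try:
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("data", data=image.pixels, compression="gzip")
            ds.attrs["calibration_um"] = float(image.calibration_um)
    except OSError as exc:
        raise IOError(f"cannot write HDF5 file {path}: {exc}") from exc
    return path


def write_segmentation_image(seg, class_table: ClassTable, path: str) -> str:
    """Export a label map as a colour raster using the class display colours.

    The colour mapping is bijective over the class table, so the label map is
    recoverable from the exported image (see :func:`read_segmentation_image`).
    """
    labels = np.asarray(seg.labels if hasattr(seg, "labels") else seg)
    present = set(np.unique(labels).tolist())
    valid = set(class_table.ids)
    if not present <= valid:
        raise DomainError(f"segmentation contains ids absent from class table: {sorted(present - valid)}")
    lut = np.zeros((max(valid) + 1, 3), dtype=np.uint8)
    for e in class_table:
        lut[e.id] = e.display_colour
    rgb = lut[labels]
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        tifffile.imwrite(path, rgb)
    elif ext == ".png":
        iio.imwrite(path, rgb)
    else:
        raise FormatError(f"{path}: unsupported extension {ext!r}")
    return path


def read_segmentation_image(path: str, class_table: ClassTable) -> np.ndarray:
    """Invert :func:`write_segmentation_image`: recover the label map from colours."""
    rgb = _promote_to_rgb(np.asarray(iio.imread(path) if path.lower().endswith(".png") else tifffile.imread(path)), path)
    labels = np.zeros(rgb.shape[:2], dtype=np.uint8)
    matched = np.zeros(rgb.shape[:2], dtype=bool)
    for e in class_table:
        hit = np.all(rgb == np.array(e.display_colour, dtype=np.uint8), axis=2)
        labels[hit] = e.id
        matched |= hit
    if not matched.all():
        raise FormatError(f"{path}: colours present that match no class in the table")
    return labels


def write_annotation_raster(annotation: AnnotationMap, path: str) -> str:
    """Write sparse labels as a single-channel PNG/TIFF (values 0..K)."""
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        tifffile.imwrite(path, annotation.labels)
    elif ext == ".png":
        iio.imwrite(path, annotation.labels)
    else:
        raise FormatError(f"{path}: unsupported extension {ext!r}")
    return path


def read_annotation_raster(path: str, class_table: ClassTable | None = None) -> AnnotationMap:
    if not os.path.exists(path):
        raise IOError(f"annotation file not found: {path}")
    arr = np.asarray(iio.imread(path) if path.lower().endswith(".png") else tifffile.imread(path))
    if arr.ndim == 3:  # some writers store single-channel as (H, W, 1)
        arr = arr[:, :, 0]
    return AnnotationMap(arr, class_table or default_class_table())


_CSV_COLUMNS = (
    "image_id",
    "osteoclast_count",
    "osteoclast_area_mm2",
    "resorption_area_mm2",
    "preosteoclast_area_mm2",
    "dentine_area_mm2",
    "calibration_um",
    "threshold_um2",
)


def write_endpoint_csv(reports, path: str) -> str:
    """Write per-image endpoint measurements, one row per image.

    Values are printed to 6 significant digits with a ``.`` decimal separator
    and comma delimiter, locale-independent.
    """
    reports = list(reports)
    if not reports:
        raise DomainError("empty report list")
    lines = [",".join(_CSV_COLUMNS)]
    for r in reports:
        row = [
            str(r.image_id),
            str(r.osteoclast_count),
            format(r.area_mm2[4], ".6g"),
            format(r.area_mm2[3], ".6g"),
            format(r.area_mm2[2], ".6g"),
            format(r.area_mm2[1], ".6g"),
            format(r.calibration_um, ".6g"),
            format(r.threshold_um2, ".6g"),
        ]
        lines.append(",".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path
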