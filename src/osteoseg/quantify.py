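"""Endpoint extraction from a segmentation: osteoclast counts and class areas.

Osteoclast number is obtained by connected-component analysis of the
osteoclast class followed by a minimum-size filter: a purple object only
counts as a mature osteoclast if its area reaches 825 µm² (inclusive), the
calibrated size threshold separating mature cells from pre-osteoclasts.
Areas are reported per class in µm² and mm²; the four class areas always sum
to the full image area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .classifier import SegmentationMap
from .errors import DomainError
from .io import DEFAULT_MIN_OSTEOCLAST_AREA_UM2

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}

OSTEOCLAST_CLASS = 4


@dataclass(frozen=True)
class ObjectRecord:
    """One connected component of a single class."""

    object_id: int
    class_id: int
    pixel_count: int
    area_um2: float
    centroid: tuple[float, float]  # (row, col)
    bbox: tuple[int, int, int, int]  # top, left, bottom, right (exclusive)


@dataclass
class EndpointReport:
    """Per-image quantification endpoints."""

    image_id: str
    osteoclast_count: int
    area_um2: dict[int, float]  # class id -> area
    area_mm2: dict[int, float]
    objects: list[ObjectRecord] = field(default_factory=list)
    threshold_um2: float = DEFAULT_MIN_OSTEOCLAST_AREA_UM2
    calibration_um: float = 0.0


def label_components(seg: SegmentationMap, class_id: int, connectivity: int = 8) -> list[ObjectRecord]:
    """Connected components of one class, in raster-scan order of first pixel.

    ``connectivity`` is 4 (edge-adjacent) or 8 (edge- or corner-adjacent).
    """
    if class_id not in seg.class_table.ids:
        raise DomainError(f"invalid class id {class_id}")
    if connectivity not in _STRUCTURES:
        raise DomainError(f"connectivity must be 4 or 8, got {connectivity}")
    mask = seg.labels == class_id
    lab, n = ndi.label(mask, structure=_STRUCTURES[connectivity])
    if n == 0:
        return []
    # scipy assigns labels in raster order of first pixel already; make the
    # ordering explicit so object ids are a documented contract
    flat = lab.ravel()
    first_idx = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    np.minimum.at(first_idx, flat[nz], nz)
    order = np.argsort(first_idx[1:], kind="stable")
    pixel_area = seg.calibration_um**2
    counts = np.bincount(flat, minlength=n + 1)
    centroids = ndi.center_of_mass(mask, lab, index=np.arange(1, n + 1))
    slices = ndi.find_objects(lab)
    records = []
    for new_id, old in enumerate(order, start=1):
        comp = int(old) + 1
        sl = slices[comp - 1]
        records.append(
            ObjectRecord(
                object_id=new_id,
                class_id=class_id,
                pixel_count=int(counts[comp]),
                area_um2=float(counts[comp]) * pixel_area,
                centroid=(float(centroids[comp - 1][0]), float(centroids[comp - 1][1])),
                bbox=(sl[0].start, sl[1].start, sl[0].stop, sl[1].stop),
            )
        )
    return records


def apply_size_threshold(objects: list[ObjectRecord], min_area_um2: float) -> list[ObjectRecord]:
    """Retain objects with area ≥ ``min_area_um2`` (inclusive), preserving order."""
    if min_area_um2 < 0:
        raise DomainError("size threshold must be non-negative")
    return [o for o in objects if o.area_um2 >= min_area_um2]


def quantify_endpoints(
    seg: SegmentationMap,
    threshold_um2: float = DEFAULT_MIN_OSTEOCLAST_AREA_UM2,
    image_id: str = "",
    connectivity: int = 8,
) -> EndpointReport:
    """Compute osteoclast number and per-class areas for one segmentation.

    Objects touching the image border are retained; no morphological cleanup
    is applied before counting.
    """
    pixel_area = seg.calibration_um**2
    area_um2 = {}
    for cid in seg.class_table.ids:
        area_um2[cid] = float(np.sum(seg.labels == cid)) * pixel_area
    objects = apply_size_threshold(
        label_components(seg, OSTEOCLAST_CLASS, connectivity), threshold_um2
    )
    return EndpointReport(
        image_id=image_id,
        osteoclast_count=len(objects),
        area_um2=area_um2,
        area_mm2={cid: a / 1e6 for cid, a in area_um2.items()},
        objects=objects,
        threshold_um2=float(threshold_um2),
        calibration_um=float(seg.calibration_um),
    )
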