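"""Manual grid-overlay morphometry and method-agreement statistics.

The manual comparator is stereological dot counting: a uniform 16 × 12 point
lattice is overlaid on the image and the class beneath each point is tallied;
each point stands for 0.034 mm² of dentine surface.  Agreement between manual
and automated measurements is summarised by the Pearson correlation and a
simple least-squares line, and operator repeatability by per-item coefficients
of variation (sample SD over mean, in percent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DomainError

#: Dentine-surface area represented by one grid point, mm².
DEFAULT_POINT_AREA_MM2 = 0.034


@dataclass(frozen=True)
class GridOverlay:
    """Uniform counting lattice; points sit at cell centres so all lie inside the image."""

    rows: int = 12
    cols: int = 16
    per_point_area_mm2: float = DEFAULT_POINT_AREA_MM2

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise DomainError("grid must have at least one row and column")
        if not self.per_point_area_mm2 > 0:
            raise DomainError("per-point area must be positive")

    def point_coords(self, shape: tuple[int, int]) -> list[tuple[int, int]]:
        """Pixel positions of the rows × cols points on an image of the given shape."""
        h, w = shape
        if h < self.rows or w < self.cols:
            raise DomainError(f"grid {self.rows}x{self.cols} does not fit raster {shape}")
        return [
            (int((i + 0.5) * h / self.rows), int((j + 0.5) * w / self.cols))
            for i in range(self.rows)
            for j in range(self.cols)
        ]


def overlay_and_count(mask, grid: GridOverlay, target_class: int = 1) -> int:
    """Number of grid points whose underlying pixel belongs to ``target_class``.

    ``mask`` is a label raster (or a SegmentationMap); for a binary raster use
    ``target_class=1``.
    """
    labels = np.asarray(mask.labels if hasattr(mask, "labels") else mask)
    hits = 0
    for r, c in grid.point_coords(labels.shape):
        if not (0 <= r < labels.shape[0] and 0 <= c < labels.shape[1]):
            raise DomainError(f"grid point ({r}, {c}) outside raster {labels.shape}")
        if labels[r, c] == target_class:
            hits += 1
    return hits


def area_from_points(hits: int, per_point_area_mm2: float = DEFAULT_POINT_AREA_MM2) -> float:
    """Stereological area estimate: hits × area-per-point (mm²)."""
    if hits < 0:
        raise DomainError("hit count must be non-negative")
    return hits * per_point_area_mm2


@dataclass
class CVReport:
    per_item_cv_percent: list[float]
    mean_cv_percent: float


def cv_report(measurements) -> CVReport:
    """Coefficient of variation of repeated measurements, per item and averaged.

    ``measurements`` maps item identifiers to lists of repeated values (or is a
    plain list of such lists).  Each CV is 100 × sample SD (n−1 denominator)
    over the item mean; the summary is the unweighted mean across items.
    """
    if hasattr(measurements, "items"):
        items = list(measurements.items())
    else:
        items = list(enumerate(measurements))
    if not items:
        raise DomainError("no items to report on")
    cvs = []
    for key, repeats in items:
        vals = np.asarray(repeats, dtype=np.float64)
        if vals.size < 2:
            raise DomainError(f"item {key!r} has fewer than 2 repeats")
        mean = vals.mean()
        if not mean > 0:
            raise DomainError(f"item {key!r} has non-positive mean {mean}")
        cvs.append(100.0 * vals.std(ddof=1) / mean)
    return CVReport(cvs, float(np.mean(cvs)))


def percent_reduction(cv_manual_percent: float, cv_auto_percent: float) -> int:
    """Reduction in variability from automation, to the nearest integer percent."""
    if not cv_manual_percent > 0:
        raise DomainError("manual CV must be positive")
    return round(100.0 * (cv_manual_percent - cv_auto_percent) / cv_manual_percent)


@dataclass
class AgreementStats:
    pearson_r: float
    p_value: float
    slope: float
    intercept: float
    n: int


def agreement(x, y) -> AgreementStats:
    """Pearson correlation and least-squares line between two measurement series."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be equal-length 1D series")
    if x.size < 3:
        raise DomainError("need at least 3 pairs for a defined correlation")
    if x.std() == 0 or y.std() == 0:
        raise DomainError("zero variance in one of the series")
    fit = stats.linregress(x, y)
    return AgreementStats(
        pearson_r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=int(x.size),
    )
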