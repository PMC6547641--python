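"""RNA distribution metrics: polarization, dispersion, peripheral indexes.

All moment arithmetic uses pixel-center coordinates: pixel (row j, col i)
sits at (x=i, y=j).  The polarization index (PI) is the displacement of the
intensity-weighted RNA centroid from the cell centroid, normalized by the
cell's radius of gyration.  The dispersion index (DI) is the second moment
of RNA intensity about the RNA centroid divided by the second moment of a
hypothetical uniform distribution over the cell mask about the mask
centroid.  The peripheral distribution index (PDI) is the same ratio with
both moments taken about the nucleus centroid, so a uniform field scores
exactly 1 regardless of where the nucleus sits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFieldError, InputError
from .segmentation import BinaryMask

BACKGROUND_MODES = ("threshold", "subtract")


@dataclass
class IntensityField:
    """An RNA channel after background handling, supported on the cell mask."""

    values: np.ndarray  # 2-D float, zero outside the cell mask
    support: BinaryMask
    background_threshold: float = 0.0
    background_mode: str = "threshold"

    @property
    def total(self) -> float:
        return float(self.values.sum())

    @property
    def is_degenerate(self) -> bool:
        return self.total <= 0.0


@dataclass
class CellGeometry:
    """Centroids, radius of gyration and area of a segmented cell."""

    cell_centroid: tuple[float, float]
    nucleus_centroid: tuple[float, float]
    radius_of_gyration: float
    area_px: int
    area_um2: float | None = None


@dataclass
class MetricsResult:
    """One output row: indexes for one RNA channel of one cell."""

    source_id: str
    cell_id: str
    rna_role: str
    pdi: float | None = None
    pi: float | None = None
    di: float | None = None
    mean_intensity: float | None = None
    area_px: int | None = None
    area_um2: float | None = None
    background_threshold: float | None = None
    background_mode: str | None = None
    status: str = "ok"


def apply_background(
    raw_channel: np.ndarray,
    cell: BinaryMask,
    threshold: float,
    mode: str = "threshold",
) -> IntensityField:
    """Mask an RNA channel to the cell and remove background.

    In ``threshold`` mode (default) pixels with raw value <= threshold are
    zeroed and the rest keep their raw value.  In ``subtract`` mode the
    threshold is subtracted from every pixel and negatives clip to zero.
    A field left with zero total mass is returned with its degenerate flag
    set; the moment operations then refuse it explicitly.
    """
    raw = np.asarray(raw_channel, dtype=np.float64)
    if raw.shape != cell.pixels.shape:
        raise InputError("channel and cell mask extents differ")
    if threshold < 0:
        raise InputError("background threshold must be non-negative")
    if mode not in BACKGROUND_MODES:
        raise InputError(f"background mode must be one of {BACKGROUND_MODES}")
    if mode == "threshold":
        values = np.where(raw > threshold, raw, 0.0)
    else:
        values = np.maximum(raw - threshold, 0.0)
    values = values * cell.pixels
    return IntensityField(values, cell, float(threshold), mode)


def _require_mass(field: IntensityField) -> None:
    if field.is_degenerate:
        raise DegenerateFieldError(
            "intensity field has zero total mass (background threshold too high?)"
        )


def rna_centroid(field: IntensityField) -> tuple[float, float]:
    """Intensity-weighted mean position (x, y) of the field."""
    _require_mass(field)
    ys, xs = np.nonzero(field.values)
    w = field.values[ys, xs]
    total = w.sum()
    return float((w * xs).sum() / total), float((w * ys).sum() / total)


def second_moment(field_values: np.ndarray, center: tuple[float, float]) -> float:
    """Intensity-weighted mean squared distance to ``center`` (x, y)."""
    values = np.asarray(field_values, dtype=np.float64)
    ys, xs = np.nonzero(values)
    w = values[ys, xs]
    total = w.sum()
    if total <= 0:
        raise DegenerateFieldError("second moment of a zero field is undefined")
    r2 = (xs - center[0]) ** 2 + (ys - center[1]) ** 2
    return float((w * r2).sum() / total)


def cell_geometry(
    cell: BinaryMask, nucleus: BinaryMask, pixel_size_um: float | None = None
) -> CellGeometry:
    """Centroids (unweighted), radius of gyration and area of the cell.

    The radius of gyration is the root-mean-square distance of every
    cell-mask pixel to the cell centroid.
    """
    if not cell.pixels.any() or not nucleus.pixels.any():
        raise InputError("cell and nucleus masks must be non-empty")
    ys, xs = np.nonzero(cell.pixels)
    cx, cy = float(xs.mean()), float(ys.mean())
    rg = float(np.sqrt(np.mean((xs - cx) ** 2 + (ys - cy) ** 2)))
    area_px = int(xs.size)
    area_um2 = area_px * pixel_size_um**2 if pixel_size_um is not None else None
    return CellGeometry(
        cell_centroid=(cx, cy),
        nucleus_centroid=nucleus.centroid,
        radius_of_gyration=rg,
        area_px=area_px,
        area_um2=area_um2,
    )


def polarization_index(field: IntensityField, geom: CellGeometry) -> float:
    """Displacement of the RNA centroid from the cell centroid over Rg."""
    if geom.radius_of_gyration <= 0:
        raise InputError("radius of gyration must be positive")
    rx, ry = rna_centroid(field)
    cx, cy = geom.cell_centroid
    return float(np.hypot(rx - cx, ry - cy) / geom.radius_of_gyration)


def _uniform_reference(cell: BinaryMask) -> np.ndarray:
    return cell.pixels.astype(np.float64)


def dispersion_index(field: IntensityField, cell: BinaryMask) -> float:
    """Second moment about the RNA centroid, over the uniform reference.

    The reference assigns equal intensity to every cell-mask pixel and is
    taken about the mask centroid; a diffuse field scores 1, concentration
    anywhere scores < 1, peripheral accumulation scores > 1.
    """
    _require_mass(field)
    numerator = second_moment(field.values, rna_centroid(field))
    reference = second_moment(_uniform_reference(cell), cell.centroid)
    return float(numerator / reference)


def peripheral_distribution_index(
    field: IntensityField, cell: BinaryMask, geom: CellGeometry
) -> float:
    """DI-like ratio with both moments about the nucleus centroid.

    Invariant to polarization of the field at fixed distance from the
    nucleus; 1 for diffuse, < 1 perinuclear, > 1 peripheral.
    """
    _require_mass(field)
    center = geom.nucleus_centroid
    numerator = second_moment(field.values, center)
    reference = second_moment(_uniform_reference(cell), center)
    return float(numerator / reference)


def mean_rna_intensity(raw_channel: np.ndarray, cell: BinaryMask) -> float:
    """Total raw (un-thresholded) RNA signal inside the cell over its area."""
    raw = np.asarray(raw_channel, dtype=np.float64)
    if raw.shape != cell.pixels.shape:
        raise InputError("channel and cell mask extents differ")
    n = cell.area_px
    if n == 0:
        raise InputError("empty cell mask")
    return float(raw[cell.pixels].sum() / n)


def compute_metrics(
    raw_channel: np.ndarray,
    cell: BinaryMask,
    geom: CellGeometry,
    *,
    source_id: str = "",
    cell_id: str = "0",
    rna_role: str = "rna_localized",
    background_threshold: float = 0.0,
    background_mode: str = "threshold",
) -> MetricsResult:
    """All metrics for one RNA channel; degenerate fields yield a flagged row."""
    field = apply_background(raw_channel, cell, background_threshold, background_mode)
    result = MetricsResult(
        source_id=source_id,
        cell_id=cell_id,
        rna_role=rna_role,
        mean_intensity=mean_rna_intensity(raw_channel, cell),
        area_px=geom.area_px,
        area_um2=geom.area_um2,
        background_threshold=float(background_threshold),
        background_mode=background_mode,
    )
    if field.is_degenerate:
        result.status = "degenerate_field"
        return result
    result.pi = polarization_index(field, geom)
    result.di = dispersion_index(field, cell)
    result.pdi = peripheral_distribution_index(field, cell, geom)
    return result


def threshold_sweep(
    raw_channel: np.ndarray,
    cell: BinaryMask,
    geom: CellGeometry,
    thresholds,
    mode: str = "threshold",
) -> list[dict]:
    """PDI/PI/DI as a function of the background threshold.

    Returns one record per threshold; degenerate fields yield None metrics.
    Used to locate the plateau of the PDI-vs-threshold response curve when
    choosing a background level.
    """
    records = []
    for t in thresholds:
        field = apply_background(raw_channel, cell, float(t), mode)
        rec = {"threshold": float(t), "pdi": None, "pi": None, "di": None}
        if not field.is_degenerate:
            rec["pdi"] = peripheral_distribution_index(field, cell, geom)
            rec["pi"] = polarization_index(field, geom)
            rec["di"] = dispersion_index(field, cell)
        records.append(rec)
    return records
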