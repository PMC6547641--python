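"""Synthetic 4-channel cell images with known ground truth.

Every generated image contains a cell-shaped region with a nucleus-shaped
subregion and RNA intensity laid down under a controlled distribution class
(uniform, perinuclear, peripheral rim, polarized blob, clustered spots).
The ground-truth record carries the generating masks, true centroids and —
where a closed form exists — the expected index values, so segmentation and
metrics are testable without any external image data.

Identical spec + seed always produces a bit-identical image.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import InputError
from .image_io import MultiChannelImage
from .segmentation import BinaryMask, rasterize_polygon

RNA_CLASSES = ("uniform", "perinuclear", "peripheral_rim", "polarized", "clustered")

# stain levels as fractions of the dynamic range
_NUCLEUS_LEVEL = 0.8
_CELL_LEVEL = 0.45


@dataclass
class SyntheticCellSpec:
    """Parameters of one generated test image.

    ``cell_shape`` / ``nucleus_shape`` are tuples: ``("disk", radius)``,
    ``("ellipse", a, b)`` (semi-axes along x and y) or
    ``("polygon", vertices)``.  ``rna_class`` is a tuple whose head names
    the distribution class and whose tail holds its parameters:

    - ``("uniform",)``
    - ``("perinuclear", sigma)`` — Gaussian decay of weight with distance
      from the nucleus centroid
    - ``("peripheral_rim", inner_frac)`` — weight on the band of cell
      pixels within ``(1 - inner_frac) * max depth`` of the cell edge
    - ``("polarized", direction_deg, displacement_frac)`` — compact blob
      displaced from the cell centroid by ``displacement_frac`` of the
      effective radius, along ``direction_deg``
    - ``("clustered", n_clusters, cluster_sigma)`` — random Gaussian spots

    ``noise`` is ``None``, ``("uniform", level)`` (i.i.d. uniform floor on
    [0, level) at every pixel of the RNA channels) or
    ``("gaussian", sigma)``.
    """

    image_size: tuple[int, int] = (512, 512)
    cell_shape: tuple = ("disk", 150)
    cell_center: tuple[float, float] | None = None  # (x, y); default image center
    nucleus_shape: tuple = ("disk", 40)
    nucleus_offset: tuple[float, float] = (30.0, 0.0)  # (dx, dy) from cell center
    rna_class: tuple = ("uniform",)
    control_class: tuple = ("uniform",)
    total_intensity: float = 2.0e6
    noise: tuple | None = None
    n_planes: int = 1
    bit_depth: int = 12
    pixel_size_um: float | None = 0.2
    seed: int = 0
    source_id: str = ""

    def resolved_center(self) -> tuple[float, float]:
        if self.cell_center is not None:
            return self.cell_center
        h, w = self.image_size
        return ((w - 1) / 2.0, (h - 1) / 2.0)


def _coordinate_grids(image_size: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    h, w = image_size
    ys, xs = np.mgrid[0:h, 0:w]
    return xs.astype(np.float64), ys.astype(np.float64)


def shape_mask(
    shape: tuple, center: tuple[float, float], image_size: tuple[int, int]
) -> np.ndarray:
    """Boolean raster of a disk / ellipse / polygon centered at ``center``."""
    xs, ys = _coordinate_grids(image_size)
    kind = shape[0]
    cx, cy = center
    if kind == "disk":
        (radius,) = shape[1:]
        return (xs - cx) ** 2 + (ys - cy) ** 2 <= radius**2
    if kind == "ellipse":
        a, b = shape[1:]
        return ((xs - cx) / a) ** 2 + ((ys - cy) / b) ** 2 <= 1.0
    if kind == "polygon":
        (vertices,) = shape[1:]
        verts = np.asarray(vertices, dtype=np.float64) + [cx, cy]
        return rasterize_polygon(verts, image_size)
    raise InputError(f"unknown shape kind {kind!r}")


def _rna_weights(
    spec: SyntheticCellSpec,
    rna_class: tuple,
    cell: np.ndarray,
    cell_center: tuple[float, float],
    nucleus_center: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    xs, ys = _coordinate_grids(spec.image_size)
    kind = rna_class[0]
    if kind == "uniform":
        w = np.ones(spec.image_size)
    elif kind == "perinuclear":
        (sigma,) = rna_class[1:]
        d2 = (xs - nucleus_center[0]) ** 2 + (ys - nucleus_center[1]) ** 2
        w = np.exp(-d2 / (2.0 * sigma**2))
    elif kind == "peripheral_rim":
        (inner_frac,) = rna_class[1:]
        if not 0.0 < inner_frac < 1.0:
            raise InputError("peripheral_rim inner_frac must be in (0, 1)")
        depth = ndimage.distance_transform_edt(cell)
        w = (depth > 0) & (depth <= (1.0 - inner_frac) * depth.max())
        w = w.astype(np.float64)
    elif kind == "polarized":
        direction_deg, displacement_frac = rna_class[1:3]
        sigma = rna_class[3] if len(rna_class) > 3 else None
        r_eff = np.sqrt(cell.sum() / np.pi)
        if sigma is None:
            sigma = 0.06 * r_eff
        theta = np.deg2rad(direction_deg)
        bx = cell_center[0] + displacement_frac * r_eff * np.cos(theta)
        by = cell_center[1] + displacement_frac * r_eff * np.sin(theta)
        d2 = (xs - bx) ** 2 + (ys - by) ** 2
        w = np.exp(-d2 / (2.0 * sigma**2))
    elif kind == "clustered":
        n_clusters, cluster_sigma = rna_class[1:3]
        interior = ndimage.binary_erosion(
            cell, iterations=max(1, int(np.ceil(3 * cluster_sigma)))
        )
        cys, cxs = np.nonzero(interior if interior.any() else cell)
        picks = rng.choice(cys.size, size=int(n_clusters), replace=True)
        w = np.zeros(spec.image_size)
        for p in picks:
            d2 = (xs - cxs[p]) ** 2 + (ys - cys[p]) ** 2
            w += np.exp(-d2 / (2.0 * cluster_sigma**2))
    else:
        raise InputError(f"unknown rna_class {kind!r}; valid: {RNA_CLASSES}")
    w = w * cell
    if w.sum() <= 0:
        raise InputError(f"rna_class {kind!r} produced zero mass inside the cell")
    return w


def _expected_indexes(spec: SyntheticCellSpec) -> dict:
    """Closed-form index values where the geometry admits them."""
    kind = spec.rna_class[0]
    if kind == "uniform":
        return {"di": 1.0, "pdi": 1.0, "pi": 0.0}
    if kind == "polarized" and spec.cell_shape[0] == "disk":
        # Rg of a uniform disk is R / sqrt(2), so PI = d / (R/sqrt2) = frac * sqrt2
        displacement_frac = spec.rna_class[2]
        return {"pi": float(displacement_frac * np.sqrt(2.0))}
    return {}


def _spread_over_planes(
    plane: np.ndarray, n_planes: int, rng: np.random.Generator
) -> np.ndarray:
    """Build a z-stack whose per-pixel maximum equals ``plane``.

    One random plane per pixel carries the full value; the others carry a
    random fraction below 0.8 of it, so projection is exercised for real.
    """
    if n_planes == 1:
        return plane[np.newaxis]
    h, w = plane.shape
    stack = plane[np.newaxis] * (rng.random((n_planes, h, w)) * 0.8)
    carrier = rng.integers(0, n_planes, size=(h, w))
    zs = np.arange(n_planes)[:, None, None]
    stack = np.where(zs == carrier[None], plane[np.newaxis], stack)
    return stack


def generate(spec: SyntheticCellSpec) -> tuple[MultiChannelImage, dict]:
    """Render a 4-channel synthetic image and its ground-truth record.

    Channels: 0 nucleus stain, 1 cell stain, 2 RNA (localized), 3 RNA
    (control).  The truth record holds the generating masks, centroids,
    the noise-free RNA planes and expected index values where closed-form.
    """
    rng = np.random.default_rng(spec.seed)
    cell_center = spec.resolved_center()
    nucleus_center = (
        cell_center[0] + spec.nucleus_offset[0],
        cell_center[1] + spec.nucleus_offset[1],
    )
    cell = shape_mask(spec.cell_shape, cell_center, spec.image_size)
    nucleus = shape_mask(spec.nucleus_shape, nucleus_center, spec.image_size)
    if not cell.any():
        raise InputError("cell shape rasterizes to an empty mask")
    grown = ndimage.binary_dilation(nucleus, structure=np.ones((3, 3), bool))
    if np.any(grown & ~cell):
        raise InputError("nucleus must lie strictly inside the cell")

    maxval = 2**spec.bit_depth - 1
    nucleus_plane = np.where(nucleus, _NUCLEUS_LEVEL * maxval, 0.0)
    cell_plane = np.where(cell, _CELL_LEVEL * maxval, 0.0)

    rna_planes = []
    for cls in (spec.rna_class, spec.control_class):
        w = _rna_weights(spec, cls, cell, cell_center, nucleus_center, rng)
        rna_planes.append(w * (spec.total_intensity / w.sum()))

    truth = {
        "spec": spec,
        "seed": spec.seed,
        "cell_mask": BinaryMask(cell, kind="cell"),
        "nucleus_mask": BinaryMask(nucleus, kind="nucleus"),
        "cell_center": cell_center,
        "nucleus_center": nucleus_center,
        "rna_signal": {
            "rna_localized": rna_planes[0].copy(),
            "rna_control": rna_planes[1].copy(),
        },
        "expected": _expected_indexes(spec),
    }

    if spec.noise is not None:
        noise_kind = spec.noise[0]
        h, w_ = spec.image_size
        for i in range(2):
            if noise_kind == "uniform":
                rna_planes[i] = rna_planes[i] + rng.random((h, w_)) * spec.noise[1]
            elif noise_kind == "gaussian":
                rna_planes[i] = rna_planes[i] + np.maximum(
                    rng.normal(0.0, spec.noise[1], (h, w_)), 0.0
                )
            else:
                raise InputError(f"unknown noise kind {noise_kind!r}")

    planes = [nucleus_plane, cell_plane, *rna_planes]
    stack = np.stack(
        [_spread_over_planes(p, spec.n_planes, rng) for p in planes], axis=0
    )
    dtype = np.uint8 if spec.bit_depth <= 8 else np.uint16
    pixels = np.clip(np.rint(stack), 0, maxval).astype(dtype)

    img = MultiChannelImage(
        pixels=pixels,
        channel_roles={0: "nucleus", 1: "cell", 2: "rna_localized", 3: "rna_control"},
        bit_depth=spec.bit_depth,
        pixel_size_um=spec.pixel_size_um,
        source_id=spec.source_id or f"synthetic-{spec.rna_class[0]}-seed{spec.seed}",
    )
    return img, truth


def spot_field(
    coords: Sequence[tuple[float, float]],
    psf_sigma: float,
    cell: BinaryMask,
) -> np.ndarray:
    """Render unit-mass Gaussian spots at (x, y) coordinates.

    Each spot integrates to 1 over the image grid (within truncation error
    for spots near the border).  Supports the equivalence check between
    intensity-based and coordinate-based index computation.
    """
    if psf_sigma <= 0:
        raise InputError("psf_sigma must be positive")
    h, w = cell.pixels.shape
    xs, ys = _coordinate_grids((h, w))
    out = np.zeros((h, w))
    norm = 2.0 * np.pi * psf_sigma**2
    for x, y in coords:
        ix, iy = int(round(x)), int(round(y))
        if not (0 <= iy < h and 0 <= ix < w) or not cell.pixels[iy, ix]:
            raise InputError(f"spot ({x}, {y}) is outside the cell mask")
        d2 = (xs - x) ** 2 + (ys - y) ** 2
        out += np.exp(-d2 / (2.0 * psf_sigma**2)) / norm
    return out


def default_fixture_specs(seed: int = 0) -> list[SyntheticCellSpec]:
    """The packaged fixture set: one image per distribution class."""
    common = dict(
        image_size=(384, 384),
        cell_shape=("disk", 120),
        nucleus_shape=("disk", 32),
        nucleus_offset=(24.0, 0.0),
        pixel_size_um=0.2,
    )
    return [
        SyntheticCellSpec(
            rna_class=("uniform",), seed=seed, source_id="fix-uniform", **common
        ),
        SyntheticCellSpec(
            rna_class=("perinuclear", 30.0),
            seed=seed + 1,
            source_id="fix-perinuclear",
            **common,
        ),
        SyntheticCellSpec(
            rna_class=("peripheral_rim", 0.85),
            seed=seed + 2,
            source_id="fix-peripheral",
            **common,
        ),
        SyntheticCellSpec(
            rna_class=("polarized", 0.0, 0.5),
            seed=seed + 3,
            source_id="fix-polarized",
            **common,
        ),
        SyntheticCellSpec(
            rna_class=("clustered", 6, 4.0),
            seed=seed + 4,
            source_id="fix-clustered",
            **common,
        ),
    ]
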