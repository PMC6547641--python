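"""Binary cell / nucleus mask generation and programmatic mask editing.

Cell masks come from a Sobel gradient → threshold → dilate → flood-fill →
largest-component pipeline; nuclear masks from an adaptive (Wiener) denoise →
Otsu threshold restricted to the cell mask.  All editing operations (draw /
limit / expand polygons, dilation) are plain functions over masks so an
entire edited analysis replays from configuration.

Conventions: 8-connectivity for component labeling, 4-connectivity for hole
identification; dilation uses a 3x3 square element ("one pixel in all
directions", diagonals included); Sobel borders are edge-replicated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon
from skimage.draw import polygon2mask

from .errors import InputError, SegmentationFailure

#: Automatic Sobel threshold heuristic: base = RMS(gradient) * this constant.
#: The effective threshold is base * ``edge_threshold_multiplier``.
EDGE_THRESHOLD_RMS_FACTOR = 4.0

_SQUARE3 = np.ones((3, 3), dtype=bool)


@dataclass
class SegmentationParams:
    """Tunables of automatic mask generation.

    Defaults reproduce the fully automatic path: multiplier 0.5, a single
    1-pixel dilation, and no Wiener or sharpening pre-processing of the
    cell channel.
    """

    edge_threshold_multiplier: float = 0.5
    dilation_iterations: int = 1
    wiener_iterations: int = 0
    sharpen_iterations: int = 0
    edge_threshold_rms_factor: float = EDGE_THRESHOLD_RMS_FACTOR

    def __post_init__(self) -> None:
        if self.edge_threshold_multiplier <= 0:
            raise InputError("edge_threshold_multiplier must be positive")
        for name in ("dilation_iterations", "wiener_iterations", "sharpen_iterations"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative")


@dataclass
class MaskEdit:
    """One editing operation: mode 'draw' | 'limit' | 'expand' | 'dilate'.

    Polygon vertices are ``(x, y)`` pairs in image coordinates; 'dilate'
    takes no vertices.
    """

    mode: str
    vertices: list | None = None


@dataclass
class BinaryMask:
    """A cell or nucleus mask with provenance and an ordered edit log."""

    pixels: np.ndarray
    kind: str  # 'cell' | 'nucleus'
    provenance: str = "auto"  # 'auto' | 'edited'
    edit_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise InputError("mask must be 2-D")
        if self.kind not in ("cell", "nucleus"):
            raise InputError("mask kind must be 'cell' or 'nucleus'")

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    @property
    def centroid(self) -> tuple[float, float]:
        """Unweighted mean pixel position as (x, y)."""
        ys, xs = np.nonzero(self.pixels)
        if xs.size == 0:
            raise InputError("empty mask has no centroid")
        return float(xs.mean()), float(ys.mean())

    def contains(self, other: "BinaryMask") -> bool:
        return bool(np.all(self.pixels | ~other.pixels))


def sobel_gradient(channel: np.ndarray) -> np.ndarray:
    """Gradient magnitude from the standard 3x3 Sobel kernels in x and y.

    Borders are edge-replicated; the x and y responses combine as the
    Euclidean norm.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if channel.ndim != 2 or min(channel.shape) < 3:
        raise InputError("sobel_gradient needs a 2-D array of extent >= 3x3")
    gx = ndimage.sobel(channel, axis=1, mode="nearest")
    gy = ndimage.sobel(channel, axis=0, mode="nearest")
    return np.hypot(gx, gy)


def auto_edge_threshold(
    gradient: np.ndarray, rms_factor: float = EDGE_THRESHOLD_RMS_FACTOR
) -> float:
    """Automatic base threshold for a Sobel gradient image.

    Computed as the root-mean-square gradient magnitude times
    ``rms_factor``; callers scale it by their edge-threshold multiplier.
    """
    gradient = np.asarray(gradient, dtype=np.float64)
    if not np.any(gradient):
        raise InputError("gradient is all zero: no edges detectable")
    return float(np.sqrt(np.mean(gradient**2)) * rms_factor)


def wiener_denoise(channel: np.ndarray) -> np.ndarray:
    """Adaptive local-mean / local-variance (Wiener) filter, 5x5 window.

    The noise power is estimated as the mean of the local variances.  Flat
    regions collapse to their local mean; high-variance regions (edges) are
    nearly unchanged.  Returns float64.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if channel.ndim != 2 or min(channel.shape) < 5:
        raise InputError("wiener_denoise needs a 2-D array of extent >= 5x5")
    local_mean = ndimage.uniform_filter(channel, size=5, mode="nearest")
    local_sqmean = ndimage.uniform_filter(channel**2, size=5, mode="nearest")
    local_var = np.maximum(local_sqmean - local_mean**2, 0.0)
    noise = local_var.mean()
    gain = np.zeros_like(channel)
    np.divide(local_var - noise, local_var, out=gain, where=local_var > noise)
    return local_mean + gain * (channel - local_mean)


def unsharp_mask(
    channel: np.ndarray,
    amount: float = 1.0,
    sigma: float = 1.0,
    clip_max: float | None = None,
) -> np.ndarray:
    """Sharpen: input + amount * (input - Gaussian blur), clipped at 0 (and
    ``clip_max`` when given)."""
    channel = np.asarray(channel, dtype=np.float64)
    if channel.ndim != 2:
        raise InputError("unsharp_mask needs a 2-D array")
    blurred = ndimage.gaussian_filter(channel, sigma=sigma, mode="nearest")
    return np.clip(channel + amount * (channel - blurred), 0.0, clip_max)


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Threshold maximizing inter-class variance, by exhaustive search.

    For integer input every occupied integer level is a candidate and the
    result is exact; float input is histogrammed into ``nbins`` equal bins.
    Pixels with value <= threshold form the background class.
    """
    values = np.asarray(values)
    flat = values.ravel()
    if flat.size == 0:
        raise InputError("cannot threshold an empty array")
    if np.issubdtype(values.dtype, np.integer):
        lo, hi = int(flat.min()), int(flat.max())
        levels = np.arange(lo, hi + 1, dtype=np.float64)
        counts = np.bincount((flat - lo).astype(np.int64), minlength=hi - lo + 1)
    else:
        lo, hi = float(flat.min()), float(flat.max())
        if hi == lo:
            return lo
        counts, edges = np.histogram(flat, bins=nbins, range=(lo, hi))
        levels = (edges[:-1] + edges[1:]) / 2.0
    counts = counts.astype(np.float64)
    if len(levels) < 2:
        return float(levels[0])
    w0 = np.cumsum(counts)
    w1 = w0[-1] - w0
    cum_mass = np.cumsum(counts * levels)
    total_mass = cum_mass[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_mass / w0
        mu1 = (total_mass - cum_mass) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -np.inf
    # candidates exclude the last level (one class would be empty)
    return float(levels[int(np.argmax(between[:-1]))])


def _fill_and_keep_largest(binary: np.ndarray) -> np.ndarray:
    filled = ndimage.binary_fill_holes(binary)  # 4-connected holes
    labels, n = ndimage.label(filled, structure=_SQUARE3)  # 8-connected components
    if n == 0:
        return filled
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return labels == int(np.argmax(sizes))


def cell_mask(
    cell_channel: np.ndarray, params: SegmentationParams | None = None
) -> BinaryMask:
    """Automatic cell mask from the whole-cell stain channel.

    Pipeline: optional Wiener denoise and unsharp-mask pre-processing,
    Sobel gradient, binarize at the automatic threshold scaled by the
    multiplier, dilate 1 px per iteration, flood-fill enclosed holes, and
    keep the connected component covering the largest area.
    """
    params = params or SegmentationParams()
    img = np.asarray(cell_channel, dtype=np.float64)
    for _ in range(params.wiener_iterations):
        img = wiener_denoise(img)
    for _ in range(params.sharpen_iterations):
        img = unsharp_mask(img)
    gradient = sobel_gradient(img)
    try:
        base = auto_edge_threshold(gradient, params.edge_threshold_rms_factor)
    except InputError as exc:
        raise SegmentationFailure(
            "no intensity edges in cell channel", {"gradient": gradient}
        ) from exc
    edges = gradient > base * params.edge_threshold_multiplier
    if not edges.any():
        raise SegmentationFailure(
            "no pixels above edge threshold",
            {"gradient": gradient, "threshold": base * params.edge_threshold_multiplier},
        )
    binary = edges
    for _ in range(params.dilation_iterations):
        binary = ndimage.binary_dilation(binary, structure=_SQUARE3)
    mask = _fill_and_keep_largest(binary)
    if not mask.any():
        raise SegmentationFailure(
            "cell mask empty after flood fill", {"edges": edges, "binary": binary}
        )
    return BinaryMask(mask, kind="cell", provenance="auto")


def nuclear_mask(nucleus_channel: np.ndarray, cell: BinaryMask) -> BinaryMask:
    """Automatic nuclear mask restricted to the given cell mask.

    Pipeline: Wiener denoise, Otsu threshold, elementwise AND with the cell
    mask (discarding nuclei of neighboring cells), flood-fill holes.
    """
    channel = np.asarray(nucleus_channel)
    if channel.shape != cell.pixels.shape:
        raise InputError("nucleus channel and cell mask extents differ")
    denoised = wiener_denoise(channel)
    threshold = otsu_threshold(denoised)
    binary = (denoised > threshold) & cell.pixels
    if not binary.any():
        raise SegmentationFailure(
            "nuclear mask empty after Otsu threshold inside cell mask",
            {"denoised": denoised, "threshold": threshold},
        )
    filled = ndimage.binary_fill_holes(binary) & cell.pixels
    return BinaryMask(filled, kind="nucleus", provenance="auto")


def rasterize_polygon(
    vertices: Sequence[Sequence[float]], shape: tuple[int, int]
) -> np.ndarray:
    """Filled-polygon raster for (x, y) vertices on an image of given shape."""
    verts = np.asarray(vertices, dtype=np.float64)
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
        raise InputError("polygon needs >= 3 (x, y) vertex pairs")
    poly = Polygon(verts)
    if not poly.is_valid or poly.area == 0:
        raise InputError("polygon must be simple (non-self-intersecting), non-degenerate")
    return polygon2mask(shape, verts[:, ::-1])  # polygon2mask wants (row, col)


def edit_mask(mask: BinaryMask, edit: MaskEdit) -> BinaryMask:
    """Apply one editing operation, returning a new mask with provenance
    'edited' and the edit appended to the log.

    draw: replace the mask with the rasterized polygon. limit: AND with the
    polygon. expand: OR with the polygon. dilate: grow by 1 px in all
    directions.  When a *cell* mask is edited, any nuclear mask derived from
    it must be recomputed by the caller.
    """
    if edit.mode == "dilate":
        new_pixels = ndimage.binary_dilation(mask.pixels, structure=_SQUARE3)
    elif edit.mode in ("draw", "limit", "expand"):
        if edit.vertices is None:
            raise InputError(f"edit mode {edit.mode!r} requires polygon vertices")
        poly = rasterize_polygon(edit.vertices, mask.pixels.shape)
        if edit.mode == "draw":
            new_pixels = poly
        elif edit.mode == "limit":
            new_pixels = mask.pixels & poly
            if not new_pixels.any():
                raise SegmentationFailure(
                    "limit polygon excludes the entire mask", {"polygon": poly}
                )
        else:
            new_pixels = mask.pixels | poly
    else:
        raise InputError(f"unknown edit mode {edit.mode!r}")
    return BinaryMask(
        new_pixels,
        kind=mask.kind,
        provenance="edited",
        edit_log=[*mask.edit_log, edit],
    )


def apply_edits(mask: BinaryMask, edits: Sequence[MaskEdit]) -> BinaryMask:
    """Replay a sequence of edits in order."""
    for edit in edits:
        mask = edit_mask(mask, edit)
    return mask
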