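"""Read multi-channel microscopy TIFFs, project z-stacks, export result CSVs.

Channel roles are always supplied explicitly by the caller; nothing is
guessed from channel order.  Arrays are indexed ``(channel, z, y, x)`` with
the origin at the top-left pixel and pixel centers at integer coordinates;
``x`` is the column index and ``y`` the row index.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile

from .errors import ConfigError, InputError

ROLE_NUCLEUS = "nucleus"
ROLE_CELL = "cell"
RNA_ROLES = ("rna_localized", "rna_control")
VALID_ROLES = (ROLE_NUCLEUS, ROLE_CELL) + RNA_ROLES

#: Column order of the results CSV written by :func:`write_results`.
RESULT_COLUMNS = (
    "source_id",
    "cell_id",
    "rna_role",
    "area_px",
    "area_um2",
    "pdi",
    "pi",
    "di",
    "mean_intensity",
    "background_threshold",
    "background_mode",
    "status",
)


def _validate_roles(channel_roles: Mapping[int, str], n_channels: int) -> None:
    roles = list(channel_roles.values())
    for r in roles:
        if r not in VALID_ROLES:
            raise ConfigError(f"unknown channel role {r!r}; valid: {VALID_ROLES}")
    if roles.count(ROLE_NUCLEUS) != 1 or roles.count(ROLE_CELL) != 1:
        raise ConfigError(
            "channel_roles must assign exactly one 'nucleus' and one 'cell' channel"
        )
    n_rna = sum(r in RNA_ROLES for r in roles)
    if not 1 <= n_rna <= 2:
        raise ConfigError("channel_roles must assign one or two RNA channels")
    if len(set(channel_roles)) != len(roles):
        raise ConfigError("duplicate channel indices in role mapping")
    for idx in channel_roles:
        if not 0 <= idx < n_channels:
            raise ConfigError(
                f"channel index {idx} out of range for {n_channels}-channel image"
            )


@dataclass
class MultiChannelImage:
    """A (channel, z, y, x) intensity stack with role labels and metadata."""

    pixels: np.ndarray
    channel_roles: dict[int, str]
    bit_depth: int
    pixel_size_um: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise InputError("pixels must be a 4-D (channel, z, y, x) array")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise InputError("pixels must have an integer dtype")
        _validate_roles(self.channel_roles, self.pixels.shape[0])
        if self.bit_depth <= 0:
            raise InputError("bit_depth must be positive")
        maxval = 2 ** self.bit_depth - 1
        if self.pixels.min() < 0 or self.pixels.max() > maxval:
            raise InputError(
                f"intensities out of range [0, {maxval}] for bit depth {self.bit_depth}"
            )
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise InputError("pixel_size_um must be positive when given")

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_planes(self) -> int:
        return self.pixels.shape[1]

    def channel_index(self, role: str) -> int:
        for idx, r in self.channel_roles.items():
            if r == role:
                return idx
        raise ConfigError(f"no channel with role {role!r}")

    @property
    def rna_roles(self) -> list[str]:
        return [r for r in self.channel_roles.values() if r in RNA_ROLES]


@dataclass
class ProjectedImage:
    """Per-channel 2-D images: the maximum-intensity z-projection of a stack."""

    pixels: np.ndarray  # (channel, y, x)
    channel_roles: dict[int, str]
    bit_depth: int
    pixel_size_um: float | None = None
    source_id: str = ""

    def channel(self, role: str) -> np.ndarray:
        for idx, r in self.channel_roles.items():
            if r == role:
                return self.pixels[idx]
        raise ConfigError(f"no channel with role {role!r}")

    @property
    def rna_roles(self) -> list[str]:
        return [r for r in self.channel_roles.values() if r in RNA_ROLES]


_UNIT_TO_UM = {"µm": 1.0, "um": 1.0, "micron": 1.0, "microns": 1.0,
               "nm": 1e-3, "mm": 1e3, "cm": 1e4}


def source_id_from_path(path: str | Path) -> str:
    """File name without TIFF extensions, including the '.ome' of OME-TIFFs."""
    name = Path(path).name
    for ext in (".tif", ".tiff", ".TIF", ".TIFF"):
        if name.endswith(ext):
            name = name[: -len(ext)]
            break
    if name.endswith(".ome"):
        name = name[: -len(".ome")]
    return name


def _pixel_size_from_tiff(tf: tifffile.TiffFile) -> float | None:
    """Best-effort pixel size (µm/px) from OME or ImageJ/resolution metadata."""
    if tf.ome_metadata:
        m = re.search(r'PhysicalSizeX="([0-9.eE+\-]+)"', tf.ome_metadata)
        if m:
            size = float(m.group(1))
            mu = re.search(r'PhysicalSizeXUnit="([^"]+)"', tf.ome_metadata)
            scale = _UNIT_TO_UM.get(mu.group(1) if mu else "µm")
            if scale is not None:
                return size * scale
    unit = None
    if tf.imagej_metadata:
        unit = tf.imagej_metadata.get("unit")
    if unit in _UNIT_TO_UM:
        page = tf.pages[0]
        tag = page.tags.get("XResolution")
        if tag is not None:
            num, den = tag.value
            if num:
                return (den / num) * _UNIT_TO_UM[unit]
    return None


def _normalize_axes(arr: np.ndarray, axes: str) -> np.ndarray:
    """Rearrange an array described by a tifffile axes string into (C,Z,Y,X)."""
    axes = axes.upper().replace("S", "C").replace("I", "Z").replace("Q", "Z")
    if len(axes) != arr.ndim:
        raise ConfigError(f"axis order {axes!r} does not match array rank {arr.ndim}")
    if len(set(axes)) != len(axes):
        raise ConfigError(f"duplicate axes in axis order {axes!r}")
    unknown = set(axes) - set("CZYX")
    if unknown:
        raise ConfigError(
            f"unsupported axes {sorted(unknown)}; pass axis_order to override"
        )
    for ax in "CZYX":
        if ax not in axes:
            arr = arr[np.newaxis]
            axes = ax + axes
    order = [axes.index(ax) for ax in "CZYX"]
    return np.transpose(arr, order)


def read_image(
    path: str | Path,
    channel_roles: Mapping[int, str],
    *,
    axis_order: str | None = None,
    bit_depth: int | None = None,
    pixel_size_um: float | None = None,
    source_id: str | None = None,
) -> MultiChannelImage:
    """Decode a TIFF / OME-TIFF into a :class:`MultiChannelImage`.

    Parameters
    ----------
    channel_roles:
        Mapping from channel index to role; must name exactly one nucleus
        and one cell channel plus one or two RNA channels.
    axis_order:
        Override for the axis layout (e.g. ``"ZCYX"``) when the file's own
        metadata is wrong or missing.
    bit_depth:
        Intensity bit depth; defaults to the dtype's bit width (TIFF files
        store 12-bit data in 16-bit containers, so pass ``12`` explicitly
        for such data).
    pixel_size_um:
        Explicit pixel size, overriding file metadata.  When neither is
        available a warning is issued and areas are reported in pixels.
    """
    path = Path(path)
    try:
        tf = tifffile.TiffFile(path)
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc
    with tf:
        series = tf.series[0]
        arr = series.asarray()
        axes = axis_order if axis_order is not None else series.axes
        if pixel_size_um is None:
            pixel_size_um = _pixel_size_from_tiff(tf)
    arr = _normalize_axes(np.asarray(arr), axes)
    if arr.shape[0] < max(channel_roles) + 1:
        raise ConfigError(
            f"{path.name}: {arr.shape[0]} channels but roles reference "
            f"channel {max(channel_roles)}"
        )
    if pixel_size_um is None:
        warnings.warn(
            f"{path.name}: no pixel-size metadata; areas will be in pixel units",
            stacklevel=2,
        )
    if bit_depth is None:
        bit_depth = arr.dtype.itemsize * 8
    return MultiChannelImage(
        pixels=arr,
        channel_roles=dict(channel_roles),
        bit_depth=bit_depth,
        pixel_size_um=pixel_size_um,
        source_id=source_id if source_id is not None else source_id_from_path(path),
    )


def max_project(img: MultiChannelImage) -> ProjectedImage:
    """Maximum-intensity projection over z.  Identity for single-plane input."""
    return ProjectedImage(
        pixels=img.pixels.max(axis=1),
        channel_roles=dict(img.channel_roles),
        bit_depth=img.bit_depth,
        pixel_size_um=img.pixel_size_um,
        source_id=img.source_id,
    )


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return format(value, ".9g")
    return str(value)


def write_results(rows, path: str | Path) -> Path:
    """Write result rows as an RFC-4180 CSV with a header line.

    ``rows`` is any iterable of objects exposing the attributes named in
    :data:`RESULT_COLUMNS` (missing attributes serialize as empty fields).
    Numbers are written with 9 significant digits.
    """
    path = Path(path)
    try:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(RESULT_COLUMNS)
            for row in rows:
                writer.writerow(
                    [_fmt(getattr(row, col, None)) for col in RESULT_COLUMNS]
                )
    except OSError as exc:
        raise OSError(f"cannot write results CSV {path}: {exc}") from exc
    return path
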