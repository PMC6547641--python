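"""Batch orchestration: read → project → segment → review/edit → metrics → CSV.

The interactive accept/edit loop is a two-pass workflow: an automatic run
writes mask-outline overlays; the user records accept/edit decisions in a
YAML decision file keyed by source_id; replaying the run applies those
edits.  Decisions are data, so every analysis is reproducible from the
configuration and inputs alone.
"""

from __future__ import annotations

import glob as globmod
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml
from scipy import ndimage

from .errors import ConfigError, DegenerateFieldError, RnadistError, SegmentationFailure
from .image_io import (
    RNA_ROLES,
    source_id_from_path,
    MultiChannelImage,
    ProjectedImage,
    max_project,
    read_image,
    write_results,
)
from .metrics import MetricsResult, cell_geometry, compute_metrics
from .segmentation import (
    BinaryMask,
    MaskEdit,
    SegmentationParams,
    apply_edits,
    cell_mask,
    nuclear_mask,
)

logger = logging.getLogger("rnadist")


@dataclass
class Decision:
    """Reviewed outcome for one image: accept as-is, or apply edits."""

    action: str = "accept"  # 'accept' | 'edit'
    edits: list[MaskEdit] = field(default_factory=list)


@dataclass
class RunConfig:
    """Everything needed to (re)run one batch analysis."""

    inputs: list[str]
    channel_roles: dict[int, str]
    output_dir: str = "rnadist-out"
    params: SegmentationParams = field(default_factory=SegmentationParams)
    background_thresholds: dict[str, float] = field(default_factory=dict)
    background_mode: str = "threshold"
    decisions: dict[str, Decision] = field(default_factory=dict)
    overlay: bool = True
    axis_order: str | None = None
    bit_depth: int | None = None
    pixel_size_um: float | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if "inputs" not in raw or "channel_roles" not in raw:
            raise ConfigError("config requires 'inputs' and 'channel_roles'")
        inputs = raw["inputs"]
        if isinstance(inputs, str):
            inputs = [inputs]
        try:
            roles = {int(k): str(v) for k, v in raw["channel_roles"].items()}
        except (TypeError, ValueError, AttributeError) as exc:
            raise ConfigError(f"malformed channel_roles: {exc}") from exc
        params = SegmentationParams(**raw.get("segmentation", {}))
        decisions = parse_decisions(raw.get("decisions", {}))
        return cls(
            inputs=inputs,
            channel_roles=roles,
            output_dir=raw.get("output_dir", "rnadist-out"),
            params=params,
            background_thresholds={
                str(k): float(v)
                for k, v in raw.get("background_thresholds", {}).items()
            },
            background_mode=raw.get("background_mode", "threshold"),
            decisions=decisions,
            overlay=bool(raw.get("overlay", True)),
            axis_order=raw.get("axis_order"),
            bit_depth=raw.get("bit_depth"),
            pixel_size_um=raw.get("pixel_size_um"),
            log_level=raw.get("log_level", "INFO"),
        )


def parse_decisions(raw: dict) -> dict[str, Decision]:
    """Parse {source_id: {action, edits: [{mode, vertices}]}} mappings."""
    if not isinstance(raw, dict):
        raise ConfigError("decisions must be a mapping keyed by source_id")
    decisions = {}
    for source_id, rec in raw.items():
        rec = rec or {}
        if not isinstance(rec, dict):
            raise ConfigError(f"decision for {source_id!r} must be a mapping")
        action = rec.get("action", "accept")
        if action not in ("accept", "edit"):
            raise ConfigError(f"decision action must be accept|edit, got {action!r}")
        edits = []
        for e in rec.get("edits", []):
            if "mode" not in e:
                raise ConfigError(f"edit for {source_id!r} lacks a mode")
            edits.append(MaskEdit(mode=e["mode"], vertices=e.get("vertices")))
        if action == "edit" and not edits:
            raise ConfigError(f"decision 'edit' for {source_id!r} lists no edits")
        decisions[str(source_id)] = Decision(action=action, edits=edits)
    return decisions


def load_decisions(path: str | Path) -> dict[str, Decision]:
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed decision file {path}: {exc}") from exc
    return parse_decisions(raw)


def review(
    proj: ProjectedImage,
    cell: BinaryMask,
    decisions: dict[str, Decision],
) -> tuple[BinaryMask, BinaryMask, Decision]:
    """Apply the recorded decision for this image (auto-accept by default).

    Edits apply to the cell mask in the order listed; the nuclear mask is
    always (re)computed from the final cell mask, matching the rule that
    nuclear boundaries are derived after any cell-mask editing.
    """
    decision = decisions.get(proj.source_id, Decision())
    if decision.action == "edit":
        cell = apply_edits(cell, decision.edits)
    nucleus = nuclear_mask(proj.channel("nucleus"), cell)
    return cell, nucleus, decision


def _outline(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndimage.binary_erosion(mask)


def save_overlay(
    proj: ProjectedImage,
    cell: BinaryMask,
    nucleus: BinaryMask,
    path: str | Path,
    channel_role: str = "cell",
) -> Path:
    """PNG of the chosen channel with the cell outline in red and the
    nuclear outline in white."""
    base = proj.channel(channel_role).astype(np.float64)
    hi = base.max() or 1.0
    gray = (base / hi * 255.0).astype(np.uint8)
    rgb = np.stack([gray, gray, gray], axis=-1)
    rgb[_outline(cell.pixels)] = (255, 0, 0)
    rgb[_outline(nucleus.pixels)] = (255, 255, 255)
    path = Path(path)
    iio.imwrite(path, rgb)
    return path


def _resolve_inputs(patterns: list[str]) -> list[Path]:
    paths: list[Path] = []
    for pattern in patterns:
        matches = sorted(globmod.glob(pattern))
        if matches:
            paths.extend(Path(m) for m in matches)
        elif Path(pattern).exists():
            paths.append(Path(pattern))
    return paths


def analyze_projection(
    proj: ProjectedImage, config: RunConfig
) -> tuple[list[MetricsResult], BinaryMask, BinaryMask]:
    """Segment one projected image and compute metrics for each RNA channel."""
    cell = cell_mask(proj.channel("cell"), config.params)
    cell, nucleus, _ = review(proj, cell, config.decisions)
    geom = cell_geometry(cell, nucleus, proj.pixel_size_um)
    rows = []
    for role in proj.rna_roles:
        rows.append(
            compute_metrics(
                proj.channel(role),
                cell,
                geom,
                source_id=proj.source_id,
                cell_id="0",
                rna_role=role,
                background_threshold=config.background_thresholds.get(role, 0.0),
                background_mode=config.background_mode,
            )
        )
    return rows, cell, nucleus


def analyze_image(
    img: MultiChannelImage, config: RunConfig
) -> tuple[list[MetricsResult], BinaryMask, BinaryMask]:
    return analyze_projection(max_project(img), config)


def _failure_rows(source_id: str, roles, status: str) -> list[MetricsResult]:
    rna = [r for r in roles.values() if r in RNA_ROLES] or list(RNA_ROLES)
    return [
        MetricsResult(source_id=source_id, cell_id="0", rna_role=role, status=status)
        for role in rna
    ]


def run(config: RunConfig) -> Path:
    """Run the whole batch; returns the path of the results CSV.

    Per-image failures (unreadable file, segmentation failure, degenerate
    field) are logged and written as flagged rows; they never abort the
    batch.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = _resolve_inputs(config.inputs)
    if not paths:
        raise RnadistError(f"no readable inputs among {config.inputs}")
    known_ids = {source_id_from_path(p) for p in paths}
    unknown = set(config.decisions) - known_ids
    if unknown:
        raise ConfigError(f"decisions reference unknown source_ids: {sorted(unknown)}")

    all_rows: list[MetricsResult] = []
    for path in paths:
        try:
            img = read_image(
                path,
                config.channel_roles,
                axis_order=config.axis_order,
                bit_depth=config.bit_depth,
                pixel_size_um=config.pixel_size_um,
            )
        except (OSError, ConfigError) as exc:
            logger.error("failed to read %s: %s", path, exc)
            all_rows.extend(
                _failure_rows(source_id_from_path(path), config.channel_roles, "read_error")
            )
            continue
        proj = max_project(img)
        try:
            rows, cell, nucleus = analyze_projection(proj, config)
        except SegmentationFailure as exc:
            logger.error("segmentation failed for %s: %s", proj.source_id, exc)
            all_rows.extend(
                _failure_rows(
                    proj.source_id, config.channel_roles, "segmentation_failure"
                )
            )
            continue
        except DegenerateFieldError as exc:
            logger.error("degenerate field for %s: %s", proj.source_id, exc)
            all_rows.extend(
                _failure_rows(proj.source_id, config.channel_roles, "degenerate_field")
            )
            continue
        all_rows.extend(rows)
        if config.overlay:
            save_overlay(proj, cell, nucleus, out_dir / f"{proj.source_id}_overlay.png")
    csv_path = out_dir / "results.csv"
    write_results(all_rows, csv_path)
    logger.info("wrote %d rows to %s", len(all_rows), csv_path)
    return csv_path
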