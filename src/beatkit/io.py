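"""Containers and readers/writers for the formats the pipeline touches.

Images travel as multi-page TIFF with a small JSON sidecar carrying the
physical metadata (frame rate, pixel width, z-step); annotations and ground
truth are plain JSON; result tables are CSV. Coordinates are 0-based pixel
indices, x rightward, y downward; conversion to micrometres happens once, at
reporting time, through ``pixel_width``.

Annotation JSON schema (two heart-wall traces, inflow first)::

    {
      "wall_a": [[x, y], ...],     # >= 4 vertices, inflow -> outflow
      "wall_b": [[x, y], ...],
      "av_marker_a": <int>,        # vertex index on wall_a, strictly interior
      "av_marker_b": <int>,
      "pixel_width": <um per pixel>
    }
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .errors import FormatError, MetadataError, ValidationError
from .geometry import polyline_is_simple


# ---------------------------------------------------------------------------
# containers


@dataclass
class MovieStack:
    """A T x Y x X intensity movie with its physical metadata."""

    pixels: np.ndarray
    frame_rate: float
    pixel_width: float
    origin_label: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[0] < 2:
            raise ValidationError("movie must be T x Y x X with T >= 2")
        if not self.frame_rate > 0:
            raise ValidationError("frame_rate must be positive")
        if not self.pixel_width > 0:
            raise ValidationError("pixel_width must be positive")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape


@dataclass
class ZStack:
    """A static Z x Y x X stack (stopped heart) with its physical metadata."""

    pixels: np.ndarray
    z_step: float
    pixel_width: float

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[0] < 1:
            raise ValidationError("stack must be Z x Y x X with Z >= 1")
        if not self.z_step > 0:
            raise ValidationError("z_step must be positive")
        if not self.pixel_width > 0:
            raise ValidationError("pixel_width must be positive")

    @property
    def n_planes(self) -> int:
        return self.pixels.shape[0]


@dataclass
class HeartAnnotation:
    """Two ordered heart-wall polylines (inflow -> outflow) with AV markers.

    The first vertex of each wall is the inflow (atrial) end. ``av_marker_*``
    are vertex indices marking where each wall passes the AV canal.
    """

    wall_a: np.ndarray
    wall_b: np.ndarray
    av_marker_a: int
    av_marker_b: int
    pixel_width: float

    def __post_init__(self):
        self.wall_a = np.asarray(self.wall_a, dtype=float)
        self.wall_b = np.asarray(self.wall_b, dtype=float)
        for name, wall, marker in (
            ("wall_a", self.wall_a, self.av_marker_a),
            ("wall_b", self.wall_b, self.av_marker_b),
        ):
            if wall.ndim != 2 or wall.shape[1] != 2 or wall.shape[0] < 4:
                raise ValidationError(f"{name} must be an (N, 2) polyline with N >= 4")
            if not (0 < marker < wall.shape[0] - 1):
                raise ValidationError(
                    f"AV marker on {name} must be strictly interior (got {marker})"
                )
            if not polyline_is_simple(wall):
                raise ValidationError(f"{name} is self-intersecting")
        if not self.pixel_width > 0:
            raise ValidationError("pixel_width must be positive")

    def reversed(self) -> "HeartAnnotation":
        """Annotation with the inflow/outflow orientation flipped."""
        return HeartAnnotation(
            wall_a=self.wall_a[::-1].copy(),
            wall_b=self.wall_b[::-1].copy(),
            av_marker_a=len(self.wall_a) - 1 - self.av_marker_a,
            av_marker_b=len(self.wall_b) - 1 - self.av_marker_b,
            pixel_width=self.pixel_width,
        )


# ---------------------------------------------------------------------------
# movies / stacks


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_movie(stack: MovieStack, path) -> None:
    """Write a movie as multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.pixels, photometric="minisblack")
    meta = {
        "kind": "movie",
        "frame_rate": stack.frame_rate,
        "pixel_width": stack.pixel_width,
        "origin_label": stack.origin_label,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_movie(path, frame_rate: float | None = None, pixel_width: float | None = None) -> MovieStack:
    """Read a multi-page TIFF movie; metadata from the sidecar or overrides."""
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            shapes = {p.shape for p in tif.pages}
            if len(shapes) > 1:
                raise FormatError(f"{path}: pages have non-uniform shapes {shapes}")
            pixels = tif.asarray()
    except FormatError:
        raise
    except Exception as exc:  # truncated / not a TIFF
        raise FormatError(f"{path}: cannot be read as a TIFF movie ({exc})") from exc
    if pixels.ndim == 2:
        pixels = pixels[None]
    if pixels.size == 0 or pixels.ndim != 3:
        raise FormatError(f"{path}: no image pages found")
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    frame_rate = frame_rate if frame_rate is not None else meta.get("frame_rate")
    pixel_width = pixel_width if pixel_width is not None else meta.get("pixel_width")
    if frame_rate is None or pixel_width is None:
        raise MetadataError(
            f"{path}: frame_rate/pixel_width not in sidecar and not supplied"
        )
    return MovieStack(
        pixels=pixels,
        frame_rate=float(frame_rate),
        pixel_width=float(pixel_width),
        origin_label=meta.get("origin_label", ""),
    )


def write_zstack(stack: ZStack, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, stack.pixels, photometric="minisblack")
    meta = {"kind": "zstack", "z_step": stack.z_step, "pixel_width": stack.pixel_width}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_zstack(path, z_step: float | None = None, pixel_width: float | None = None) -> ZStack:
    path = Path(path)
    try:
        pixels = tifffile.imread(path)
    except Exception as exc:
        raise FormatError(f"{path}: cannot be read as a TIFF stack ({exc})") from exc
    if pixels.ndim == 2:
        pixels = pixels[None]
    if pixels.size == 0 or pixels.ndim != 3:
        raise FormatError(f"{path}: no image pages found")
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    z_step = z_step if z_step is not None else meta.get("z_step")
    pixel_width = pixel_width if pixel_width is not None else meta.get("pixel_width")
    if z_step is None or pixel_width is None:
        raise MetadataError(f"{path}: z_step/pixel_width not in sidecar and not supplied")
    return ZStack(pixels=pixels, z_step=float(z_step), pixel_width=float(pixel_width))


# ---------------------------------------------------------------------------
# annotations


def write_annotation(annotation: HeartAnnotation, path) -> None:
    payload = {
        "wall_a": annotation.wall_a.tolist(),
        "wall_b": annotation.wall_b.tolist(),
        "av_marker_a": int(annotation.av_marker_a),
        "av_marker_b": int(annotation.av_marker_b),
        "pixel_width": float(annotation.pixel_width),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_annotation(path) -> HeartAnnotation:
    """Load and validate a heart-wall annotation JSON file."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except Exception as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    try:
        return HeartAnnotation(
            wall_a=np.asarray(payload["wall_a"], dtype=float),
            wall_b=np.asarray(payload["wall_b"], dtype=float),
            av_marker_a=int(payload["av_marker_a"]),
            av_marker_b=int(payload["av_marker_b"]),
            pixel_width=float(payload["pixel_width"]),
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing annotation field {exc}") from exc
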