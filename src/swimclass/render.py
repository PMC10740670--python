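"""Rasterize track segments into speed-colored path images.

A segment's path is drawn top-down (the camera plane) on a square canvas:
the arena's bounding square maps affinely onto the image area minus a
margin, consecutive points are joined by strokes, and each stroke is
colored by the relative speed of that step through a fixed perceptually
ordered colormap.  Anti-aliasing is off, so renders are bitwise
reproducible across platforms — the classifier's input representation is
deterministic.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw
from matplotlib import colormaps

from .trajectory import TrackSegment, ValidationError, step_speeds

__all__ = ["RenderConfig", "RenderedImage", "relative_speed_colors", "render_segment",
           "render_dataset", "render_array"]


@dataclass(frozen=True)
class RenderConfig:
    """How a segment is drawn.

    ``speed_norm='segment_minmax'`` rescales speeds within each segment to
    [0, 1] (a constant-speed segment maps to the middle of the colormap);
    ``'global_fixed'`` uses the fixed range ``global_speed_range`` instead,
    making colors comparable across segments.
    """

    image_size: int = 224
    line_width: int = 1
    colormap: str = "viridis"
    speed_norm: str = "segment_minmax"  # or "global_fixed"
    global_speed_range: tuple[float, float] = (0.0, 100.0)
    background: tuple[int, int, int] = (0, 0, 0)
    margin: float = 0.05

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValidationError("image_size must be >= 32")
        if self.line_width < 1:
            raise ValidationError("line_width must be >= 1")
        if self.speed_norm not in ("segment_minmax", "global_fixed"):
            raise ValidationError(f"unknown speed_norm {self.speed_norm!r}")

    @property
    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class RenderedImage:
    pixels: np.ndarray  # (image_size, image_size, 3) uint8
    segment_ref: tuple[str, int]
    config_hash: str


def _colormap_lut(name: str) -> np.ndarray:
    cmap = colormaps[name]
    return (np.asarray(cmap(np.linspace(0.0, 1.0, 256)))[:, :3] * 255).round().astype(np.uint8)


def relative_speed_colors(speeds: np.ndarray, config: RenderConfig) -> np.ndarray:
    """Map step speeds to RGB stroke colors (uint8, one row per step)."""
    speeds = np.asarray(speeds, dtype=np.float64)
    if speeds.size == 0:
        raise ValidationError("speeds must be non-empty")
    if config.speed_norm == "segment_minmax":
        lo, hi = speeds.min(), speeds.max()
        # treat float-noise-level spread as constant speed
        if hi - lo <= 1e-9 * max(abs(hi), 1.0):
            t = np.full(speeds.shape, 0.5)
        else:
            t = (speeds - lo) / (hi - lo)
    else:
        lo, hi = config.global_speed_range
        t = np.clip((speeds - lo) / max(hi - lo, 1e-12), 0.0, 1.0)
    lut = _colormap_lut(config.colormap)
    return lut[np.round(t * 255).astype(int)]


def render_segment(seg: TrackSegment, config: RenderConfig | None = None) -> RenderedImage:
    """Draw one segment; identical inputs produce bitwise-identical rasters."""
    if config is None:
        config = RenderConfig()
    if seg.arena.radius <= 0:
        raise ValidationError("degenerate arena")
    size = config.image_size
    pad = config.margin * size
    span = size - 2 * pad
    xmin, ymin, xmax, ymax = seg.arena.bounding_box
    scale = span / (xmax - xmin)  # bounding box is square: same scale both axes

    pts = (seg.coords - np.array([xmin, ymin])) * scale + pad
    img = Image.new("RGB", (size, size), tuple(config.background))
    draw = ImageDraw.Draw(img)
    colors = relative_speed_colors(step_speeds(seg), config)
    moved = np.any(np.diff(seg.coords, axis=0) != 0, axis=1)
    half = config.line_width / 2.0
    if not moved.any():
        # stationary segment: a single dot at the (constant) position
        x, y = pts[0]
        draw.ellipse([x - half, y - half, x + half, y + half], fill=tuple(colors[0]))
    else:
        for i in range(len(pts) - 1):
            if not moved[i]:
                continue
            draw.line(
                [tuple(pts[i]), tuple(pts[i + 1])],
                fill=tuple(colors[i]),
                width=config.line_width,
            )
    return RenderedImage(
        pixels=np.asarray(img, dtype=np.uint8),
        segment_ref=seg.ref,
        config_hash=config.config_hash,
    )


def render_array(segments, config: RenderConfig | None = None) -> np.ndarray:
    """Render many segments into one (n, size, size, 3) uint8 array."""
    if config is None:
        config = RenderConfig()
    if not segments:
        return np.zeros((0, config.image_size, config.image_size, 3), dtype=np.uint8)
    return np.stack([render_segment(s, config).pixels for s in segments])


def render_dataset(segments, config: RenderConfig, out_dir) -> pd.DataFrame:
    """Render segments to PNGs under ``out_dir`` and return the image manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for seg in segments:
        rendered = render_segment(seg, config)
        fname = f"{seg.fish_id}_seg{seg.segment_id:04d}.png"
        Image.fromarray(rendered.pixels).save(out / fname)
        rows.append(
            {
                "file": fname,
                "fish_id": seg.fish_id,
                "segment_id": seg.segment_id,
                "label": seg.label.name,
                "concentration": seg.label.concentration,
                "start_time": seg.start_time,
                "config_hash": rendered.config_hash,
            }
        )
    manifest = pd.DataFrame(
        rows,
        columns=["file", "fish_id", "segment_id", "label", "concentration",
                 "start_time", "config_hash"],
    )
    manifest.to_csv(out / "images.csv", index=False)
    return manifest
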