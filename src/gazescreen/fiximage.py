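"""Render recordings into Fix-images.

A Fix-image is a 2D summary of the event-level fixations of one reading
trial: each fixation becomes one filled ellipse on a canvas bounded by the
displayed-text area, centred at the fixation position, with per-axis radii
given by half the fixation dispersion, and coloured by the fixation duration
along a black -> red -> orange -> yellow ramp (short to long).  The native
canvas (roughly the 1200 x 400 px text area) is then rescaled to the square
input size of the image classifier.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image, ImageDraw

from .events import Recording

DEFAULT_COLORMAP = ((0, 0, 0), (255, 0, 0), (255, 165, 0), (255, 255, 0))


class ConfigError(ValueError):
    """Rendering configuration inconsistent with the supplied recordings."""


@dataclass(frozen=True)
class CanvasGeometry:
    """Screen-pixel bounds of the displayed-text area (upper-left, lower-right)."""

    text_x0: float
    text_y0: float
    text_x1: float
    text_y1: float

    def __post_init__(self) -> None:
        if not (self.text_x1 > self.text_x0 and self.text_y1 > self.text_y0):
            raise ValueError("text area corners must be ordered x1 > x0, y1 > y0")

    @property
    def width(self) -> int:
        return int(round(self.text_x1 - self.text_x0))

    @property
    def height(self) -> int:
        return int(round(self.text_y1 - self.text_y0))


#: Text area of the bundled stimuli on a 1680 x 1050 screen (~1200 x 400 px).
DEFAULT_GEOMETRY = CanvasGeometry(240.0, 300.0, 1440.0, 700.0)


@dataclass(frozen=True)
class RenderConfig:
    """Rendering knobs.

    ``ellipse_mode="dispersion"`` sets per-axis radii to dispersion / 2
    (dispersion is a full max-min extent, so it acts as the diameter);
    ``"constant"`` ignores dispersion and uses ``constant_radius_px``, which
    also serves as the fallback when a fixation carries no dispersion.
    ``normalization_scope`` decides whether durations are min-max scaled
    within each recording or across a whole task cohort.
    """

    output_size: int = 224
    colormap: tuple[tuple[int, int, int], ...] = DEFAULT_COLORMAP
    ellipse_mode: str = "dispersion"
    constant_radius_px: float = 10.0
    min_radius_px: float = 2.0
    background: tuple[int, int, int] = (255, 255, 255)
    normalization_scope: str = "per_recording"

    def __post_init__(self) -> None:
        if self.output_size <= 0:
            raise ValueError("output_size must be positive")
        if self.min_radius_px <= 0:
            raise ValueError("min_radius_px must be positive")
        if self.ellipse_mode not in ("dispersion", "constant"):
            raise ValueError("ellipse_mode must be 'dispersion' or 'constant'")
        if self.normalization_scope not in ("per_recording", "per_task_cohort"):
            raise ValueError(
                "normalization_scope must be 'per_recording' or 'per_task_cohort'"
            )
        if len(self.colormap) < 2:
            raise ValueError("colormap needs at least two stops")

    def config_hash(self) -> str:
        return hashlib.sha1(repr(self).encode()).hexdigest()[:12]


@dataclass
class FixImage:
    """An output_size x output_size x 3 uint8 raster plus provenance."""

    pixels: np.ndarray
    participant_id: str
    task_id: str
    config_hash: str
    label: str = "unknown"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.uint8)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] != px.shape[1]:
            raise ValueError(f"pixels must be square HxWx3, got {px.shape}")
        self.pixels = px


def normalise_durations(
    durations: Sequence[float], scope_pool: Sequence[float] | None = None
) -> list[float]:
    """Min-max map durations to [0, 1] using the pool's extremes.

    The pool defaults to the durations themselves.  A constant pool maps
    everything to 1.0: a lone duration is "the longest observed".
    """
    durations = list(durations)
    if not durations:
        return []
    pool = list(scope_pool) if scope_pool is not None else durations
    lo, hi = min(pool), max(pool)
    if hi == lo:
        return [1.0] * len(durations)
    return [(d - lo) / (hi - lo) for d in durations]


def duration_to_colour(
    u: float, colormap: tuple[tuple[int, int, int], ...] = DEFAULT_COLORMAP
) -> tuple[int, int, int]:
    """Piecewise-linear interpolation of a unit-interval value along the ramp."""
    if not 0.0 <= u <= 1.0:
        raise ValueError(f"normalised duration must lie in [0, 1], got {u}")
    n_seg = len(colormap) - 1
    x = u * n_seg
    seg = min(int(x), n_seg - 1)
    t = x - seg
    c0, c1 = colormap[seg], colormap[seg + 1]
    return tuple(int(round(a + t * (b - a))) for a, b in zip(c0, c1))


def _radii(fix, config: RenderConfig) -> tuple[float, float]:
    if (
        config.ellipse_mode == "constant"
        or fix.disp_x is None
        or fix.disp_y is None
    ):
        rx = ry = config.constant_radius_px
    else:
        rx, ry = fix.disp_x / 2.0, fix.disp_y / 2.0
    return max(rx, config.min_radius_px), max(ry, config.min_radius_px)


def render_native(
    recording: Recording,
    geometry: CanvasGeometry = DEFAULT_GEOMETRY,
    config: RenderConfig = RenderConfig(),
    duration_pool: Sequence[float] | None = None,
) -> Image.Image:
    """Draw the ellipses at native text-area resolution (no rescale).

    Fixations are drawn fully opaque in temporal order, so later fixations
    over-paint earlier ones; ellipses extending beyond the text area are
    clipped rather than dropped.  Zero fixations yield a pure background
    canvas.
    """
    img = Image.new("RGB", (geometry.width, geometry.height), config.background)
    draw = ImageDraw.Draw(img)
    durations = [f.duration_ms for f in recording.fixations]
    units = normalise_durations(durations, duration_pool)
    for fix, u in zip(recording.fixations, units):
        colour = duration_to_colour(u, config.colormap)
        rx, ry = _radii(fix, config)
        cx = fix.pos_x - geometry.text_x0
        cy = fix.pos_y - geometry.text_y0
        draw.ellipse((cx - rx, cy - ry, cx + rx, cy + ry), fill=colour)
    return img


def render_fiximage(
    recording: Recording,
    geometry: CanvasGeometry = DEFAULT_GEOMETRY,
    config: RenderConfig = RenderConfig(),
    duration_pool: Sequence[float] | None = None,
) -> FixImage:
    """Render one recording and rescale to the classifier input size.

    Bilinear rescale to ``output_size`` square; aspect ratio is not
    preserved (the text-area crop is stretched directly, matching the
    fixed-size classifier input).
    """
    native = render_native(recording, geometry, config, duration_pool)
    resized = native.resize(
        (config.output_size, config.output_size), Image.Resampling.BILINEAR
    )
    return FixImage(
        pixels=np.asarray(resized, dtype=np.uint8),
        participant_id=recording.participant_id,
        task_id=recording.task_id,
        config_hash=config.config_hash(),
        label=recording.label,
    )


def render_cohort(
    recordings: Iterable[Recording],
    geometry: CanvasGeometry = DEFAULT_GEOMETRY,
    config: RenderConfig = RenderConfig(),
    out_dir: str | Path | None = None,
) -> list[FixImage]:
    """Render a batch of recordings, optionally writing one PNG each.

    Under ``per_task_cohort`` scope the duration pool is the union of all
    recordings' fixation durations (all recordings must share one task), so
    a long fixation in one subject renders yellower than a short fixation
    in another.  Files are named ``{participant}_{task}.png``.
    """
    recordings = list(recordings)
    pool: list[float] | None = None
    if config.normalization_scope == "per_task_cohort":
        tasks = {r.task_id for r in recordings}
        if len(tasks) > 1:
            raise ConfigError(
                f"per_task_cohort normalisation requires a single task, got {sorted(tasks)}"
            )
        pool = [f.duration_ms for r in recordings for f in r.fixations]
        if not pool:
            pool = None
    images = [render_fiximage(r, geometry, config, pool) for r in recordings]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for img in images:
            Image.fromarray(img.pixels).save(
                out_dir / f"{img.participant_id}_{img.task_id}.png"
            )
    return images
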