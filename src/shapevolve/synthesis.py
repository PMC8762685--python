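"""Shape synthesis: genomes and point lists -> contours, masks, measurements.

A radial-frequency contour is a circle of ``base_radius`` pixels whose
radius is modulated by a sum of sinusoids:

    r(theta) = R + s * sum_f gate_f * A_f * sin(f*theta + phi_f * pi/180)

with the amplitude scale ``s = base_radius / 100`` by default, so an
amplitude of 100 internal units modulates by one full radius.  A negative
modulated radius is permitted; the point reflects through the origin,
producing the characteristic internal loops of high-amplitude shapes.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path as FsPath

import numpy as np
from matplotlib.path import Path as MplPath
from shapely.geometry import LineString

from .genome import RFGenome

__all__ = [
    "ShapeContour",
    "ShapeMask",
    "SynthConfig",
    "synthesize_contour",
    "rasterize",
    "perimeter_area",
    "isoperimetric_ratio",
    "load_silhouette",
    "save_contour",
    "resample_contour",
    "render_stimulus",
]

logger = logging.getLogger(__name__)

#: Outline color of rendered stimuli (green on black).
STIMULUS_RGB = (83, 187, 121)


class ContourError(ValueError):
    """Raised for degenerate contours or unusable contour files."""


@dataclass(frozen=True)
class SynthConfig:
    """Synthesis and rasterization settings.

    amp_scale defaults to base_radius / 100: genome amplitudes are kept in
    the 50-150 bookkeeping units while 100 units correspond to one full
    base radius of modulation.
    """

    base_radius: float = 30.0
    n_points: int = 360
    amp_scale: float | None = None
    canvas: int = 128

    def __post_init__(self) -> None:
        if self.base_radius <= 0:
            raise ContourError("base_radius must be positive")
        if self.n_points < 32:
            raise ContourError("n_points must be >= 32")
        if self.amp_scale is None:
            object.__setattr__(self, "amp_scale", self.base_radius / 100.0)
        if self.amp_scale <= 0:
            raise ContourError("amp_scale must be positive")
        if self.canvas < 8:
            raise ContourError("canvas must be at least 8 px")


@dataclass(frozen=True)
class ShapeContour:
    """Closed planar polyline in pixel units (last point connects to first)."""

    points: np.ndarray
    source: str = "silhouette"
    base_radius: float = 30.0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise ContourError("contour needs >= 3 (x, y) points")
        closed = np.vstack([pts, pts[:1]])
        if np.any(np.all(np.diff(closed, axis=0) == 0, axis=1)):
            raise ContourError("contour has identical consecutive points")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def translated(self, dx: float, dy: float) -> "ShapeContour":
        return ShapeContour(self.points + [dx, dy], self.source, self.base_radius)

    def rotated(self, degrees: float) -> "ShapeContour":
        """Rigid rotation about the contour centroid."""
        a = np.deg2rad(degrees)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        c = self.centroid
        return ShapeContour((self.points - c) @ rot.T + c, self.source, self.base_radius)

    def scaled(self, factor: float) -> "ShapeContour":
        c = self.centroid
        return ShapeContour((self.points - c) * factor + c, self.source, self.base_radius)

    def is_simple(self) -> bool:
        """True if the closed contour does not self-intersect."""
        ring = np.vstack([self.points, self.points[:1]])
        return LineString(ring).is_simple


@dataclass(frozen=True)
class ShapeMask:
    """Filled or outline binary raster of a shape."""

    grid: np.ndarray
    pixel_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=bool)
        if grid.ndim != 2:
            raise ContourError("mask grid must be 2-D")
        if not grid.any():
            raise ContourError("mask has no foreground")
        object.__setattr__(self, "grid", grid)

    @property
    def area(self) -> float:
        return float(self.grid.sum()) * self.pixel_size**2


def synthesize_contour(g: RFGenome, cfg: SynthConfig = SynthConfig()) -> ShapeContour:
    """Realize a genome as a closed contour sampled at n_points angles."""
    theta = 2.0 * np.pi * np.arange(cfg.n_points) / cfg.n_points
    freqs = np.arange(1, g.amplitudes.size + 1)
    # (n_points, n_freq) sinusoid bank; phases converted degrees -> radians
    waves = np.sin(np.outer(theta, freqs) + np.deg2rad(g.phases))
    r = cfg.base_radius + cfg.amp_scale * waves @ (g.gates * g.amplitudes)
    if np.max(np.abs(r)) < 1e-12:
        raise ContourError("null contour: modulated radius vanishes everywhere")
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    return ShapeContour(points=pts, source=g.id, base_radius=cfg.base_radius)


def _closed(points: np.ndarray) -> np.ndarray:
    return np.vstack([points, points[:1]])


def perimeter_area(c: ShapeContour, cfg: SynthConfig = SynthConfig()) -> tuple[float, float]:
    """Perimeter and enclosed area of a closed contour.

    Perimeter sums consecutive-point Euclidean distances (closed).  Area is
    the shoelace formula for simple contours; a self-intersecting contour
    falls back to the foreground pixel count of its nonzero-winding filled
    mask, so internal loops count as filled lobes.
    """
    ring = _closed(c.points)
    perimeter = float(np.sum(np.hypot(*np.diff(ring, axis=0).T)))
    x, y = ring[:-1, 0], ring[:-1, 1]
    shoelace = 0.5 * abs(float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))
    if shoelace < 1e-12:
        raise ContourError("null contour: zero enclosed area")
    if c.is_simple():
        return perimeter, shoelace
    area = rasterize(c, cfg, fill=True).area
    return perimeter, float(area)


def isoperimetric_ratio(c: ShapeContour, cfg: SynthConfig = SynthConfig()) -> float:
    """Total-curvature index P^2 / A (4*pi for a circle, larger otherwise)."""
    p, a = perimeter_area(c, cfg)
    return p * p / a


def rasterize(c: ShapeContour, cfg: SynthConfig = SynthConfig(), fill: bool = True) -> ShapeMask:
    """Rasterize a contour onto a square canvas, centered on its centroid.

    fill=True fills the interior by the nonzero winding rule (internal
    loops render as filled lobes); fill=False traces a 1-px outline.
    A contour too large for the canvas is shrunk (never enlarged) with a
    logged warning.
    """
    pts = c.points - c.centroid
    half = cfg.canvas / 2.0 - 1.5
    extent = np.max(np.abs(pts))
    if extent > half:
        factor = half / extent
        if factor < 1e-3:
            raise ContourError("canvas too small for contour even after maximal shrink")
        logger.warning("contour exceeds canvas; auto-scaling by %.4f", factor)
        pts = pts * factor
    pts = pts + cfg.canvas / 2.0

    grid = np.zeros((cfg.canvas, cfg.canvas), dtype=bool)
    if fill:
        ii, jj = np.mgrid[0 : cfg.canvas, 0 : cfg.canvas]
        centers = np.column_stack([jj.ravel() + 0.5, ii.ravel() + 0.5])  # (x, y)
        path = MplPath(_closed(pts), closed=True)
        inside = path.contains_points(centers)  # nonzero winding rule
        grid = inside.reshape(cfg.canvas, cfg.canvas)
    else:
        from skimage.draw import line

        ring = np.rint(_closed(pts)).astype(int)
        for (x0, y0), (x1, y1) in zip(ring[:-1], ring[1:]):
            rr, cc = line(y0, x0, y1, x1)
            ok = (rr >= 0) & (rr < cfg.canvas) & (cc >= 0) & (cc < cfg.canvas)
            grid[rr[ok], cc[ok]] = True
    if not grid.any():
        raise ContourError("rasterization produced an empty mask")
    return ShapeMask(grid=grid, pixel_size=1.0, origin=(0.0, 0.0))


def resample_contour(points: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a closed polyline to n_points equally spaced by arc length."""
    ring = _closed(np.asarray(points, dtype=float))
    seg = np.hypot(*np.diff(ring, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ContourError("degenerate polyline: zero total length")
    targets = np.linspace(0.0, total, n_points, endpoint=False)
    x = np.interp(targets, s, ring[:, 0])
    y = np.interp(targets, s, ring[:, 1])
    return np.column_stack([x, y])


def load_silhouette(
    path: str | FsPath, cfg: SynthConfig = SynthConfig(), resample: bool = True
) -> ShapeContour:
    """Load a closed silhouette contour from a CSV of ``x,y`` rows.

    An open polyline (first point != last) is closed automatically; the
    contour is resampled to cfg.n_points by arc length unless it already
    has that many points or resample=False.
    """
    path = FsPath(path)
    pts: list[tuple[float, float]] = []
    with path.open(newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].strip().lower() in ("x", "# x", "#x"):
                continue  # header
            try:
                pts.append((float(row[0]), float(row[1])))
            except (ValueError, IndexError) as exc:
                raise ContourError(f"{path}:{lineno}: not a numeric x,y row: {row!r}") from exc
    arr = np.asarray(pts, dtype=float)
    if arr.shape[0] >= 2 and np.allclose(arr[0], arr[-1]):
        arr = arr[:-1]  # stored closed; drop duplicate closing point
    keep = np.ones(len(arr), dtype=bool)
    keep[1:] = np.any(np.diff(arr, axis=0) != 0, axis=1)
    arr = arr[keep]
    if arr.shape[0] < 3:
        raise ContourError(f"{path}: a silhouette needs at least 3 distinct points")
    if resample and arr.shape[0] != cfg.n_points:
        arr = resample_contour(arr, cfg.n_points)
    return ShapeContour(points=arr, source="silhouette", base_radius=cfg.base_radius)


def save_contour(c: ShapeContour, path: str | FsPath) -> None:
    """Write a contour as CSV, one ``x,y`` row per point."""
    np.savetxt(path, c.points, delimiter=",", fmt="%.6f")


def render_stimulus(
    c: ShapeContour,
    path: str | FsPath,
    cfg: SynthConfig = SynthConfig(),
    color: tuple[int, int, int] = STIMULUS_RGB,
) -> None:
    """Render the contour as a colored outline on black and save as PNG."""
    import imageio.v3 as iio

    outline = rasterize(c, cfg, fill=False).grid
    img = np.zeros((*outline.shape, 3), dtype=np.uint8)
    img[outline] = color
    iio.imwrite(FsPath(path), img)
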