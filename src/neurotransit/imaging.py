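"""Confocal-stack quantification of GFP / Myc / pRb signals.

Reimplements the two quantification macros for 3-channel z-stacks:

1. subtract an "average background" stack acquired off-tissue;
2. subtract the z- and channel-resolved mean of a user-drawn tissue ROI
   (tracking the progressive loss of background with depth), then fixed
   per-channel constants (GFP 5, Myc 5, pRb 60), clamping at zero;
3. rotate so the apical surface is horizontal and crop at the surface, so
   a pixel's y coordinate is its distance to the apical surface in um;
4. measure each selected cell as the mean intensity inside a fixed-diameter
   circle at a single z-level; call pRb status with the strict > 30 rule.

The two subtraction steps must run in that order; the pipeline runner
enforces it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.draw import polygon as sk_polygon

__all__ = [
    "ImageStack",
    "BackgroundSpec",
    "CellMeasurement",
    "average_background_stack",
    "subtract_average_background",
    "subtract_tissue_background",
    "align_apical_surface",
    "measure_cell",
    "call_prb_status",
    "apicobasal_profile",
    "quantify_stack",
]

CHANNELS = ("GFP", "Myc", "pRb")
DEFAULT_CONSTANTS = {"GFP": 5.0, "Myc": 5.0, "pRb": 60.0}
PRB_THRESHOLD = 30.0
DEFAULT_DIAMETER_UM = 8.0


@dataclass
class ImageStack:
    """z x channel x y x x fluorescence volume with physical spacing."""

    pixels: np.ndarray
    z_step_um: float = 1.0
    pixel_size_um: float = 0.2
    channels: tuple[str, ...] = CHANNELS
    apical_axis_aligned: bool = False

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 4:
            raise ValueError("pixels must be z x channel x y x x")
        if self.pixels.shape[1] != len(self.channels):
            raise ValueError("channel axis does not match channel names")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("intensities must be finite and >= 0")

    @property
    def n_z(self) -> int:
        return self.pixels.shape[0]

    def channel_index(self, name: str) -> int:
        return self.channels.index(name)

    @classmethod
    def from_tiff(cls, path, **kwargs) -> "ImageStack":
        arr = tifffile.imread(str(path))
        if arr.ndim == 3:  # single z-level, c x y x x
            arr = arr[None]
        return cls(pixels=np.asarray(arr, dtype=float), **kwargs)

    def to_tiff(self, path) -> None:
        tifffile.imwrite(str(path), self.pixels.astype(np.float32))


@dataclass
class BackgroundSpec:
    """Tissue-ROI polygon and per-channel residual constants."""

    tissue_roi: np.ndarray  # polygon vertices, (n, 2) as (x, y) in pixels
    channel_constants: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CONSTANTS))

    def __post_init__(self):
        self.tissue_roi = np.asarray(self.tissue_roi, dtype=float)
        if self.tissue_roi.ndim != 2 or self.tissue_roi.shape[0] < 3:
            raise ValueError("ROI polygon needs >= 3 vertices")
        if any(v < 0 for v in self.channel_constants.values()):
            raise ValueError("channel constants must be >= 0")


@dataclass
class CellMeasurement:
    x_um: float
    y_um: float
    z_index: int
    mean_gfp: float
    mean_myc: float
    mean_prb: float
    prb_pos: bool | None = None
    in_bounds: bool = True


def average_background_stack(raw_background: np.ndarray, n_z: int | None = None) -> np.ndarray:
    """Average-project a background acquisition and restack identical z-levels."""
    raw = np.asarray(raw_background, dtype=float)
    if raw.ndim != 4:
        raise ValueError("background acquisition must be z x channel x y x x")
    proj = raw.mean(axis=0)
    return np.repeat(proj[None], n_z or raw.shape[0], axis=0)


def subtract_average_background(stack: ImageStack, bg_stack: np.ndarray) -> ImageStack:
    """Per-pixel subtraction of the average-background stack, clamped at 0."""
    if getattr(stack, "_tissue_bg_done", False):
        raise RuntimeError(
            "average-background subtraction must run before tissue-ROI subtraction"
        )
    bg = np.asarray(bg_stack, dtype=float)
    try:
        out = np.maximum(stack.pixels - bg, 0.0)
    except ValueError as e:
        raise ValueError(f"background stack shape incompatible: {e}") from e
    s = ImageStack(out, stack.z_step_um, stack.pixel_size_um, stack.channels, stack.apical_axis_aligned)
    s._avg_bg_done = True  # type: ignore[attr-defined]
    return s


def subtract_tissue_background(stack: ImageStack, spec: BackgroundSpec) -> ImageStack:
    """Z-progressive background removal from a signal-free tissue ROI.

    For every channel and z-level, the mean intensity inside the ROI is
    subtracted, then the channel constant, clamping at zero after each
    step.  The measured channel x z background table is attached to the
    returned stack as ``tissue_background_table``.
    """
    ny, nx = stack.pixels.shape[2:]
    rr, cc = sk_polygon(spec.tissue_roi[:, 1], spec.tissue_roi[:, 0], shape=(ny, nx))
    if rr.size == 0:
        raise ValueError("ROI polygon lies outside the image")
    out = stack.pixels.copy()
    table = np.zeros((len(stack.channels), stack.n_z))
    for ci, ch in enumerate(stack.channels):
        const = spec.channel_constants.get(ch, 0.0)
        for z in range(stack.n_z):
            level = float(out[z, ci, rr, cc].mean())
            table[ci, z] = level
            out[z, ci] = np.maximum(out[z, ci] - level, 0.0)
            out[z, ci] = np.maximum(out[z, ci] - const, 0.0)
    s = ImageStack(out, stack.z_step_um, stack.pixel_size_um, stack.channels, stack.apical_axis_aligned)
    s.tissue_background_table = pd.DataFrame(  # type: ignore[attr-defined]
        table, index=list(stack.channels), columns=[f"z{z}" for z in range(stack.n_z)]
    )
    s._avg_bg_done = getattr(stack, "_avg_bg_done", False)  # type: ignore[attr-defined]
    s._tissue_bg_done = True  # type: ignore[attr-defined]
    return s


def align_apical_surface(stack: ImageStack, surface_line: np.ndarray) -> ImageStack:
    """Rotate so the apical-surface line is horizontal, then crop at it.

    ``surface_line`` is two (x, y) pixel points on the apical surface; the
    tissue is assumed to lie on the larger-y side.  Bilinear interpolation;
    after alignment a pixel's y index times the pixel size is its distance
    from the apical surface in um.
    """
    pts = np.asarray(surface_line, dtype=float)
    if pts.shape != (2, 2):
        raise ValueError("surface_line must be two (x, y) points")
    (x0, y0), (x1, y1) = pts
    if np.hypot(x1 - x0, y1 - y0) < 1e-9:
        raise ValueError("degenerate surface line (identical points)")
    angle = np.degrees(np.arctan2(y1 - y0, x1 - x0))
    nz, nc, ny, nx = stack.pixels.shape
    center = np.array([(nx - 1) / 2.0, (ny - 1) / 2.0])
    out = np.empty_like(stack.pixels)
    for z in range(nz):
        for c in range(nc):
            out[z, c] = ndimage.rotate(
                stack.pixels[z, c], angle, reshape=False, order=1, mode="constant", cval=0.0
            )
    out = np.maximum(out, 0.0)
    # y position of the (rotated) surface line: rotate its midpoint about the center
    mid = pts.mean(axis=0) - center
    rad = np.radians(-angle)
    rot = np.array([[np.cos(rad), -np.sin(rad)], [np.sin(rad), np.cos(rad)]])
    y_line = (rot @ mid)[1] + center[1]
    row0 = int(np.clip(np.round(y_line), 0, ny - 1))
    cropped = out[:, :, row0:, :]
    return ImageStack(cropped, stack.z_step_um, stack.pixel_size_um, stack.channels, apical_axis_aligned=True)


def aligned_coords(
    stack: ImageStack, surface_line: np.ndarray, points_xy_px: np.ndarray
) -> np.ndarray:
    """Map raw-frame pixel (x, y) points into the aligned-cropped frame (um).

    Applies the same rotation-about-center and surface crop as
    :func:`align_apical_surface`; returns (x_um, y_um) with y the distance
    from the apical surface.
    """
    pts = np.atleast_2d(np.asarray(points_xy_px, dtype=float))
    (x0, y0), (x1, y1) = np.asarray(surface_line, dtype=float)
    angle = np.degrees(np.arctan2(y1 - y0, x1 - x0))
    ny, nx = stack.pixels.shape[2:]
    center = np.array([(nx - 1) / 2.0, (ny - 1) / 2.0])
    rad = np.radians(-angle)
    rot = np.array([[np.cos(rad), -np.sin(rad)], [np.sin(rad), np.cos(rad)]])
    moved = (rot @ (pts - center).T).T + center
    mid = np.asarray(surface_line, dtype=float).mean(axis=0) - center
    y_line = (rot @ mid)[1] + center[1]
    row0 = int(np.clip(np.round(y_line), 0, ny - 1))
    out = np.column_stack([moved[:, 0], moved[:, 1] - row0]) * stack.pixel_size_um
    return out


def measure_cell(
    stack: ImageStack,
    x_um: float,
    y_um: float,
    z_index: int,
    diameter_um: float = DEFAULT_DIAMETER_UM,
    prb_threshold: float = PRB_THRESHOLD,
) -> CellMeasurement:
    """Mean channel intensities in a fixed circle at a single z-level.

    The circle includes pixels whose center lies within ``diameter_um/2``
    of (x, y).  Circles reaching outside the image are flagged and measured
    over the in-bounds pixels only.
    """
    px = stack.pixel_size_um
    ny, nx = stack.pixels.shape[2:]
    cx, cy = x_um / px, y_um / px
    r = diameter_um / 2.0 / px
    xs = np.arange(nx)
    ys = np.arange(ny)
    mask = (xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2 <= r**2
    in_bounds = (cx - r >= -0.5) and (cx + r <= nx - 0.5) and (cy - r >= -0.5) and (cy + r <= ny - 0.5)
    if not mask.any():
        raise ValueError("measurement circle contains no pixels")
    if not in_bounds:
        warnings.warn("measurement circle partially outside image; mean over in-bounds pixels")
    means = {ch: float(stack.pixels[z_index, ci][mask].mean()) for ci, ch in enumerate(stack.channels)}
    m = CellMeasurement(
        x_um=float(x_um),
        y_um=float(y_um),
        z_index=int(z_index),
        mean_gfp=means.get("GFP", np.nan),
        mean_myc=means.get("Myc", np.nan),
        mean_prb=means.get("pRb", np.nan),
        in_bounds=bool(in_bounds),
    )
    m.prb_pos = call_prb_status(m, prb_threshold)
    return m


def call_prb_status(m: CellMeasurement, threshold: float = PRB_THRESHOLD) -> bool:
    """pRb positivity: strictly greater than the threshold (30 -> negative)."""
    return bool(m.mean_prb > threshold)


def apicobasal_profile(measurements: list[CellMeasurement], bin_width_um: float | None = None) -> pd.DataFrame:
    """Long-form table of Myc intensity versus apico-basal position.

    One row per cell with its distance from the apical surface, Myc mean
    and pRb status; optionally adds the y-bin mean Myc per pRb group.
    """
    if not measurements:
        return pd.DataFrame(columns=["y_um", "myc_intensity", "prb_pos"])
    df = pd.DataFrame(
        {
            "y_um": [m.y_um for m in measurements],
            "myc_intensity": [m.mean_myc for m in measurements],
            "prb_pos": [bool(m.prb_pos) for m in measurements],
        }
    )
    if bin_width_um is not None:
        df["y_bin"] = (df["y_um"] // bin_width_um) * bin_width_um
    return df


def quantify_stack(
    stack: ImageStack,
    bg_stack: np.ndarray | None,
    spec: BackgroundSpec,
    surface_line: np.ndarray,
    seeds: pd.DataFrame,
    diameter_um: float = DEFAULT_DIAMETER_UM,
) -> list[CellMeasurement]:
    """Run the full macro pipeline in its fixed order.

    average-background subtraction -> tissue-ROI subtraction -> apical
    alignment -> circle measurements at the seed points (columns x_um,
    y_um, z_index, given in the aligned frame).
    """
    s = stack
    if bg_stack is not None:
        s = subtract_average_background(s, bg_stack)
    s = subtract_tissue_background(s, spec)
    if not getattr(s, "_avg_bg_done", bg_stack is None):
        raise RuntimeError("average-background subtraction must precede tissue subtraction")
    s = align_apical_surface(s, surface_line)
    return [
        measure_cell(s, row.x_um, row.y_um, int(row.z_index), diameter_um)
        for row in seeds.itertuples()
    ]
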