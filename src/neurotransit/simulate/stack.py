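"""Synthetic 3-channel confocal stacks of nuclei in tissue.

Nuclei are 2-D Gaussian blobs placed at one z-level each, with channel
amplitudes drawn from a planted apico-basal state model: apical cells are
pRb-bright and Myc-dim (cycling progenitors), basal cells pRb-dark and
Myc-bright (differentiating neurons).  Backgrounds decay linearly with z
per channel; Poisson-Gaussian sensor noise on top.  The apical surface is
drawn at a configurable tilt and the nucleus table is expressed in both
raw-frame and surface-aligned coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..imaging import CHANNELS, ImageStack

__all__ = ["StackSimParams", "simulate_image_stack"]


@dataclass(frozen=True)
class StackSimParams:
    n_nuclei: int = 40
    shape_xy: tuple[int, int] = (240, 240)   # (ny, nx)
    n_z: int = 31
    z_step_um: float = 1.0
    pixel_size_um: float = 0.5
    nucleus_sigma_um: float = 1.6
    # additive background: value = b0 + b1 * z per channel
    bg_b0: tuple[float, float, float] = (40.0, 35.0, 90.0)
    bg_b1: tuple[float, float, float] = (-0.8, -0.7, -1.5)
    # residual flat background (the macros' per-channel constants)
    bg_const: tuple[float, float, float] = (5.0, 5.0, 60.0)
    noise_gauss_sd: float = 1.0
    poisson_noise: bool = True
    surface_tilt_deg: float = 8.0
    surface_offset_px: float = 15.0
    apical_cut_um: float = 50.0              # apical (pRb+) vs basal (pRb-) boundary
    gfp_amp: tuple[float, float] = (150.0, 40.0)
    myc_apical: tuple[float, float] = (60.0, 15.0)
    myc_basal: tuple[float, float] = (220.0, 40.0)
    prb_apical: tuple[float, float] = (180.0, 40.0)
    prb_basal: tuple[float, float] = (8.0, 4.0)


def simulate_image_stack(params: StackSimParams, seed: int = 0) -> tuple[ImageStack, pd.DataFrame]:
    """Returns (stack, nuclei truth table).

    Truth columns: x_px, y_px, z_index, dist_um (distance from the apical
    surface), prb_state, amp_gfp, amp_myc, amp_prb (planted amplitudes).
    """
    p = params
    rng = np.random.default_rng(seed)
    ny, nx = p.shape_xy
    yy, xx = np.mgrid[0:ny, 0:nx]

    # apical surface: y = offset + tan(tilt) * x ; tissue below (larger y)
    slope = np.tan(np.radians(p.surface_tilt_deg))
    surf_y = p.surface_offset_px + slope * xx[0]

    # z-gradient background everywhere; the flat residual constants only
    # inside the tissue (below the apical surface), so an off-tissue ROI
    # measures the gradient and the macro's constant handles the residual
    tissue = yy > (p.surface_offset_px + slope * xx)
    pixels = np.zeros((p.n_z, len(CHANNELS), ny, nx))
    for ci in range(len(CHANNELS)):
        for z in range(p.n_z):
            pixels[z, ci] += p.bg_b0[ci] + p.bg_b1[ci] * z
            pixels[z, ci] += np.where(tissue, p.bg_const[ci], 0.0)

    sig_px = p.nucleus_sigma_um / p.pixel_size_um
    rows = []
    margin = 4 * sig_px
    placed: list[tuple[int, float, float]] = []  # (z, x, y) of accepted nuclei
    min_sep_px = 6 * sig_px  # nuclei at the same z-level exclude each other
    attempts = 0
    while len(rows) < p.n_nuclei and attempts < 40 * p.n_nuclei:
        attempts += 1
        x = rng.uniform(margin, nx - margin)
        dist_um = rng.uniform(3.0, 85.0)
        # place along the surface normal so dist_um is perpendicular distance
        tilt = np.radians(p.surface_tilt_deg)
        nx_, ny_ = -np.sin(tilt), np.cos(tilt)
        y = (p.surface_offset_px + slope * x) + dist_um / p.pixel_size_um * ny_
        x_eff = x + dist_um / p.pixel_size_um * nx_
        if not (margin < x_eff < nx - margin and margin < y < ny - margin):
            continue
        z = int(rng.integers(3, p.n_z - 3))
        if any(
            zz == z and (xx - x_eff) ** 2 + (yy_ - y) ** 2 < min_sep_px**2
            for zz, xx, yy_ in placed
        ):
            continue
        placed.append((z, x_eff, y))
        apical = dist_um < p.apical_cut_um
        amp_gfp = max(rng.normal(*p.gfp_amp), 5.0)
        amp_myc = max(rng.normal(*(p.myc_apical if apical else p.myc_basal)), 1.0)
        amp_prb = max(rng.normal(*(p.prb_apical if apical else p.prb_basal)), 0.0)
        blob = np.exp(-(((xx - x_eff) ** 2 + (yy - y) ** 2) / (2 * sig_px**2)))
        for ci, amp in enumerate((amp_gfp, amp_myc, amp_prb)):
            pixels[z, ci] += amp * blob
        rows.append(
            (float(x_eff), float(y), z, float(dist_um), "apical_prb_pos" if apical else "basal_prb_neg",
             amp_gfp, amp_myc, amp_prb)
        )

    if p.poisson_noise:
        pixels = rng.poisson(np.maximum(pixels, 0)).astype(float)
    if p.noise_gauss_sd > 0:
        pixels = pixels + rng.normal(0, p.noise_gauss_sd, pixels.shape)
    pixels = np.maximum(pixels, 0.0)

    stack = ImageStack(
        pixels=pixels,
        z_step_um=p.z_step_um,
        pixel_size_um=p.pixel_size_um,
    )
    truth = pd.DataFrame(
        rows,
        columns=["x_px", "y_px", "z_index", "dist_um", "prb_state", "amp_gfp", "amp_myc", "amp_prb"],
    )
    stack.surface_line = np.array(  # type: ignore[attr-defined]
        [[0.0, p.surface_offset_px], [nx - 1.0, p.surface_offset_px + slope * (nx - 1.0)]]
    )
    return stack, truth
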