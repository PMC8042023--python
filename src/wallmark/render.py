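"""Rendering of synthetic fluorescence and cell-body image stacks.

Pixel convention: pixel centers sit at integer (row, col) coordinates and
``row = y_um / pixel_size``, ``col = x_um / pixel_size`` -- a landmark at
lab position (y, x) = (3.000, 1.500) um at 52 nm/px renders at pixel
(57.69, 28.85).  The movie renderer shifts lab coordinates by a recorded
origin so the growing cell stays inside the canvas; the shift is part of
the output and can be inverted exactly.

Fluorescence frames are sums of symmetric 2D Gaussian spots (the
point-spread function) scaled by the photon count, on a constant
background, with optional Poisson shot noise (seeded).  Cell-body frames
mimic phase contrast: a dark filled spherocylinder on a light background,
with a mid-cell waist that deepens as the septum constricts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import tifffile

from wallmark.config import RenderConfig
from wallmark.rng import substream

if TYPE_CHECKING:  # pragma: no cover
    from wallmark.simulate import GroundTruthCell


def render_fluorescence_frame(shape: tuple[int, int], centers_um: np.ndarray,
                              cfg: RenderConfig,
                              rng: np.random.Generator | None = None) -> np.ndarray:
    """One fluorescence frame from spot centers given in (y_um, x_um) pairs."""
    h, w = shape
    rows = np.arange(h, dtype=float)
    cols = np.arange(w, dtype=float)
    img = np.full(shape, float(cfg.background))
    sig_px = cfg.psf_sigma_um / cfg.pixel_size
    for y_um, x_um in np.atleast_2d(centers_um) if len(centers_um) else []:
        r0 = y_um / cfg.pixel_size
        c0 = x_um / cfg.pixel_size
        gr = np.exp(-0.5 * ((rows - r0) / sig_px) ** 2)
        gc = np.exp(-0.5 * ((cols - c0) / sig_px) ** 2)
        img += cfg.photon_count * np.outer(gr, gc)
    if cfg.shot_noise and rng is not None:
        img = rng.poisson(img).astype(float)
    return img


def _capsule_mask(shape: tuple[int, int], pixel_size: float, y_lo_um: float,
                  y_hi_um: float, x_c_um: float, radius_um: float,
                  waist_center_um: float | None = None,
                  waist_depth_um: float = 0.0,
                  waist_halfwidth_um: float = 0.3) -> np.ndarray:
    """Filled spherocylinder silhouette, optionally pinched at a waist."""
    h, w = shape
    yy = np.arange(h, dtype=float)[:, None] * pixel_size
    xx = np.arange(w, dtype=float)[None, :] * pixel_size
    # distance to the axial segment between the two cap centers
    a_lo = y_lo_um + radius_um
    a_hi = y_hi_um - radius_um
    ay = np.clip(yy, a_lo, a_hi)
    dist = np.hypot(yy - ay, xx - x_c_um)
    mask = dist <= radius_um
    if waist_center_um is not None and waist_depth_um > 0:
        u = (yy - waist_center_um) / waist_halfwidth_um
        local_r = radius_um - waist_depth_um * np.exp(-0.5 * u * u)
        mask &= np.abs(xx - x_c_um) <= local_r
    return mask


@dataclass
class RenderedMovie:
    fluor: np.ndarray  # (T, H, W) float
    body: np.ndarray  # (T, H, W) float
    pixel_size: float
    origin_um: tuple[float, float]  # (y, x) lab position of pixel (0, 0)
    times_min: np.ndarray

    def lab_um_from_pixel(self, row: float, col: float) -> tuple[float, float]:
        """Invert the rendering shift: full-resolution pixel -> lab um."""
        return (row * self.pixel_size + self.origin_um[0],
                col * self.pixel_size + self.origin_um[1])

    def save(self, out_dir: str | Path, prefix: str = "") -> tuple[Path, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fp = out / f"{prefix}fluor.tif"
        bp = out / f"{prefix}body.tif"
        tifffile.imwrite(fp, np.clip(self.fluor, 0, 65535).astype(np.uint16))
        tifffile.imwrite(bp, np.clip(self.body, 0, 65535).astype(np.uint16))
        return fp, bp


def render_frames(cell: "GroundTruthCell", positions=None,
                  render_cfg: RenderConfig | None = None,
                  frames=None) -> RenderedMovie:
    """Render fluorescence + cell-body stacks for one simulated cell.

    ``positions``/``frames`` default to the cell's own tables; passing the
    observed table renders the noisy detections instead of the truth.
    """
    cfg = render_cfg or cell.config.render or RenderConfig()
    positions = cell.positions if positions is None else positions
    frames = cell.frames if frames is None else frames
    D = cell.config.diameter_D
    max_len = float(frames["cell_length_um"].max())
    margin = cfg.margin_um
    width_um = D + 2 * margin
    height_um = max_len + 2 * margin
    shape = (int(math.ceil(height_um / cfg.pixel_size)) + 1,
             int(math.ceil(width_um / cfg.pixel_size)) + 1)
    # pixel (0,0) sits at lab (anchor - margin, -width/2)
    origin = (cell.lab_anchor - margin, -width_um / 2.0)
    rng = substream(cell.config.rng_seed, "shot")
    rng_body = substream(cell.config.rng_seed, "body_noise")

    fluor_stack = []
    body_stack = []
    times = frames["time_min"].to_numpy(dtype=float)
    c = cell.config.cap_size_c
    for _, fr in frames.iterrows():
        f = int(fr["frame"])
        sub = positions[positions["frame"] == f]
        centers = np.column_stack([
            sub["lab_y_um"].to_numpy(dtype=float) - origin[0],
            sub["lab_x_um"].to_numpy(dtype=float) - origin[1],
        ]) if len(sub) else np.empty((0, 2))
        fluor_stack.append(render_fluorescence_frame(shape, centers, cfg, rng))

        length = float(fr["cell_length_um"])
        y_lo = cell.lab_anchor - origin[0]
        y_hi = y_lo + length
        s = float(fr["septal_offset_um"])
        waist = None
        depth = 0.0
        if fr["phase"] == "division" and s > 0:
            waist = 0.5 * (y_lo + y_hi)
            depth = (s / c) * (0.5 * D) * 0.8  # never fully pinched while rendered
        mask = _capsule_mask(shape, cfg.pixel_size, y_lo, y_hi, -origin[1],
                             0.5 * D, waist, depth)
        body = np.where(mask, cfg.body_foreground, cfg.body_background).astype(float)
        if cfg.body_noise_sigma > 0:
            body = body + rng_body.normal(0.0, cfg.body_noise_sigma, shape)
        body_stack.append(body)
    return RenderedMovie(np.stack(fluor_stack), np.stack(body_stack), cfg.pixel_size,
                         origin, times)
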