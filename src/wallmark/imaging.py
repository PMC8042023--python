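"""Sub-pixel spot localization and cell geometry from image stacks.

The measurement chain mirrors standard single-cell fluorescence analysis:

1. spots: Gaussian-smooth the fluorescence frame, take local maxima, crop a
   12 x 12 px region of interest around each and fit a symmetric 2D
   Gaussian with constant offset by nonlinear least squares;
2. cell outline: Gaussian-smooth the body frame, upsample 4x by bicubic
   interpolation, Otsu-threshold, keep the largest component, fill holes
   and extract a sub-pixel boundary polyline;
3. midline: find the two polar points on the contour (maximum end-to-end
   separation among vertex pairs that split the contour into near-equal
   arcs), resample each half to equally spaced points, connect midpoints;
   the arc-length midpoint of the midline is the cell center;
4. cell coordinates: a spot's axial position y is the signed arc length
   from the center to the foot of its perpendicular projection on the
   midline; x is the signed perpendicular offset; P_y the arc distance to
   the nearest pole tip;
5. division onset: a convexity defect (contour-to-convex-hull depth) at
   mid-cell exceeding a depth threshold on consecutive frames.

All geometry is computed in 4x-upsampled pixel space and converted to
micrometres once on output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from shapely.geometry import Point, Polygon
from skimage import feature, measure, transform

from wallmark.errors import GeometryError, SegmentationError

# ---------------------------------------------------------------------------
# spot detection


@dataclass
class SpotParams:
    smoothing_sigma: float = 1.0  # px, pre-detection Gaussian filter
    min_separation_px: int = 5
    threshold_abs: float | None = None  # on the smoothed image; None -> robust auto
    min_amplitude: float = 10.0
    roi_size: int = 12
    width_bounds_px: tuple[float, float] = (0.5, 4.0)
    include_border_clipped: bool = False


@dataclass
class SpotDetection:
    frame: int
    roi_origin: tuple[int, int]  # (row, col) of the ROI corner
    fitted_center: tuple[float, float]  # (row, col), full-frame sub-pixel
    amplitude: float
    psf_sigma_fit: float
    background: float
    fit_rss: float
    clipped: bool = False


def _gauss2d(params: np.ndarray, rr: np.ndarray, cc: np.ndarray) -> np.ndarray:
    a, r0, c0, sig, b = params
    return a * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sig * sig)) + b


def fit_gaussian_roi(roi: np.ndarray, origin: tuple[int, int],
                     width_bounds: tuple[float, float] = (0.5, 4.0)) -> tuple[np.ndarray, float]:
    """Least-squares symmetric-Gaussian fit on one ROI.

    Returns the parameter vector (amplitude, row0, col0, sigma, offset) in
    full-frame coordinates, and the residual sum of squares.
    """
    h, w = roi.shape
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    b0 = float(roi.min())
    a0 = float(roi.max()) - b0
    peak = np.unravel_index(int(np.argmax(roi)), roi.shape)
    x0 = np.array([max(a0, 1e-3), float(peak[0]), float(peak[1]), 1.5, b0])
    lb = np.array([0.0, 0.0, 0.0, width_bounds[0], -np.inf])
    ub = np.array([np.inf, h - 1.0, w - 1.0, width_bounds[1], np.inf])
    res = optimize.least_squares(
        lambda p: (_gauss2d(p, rr, cc) - roi).ravel(), x0, bounds=(lb, ub),
        method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    p = res.x.copy()
    p[1] += origin[0]
    p[2] += origin[1]
    return p, float(2 * res.cost)


def detect_spots(frame: np.ndarray, params: SpotParams | None = None,
                 frame_index: int = 0) -> list[SpotDetection]:
    """Detect and sub-pixel-localize fluorescent spots in one frame."""
    params = params or SpotParams()
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("frame must be 2D")
    if img.size == 0 or np.ptp(img) == 0:
        return []
    smooth = ndimage.gaussian_filter(img, params.smoothing_sigma)
    thr = params.threshold_abs
    if thr is None:
        med = float(np.median(smooth))
        mad = float(np.median(np.abs(smooth - med)))
        thr = med + 6.0 * 1.4826 * max(mad, 1e-12)
    peaks = feature.peak_local_max(smooth, min_distance=params.min_separation_px,
                                   threshold_abs=thr, exclude_border=False)
    half = params.roi_size // 2
    out: list[SpotDetection] = []
    for pr, pc in peaks:
        r0, c0 = int(pr) - half, int(pc) - half
        clipped = r0 < 0 or c0 < 0 or r0 + params.roi_size > img.shape[0] or \
            c0 + params.roi_size > img.shape[1]
        if clipped and not params.include_border_clipped:
            continue
        r0c = max(r0, 0)
        c0c = max(c0, 0)
        roi = img[r0c:r0 + params.roi_size, c0c:c0 + params.roi_size]
        p, rss = fit_gaussian_roi(roi, (r0c, c0c), params.width_bounds_px)
        a, rr0, cc0, sig, b = p
        inside = (r0c + 0.01 <= rr0 <= r0c + roi.shape[0] - 1.01 and
                  c0c + 0.01 <= cc0 <= c0c + roi.shape[1] - 1.01)
        width_ok = params.width_bounds_px[0] + 1e-6 < sig < params.width_bounds_px[1] - 1e-6
        if a < params.min_amplitude or not inside or not width_ok:
            continue
        out.append(SpotDetection(frame_index, (r0c, c0c), (float(rr0), float(cc0)),
                                 float(a), float(sig), float(b), rss, clipped))
    return out


# ---------------------------------------------------------------------------
# segmentation


def segment_cell(body_frame: np.ndarray, smoothing_sigma: float = 1.0,
                 upsample: int = 4, min_area_px: float = 50.0,
                 polarity: str = "dark") -> np.ndarray:
    """Closed sub-pixel contour of the single cell in a body frame.

    Smoothing -> ``upsample``x bicubic interpolation -> Otsu threshold ->
    largest connected component (holes filled) -> boundary polyline, in
    upsampled pixel coordinates.  ``polarity`` says whether the cell is
    darker or brighter than the background.
    """
    from skimage.filters import threshold_otsu

    img = np.asarray(body_frame, dtype=float)
    if img.ndim != 2:
        raise SegmentationError("body frame must be 2D")
    if np.ptp(img) == 0:
        raise SegmentationError("blank frame: no intensity variation to segment")
    sm = ndimage.gaussian_filter(img, smoothing_sigma)
    up = transform.rescale(sm, upsample, order=3, anti_aliasing=False,
                           preserve_range=True, mode="edge")
    thr = threshold_otsu(up)
    mask = up < thr if polarity == "dark" else up > thr
    lab, n = ndimage.label(mask)
    if n == 0:
        raise SegmentationError("no component found above the Otsu threshold")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1]
    if sizes[order[0]] < min_area_px * upsample * upsample:
        raise SegmentationError("largest component below the minimum area")
    if n > 1 and sizes[order[1]] > 0.25 * sizes[order[0]]:
        raise SegmentationError(
            "multiple comparable components found: crop the field to a single "
            "cell before segmentation (multi-cell scenes are not supported)"
        )
    comp = ndimage.binary_fill_holes(lab == (order[0] + 1))
    contours = measure.find_contours(comp.astype(float), 0.5)
    if not contours:
        raise SegmentationError("no boundary found for the segmented component")
    contour = max(contours, key=len)
    if not np.allclose(contour[0], contour[-1]):
        contour = np.vstack([contour, contour[0]])
    return contour


# ---------------------------------------------------------------------------
# midline geometry


@dataclass
class CellGeometry:
    """Per-frame cell geometry in upsampled pixel space (um on output)."""

    frame: int
    contour: np.ndarray  # (N, 2) closed, upsampled px (row, col)
    pole_points: np.ndarray  # (2, 2)
    midline: np.ndarray  # (M, 2), pole to pole
    center: np.ndarray  # (2,)
    length_um: float
    diameter_um: float
    pixel_size: float
    upsample: int
    phase: str = "elongation"
    widths_um: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def is_rod(self) -> bool:
        return self.length_um > self.diameter_um

    @property
    def um_per_upx(self) -> float:
        return self.pixel_size / self.upsample


def _resample_polyline(poly: np.ndarray, m: int) -> np.ndarray:
    """Arc-length resampling of a polyline to m equally spaced points."""
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    u = np.linspace(0.0, s[-1], m)
    r = np.interp(u, s, poly[:, 0])
    c = np.interp(u, s, poly[:, 1])
    return np.column_stack([r, c])


def _find_poles(contour: np.ndarray, arc_balance: float = 0.2,
                max_candidates: int = 400) -> tuple[int, int]:
    """Indices of the two polar vertices.

    Maximizes the Euclidean end-to-end separation over vertex pairs whose
    two connecting arcs differ in length by less than ``arc_balance`` of
    the total perimeter -- robust to boundary noise, and guaranteed to pick
    opposite ends of a rod.
    """
    pts = contour[:-1]  # drop duplicate closing vertex
    n = len(pts)
    if n < 8:
        raise GeometryError(f"contour too small ({n} vertices)")
    seg = np.linalg.norm(np.diff(contour, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])[:n]
    total = cum[-1] + seg[-1]
    stride = max(1, n // max_candidates)
    idx = np.arange(0, n, stride)
    p = pts[idx]
    d2 = ((p[:, None, :] - p[None, :, :]) ** 2).sum(-1)
    arc = np.abs(cum[idx][:, None] - cum[idx][None, :])
    arc = np.minimum(arc, total - arc)
    balanced = np.abs(2 * arc - total) < arc_balance * total
    d2 = np.where(balanced, d2, -1.0)
    i, j = np.unravel_index(int(np.argmax(d2)), d2.shape)
    if d2[i, j] <= 0:
        raise GeometryError("no balanced vertex pair found (degenerate contour)")
    pi, pj = int(idx[i]), int(idx[j])
    # Quantized cap tips are flat plateaus: several vertices are almost
    # equally far from the opposite pole, and the raw argmax can land on a
    # plateau corner, tilting the midline.  Refine each pole to the
    # arc-median of the near-maximal vertices at its end.
    pi = _refine_pole(pts, pi, pj, cum, total)
    pj = _refine_pole(pts, pj, pi, cum, total)
    return pi, pj


def _refine_pole(pts: np.ndarray, at: int, other: int, cum: np.ndarray,
                 total: float, tol: float = 1.0, window: float = 0.15) -> int:
    """Arc-median of the vertices near ``at`` that are ~maximally far from
    ``other`` (within ``tol`` of the best, inside an arc window)."""
    n = len(pts)
    arc = np.abs(cum - cum[at])
    arc = np.minimum(arc, total - arc)
    near = arc <= window * total
    d = np.linalg.norm(pts - pts[other], axis=1)
    dmax = d[near].max()
    cand = np.where(near & (d >= dmax - tol))[0]
    # median position along the contour, unwrapped around `at`
    offs = (cand - at + n // 2) % n - n // 2
    return int((at + int(np.median(offs))) % n)


def compute_midline(contour: np.ndarray, pixel_size: float = 0.052,
                    upsample: int = 4, n_points: int = 200,
                    smoothing_upx: float = 0.5,
                    frame_index: int = 0) -> CellGeometry:
    """Midline, poles, center, length and diameter from a closed contour.

    The raw midpoint chain inherits boundary quantization wiggle, which
    systematically inflates its arc length; a light smoothing spline
    (``smoothing_upx``, in upsampled pixels) removes it before the length
    is measured.
    """
    if len(contour) < 8:
        raise GeometryError(f"contour too small ({len(contour)} vertices)")
    i, j = _find_poles(contour)
    pts = contour[:-1]
    n = len(pts)
    if i > j:
        i, j = j, i
    half1 = pts[i:j + 1]
    half2 = np.vstack([pts[j:], pts[:i + 1]])  # j -> n-1 -> 0 -> i
    h1 = _resample_polyline(half1, n_points)
    h2 = _resample_polyline(half2[::-1], n_points)  # reversed: also pole_i -> pole_j
    midline = 0.5 * (h1 + h2)
    if smoothing_upx > 0 and len(midline) >= 8:
        from scipy import interpolate as _interp

        tck, _ = _interp.splprep([midline[:, 0], midline[:, 1]], k=3,
                                 s=len(midline) * smoothing_upx ** 2)
        uu = np.linspace(0.0, 1.0, n_points)
        midline = np.column_stack(_interp.splev(uu, tck))
        # keep the endpoints anchored on the detected pole vertices
        midline[0], midline[-1] = h1[0], h1[-1]
    scale = pixel_size / upsample
    seg = np.linalg.norm(np.diff(midline, axis=0), axis=1)
    length_um = float(seg.sum() * scale)
    widths = np.linalg.norm(h1 - h2, axis=1) * scale
    lo, hi = n_points // 4, 3 * n_points // 4
    diameter_um = float(widths[lo:hi].mean())
    # arc-length midpoint of the midline
    s = np.concatenate([[0.0], np.cumsum(seg)])
    mid_s = 0.5 * s[-1]
    k = int(np.searchsorted(s, mid_s))
    k = min(max(k, 1), len(s) - 1)
    t = (mid_s - s[k - 1]) / max(s[k] - s[k - 1], 1e-12)
    center = midline[k - 1] + t * (midline[k] - midline[k - 1])
    return CellGeometry(
        frame=frame_index, contour=contour, pole_points=np.array([midline[0], midline[-1]]),
        midline=midline, center=center, length_um=length_um, diameter_um=diameter_um,
        pixel_size=pixel_size, upsample=upsample, widths_um=widths,
    )


def orient_geometry_series(geoms: list[CellGeometry]) -> list[CellGeometry]:
    """Flip midlines so pole identity is consistent across frames."""
    if not geoms:
        return geoms
    out = [geoms[0]]
    for g in geoms[1:]:
        prev = out[-1]
        keep = np.linalg.norm(g.pole_points[0] - prev.pole_points[0]) + \
            np.linalg.norm(g.pole_points[1] - prev.pole_points[1])
        flip = np.linalg.norm(g.pole_points[0] - prev.pole_points[1]) + \
            np.linalg.norm(g.pole_points[1] - prev.pole_points[0])
        if flip < keep:
            g = CellGeometry(
                frame=g.frame, contour=g.contour, pole_points=g.pole_points[::-1].copy(),
                midline=g.midline[::-1].copy(), center=g.center, length_um=g.length_um,
                diameter_um=g.diameter_um, pixel_size=g.pixel_size, upsample=g.upsample,
                phase=g.phase, widths_um=g.widths_um[::-1].copy(),
            )
        out.append(g)
    return out


def map_to_cell_coords(spot_center: tuple[float, float], geom: CellGeometry) -> tuple[float, float, float]:
    """Map a full-resolution spot center (row, col) to cell coordinates.

    Returns (x_um, y_um, P_y_um): y is the signed arc length along the
    midline from the cell center to the spot's perpendicular foot (positive
    toward the second pole), x the signed perpendicular offset, P_y the arc
    distance to the nearest pole tip.
    """
    p = (np.asarray(spot_center, dtype=float) + 0.5) * geom.upsample - 0.5
    ml = geom.midline
    a = ml[:-1]
    b = ml[1:]
    ab = b - a
    ab2 = (ab ** 2).sum(1)
    t = np.clip(((p - a) * ab).sum(1) / np.maximum(ab2, 1e-12), 0.0, 1.0)
    foot = a + t[:, None] * ab
    dist = np.linalg.norm(p - foot, axis=1)
    k = int(np.argmin(dist))
    seg = np.sqrt(ab2)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    arc = s[k] + t[k] * seg[k]
    total = s[-1]
    scale = geom.pixel_size / geom.upsample
    tangent = ab[k] / max(seg[k], 1e-12)
    offset = p - foot[k]
    lateral_sign = float(np.sign(tangent[0] * offset[1] - tangent[1] * offset[0]))
    x_um = lateral_sign * dist[k] * scale
    y_um = (arc - 0.5 * total) * scale
    p_y_um = min(arc, total - arc) * scale
    return x_um, y_um, p_y_um


# ---------------------------------------------------------------------------
# division detection


@dataclass
class DivisionDetection:
    onset_frame: int | None
    depth_um: np.ndarray  # per-frame max central convexity-defect depth
    phases: list[str]  # 'elongation' | 'transition' | 'division'


def convexity_defect_depth(geom: CellGeometry, central_fraction: float = 0.2) -> float:
    """Maximum contour-to-convex-hull depth within the central cell region."""
    poly = Polygon(geom.contour)
    hull = poly.convex_hull
    axis = geom.pole_points[1] - geom.pole_points[0]
    axis = axis / max(np.linalg.norm(axis), 1e-12)
    mid = 0.5 * (geom.pole_points[0] + geom.pole_points[1])
    proj = (geom.contour - mid) @ axis
    span = np.abs((geom.pole_points[1] - mid) @ axis)
    central = np.abs(proj) <= central_fraction * span
    if not central.any():
        return 0.0
    depths = [hull.exterior.distance(Point(v)) for v in geom.contour[central]]
    return float(max(depths) * geom.pixel_size / geom.upsample)


def detect_division(geoms: list[CellGeometry], depth_threshold_um: float = 0.05,
                    central_fraction: float = 0.2, min_consecutive: int = 2,
                    frame_interval_min: float = 10.0,
                    elongation_margin_min: float = 10.0) -> DivisionDetection:
    """Find the division onset from mid-cell convexity defects.

    Onset is the first frame whose central defect depth exceeds the
    threshold on at least ``min_consecutive`` consecutive frames.  Frames
    up to ``elongation_margin_min`` before onset are labelled elongation,
    frames from onset on are division, and the margin in between is
    transition (excluded from elongation-phase statistics).
    """
    depths = np.array([convexity_defect_depth(g, central_fraction) for g in geoms])
    above = depths > depth_threshold_um
    onset = None
    run = 0
    for f, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= min_consecutive:
            onset = f - min_consecutive + 1
            break
    phases = []
    margin_frames = int(math.ceil(elongation_margin_min / frame_interval_min))
    for f in range(len(geoms)):
        if onset is None or f <= onset - 1 - margin_frames:
            phases.append("elongation")
        elif f >= onset:
            phases.append("division")
        else:
            phases.append("transition")
    for g, ph in zip(geoms, phases):
        g.phase = ph
    return DivisionDetection(onset, depths, phases)


# ---------------------------------------------------------------------------
# movie-level driver


def extract_positions(fluor_stack: np.ndarray, body_stack: np.ndarray,
                      pixel_size: float = 0.052, times_min: np.ndarray | None = None,
                      spot_params: SpotParams | None = None,
                      upsample: int = 4, cell_id: str = "0",
                      smoothing_sigma: float = 1.0) -> tuple[pd.DataFrame, pd.DataFrame, list[CellGeometry]]:
    """Full measurement chain on one movie: spots + geometry -> cell coords.

    Returns (positions, geometry, geoms): ``positions`` has one row per
    detection with cell-centred coordinates; ``geometry`` one row per frame
    with length, diameter and phase.
    """
    n_frames = fluor_stack.shape[0]
    times = np.arange(n_frames, dtype=float) if times_min is None else np.asarray(times_min, dtype=float)
    dt = float(np.median(np.diff(times))) if n_frames > 1 else 1.0
    geoms = []
    for f in range(n_frames):
        contour = segment_cell(body_stack[f], smoothing_sigma=smoothing_sigma, upsample=upsample)
        geoms.append(compute_midline(contour, pixel_size=pixel_size, upsample=upsample,
                                     frame_index=f))
    geoms = orient_geometry_series(geoms)
    detect_division(geoms, frame_interval_min=dt)
    pos_rows = []
    for f in range(n_frames):
        spots = detect_spots(fluor_stack[f], spot_params, frame_index=f)
        for sp in spots:
            x_um, y_um, p_y = map_to_cell_coords(sp.fitted_center, geoms[f])
            pos_rows.append((cell_id, f, times[f], x_um, y_um, p_y,
                             sp.fitted_center[0], sp.fitted_center[1], sp.amplitude))
    positions = pd.DataFrame(
        pos_rows, columns=["cell_id", "frame", "time_min", "x_um", "y_um", "P_y_um",
                           "row_px", "col_px", "amplitude"],
    )
    geometry = pd.DataFrame(
        {
            "cell_id": cell_id,
            "frame": np.arange(n_frames),
            "time_min": times,
            "cell_length_um": [g.length_um for g in geoms],
            "diameter_um": [g.diameter_um for g in geoms],
            "phase": [g.phase for g in geoms],
        }
    )
    return positions, geometry, geoms
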