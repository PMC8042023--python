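"""Growth-zone kinematics from landmark position tables.

Turns per-frame landmark positions (from the simulator's observed table or
from image analysis) into the quantities that characterise wall growth:

- per-landmark traces and axial velocities ``V_Py`` (slope of the pole
  distance ``P_y`` against time),
- the inert-zone changepoint fit: ``V_Py`` is 0 below the inert-zone size
  ``P_yc`` and ``k (P_y0 - P_yc)`` above it -- a hinge fit profiled over a
  grid of candidate changepoints with a closed-form slope at each,
- pairwise expansion kinematics: the axial relative velocity between
  landmark pairs grows linearly with separation, ``V_Dy = H D_y``, where
  ``H`` is the per-unit-length expansion rate ("Hubble parameter" of the
  cell wall), while lateral separations do not change,
- normalized-coordinate dynamics ``N_y = Y / L`` in the elongation vs
  division phases, and the outward displacement of mid-cell landmarks
  during septation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from wallmark.errors import NonIdentifiableError, SchemaError
from wallmark.rng import substream

# ---------------------------------------------------------------------------
# traces


@dataclass
class MotorTrace:
    """Time series of one landmark in cell-centred coordinates."""

    cell_id: str
    motor_id: int
    time_min: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    P_y_um: np.ndarray
    color: str = "inherited"

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("trace times must be strictly increasing")

    @property
    def P_y0(self) -> float:
        """Pole distance at the first sample."""
        return float(self.P_y_um[0])

    def __len__(self) -> int:
        return len(self.time_min)


def traces_from_table(table: pd.DataFrame) -> list[MotorTrace]:
    """Build traces from a table already carrying motor identities."""
    need = {"cell_id", "motor_id", "time_min", "x_um", "y_um", "P_y_um"}
    missing = need - set(table.columns)
    if missing:
        raise SchemaError(f"missing columns: {sorted(missing)}")
    out = []
    for (cid, mid), g in table.groupby(["cell_id", "motor_id"], sort=True):
        g = g.sort_values("time_min")
        color = str(g["color"].iloc[0]) if "color" in g else "inherited"
        out.append(
            MotorTrace(str(cid), int(mid), g["time_min"].to_numpy(dtype=float),
                       g["x_um"].to_numpy(dtype=float), g["y_um"].to_numpy(dtype=float),
                       g["P_y_um"].to_numpy(dtype=float), color)
        )
    return out


def link_traces(spots: pd.DataFrame, gate_um_per_10min: float = 0.3,
                max_gap_frames: int = 1) -> list[MotorTrace]:
    """Greedy nearest-neighbour frame-to-frame linking of detections.

    ``spots`` needs columns frame, time_min, x_um, y_um (P_y_um optional,
    cell_id optional).  The gate distance is 0.3 um per 10 min, scaled by
    the actual frame interval; candidate links are assigned globally in
    order of increasing displacement (ties by detection order, so linking
    is deterministic).  A trace survives up to ``max_gap_frames`` missed
    frames.
    """
    df = spots.copy()
    if "cell_id" not in df:
        df["cell_id"] = "0"
    if df.duplicated(subset=["cell_id", "frame", "x_um", "y_um"]).any():
        raise SchemaError("duplicate (frame, position) rows in spot table")
    traces_out: list[MotorTrace] = []
    for cid, cell_df in df.groupby("cell_id", sort=True):
        frames = sorted(cell_df["frame"].unique())
        open_tracks: list[dict] = []
        done: list[dict] = []
        next_id = 0
        for f in frames:
            sub = cell_df[cell_df["frame"] == f].sort_values(["y_um", "x_um"]).reset_index(drop=True)
            t = float(sub["time_min"].iloc[0])
            pts = sub[["x_um", "y_um"]].to_numpy(dtype=float)
            # close tracks that exceeded the gap allowance
            still = []
            for tr in open_tracks:
                if f - tr["last_frame"] > max_gap_frames + 1:
                    done.append(tr)
                else:
                    still.append(tr)
            open_tracks = still
            # candidate (track, detection) pairs within the gate
            cands = []
            for ti, tr in enumerate(open_tracks):
                dt_gap = t - tr["t"][-1]
                gate = gate_um_per_10min * max(dt_gap, 1e-9) / 10.0
                d = np.hypot(pts[:, 0] - tr["x"][-1], pts[:, 1] - tr["y"][-1])
                for di in np.where(d <= gate)[0]:
                    cands.append((d[di], ti, int(di)))
            cands.sort()
            used_t: set[int] = set()
            used_d: set[int] = set()
            for dist, ti, di in cands:
                if ti in used_t or di in used_d:
                    continue
                used_t.add(ti)
                used_d.add(di)
                tr = open_tracks[ti]
                tr["t"].append(t)
                tr["x"].append(pts[di, 0])
                tr["y"].append(pts[di, 1])
                tr["rows"].append(sub.iloc[di])
                tr["last_frame"] = f
            for di in range(len(pts)):
                if di not in used_d:
                    open_tracks.append(
                        dict(id=next_id, t=[t], x=[pts[di, 0]], y=[pts[di, 1]],
                             rows=[sub.iloc[di]], last_frame=f)
                    )
                    next_id += 1
        done.extend(open_tracks)
        done.sort(key=lambda tr: tr["id"])
        for tr in done:
            rows = pd.DataFrame(tr["rows"])
            p_y = rows["P_y_um"].to_numpy(dtype=float) if "P_y_um" in rows else np.full(len(rows), np.nan)
            color = str(rows["color"].iloc[0]) if "color" in rows else "inherited"
            traces_out.append(
                MotorTrace(str(cid), tr["id"], np.asarray(tr["t"], dtype=float),
                           np.asarray(tr["x"], dtype=float), np.asarray(tr["y"], dtype=float),
                           p_y, color)
            )
    return traces_out


# ---------------------------------------------------------------------------
# axial velocity and the inert-zone changepoint


@dataclass
class VelocityFit:
    motor_id: int
    V_Py: float  # um/min, OLS slope of P_y vs t
    stderr: float
    n_samples: int
    P_y0: float


def fit_VPy(trace: MotorTrace) -> VelocityFit:
    """Ordinary least-squares slope of the pole distance against time."""
    t, p = trace.time_min, trace.P_y_um
    n = len(t)
    tc = t - t.mean()
    denom = float(tc @ tc)
    slope = float(tc @ (p - p.mean())) / denom
    resid = (p - p.mean()) - slope * tc
    dof = max(n - 2, 1)
    stderr = float(np.sqrt((resid @ resid) / dof / denom))
    return VelocityFit(trace.motor_id, slope, stderr, n, trace.P_y0)


@dataclass
class InertZoneFit:
    P_yc: float  # um, inert-zone size (changepoint)
    k: float  # 1/min, hinge slope
    rss: float
    ci_Pyc: tuple[float, float] | None
    n_motors: int


def _profile_hinge(p: np.ndarray, v: np.ndarray, grid: np.ndarray) -> tuple[int, np.ndarray, np.ndarray]:
    """RSS and closed-form slope of the zero-plateau hinge at each candidate.

    Model: v = 0 for p < c, v = k (p - c) for p >= c.  For fixed c the
    least-squares k is sum(v (p-c)) / sum((p-c)^2) over p >= c.
    """
    # (C, N) broadcast; N and C are a few hundred/thousand, fine in memory
    diff = p[None, :] - grid[:, None]
    on = diff >= 0
    w = np.where(on, diff, 0.0)
    num = w @ v
    den = np.einsum("ij,ij->i", w, w)
    k = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    k = np.maximum(k, 0.0)  # a negative hinge slope is unphysical
    # rss = sum v^2 (plateau part) + sum (v - k (p-c))^2 (hinge part)
    total_v2 = float(v @ v)
    rss = total_v2 - 2 * k * num + k * k * den
    best = int(np.argmin(rss))
    return best, k, rss


def fit_inert_zone(fits: Sequence[VelocityFit] | pd.DataFrame,
                   grid_resolution_um: float = 0.001,
                   n_boot: int = 1000, seed: int = 0,
                   ci_level: float = 0.95) -> InertZoneFit:
    """Changepoint fit of the hinge law V_Py = max(0, k (P_y0 - P_yc)).

    The changepoint is profiled over a grid (default 1 nm steps) between
    the smallest and largest initial pole distance, with the slope solved
    in closed form at each candidate; this is a deterministic global
    optimum over the grid.  The confidence interval on P_yc is a
    case-resampling percentile bootstrap (seeded).
    """
    if isinstance(fits, pd.DataFrame):
        p = fits["P_y0"].to_numpy(dtype=float)
        v = fits["V_Py"].to_numpy(dtype=float)
    else:
        p = np.array([f.P_y0 for f in fits], dtype=float)
        v = np.array([f.V_Py for f in fits], dtype=float)
    n = len(p)
    if n < 2:
        raise NonIdentifiableError("need at least 2 motors for the changepoint fit")
    if np.allclose(v, 0.0, atol=1e-15):
        raise NonIdentifiableError(
            "all axial velocities are zero: no hinge is identifiable "
            "(every candidate changepoint fits equally well)"
        )
    lo, hi = float(p.min()), float(p.max())
    if hi <= lo:
        raise NonIdentifiableError("all motors share one P_y0; changepoint not identifiable")
    grid = np.arange(lo, hi + 0.5 * grid_resolution_um, grid_resolution_um)
    best, k_all, rss_all = _profile_hinge(p, v, grid)
    p_yc, k, rss = float(grid[best]), float(k_all[best]), float(rss_all[best])
    if k <= 0:
        raise NonIdentifiableError("fitted hinge slope is not positive; no active zone detected")

    ci = None
    if n_boot > 0:
        rng = substream(seed, "bootstrap")
        idx = rng.integers(0, n, size=(n_boot, n))
        est = np.empty(n_boot)
        for b in range(n_boot):
            pb, vb = p[idx[b]], v[idx[b]]
            gb = grid[(grid >= pb.min()) & (grid <= pb.max())]
            if len(gb) == 0 or np.allclose(vb, 0.0, atol=1e-15):
                est[b] = np.nan
                continue
            bi, _, _ = _profile_hinge(pb, vb, gb)
            est[b] = gb[bi]
        est = est[np.isfinite(est)]
        a = (1 - ci_level) / 2
        ci = (float(np.quantile(est, a)), float(np.quantile(est, 1 - a)))
    return InertZoneFit(p_yc, k, rss, ci, n)


def hinge_model(p_y: np.ndarray, p_yc: float, k: float) -> np.ndarray:
    """Evaluate the fitted piecewise-linear law."""
    return np.maximum(0.0, k * (np.asarray(p_y, dtype=float) - p_yc))


# ---------------------------------------------------------------------------
# pairwise expansion and the Hubble law


PAIR_COLUMNS = ["cell_id", "motor_i", "motor_j", "time_min", "dt_min",
                "D_x_um", "D_y_um", "V_Dx_um_min", "V_Dy_um_min"]


def pair_kinematics(traces: Iterable[MotorTrace], P_yc: float,
                    dt: float | None = None) -> pd.DataFrame:
    """Per-interval pairwise separations and relative velocities.

    For every unordered pair of landmarks on the same cell that are both in
    the active zone at the interval start (P_y >= P_yc), reports the
    unsigned separations D_x, D_y at interval start and the relative
    velocities V_D = (D' - D) / dt.  Pairs with a landmark inside the inert
    zone are excluded, as the expansion law only holds on the active zone.
    """
    by_cell: dict[str, list[MotorTrace]] = {}
    for tr in traces:
        by_cell.setdefault(tr.cell_id, []).append(tr)
    rows = []
    for cid, trs in sorted(by_cell.items()):
        for a, b in combinations(sorted(trs, key=lambda t: t.motor_id), 2):
            common, ia, ib = np.intersect1d(a.time_min, b.time_min, return_indices=True)
            if len(common) < 2:
                continue
            for s in range(len(common) - 1):
                step_dt = common[s + 1] - common[s]
                if dt is not None and abs(step_dt - dt) > 1e-9 * max(1.0, dt):
                    continue
                if a.P_y_um[ia[s]] < P_yc or b.P_y_um[ib[s]] < P_yc:
                    continue
                dx0 = abs(a.x_um[ia[s]] - b.x_um[ib[s]])
                dy0 = abs(a.y_um[ia[s]] - b.y_um[ib[s]])
                dx1 = abs(a.x_um[ia[s + 1]] - b.x_um[ib[s + 1]])
                dy1 = abs(a.y_um[ia[s + 1]] - b.y_um[ib[s + 1]])
                rows.append((cid, a.motor_id, b.motor_id, common[s], step_dt,
                             dx0, dy0, (dx1 - dx0) / step_dt, (dy1 - dy0) / step_dt))
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


@dataclass
class HubbleEstimate:
    cell_id: str
    time_min: float
    H: float  # 1/min
    stderr: float
    n_pairs: int
    normalized: pd.DataFrame  # columns D_y_um, V_over_H


def estimate_H(pairs: pd.DataFrame) -> HubbleEstimate:
    """No-intercept least squares of V_Dy on D_y over one interval dataset.

    Also emits the normalized points (D_y, V_Dy / H) which collapse onto
    the line of slope 1 for homogeneous axial expansion.
    """
    d = pairs["D_y_um"].to_numpy(dtype=float)
    v = pairs["V_Dy_um_min"].to_numpy(dtype=float)
    if len(d) == 0 or float(d @ d) == 0.0:
        raise NonIdentifiableError("no usable pairs for the expansion-rate fit")
    h = float(d @ v) / float(d @ d)
    resid = v - h * d
    dof = max(len(d) - 1, 1)
    stderr = float(np.sqrt((resid @ resid) / dof / float(d @ d)))
    norm = pd.DataFrame({"D_y_um": d, "V_over_H": v / h if h != 0 else np.full_like(v, np.nan)})
    cid = str(pairs["cell_id"].iloc[0]) if "cell_id" in pairs and len(pairs) else "0"
    t = float(pairs["time_min"].iloc[0]) if "time_min" in pairs and len(pairs) else float("nan")
    return HubbleEstimate(cid, t, h, stderr, len(d), norm)


def hubble_series(pairs: pd.DataFrame) -> pd.DataFrame:
    """Expansion-rate estimate per (cell, interval-start time)."""
    rows = []
    for (cid, t), g in pairs.groupby(["cell_id", "time_min"], sort=True):
        est = estimate_H(g)
        rows.append((cid, t, est.H, est.stderr, est.n_pairs))
    return pd.DataFrame(rows, columns=["cell_id", "time_min", "H_per_min", "stderr", "n_pairs"])


# ---------------------------------------------------------------------------
# normalized coordinates


def normalize_positions(traces: Iterable[MotorTrace], geometry: pd.DataFrame,
                        P_yc: float) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalized coordinate N_y = Y / L per sample and per-phase slopes.

    ``geometry`` needs columns cell_id, time_min, cell_length_um and phase;
    the active-zone length is L = cell length - 2 P_yc with the fitted
    inert-zone size of the condition.  Returns (samples, slopes); slopes
    are per-motor OLS slopes of N_y against time computed separately within
    the elongation and division phases (phases with < 2 samples give NaN).
    """
    geo = geometry.set_index(["cell_id", "time_min"])
    samp_rows = []
    slope_rows = []
    for tr in traces:
        rec = []
        for i, t in enumerate(tr.time_min):
            try:
                g = geo.loc[(tr.cell_id, t)]
            except KeyError:
                continue
            L = float(g["cell_length_um"]) - 2.0 * P_yc
            ny = tr.y_um[i] / L
            rec.append((t, ny, str(g["phase"])))
            samp_rows.append((tr.cell_id, tr.motor_id, t, tr.y_um[i], L, ny, str(g["phase"])))
        rec_df = pd.DataFrame(rec, columns=["t", "ny", "phase"])
        row: dict = {"cell_id": tr.cell_id, "motor_id": tr.motor_id}
        for phase in ("elongation", "division"):
            sub = rec_df[rec_df["phase"] == phase]
            if len(sub) >= 2:
                t = sub["t"].to_numpy()
                ny = sub["ny"].to_numpy()
                tc = t - t.mean()
                row[f"slope_{phase}"] = float(tc @ (ny - ny.mean())) / float(tc @ tc)
                row[f"mean_Ny_{phase}"] = float(ny.mean())
            else:
                row[f"slope_{phase}"] = np.nan
                row[f"mean_Ny_{phase}"] = np.nan
        slope_rows.append(row)
    samples = pd.DataFrame(
        samp_rows, columns=["cell_id", "motor_id", "time_min", "Y_um", "L_um", "N_y", "phase"]
    )
    slopes = pd.DataFrame(slope_rows)
    return samples, slopes


def central_motor_displacement(traces: Iterable[MotorTrace], onset_time: float,
                               end_time: float | None = None,
                               central_threshold_um: float = 0.1) -> pd.DataFrame:
    """Outward displacement of near-mid-cell landmarks during division.

    For landmarks with |Y| below the threshold at division onset, reports
    |Y(end)| - |Y(onset)| -- how far septal insertion pushed them from the
    division plane.
    """
    rows = []
    for tr in traces:
        i0 = int(np.argmin(np.abs(tr.time_min - onset_time)))
        if abs(tr.time_min[i0] - onset_time) > 1e-6:
            continue
        y0 = tr.y_um[i0]
        if abs(y0) >= central_threshold_um:
            continue
        i1 = len(tr.time_min) - 1 if end_time is None else int(np.argmin(np.abs(tr.time_min - end_time)))
        rows.append((tr.cell_id, tr.motor_id, y0, tr.y_um[i1], abs(tr.y_um[i1]) - abs(y0)))
    return pd.DataFrame(rows, columns=["cell_id", "motor_id", "Y_onset_um", "Y_end_um",
                                       "displacement_um"])
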