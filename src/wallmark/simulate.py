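"""Ground-truthed simulation of growing, dividing rod-shaped cells carrying
wall-anchored landmarks.

Model
-----
The cell is a spherocylinder: a cylindrical active zone of length ``L(t)``
flanked by two inert polar caps of axial size ``c`` (the inert zone), so the
total cell length is ``L + 2c``.  New wall is inserted homogeneously along
the axis of the active zone only:

- a landmark inside the active zone at axial position ``y`` (cell-centred
  coordinates, ``|y| <= L/2``) moves with velocity ``H(t) * y``, hence its
  normalized coordinate ``N_y = y / L`` is a constant of the motion;
- a landmark in an inert cap rides rigidly with its pole: its pole distance
  ``P_y`` is constant, and ``V_Py = H * (P_y - c)`` for active landmarks --
  the piecewise-linear hinge law the changepoint fit recovers;
- the active zone grows as ``dL/dt = H(t) L`` with
  ``H(t) = H0 (1 + beta t)``;
- lateral positions never change (no diameter growth, no twist).

Division is a second, independent insertion mode: once the cell reaches the
trigger length, new wall is inserted locally at mid-cell, displacing every
landmark on the upper/lower half outward by the septal offset ``s(t)``
(linear in time, 0 -> c over the division duration) while both half-rods
keep elongating homogeneously.  At completion the cell splits at mid-cell
and each daughter gains a new inert cap of size ``c``; in normalized
coordinates the landmark position maps across the division exactly by the
Bernoulli shift map (see :mod:`wallmark.bernoulli`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from wallmark.config import SimConfig
from wallmark.errors import ConfigurationError, PlacementError, StateError
from wallmark.rng import substream

_FLOAT_FMT = "%.9g"

#: columns of the long-format position table
POSITION_COLUMNS = [
    "cell_id",
    "motor_id",
    "frame",
    "time_min",
    "x_um",
    "y_um",
    "P_y_um",
    "N_y",
    "lab_x_um",
    "lab_y_um",
    "color",
    "phase",
]

FRAME_COLUMNS = [
    "cell_id",
    "frame",
    "time_min",
    "active_L_um",
    "cell_length_um",
    "septal_offset_um",
    "phase",
    "lab_anchor_um",
]


@dataclass
class GroundTruthCell:
    """One simulated cell: per-frame geometry plus per-landmark positions.

    ``motors`` has one row per landmark with its conserved state (material
    coordinate): ``kind`` is ``active`` (constant ``N_y``) or ``inert``
    (constant pole distance ``pole_dist`` on pole ``pole_sign``).
    ``positions`` is the long table over (motor, frame); ``frames`` the
    per-frame geometry.  ``lab_anchor`` is the lab-frame position of the
    lower pole tip (the lab frame is anchored at the founding cell's lower
    pole, which is inert and therefore static).
    """

    cell_id: str
    config: SimConfig
    t0: float
    L0: float
    motors: pd.DataFrame
    frames: pd.DataFrame
    positions: pd.DataFrame
    lab_anchor: float = 0.0

    @property
    def final_time(self) -> float:
        return float(self.frames["time_min"].iloc[-1])

    def active_length(self, t: float) -> float:
        return self.L0 * math.exp(self.config.growth_log_factor(self.t0, t))

    def cell_length(self, t: float) -> float:
        return self.active_length(t) + 2.0 * self.config.cap_size_c


@dataclass
class DaughterSpec:
    """Initial state of a daughter cell produced by a division."""

    cell_id: str
    t0: float
    L0: float
    motors: pd.DataFrame
    lab_anchor: float


@dataclass
class DivisionResult:
    frames: pd.DataFrame
    positions: pd.DataFrame
    daughters: tuple[DaughterSpec, DaughterSpec]
    lineage: pd.DataFrame


@dataclass
class LineageResult:
    """Multi-generation simulation output."""

    lineage: pd.DataFrame
    positions: pd.DataFrame
    frames: pd.DataFrame
    cells: dict[str, GroundTruthCell] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# landmark placement


def _motors_frame(u: np.ndarray, x: np.ndarray, config: SimConfig, color: str,
                  id_offset: int = 0) -> pd.DataFrame:
    """Build the conserved motor-state table from placement coordinates.

    ``u`` is the extended placement coordinate: |u| <= 0.5 places the
    landmark in the active zone at N_y = u; 0.5 < |u| <= 0.5 + c/L0 places
    it inside the cap at pole distance (0.5 + c/L0 - |u|) * L0.
    """
    c, L0 = config.cap_size_c, config.initial_active_length_L0
    umax = 0.5 + c / L0
    if np.any(np.abs(u) > umax + 1e-12):
        bad = u[np.abs(u) > umax + 1e-12]
        raise PlacementError(
            f"placement coordinate(s) {bad} outside allowed span [-{umax:.4f}, {umax:.4f}]"
        )
    active = np.abs(u) <= 0.5
    n = len(u)
    df = pd.DataFrame(
        {
            "motor_id": np.arange(id_offset, id_offset + n),
            "kind": np.where(active, "active", "inert"),
            "N_y": np.where(active, u, np.nan),
            "pole_sign": np.where(active, 0.0, np.sign(u)),
            "pole_dist": np.where(active, np.nan, (umax - np.abs(u)) * L0),
            "x_um": x,
            "color": color,
        }
    )
    return df


def place_motors(config: SimConfig, n: int | None = None, color: str = "inherited",
                 rng: np.random.Generator | None = None,
                 rng_lateral: np.random.Generator | None = None) -> pd.DataFrame:
    """Place ``n`` landmarks according to ``config.motor_placement``.

    Lateral positions are the projection of a uniform angular position on
    the cylinder wall, x = (D/2) sin(theta).
    """
    n = config.n_motors if n is None else n
    rng = rng or substream(config.rng_seed, "placement")
    rng_lateral = rng_lateral or substream(config.rng_seed, "lateral")
    spec = config.motor_placement
    if spec.kind == "uniform":
        umax = 0.5 + config.cap_size_c / config.initial_active_length_L0
        u = rng.uniform(-umax, umax, n)
    else:
        u = sample_truncated_gaussian(n, spec.sigma, rng)
    x = 0.5 * config.diameter_D * np.sin(rng_lateral.uniform(-np.pi, np.pi, n))
    return _motors_frame(u, x, config, color)


def sample_truncated_gaussian(n: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample N(0, sigma^2) truncated to [-0.5, 0.5]."""
    if not sigma > 0:
        raise ConfigurationError("sigma must be > 0")
    out = np.empty(0)
    while out.size < n:
        draw = rng.normal(0.0, sigma, max(n, 1024))
        out = np.concatenate([out, draw[np.abs(draw) <= 0.5]])
    return out[:n]


def place_new_motors(cell: GroundTruthCell, config: SimConfig | None = None,
                     n: int | None = None,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Place newly produced landmarks on ``cell``, tagged ``color='new'``.

    New landmarks follow the configured placement law restricted to the
    active zone; the default is the center-biased truncated Gaussian
    (sigma = 0.4) observed for newly assembled motors.
    """
    config = config or cell.config
    n = config.n_motors if n is None else n
    rng = rng or substream(config.rng_seed, "placement")
    sigma = config.motor_placement.sigma
    u = sample_truncated_gaussian(n, sigma, rng)
    rng_lat = substream(config.rng_seed, "lateral")
    x = 0.5 * config.diameter_D * np.sin(rng_lat.uniform(-np.pi, np.pi, n))
    id_offset = int(cell.motors["motor_id"].max()) + 1 if len(cell.motors) else 0
    return _motors_frame(u, x, config, "new", id_offset=id_offset)


# ---------------------------------------------------------------------------
# elongation


def _positions_at(motors: pd.DataFrame, L: float, c: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noise-free cell-centred (y, P_y, N_y) of every landmark at active length L."""
    half = 0.5 * L + c
    active = motors["kind"].to_numpy() == "active"
    ny = motors["N_y"].to_numpy()
    sign = motors["pole_sign"].to_numpy()
    pdist = motors["pole_dist"].to_numpy()
    y = np.where(active, ny * L, sign * (half - pdist))
    p_y = half - np.abs(y)
    n_y = y / L  # measured normalized coordinate (equals material N_y while elongating)
    return y, p_y, n_y


def simulate_elongation(config: SimConfig, *, cell_id: str = "0", t0: float = 0.0,
                        L0: float | None = None, motors: pd.DataFrame | None = None,
                        n_frames: int | None = None, until_trigger: bool = False,
                        lab_anchor: float = 0.0, placement_u: np.ndarray | None = None,
                        max_frames: int = 500) -> GroundTruthCell:
    """Simulate the elongation phase of one cell.

    Landmarks come from ``motors`` (a conserved-state table, e.g. from a
    previous division), from explicit placement coordinates ``placement_u``,
    or are drawn from the configured placement law.  With ``until_trigger``
    the movie runs until the cell length reaches the division trigger.
    """
    config.validate()
    c = config.cap_size_c
    L0 = config.initial_active_length_L0 if L0 is None else L0
    if not L0 > 0:
        raise ConfigurationError("initial active length must be > 0")
    if motors is None:
        if placement_u is not None:
            rng_lat = substream(config.rng_seed, "lateral")
            x = 0.5 * config.diameter_D * np.sin(rng_lat.uniform(-np.pi, np.pi, len(placement_u)))
            motors = _motors_frame(np.asarray(placement_u, dtype=float), x, config, "inherited")
        else:
            motors = place_motors(config)
    n_frames = config.n_frames if n_frames is None else n_frames
    if n_frames < 2 and not until_trigger:
        raise ConfigurationError("n_frames must be >= 2")

    dt = config.frame_interval_dt
    times: list[float] = []
    i = 0
    while True:
        t = t0 + i * dt
        times.append(t)
        L = L0 * math.exp(config.growth_log_factor(t0, t))
        if until_trigger:
            if L + 2 * c >= config.division_trigger_length and i >= 1:
                break
            if i >= max_frames:
                raise StateError(
                    f"division trigger length {config.division_trigger_length} um "
                    f"not reached within {max_frames} frames"
                )
        elif i >= n_frames - 1:
            break
        i += 1

    frame_rows = []
    pos_rows = []
    for f, t in enumerate(times):
        L = L0 * math.exp(config.growth_log_factor(t0, t))
        y, p_y, n_y = _positions_at(motors, L, c)
        half = 0.5 * L + c
        frame_rows.append((cell_id, f, t, L, L + 2 * c, 0.0, "elongation", lab_anchor))
        pos_rows.append(
            pd.DataFrame(
                {
                    "cell_id": cell_id,
                    "motor_id": motors["motor_id"].to_numpy(),
                    "frame": f,
                    "time_min": t,
                    "x_um": motors["x_um"].to_numpy(),
                    "y_um": y,
                    "P_y_um": p_y,
                    "N_y": n_y,
                    "lab_x_um": motors["x_um"].to_numpy(),
                    "lab_y_um": y + half + lab_anchor,
                    "color": motors["color"].to_numpy(),
                    "phase": "elongation",
                }
            )
        )
    frames = pd.DataFrame(frame_rows, columns=FRAME_COLUMNS)
    positions = pd.concat(pos_rows, ignore_index=True)[POSITION_COLUMNS]
    return GroundTruthCell(cell_id, config, t0, L0, motors.reset_index(drop=True),
                           frames, positions, lab_anchor)


# ---------------------------------------------------------------------------
# division


def simulate_division(cell: GroundTruthCell, config: SimConfig | None = None,
                      rng_coin: np.random.Generator | None = None) -> DivisionResult:
    """Simulate septation and splitting of ``cell`` after its last frame.

    Mid-cell insertion displaces every landmark outward by the septal
    offset ``s(t)``, linear from 0 to the cap size over the division
    duration, while the two half-rods keep elongating homogeneously (unless
    ``elongation_during_division`` is off).  At completion each landmark is
    assigned to the daughter matching the sign of its position at division
    onset; a landmark exactly at mid-cell is assigned by a seeded fair coin.
    """
    config = config or cell.config
    c = config.cap_size_c
    dt = config.frame_interval_dt
    t_d = cell.final_time
    L_d = cell.active_length(t_d)
    if L_d + 2 * c < config.division_trigger_length - 1e-9:
        raise StateError(
            f"cell length {L_d + 2 * c:.3f} um below division trigger "
            f"{config.division_trigger_length} um"
        )
    rng_coin = rng_coin or substream(config.rng_seed, "coin")

    motors = cell.motors
    active = motors["kind"].to_numpy() == "active"
    ny = motors["N_y"].to_numpy()
    # effective side: sign of position at onset; fair coin at exactly zero
    sign_eff = np.sign(np.where(active, ny, motors["pole_sign"].to_numpy()))
    zero = active & (sign_eff == 0)
    if zero.any():
        sign_eff[zero] = rng_coin.choice([-1.0, 1.0], size=int(zero.sum()))

    duration = config.division_duration
    n_steps = max(1, math.ceil(duration / dt - 1e-9))
    times = [t_d + i * dt for i in range(1, n_steps + 1)]
    if times[-1] < t_d + duration - 1e-9:
        times.append(t_d + duration)

    def half_rod(t: float) -> float:
        if config.elongation_during_division:
            return 0.5 * L_d * math.exp(config.growth_log_factor(t_d, t))
        return 0.5 * L_d

    frame_rows = []
    pos_rows = []
    f0 = int(cell.frames["frame"].iloc[-1])
    pole_sign = motors["pole_sign"].to_numpy()
    pdist = motors["pole_dist"].to_numpy()
    for j, t in enumerate(times, start=1):
        s = c * min(1.0, (t - t_d) / duration)
        h = half_rod(min(t, t_d + duration))
        y = np.where(active, 2.0 * ny * h + sign_eff * s,
                     pole_sign * (s + h + c - pdist))
        chalf = s + h + c
        p_y = chalf - np.abs(y)
        n_y = y / (2.0 * (h + s))  # measured convention: Y / (cell length - 2c)
        f = f0 + j
        frame_rows.append((cell.cell_id, f, t, 2 * h, 2 * chalf, s, "division", cell.lab_anchor))
        pos_rows.append(
            pd.DataFrame(
                {
                    "cell_id": cell.cell_id,
                    "motor_id": motors["motor_id"].to_numpy(),
                    "frame": f,
                    "time_min": t,
                    "x_um": motors["x_um"].to_numpy(),
                    "y_um": y,
                    "P_y_um": p_y,
                    "N_y": n_y,
                    "lab_x_um": motors["x_um"].to_numpy(),
                    "lab_y_um": y + chalf + cell.lab_anchor,
                    "color": motors["color"].to_numpy(),
                    "phase": "division",
                }
            )
        )
    frames = pd.DataFrame(frame_rows, columns=FRAME_COLUMNS)
    positions = pd.concat(pos_rows, ignore_index=True)[POSITION_COLUMNS]

    # --- split at mid-cell
    t_c = t_d + duration
    h_c = half_rod(t_c)
    specs = []
    lineage_rows = []
    for side, tag in ((1.0, "U"), (-1.0, "L")):
        take = (active & (sign_eff == side)) | (~active & (pole_sign == side))
        sub = motors.loc[take].copy()
        sub_active = sub["kind"].to_numpy() == "active"
        ny_m = sub["N_y"].to_numpy()
        ny_d = np.where(side > 0, 2.0 * ny_m - 0.5, 2.0 * ny_m + 0.5)
        sub["N_y"] = np.where(sub_active, ny_d, np.nan)
        # old-pole inert landmarks keep their pole; in the daughter that pole
        # is the one away from the division plane, i.e. sign = side
        sub["pole_sign"] = np.where(sub_active, 0.0, side)
        did = cell.cell_id + tag
        anchor = cell.lab_anchor if side < 0 else cell.lab_anchor + (h_c + 2 * c)
        specs.append(DaughterSpec(did, t_c, h_c, sub.reset_index(drop=True), anchor))
        for mid, a_flag, nm, nd in zip(sub["motor_id"], sub_active, ny_m, ny_d):
            if a_flag:
                lineage_rows.append((cell.cell_id, did, int(mid), float(nm), float(nd)))
    lineage = pd.DataFrame(
        lineage_rows,
        columns=["mother_id", "daughter_id", "motor_id", "N_y_mother", "N_y_daughter"],
    )
    return DivisionResult(frames, positions, (specs[0], specs[1]), lineage)


def simulate_generations(config: SimConfig, n_generations: int,
                         daughter_frames: int = 2) -> LineageResult:
    """Simulate ``n_generations`` successive divisions from one founder cell.

    Each cell elongates until the trigger length, divides, and both
    daughters are followed.  The lineage table records every active-zone
    landmark's normalized position in mother and daughter at each division.
    """
    config.validate()
    founder = simulate_elongation(config, until_trigger=True)
    current: list[GroundTruthCell] = [founder]
    all_pos = [founder.positions]
    all_frames = [founder.frames]
    lineages = []
    cells = {founder.cell_id: founder}
    coin = substream(config.rng_seed, "coin")
    for gen in range(n_generations):
        nxt: list[GroundTruthCell] = []
        for cell in current:
            res = simulate_division(cell, config, rng_coin=coin)
            all_pos.append(res.positions)
            all_frames.append(res.frames)
            lin = res.lineage.copy()
            lin.insert(0, "generation", gen)
            lineages.append(lin)
            last_gen = gen == n_generations - 1
            for spec in res.daughters:
                d = simulate_elongation(
                    config, cell_id=spec.cell_id, t0=spec.t0, L0=spec.L0,
                    motors=spec.motors, lab_anchor=spec.lab_anchor,
                    n_frames=daughter_frames if last_gen else None,
                    until_trigger=not last_gen,
                )
                cells[d.cell_id] = d
                all_pos.append(d.positions)
                all_frames.append(d.frames)
                nxt.append(d)
        current = nxt
    lineage = pd.concat(lineages, ignore_index=True)
    return LineageResult(
        lineage=lineage,
        positions=pd.concat(all_pos, ignore_index=True),
        frames=pd.concat(all_frames, ignore_index=True),
        cells=cells,
    )


# ---------------------------------------------------------------------------
# observation model


def add_noise_and_export(positions: pd.DataFrame, config: SimConfig,
                         out_dir: str | Path | None = None,
                         frames: pd.DataFrame | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the observation model and optionally write truth/observed CSVs.

    Observed x and y get i.i.d. Gaussian localization noise
    (``localization_sigma``); detections are dropped independently with
    ``detection_miss_rate``.  The observed pole distance is recomputed from
    the noisy y against the true pole position (cell geometry from the
    cell-body channel is far more precise than single-spot localization).
    Output is bit-stable for a fixed seed.
    """
    truth = positions.copy()
    obs = positions.copy()
    rng_noise = substream(config.rng_seed, "noise")
    rng_miss = substream(config.rng_seed, "miss")
    n = len(obs)
    sig = config.localization_sigma
    if sig > 0:
        obs["x_um"] = obs["x_um"] + rng_noise.normal(0.0, sig, n)
        obs["y_um"] = obs["y_um"] + rng_noise.normal(0.0, sig, n)
    half = truth["P_y_um"].to_numpy() + np.abs(truth["y_um"].to_numpy())
    obs["P_y_um"] = half - np.abs(obs["y_um"].to_numpy())
    for col in ("x_um", "y_um", "P_y_um", "N_y"):
        obs[f"{col}_true"] = truth[col].to_numpy()
    # active-zone length from the (noise-free) geometry: L = 2*(half - c)
    L_meas = 2.0 * (half - config.cap_size_c)
    obs["N_y"] = obs["y_um"].to_numpy() / L_meas
    if config.detection_miss_rate > 0:
        keep = rng_miss.uniform(size=n) >= config.detection_miss_rate
        obs = obs.loc[keep].reset_index(drop=True)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        truth.to_csv(out / "truth.csv", index=False, float_format=_FLOAT_FMT)
        obs.to_csv(out / "observed.csv", index=False, float_format=_FLOAT_FMT)
        if frames is not None:
            frames.to_csv(out / "geometry.csv", index=False, float_format=_FLOAT_FMT)
    return truth, obs


# rendering lives in its own module but is part of the simulator surface
from wallmark.render import RenderedMovie, render_frames  # noqa: E402,F401
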