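"""Simulation configuration, growth-medium presets and YAML loading.

Units are micrometres and minutes throughout; pixels appear only in the
rendering block.  The axial growth rate per unit length is affine in time,
``H(t) = H0 * (1 + beta * t)``; ``beta = 0`` gives pure exponential
elongation of the active zone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from wallmark.errors import ConfigurationError


@dataclass
class PlacementSpec:
    """Distribution of landmark placement along the cell axis.

    ``uniform`` spreads landmarks over the full axial extent of the cell,
    polar caps included (placement coordinate u with |u| <= 0.5 + cap/L).
    ``truncated_gaussian`` places them on the active zone only, N_y in
    [-0.5, 0.5], with the given sigma -- the center-biased law observed for
    newly produced motors.
    """

    kind: str = "uniform"  # "uniform" | "truncated_gaussian"
    sigma: float = 0.4

    def validate(self) -> None:
        if self.kind not in ("uniform", "truncated_gaussian"):
            raise ConfigurationError(
                f"motor_placement.kind must be 'uniform' or 'truncated_gaussian', got {self.kind!r}"
            )
        if self.kind == "truncated_gaussian" and not self.sigma > 0:
            raise ConfigurationError("motor_placement.sigma must be > 0")


@dataclass
class RenderConfig:
    """Rendering of fluorescence + cell-body frames.

    pixel_size fixes the camera sampling (52 nm/px at 100x on a 13 um
    EMCCD pixel); psf_sigma_um is the Gaussian spot width; photon_count
    scales spot amplitude before Poisson shot noise.
    """

    pixel_size: float = 0.052  # um / px
    psf_sigma_um: float = 0.10
    photon_count: float = 500.0
    background: float = 10.0
    shot_noise: bool = True
    margin_um: float = 0.8
    body_foreground: float = 50.0
    body_background: float = 200.0
    body_noise_sigma: float = 0.0

    def validate(self) -> None:
        if not self.pixel_size > 0:
            raise ConfigurationError("render.pixel_size must be > 0")
        if not self.psf_sigma_um > 0:
            raise ConfigurationError("render.psf_sigma_um must be > 0")
        if self.photon_count < 0 or self.background < 0:
            raise ConfigurationError("render.photon_count and render.background must be >= 0")


@dataclass
class SimConfig:
    """Parameters of one simulated growing cell (and its lineage).

    cap_size_c is the axial size of the inert polar zone P_yc: landmarks
    closer than this to a pole tip keep a constant pole distance.  It may be
    at most half the cell diameter (the caps are hemispherical) and the
    measured values are indeed below D/2.
    """

    cap_size_c: float = 0.27  # um, inert-zone axial size (ground-truth P_yc)
    diameter_D: float = 1.06  # um
    initial_active_length_L0: float = 2.0  # um, active zone at t = 0
    growth_rate_H0: float = 0.01  # 1/min
    growth_acceleration_beta: float = 0.005  # 1/min^2: H(t) = H0*(1 + beta*t)
    frame_interval_dt: float = 10.0  # min
    n_frames: int = 7
    division_trigger_length: float = 5.0  # um, total cell length
    division_duration: float = 20.0  # min
    elongation_during_division: bool = True
    n_motors: int = 20
    motor_placement: PlacementSpec = field(default_factory=PlacementSpec)
    localization_sigma: float = 0.0  # um, i.i.d. Gaussian noise on x and y
    detection_miss_rate: float = 0.0
    rng_seed: int = 0
    render: RenderConfig | None = None

    def validate(self) -> None:
        errs = []
        if not self.cap_size_c > 0:
            errs.append("cap_size_c must be > 0")
        if not self.diameter_D > 0:
            errs.append("diameter_D must be > 0")
        if not self.initial_active_length_L0 > 0:
            errs.append("initial_active_length_L0 must be > 0")
        if not self.frame_interval_dt > 0:
            errs.append("frame_interval_dt must be > 0")
        if self.n_frames < 2:
            errs.append("n_frames must be >= 2")
        if not self.growth_rate_H0 > 0:
            errs.append("growth_rate_H0 must be > 0")
        if not self.division_duration > 0:
            errs.append("division_duration must be > 0")
        if self.n_motors < 0:
            errs.append("n_motors must be >= 0")
        if not 0.0 <= self.detection_miss_rate < 1.0:
            errs.append("detection_miss_rate must be in [0, 1)")
        if self.localization_sigma < 0:
            errs.append("localization_sigma must be >= 0")
        if errs:
            raise ConfigurationError("; ".join(errs))
        self.motor_placement.validate()
        if self.render is not None:
            self.render.validate()

    # -- growth law -------------------------------------------------------

    def growth_log_factor(self, t1: float, t2: float) -> float:
        """Integral of H(t) dt from t1 to t2 (log of the stretch factor)."""
        h0, b = self.growth_rate_H0, self.growth_acceleration_beta
        return h0 * ((t2 - t1) + 0.5 * b * (t2 * t2 - t1 * t1))

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


#: Growth-medium presets.  Inert-zone sizes and the TB/SOC diameters are the
#: measured values for cells grown in each medium; the LB diameter and the
#: growth-rate parameters are representative choices documented in the
#: methods note.
PRESETS: dict[str, dict[str, Any]] = {
    "LB": dict(cap_size_c=0.27, diameter_D=1.06, growth_rate_H0=0.010, growth_acceleration_beta=0.005),
    "TB": dict(cap_size_c=0.22, diameter_D=1.02, growth_rate_H0=0.008, growth_acceleration_beta=0.004),
    "SOC": dict(cap_size_c=0.37, diameter_D=1.11, growth_rate_H0=0.012, growth_acceleration_beta=0.005),
}


def preset(name: str, **overrides: Any) -> SimConfig:
    """Build a SimConfig from a named growth-medium preset."""
    if name not in PRESETS:
        raise ConfigurationError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs: dict[str, Any] = dict(PRESETS[name])
    kwargs.update(overrides)
    cfg = SimConfig(**kwargs)
    cfg.validate()
    return cfg


def config_from_dict(d: dict[str, Any]) -> SimConfig:
    """Build and validate a SimConfig from a plain mapping (YAML/JSON)."""
    d = dict(d)
    name = d.pop("preset", None)
    placement = d.pop("motor_placement", None)
    render = d.pop("render", None)
    base: dict[str, Any] = dict(PRESETS[name]) if name else {}
    unknown = set(d) - set(SimConfig.__dataclass_fields__)
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    base.update(d)
    cfg = SimConfig(**base)
    if placement is not None:
        cfg.motor_placement = PlacementSpec(**placement) if isinstance(placement, dict) else placement
    if render is not None and render is not False:
        cfg.render = RenderConfig(**render) if isinstance(render, dict) else render
    cfg.validate()
    return cfg


def load_config(path: str | Path) -> SimConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path} must contain a mapping")
    return config_from_dict(data)
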