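"""The Bernoulli shift map model of landmark partitioning across divisions.

A wall-anchored landmark in the active zone sits at a fixed normalized
axial coordinate ``N_y = Y / L`` in [-0.5, 0.5] while the cell elongates.
At division the cell splits at mid-cell and each daughter gains a new inert
cap, so the landmark's coordinate in the daughter is

    N_y(n+1) = 2 N_y(n) - 0.5   if 0 < N_y(n) <= 0.5
    N_y(n+1) = 2 N_y(n) + 0.5   if -0.5 <= N_y(n) < 0

The two boundary points +-0.5 (the active/inert border) are fixed points;
the point 0 (exactly at the division plane) is undefined -- physically the
landmark falls into one daughter or the other, so an optional seeded
fair-coin policy applies the corresponding branch to 0 (giving -0.5 or
+0.5).  The map preserves the uniform law on [-0.5, 0.5] and exponentially
smooths any density on the central rod, which is the model's biological
point: uneven surface-protein distributions even out within a few
generations.

Orbit analysis of rational starting points uses exact
:class:`fractions.Fraction` arithmetic so that periodicity is not destroyed
by floating-point drift; the population simulation uses floats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Rational

import numpy as np
import pandas as pd
from scipy import stats

from wallmark.errors import DomainError, UndefinedPointError
from wallmark.rng import substream
from wallmark.simulate import sample_truncated_gaussian

Number = float | Fraction


def step(n_y: Number, *, zero_policy: str = "error",
         rng: np.random.Generator | None = None) -> Number:
    """Apply the shift map once.  Exact for :class:`~fractions.Fraction` input.

    ``zero_policy``: ``"error"`` (default) refuses N_y = 0; ``"coin"``
    applies a fair-coin-chosen branch (requires ``rng``).
    """
    half = Fraction(1, 2) if isinstance(n_y, Rational) else 0.5
    if n_y < -half or n_y > half:
        raise DomainError(f"N_y = {n_y} outside [-0.5, 0.5]")
    if n_y > 0:
        return 2 * n_y - half
    if n_y < 0:
        return 2 * n_y + half
    if zero_policy == "coin":
        if rng is None:
            raise ValueError("zero_policy='coin' requires an rng")
        return half if rng.random() < 0.5 else -half
    raise UndefinedPointError(
        "the shift map is undefined at N_y = 0 (both branches exclude it); "
        "pass zero_policy='coin' to emulate the seeded division-side coin"
    )


@dataclass
class BernoulliTrajectory:
    """Orbit of one landmark across generations."""

    n_y_sequence: list[Number]
    daughter_choices: list[str] = field(default_factory=list)  # 'upper'|'lower'

    def __len__(self) -> int:
        return len(self.n_y_sequence)


def iterate(n_y0: Number, n_generations: int, *, exact: bool | None = None,
            zero_policy: str = "error",
            rng: np.random.Generator | None = None) -> BernoulliTrajectory:
    """Iterate the map ``n_generations`` times from ``n_y0``.

    ``exact=True`` converts the start to a Fraction (via
    ``Fraction(str(n_y0))`` for floats, so ``0.1`` means the decimal 1/10)
    and iterates in exact rational arithmetic.
    """
    if exact is None:
        exact = isinstance(n_y0, Rational)
    x: Number
    if exact and not isinstance(n_y0, Rational):
        x = Fraction(str(n_y0))
    else:
        x = n_y0
    seq: list[Number] = [x]
    choices: list[str] = []
    for _ in range(n_generations):
        choices.append("upper" if x > 0 else ("lower" if x < 0 else "coin"))
        x = step(x, zero_policy=zero_policy, rng=rng)
        seq.append(x)
    return BernoulliTrajectory(n_y_sequence=seq, daughter_choices=choices)


def orbit_period(p: int, q: int, max_period: int = 10_000) -> int:
    """Exact eventual period of the orbit of p/q (in lowest terms).

    Returns the length of the cycle the orbit falls into (1 for the fixed
    points +-1/2).  Uses exact rational arithmetic.
    """
    x = Fraction(p, q)
    seen: dict[Fraction, int] = {}
    for i in range(max_period):
        if x in seen:
            return i - seen[x]
        seen[x] = i
        if x == 0:
            raise UndefinedPointError("orbit hits the undefined point 0")
        x = step(x)
    raise RuntimeError(f"no cycle within {max_period} steps for {p}/{q}")


# ---------------------------------------------------------------------------
# population distribution evolution


@dataclass
class DistributionSim:
    """Configuration of a population pushforward simulation."""

    n_particles: int = 200_000
    sigma: float = 0.4  # truncated-Gaussian width of the initial law
    generations: int = 3
    n_bins: int = 50
    rng_seed: int = 0
    initial_positions: np.ndarray | None = None  # overrides the Gaussian law


@dataclass
class DistributionEvolution:
    histograms: pd.DataFrame  # columns: generation, bin_left, bin_right, mass
    ks_to_uniform: list[float]
    positions: list[np.ndarray]


def _uniform_cdf(v: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(v) + 0.5, 0.0, 1.0)


def ks_to_uniform(sample: np.ndarray) -> float:
    """Exact-CDF Kolmogorov-Smirnov distance to the uniform law on [-0.5, 0.5]."""
    return float(stats.kstest(sample, _uniform_cdf).statistic)


def evolve_distribution(config: DistributionSim) -> DistributionEvolution:
    """Deterministically push a sampled population through the map.

    The initial law is a truncated Gaussian (rejection-sampled, seeded) or a
    user-supplied position array; each generation applies the map to every
    particle (particles exactly at 0 -- probability zero for continuous
    laws -- take the seeded coin branch).  Particle count is conserved.
    """
    rng = substream(config.rng_seed, "initial_law")
    if config.initial_positions is not None:
        x = np.asarray(config.initial_positions, dtype=float).copy()
        if np.any(np.abs(x) > 0.5):
            raise DomainError("initial positions outside [-0.5, 0.5]")
    else:
        x = sample_truncated_gaussian(config.n_particles, config.sigma, rng)
    coin = substream(config.rng_seed, "coin")
    edges = np.linspace(-0.5, 0.5, config.n_bins + 1)
    hist_rows = []
    ks = []
    snapshots = []
    for gen in range(config.generations + 1):
        counts, _ = np.histogram(x, bins=edges)
        mass = counts / counts.sum()
        for bl, br, m in zip(edges[:-1], edges[1:], mass):
            hist_rows.append((gen, bl, br, m))
        ks.append(ks_to_uniform(x))
        snapshots.append(x.copy())
        if gen == config.generations:
            break
        zero = x == 0.0
        if zero.any():
            x[zero] = np.where(coin.random(int(zero.sum())) < 0.5, 0.5, -0.5)
        x = np.where(x > 0, 2 * x - 0.5, np.where(x < 0, 2 * x + 0.5, x))
    histograms = pd.DataFrame(hist_rows, columns=["generation", "bin_left", "bin_right", "mass"])
    return DistributionEvolution(histograms, ks, snapshots)


# ---------------------------------------------------------------------------
# model vs observation


@dataclass
class MapComparison:
    residuals: pd.DataFrame  # motor_id, N_y_mother, N_y_daughter, predicted, residual
    fraction_on_map: float
    tolerance: float


def predict_vs_observed(pairs: pd.DataFrame, tolerance: float = 0.05) -> MapComparison:
    """Compare observed mother/daughter normalized-position pairs to the map.

    ``pairs`` needs columns ``N_y_mother`` and ``N_y_daughter`` (extra
    columns are carried through).  The residual is
    ``|N_y_daughter - step(N_y_mother)|``; for a mother exactly at 0 the
    better of the two branches is used (the daughter identity tells which
    side it fell).  Mothers outside [-0.5, 0.5] raise a domain error.
    """
    m = pairs["N_y_mother"].to_numpy(dtype=float)
    d = pairs["N_y_daughter"].to_numpy(dtype=float)
    if np.any(np.abs(m) > 0.5 + 1e-12):
        raise DomainError("N_y_mother outside [-0.5, 0.5]")
    up = 2 * m - 0.5
    lo = 2 * m + 0.5
    pred = np.where(m > 0, up, lo)
    pred_zero = np.where(np.abs(d - up) <= np.abs(d - lo), up, lo)
    pred = np.where(m == 0, pred_zero, pred)
    resid = np.abs(d - pred)
    out = pairs.copy()
    out["predicted"] = pred
    out["residual"] = resid
    frac = float(np.mean(resid <= tolerance)) if len(resid) else float("nan")
    return MapComparison(out, frac, tolerance)
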