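"""Monte Carlo simulation of single particles transiting two offset laser beams.

The simulated instrument is a micrometer-scale flow channel interrogated by
two spatially offset lasers (an upstream "red" beam and a downstream "blue"
beam). Flow is laminar, so particle speed follows the Poiseuille parabola

    v(r) = v_max * (1 - (r / R)^2)

with ``R`` the channel radius: fastest on the axis, zero at the wall.
Because particles are not flow-focused, each one carries its own speed,
and the transit order observed at the two lasers can differ (slow
particles are overtaken between beams). This order scrambling is exactly
what breaks global-lag colocalization and what the transit-time approach
is designed to survive.

For each particle the simulator draws a radial position, converts it to a
speed, and derives:

* ``t_red``   — time the particle crosses the red beam center (ms),
* ``t_blue``  — ``t_red + dx3 / v`` (red-to-blue flow direction),
* true transit times ``pt = beam_width / v`` per beam,
* observed transit times, the true ones perturbed by a multiplicative
  random error emulating the uncertainty of transit-time estimation,
* a brightness class (dim or bright) and an intensity.

Arrivals form a homogeneous Poisson process. All randomness flows from a
single seed, so a fixed seed reproduces the ground truth bit-identically.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trace import Trace, add_gaussian_pulses

CHANNEL_RED = "red"
CHANNEL_BLUE = "blue"

#: Radial positions whose speed falls below this fraction of v_max are
#: resampled: such particles would not exit the channel within any
#: realistic record.
_MIN_SPEED_FRACTION = 1e-3

_RADIAL_SCHEMES = ("flux", "area")
_PT_ERROR_MODELS = ("uniform", "gaussian")

_PARTICLE_COLUMNS = [
    "particle_id",
    "speed_um_per_ms",
    "t_red_ms",
    "t_blue_ms",
    "pt_red_ms",
    "pt_blue_ms",
    "pt_red_true_ms",
    "pt_blue_true_ms",
    "brightness_class",
    "intensity",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated acquisition.

    Attributes
    ----------
    v_max : float
        Center-line speed, μm/ms.
    channel_radius : float
        Channel radius, μm (half the channel diameter).
    beam_width_blue, beam_width_red : float
        Widths of the blue (downstream, ΔX1) and red (upstream, ΔX2)
        beams, μm. A particle's true transit time across a beam is
        ``width / v``.
    laser_separation : float
        Center-to-center distance between the lasers, μm (ΔX3).
    arrival_rate : float
        Mean particle arrival rate at the red laser, particles/s.
    duration : float
        Acquisition length, s.
    bright_fraction : float
        Probability that a particle is bright (vs dim), in [0, 1].
    bright_dim_ratio : float
        Intensity of bright particles relative to dim ones (dim = 1).
    pt_error_cv : float
        Relative scale of the random error applied to observed transit
        times (0.10 = "10% error").
    pt_error_model : str
        ``"uniform"`` — multiplicative factor uniform on
        [1 - cv, 1 + cv] (a literal bounded "10% error", the default);
        ``"gaussian"`` — factor 1 + N(0, cv), redrawn while nonpositive.
    radial_sampling : str
        ``"flux"`` — radial density ∝ r·v(r): particles observed crossing
        a plane in steady laminar flow arrive in proportion to their
        speed (the default, and the physically expected observation
        bias); ``"area"`` — density ∝ r, i.e. uniform over the channel
        cross-section.
    sample_rate : float
        Sampling rate for rendered traces, Hz.
    seed : int or None
        Seed for all randomness; ``None`` draws fresh entropy.
    """

    v_max: float = 3.0
    channel_radius: float = 1.0
    beam_width_blue: float = 1.0
    beam_width_red: float = 1.0
    laser_separation: float = 15.0
    arrival_rate: float = 35.0
    duration: float = 120.0
    bright_fraction: float = 0.5
    bright_dim_ratio: float = 3.0
    pt_error_cv: float = 0.10
    pt_error_model: str = "uniform"
    radial_sampling: str = "flux"
    sample_rate: float = 10_000.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.v_max <= 0:
            raise ValueError("v_max must be positive")
        if self.channel_radius <= 0:
            raise ValueError("channel_radius must be positive")
        for name in ("beam_width_blue", "beam_width_red", "laser_separation"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.arrival_rate < 0:
            raise ValueError("arrival_rate must be nonnegative")
        if not 0.0 <= self.bright_fraction <= 1.0:
            raise ValueError("bright_fraction must lie in [0, 1]")
        if self.bright_dim_ratio < 1.0:
            raise ValueError("bright_dim_ratio must be >= 1")
        if self.pt_error_cv < 0:
            raise ValueError("pt_error_cv must be nonnegative")
        if self.pt_error_model not in _PT_ERROR_MODELS:
            raise ValueError(f"pt_error_model must be one of {_PT_ERROR_MODELS}")
        if self.radial_sampling not in _RADIAL_SCHEMES:
            raise ValueError(f"radial_sampling must be one of {_RADIAL_SCHEMES}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)


@dataclass
class GroundTruth:
    """Simulated particle list plus the configuration that produced it.

    ``particles`` is a DataFrame sorted by red-crossing time with one row
    per particle (columns listed in ``_PARTICLE_COLUMNS``): ``pt_*_ms``
    are the observed (error-perturbed) transit times, ``pt_*_true_ms``
    the exact ones.
    """

    particles: pd.DataFrame
    config: SimulationConfig | None = None

    def __len__(self) -> int:
        return len(self.particles)


def sample_velocity(config: SimulationConfig, r) -> np.ndarray | float:
    """Poiseuille speed at radial position ``r`` (μm), in μm/ms.

    Raises ``ValueError`` for positions at or beyond the channel wall,
    where the no-slip condition means the particle never transits.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= config.channel_radius):
        raise ValueError("radial position must satisfy 0 <= r < channel_radius")
    v = config.v_max * (1.0 - (r / config.channel_radius) ** 2)
    return float(v) if v.ndim == 0 else v


def _sample_radii(rng: np.random.Generator, config: SimulationConfig, n: int) -> np.ndarray:
    """Draw radial positions under the configured scheme, with the
    zero-velocity guard (near-wall positions resampled)."""
    # Work in u = (r/R)^2, so v = v_max (1 - u).
    #   area: u ~ Uniform(0, 1)
    #   flux: density(u) ∝ (1 - u)  =>  u = 1 - sqrt(1 - U)
    u = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        draw = rng.random(todo.size)
        if config.radial_sampling == "area":
            cand = draw
        else:
            cand = 1.0 - np.sqrt(1.0 - draw)
        u[todo] = cand
        todo = todo[cand > 1.0 - _MIN_SPEED_FRACTION]
    return config.channel_radius * np.sqrt(u)


def _pt_error_factors(rng: np.random.Generator, config: SimulationConfig, n: int) -> np.ndarray:
    """Multiplicative factors applied to true transit times (always > 0)."""
    cv = config.pt_error_cv
    if cv == 0:
        return np.ones(n)
    if config.pt_error_model == "uniform":
        if cv >= 1.0:
            raise ValueError("uniform pt_error_model requires pt_error_cv < 1")
        return rng.uniform(1.0 - cv, 1.0 + cv, n)
    factors = 1.0 + rng.normal(0.0, cv, n)
    bad = np.flatnonzero(factors <= 0)
    while bad.size:
        factors[bad] = 1.0 + rng.normal(0.0, cv, bad.size)
        bad = bad[factors[bad] <= 0]
    return factors


def simulate_particles(config: SimulationConfig) -> GroundTruth:
    """Generate the ground-truth particle list for one acquisition.

    Arrival times at the red laser are a homogeneous Poisson process at
    ``arrival_rate`` over ``duration``; each particle independently gets
    a radial position, hence a speed, hence its blue-crossing time and
    true transit times; observed transit times add the configured random
    error, independently per laser.
    """
    if config.duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(config.seed)
    n = int(rng.poisson(config.arrival_rate * config.duration))
    t_red = np.sort(rng.uniform(0.0, config.duration * 1000.0, n))  # ms
    r = _sample_radii(rng, config, n)
    v = config.v_max * (1.0 - (r / config.channel_radius) ** 2)
    t_blue = t_red + config.laser_separation / v
    pt_red_true = config.beam_width_red / v
    pt_blue_true = config.beam_width_blue / v
    pt_red_obs = pt_red_true * _pt_error_factors(rng, config, n)
    pt_blue_obs = pt_blue_true * _pt_error_factors(rng, config, n)
    bright = rng.random(n) < config.bright_fraction
    particles = pd.DataFrame(
        {
            "particle_id": np.arange(n),
            "speed_um_per_ms": v,
            "t_red_ms": t_red,
            "t_blue_ms": t_blue,
            "pt_red_ms": pt_red_obs,
            "pt_blue_ms": pt_blue_obs,
            "pt_red_true_ms": pt_red_true,
            "pt_blue_true_ms": pt_blue_true,
            "brightness_class": np.where(bright, "bright", "dim"),
            "intensity": np.where(bright, config.bright_dim_ratio, 1.0),
        },
        columns=_PARTICLE_COLUMNS,
    )
    return GroundTruth(particles=particles, config=config)


def peak_tables(gt: GroundTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observed per-channel peak tables for a simulated acquisition.

    Returns ``(red, blue)`` peak tables in the package's standard schema
    (``channel, t_center_ms, height, pt_ms, fit_quality,
    true_particle_id, brightness_class``), each sorted by its own
    crossing time — so at high density the blue table's particle order
    differs from the red one's wherever particles overtook each other
    between the lasers.
    """
    p = gt.particles

    def _table(channel: str, t_col: str, pt_col: str) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "channel": channel,
                "t_center_ms": p[t_col].to_numpy(),
                "height": p["intensity"].to_numpy(),
                "pt_ms": p[pt_col].to_numpy(),
                "fit_quality": 1.0,
                "true_particle_id": p["particle_id"].to_numpy(),
                "brightness_class": p["brightness_class"].to_numpy(),
            }
        )
        return df.sort_values("t_center_ms", kind="mergesort", ignore_index=True)

    red = _table(CHANNEL_RED, "t_red_ms", "pt_red_ms")
    blue = _table(CHANNEL_BLUE, "t_blue_ms", "pt_blue_ms")
    return red, blue


def render_traces(
    gt: GroundTruth,
    baseline_sigma: float = 0.02,
    seed: int | None = None,
) -> dict[str, Trace]:
    """Render raw per-channel traces from the ground truth.

    Each particle contributes a Gaussian pulse centered at its
    beam-center crossing time whose FWHM equals its *true* transit time
    in that channel and whose amplitude equals its intensity; additive
    Gaussian baseline noise of standard deviation ``baseline_sigma``
    (default small relative to the dim amplitude of 1) is superimposed.
    Warns when the sample rate leaves fewer than 5 samples per narrowest
    pulse FWHM.
    """
    config = gt.config
    if config is None:
        raise ValueError("ground truth carries no configuration")
    p = gt.particles
    n_samples = int(round(config.duration * config.sample_rate))
    if seed is None and config.seed is not None:
        seed = config.seed + 0x5EED
    rng = np.random.default_rng(seed)
    if len(p):
        narrowest = float(min(p["pt_red_true_ms"].min(), p["pt_blue_true_ms"].min()))
        samples_per_fwhm = narrowest * config.sample_rate / 1000.0
        if samples_per_fwhm < 5:
            warnings.warn(
                f"sample rate {config.sample_rate:g} Hz yields only "
                f"{samples_per_fwhm:.1f} samples across the narrowest transit "
                f"({narrowest:.3g} ms); expect degraded peak fitting",
                stacklevel=2,
            )
    traces: dict[str, Trace] = {}
    for channel, t_col, pt_col in (
        (CHANNEL_RED, "t_red_ms", "pt_red_true_ms"),
        (CHANNEL_BLUE, "t_blue_ms", "pt_blue_true_ms"),
    ):
        values = rng.normal(0.0, baseline_sigma, n_samples) if baseline_sigma > 0 else np.zeros(n_samples)
        add_gaussian_pulses(
            values,
            config.sample_rate,
            p[t_col].to_numpy(),
            p[pt_col].to_numpy(),
            p["intensity"].to_numpy(),
        )
        traces[channel] = Trace(channel=channel, sample_rate=config.sample_rate, values=values)
    return traces


def write_ground_truth(gt: GroundTruth, path) -> None:
    """Write the particle list as CSV (times in ms to 6 decimals)."""
    gt.particles.to_csv(path, index=False, float_format="%.6f")


def read_ground_truth(path, config: SimulationConfig | None = None) -> GroundTruth:
    particles = pd.read_csv(path)
    missing = [c for c in _PARTICLE_COLUMNS[:6] if c not in particles.columns]
    if missing:
        raise ValueError(f"ground-truth file missing required column(s): {', '.join(missing)}")
    return GroundTruth(particles=particles, config=config)
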