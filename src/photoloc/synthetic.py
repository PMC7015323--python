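"""Synthetic stand-ins for the field inputs of the photolocation analysis.

No spectral or behavioural data are deposited with the study this package
models, so every downstream stage is exercised on generated inputs that
carry the same structure:

* blue-shifted underwater downwelling irradiance at depth, via Beer–Lambert
  attenuation with a Jerlov-style diffuse attenuation coefficient K(λ)
  rising toward the red;
* photoreceptor spectral sensitivities from the Govardovskii A1
  visual-pigment template (α and β bands), peak-normalised to 1;
* reflectance / radiance shapes for the blue ocular spark, the
  retroreflective scorpionfish pupil (values may exceed 1 relative to a
  diffuse white standard), the scorpionfish iris, and baseline pupil
  radiance;
* approach/retreat distance trajectories of hatted triplefins in a 50-cm
  arena, with an AR(1)-correlated noise process on a logit-transformed
  bounded distance.

All spectra come back on the canonical 400–700 nm, 1-nm grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import Spectrum, SpectrumKind, default_grid

__all__ = [
    "AmbientModel",
    "BehaviorSimConfig",
    "make_ambient",
    "make_pigment_sensitivity",
    "make_reflectance",
    "simulate_behavior",
    "default_ambient_model",
    "DEFAULT_LAMBDA_MAX",
]

#: λmax placeholders for the SWS single cone and the MWS/LWS double-cone
#: members. The study species' true values live in cited references, not in
#: any printed table; override freely.
DEFAULT_LAMBDA_MAX = {"sws": 468.0, "mws": 516.0, "lws": 530.0}


@dataclass(frozen=True)
class AmbientModel:
    """Surface irradiance plus diffuse attenuation, evaluated at depth."""

    surface_irradiance: Spectrum
    attenuation_coeff: Spectrum  # per-metre K(λ), ≥ 0
    depth_m: float = 10.0

    def __post_init__(self) -> None:
        if self.depth_m < 0:
            raise ValueError("depth must be nonnegative")


def default_ambient_model(depth_m: float = 10.0, surface_level: float = 1e18) -> AmbientModel:
    """Flat surface spectrum with a monotone, red-weighted K(λ).

    K rises smoothly from ~0.04 m⁻¹ at 400 nm to ~0.55 m⁻¹ at 700 nm
    (clear-ocean-like), which leaves a blue-green spectrum at 10 m.
    ``surface_level`` is in photons s⁻¹ m⁻² nm⁻¹.
    """
    grid = default_grid()
    surface = Spectrum.constant(surface_level, SpectrumKind.IRRADIANCE, grid)
    k = 0.04 + 0.51 * ((grid - 400.0) / 300.0) ** 2
    # K is per-metre and unbounded above; reuse the unbounded dimensionless tag
    katt = Spectrum(grid, k, SpectrumKind.REFLECTANCE)
    return AmbientModel(surface, katt, depth_m)


def make_ambient(model: AmbientModel) -> Spectrum:
    """Downwelling irradiance at depth: E(λ) = E₀(λ)·exp(−K(λ)·z)."""
    e0 = model.surface_irradiance
    e0._check_grid(model.attenuation_coeff)
    v = e0.values * np.exp(-model.attenuation_coeff.values * model.depth_m)
    return Spectrum(e0.wavelengths_nm, v, SpectrumKind.IRRADIANCE)


# -- Govardovskii et al. A1 template ---------------------------------------

def make_pigment_sensitivity(lambda_max_nm: float, grid: np.ndarray | None = None) -> Spectrum:
    """A1 visual-pigment absorbance template, peak-normalised.

    Standard vitamin-A1 rhodopsin nomogram: α-band as a sum of
    exponentials in x = λmax/λ plus a Gaussian β-band, normalised so the
    maximum on the grid is 1. Valid for 330 ≤ λmax ≤ 650 nm.
    """
    lm = float(lambda_max_nm)
    if not (330.0 <= lm <= 650.0):
        raise ValueError(f"lambda_max {lm:g} nm outside template range 330–650 nm")
    wl = default_grid() if grid is None else np.asarray(grid, dtype=float)
    x = lm / wl
    a = 0.8795 + 0.0459 * np.exp(-((lm - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    lmb = 189.0 + 0.315 * lm
    b = -40.5 + 0.195 * lm
    beta = 0.26 * np.exp(-(((wl - lmb) / b) ** 2))
    s = alpha + beta
    s = np.clip(s / s.max(), 0.0, 1.0)
    return Spectrum(wl, s, SpectrumKind.SENSITIVITY)


# -- reflectance / radiance shapes -----------------------------------------

_SPARK_PEAK_NM = 475.0  # blue ocular spark
_SPARK_WIDTH_NM = 45.0


def make_reflectance(
    kind: str,
    level: float = 1.0,
    peak_nm: float | None = None,
    width_nm: float | None = None,
) -> Spectrum:
    """Synthetic reflectance (or radiance-shape) spectrum of a scene surface.

    kinds:
      ``spark``                 blue-peaked Gaussian, max = level
      ``retro_pupil``           slightly long-pass retroreflectance, max = level
                                (level may exceed 1: proportion relative to a
                                diffuse white standard)
      ``iris``                  flat dull reflectance = level
      ``baseline_pupil_radiance`` broad dim eyeshine shape, max = level,
                                tagged radiance
    """
    if level < 0:
        raise ValueError("level must be nonnegative")
    grid = default_grid()
    if kind == "spark":
        p = _SPARK_PEAK_NM if peak_nm is None else peak_nm
        w = _SPARK_WIDTH_NM if width_nm is None else width_nm
        v = level * np.exp(-0.5 * ((grid - p) / w) ** 2)
        return Spectrum(grid, v, SpectrumKind.REFLECTANCE)
    if kind == "retro_pupil":
        # gentle rise toward long wavelengths, typical of stratum-argenteum
        # eyeshine; normalised so the grid maximum equals `level`
        raw = 0.55 + 0.45 / (1.0 + np.exp(-(grid - 520.0) / 40.0))
        v = level * raw / raw.max()
        return Spectrum(grid, v, SpectrumKind.REFLECTANCE)
    if kind == "iris":
        return Spectrum.constant(level, SpectrumKind.REFLECTANCE, grid)
    if kind == "baseline_pupil_radiance":
        raw = 0.55 + 0.45 / (1.0 + np.exp(-(grid - 520.0) / 40.0))
        v = level * raw / raw.max()
        return Spectrum(grid, v, SpectrumKind.RADIANCE)
    raise ValueError(f"unknown reflectance kind {kind!r}")


# -- behavioural simulation -------------------------------------------------

@dataclass(frozen=True)
class BehaviorSimConfig:
    """Arena trajectories of shaded vs clear-hatted fish.

    The shaded arm sits ``treatment_effect_cm`` closer to the stimulus than
    the clear-hatted arm at the first timepoint (in expectation); the gap
    closes linearly by ~50 min, after which both arms coincide. Both arms
    drift toward the far wall with a quadratic-in-time saturating retreat.
    Noise is Gaussian AR(1) within individual, applied on the logit of
    distance/arena so trajectories respect the arena bounds.
    """

    n_per_treatment: int = 40
    arena_length_cm: float = 50.0
    release_point_cm: float = 25.0
    n_timepoints: int = 7
    treatment_effect_cm: float = 8.0
    retreat_rate: float = 0.5  # cm per minute initial drift to far wall
    ar1_rho: float = 0.5
    noise_sd_cm: float = 6.0
    seed: int = 0
    total_time_min: float = 100.0
    effect_decay_min: float = 50.0

    def __post_init__(self) -> None:
        if not (0 < self.release_point_cm < self.arena_length_cm):
            raise ValueError("release point must lie inside the arena")
        if self.n_timepoints < 1:
            raise ValueError("need at least one timepoint")
        if not (-1 < self.ar1_rho < 1):
            raise ValueError("|ar1_rho| must be < 1")

    @property
    def times_min(self) -> np.ndarray:
        """First observation at 1 min, then evenly spaced to total_time."""
        if self.n_timepoints == 1:
            return np.array([1.0])
        return np.linspace(1.0, self.total_time_min, self.n_timepoints)


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _mean_trajectory(cfg: BehaviorSimConfig, t: np.ndarray, shaded: bool) -> np.ndarray:
    T = cfg.total_time_min
    # quadratic-in-time retreat saturating (zero slope) at T
    drift = cfg.retreat_rate * t * (1.0 - t / (2.0 * T))
    mu = cfg.release_point_cm + drift
    if shaded:
        decay = np.clip(1.0 - (t - t[0]) / max(cfg.effect_decay_min, 1e-9), 0.0, 1.0)
        mu = mu - cfg.treatment_effect_cm * decay
    return np.clip(mu, 0.0, cfg.arena_length_cm)


def simulate_behavior(cfg: BehaviorSimConfig) -> pd.DataFrame:
    """Distance records: columns individual_id, treatment, time_min, distance_cm."""
    rng = np.random.default_rng(cfg.seed)
    t = cfg.times_min
    L = cfg.arena_length_cm
    # noise_sd is stated in cm; convert to logit units via the slope of the
    # inverse transform at the release point (L·x(1−x) cm per logit unit)
    x0 = cfg.release_point_cm / L
    sd_z = cfg.noise_sd_cm / (L * x0 * (1.0 - x0))
    frames = []
    eps_margin = 1e-6
    n, T = cfg.n_per_treatment, len(t)
    for treatment, shaded in (("clear", False), ("shaded", True)):
        mu = _mean_trajectory(cfg, t, shaded)
        z_mu = _logit(np.clip(mu / L, eps_margin, 1.0 - eps_margin))
        eps = np.zeros((n, T))
        if sd_z > 0:
            innov = rng.normal(0.0, sd_z, size=(n, T))
            eps[:, 0] = innov[:, 0]
            scale = np.sqrt(1.0 - cfg.ar1_rho**2)
            for k in range(1, T):  # stationary AR(1) within individual
                eps[:, k] = cfg.ar1_rho * eps[:, k - 1] + scale * innov[:, k]
        d = L / (1.0 + np.exp(-(z_mu[None, :] + eps)))
        ids = np.array([f"{treatment}_{i:03d}" for i in range(n)])
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": np.repeat(ids, T),
                    "treatment": treatment,
                    "time_min": np.tile(t, n),
                    "distance_cm": np.clip(d, 0.0, L).ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
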