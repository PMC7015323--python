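"""On-axis radiometric propagation for the spark–eyeshine geometry.

Two photon paths reach the observing triplefin's pupil from the
scorpionfish eye, both with observer and target looking orthogonally at
one another at eye-to-eye distance d:

* baseline path — the scorpionfish pupil's own radiance L_base seen
  through the solid angle the triplefin pupil subtends:
  Φ₂(λ) = L_base(λ) · A_sp · A_tf / d²            (∝ d⁻²)

* spark retro path — the triplefin's ocular spark (a diffuse Lambertian
  patch, L_spark = R_spark·E_down/π) illuminates the scorpionfish pupil
  (E_t = L_spark·A_spark/d²), which retroreflects it (L_r = E_t·R_retro/π,
  R_retro relative to a diffuse white standard and allowed to exceed 1),
  and the return beam is collected by the triplefin pupil:
  Φ_r(λ) = L_r(λ) · A_sp · A_tf / d²              (∝ d⁻⁴)

flux₁ = Φ₂ + Φ_r (spark on), flux₂ = Φ₂ (spark off). Solid angles use the
small-angle approximation Ω = A/d²; any directional narrowing of the
retroreflected beam is absorbed into the magnitude of R_retro rather than
modelled as an angular lobe. All areas mm², distances mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .spectra import Spectrum, SpectrumKind

__all__ = [
    "GeometryParams",
    "SceneFluxes",
    "solid_angle",
    "baseline_flux",
    "spark_radiance",
    "retro_flux",
    "scene_fluxes",
]


@dataclass(frozen=True)
class GeometryParams:
    """Areas of the three apertures and the on-axis eye-to-eye distance.

    Defaults are order-of-magnitude placeholders for a ~5 cm triplefin
    facing a scorpionfish: ~1 mm² spark, ~2 mm² triplefin pupil, ~28 mm²
    scorpionfish pupil (6 mm diameter).
    """

    area_spark_mm2: float = 1.0
    area_tf_pupil_mm2: float = 2.0
    area_sp_pupil_mm2: float = 28.0
    distance_mm: float = 100.0

    def __post_init__(self) -> None:
        for name in ("area_spark_mm2", "area_tf_pupil_mm2", "area_sp_pupil_mm2", "distance_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        worst = max(
            np.sqrt(self.area_spark_mm2),
            np.sqrt(self.area_tf_pupil_mm2),
            np.sqrt(self.area_sp_pupil_mm2),
        )
        if worst / self.distance_mm > 0.3:
            warnings.warn(
                "aperture size comparable to distance: small-angle solid-angle "
                "approximation degrades",
                stacklevel=2,
            )

    def at_distance(self, distance_mm: float) -> "GeometryParams":
        return replace(self, distance_mm=distance_mm)


@dataclass(frozen=True)
class SceneFluxes:
    """Photon flux spectra at the observer pupil, spark on vs spark off."""

    flux_with_spark: Spectrum
    flux_without_spark: Spectrum
    distance_mm: float

    def __post_init__(self) -> None:
        self.flux_with_spark._check_grid(self.flux_without_spark)
        if np.any(self.flux_with_spark.values < self.flux_without_spark.values - 1e-30):
            raise ValueError("spark can only add photons: flux₁ must dominate flux₂")


def solid_angle(area_mm2: float, distance_mm: float) -> float:
    """Small-angle solid angle Ω = A/d² (steradians)."""
    if area_mm2 <= 0 or distance_mm <= 0:
        raise ValueError("area and distance must be strictly positive")
    return area_mm2 / distance_mm**2


def baseline_flux(L_base: Spectrum, g: GeometryParams) -> Spectrum:
    """Photon flux from the target pupil's own radiance; scales as d⁻²."""
    if L_base.kind is not SpectrumKind.RADIANCE:
        raise ValueError("L_base must be radiance-tagged")
    omega = solid_angle(g.area_tf_pupil_mm2, g.distance_mm)
    return L_base.with_values(
        L_base.values * g.area_sp_pupil_mm2 * omega, SpectrumKind.FLUX
    )


def spark_radiance(R_spark: Spectrum, E_down: Spectrum) -> Spectrum:
    """Lambertian spark radiance L = R·E/π under downwelling irradiance."""
    if R_spark.kind is not SpectrumKind.REFLECTANCE:
        raise ValueError("R_spark must be reflectance-tagged")
    if E_down.kind is not SpectrumKind.IRRADIANCE:
        raise ValueError("E_down must be irradiance-tagged")
    R_spark._check_grid(E_down)
    return R_spark.with_values(
        R_spark.values * E_down.values / np.pi, SpectrumKind.RADIANCE
    )


def retro_flux(L_spark: Spectrum, R_retro: Spectrum, g: GeometryParams) -> Spectrum:
    """Spark → target pupil → retroreflection → observer pupil; scales as d⁻⁴."""
    if L_spark.kind is not SpectrumKind.RADIANCE:
        raise ValueError("L_spark must be radiance-tagged")
    if R_retro.kind is not SpectrumKind.REFLECTANCE:
        raise ValueError("R_retro must be reflectance-tagged")
    L_spark._check_grid(R_retro)
    d2 = g.distance_mm**2
    E_target = L_spark.values * g.area_spark_mm2 / d2
    L_return = E_target * R_retro.values / np.pi
    phi = L_return * g.area_sp_pupil_mm2 * g.area_tf_pupil_mm2 / d2
    return L_spark.with_values(phi, SpectrumKind.FLUX)


def scene_fluxes(
    L_base: Spectrum,
    L_spark: Spectrum,
    R_retro: Spectrum,
    g: GeometryParams,
) -> SceneFluxes:
    """flux₂ = baseline only; flux₁ = baseline + spark retroreflection."""
    phi2 = baseline_flux(L_base, g)
    phi_r = retro_flux(L_spark, R_retro, g)
    return SceneFluxes(
        flux_with_spark=phi2 + phi_r,
        flux_without_spark=phi2,
        distance_mm=g.distance_mm,
    )
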