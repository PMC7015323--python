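"""Quantum catches and the two contrast metrics of the triplefin observer.

The triplefin retina is modelled with three cone channels: an SWS single
cone and the MWS/LWS members of the double cone, at relative density
1 : 4 : 4 (single : double members, as in the foveal retina). Per-channel
quantum catch is the rectangle-sum integral of photon flux filtered by
ocular media transmission and spectral sensitivity over 400–700 nm:

    qᵢ = Σ_λ Φ(λ)·T(λ)·Sᵢ(λ)·Δλ

Chromatic discriminability between the spark-on and spark-off scenes uses
the receptor-noise-limited (RNL) model in its log form: receptor signals
fᵢ = ln(qᵢ,₁/qᵢ,₂) and channel noise eᵢ = ω·√(η_max/ηᵢ), with the Weber
fraction ω = 0.05 anchored to the most abundant class (the double cones).
The double cones are treated as two independent chromatic channels; their
summed catches form the achromatic channel, compared between scenes with
the Michelson contrast C = (Q₁−Q₂)/(Q₁+Q₂). Detection thresholds: 1.0 JND
(chromatic) and 0.008 (achromatic Michelson).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import Spectrum, SpectrumKind
from .synthetic import DEFAULT_LAMBDA_MAX, make_pigment_sensitivity

__all__ = [
    "VisualSystemParams",
    "QuantumCatches",
    "ContrastResult",
    "quantum_catch",
    "michelson_contrast",
    "rnl_chromatic_contrast",
    "default_visual_system",
]


@dataclass(frozen=True)
class VisualSystemParams:
    sensitivities: tuple[Spectrum, Spectrum, Spectrum]  # (SWS, MWS, LWS)
    ocular_media: Spectrum
    cone_abundance: tuple[float, float, float] = (1.0, 4.0, 4.0)
    weber_fraction: float = 0.05
    chromatic_threshold_jnd: float = 1.0
    achromatic_threshold: float = 0.008

    def __post_init__(self) -> None:
        if len(self.sensitivities) != 3:
            raise ValueError("exactly three sensitivity channels (SWS, MWS, LWS)")
        if any(a <= 0 for a in self.cone_abundance):
            raise ValueError("cone abundances must be positive")
        if self.weber_fraction <= 0:
            raise ValueError("Weber fraction must be positive")
        if self.chromatic_threshold_jnd <= 0 or self.achromatic_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.ocular_media.kind is not SpectrumKind.TRANSMISSION:
            raise ValueError("ocular media must be transmission-tagged")

    @property
    def receptor_noise(self) -> np.ndarray:
        """Per-channel noise eᵢ = ω·√(η_max/ηᵢ), ω on the most abundant class."""
        eta = np.asarray(self.cone_abundance, dtype=float)
        return self.weber_fraction * np.sqrt(eta.max() / eta)


@dataclass(frozen=True)
class QuantumCatches:
    q_sws: float
    q_mws: float
    q_lws: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError("quantum catches must be finite and nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([self.q_sws, self.q_mws, self.q_lws], dtype=float)

    @property
    def double_cone_sum(self) -> float:
        return self.q_mws + self.q_lws


@dataclass(frozen=True)
class ContrastResult:
    chromatic_jnd: float
    achromatic_michelson: float
    distance_mm: float


def default_visual_system(
    lambda_max: dict[str, float] | None = None,
    ocular_media: Spectrum | None = None,
    **overrides,
) -> VisualSystemParams:
    """Template-based sensitivities and a long-pass ocular media default.

    The default ocular media is a smooth long-pass curve with 50%
    transmission at 410 nm, a generic small-fish lens/cornea shape; the
    species' measured curve should replace it where available.
    """
    lm = dict(DEFAULT_LAMBDA_MAX)
    if lambda_max:
        lm.update(lambda_max)
    sens = tuple(make_pigment_sensitivity(lm[k]) for k in ("sws", "mws", "lws"))
    if ocular_media is None:
        from .spectra import default_grid

        grid = default_grid()
        t = 1.0 / (1.0 + np.exp(-(grid - 410.0) / 10.0))
        ocular_media = Spectrum(grid, t, SpectrumKind.TRANSMISSION)
    return VisualSystemParams(sens, ocular_media, **overrides)


def quantum_catch(flux: Spectrum, vsp: VisualSystemParams) -> QuantumCatches:
    """Per-cone catches qᵢ = Σ Φ·T·Sᵢ·Δλ; linear in the flux."""
    t = vsp.ocular_media
    flux._check_grid(t)
    step = flux.step_nm
    qs = []
    for s in vsp.sensitivities:
        flux._check_grid(s)
        qs.append(float(np.sum(flux.values * t.values * s.values) * step))
    return QuantumCatches(*qs)


def michelson_contrast(qc1: QuantumCatches, qc2: QuantumCatches) -> float:
    """C = (Q₁−Q₂)/(Q₁+Q₂) on the summed double-cone (achromatic) channel."""
    q1, q2 = qc1.double_cone_sum, qc2.double_cone_sum
    if q1 + q2 == 0:
        raise ValueError("undefined Michelson contrast: both achromatic catches zero")
    return (q1 - q2) / (q1 + q2)


def rnl_chromatic_contrast(
    qc1: QuantumCatches, qc2: QuantumCatches, vsp: VisualSystemParams
) -> float:
    """Trichromatic RNL distance in JND between two scenes (log signals)."""
    a1, a2 = qc1.as_array(), qc2.as_array()
    if np.any(a1 <= 0) or np.any(a2 <= 0):
        raise ValueError("all quantum catches must be positive for the log RNL model")
    f = np.log(a1 / a2)  # (f_sws, f_mws, f_lws)
    e = vsp.receptor_noise
    num = (
        e[0] ** 2 * (f[1] - f[2]) ** 2
        + e[1] ** 2 * (f[0] - f[2]) ** 2
        + e[2] ** 2 * (f[0] - f[1]) ** 2
    )
    den = (e[0] * e[1]) ** 2 + (e[0] * e[2]) ** 2 + (e[1] * e[2]) ** 2
    return float(np.sqrt(num / den))
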