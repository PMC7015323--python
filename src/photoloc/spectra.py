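"""Spectral data container, resampling, integration and CSV I/O.

Every quantity in the pipeline — radiance, irradiance, reflectance,
transmission, photoreceptor sensitivity, photon flux — is carried as a
:class:`Spectrum`: values on a uniform wavelength grid, by default
400–700 nm at 1 nm (301 samples), the range over which per-cone quantum
catches are computed. All spectral integrals are rectangle sums on that
grid; at 1 nm resolution higher-order quadrature buys nothing.

Units are context-dependent and tracked only through the ``kind`` tag:
radiance in photons s⁻¹ m⁻² sr⁻¹ nm⁻¹, irradiance in photons s⁻¹ m⁻²
nm⁻¹, and reflectance / transmission / sensitivity dimensionless.
Reflectance is expressed as a proportion relative to a diffuse white
standard, so retroreflective surfaces may legitimately exceed 1.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpectrumKind",
    "Spectrum",
    "default_grid",
    "resample",
    "integrate",
    "read_spectrum_csv",
    "write_spectrum_csv",
]

DEFAULT_WL_MIN = 400.0
DEFAULT_WL_MAX = 700.0
DEFAULT_WL_STEP = 1.0


class SpectrumKind(str, enum.Enum):
    RADIANCE = "radiance"
    IRRADIANCE = "irradiance"
    REFLECTANCE = "reflectance"
    TRANSMISSION = "transmission"
    SENSITIVITY = "sensitivity"
    FLUX = "flux"


#: kinds whose values are dimensionless proportions bounded above by 1
_UNIT_BOUNDED = {SpectrumKind.TRANSMISSION, SpectrumKind.SENSITIVITY}


def default_grid() -> np.ndarray:
    """The canonical 400–700 nm, 1-nm wavelength grid (301 samples)."""
    n = int(round((DEFAULT_WL_MAX - DEFAULT_WL_MIN) / DEFAULT_WL_STEP)) + 1
    return DEFAULT_WL_MIN + DEFAULT_WL_STEP * np.arange(n)


@dataclass(frozen=True)
class Spectrum:
    """Nonnegative spectral values on a strictly increasing uniform grid."""

    wavelengths_nm: np.ndarray
    values: np.ndarray
    kind: SpectrumKind = SpectrumKind.REFLECTANCE

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "kind", SpectrumKind(self.kind))
        if wl.ndim != 1 or v.ndim != 1 or wl.size != v.size:
            raise ValueError("wavelengths and values must be 1-D and equal length")
        if wl.size < 2:
            raise ValueError("a Spectrum needs at least two samples")
        steps = np.diff(wl)
        if not np.all(steps > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
            raise ValueError("wavelength grid must be uniform")
        if not np.all(np.isfinite(v)):
            raise ValueError("spectral values must be finite")
        if np.any(v < 0):
            raise ValueError("spectral values must be nonnegative")
        if self.kind in _UNIT_BOUNDED and np.any(v > 1 + 1e-12):
            raise ValueError(f"{self.kind.value} values must lie in [0, 1]")

    @property
    def step_nm(self) -> float:
        return float(self.wavelengths_nm[1] - self.wavelengths_nm[0])

    # -- arithmetic on matching grids -------------------------------------
    def _check_grid(self, other: "Spectrum") -> None:
        if self.wavelengths_nm.shape != other.wavelengths_nm.shape or not np.allclose(
            self.wavelengths_nm, other.wavelengths_nm
        ):
            raise ValueError("spectra are on different wavelength grids")

    def with_values(self, values: np.ndarray, kind: SpectrumKind | None = None) -> "Spectrum":
        return Spectrum(self.wavelengths_nm, values, kind or self.kind)

    def __mul__(self, other):
        if isinstance(other, Spectrum):
            self._check_grid(other)
            return self.with_values(self.values * other.values)
        return self.with_values(self.values * float(other))

    __rmul__ = __mul__

    def __add__(self, other: "Spectrum") -> "Spectrum":
        self._check_grid(other)
        return self.with_values(self.values + other.values)

    @classmethod
    def constant(
        cls,
        value: float,
        kind: SpectrumKind = SpectrumKind.REFLECTANCE,
        grid: np.ndarray | None = None,
    ) -> "Spectrum":
        g = default_grid() if grid is None else np.asarray(grid, dtype=float)
        return cls(g, np.full(g.shape, float(value)), kind)


def resample(s: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linearly interpolate ``s`` onto ``grid``; outside its support → 0.

    Sensitivities and transmissions measured over a narrower range are
    treated as dark beyond it (zero-fill, never constant extrapolation).
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = s.wavelengths_nm[0], s.wavelengths_nm[-1]
    if grid[-1] < lo or grid[0] > hi:
        raise ValueError(
            f"no overlap between spectrum support [{lo:g}, {hi:g}] nm "
            f"and target grid [{grid[0]:g}, {grid[-1]:g}] nm"
        )
    v = np.interp(grid, s.wavelengths_nm, s.values, left=0.0, right=0.0)
    return Spectrum(grid, v, s.kind)


def integrate(s: Spectrum) -> float:
    """Rectangle-rule integral: Σ value(λ)·Δλ over the grid."""
    return float(np.sum(s.values) * s.step_nm)


def read_spectrum_csv(path, kind: SpectrumKind | str) -> Spectrum:
    """Read a two-column ``wavelength_nm,value`` CSV (``#`` comments allowed)."""
    kind = SpectrumKind(kind)
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns wavelength_nm,value")
    wl_raw, val_raw = df.iloc[:, 0], df.iloc[:, 1]
    wl = pd.to_numeric(wl_raw, errors="coerce")
    val = pd.to_numeric(val_raw, errors="coerce")
    for col, name in ((wl, "wavelength"), (val, "value")):
        bad = col.index[col.isna()]
        if len(bad):
            # +2: header row plus 1-based counting
            raise ValueError(f"{path}: non-numeric {name} at row {bad[0] + 2}")
    dup = wl.duplicated()
    if dup.any():
        row = dup.idxmax()
        raise ValueError(
            f"{path}: duplicate wavelength {wl.iloc[row]:g} nm at row {row + 2}"
        )
    order = np.argsort(wl.to_numpy())
    try:
        return Spectrum(wl.to_numpy()[order], val.to_numpy()[order], kind)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_spectrum_csv(s: Spectrum, path) -> None:
    pd.DataFrame({"wavelength_nm": s.wavelengths_nm, "value": s.values}).to_csv(
        path, index=False
    )
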