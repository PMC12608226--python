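"""Core domain containers shared across the pipeline.

The pipeline operates on leaf reflectance spectra sampled on a uniform
wavelength grid (nominally 450-950 nm, 1 nm step), per-sample pigment
ground truth (total chlorophyll and total carotenoid concentration of the
leaf extract, mg/L), and Gaussian spectral channels parameterized by a
central wavelength and a full-width-at-half-maximum bandwidth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PigmentProfile",
    "ExtractODs",
    "ChannelSpec",
    "Spectrum",
    "SampleSet",
    "default_grid",
]

#: nominal wavelength range of the instrument (nm)
WAVELENGTH_MIN = 450.0
WAVELENGTH_MAX = 950.0


def default_grid(start: float = WAVELENGTH_MIN, stop: float = WAVELENGTH_MAX,
                 step: float = 1.0) -> np.ndarray:
    """Uniform wavelength grid in nm, inclusive of both endpoints."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


@dataclass(frozen=True)
class PigmentProfile:
    """Ground-truth pigment content of one leaf sample.

    Attributes
    ----------
    chl : float
        Total chlorophyll concentration of the extract, mg/L.
    car : float
        Total carotenoid concentration of the extract, mg/L.
    """

    chl: float
    car: float

    def __post_init__(self) -> None:
        if self.chl < 0 or self.car < 0:
            raise ValueError(
                f"pigment concentrations must be non-negative, "
                f"got chl={self.chl}, car={self.car}"
            )


@dataclass(frozen=True)
class ExtractODs:
    """Optical densities of an ethanol pigment extract.

    ``d440_5``, ``d649`` and ``d665`` are the absorbances at 440.5 nm,
    649 nm and 665 nm used by the spectrophotometric reference equations.
    """

    d440_5: float
    d649: float
    d665: float

    def __post_init__(self) -> None:
        if min(self.d440_5, self.d649, self.d665) < 0:
            raise ValueError("optical densities must be non-negative")


@dataclass(frozen=True)
class ChannelSpec:
    """One spectral channel: Gaussian transmission with given center/FWHM.

    ``center`` is the central wavelength (nm) and ``fwhm`` the full width
    at half maximum (nm) of the transmission function.  Centers slightly
    outside the sampled grid are allowed (auxiliary index bands sit at
    445 nm); overlap with the grid is validated when weights are built.
    """

    center: float
    fwhm: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.center) or not (300.0 <= self.center <= 1100.0):
            raise ValueError(f"channel center {self.center} nm outside physical range")
        if not np.isfinite(self.fwhm) or self.fwhm <= 0:
            raise ValueError(f"channel fwhm must be positive, got {self.fwhm}")

    @property
    def sigma(self) -> float:
        """Gaussian standard deviation (nm) for this FWHM."""
        return self.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class Spectrum:
    """A single spectrum on a strictly increasing wavelength grid.

    ``values`` are dimensionless reflectances for processed spectra, or
    radiance counts for raw object/reference-panel recordings.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.ndim != 1 or self.values.ndim != 1:
            raise ValueError("wavelengths and values must be 1-D")
        if self.wavelengths.shape != self.values.shape:
            raise ValueError("wavelengths and values must have equal length")
        if self.wavelengths.size < 2:
            raise ValueError("a spectrum needs at least two grid points")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum values must be finite")

    @property
    def step(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])

    def copy_with(self, values: np.ndarray, sample_id: str | None = None) -> "Spectrum":
        return Spectrum(self.wavelengths.copy(), np.asarray(values, dtype=float),
                        self.sample_id if sample_id is None else sample_id)


@dataclass
class SampleSet:
    """A calibration set: spectra on a shared grid plus pigment ground truth.

    Attributes
    ----------
    wavelengths : (m,) array
        Shared wavelength grid, nm.
    reflectance : (n, m) array
        One row per sample.
    pigments : DataFrame
        Columns ``sample_id``, ``chl_mg_per_l``, ``car_mg_per_l``; row
        order matches ``reflectance``.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    pigments: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.reflectance.ndim != 2:
            raise ValueError("reflectance must be 2-D (samples x wavelengths)")
        if self.reflectance.shape[1] != self.wavelengths.size:
            raise ValueError("reflectance width must match the wavelength grid")
        if len(self.pigments) != self.reflectance.shape[0]:
            raise ValueError("pigment table length must match the sample count")
        required = {"sample_id", "chl_mg_per_l", "car_mg_per_l"}
        missing = required - set(self.pigments.columns)
        if missing:
            raise ValueError(f"pigment table missing columns: {sorted(missing)}")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    def pigment_values(self, pigment: str) -> np.ndarray:
        """Ground-truth vector for ``pigment`` in {'chl', 'car'} (mg/L)."""
        col = {"chl": "chl_mg_per_l", "car": "car_mg_per_l"}.get(pigment)
        if col is None:
            raise ValueError(f"pigment must be 'chl' or 'car', got {pigment!r}")
        return self.pigments[col].to_numpy(dtype=float)

    def spectra(self) -> list[Spectrum]:
        ids = self.pigments["sample_id"].astype(str).tolist()
        return [Spectrum(self.wavelengths, row, sid)
                for sid, row in zip(ids, self.reflectance)]

    @classmethod
    def from_spectra(cls, spectra: list[Spectrum], pigments: pd.DataFrame) -> "SampleSet":
        if not spectra:
            raise ValueError("need at least one spectrum")
        grid = spectra[0].wavelengths
        for s in spectra[1:]:
            if not np.array_equal(s.wavelengths, grid):
                raise ValueError("all spectra must share one wavelength grid")
        refl = np.vstack([s.values for s in spectra])
        return cls(grid, refl, pigments.reset_index(drop=True))
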