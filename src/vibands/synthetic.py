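"""Synthetic leaf samples: pigments, reflectance spectra, extract ODs.

No raw spectra accompany the study this package models, so every
downstream stage is exercised on generated data with the same
statistical structure: two crop presets (cucumber-like, lettuce-like)
with published pigment means/SDs, strongly correlated chlorophyll and
carotenoid content, pigment-dependent absorption in the 450-740 nm
visible region, a stable NIR plateau, and a red edge that shifts to
longer wavelengths with chlorophyll.

The spectral model is a Beer-Lambert-style attenuation of a smooth
baseline:

    R(lambda) = clip( B(lambda) * exp(-[chl*A_chl + car*A_car])
                      * (1 + eps_mult) + eps_add, 0, 1 )

where A_chl and A_car are sums of Gaussian absorption components
(1/(mg/L) at their peaks) and B(lambda) is a NIR plateau with a mild
green bump.  This is an invented stand-in for measured leaf optics: it
reproduces the qualitative features the band search exploits (550 nm
peak, deep red absorption, red edge, flat NIR) but not radiative
transfer in a real mesophyll.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import ExtractODs, PigmentProfile, SampleSet, Spectrum, default_grid
from .reference import DEFAULT_COEFFICIENTS, ReferenceCoefficients

__all__ = [
    "CropPreset", "PRESETS", "AbsorptionComponent", "LeafSpectrumModel",
    "default_leaf_model", "NOISE_LEVELS",
    "sample_pigments", "generate_reflectance", "ods_from_pigments",
    "generate_sample_set", "ods_table",
]


@dataclass(frozen=True)
class CropPreset:
    """Pigment statistics of one crop/stage group (mg/L)."""

    name: str
    chl_mean: float
    chl_sd: float
    car_mean: float
    car_sd: float
    pigment_correlation: float = 0.8

    def __post_init__(self) -> None:
        if self.chl_mean <= 0 or self.car_mean <= 0:
            raise ValueError("pigment means must be positive")
        if self.chl_sd < 0 or self.car_sd < 0:
            raise ValueError("pigment SDs must be non-negative")
        if not 0.0 <= self.pigment_correlation <= 1.0:
            raise ValueError("pigment correlation must lie in [0, 1]")


#: Published group statistics (mean +/- SD, mg/L) for the four crop/stage
#: groups, plus two convenience aliases used throughout the examples.
PRESETS: dict[str, CropPreset] = {
    "lettuce-credo": CropPreset("lettuce-credo", 3.94, 0.83, 1.13, 0.17),
    "lettuce-moskovskiy": CropPreset("lettuce-moskovskiy", 8.24, 0.85, 1.92, 0.18),
    "cucumber-bbch10-19": CropPreset("cucumber-bbch10-19", 7.88, 2.77, 1.86, 0.31),
    "cucumber-bbch50-59": CropPreset("cucumber-bbch50-59", 7.53, 3.14, 1.70, 0.46),
}
PRESETS["cucumber-like"] = replace(PRESETS["cucumber-bbch10-19"], name="cucumber-like")
PRESETS["lettuce-like"] = replace(PRESETS["lettuce-credo"], name="lettuce-like")


@dataclass(frozen=True)
class AbsorptionComponent:
    """One Gaussian absorption feature of a pigment.

    ``strength`` is the peak specific absorption, 1/(mg/L); the feature
    contributes strength * exp(-(lambda-center)^2 / (2 width^2)) per
    mg/L of its pigment to the attenuation exponent.
    """

    pigment: str  # "chl" or "car"
    center: float  # nm
    width: float  # nm (Gaussian SD)
    strength: float  # per mg/L

    def __post_init__(self) -> None:
        if self.pigment not in ("chl", "car"):
            raise ValueError("pigment must be 'chl' or 'car'")
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.strength < 0:
            raise ValueError("strength must be non-negative")


@dataclass(frozen=True)
class LeafSpectrumModel:
    """Parameters of the synthetic reflectance model."""

    nir_plateau: float = 0.50
    green_bump_amplitude: float = 0.08  # relative bump on the baseline
    green_bump_center: float = 550.0
    green_bump_width: float = 50.0
    components: tuple[AbsorptionComponent, ...] = ()
    mult_noise_sd: float = 0.0
    add_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.nir_plateau < 1.0:
            raise ValueError("NIR plateau must lie in (0, 1)")
        if self.mult_noise_sd < 0 or self.add_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")

    def baseline(self, grid: np.ndarray) -> np.ndarray:
        """Pigment-free reflectance envelope on ``grid``."""
        grid = np.asarray(grid, dtype=float)
        bump = self.green_bump_amplitude * np.exp(
            -0.5 * ((grid - self.green_bump_center) / self.green_bump_width) ** 2)
        base = self.nir_plateau * (1.0 + bump)
        if np.any(base <= 0) or np.any(base >= 1):
            raise ValueError("baseline must stay inside (0, 1) on the grid")
        return base

    def absorption(self, grid: np.ndarray, pigment: str) -> np.ndarray:
        """Specific absorption A_pigment(lambda), 1/(mg/L)."""
        grid = np.asarray(grid, dtype=float)
        total = np.zeros_like(grid)
        for comp in self.components:
            if comp.pigment == pigment:
                total += comp.strength * np.exp(
                    -0.5 * ((grid - comp.center) / comp.width) ** 2)
        return total


#: Default absorption features: chlorophyll Soret band (430 nm), the red
#: Chl a/b pair (662/649 nm) and a red-edge shoulder (700 nm); carotenoid
#: blue bands (450/478 nm).  Strengths give a leaf at the cucumber-like
#: mean (~7.9 mg/L Chl) a red-minimum reflectance near 0.03 and lettuce
#: (~3.9 mg/L) near 0.11, matching the qualitative species contrast.
DEFAULT_COMPONENTS: tuple[AbsorptionComponent, ...] = (
    AbsorptionComponent("chl", 430.0, 25.0, 0.060),
    AbsorptionComponent("chl", 662.0, 28.0, 0.250),
    AbsorptionComponent("chl", 649.0, 25.0, 0.180),
    AbsorptionComponent("chl", 700.0, 14.0, 0.100),
    AbsorptionComponent("car", 450.0, 22.0, 0.300),
    AbsorptionComponent("car", 478.0, 20.0, 0.350),
)

#: named noise levels: (multiplicative SD, additive SD)
NOISE_LEVELS: dict[str, tuple[float, float]] = {
    "none": (0.0, 0.0),
    "low": (0.01, 0.002),
    "medium": (0.03, 0.005),
    "high": (0.08, 0.010),
}


def default_leaf_model(noise: str | tuple[float, float] = "none") -> LeafSpectrumModel:
    """The shipped spectral model with a named or explicit noise level."""
    if isinstance(noise, str):
        try:
            mult, add = NOISE_LEVELS[noise]
        except KeyError:
            raise ValueError(f"unknown noise level {noise!r}; "
                             f"known: {sorted(NOISE_LEVELS)}") from None
    else:
        mult, add = noise
    return LeafSpectrumModel(components=DEFAULT_COMPONENTS,
                             mult_noise_sd=mult, add_noise_sd=add)


def sample_pigments(n: int, preset: CropPreset, seed: int) -> list[PigmentProfile]:
    """Draw pigment profiles from a truncated bivariate normal.

    Chlorophyll and carotenoid content are jointly normal with the
    preset's means/SDs and correlation; draws with any negative
    coordinate are rejected and redrawn, so moments are approximate
    near zero.  Reproducible under a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    mean = np.array([preset.chl_mean, preset.car_mean])
    if preset.chl_sd == 0 and preset.car_sd == 0:
        return [PigmentProfile(*mean)] * n
    rho = preset.pigment_correlation
    cov = np.array([
        [preset.chl_sd ** 2, rho * preset.chl_sd * preset.car_sd],
        [rho * preset.chl_sd * preset.car_sd, preset.car_sd ** 2],
    ])
    out: list[PigmentProfile] = []
    while len(out) < n:
        draws = rng.multivariate_normal(mean, cov, size=max(n - len(out), 16),
                                        method="cholesky")
        for chl, car in draws:
            if chl >= 0 and car >= 0:
                out.append(PigmentProfile(float(chl), float(car)))
                if len(out) == n:
                    break
    return out


def generate_reflectance(profile: PigmentProfile, model: LeafSpectrumModel,
                         grid: np.ndarray | None = None,
                         seed: int | None = None) -> Spectrum:
    """One synthetic reflectance spectrum for ``profile`` on ``grid``."""
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if grid[0] < 450.0 - 1e-9 or grid[-1] > 950.0 + 1e-9:
        raise ValueError("grid must lie within the 450-950 nm model support")
    attenuation = (profile.chl * model.absorption(grid, "chl")
                   + profile.car * model.absorption(grid, "car"))
    clean = model.baseline(grid) * np.exp(-attenuation)
    if model.mult_noise_sd > 0 or model.add_noise_sd > 0:
        rng = np.random.default_rng(seed)
        clean = (clean * (1.0 + rng.normal(0.0, model.mult_noise_sd, grid.size))
                 + rng.normal(0.0, model.add_noise_sd, grid.size))
    return Spectrum(grid, np.clip(clean, 0.0, 1.0))


def ods_from_pigments(profile: PigmentProfile, a_b_split: float = 0.7,
                      coefficients: ReferenceCoefficients = DEFAULT_COEFFICIENTS,
                      ) -> ExtractODs:
    """Extract optical densities consistent with the reference equations.

    ``a_b_split`` (phi) partitions the chlorophyll signal between the
    665 nm and 649 nm densities; it only splits D665/D649 and cancels in
    the round trip.  Passing the result through the reference equations
    reproduces the profile exactly.
    """
    if not 0.0 < a_b_split < 1.0:
        raise ValueError("a_b_split must lie strictly inside (0, 1)")
    phi = a_b_split
    c = coefficients
    scale = profile.chl / (c.chl_d665_coef * phi + c.chl_d649_coef * (1.0 - phi))
    d665 = phi * scale
    d649 = (1.0 - phi) * scale
    d440_5 = (profile.car + c.car_chl_coef * profile.chl) / c.car_d440_coef
    return ExtractODs(d440_5=d440_5, d649=d649, d665=d665)


def ods_table(profiles: list[PigmentProfile], a_b_split: float = 0.7) -> pd.DataFrame:
    rows = []
    for i, p in enumerate(profiles):
        od = ods_from_pigments(p, a_b_split)
        rows.append({"sample_id": f"s{i:03d}", "d440_5": od.d440_5,
                     "d649": od.d649, "d665": od.d665})
    return pd.DataFrame(rows)


def generate_sample_set(
    n: int = 50,
    preset: CropPreset | str = "cucumber-like",
    model: LeafSpectrumModel | None = None,
    grid: np.ndarray | None = None,
    seed: int = 0,
    noise: str | tuple[float, float] = "low",
) -> SampleSet:
    """Generate a full calibration set (spectra + pigment ground truth).

    ``n`` defaults to 50 — the per-group sample count of the study this
    generator emulates.  ``model`` overrides ``noise`` when given.
    """
    if isinstance(preset, str):
        try:
            preset = PRESETS[preset]
        except KeyError:
            raise ValueError(f"unknown preset {preset!r}; known: "
                             f"{sorted(PRESETS)}") from None
    if model is None:
        model = default_leaf_model(noise)
    if grid is None:
        grid = default_grid()
    profiles = sample_pigments(n, preset, seed)
    rng = np.random.default_rng((seed, 1))
    spectra = []
    for i, p in enumerate(profiles):
        s = generate_reflectance(p, model, grid,
                                 seed=int(rng.integers(2 ** 31)))
        s.sample_id = f"s{i:03d}"
        spectra.append(s)
    pigments = pd.DataFrame({
        "sample_id": [s.sample_id for s in spectra],
        "chl_mg_per_l": [p.chl for p in profiles],
        "car_mg_per_l": [p.car for p in profiles],
    })
    return SampleSet.from_spectra(spectra, pigments)
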