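"""Raw-spectrum preprocessing: reflectance ratio, denoising, resampling.

The leaf reflectance spectrum R(lambda) is the ratio of the leaf
radiance to that of a uniformly reflecting reference panel, followed by
Gaussian smoothing (sigma = 20 nm by default) to remove high-frequency
noise, and linear resampling onto the uniform 450-950 nm / 1 nm
analysis grid.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import Spectrum

__all__ = ["compute_reflectance", "gaussian_smooth", "resample_to_grid",
           "DEFAULT_SMOOTH_SIGMA_NM"]

DEFAULT_SMOOTH_SIGMA_NM = 20.0


def compute_reflectance(i_obj: Spectrum, i_ref: Spectrum) -> Spectrum:
    """Elementwise ratio of leaf radiance to reference-panel radiance.

    Both spectra must share the same wavelength grid, and the reference
    radiance must be strictly positive everywhere.
    """
    if not np.array_equal(i_obj.wavelengths, i_ref.wavelengths):
        raise ValueError("object and reference spectra must share one grid")
    if np.any(i_ref.values <= 0):
        raise ValueError("reference radiance must be strictly positive")
    return i_obj.copy_with(i_obj.values / i_ref.values)


def gaussian_smooth(spectrum: Spectrum,
                    sigma: float = DEFAULT_SMOOTH_SIGMA_NM) -> Spectrum:
    """Convolve with a normalized Gaussian kernel of SD ``sigma`` (nm).

    The sigma is converted to grid samples; the kernel is truncated at
    +/-4 sigma and the boundary is handled by reflection, which avoids
    attenuating the 450/950 nm ends where the optimizer may place
    channels.  ``sigma=0`` is the identity.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return spectrum.copy_with(spectrum.values.copy())
    sigma_samples = sigma / spectrum.step
    smoothed = gaussian_filter1d(spectrum.values, sigma_samples,
                                 mode="reflect", truncate=4.0)
    return spectrum.copy_with(smoothed)


def resample_to_grid(spectrum: Spectrum, start: float = 450.0,
                     stop: float = 950.0, step: float = 1.0) -> Spectrum:
    """Linear interpolation onto a uniform [start, stop] grid (501 points
    for the defaults).  The input grid must span the requested range."""
    wl = spectrum.wavelengths
    if wl[0] > start or wl[-1] < stop:
        raise ValueError(
            f"requested range [{start}, {stop}] nm outside input support "
            f"[{wl[0]}, {wl[-1]}] nm"
        )
    n = int(round((stop - start) / step)) + 1
    target = start + step * np.arange(n)
    values = np.interp(target, wl, spectrum.values)
    return Spectrum(target, values, spectrum.sample_id)
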