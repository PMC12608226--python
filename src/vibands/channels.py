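"""Gaussian spectral-channel model and band-integrated reflectance.

A sensor channel is modeled as a Gaussian transmission function with
central wavelength ``center`` and bandwidth ``fwhm`` (full width at half
maximum).  Band reflectance is the transmission-weighted mean of the
spectrum over the channel support, computed by discrete summation on the
sampling grid.  Channels clipped by the 450/950 nm grid boundary are
renormalized over the visible part rather than rejected — optimal
configurations do occur right at the grid edge.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .core import ChannelSpec, Spectrum

__all__ = [
    "gaussian_weights",
    "band_reflectance",
    "band_reflectance_matrix",
    "INSTRUMENT_PRESETS",
    "load_instrument_presets",
    "save_instrument_presets",
]

#: half-width of the truncation window in units of sigma
TRUNCATE_SIGMA = 4.0


def gaussian_weights(channel: ChannelSpec, grid: np.ndarray) -> np.ndarray:
    """Normalized transmission weights of ``channel`` on ``grid``.

    Weights are proportional to exp(-(lambda - center)^2 / (2 sigma^2))
    with sigma = fwhm / (2 sqrt(2 ln 2)), truncated at +/-4 sigma (clipped
    to the grid) and normalized to sum to one.  A channel whose truncation
    window falls entirely off the grid degrades gracefully to the
    renormalized Gaussian tail (dominated by the nearest grid edge); a
    channel with no numerical overlap at all raises ``ValueError``.
    """
    grid = np.asarray(grid, dtype=float)
    sigma = channel.sigma
    z = (grid - channel.center) / sigma
    with np.errstate(under="ignore"):
        w = np.exp(-0.5 * z * z)
    inside = np.abs(z) <= TRUNCATE_SIGMA
    if inside.any():
        w = np.where(inside, w, 0.0)
    total = w.sum()
    if total <= 0.0:
        raise ValueError(
            f"channel (center={channel.center} nm, fwhm={channel.fwhm} nm) "
            f"has no support on the grid [{grid[0]}, {grid[-1]}] nm"
        )
    return w / total


def band_reflectance(spectrum: Spectrum, channel: ChannelSpec) -> float:
    """Band-integrated reflectance: weighted mean of R(lambda) under the channel."""
    w = gaussian_weights(channel, spectrum.wavelengths)
    return float(np.dot(w, spectrum.values))


def band_reflectance_matrix(
    reflectance: np.ndarray,
    grid: np.ndarray,
    centers: np.ndarray,
    fwhm: float,
) -> np.ndarray:
    """Band reflectance of every sample at every channel center.

    Parameters
    ----------
    reflectance : (n_samples, m) array
        Spectra on ``grid``.
    centers : (k,) array
        Channel central wavelengths, nm; all share ``fwhm``.

    Returns
    -------
    (k, n_samples) array of band reflectances.
    """
    grid = np.asarray(grid, dtype=float)
    centers = np.asarray(centers, dtype=float)
    reflectance = np.asarray(reflectance, dtype=float)
    W = np.empty((centers.size, grid.size))
    for i, c in enumerate(centers):
        W[i] = gaussian_weights(ChannelSpec(float(c), fwhm), grid)
    return W @ reflectance.T


#: Channel layouts of commercial pigment-estimation instruments
#: (center nm / FWHM nm per channel; bandwidth None where unpublished).
INSTRUMENT_PRESETS: dict[str, dict] = {
    "SPAD-502Plus": {"vi": "DI", "channels": [(650, 30), (940, 10)]},
    "Dualex-4": {"vi": "SR", "channels": [(710, None), (850, None)]},
    "PSR-1100F": {"vi": "NDVI", "channels": [(531, 3), (570, 3)]},
    "FieldSpec-3": {"vi": "NDVI", "channels": [(705, 3), (750, 3)]},
    "Parrot-Sequoia": {"vi": "NDVI", "channels": [(660, 40), (790, 40)]},
    "Micasense-Altum": {"vi": "NDVI", "channels": [(668, 14), (717, 12)]},
    "Micro-HyperspecVNIR": {"vi": "SR", "channels": [(515, 6.4), (550, 6.4)]},
    "Senop-HSC-2": {"vi": "NDVI", "channels": [(531, 6), (570, 6)]},
}


def load_instrument_presets(path: str | Path) -> dict[str, dict]:
    """Read a named channel-set file (YAML or JSON)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    out = {}
    for name, entry in data.items():
        out[name] = {
            "vi": entry.get("vi"),
            "channels": [tuple(ch) for ch in entry["channels"]],
        }
    return out


def save_instrument_presets(presets: dict[str, dict], path: str | Path) -> None:
    path = Path(path)
    data = {
        name: {"vi": p.get("vi"), "channels": [list(ch) for ch in p["channels"]]}
        for name, p in presets.items()
    }
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
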