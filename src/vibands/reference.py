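"""Spectrophotometric reference equations for extract pigment content.

Total chlorophyll and carotenoid concentrations (mg/L) of an ethanol
leaf extract from its optical densities at 665, 649 and 440.5 nm:

    Chl = 6.1 * D665 + 20.04 * D649
    Car = 4.695 * D440.5 - 0.268 * Chl

The carotenoid equation can return a negative value for inconsistent
inputs; it is returned as-is with a warning (clipping would bias
round-trip checks against the synthetic OD generator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceCoefficients",
    "DEFAULT_COEFFICIENTS",
    "NonPhysicalCarotenoidWarning",
    "chl_from_od",
    "car_from_od",
    "pigments_from_od_table",
    "convert_od_csv",
]


class NonPhysicalCarotenoidWarning(UserWarning):
    """The carotenoid equation produced a negative concentration."""


@dataclass(frozen=True)
class ReferenceCoefficients:
    """Multipliers of the extract equations (ethanol solvent)."""

    chl_d665_coef: float = 6.1
    chl_d649_coef: float = 20.04
    car_d440_coef: float = 4.695
    car_chl_coef: float = 0.268


DEFAULT_COEFFICIENTS = ReferenceCoefficients()


def _check_nonneg(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative")
    return arr


def chl_from_od(d665, d649, coefficients: ReferenceCoefficients = DEFAULT_COEFFICIENTS):
    """Total chlorophyll (mg/L) from extract optical densities at 665/649 nm."""
    d665 = _check_nonneg("d665", d665)
    d649 = _check_nonneg("d649", d649)
    out = coefficients.chl_d665_coef * d665 + coefficients.chl_d649_coef * d649
    return float(out) if out.ndim == 0 else out


def car_from_od(d440_5, chl, coefficients: ReferenceCoefficients = DEFAULT_COEFFICIENTS):
    """Total carotenoids (mg/L) from the 440.5 nm density and chlorophyll.

    May return a negative value for inconsistent inputs; a
    ``NonPhysicalCarotenoidWarning`` is issued in that case.
    """
    d440_5 = _check_nonneg("d440_5", d440_5)
    chl = _check_nonneg("chl", chl)
    out = coefficients.car_d440_coef * d440_5 - coefficients.car_chl_coef * chl
    if np.any(np.asarray(out) < 0):
        warnings.warn("carotenoid equation returned a negative concentration",
                      NonPhysicalCarotenoidWarning, stacklevel=2)
    return float(out) if out.ndim == 0 else out


def pigments_from_od_table(ods: pd.DataFrame,
                           coefficients: ReferenceCoefficients = DEFAULT_COEFFICIENTS,
                           ) -> pd.DataFrame:
    """Apply the reference equations to a table of extract optical densities.

    Expects columns ``sample_id``, ``d440_5``, ``d649``, ``d665``;
    returns ``sample_id``, ``chl_mg_per_l``, ``car_mg_per_l``.
    """
    required = {"sample_id", "d440_5", "d649", "d665"}
    missing = required - set(ods.columns)
    if missing:
        raise ValueError(f"OD table missing columns: {sorted(missing)}")
    chl = chl_from_od(ods["d665"].to_numpy(), ods["d649"].to_numpy(), coefficients)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NonPhysicalCarotenoidWarning)
        car = car_from_od(ods["d440_5"].to_numpy(), chl, coefficients)
    return pd.DataFrame({"sample_id": ods["sample_id"],
                         "chl_mg_per_l": chl, "car_mg_per_l": car})


def convert_od_csv(in_path: str | Path, out_path: str | Path,
                   coefficients: ReferenceCoefficients = DEFAULT_COEFFICIENTS) -> pd.DataFrame:
    """CSV-to-CSV wrapper around :func:`pigments_from_od_table`."""
    result = pigments_from_od_table(pd.read_csv(in_path), coefficients)
    result.to_csv(out_path, index=False)
    return result
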