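"""The seven two-band vegetation-index formulas.

All indices combine the band reflectances of two searched channels
``rho1`` and ``rho2``; mSR, mNDI and TVI additionally use a fixed
auxiliary band (blue at 445 nm for mSR/mNDI, green at 550 nm for TVI)
that is not part of the wavelength search.  Denominators smaller in
magnitude than ``DIV_GUARD`` yield NaN so that map cells can be masked
instead of propagating infinities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "FORMULA_NAMES",
    "AUX_CENTERS",
    "SAVI_L",
    "TVI_COEFFS",
    "DIV_GUARD",
    "compute_vi",
    "needs_aux",
    "formula_registry",
]

FORMULA_NAMES: tuple[str, ...] = ("SR", "DI", "mSR", "mNDI", "TVI", "SAVI", "NDVI")

#: fixed auxiliary-band centers (nm) per formula
AUX_CENTERS: dict[str, float] = {"mSR": 445.0, "mNDI": 445.0, "TVI": 550.0}

SAVI_L: float = 0.5
TVI_COEFFS: tuple[float, float, float] = (120.0, 200.0, 0.5)
DIV_GUARD: float = 1e-9


def needs_aux(formula: str) -> bool:
    """True if ``formula`` requires the fixed auxiliary band."""
    _check_name(formula)
    return formula in AUX_CENTERS


def _check_name(formula: str) -> None:
    if formula not in FORMULA_NAMES:
        raise ValueError(f"unknown VI formula {formula!r}; known: {FORMULA_NAMES}")


def _guarded_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    bad = np.abs(den) < DIV_GUARD
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / np.where(bad, 1.0, den)
    return np.where(bad, np.nan, out)


def compute_vi(formula, rho1, rho2, rho_aux=None, *, savi_l: float = SAVI_L):
    """Evaluate one index formula on band reflectances.

    Accepts scalars or broadcastable arrays.  Returns NaN (the invalid
    marker) wherever a denominator magnitude falls below ``DIV_GUARD``.
    ``rho_aux`` is the auxiliary band reflectance, required for mSR,
    mNDI and TVI.
    """
    _check_name(formula)
    rho1 = np.asarray(rho1, dtype=float)
    rho2 = np.asarray(rho2, dtype=float)
    if formula in AUX_CENTERS:
        if rho_aux is None:
            raise ValueError(f"{formula} requires the auxiliary band reflectance")
        rho_aux = np.asarray(rho_aux, dtype=float)

    if formula == "SR":
        out = _guarded_div(rho1, rho2)
    elif formula == "DI":
        out = rho1 - rho2
    elif formula == "NDVI":
        out = _guarded_div(rho1 - rho2, rho1 + rho2)
    elif formula == "mSR":
        out = _guarded_div(rho1 - rho_aux, rho2 - rho_aux)
    elif formula == "mNDI":
        out = _guarded_div(rho1 - rho2, rho1 + rho2 - 2.0 * rho_aux)
    elif formula == "TVI":
        c1, c2, half = TVI_COEFFS
        out = half * (c1 * (rho2 - rho_aux) - c2 * (rho1 - rho_aux))
    else:  # SAVI
        out = (1.0 + savi_l) * _guarded_div(rho1 - rho2, rho1 + rho2 + savi_l)

    if out.ndim == 0:
        return float(out)
    return out


def formula_registry() -> pd.DataFrame:
    """Machine-readable formula table (name, expression, constants, aux band)."""
    rows = [
        ("SR", "rho1 / rho2", "", np.nan),
        ("DI", "rho1 - rho2", "", np.nan),
        ("mSR", "(rho1 - rhoA) / (rho2 - rhoA)", "", 445.0),
        ("mNDI", "(rho1 - rho2) / (rho1 + rho2 - 2*rhoA)", "", 445.0),
        ("TVI", "0.5 * (120*(rho2 - rhoG) - 200*(rho1 - rhoG))",
         "coeffs=120,200,0.5", 550.0),
        ("SAVI", "(1 + L) * (rho1 - rho2) / (rho1 + rho2 + L)", "L=0.5", np.nan),
        ("NDVI", "(rho1 - rho2) / (rho1 + rho2)", "", np.nan),
    ]
    return pd.DataFrame(rows, columns=["name", "expression", "constants",
                                       "aux_center_nm"])
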