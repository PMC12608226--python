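"""Exhaustive two-band search over wavelengths, bandwidths and formulas.

For each vegetation-index formula and bandwidth pair (dl1, dl2), every
ordered pair of distinct central wavelengths (lambda1, lambda2) on the
search grid is evaluated: band reflectances -> VI per sample ->
exponential calibration fit -> R^2 / RMSE / RE.  The result is one
metric map per (formula, dl1, dl2) setting; optimal configurations are
the unmasked cells maximizing R^2 (ties broken by minimal RMSE, then
lexicographically by wavelengths), with a minimal-RMSE criterion
available for the robustness cross-check.

The map computation is vectorized over all wavelength pairs; a scalar
per-cell path built from the single-channel / single-fit primitives is
provided for verification and for recomputing selected optima exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .channels import band_reflectance, band_reflectance_matrix
from .core import ChannelSpec, SampleSet
from .indices import AUX_CENTERS, FORMULA_NAMES, compute_vi, needs_aux
from .regression import (MIN_VALID_PAIRS, ExpModel, FitMetrics, evaluate_metrics,
                         fit_exponential)

__all__ = [
    "GridConfig", "MetricMap", "CalibrationResult",
    "enumerate_configs", "count_configs",
    "config_vi_values", "evaluate_config",
    "evaluate_map", "evaluate_map_scalar",
    "select_optimal", "compare_criteria",
]

_VAR_EPS = 1e-30
# cap on the (rows x k x n) work-array size of one vectorized block
_BLOCK_ELEMENTS = 4_000_000


@dataclass(frozen=True)
class GridConfig:
    """Search space: wavelength grid, bandwidth set, formula set."""

    start: float = 450.0
    stop: float = 950.0
    step: float = 1.0
    bandwidths: tuple[float, ...] = (1.0, 5.0, 10.0, 30.0, 50.0)
    formulas: tuple[str, ...] = FORMULA_NAMES
    pair_bandwidths: str = "product"  # or "equal"

    def __post_init__(self) -> None:
        if self.start >= self.stop:
            raise ValueError("start must be below stop")
        if self.step <= 0:
            raise ValueError("step must be positive")
        if any(b <= 0 for b in self.bandwidths):
            raise ValueError("bandwidths must be positive")
        unknown = set(self.formulas) - set(FORMULA_NAMES)
        if unknown:
            raise ValueError(f"unknown formulas: {sorted(unknown)}")
        if self.pair_bandwidths not in ("product", "equal"):
            raise ValueError("pair_bandwidths must be 'product' or 'equal'")

    def centers(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        return self.start + self.step * np.arange(n)

    def bandwidth_pairs(self) -> list[tuple[float, float]]:
        if self.pair_bandwidths == "equal":
            return [(b, b) for b in self.bandwidths]
        return [(b1, b2) for b1 in self.bandwidths for b2 in self.bandwidths]


def enumerate_configs(grid: GridConfig, dl1: float, dl2: float,
                      ) -> Iterator[tuple[float, float, float, float]]:
    """All ordered distinct wavelength pairs, row-major, as
    (lambda1, dl1, lambda2, dl2)."""
    centers = grid.centers()
    if centers.size == 0:
        raise ValueError("empty wavelength grid")
    for l1 in centers:
        for l2 in centers:
            if l1 != l2:
                yield (float(l1), dl1, float(l2), dl2)


def count_configs(grid: GridConfig) -> dict:
    """Configuration counts: per bandwidth pair and total."""
    m = grid.centers().size
    per_pair = m * (m - 1)
    pairs = grid.bandwidth_pairs()
    return {
        "wavelengths": m,
        "per_bandwidth_pair": per_pair,
        "bandwidth_pairs": len(pairs),
        "per_formula": per_pair * len(pairs),
        "total": per_pair * len(pairs) * len(grid.formulas),
    }


@dataclass
class MetricMap:
    """Metric grids over all ordered (lambda1, lambda2) pairs.

    Masked cells (``valid`` False) hold NaN metrics: the diagonal, cells
    with fewer than three valid samples, and zero-variance VI cells.
    """

    lambda1: np.ndarray  # (k,) axis, nm
    lambda2: np.ndarray  # (k,) axis, nm
    r2: np.ndarray  # (k, k)
    rmse: np.ndarray  # (k, k)
    re_percent: np.ndarray  # (k, k)
    n_valid: np.ndarray  # (k, k) int
    valid: np.ndarray  # (k, k) bool
    formula: str
    dl1: float
    dl2: float
    pigment: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table (lambda1_nm, lambda2_nm, r2, rmse, ...)."""
        l1, l2 = np.meshgrid(self.lambda1, self.lambda2, indexing="ij")
        return pd.DataFrame({
            "lambda1_nm": l1.ravel(), "lambda2_nm": l2.ravel(),
            "r2": self.r2.ravel(), "rmse": self.rmse.ravel(),
            "re_percent": self.re_percent.ravel(),
            "n_valid": self.n_valid.ravel(), "valid": self.valid.ravel(),
        })

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class CalibrationResult:
    """One calibrated configuration — a row of the optimal-model tables."""

    formula: str
    lambda1: float
    dl1: float
    lambda2: float
    dl2: float
    model: ExpModel
    metrics: FitMetrics
    pigment: str = ""
    aux_fwhm: float | None = None

    def to_dict(self) -> dict:
        return {
            "formula": self.formula, "pigment": self.pigment,
            "lambda1_nm": self.lambda1, "dl1_nm": self.dl1,
            "lambda2_nm": self.lambda2, "dl2_nm": self.dl2,
            "aux_fwhm_nm": self.aux_fwhm,
            "a": self.model.a, "b": self.model.b,
            "r2": self.metrics.r2, "rmse": self.metrics.rmse,
            "re_percent": self.metrics.re_percent, "n_valid": self.metrics.n,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationResult":
        return cls(formula=d["formula"], lambda1=d["lambda1_nm"], dl1=d["dl1_nm"],
                   lambda2=d["lambda2_nm"], dl2=d["dl2_nm"],
                   model=ExpModel(d["a"], d["b"]),
                   metrics=FitMetrics(d["r2"], d["rmse"], d["re_percent"],
                                      int(d["n_valid"])),
                   pigment=d.get("pigment", ""), aux_fwhm=d.get("aux_fwhm_nm"))

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def read_json(cls, path: str | Path) -> "CalibrationResult":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _aux_reflectance(samples: SampleSet, formula: str, aux_fwhm: float) -> np.ndarray:
    center = AUX_CENTERS[formula]
    return band_reflectance_matrix(samples.reflectance, samples.wavelengths,
                                   np.array([center]), aux_fwhm)[0]


def config_vi_values(samples: SampleSet, formula: str, lambda1: float, dl1: float,
                     lambda2: float, dl2: float,
                     aux_fwhm: float | None = None) -> np.ndarray:
    """Per-sample VI values at one channel configuration (scalar path).

    The auxiliary band (mSR/mNDI/TVI) inherits ``dl1`` unless
    ``aux_fwhm`` overrides it.
    """
    rho_aux = None
    if needs_aux(formula):
        aux = ChannelSpec(AUX_CENTERS[formula], aux_fwhm if aux_fwhm else dl1)
        rho_aux = np.empty(samples.n_samples)
    ch1 = ChannelSpec(lambda1, dl1)
    ch2 = ChannelSpec(lambda2, dl2)
    x = np.empty(samples.n_samples)
    for i, spec in enumerate(samples.spectra()):
        r1 = band_reflectance(spec, ch1)
        r2 = band_reflectance(spec, ch2)
        if rho_aux is not None:
            rho_aux[i] = band_reflectance(spec, aux)
            x[i] = compute_vi(formula, r1, r2, rho_aux[i])
        else:
            x[i] = compute_vi(formula, r1, r2)
    return x


def evaluate_config(samples: SampleSet, pigment: str, formula: str,
                    lambda1: float, dl1: float, lambda2: float, dl2: float,
                    aux_fwhm: float | None = None) -> CalibrationResult:
    """Fit and score one configuration through the scalar path."""
    x = config_vi_values(samples, formula, lambda1, dl1, lambda2, dl2, aux_fwhm)
    y = samples.pigment_values(pigment)
    model = fit_exponential(x, y)
    metrics = evaluate_metrics(model, x, y)
    return CalibrationResult(formula, lambda1, dl1, lambda2, dl2, model,
                             metrics, pigment, aux_fwhm)


def _fit_block(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, ...]:
    """Closed-form log-linear fit + metrics for a block of map cells.

    ``X``: (r, k, n) VI values (NaN = invalid); ``y``: (n,) pigments.
    Returns r2, rmse, re, n_valid, valid arrays of shape (r, k).
    """
    valid_y = np.isfinite(y) & (y > 0)
    V = np.isfinite(X) & valid_y  # (r, k, n)
    nv = V.sum(axis=-1)
    enough = nv >= MIN_VALID_PAIRS
    nv_safe = np.where(enough, nv, MIN_VALID_PAIRS).astype(float)

    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        z = np.where(valid_y, np.log(np.where(valid_y, y, 1.0)), 0.0)
        Xv = np.where(V, X, 0.0)
        xbar = Xv.sum(axis=-1) / nv_safe
        zbar = (V * z).sum(axis=-1) / nv_safe
        ybar = (V * y).sum(axis=-1) / nv_safe

        # centered sums, matching the scalar fit's formulas term by term
        xc = np.where(V, X - xbar[..., None], 0.0)
        zc = np.where(V, z - zbar[..., None], 0.0)
        var_x = (xc * xc).sum(axis=-1)
        cov_xz = (xc * zc).sum(axis=-1)
        has_var = var_x > _VAR_EPS
        b = np.where(has_var, cov_xz / np.where(has_var, var_x, 1.0), 0.0)
        a = np.exp(zbar - b * xbar)

        Yhat = a[..., None] * np.exp(b[..., None] * Xv)
        resid2 = (V * (Yhat - y) ** 2).sum(axis=-1)
        absresid = (V * np.abs(Yhat - y)).sum(axis=-1)
        ss_tot = (V * (y - ybar[..., None]) ** 2).sum(axis=-1)
        has_ss = ss_tot > _VAR_EPS

        ok = enough & has_var & has_ss
        r2 = 1.0 - resid2 / np.where(has_ss, ss_tot, 1.0)
        rmse = np.sqrt(resid2 / nv_safe)
        re = absresid / nv_safe * 100.0 / np.where(ok, ybar, 1.0)
        # extreme rate estimates can overflow the exponential; such
        # cells carry no usable calibration and are masked
        ok &= np.isfinite(r2) & np.isfinite(rmse) & np.isfinite(re)
        r2 = np.where(ok, r2, np.nan)
        rmse = np.where(ok, rmse, np.nan)
        re = np.where(ok, re, np.nan)
    return r2, rmse, re, nv, ok


def evaluate_map(samples: SampleSet, pigment: str, formula: str,
                 dl1: float, dl2: float, grid: GridConfig | None = None,
                 aux_fwhm: float | None = None) -> MetricMap:
    """Vectorized metric map over all ordered (lambda1, lambda2) pairs."""
    if grid is None:
        grid = GridConfig()
    if samples.n_samples < MIN_VALID_PAIRS:
        raise ValueError(f"need at least {MIN_VALID_PAIRS} samples")
    centers = grid.centers()
    k = centers.size
    n = samples.n_samples
    y = samples.pigment_values(pigment)

    B1 = band_reflectance_matrix(samples.reflectance, samples.wavelengths,
                                 centers, dl1)  # (k, n)
    B2 = (B1 if dl2 == dl1 else
          band_reflectance_matrix(samples.reflectance, samples.wavelengths,
                                  centers, dl2))
    rho_aux = (_aux_reflectance(samples, formula, aux_fwhm if aux_fwhm else dl1)
               if needs_aux(formula) else None)

    r2 = np.full((k, k), np.nan)
    rmse = np.full((k, k), np.nan)
    re = np.full((k, k), np.nan)
    n_valid = np.zeros((k, k), dtype=int)
    valid = np.zeros((k, k), dtype=bool)

    block = max(1, _BLOCK_ELEMENTS // (k * n))
    for i0 in range(0, k, block):
        i1 = min(i0 + block, k)
        X = compute_vi(formula, B1[i0:i1, None, :], B2[None, :, :], rho_aux)
        br2, brmse, bre, bnv, bok = _fit_block(X, y)
        r2[i0:i1], rmse[i0:i1], re[i0:i1] = br2, brmse, bre
        n_valid[i0:i1], valid[i0:i1] = bnv, bok

    diag = np.arange(k)
    valid[diag, diag] = False
    for arr in (r2, rmse, re):
        arr[diag, diag] = np.nan
    n_valid[diag, diag] = 0
    r2[~valid] = np.nan
    rmse[~valid] = np.nan
    re[~valid] = np.nan
    return MetricMap(centers.copy(), centers.copy(), r2, rmse, re,
                     n_valid, valid, formula, dl1, dl2, pigment)


def evaluate_map_scalar(samples: SampleSet, pigment: str, formula: str,
                        dl1: float, dl2: float, grid: GridConfig | None = None,
                        aux_fwhm: float | None = None) -> MetricMap:
    """Per-cell loop through the scalar primitives; reference path for
    verifying the vectorized map on small grids."""
    if grid is None:
        grid = GridConfig()
    centers = grid.centers()
    k = centers.size
    y = samples.pigment_values(pigment)
    r2 = np.full((k, k), np.nan)
    rmse = np.full((k, k), np.nan)
    re = np.full((k, k), np.nan)
    n_valid = np.zeros((k, k), dtype=int)
    valid = np.zeros((k, k), dtype=bool)
    for i, l1 in enumerate(centers):
        for j, l2 in enumerate(centers):
            if i == j:
                continue
            x = config_vi_values(samples, formula, float(l1), dl1,
                                 float(l2), dl2, aux_fwhm)
            n_valid[i, j] = int(np.sum(np.isfinite(x) & (y > 0)))
            try:
                model = fit_exponential(x, y)
                m = evaluate_metrics(model, x, y)
            except ValueError:
                continue
            if not (np.isfinite(m.r2) and np.isfinite(m.rmse)
                    and np.isfinite(m.re_percent)):
                continue  # overflowed calibration, masked like the fast path
            r2[i, j], rmse[i, j], re[i, j] = m.r2, m.rmse, m.re_percent
            valid[i, j] = True
    return MetricMap(centers.copy(), centers.copy(), r2, rmse, re,
                     n_valid, valid, formula, dl1, dl2, pigment)


def _best_cell(m: MetricMap, criterion: str) -> tuple[float, float, float, float] | None:
    """Winning (r2, rmse, lambda1, lambda2) of one map, or None if all masked."""
    if not m.valid.any():
        return None
    if criterion == "r2":
        keys = np.where(m.valid, m.r2, -np.inf)
        best = keys.max()
        cand = m.valid & (keys == best)
    elif criterion == "rmse":
        keys = np.where(m.valid, m.rmse, np.inf)
        best = keys.min()
        cand = m.valid & (keys == best)
    else:
        raise ValueError("criterion must be 'r2' or 'rmse'")
    ii, jj = np.nonzero(cand)
    # tie-breaks: secondary metric, then lexicographic (lambda1, lambda2)
    secondary = m.rmse[ii, jj] if criterion == "r2" else -m.r2[ii, jj]
    order = np.lexsort((m.lambda2[jj], m.lambda1[ii], secondary))
    i, j = ii[order[0]], jj[order[0]]
    return (float(m.r2[i, j]), float(m.rmse[i, j]),
            float(m.lambda1[i]), float(m.lambda2[j]))


def select_optimal(maps: Sequence[MetricMap], samples: SampleSet, pigment: str,
                   criterion: str = "r2", aux_fwhm: float | None = None,
                   ) -> tuple[dict[str, CalibrationResult], CalibrationResult]:
    """Optimal configuration per formula and overall across ``maps``.

    Primary criterion: maximal R^2; ties broken by minimal RMSE, then by
    the lexicographically smallest (lambda1, lambda2, dl1, dl2).  The
    winning cell of each formula is re-fitted through the scalar path so
    downstream sensitivity profiles embed it exactly.
    """
    if not maps:
        raise ValueError("no maps given")
    per_formula_best: dict[str, tuple] = {}
    for m in maps:
        cell = _best_cell(m, criterion)
        if cell is None:
            continue
        r2v, rmsev, l1, l2 = cell
        key = ((-r2v, rmsev) if criterion == "r2" else (rmsev, -r2v))
        key = key + (l1, l2, m.dl1, m.dl2)
        prev = per_formula_best.get(m.formula)
        if prev is None or key < prev[0]:
            per_formula_best[m.formula] = (key, m, l1, l2)
    if not per_formula_best:
        raise ValueError("all cells masked in every map")
    results: dict[str, CalibrationResult] = {}
    for formula, (_, m, l1, l2) in per_formula_best.items():
        results[formula] = evaluate_config(samples, pigment, formula,
                                           l1, m.dl1, l2, m.dl2, aux_fwhm)
    overall = min(
        results.values(),
        key=lambda r: ((-r.metrics.r2, r.metrics.rmse) if criterion == "r2"
                       else (r.metrics.rmse, -r.metrics.r2))
        + (r.lambda1, r.lambda2, r.dl1, r.dl2),
    )
    return results, overall


def compare_criteria(maps: Sequence[MetricMap], samples: SampleSet, pigment: str,
                     aux_fwhm: float | None = None) -> pd.DataFrame:
    """Wavelength displacement between the max-R^2 and min-RMSE optima.

    Mirrors the robustness check that switching selection criteria moves
    the best wavelengths only marginally when the R^2 surface is peaked.
    """
    by_r2, _ = select_optimal(maps, samples, pigment, "r2", aux_fwhm)
    by_rmse, _ = select_optimal(maps, samples, pigment, "rmse", aux_fwhm)
    rows = []
    for formula in sorted(by_r2):
        a, b = by_r2[formula], by_rmse[formula]
        rows.append({
            "formula": formula,
            "r2_opt_lambda1": a.lambda1, "r2_opt_lambda2": a.lambda2,
            "rmse_opt_lambda1": b.lambda1, "rmse_opt_lambda2": b.lambda2,
            "max_lambda_shift_nm": max(abs(a.lambda1 - b.lambda1),
                                       abs(a.lambda2 - b.lambda2)),
            "bandwidths_changed": (a.dl1, a.dl2) != (b.dl1, b.dl2),
            "delta_r2": a.metrics.r2 - b.metrics.r2,
            "delta_rmse": a.metrics.rmse - b.metrics.rmse,
        })
    return pd.DataFrame(rows)
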