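"""Sensitivity of a calibrated configuration to channel and formula changes.

Three perturbation studies around a reference calibration:

* wavelength shift — displace the central wavelengths (jointly, or each
  channel independently on a 2-D offset grid), re-fit, and track
  R^2 / RMSE plus the prediction deviation from ground truth;
* bandwidth sweep — re-fit at alternative FWHM values at fixed centers,
  with a stability score (the worst R^2 change under a +/-5 nm joint
  center shift) quantifying the smoothing/stability trade-off of wide
  channels;
* formula substitution — evaluate all seven index formulas on the very
  same band reflectances, each with its own exponential calibration.

The regression is re-fitted at every perturbed configuration by default
(comparing calibrated models, not a frozen model fed shifted bands); a
frozen-model mode simulates device drift against a fixed calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import SampleSet
from .indices import FORMULA_NAMES
from .optimizer import CalibrationResult, config_vi_values, evaluate_config
from .regression import evaluate_metrics, fit_exponential

__all__ = ["ShiftProfile", "BandwidthProfile", "FormulaComparison",
           "shift_profile", "bandwidth_profile", "formula_comparison"]


def _grid_bounds(samples: SampleSet) -> tuple[float, float]:
    return float(samples.wavelengths[0]), float(samples.wavelengths[-1])


def _deviation_stats(yhat: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(max, mean) per-sample deviation as % of the mean concentration."""
    dev = np.abs(yhat - y) * 100.0 / y.mean()
    return float(dev.max()), float(dev.mean())


@dataclass
class ShiftProfile:
    """Metrics under central-wavelength displacement of the reference."""

    offsets: np.ndarray  # probed offsets, nm (joint mode) or per-channel axes
    r2: np.ndarray
    rmse: np.ndarray
    max_deviation_percent: np.ndarray
    mean_deviation_percent: np.ndarray
    dropped_offsets: list = field(default_factory=list)
    reference: CalibrationResult | None = None
    mode: str = "joint"

    def to_dataframe(self) -> pd.DataFrame:
        if self.mode == "joint":
            return pd.DataFrame({
                "offset_nm": self.offsets, "r2": self.r2, "rmse": self.rmse,
                "max_deviation_percent": self.max_deviation_percent,
                "mean_deviation_percent": self.mean_deviation_percent,
            })
        d1, d2 = np.meshgrid(self.offsets, self.offsets, indexing="ij")
        return pd.DataFrame({
            "offset1_nm": d1.ravel(), "offset2_nm": d2.ravel(),
            "r2": self.r2.ravel(), "rmse": self.rmse.ravel(),
            "max_deviation_percent": self.max_deviation_percent.ravel(),
            "mean_deviation_percent": self.mean_deviation_percent.ravel(),
        })


def _shift_point(samples: SampleSet, ref: CalibrationResult, pigment: str,
                 off1: float, off2: float, refit: bool,
                 ) -> tuple[float, float, float, float]:
    x = config_vi_values(samples, ref.formula, ref.lambda1 + off1, ref.dl1,
                         ref.lambda2 + off2, ref.dl2, ref.aux_fwhm)
    y = samples.pigment_values(pigment)
    model = fit_exponential(x, y) if refit else ref.model
    m = evaluate_metrics(model, x, y)
    ok = np.isfinite(x) & (y > 0)
    mx, mn = _deviation_stats(model.predict(x[ok]), y[ok])
    return m.r2, m.rmse, mx, mn


def shift_profile(samples: SampleSet, pigment: str, reference: CalibrationResult,
                  max_shift: float = 20.0, step: float = 1.0,
                  mode: str = "joint", refit: bool = True) -> ShiftProfile:
    """Re-fit the reference formula at displaced central wavelengths.

    ``mode='joint'`` shifts both channels by the same offset in
    [-max_shift, +max_shift]; ``mode='per-channel'`` probes the full 2-D
    offset grid.  Offsets pushing either channel center outside the
    sampled wavelength range are dropped and recorded.
    """
    if reference is None:
        raise ValueError("reference calibration is required")
    if mode not in ("joint", "per-channel"):
        raise ValueError("mode must be 'joint' or 'per-channel'")
    lo, hi = _grid_bounds(samples)
    n = int(round(max_shift / step))
    offsets = step * np.arange(-n, n + 1)

    def in_range(o1: float, o2: float) -> bool:
        return (lo <= reference.lambda1 + o1 <= hi
                and lo <= reference.lambda2 + o2 <= hi)

    if mode == "joint":
        kept = np.array([d for d in offsets if in_range(d, d)])
        dropped = [float(d) for d in offsets if not in_range(d, d)]
        out = np.array([_shift_point(samples, reference, pigment, d, d, refit)
                        for d in kept])
        return ShiftProfile(kept, out[:, 0], out[:, 1], out[:, 2], out[:, 3],
                            dropped, reference, mode)

    k = offsets.size
    r2 = np.full((k, k), np.nan)
    rmse = np.full((k, k), np.nan)
    mxdev = np.full((k, k), np.nan)
    mndev = np.full((k, k), np.nan)
    dropped = []
    for i, d1 in enumerate(offsets):
        for j, d2 in enumerate(offsets):
            if not in_range(d1, d2):
                dropped.append((float(d1), float(d2)))
                continue
            if reference.lambda1 + d1 == reference.lambda2 + d2:
                continue  # degenerate coincident channels
            r2[i, j], rmse[i, j], mxdev[i, j], mndev[i, j] = _shift_point(
                samples, reference, pigment, float(d1), float(d2), refit)
    return ShiftProfile(offsets, r2, rmse, mxdev, mndev, dropped,
                        reference, mode)


@dataclass
class BandwidthProfile:
    """Metrics and center-shift stability across bandwidth settings."""

    bandwidth_pairs: list  # evaluated (dl1, dl2) settings
    r2: np.ndarray
    rmse: np.ndarray
    stability: np.ndarray  # max |R^2(center+/-5) - R^2(center)| per setting
    reference: CalibrationResult | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "dl1_nm": [p[0] for p in self.bandwidth_pairs],
            "dl2_nm": [p[1] for p in self.bandwidth_pairs],
            "r2": self.r2, "rmse": self.rmse,
            "stability_max_dr2": self.stability,
        })


def bandwidth_profile(samples: SampleSet, pigment: str,
                      reference: CalibrationResult,
                      bandwidths=(1.0, 5.0, 10.0, 30.0, 50.0),
                      mode: str = "joint",
                      stability_shift: float = 5.0) -> BandwidthProfile:
    """Re-fit at alternative bandwidths with the reference centers fixed.

    ``mode='joint'`` applies each bandwidth to both channels; the exact
    reference (dl1, dl2) pair is always appended when the joint sweep
    does not already contain it, so the profile embeds its reference.
    ``mode='per-channel'`` sweeps the full bandwidth product.  The
    stability score of each setting is the largest |delta R^2| produced
    by a joint center shift of +/-``stability_shift`` nm.
    """
    if mode == "joint":
        pairs = [(b, b) for b in bandwidths]
    elif mode == "per-channel":
        pairs = [(b1, b2) for b1 in bandwidths for b2 in bandwidths]
    else:
        raise ValueError("mode must be 'joint' or 'per-channel'")
    ref_pair = (reference.dl1, reference.dl2)
    if ref_pair not in pairs:
        pairs = pairs + [ref_pair]

    lo, hi = _grid_bounds(samples)
    y = samples.pigment_values(pigment)
    r2 = np.empty(len(pairs))
    rmse = np.empty(len(pairs))
    stability = np.empty(len(pairs))
    for idx, (b1, b2) in enumerate(pairs):
        res = evaluate_config(samples, pigment, reference.formula,
                              reference.lambda1, b1, reference.lambda2, b2,
                              reference.aux_fwhm)
        r2[idx], rmse[idx] = res.metrics.r2, res.metrics.rmse
        worst = 0.0
        for d in (-stability_shift, stability_shift):
            if not (lo <= reference.lambda1 + d <= hi
                    and lo <= reference.lambda2 + d <= hi):
                continue
            x = config_vi_values(samples, reference.formula,
                                 reference.lambda1 + d, b1,
                                 reference.lambda2 + d, b2, reference.aux_fwhm)
            m = evaluate_metrics(fit_exponential(x, y), x, y)
            worst = max(worst, abs(m.r2 - r2[idx]))
        stability[idx] = worst
    return BandwidthProfile(pairs, r2, rmse, stability, reference)


@dataclass
class FormulaComparison:
    """All formulas evaluated on identical band reflectances."""

    summary: pd.DataFrame  # formula, a, b, r2, rmse, re_percent, rank
    per_sample_errors: pd.DataFrame  # sample_id x formula, % of mean truth
    lambda1: float
    dl1: float
    lambda2: float
    dl2: float
    pigment: str


def formula_comparison(samples: SampleSet, pigment: str,
                       lambda1: float, dl1: float, lambda2: float, dl2: float,
                       formulas=FORMULA_NAMES,
                       aux_fwhm: float | None = None) -> FormulaComparison:
    """Swap the index formula at one fixed channel configuration.

    Every formula sees the same two band reflectances (plus its own
    fixed auxiliary band where required) and gets its own exponential
    calibration; per-sample relative errors are reported as a percentage
    of the mean measured concentration.
    """
    y = samples.pigment_values(pigment)
    ids = samples.pigments["sample_id"].tolist()
    rows = []
    errors = {"sample_id": ids}
    for formula in formulas:
        res = evaluate_config(samples, pigment, formula, lambda1, dl1,
                              lambda2, dl2, aux_fwhm)
        x = config_vi_values(samples, formula, lambda1, dl1, lambda2, dl2,
                             aux_fwhm)
        yhat = res.model.predict(x)
        errors[formula] = np.abs(yhat - y) * 100.0 / y.mean()
        rows.append({"formula": formula, **res.model.to_dict(),
                     **res.metrics.to_dict()})
    summary = pd.DataFrame(rows)
    summary["rank"] = summary["r2"].rank(ascending=False, method="min").astype(int)
    return FormulaComparison(summary, pd.DataFrame(errors),
                             lambda1, dl1, lambda2, dl2, pigment)
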