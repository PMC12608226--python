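"""Quick-look figures for metric maps and sensitivity profiles."""

from __future__ import annotations

import numpy as np

from .optimizer import MetricMap
from .sensitivity import BandwidthProfile, ShiftProfile

__all__ = ["plot_metric_map", "plot_shift_profile", "plot_bandwidth_profile"]


def _get_axes(ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    return ax


def plot_metric_map(metric_map: MetricMap, metric: str = "r2", ax=None,
                    **imshow_kwargs):
    """Heat map of one metric grid (lambda2 on x, lambda1 on y)."""
    ax = _get_axes(ax)
    data = getattr(metric_map, metric)
    extent = (metric_map.lambda2[0], metric_map.lambda2[-1],
              metric_map.lambda1[0], metric_map.lambda1[-1])
    im = ax.imshow(np.ma.masked_invalid(data), origin="lower", extent=extent,
                   aspect="auto", **imshow_kwargs)
    ax.figure.colorbar(im, ax=ax, label=metric)
    ax.set_xlabel("$\\lambda_2$ (nm)")
    ax.set_ylabel("$\\lambda_1$ (nm)")
    ax.set_title(f"{metric_map.formula} {metric} "
                 f"($\\Delta\\lambda$ = {metric_map.dl1}/{metric_map.dl2} nm)")
    return ax


def plot_shift_profile(profile: ShiftProfile, ax=None):
    """R^2 (left axis) and max prediction deviation (right) vs offset."""
    if profile.mode != "joint":
        raise ValueError("plotting supports joint-shift profiles")
    ax = _get_axes(ax)
    ax.plot(profile.offsets, profile.r2, "o-", label="$R^2$")
    ax.set_xlabel("center-wavelength offset (nm)")
    ax.set_ylabel("$R^2$")
    twin = ax.twinx()
    twin.plot(profile.offsets, profile.max_deviation_percent, "s--",
              color="tab:red", label="max deviation")
    twin.set_ylabel("max prediction deviation (%)")
    return ax


def plot_bandwidth_profile(profile: BandwidthProfile, ax=None):
    """R^2 and stability score vs bandwidth (joint sweeps)."""
    ax = _get_axes(ax)
    widths = [p[0] for p in profile.bandwidth_pairs]
    ax.plot(widths, profile.r2, "o-", label="$R^2$")
    ax.plot(widths, profile.stability, "s--", label="stability (max $|\\Delta R^2|$)")
    ax.set_xlabel("bandwidth $\\Delta\\lambda$ (nm)")
    ax.legend()
    return ax
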