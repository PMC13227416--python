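"""Exponential closure kinetics of the heart lumen.

The luminal area after the registration origin decays as

    a(t) = A * exp(-k * t)

with A the maximum luminal area (μm²) and k the closure rate constant
(hr⁻¹).  The fit is damped nonlinear least squares initialised from the
log-linear regression of ln(a) on t, with k constrained non-negative.
Only frames with registered time t >= 0 enter the fit — pre-origin frames
are plateau, not decay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .datatypes import LumenSeries, RunConfig
from .errors import InsufficientDataError, ValidationError
from .lumen import compute_lumen_metrics

log = logging.getLogger("cardiodyn")


@dataclass
class ClosureFit:
    """Result of the decaying-exponential fit to a luminal-area series."""

    A: float  # μm², amplitude (maximum luminal area)
    k: float  # hr⁻¹, closure rate constant
    rmse: float  # μm², root-mean-square residual
    n_frames_fit: int
    converged: bool


def fit_closure(t, a, time_unit: str = "min") -> ClosureFit:
    """Fit a(t) = A·exp(−k·t) and report k in hr⁻¹.

    Parameters
    ----------
    t : array-like
        Registered times, all >= 0, in ``time_unit`` ("min" or "hr").
    a : array-like
        Luminal areas in μm², all > 0.
    """
    t = np.asarray(t, dtype=float)
    a = np.asarray(a, dtype=float)
    if t.shape != a.shape or t.ndim != 1:
        raise ValidationError("t and a must be 1-D arrays of equal length")
    if len(t) < 3:
        raise InsufficientDataError(f"need >= 3 points to fit, got {len(t)}")
    if np.any(a <= 0):
        raise ValidationError("areas must be positive")
    if time_unit == "min":
        t_hr = t / 60.0
    elif time_unit == "hr":
        t_hr = t
    else:
        raise ValidationError(f"unknown time_unit {time_unit!r}")

    # log-linear initialisation: ln a = ln A - k t
    slope, intercept = np.polyfit(t_hr, np.log(a), 1)
    k0 = max(0.0, -slope)
    A0 = float(np.exp(intercept))

    def resid(params):
        A, k = params
        return A * np.exp(-k * t_hr) - a

    res = least_squares(
        resid,
        x0=[A0, k0],
        bounds=([1e-12, 0.0], [np.inf, np.inf]),
        method="trf",
        xtol=1e-13,
        ftol=1e-13,
        gtol=1e-13,
    )
    A_hat, k_hat = res.x
    if not res.success:
        log.warning("closure fit did not converge (status %d)", res.status)
    return ClosureFit(
        A=float(A_hat),
        k=float(k_hat),
        rmse=float(np.sqrt(np.mean(res.fun**2))),
        n_frames_fit=len(t),
        converged=bool(res.success),
    )


def closure_rate_pipeline(series: LumenSeries, config: RunConfig | None = None) -> ClosureFit:
    """Register a lumen series, compute metrics, and fit the closure model.

    Composition of :func:`register_lumen_time` (via
    :func:`compute_lumen_metrics`) and :func:`fit_closure` restricted to
    frames with registered t >= 0.
    """
    config = config or RunConfig()
    metrics = compute_lumen_metrics(series, config)
    post = metrics[metrics["t_min"] >= 0]
    return fit_closure(post["t_min"].to_numpy(), post["area_um2"].to_numpy(), time_unit="min")
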