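"""Classical model-fitting baseline: per-curve nonlinear least squares.

For a fixed fluidity gamma the model force is linear in E0, so E0 has a
closed-form least-squares solution and the two-parameter fit reduces to a
bounded one-dimensional search over gamma. That removes the initialization
sensitivity that makes naive two-parameter fitting of indentation curves
error prone.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .contact import (
    GAMMA_MAX,
    ForceCurve,
    ProbeCellGeometry,
    dimensionless_force,
)
from .profiles import IndentationProfile


@dataclass
class FitResult:
    """Outcome of one per-curve least-squares inversion."""

    E0_hat: float
    gamma_hat: float
    f_bar_hat: float
    residual_norm: float
    iterations: int
    converged: bool
    wall_time_s: float


def _unit_model(
    profile: IndentationProfile,
    gamma: float,
    geometry: ProbeCellGeometry,
    t_data: np.ndarray,
    t0: float,
    n_points: int,
) -> tuple[np.ndarray, float]:
    """Model force for E0 = 1 Pa on the data time grid, and its f_bar."""
    df = dimensionless_force(profile, gamma, geometry, n_points)
    scale = (
        math.tan(geometry.theta)
        * profile.I_max**2
        * (profile.t_tot / t0) ** (-gamma)
        * df.w
    )
    g = np.interp(t_data / profile.t_tot, df.s, df.f) * scale
    return g, df.f_bar


def fit_curve(
    curve: ForceCurve,
    profile: IndentationProfile,
    geometry: ProbeCellGeometry,
    init: float | None = None,
    bounds: tuple[float, float] = (0.0, GAMMA_MAX),
    t0: float = 1.0,
    xatol: float = 1e-6,
    n_points: int | None = None,
) -> FitResult:
    """Least-squares fit of (E0, gamma) to one force curve.

    Minimizes sum (F_model - F_data)^2 with E0 solved in closed form per
    candidate gamma (profile likelihood), then a bounded scalar search over
    gamma. `init`, when given, only seeds an extra candidate; the bounded
    search itself is initialization free. Never raises for clean data that
    merely fits poorly: non-convergence is reported on the result.
    """
    t_start = time.time()
    F_data = np.asarray(curve.F, dtype=float)
    if np.max(np.abs(F_data)) == 0.0:
        raise ValueError("cannot fit an all-zero force curve")
    n_points = n_points or len(curve.t)
    n_eval = 0

    def sse(gamma: float) -> float:
        nonlocal n_eval
        n_eval += 1
        g, _ = _unit_model(profile, gamma, geometry, curve.t, t0, n_points)
        denom = float(g @ g)
        if denom <= 0:
            return float(F_data @ F_data)
        E0 = max(float(g @ F_data) / denom, 0.0)
        r = E0 * g - F_data
        return float(r @ r)

    res = minimize_scalar(
        sse, bounds=bounds, method="bounded", options={"xatol": xatol}
    )
    gamma_hat = float(res.x)
    if init is not None and bounds[0] <= init <= bounds[1]:
        if sse(float(init)) < res.fun:
            gamma_hat = float(init)

    g, f_bar = _unit_model(profile, gamma_hat, geometry, curve.t, t0, n_points)
    E0_hat = max(float(g @ F_data) / float(g @ g), 0.0)
    residual = float(np.linalg.norm(E0_hat * g - F_data))
    return FitResult(
        E0_hat=E0_hat,
        gamma_hat=gamma_hat,
        f_bar_hat=f_bar,
        residual_norm=residual,
        iterations=n_eval,
        converged=bool(res.success),
        wall_time_s=time.time() - t_start,
    )
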