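"""Indentation histories for AFM nanoindentation.

A profile is the dimensionless indentation i(s) on s in [0, 1] (s = t/t_tot,
i = I/I_max): it starts and ends near zero, rises monotonically to a single
interior maximum i(p) = 1, and decreases monotonically afterwards. Those are
exactly the conditions met by the triangular, capped-sinusoidal, and
random-spline drive signals used in force-spectroscopy experiments.

Analytic profile kinds (triangle, capped sinusoid) are evaluated exactly
when simulating; the B-spline expansion is their representation for the
functional regressor, where a kink-free coefficient vector is all that is
needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .basis import BSplineBasis, fit_bspline

#: default boundary tolerance for eps, eps' ("numbers close to 0")
EPS_TOL = 0.02
#: default range for the dimensionless peak time p
P_RANGE = (0.3, 0.7)

_DENSE_N = 2001


class ProfileGenerationError(RuntimeError):
    """Random profile construction failed to satisfy the constraints."""


@dataclass
class IndentationProfile:
    """Spline-represented indentation history with dimensional scales.

    coeffs are the expansion of the dimensionless i(s) on `basis`; p is the
    dimensionless peak time; I_max (m) and t_tot (s) restore dimensions.
    For analytic kinds `exact_i`/`exact_di` evaluate the underlying function
    without spline projection error.
    """

    basis: BSplineBasis
    coeffs: np.ndarray
    p: float
    I_max: float
    t_tot: float
    eps_start: float = 0.0
    eps_end: float = 0.0
    kind: str = "bspline"
    exact_i: Callable[[np.ndarray], np.ndarray] | None = field(
        default=None, repr=False
    )
    exact_di: Callable[[np.ndarray], np.ndarray] | None = field(
        default=None, repr=False
    )

    def __post_init__(self) -> None:
        if not (0.0 < self.p < 1.0):
            raise ValueError("peak time p must lie in (0, 1)")
        if self.I_max <= 0 or self.t_tot <= 0:
            raise ValueError("I_max and t_tot must be positive")
        self.coeffs = np.asarray(self.coeffs, dtype=float)

    # -- dimensionless evaluation ------------------------------------
    def i(self, s: np.ndarray) -> np.ndarray:
        """Dimensionless indentation i(s)."""
        s = np.asarray(s, dtype=float)
        if self.exact_i is not None:
            return self.exact_i(s)
        out = self.basis.spline(self.coeffs)(np.clip(s, 0.0, 1.0))
        return np.asarray(out, dtype=float)

    def di(self, s: np.ndarray) -> np.ndarray:
        """Dimensionless velocity di/ds."""
        s = np.asarray(s, dtype=float)
        if self.exact_di is not None:
            return self.exact_di(s)
        out = self.basis.spline(self.coeffs).derivative()(np.clip(s, 0.0, 1.0))
        return np.asarray(out, dtype=float)

    @property
    def t_max(self) -> float:
        """Dimensional time of peak indentation (s)."""
        return self.p * self.t_tot

    def grid(self, n: int) -> np.ndarray:
        """Peak-split s-grid of ~n points: uniform within each branch and
        containing s = p exactly (required for kink-exact triangles)."""
        n_app = max(2, int(round(n * self.p)))
        n_ret = max(2, n - n_app + 1)
        return np.concatenate(
            [
                np.linspace(0.0, self.p, n_app),
                np.linspace(self.p, 1.0, n_ret)[1:],
            ]
        )


@dataclass
class ProfileReport:
    """Per-condition constraint report from validate_profile."""

    starts_near_zero: bool
    ends_near_zero: bool
    interior_peak: bool
    unit_maximum: bool
    monotone_approach: bool
    monotone_retract: bool
    non_negative: bool
    messages: list[str]

    @property
    def ok(self) -> bool:
        return (
            self.starts_near_zero
            and self.ends_near_zero
            and self.interior_peak
            and self.unit_maximum
            and self.monotone_approach
            and self.monotone_retract
            and self.non_negative
        )


def validate_profile(
    profile: IndentationProfile,
    n_grid: int = _DENSE_N,
    eps_tol: float = EPS_TOL,
    peak_exclusion: float = 0.01,
) -> ProfileReport:
    """Check the admissibility conditions on a dense grid.

    Monotonicity is checked by finite differences outside a small window
    around the peak (the derivative crosses zero there by construction; for
    triangles it jumps).
    """
    s = np.linspace(0.0, 1.0, n_grid)
    y = profile.i(s)
    msgs: list[str] = []

    starts = abs(y[0]) <= eps_tol
    if not starts:
        msgs.append(f"i(0) = {y[0]:.4g} exceeds eps tolerance {eps_tol}")
    ends = abs(y[-1]) <= eps_tol
    if not ends:
        msgs.append(f"i(1) = {y[-1]:.4g} exceeds eps tolerance {eps_tol}")

    k_max = int(np.argmax(y))
    interior = 0 < k_max < n_grid - 1
    if not interior:
        msgs.append(f"maximum at boundary s = {s[k_max]:.4g}")
    unit_max = abs(y[k_max] - 1.0) <= 1e-3
    if not unit_max:
        msgs.append(f"max i = {y[k_max]:.6g} != 1")

    dy = np.diff(y)
    mid = 0.5 * (s[:-1] + s[1:])
    tol = -1e-9
    app = mid < profile.p - peak_exclusion
    ret = mid > profile.p + peak_exclusion
    mono_app = bool(np.all(dy[app] > tol))
    if not mono_app:
        bad = mid[app][dy[app] <= tol]
        msgs.append(f"non-increasing approach near s = {bad[0]:.4g}")
    mono_ret = bool(np.all(dy[ret] < -tol))
    if not mono_ret:
        bad = mid[ret][dy[ret] >= -tol]
        msgs.append(f"non-decreasing retraction near s = {bad[0]:.4g}")

    nonneg = bool(np.all(y >= -1e-9))
    if not nonneg:
        msgs.append(f"negative indentation, min i = {y.min():.4g}")

    return ProfileReport(
        starts, ends, interior, unit_max, mono_app, mono_ret, nonneg, msgs
    )


def _project(
    fn: Callable[[np.ndarray], np.ndarray], basis: BSplineBasis
) -> np.ndarray:
    s = np.linspace(0.0, 1.0, _DENSE_N)
    coeffs, _ = fit_bspline(s, fn(s), basis)
    return coeffs


def make_triangular(
    I_max: float,
    v_app: float,
    v_ret: float,
    basis: BSplineBasis | None = None,
) -> IndentationProfile:
    """Triangular ramp: constant approach speed v_app, retract speed v_ret."""
    if I_max <= 0 or v_app <= 0 or v_ret <= 0:
        raise ValueError("I_max and speeds must be positive")
    basis = basis or BSplineBasis()
    t_app = I_max / v_app
    t_ret = I_max / v_ret
    t_tot = t_app + t_ret
    p = t_app / t_tot

    def i(s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return np.where(s <= p, s / p, np.clip((1.0 - s) / (1.0 - p), 0.0, None))

    def di(s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return np.where(s <= p, 1.0 / p, -1.0 / (1.0 - p))

    return IndentationProfile(
        basis=basis,
        coeffs=_project(i, basis),
        p=p,
        I_max=I_max,
        t_tot=t_tot,
        kind="triangular",
        exact_i=i,
        exact_di=di,
    )


def make_capped_sinusoid(
    I_max: float, period: float, basis: BSplineBasis | None = None
) -> IndentationProfile:
    """Half-sine arch i(s) = sin(pi s); duration is half the drive period."""
    if I_max <= 0 or period <= 0:
        raise ValueError("I_max and period must be positive")
    basis = basis or BSplineBasis()

    def i(s: np.ndarray) -> np.ndarray:
        return np.sin(np.pi * np.asarray(s, dtype=float))

    def di(s: np.ndarray) -> np.ndarray:
        return np.pi * np.cos(np.pi * np.asarray(s, dtype=float))

    return IndentationProfile(
        basis=basis,
        coeffs=_project(i, basis),
        p=0.5,
        I_max=I_max,
        t_tot=period / 2.0,
        kind="capped_sinusoid",
        exact_i=i,
        exact_di=di,
    )


def random_profile(
    seed: int | np.random.Generator,
    basis: BSplineBasis | None = None,
    eps_tol: float = EPS_TOL,
    p_range: tuple[float, float] = P_RANGE,
    I_max: float = 1e-6,
    t_tot: float = 1.0,
    max_retries: int = 50,
) -> IndentationProfile:
    """Random admissible profile built directly in coefficient space.

    A target peak position is drawn uniformly in p_range; strictly positive
    coefficient increments are drawn left of the matching control point and
    strictly negative ones to its right, tapered towards the peak (smooth
    maximum) and smoothed; the result is rescaled to unit maximum and the
    boundary control points are perturbed within the eps tolerance.
    Deterministic given the seed.
    """
    basis = basis or BSplineBasis()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = basis.n_basis
    if n < 8:
        raise ValueError("basis too small for random profile generation")
    xi = basis.greville()
    s_dense = np.linspace(0.0, 1.0, _DENSE_N)
    B_dense = basis.design_matrix(s_dense)

    for _ in range(max_retries):
        p_target = rng.uniform(*p_range)
        k_peak = int(np.clip(np.argmin(np.abs(xi - p_target)), 3, n - 4))

        # taper factor suppressing increments next to the peak
        taper = 1.0 - np.exp(-((xi - xi[k_peak]) / 0.10) ** 2)

        d_left = (rng.gamma(1.5, 1.0, size=k_peak) + 0.05) * np.clip(
            taper[:k_peak], 0.02, None
        )
        d_right = (rng.gamma(1.5, 1.0, size=n - 1 - k_peak) + 0.05) * np.clip(
            taper[k_peak + 1 :], 0.02, None
        )
        # mild smoothing of increments keeps the profile from wiggling
        kernel = np.array([0.25, 0.5, 0.25])
        if len(d_left) >= 3:
            d_left = np.convolve(d_left, kernel, mode="same")
            d_left[0] *= 2.0  # compensate edge attenuation
            d_left[-1] *= 2.0
        if len(d_right) >= 3:
            d_right = np.convolve(d_right, kernel, mode="same")
            d_right[0] *= 2.0
            d_right[-1] *= 2.0

        c = np.empty(n)
        c[: k_peak + 1] = np.concatenate([[0.0], np.cumsum(d_left)])
        peak_val = c[k_peak]
        d_right *= peak_val / d_right.sum()  # descend exactly back to zero
        c[k_peak + 1 :] = peak_val - np.cumsum(d_right)

        y = B_dense @ c
        c /= y.max()
        # boundary perturbation within the eps tolerance
        c[0] = rng.uniform(0.0, 0.5 * eps_tol)
        c[-1] = rng.uniform(0.0, 0.5 * eps_tol)

        y = B_dense @ c
        k_max = int(np.argmax(y))
        c /= y[k_max]

        # quadratic refinement of the peak location
        if 0 < k_max < _DENSE_N - 1:
            y0, y1, y2 = y[k_max - 1 : k_max + 2] / y[k_max]
            denom = y0 - 2.0 * y1 + y2
            shift = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-15 else 0.0
            p_hat = s_dense[k_max] + np.clip(shift, -1.0, 1.0) * (
                s_dense[1] - s_dense[0]
            )
        else:
            p_hat = s_dense[k_max]
        p_hat = float(np.clip(p_hat, 1e-3, 1.0 - 1e-3))

        profile = IndentationProfile(
            basis=basis,
            coeffs=c,
            p=p_hat,
            I_max=I_max,
            t_tot=t_tot,
            eps_start=float(c[0]),
            eps_end=float(c[-1]),
            kind="bspline",
        )
        if validate_profile(profile, eps_tol=eps_tol).ok:
            return profile

    raise ProfileGenerationError(
        f"no admissible profile after {max_retries} retries"
    )
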