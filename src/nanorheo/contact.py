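"""Power-law-rheology contact model for conical AFM tips on thin cells.

Force on the approach branch is the hereditary integral

    F(t) = sum_j alpha_j int_0^t psi(t-t') d/dt'[I(t')^beta_j] dt'

with the power-law relaxation function psi(t) = E0/Gamma(1-gamma) (t/t0)^-gamma
and geometry coefficients beta_j = 2 + j, alpha_j = a_j tan^(j+1)(theta) / h^j
(the j >= 1 terms are the bottom-effect correction for a sample of finite
thickness h bonded to a rigid substrate). During retraction the contact area
shrinks and the upper limit is replaced by the auxiliary time t1(t) solving

    int_{t1}^{t} psi(t - t') v(t') dt' = 0        (Ting's construction).

Everything is computed in dimensionless variables s = t/t_tot, i = I/I_max:
the dimensionless force f(s) depends only on (gamma, profile shape,
r_max/h), which is what makes a single trained regressor valid across
moduli, indentation depths, and speeds.

Numerics: the indentation history is sampled on a peak-split grid and
treated as piecewise linear. The weakly singular kernel (s - s')^-gamma is
integrated analytically against the piecewise-linear i^beta (product
integration), and the retraction-balance equation is solved exactly within
the sign-change interval of its piecewise-analytic cumulative integral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .profiles import IndentationProfile

#: fluidity values at and above this are rejected: Gamma(1 - gamma) diverges
#: at the Newtonian limit gamma = 1, which has no pointwise relaxation modulus
GAMMA_MAX = 0.99

#: default number of output grid points of a simulated curve
DEFAULT_GRID = 500

#: named bottom-effect coefficient tables: relative coefficients a_j / a_0 of
#: the correction polynomial 1 + sum_{j>=1} (a_j/a_0) (r/h)^j for a conical
#: tip on a sample bonded to a rigid substrate, truncated at the cubic force
#: term.  Published series differ in their higher-order terms; override via
#: ProbeCellGeometry(a_rel=...).
BEC_TABLES: dict[str, tuple[float, ...]] = {
    "cone-bonded-v1": (1.0, 0.360601, 0.520103),
    "none": (1.0,),
}

#: Sneddon cone prefactor: F = a0 * E0 * tan(theta) * I^2 for a thick sample
CONE_PREFACTOR = 2.0 / math.pi


class GammaDomainError(ValueError):
    """Fluidity coefficient outside [0, GAMMA_MAX]."""


class ValidityError(ValueError):
    """Inputs outside the validity range of the bottom-effect correction."""


class NoRetractionError(RuntimeError):
    """Retraction contact time requested for a profile with no retraction."""


def _check_gamma(gamma: float) -> None:
    if not (0.0 <= gamma <= GAMMA_MAX):
        raise GammaDomainError(
            f"gamma = {gamma} outside [0, {GAMMA_MAX}]; the Newtonian limit "
            "gamma = 1 is not representable pointwise"
        )


@dataclass(frozen=True)
class PLRMaterial:
    """Power-law-rheology constitutive triple.

    E0 : scaling modulus, Pa (apparent modulus at the reference time t0).
    gamma : fluidity coefficient; 0 is an elastic solid, 1 a Newtonian
        liquid of viscosity E0*t0 (excluded, see GAMMA_MAX).
    t0 : reference time, s.
    """

    E0: float
    gamma: float
    t0: float = 1.0

    def __post_init__(self) -> None:
        if self.E0 <= 0:
            raise ValueError("E0 must be positive")
        _check_gamma(self.gamma)
        if self.t0 <= 0:
            raise ValueError("t0 must be positive")


@dataclass(frozen=True)
class ProbeCellGeometry:
    """Conical probe of semiangle theta on a cell of thickness h.

    a_rel are the relative bottom-effect coefficients a_j/a_0 (table
    'cone-bonded-v1' by default); a0 is the cone prefactor fixing the
    modulus convention. h may be infinite (no bottom effect).
    """

    theta: float
    h: float = math.inf
    a_rel: tuple[float, ...] = BEC_TABLES["cone-bonded-v1"]
    a0: float = CONE_PREFACTOR
    bec_table: str = "cone-bonded-v1"

    def __post_init__(self) -> None:
        if not (0.0 < self.theta < math.pi / 2):
            raise ValueError("theta must lie in (0, pi/2)")
        if self.h <= 0:
            raise ValueError("h must be positive")
        if len(self.a_rel) < 1 or self.a_rel[0] != 1.0:
            raise ValueError("a_rel must start with 1.0")

    @classmethod
    def from_table(
        cls, theta: float, h: float = math.inf, table: str = "cone-bonded-v1"
    ) -> "ProbeCellGeometry":
        return cls(theta=theta, h=h, a_rel=BEC_TABLES[table], bec_table=table)

    @property
    def a_coeffs(self) -> np.ndarray:
        """Absolute dimensionless coefficients a_j = a0 * (a_j/a_0)."""
        if math.isinf(self.h):
            return np.array([self.a0])
        return self.a0 * np.asarray(self.a_rel, dtype=float)

    def rmax_over_h(self, I_max: float) -> float:
        """Bottom-effect strength r_max/h = tan(theta) * I_max / h."""
        if math.isinf(self.h):
            return 0.0
        return math.tan(self.theta) * I_max / self.h


def bec_terms(
    geometry: ProbeCellGeometry,
) -> list[tuple[float, float]]:
    """Dimensional series terms [(alpha_j, beta_j)] of the contact model.

    beta_j = 2 + j and alpha_j = a_j tan^(j+1)(theta) / h^j; for infinite
    thickness only the Sneddon term j = 0 survives.
    """
    tan_t = math.tan(geometry.theta)
    a = geometry.a_coeffs
    return [
        (float(a[j]) * tan_t ** (j + 1) / geometry.h**j, 2.0 + j)
        for j in range(len(a))
    ]


def relaxation_modulus(t: np.ndarray | float, material: PLRMaterial) -> np.ndarray | float:
    """Stress-relaxation modulus psi(t) = E0/Gamma(1-gamma) (t/t0)^-gamma."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise ValueError("relaxation modulus requires t > 0")
    out = (
        material.E0
        / math.gamma(1.0 - material.gamma)
        * (t_arr / material.t0) ** (-material.gamma)
    )
    return float(out) if np.isscalar(t) else out


# ---------------------------------------------------------------------------
# dimensionless core
# ---------------------------------------------------------------------------


def _slope_derivative(
    mu: np.ndarray, mid: np.ndarray, p_idx: int
) -> np.ndarray:
    """Second derivative per interval from differences of interval slopes,
    centered where possible and never differencing across the peak kink."""
    n_int = len(mu)
    dd = np.zeros(n_int)
    for lo, hi in ((0, p_idx), (p_idx, n_int)):
        if hi - lo >= 2:
            seg = slice(lo, hi)
            grad = np.gradient(mu[seg], mid[seg])
            dd[seg] = grad
    return dd


def _kernel_weights(
    sq: np.ndarray, s: np.ndarray, om: float, cutoff: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Product-integration weights of the (s - s')^-(1-om) kernel.

    I0[m, k] integrates the kernel over interval k (truncated at the upper
    limit cutoff_m, default sq_m); T[m, k] integrates kernel *
    (s' - midpoint_k), the first-order moment used by the midpoint slope
    correction. Both vanish for intervals beyond the cutoff, and T vanishes
    identically when om = 1 (the elastic limit stays exact).
    """
    if cutoff is None:
        lo = s[None, :-1]
        hi = s[None, 1:]
    else:
        lo = np.minimum(s[None, :-1], cutoff[:, None])
        hi = np.minimum(s[None, 1:], cutoff[:, None])
    x_lo = np.clip(sq[:, None] - lo, 0.0, None)
    x_hi = np.clip(sq[:, None] - hi, 0.0, None)
    A = x_lo**om
    B = x_hi**om
    I0 = (A - B) / om
    I1 = (A * x_lo - B * x_hi) / (1.0 + om)
    mid = 0.5 * (s[:-1] + s[1:])
    T = (sq[:, None] - mid[None, :]) * I0 - I1
    if cutoff is not None:
        # partial intervals (cutoff interior) are re-anchored exactly at the
        # interpolated endpoint by the caller; no moment correction there
        partial = (cutoff[:, None] > s[None, :-1]) & (
            cutoff[:, None] < s[None, 1:]
        )
        T[partial] = 0.0
    return I0, T


def _contact_time_s(
    s: np.ndarray,
    i_vals: np.ndarray,
    p_idx: int,
    gamma: float,
    s_query: np.ndarray,
) -> np.ndarray:
    """Dimensionless retraction contact times s1 for query times >= s[p_idx].

    The velocity is piecewise linear per interval on the profile grid, so
    the balance integral C(u) = int_u^sq (sq - s')^-gamma v(s') ds' is
    analytic per interval: the bracketing interval is located by the sign
    change of the cumulative sums and the root inverted in closed form.
    s1 = 0 marks full contact loss (no root: the whole history is
    outweighed by retraction).
    """
    om = 1.0 - gamma
    ds = np.diff(s)
    mid = 0.5 * (s[:-1] + s[1:])
    v = np.diff(i_vals) / ds
    sq = np.atleast_1d(np.asarray(s_query, dtype=float))

    I0, T = _kernel_weights(sq, s, om)
    vdd = _slope_derivative(v, mid, p_idx)
    D = v[None, :] * I0 + vdd[None, :] * T
    # C[m, k] = integral from node s_k to sq_m
    C = np.cumsum(D[:, ::-1], axis=1)[:, ::-1]

    # C decreases in k over the approach region; root interval is the last
    # k <= p_idx - 1 with C[m, k] >= 0
    k_star = (C[:, : p_idx + 1] >= 0.0).sum(axis=1) - 1
    has_root = k_star >= 0
    ks = np.clip(k_star, 0, p_idx - 1)
    rows = np.arange(len(sq))
    C_next = C[rows, ks + 1]
    base = np.clip(sq - s[ks + 1], 0.0, None) ** om
    rhs = np.clip(base - om * C_next / v[ks], 0.0, None)
    s1 = sq - rhs ** (1.0 / om)
    s1 = np.where(has_root, s1, 0.0)
    s1 = np.clip(s1, 0.0, s[p_idx])
    # at the peak itself the contact time is the peak time
    s1 = np.where(sq <= s[p_idx], np.minimum(sq, s[p_idx]), s1)
    return s1


def _core_force(
    s: np.ndarray,
    i_vals: np.ndarray,
    p_idx: int,
    gamma: float,
    rho: float,
    a_coeffs: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Dimensionless force sum_j a_j rho^j Phi_j(s) (before the 1/(Gamma w)
    normalization); returns (raw force, cutoff sigma, path length w)."""
    om = 1.0 - gamma
    n = len(s)

    sigma = s.copy()
    if p_idx < n - 1:
        sigma[p_idx + 1 :] = _contact_time_s(
            s, i_vals, p_idx, gamma, s[p_idx + 1 :]
        )

    I0, T = _kernel_weights(s, s, om, cutoff=sigma)

    ds = np.diff(s)
    mid = 0.5 * (s[:-1] + s[1:])
    n_j = len(a_coeffs)
    Q = i_vals[:, None] ** (2.0 + np.arange(n_j))[None, :]
    M = np.diff(Q, axis=0) / ds[:, None]
    Mdd = np.empty_like(M)
    for j in range(n_j):
        Mdd[:, j] = _slope_derivative(M[:, j], mid, p_idx)
    weights = a_coeffs * rho ** np.arange(n_j)
    phi = I0 @ M + T @ Mdd

    # The interval containing the retraction cutoff sigma_m enters P only up
    # to sigma_m, but M carries the full-interval slope of i^beta. Re-anchor
    # that partial interval at the exact interpolated endpoint value, which
    # makes the elastic limit exact and sharpens the retraction branch.
    ret = np.nonzero(sigma < s - 1e-300)[0]
    if len(ret) > 0:
        sig = sigma[ret]
        k_m = np.clip(np.searchsorted(s, sig, side="right") - 1, 0, n - 2)
        length = sig - s[k_m]
        good = length > 1e-12
        if np.any(good):
            ret, sig, k_m, length = ret[good], sig[good], k_m[good], length[good]
            i_sig = np.interp(sig, s, i_vals)
            q_sig = i_sig[:, None] ** (2.0 + np.arange(n_j))[None, :]
            mu_star = (q_sig - Q[k_m, :]) / length[:, None]
            P_part = (
                (s[ret] - s[k_m]) ** om - (s[ret] - sig) ** om
            ) / om
            phi[ret, :] += (mu_star - M[k_m, :]) * P_part[:, None]

    raw = phi @ weights
    w = float(np.abs(np.diff(i_vals)).sum())
    return raw, sigma, w


@dataclass(frozen=True)
class DimensionlessForce:
    """Dimensionless force history f(s) and its mean f_bar = int_0^1 f ds.

    f depends only on the fluidity gamma, the profile shape i(s), and the
    bottom-effect strength r_max/h; linear interpolation between grid nodes
    evaluates it at arbitrary s.
    """

    s: np.ndarray
    f: np.ndarray
    f_bar: float
    s1: np.ndarray
    w: float

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        return np.interp(x, self.s, self.f)


def dimensionless_force(
    profile: IndentationProfile,
    gamma: float,
    geometry: ProbeCellGeometry,
    n_points: int = DEFAULT_GRID,
) -> DimensionlessForce:
    """Dimensionless force history of a profile under the contact model."""
    _check_gamma(gamma)
    rho = geometry.rmax_over_h(profile.I_max)
    if rho > 1.0:
        raise ValidityError(
            f"r_max/h = {rho:.3f} > 1 is outside the validity range of the "
            "bottom-effect correction"
        )
    s = profile.grid(n_points)
    p_idx = int(np.argmin(np.abs(s - profile.p)))
    i_vals = np.clip(profile.i(s), 0.0, None)
    raw, sigma, w = _core_force(s, i_vals, p_idx, gamma, rho, geometry.a_coeffs)
    if w <= 0:
        raise ValidityError("degenerate profile: zero path length")
    f = raw / (math.gamma(1.0 - gamma) * w)
    f_bar = float(np.trapezoid(f, s))
    return DimensionlessForce(s=s, f=f, f_bar=f_bar, s1=sigma, w=w)


@dataclass
class ForceCurve:
    """Simulated or measured force history of one indentation cycle."""

    t: np.ndarray
    F: np.ndarray
    I: np.ndarray
    v: np.ndarray
    t_max: float
    t_tot: float
    I_max: float
    F_bar: float
    v_bar: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if not (len(self.t) == len(self.F) == len(self.I) == len(self.v)) or len(
            self.t
        ) < 2:
            raise ValueError("t, F, I, v must have equal length >= 2")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.all(np.isfinite(self.F)):
            raise ValueError("force must be finite")


def simulate_force_curve(
    profile: IndentationProfile,
    material: PLRMaterial,
    geometry: ProbeCellGeometry,
    n_points: int = DEFAULT_GRID,
) -> ForceCurve:
    """Forward-simulate the force history of an indentation profile.

    The dimensionless force is scaled back to newtons through
    F = E0 tan(theta) I_max^2 (t_tot/t0)^-gamma w f(s), with w the total
    variation of i(s) (so that v_bar = I_max w / t_tot).
    """
    df = dimensionless_force(profile, material.gamma, geometry, n_points)
    tan_t = math.tan(geometry.theta)
    scale = (
        material.E0
        * tan_t
        * profile.I_max**2
        * (profile.t_tot / material.t0) ** (-material.gamma)
        * df.w
    )
    t = df.s * profile.t_tot
    I = np.clip(profile.i(df.s), 0.0, None) * profile.I_max
    v = profile.di(df.s) * profile.I_max / profile.t_tot
    F = scale * df.f
    F_bar = scale * df.f_bar
    v_bar = profile.I_max * df.w / profile.t_tot
    return ForceCurve(
        t=t,
        F=F,
        I=I,
        v=v,
        t_max=profile.t_max,
        t_tot=profile.t_tot,
        I_max=profile.I_max,
        F_bar=F_bar,
        v_bar=v_bar,
        meta={
            "gamma": material.gamma,
            "E0": material.E0,
            "t0": material.t0,
            "theta": geometry.theta,
            "h": geometry.h,
            "rmax_over_h": geometry.rmax_over_h(profile.I_max),
            "f_bar": df.f_bar,
        },
    )


def retraction_contact_time(
    profile: IndentationProfile,
    gamma: float,
    t: np.ndarray | float,
    n_points: int = 2 * DEFAULT_GRID,
) -> np.ndarray | float:
    """Ting contact time t1(t) during retraction (t >= t_max).

    t1 solves int_{t1}^{t} (t - t')^-gamma v(t') dt' = 0 (the constant
    prefactor of the relaxation function cancels). t1(t_max) = t_max and t1
    is non-increasing in t; t1 = 0 signals complete loss of contact.
    """
    _check_gamma(gamma)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < profile.t_max - 1e-12 * profile.t_tot):
        raise ValueError("retraction contact time requires t >= t_max")
    if np.any(t_arr > profile.t_tot * (1 + 1e-12)):
        raise ValueError("t exceeds the profile duration")
    if profile.p >= 1.0 - 1e-9:
        raise NoRetractionError("profile has no retraction branch")
    s = profile.grid(n_points)
    p_idx = int(np.argmin(np.abs(s - profile.p)))
    i_vals = np.clip(profile.i(s), 0.0, None)
    s1 = _contact_time_s(s, i_vals, p_idx, gamma, t_arr / profile.t_tot)
    out = s1 * profile.t_tot
    return float(out[0]) if np.isscalar(t) else out


def recover_modulus(
    F_bar: float,
    f_bar: float,
    gamma: float,
    t_tot: float,
    I_max: float,
    v_bar: float,
    theta: float,
    t0: float = 1.0,
) -> float:
    """Scaling modulus from the mean force and mean dimensionless force.

    E0 = (F_bar/f_bar) / (t_tot^(1-gamma) I_max^(beta0-1) v_bar tan(theta))
    for a conical tip (beta0 = 2), with the reference time t0 restoring
    units when t0 != 1 s. Exact inverse of simulate_force_curve.
    """
    if f_bar <= 0:
        raise ValueError("f_bar must be positive")
    if min(F_bar, t_tot, I_max, v_bar) <= 0:
        raise ValueError("F_bar, t_tot, I_max, v_bar must be positive")
    _check_gamma(gamma)
    denom = t_tot * (t_tot / t0) ** (-gamma) * I_max * v_bar * math.tan(theta)
    return F_bar / f_bar / denom
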