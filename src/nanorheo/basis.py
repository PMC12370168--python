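"""Clamped B-spline bases on [0, 1] and their L2 geometry.

Indentation histories and functional-neuron weight functions are both
expanded on the same cubic B-spline basis; the L2 inner product between two
expansions reduces to a bilinear form through the basis Gram matrix, which
is what lets the network treat expansion coefficients as ordinary scalar
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import BSpline


@dataclass(frozen=True)
class BSplineBasis:
    """Clamped B-spline basis on [0, 1].

    Parameters
    ----------
    n_knots : int
        Number of *interior* knots, uniformly spaced in (0, 1).
    degree : int
        Spline degree (cubic by default).
    """

    n_knots: int = 40
    degree: int = 3
    knots: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.n_knots < 0:
            raise ValueError("n_knots must be non-negative")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        interior = np.linspace(0.0, 1.0, self.n_knots + 2)[1:-1]
        knots = np.concatenate(
            [np.zeros(self.degree + 1), interior, np.ones(self.degree + 1)]
        )
        object.__setattr__(self, "knots", knots)

    @property
    def n_basis(self) -> int:
        return len(self.knots) - self.degree - 1

    def design_matrix(self, x: np.ndarray) -> np.ndarray:
        """Dense collocation matrix B with B[i, j] = B_j(x_i)."""
        x = np.clip(np.asarray(x, dtype=float), 0.0, 1.0)
        return BSpline.design_matrix(x, self.knots, self.degree).toarray()

    def spline(self, coeffs: np.ndarray) -> BSpline:
        coeffs = np.asarray(coeffs, dtype=float)
        if coeffs.shape != (self.n_basis,):
            raise ValueError(
                f"expected {self.n_basis} coefficients, got {coeffs.shape}"
            )
        return BSpline(self.knots, coeffs, self.degree, extrapolate=False)

    def greville(self) -> np.ndarray:
        """Greville abscissae (mean of degree consecutive knots)."""
        k, d = self.knots, self.degree
        return np.array([k[i + 1 : i + d + 1].mean() for i in range(self.n_basis)])

    def spec(self) -> dict:
        return {"n_knots": self.n_knots, "degree": self.degree}


def gram_matrix(basis: BSplineBasis) -> np.ndarray:
    """Exact Gram matrix G_ij = int_0^1 B_i(x) B_j(x) dx.

    The product of two degree-d splines is a piecewise polynomial of degree
    2d on each knot span, so fixed-order Gauss-Legendre quadrature per span
    (order d+1, exact through degree 2d+1) integrates it exactly.
    """
    spans = np.unique(basis.knots)
    nodes, weights = leggauss(basis.degree + 1)
    a, b = spans[:-1], spans[1:]
    half = 0.5 * (b - a)
    x = (half[:, None] * (nodes[None, :] + 1.0) + a[:, None]).ravel()
    w = (half[:, None] * weights[None, :]).ravel()
    B = basis.design_matrix(x)
    G = B.T @ (w[:, None] * B)
    return 0.5 * (G + G.T)


def functional_dot(f_coeffs: np.ndarray, g_coeffs: np.ndarray, G: np.ndarray) -> float:
    """L2 inner product of two basis expansions: sum_jk c_j g_k G_jk."""
    f_coeffs = np.asarray(f_coeffs, dtype=float)
    g_coeffs = np.asarray(g_coeffs, dtype=float)
    if f_coeffs.shape[-1] != G.shape[0] or g_coeffs.shape[-1] != G.shape[1]:
        raise ValueError("coefficient/Gram dimension mismatch")
    return float(f_coeffs @ G @ g_coeffs)


def fit_bspline(
    x: np.ndarray, y: np.ndarray, basis: BSplineBasis
) -> tuple[np.ndarray, float]:
    """Least-squares projection of samples (x, y) onto the basis.

    Returns (coefficients, residual norm). Raises if the collocation matrix
    is rank deficient (too few or badly placed samples).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1-D arrays")
    if len(x) < basis.n_basis:
        raise ValueError(
            f"need at least {basis.n_basis} samples, got {len(x)}"
        )
    if x.min() < 0.0 or x.max() > 1.0:
        raise ValueError("sample abscissae must lie in [0, 1]")
    B = basis.design_matrix(x)
    coeffs, _, rank, _ = np.linalg.lstsq(B, y, rcond=None)
    if rank < basis.n_basis:
        raise np.linalg.LinAlgError(
            f"rank-deficient fit: rank {rank} < {basis.n_basis} basis functions"
        )
    residual = float(np.linalg.norm(B @ coeffs - y))
    return coeffs, residual
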