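"""Brute-force oracles for the fast product-integration force solver.

Adaptive quadrature with explicit endpoint-singularity weighting plus a
bracketed root finder for the retraction contact time. Slow but independent
of the implementation under test; built before the fast solver was tuned.
"""

import math

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq


def oracle_dimensionless_force(profile, gamma, rho, a_coeffs, s_eval):
    """f(s) at the requested points via adaptive quadrature + brentq."""
    p = profile.p

    def i(x):
        return float(profile.i(np.array([x]))[0])

    def v(x):
        return float(profile.di(np.array([x]))[0])

    def seg_quad(f, a, b, sm, singular):
        # integral of f(s') (sm - s')^-gamma over [a, b], split at the peak
        if b - a < 1e-14:
            return 0.0
        pieces = sorted({a, b, min(max(p, a), b)})
        tot = 0.0
        for aa, bb in zip(pieces[:-1], pieces[1:]):
            if bb - aa < 1e-14:
                continue
            if singular and abs(bb - sm) < 1e-13 and gamma > 0:
                val, _ = quad(f, aa, bb, weight="alg", wvar=(0.0, -gamma), limit=200)
            else:
                val, _ = quad(
                    lambda x: f(x) * (sm - x) ** (-gamma), aa, bb, limit=200
                )
            tot += val
        return tot

    def s1_of(sm):
        if sm <= p:
            return sm
        def g(u):
            return seg_quad(v, u, sm, sm, singular=True)
        if g(0.0) <= 0:
            return 0.0
        return brentq(g, 0.0, p, xtol=1e-13)

    w1, _ = quad(lambda x: abs(v(x)), 0, p)
    w2, _ = quad(lambda x: abs(v(x)), p, 1)
    w = w1 + w2
    out = []
    for sm in s_eval:
        sig = s1_of(sm)
        tot = 0.0
        for j, a_j in enumerate(a_coeffs):
            beta = 2.0 + j

            def integ(x, beta=beta):
                return beta * max(i(x), 0.0) ** (beta - 1) * v(x)

            tot += a_j * rho**j * seg_quad(
                integ, 0.0, sig, sm, singular=(sig >= sm - 1e-13)
            )
        out.append(tot / (math.gamma(1.0 - gamma) * w))
    return np.array(out)


def triangle_t1_closed_form(t, t_max, gamma):
    """t1 for a symmetric triangle, clamped at contact loss."""
    return np.clip(t - 2.0 ** (1.0 / (1.0 - gamma)) * (t - t_max), 0.0, None)
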