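"""Compiled inner loop of the piecewise-analytic propagator.

Identical mathematics to the NumPy segment propagator in ``model.py`` —
the exact solution of the lower-triangular inter-impulse system written in
phi-function form — specialized to a flat per-subject/per-segment loop and
JIT-compiled with numba.  If numba is unavailable the package transparently
falls back to the NumPy path; the test-suite asserts both paths agree.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco


_COEF4 = np.array([1.0 / math.factorial(i + 4) for i in range(17)])


@njit(cache=True)
def _phi_scalar(x):
    """phi_1..phi_4 at a scalar argument (series / expm1 split at 0.5)."""
    if abs(x) < 0.5:
        p4 = _COEF4[16]
        for i in range(15, -1, -1):
            p4 = p4 * x + _COEF4[i]
        p3 = x * p4 + 1.0 / 6.0
        p2 = x * p3 + 0.5
        p1 = x * p2 + 1.0
    else:
        p1 = math.expm1(x) / x
        p2 = (p1 - 1.0) / x
        p3 = (p2 - 0.5) / x
        p4 = (p3 - 1.0 / 6.0) / x
    return p1, p2, p3, p4


@njit(cache=True)
def propagate_core(
    kg,
    kk,
    v1,
    s,
    taus,
    ev_of_break,
    out_of_break,
    frac_killed,
    i_post,
    states,
):
    """March the batch across all breakpoints in place.

    ``v1`` is ``(n,)``, ``s`` is ``(n, 5)`` ordered (u1, u2, v2, v3, v4);
    ``taus[b]`` is the duration of the segment ending at breakpoint ``b``;
    ``ev_of_break``/``out_of_break`` give the event / output index at each
    breakpoint (or -1).  Returns the per-subject inhibition factor in force
    at the end.
    """
    n = v1.shape[0]
    i_cur = np.ones(n)
    for b in range(taus.shape[0]):
        tau = taus[b]
        if tau > 0.0:
            e_k = math.exp(-kk * tau)
            e_mu = math.exp(-(kg + kk) * tau)
            p1w, p2w, p3w, p4w = _phi_scalar(-kg * tau)
            tau2 = tau * tau
            tau3 = tau2 * tau
            tau4 = tau3 * tau
            ktau = kk * tau
            for i in range(n):
                z = kg * i_cur[i]
                lam = z - kk
                p1, p2, p3, _ = _phi_scalar(z * tau)
                e_lam = math.exp(lam * tau)
                V1 = v1[i]
                U1 = s[i, 0]
                U2 = s[i, 1]
                V2 = s[i, 2]
                V3 = s[i, 3]
                V4 = s[i, 4]
                g = kk * V1
                cv2 = g * tau * e_k * p1
                cv3 = g * kk * tau2 * e_k * p2
                cv4 = g * kk * kk * tau3 * e_k * p3
                gu = kk * U1
                cv2 += gu * tau * e_k * p1w
                cv3 += gu * kk * tau2 * e_k * p2w
                cv4 += gu * kk * kk * tau3 * e_k * p3w
                g2 = 2.0 * kg * U1
                nU2 = U2 * e_k + g2 * tau * e_k * p1w
                cv2 += g2 * kk * tau2 * e_k * p2w
                cv3 += g2 * kk * kk * tau3 * e_k * p3w
                cv4 += g2 * kk * kk * kk * tau4 * e_k * p4w
                nV2 = V2 * e_k + U2 * ktau * e_k + cv2
                nV3 = (
                    V3 * e_k
                    + V2 * ktau * e_k
                    + U2 * ktau * ktau / 2.0 * e_k
                    + cv3
                )
                nV4 = (
                    V4 * e_k
                    + V3 * ktau * e_k
                    + V2 * ktau * ktau / 2.0 * e_k
                    + U2 * ktau * ktau * ktau / 6.0 * e_k
                    + cv4
                )
                v1[i] = V1 * e_lam
                s[i, 0] = U1 * e_mu
                s[i, 1] = nU2
                s[i, 2] = nV2
                s[i, 3] = nV3
                s[i, 4] = nV4
        j = ev_of_break[b]
        if j >= 0:
            for i in range(n):
                s[i, 0] += frac_killed[i, j] * v1[i]
                v1[i] *= 1.0 - frac_killed[i, j]
                i_cur[i] = i_post[i, j]
        o = out_of_break[b]
        if o >= 0:
            for i in range(n):
                states[i, o, 0] = v1[i]
                states[i, o, 1] = s[i, 0]
                states[i, o, 2] = s[i, 1]
                states[i, o, 3] = s[i, 2]
                states[i, o, 4] = s[i, 3]
                states[i, o, 5] = s[i, 4]
    return i_cur
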