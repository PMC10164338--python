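"""Stable evaluation of the exponential phi-functions.

``phi_j(z) = (e^z - sum_{i<j} z^i / i!) / z^j`` appears in the closed-form
solution of linear ODE cascades driven by exponential forcing.  Direct
evaluation suffers catastrophic cancellation near ``z = 0`` (which is exactly
the tumor-stasis regime, where the net growth rate of the proliferating
compartment vanishes), so small arguments use a Horner-evaluated Taylor
series for ``phi_4`` plus the exact upward recurrence
``phi_j = z phi_{j+1} + 1/j!``, and large ones the downward recurrence
seeded with ``expm1``.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["phi_functions"]

_SERIES_RADIUS = 0.5
# Taylor coefficients of phi_4: sum_i z^i / (i+4)!  (term 16 < 1e-21 at |z|=0.5)
_COEF4 = np.array([1.0 / math.factorial(i + 4) for i in range(17)])
_INV6 = 1.0 / 6.0


def phi_functions(z: np.ndarray, jmax: int = 4) -> np.ndarray:
    """Evaluate ``phi_1(z) ... phi_jmax(z)`` elementwise.

    Returns an ndarray of shape ``(jmax,) + shape(z)``.
    """
    z = np.asarray(z, dtype=float)
    small = np.abs(z) < _SERIES_RADIUS
    zs = np.where(small, z, 0.0)

    # small |z|: Horner series for phi_4, then exact upward recurrence
    p4 = np.full_like(zs, _COEF4[-1])
    for c in _COEF4[-2::-1]:
        p4 = p4 * zs + c
    p3 = zs * p4 + _INV6
    p2 = zs * p3 + 0.5
    p1 = zs * p2 + 1.0

    # large |z|: downward recurrence from expm1 (no cancellation risk there)
    zl = np.where(small, 1.0, z)
    q1 = np.expm1(zl) / zl
    q2 = (q1 - 1.0) / zl
    q3 = (q2 - 0.5) / zl
    q4 = (q3 - _INV6) / zl

    out = np.empty((jmax,) + z.shape, dtype=float)
    for j, (ps, ql) in enumerate(((p1, q1), (p2, q2), (p3, q3), (p4, q4))):
        if j >= jmax:
            break
        out[j] = np.where(small, ps, ql)
    return out
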