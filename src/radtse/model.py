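"""Tumor growth under fractionated radiotherapy with a radiosensitizer.

The total tumor volume is split into six compartments:

* ``V1`` — proliferating cells, growing at rate ``kg`` and dying naturally at
  rate ``kk``;
* ``V2, V3, V4`` — a transit chain of dying cells (rate ``kk`` throughout)
  that produces the delayed volume response seen in xenograft data;
* ``U1, U2`` — lethally irradiated cells: at every radiation application a
  fraction ``F`` of ``V1`` moves instantaneously to ``U1``; those cells divide
  once (two daughters enter ``U2``) and then die through the transit chain.

Radiation acts twice.  The *short-term* effect is the per-fraction kill
``F(D_R, C) = 1 - exp(-(1 + a C)(alpha D_R + beta D_R^2))`` — the classical
linear-quadratic model with ``beta = alpha / (alpha/beta ratio)``, potentiated
by the radiosensitizer concentration ``C`` through the potency ``a``.  The
*long-term* effect inhibits the growth rate through a function
``I(D_acc)`` of the accumulated dose (exponential, saturating or linear
variant), with ``D_acc`` scaled by ``(1 + b C)`` for the radiosensitizer and
expressed in units of ``dose_scale`` gray (default 10 Gy) inside ``I``.

Between radiation applications the system is linear with constant
coefficients, so trajectories are computed by an exact piecewise-analytic
propagator (see :func:`simulate`); a general-purpose stiff integrator is kept
as an independent cross-check path.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import _core
from ._phi import phi_functions

__all__ = [
    "ModelParameters",
    "Regimen",
    "TumorState",
    "Trajectory",
    "ConfigurationError",
    "SimulationError",
    "initial_state",
    "inhibition",
    "fraction_killed",
    "apply_radiation_impulse",
    "simulate",
    "total_volume_derivative",
    "system_matrix",
]

INHIBITION_KINDS = ("exponential", "saturating", "linear")

#: Gray per unit of the scaled dose argument entering the long-term
#: inhibition function (gamma is expressed per ``DEFAULT_DOSE_SCALE`` Gy).
DEFAULT_DOSE_SCALE = 10.0


class ConfigurationError(ValueError):
    """Invalid model configuration (unknown variant, broken invariant...)."""


class SimulationError(RuntimeError):
    """Numerical integration failed; carries the offending segment."""

    def __init__(self, message: str, segment: tuple[float, float] | None = None):
        super().__init__(message)
        self.segment = segment


@dataclass(frozen=True)
class ModelParameters:
    """Structural parameters of one subject.

    Parameters
    ----------
    kg : float
        Growth rate of proliferating cells [1/day], > 0.
    kk : float
        Natural kill rate [1/day], 0 <= kk < kg.
    alpha : float
        Linear radiosensitivity of the LQ model [1/Gy].
    gamma : float
        Long-term growth-inhibition coefficient [1/(dose_scale Gy)].
    v0 : float
        Initial proliferating volume [mm^3].
    alpha_beta_ratio : float
        alpha/beta quotient [Gy]; beta is derived as ``alpha / ratio``.
    a : float
        Radiosensitizer potency on the short-term (LQ) effect [mL/ug].
    b : float
        Radiosensitizer potency on the long-term inhibition [mL/ug].
    inhibition_kind : str
        One of ``"exponential"``, ``"saturating"``, ``"linear"``.
    id50 : float or None
        Scaled accumulated dose giving half-maximal inhibition [Gy];
        required by the saturating variant only.
    dose_scale : float
        Gray per unit of the scaled dose argument of ``I`` (default 10).
    """

    kg: float
    kk: float
    alpha: float
    gamma: float
    v0: float
    alpha_beta_ratio: float = 10.0
    a: float = 0.0
    b: float = 0.0
    inhibition_kind: str = "linear"
    id50: float | None = None
    dose_scale: float = DEFAULT_DOSE_SCALE

    def __post_init__(self):
        if self.kg <= 0:
            raise ConfigurationError(f"kg must be > 0, got {self.kg}")
        if not 0 <= self.kk < self.kg:
            raise ConfigurationError(
                f"kk must satisfy 0 <= kk < kg, got kk={self.kk}, kg={self.kg}"
            )
        if self.alpha < 0:
            raise ConfigurationError(f"alpha must be >= 0, got {self.alpha}")
        if self.gamma < 0:
            raise ConfigurationError(f"gamma must be >= 0, got {self.gamma}")
        if self.v0 <= 0:
            raise ConfigurationError(f"v0 must be > 0, got {self.v0}")
        if self.a < 0 or self.b < 0:
            raise ConfigurationError("drug potencies a, b must be >= 0")
        if self.alpha_beta_ratio <= 0:
            raise ConfigurationError("alpha_beta_ratio must be > 0")
        if self.dose_scale <= 0:
            raise ConfigurationError("dose_scale must be > 0")
        if self.inhibition_kind not in INHIBITION_KINDS:
            raise ConfigurationError(
                f"unknown inhibition_kind {self.inhibition_kind!r}; "
                f"expected one of {INHIBITION_KINDS}"
            )
        if self.inhibition_kind == "saturating" and (
            self.id50 is None or self.id50 <= 0
        ):
            raise ConfigurationError(
                "saturating inhibition requires id50 > 0"
            )

    @property
    def beta(self) -> float:
        """Quadratic LQ radiosensitivity [1/Gy^2]."""
        return self.alpha / self.alpha_beta_ratio

    def replace(self, **kwargs) -> "ModelParameters":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class Regimen:
    """Ordered radiation applications with the active drug concentration.

    ``times`` are days (strictly increasing), ``doses`` the per-fraction
    radiation doses [Gy] and ``concentrations`` the radiosensitizer plasma
    concentration [ug/mL] at each application.  ``horizon`` is the
    simulation end [day].
    """

    times: tuple[float, ...]
    doses: tuple[float, ...]
    concentrations: tuple[float, ...]
    horizon: float

    def __post_init__(self):
        n = len(self.times)
        if len(self.doses) != n or len(self.concentrations) != n:
            raise ConfigurationError("times, doses, concentrations must align")
        if n and any(
            t2 <= t1 for t1, t2 in zip(self.times, self.times[1:])
        ):
            raise ConfigurationError("event times must be strictly increasing")
        if any(d < 0 for d in self.doses):
            raise ConfigurationError("doses must be >= 0")
        if any(c < 0 for c in self.concentrations):
            raise ConfigurationError("concentrations must be >= 0")
        if n and self.horizon < self.times[-1]:
            raise ConfigurationError("horizon must cover the last event")

    @classmethod
    def from_events(
        cls,
        events: Iterable[tuple[float, float, float]],
        horizon: float,
    ) -> "Regimen":
        """Build from an iterable of ``(time, dose, concentration)``."""
        ev = sorted(events)
        return cls(
            times=tuple(t for t, _, _ in ev),
            doses=tuple(d for _, d, _ in ev),
            concentrations=tuple(c for _, _, c in ev),
            horizon=horizon,
        )

    @classmethod
    def untreated(cls, horizon: float) -> "Regimen":
        return cls((), (), (), horizon)

    @property
    def total_dose(self) -> float:
        return float(sum(self.doses))

    @property
    def n_events(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class TumorState:
    """Compartment volumes [mm^3] plus the accumulated dose [Gy]."""

    v1: float
    v2: float
    v3: float
    v4: float
    u1: float
    u2: float
    d_acc: float = 0.0

    @property
    def total(self) -> float:
        return self.v1 + self.v2 + self.v3 + self.v4 + self.u1 + self.u2

    def as_array(self) -> np.ndarray:
        """Order ``(v1, u1, u2, v2, v3, v4)`` used by the propagator."""
        return np.array([self.v1, self.u1, self.u2, self.v2, self.v3, self.v4])

    @classmethod
    def from_array(cls, x: np.ndarray, d_acc: float = 0.0) -> "TumorState":
        v1, u1, u2, v2, v3, v4 = (float(v) for v in x)
        return cls(v1=v1, v2=v2, v3=v3, v4=v4, u1=u1, u2=u2, d_acc=d_acc)


@dataclass(frozen=True)
class Trajectory:
    """Simulated states at requested output times.

    At radiation event times the stored state is the post-impulse (right)
    value; the one-sided values at every event are kept separately so both
    limits remain available.
    """

    times: np.ndarray            # (T,)
    states: np.ndarray           # (T, 6) in order (v1, u1, u2, v2, v3, v4)
    d_acc: np.ndarray            # (T,)
    event_times: np.ndarray      # (E,)
    pre_event_states: np.ndarray   # (E, 6)
    post_event_states: np.ndarray  # (E, 6)

    @property
    def total_volume(self) -> np.ndarray:
        return self.states.sum(axis=1)

    def state_at(self, index: int) -> TumorState:
        return TumorState.from_array(self.states[index], float(self.d_acc[index]))


# ---------------------------------------------------------------------------
# elementary operations


def initial_state(params: ModelParameters) -> TumorState:
    """Pre-treatment steady composition giving strictly exponential growth.

    ``V_i(0) = v0 (kk/kg)^(i-1)`` for the four V compartments; the damaged
    compartments start empty.
    """
    r = params.kk / params.kg
    return TumorState(
        v1=params.v0,
        v2=params.v0 * r,
        v3=params.v0 * r**2,
        v4=params.v0 * r**3,
        u1=0.0,
        u2=0.0,
        d_acc=0.0,
    )


def inhibition(d_acc, concentration, params: ModelParameters):
    """Long-term growth-inhibition factor ``I`` in ``(-inf, 1]``.

    The effective scaled dose is ``D = d_acc (1 + b C) / dose_scale``; the
    linear variant returns ``1 - gamma D`` (allowed to go negative — net
    shrinkage), the exponential ``exp(-gamma D)`` and the saturating
    ``1 - gamma D / (id50/dose_scale + D)``.
    """
    d_acc = np.asarray(d_acc, dtype=float)
    if np.any(d_acc < 0):
        raise ValueError("accumulated dose must be >= 0")
    d_eff = d_acc * (1.0 + params.b * np.asarray(concentration, float))
    d_eff = d_eff / params.dose_scale
    kind = params.inhibition_kind
    if kind == "linear":
        out = 1.0 - params.gamma * d_eff
    elif kind == "exponential":
        out = np.exp(-params.gamma * d_eff)
    elif kind == "saturating":
        out = 1.0 - params.gamma * d_eff / (params.id50 / params.dose_scale + d_eff)
    else:  # pragma: no cover - guarded in ModelParameters
        raise ConfigurationError(f"unknown inhibition_kind {kind!r}")
    return out if out.shape else float(out)


def fraction_killed(dose, concentration, params: ModelParameters):
    """Fraction of proliferating cells lethally damaged by one fraction.

    Linear-quadratic kill ``1 - exp(-(1 + a C)(alpha D + beta D^2))``.
    """
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be >= 0")
    conc = np.asarray(concentration, dtype=float)
    expo = (1.0 + params.a * conc) * (params.alpha * dose + params.beta * dose**2)
    out = -np.expm1(-expo)
    return out if out.shape else float(out)


def apply_radiation_impulse(
    state: TumorState, dose: float, concentration: float, params: ModelParameters
) -> TumorState:
    """Instantaneous effect of one radiation application.

    Moves the killed fraction of ``V1`` into ``U1`` (total volume conserved)
    and books the fraction dose onto the accumulated dose.
    """
    f = fraction_killed(dose, concentration, params)
    return dataclasses.replace(
        state,
        v1=state.v1 * (1.0 - f),
        u1=state.u1 + f * state.v1,
        d_acc=state.d_acc + dose,
    )


def system_matrix(params: ModelParameters, inhibition_factor: float) -> np.ndarray:
    """Constant-coefficient system matrix between impulses.

    State order ``(v1, u1, u2, v2, v3, v4)``; lower triangular.
    """
    kg, kk = params.kg, params.kk
    lam = kg * inhibition_factor - kk
    a = np.zeros((6, 6))
    a[0, 0] = lam
    a[1, 1] = -(kg + kk)
    a[2, 1] = 2.0 * kg
    a[2, 2] = -kk
    a[3, 0] = kk
    a[3, 1] = kk
    a[3, 2] = kk
    a[3, 3] = -kk
    a[4, 3] = kk
    a[4, 4] = -kk
    a[5, 4] = kk
    a[5, 5] = -kk
    return a


# ---------------------------------------------------------------------------
# piecewise-analytic propagation (vectorized over subjects)


class _Batch:
    """Per-subject parameter arrays sharing kg, kk and the variant."""

    def __init__(
        self,
        template: ModelParameters,
        gamma=None,
        alpha=None,
        v0=None,
    ):
        self.template = template
        self.kg = template.kg
        self.kk = template.kk
        self.gamma = np.atleast_1d(
            np.asarray(template.gamma if gamma is None else gamma, float)
        )
        self.alpha = np.atleast_1d(
            np.asarray(template.alpha if alpha is None else alpha, float)
        )
        self.v0 = np.atleast_1d(np.asarray(template.v0 if v0 is None else v0, float))
        n = max(self.gamma.size, self.alpha.size, self.v0.size)
        self.gamma, self.alpha, self.v0 = (
            np.broadcast_to(arr, (n,)).astype(float)
            for arr in np.broadcast_arrays(self.gamma, self.alpha, self.v0)
        )
        self.n = n

    def _inhibition(self, d_acc, conc):
        p = self.template
        d_eff = np.asarray(d_acc, float) * (1.0 + p.b * conc) / p.dose_scale
        if p.inhibition_kind == "linear":
            return 1.0 - self.gamma * d_eff
        if p.inhibition_kind == "exponential":
            return np.exp(-self.gamma * d_eff)
        return 1.0 - self.gamma * d_eff / (p.id50 / p.dose_scale + d_eff)

    def _fraction_killed(self, dose, conc):
        p = self.template
        expo = (1.0 + p.a * conc) * (
            self.alpha * dose + (self.alpha / p.alpha_beta_ratio) * dose**2
        )
        return -np.expm1(-expo)


def _propagate_segment(batch: _Batch, v1, s, i_cur, tau):
    """Advance one impulse-free segment of length ``tau`` exactly.

    ``v1`` is ``(n,)``, ``s`` is ``(n, 5)`` in order (u1, u2, v2, v3, v4).
    The 5-compartment damage subsystem is a constant cascade at rate ``kk``
    fed by ``v1``'s exponential and ``u1``'s decay; its exact solution is
    expressed through phi-functions so the stasis regime (``kg I -> 0``)
    stays numerically benign.
    """
    kg, kk = batch.kg, batch.kk
    lam = kg * i_cur - kk          # (n,)
    z = lam + kk                   # = kg * I
    e_lam = np.exp(lam * tau)
    e_k = np.exp(-kk * tau)
    e_mu = np.exp(-(kg + kk) * tau)
    ktau = kk * tau

    pz = phi_functions(z * tau, jmax=3)        # phi_1..phi_3 at z*tau, (3, n)
    pw = phi_functions(np.array(-kg * tau), jmax=4)  # scalar argument

    u1, u2, v2, v3, v4 = (s[:, j] for j in range(5))

    # contributions from V1(t0) into the kk-chain (V2 -> V3 -> V4)
    g = kk * v1
    c_v2 = g * tau * e_k * pz[0]
    c_v3 = g * kk * tau**2 * e_k * pz[1]
    c_v4 = g * kk**2 * tau**3 * e_k * pz[2]

    # contributions from U1(t0): direct decay, forcing of V2 and of U2
    gu = kk * u1
    c_v2 += gu * tau * e_k * pw[0]
    c_v3 += gu * kk * tau**2 * e_k * pw[1]
    c_v4 += gu * kk**2 * tau**3 * e_k * pw[2]
    g2 = 2.0 * kg * u1
    n_u2 = u2 * e_k + g2 * tau * e_k * pw[0]
    c_v2 += g2 * kk * tau**2 * e_k * pw[1]
    c_v3 += g2 * kk**2 * tau**3 * e_k * pw[2]
    c_v4 += g2 * kk**3 * tau**4 * e_k * pw[3]

    # repeated-eigenvalue propagation of the chain's own initial content
    n_v2 = v2 * e_k + u2 * ktau * e_k + c_v2
    n_v3 = v3 * e_k + v2 * ktau * e_k + u2 * ktau**2 / 2.0 * e_k + c_v3
    n_v4 = (
        v4 * e_k
        + v3 * ktau * e_k
        + v2 * ktau**2 / 2.0 * e_k
        + u2 * ktau**3 / 6.0 * e_k
        + c_v4
    )

    out = np.empty_like(s)
    out[:, 0] = u1 * e_mu
    out[:, 1] = n_u2
    out[:, 2] = n_v2
    out[:, 3] = n_v3
    out[:, 4] = n_v4
    return v1 * e_lam, out


def _simulate_batch(
    batch: _Batch,
    event_times: np.ndarray,
    event_doses: np.ndarray,
    event_concs: np.ndarray,
    out_times: np.ndarray,
    capture_events: bool = False,
):
    """Exact trajectory of a batch of subjects sharing event times.

    ``event_doses``/``event_concs`` may be ``(m,)`` or ``(n, m)``.  Output
    states at event times are post-impulse.  Returns ``(states, d_acc,
    i_final, pre, post)`` where ``states`` is ``(n, T, 6)``.

    Dispatches to the compiled flat loop when available; the NumPy
    segment path below is the reference implementation (and the only one
    that captures one-sided event states).
    """
    if _core.HAVE_NUMBA and not capture_events:
        return _simulate_batch_fast(
            batch, event_times, event_doses, event_concs, out_times
        )
    return _simulate_batch_numpy(
        batch, event_times, event_doses, event_concs, out_times, capture_events
    )


#: longest impulse-free stretch integrated in one step; exp arguments stay
#: far from the double-precision overflow threshold
_MAX_SEGMENT = 250.0


def _densify(breaks: np.ndarray, max_gap: float = _MAX_SEGMENT) -> np.ndarray:
    """Insert plain waypoints so no inter-break gap exceeds ``max_gap``."""
    if not len(breaks):
        return breaks
    out = []
    prev = 0.0
    for t in breaks:
        gap = t - prev
        if gap > max_gap:
            k = int(np.ceil(gap / max_gap))
            out.extend(prev + gap * np.arange(1, k) / k)
        out.append(t)
        prev = t
    return np.asarray(out, float)


class _Timeline:
    """Precomputed breakpoint structure shared across repeated simulations."""

    __slots__ = ("uniq", "inv", "taus", "ev_of_break", "out_of_break", "n_applied")

    def __init__(self, event_times, out_times):
        uniq, inv = np.unique(out_times, return_inverse=True)
        if uniq.size and uniq[0] < 0:
            raise ValueError("negative times are not allowed")
        m = len(event_times)
        breaks = _densify(np.union1d(event_times, uniq))
        self.uniq = uniq
        self.inv = inv
        self.taus = np.diff(np.concatenate([[0.0], breaks]))
        ev = np.searchsorted(event_times, breaks)
        hit = (ev < m) & np.isin(breaks, event_times)
        self.ev_of_break = np.where(hit, ev, -1).astype(np.int64)
        out = np.searchsorted(uniq, breaks)
        hit = (out < uniq.size) & np.isin(breaks, uniq)
        self.out_of_break = np.where(hit, out, -1).astype(np.int64)
        self.n_applied = np.searchsorted(event_times, uniq, side="right")


_TIMELINE_CACHE: dict = {}


def _timeline(event_times: np.ndarray, out_times: np.ndarray) -> _Timeline:
    key = (event_times.tobytes(), out_times.tobytes())
    tl = _TIMELINE_CACHE.get(key)
    if tl is None:
        tl = _Timeline(event_times, out_times)
        if len(_TIMELINE_CACHE) > 512:
            _TIMELINE_CACHE.clear()
        _TIMELINE_CACHE[key] = tl
    return tl


def _simulate_batch_fast(batch, event_times, event_doses, event_concs, out_times):
    n = batch.n
    m = len(event_times)
    event_times = np.asarray(event_times, float)
    doses = np.ascontiguousarray(
        np.broadcast_to(np.asarray(event_doses, float), (n, m))
    )
    concs = np.ascontiguousarray(
        np.broadcast_to(np.asarray(event_concs, float), (n, m))
    )
    out_times = np.asarray(out_times, dtype=float)
    tl = _timeline(event_times, out_times)
    uniq, inv = tl.uniq, tl.inv

    p = batch.template
    alpha = batch.alpha[:, None]
    if m:
        expo = (1.0 + p.a * concs) * (
            alpha * doses + (alpha / p.alpha_beta_ratio) * doses**2
        )
        frac = -np.expm1(-expo)
        cum = np.cumsum(doses, axis=1)
        d_eff = cum * (1.0 + p.b * concs) / p.dose_scale
        if p.inhibition_kind == "linear":
            i_post = 1.0 - batch.gamma[:, None] * d_eff
        elif p.inhibition_kind == "exponential":
            i_post = np.exp(-batch.gamma[:, None] * d_eff)
        else:
            i_post = 1.0 - batch.gamma[:, None] * d_eff / (
                p.id50 / p.dose_scale + d_eff
            )
    else:
        frac = np.zeros((n, 0))
        i_post = np.ones((n, 0))
        cum = np.zeros((n, 0))

    r = batch.kk / batch.kg
    v1 = batch.v0.copy()
    s = np.empty((n, 5))
    s[:, 0] = 0.0
    s[:, 1] = 0.0
    s[:, 2] = batch.v0 * r
    s[:, 3] = batch.v0 * r**2
    s[:, 4] = batch.v0 * r**3
    states_u = np.zeros((n, uniq.size, 6))
    i_final = _core.propagate_core(
        batch.kg,
        batch.kk,
        v1,
        s,
        tl.taus,
        tl.ev_of_break,
        tl.out_of_break,
        frac,
        i_post,
        states_u,
    )
    # accumulated dose at each output time (post-impulse convention)
    d_u = np.zeros((n, uniq.size))
    nz = tl.n_applied > 0
    if m and nz.any():
        d_u[:, nz] = cum[:, tl.n_applied[nz] - 1]
    return states_u[:, inv, :], d_u[:, inv], i_final, None, None


def _simulate_batch_numpy(
    batch: _Batch,
    event_times: np.ndarray,
    event_doses: np.ndarray,
    event_concs: np.ndarray,
    out_times: np.ndarray,
    capture_events: bool = False,
):
    n = batch.n
    m = len(event_times)
    event_doses = np.broadcast_to(np.asarray(event_doses, float), (n, m) if m else (n, 0))
    event_concs = np.broadcast_to(np.asarray(event_concs, float), (n, m) if m else (n, 0))
    out_times = np.asarray(out_times, dtype=float)

    # timeline of breakpoints: union of events and outputs
    breaks = _densify(np.union1d(event_times, out_times))
    ev_idx = {t: j for j, t in enumerate(event_times)}
    out_pos = {}
    for j, t in enumerate(out_times):
        out_pos.setdefault(float(t), []).append(j)

    r = batch.kk / batch.kg
    v1 = batch.v0.copy()
    s = np.empty((n, 5))
    s[:, 0] = 0.0  # u1
    s[:, 1] = 0.0  # u2
    s[:, 2] = batch.v0 * r
    s[:, 3] = batch.v0 * r**2
    s[:, 4] = batch.v0 * r**3
    d_acc = np.zeros(n)
    i_cur = np.ones(n)

    states = np.empty((n, len(out_times), 6))
    d_out = np.empty((n, len(out_times)))
    pre = np.empty((n, m, 6)) if capture_events else None
    post = np.empty((n, m, 6)) if capture_events else None

    def record(js):
        for j in js:
            states[:, j, 0] = v1
            states[:, j, 1:] = s
            d_out[:, j] = d_acc

    t_prev = 0.0
    if 0.0 in out_pos and 0.0 not in ev_idx:
        record(out_pos[0.0])
    for t in breaks:
        if t < 0:
            raise ValueError("negative times are not allowed")
        tau = t - t_prev
        if tau > 0:
            v1, s = _propagate_segment(batch, v1, s, i_cur, tau)
        t_prev = t
        j_ev = ev_idx.get(float(t))
        if j_ev is not None:
            if capture_events:
                pre[:, j_ev, 0] = v1
                pre[:, j_ev, 1:] = s
            dose = event_doses[:, j_ev]
            conc = event_concs[:, j_ev]
            f = batch._fraction_killed(dose, conc)
            s[:, 0] += f * v1
            v1 = v1 * (1.0 - f)
            d_acc = d_acc + dose
            i_cur = batch._inhibition(d_acc, conc)
            if capture_events:
                post[:, j_ev, 0] = v1
                post[:, j_ev, 1:] = s
        if float(t) in out_pos and t > 0:
            record(out_pos[float(t)])
        elif float(t) in out_pos and t == 0 and j_ev is not None:
            record(out_pos[0.0])
    return states, d_out, i_cur, pre, post


def _derivative_batch(batch: _Batch, regimen_arrays, t_star: float):
    """d(V_tot)/dt at ``t_star`` for every subject, ``(n,)``."""
    event_times, event_doses, event_concs = regimen_arrays
    states, _, i_fin, _, _ = _simulate_batch(
        batch, event_times, event_doses, event_concs, np.array([t_star])
    )
    x = states[:, 0, :]
    # sum of right-hand sides collapses to kg (I V1 + U1) - kk V4
    return batch.kg * (i_fin * x[:, 0] + x[:, 1]) - batch.kk * x[:, 5]


# ---------------------------------------------------------------------------
# public single-subject interface


def _regimen_arrays(regimen: Regimen):
    return (
        np.asarray(regimen.times, float),
        np.asarray(regimen.doses, float),
        np.asarray(regimen.concentrations, float),
    )


def simulate(
    params: ModelParameters,
    regimen: Regimen,
    output_times: Sequence[float],
    method: str = "analytic",
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> Trajectory:
    """Simulate one subject under a radiation regimen.

    Parameters
    ----------
    params, regimen
        Subject parameters and dosing events.
    output_times
        Days in ``[0, horizon]``; at event times the post-impulse value is
        returned.
    method : {"analytic", "ivp"}
        ``"analytic"`` uses the exact piecewise closed form (default);
        ``"ivp"`` integrates each inter-impulse segment with a
        general-purpose stiff solver and exists as an independent
        cross-check.
    """
    out = np.asarray(output_times, dtype=float)
    if out.size and (out.min() < 0 or out.max() > regimen.horizon):
        raise ValueError("output_times must lie within [0, horizon]")
    if np.any(np.diff(out) < 0):
        out_sorted = np.sort(out)
    else:
        out_sorted = out
    ev_t, ev_d, ev_c = _regimen_arrays(regimen)

    if method == "analytic":
        batch = _Batch(params)
        states, d_acc, _, pre, post = _simulate_batch(
            batch, ev_t, ev_d, ev_c, out_sorted, capture_events=True
        )
        return Trajectory(
            times=out_sorted,
            states=states[0],
            d_acc=d_acc[0],
            event_times=ev_t,
            pre_event_states=pre[0] if len(ev_t) else np.empty((0, 6)),
            post_event_states=post[0] if len(ev_t) else np.empty((0, 6)),
        )
    if method == "ivp":
        return _simulate_ivp(params, regimen, out_sorted, rtol, atol)
    raise ConfigurationError(f"unknown method {method!r}")


def _simulate_ivp(params, regimen, out_times, rtol, atol):
    from scipy.integrate import solve_ivp

    ev_t, ev_d, ev_c = _regimen_arrays(regimen)
    state = initial_state(params)
    x = state.as_array()
    d_acc = 0.0
    i_cur = 1.0
    kg, kk = params.kg, params.kk

    def rhs(_, y, i_val):
        v1, u1, u2, v2, v3, v4 = y
        return [
            (kg * i_val - kk) * v1,
            -(kg + kk) * u1,
            2 * kg * u1 - kk * u2,
            kk * (v1 + u1 + u2) - kk * v2,
            kk * (v2 - v3),
            kk * (v3 - v4),
        ]

    # segment boundaries: 0, events, horizon
    bounds = np.concatenate([[0.0], ev_t, [regimen.horizon]])
    bounds = np.unique(bounds)
    states = np.empty((len(out_times), 6))
    d_out = np.empty(len(out_times))
    pre = np.empty((len(ev_t), 6))
    post = np.empty((len(ev_t), 6))
    ev_idx = {t: j for j, t in enumerate(ev_t)}

    filled = np.zeros(len(out_times), dtype=bool)
    if 0.0 in ev_idx:
        j = ev_idx[0.0]
        pre[j] = x
        f = fraction_killed(ev_d[j], ev_c[j], params)
        x[1] += f * x[0]
        x[0] *= 1.0 - f
        d_acc += ev_d[j]
        i_cur = inhibition(d_acc, ev_c[j], params)
        post[j] = x
    mask0 = out_times == 0.0
    states[mask0] = x
    d_out[mask0] = d_acc
    filled |= mask0

    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        sel = (~filled) & (out_times > t0) & (out_times < t1)
        t_eval = np.concatenate([out_times[sel], [t1]])
        sol = solve_ivp(
            rhs,
            (t0, t1),
            x,
            t_eval=np.unique(t_eval),
            args=(i_cur,),
            method="LSODA",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise SimulationError(
                f"integration failed on segment ({t0}, {t1}): {sol.message}",
                segment=(float(t0), float(t1)),
            )
        for tt, yy in zip(sol.t, sol.y.T):
            hit = (~filled) & (out_times == tt) & (out_times < t1)
            states[hit] = yy
            d_out[hit] = d_acc
            filled |= hit
        x = sol.y[:, -1].copy()
        j = ev_idx.get(float(t1))
        if j is not None:
            pre[j] = x
            f = fraction_killed(ev_d[j], ev_c[j], params)
            x[1] += f * x[0]
            x[0] *= 1.0 - f
            d_acc += ev_d[j]
            i_cur = inhibition(d_acc, ev_c[j], params)
            post[j] = x
        hit = (~filled) & (out_times == t1)
        states[hit] = x
        d_out[hit] = d_acc
        filled |= hit

    return Trajectory(
        times=out_times,
        states=states,
        d_acc=d_out,
        event_times=ev_t,
        pre_event_states=pre,
        post_event_states=post,
    )


def total_volume_derivative(
    params: ModelParameters, regimen: Regimen, t_star: float
) -> float:
    """Time derivative of the total volume at ``t_star`` [mm^3/day].

    Evaluated from the right-hand sides on the simulated state; the stasis
    condition of the TSE machinery is ``derivative <= epsilon``.
    """
    if t_star > regimen.horizon:
        raise ValueError("t_star beyond the regimen horizon")
    batch = _Batch(params)
    return float(_derivative_batch(batch, _regimen_arrays(regimen), t_star)[0])
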