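"""Tumor Static Exposure (TSE) curves and radiosensitizer ranking.

A TSE curve collects all exposure pairs ``(C, D_tot)`` — radiosensitizer
plasma concentration and total radiation dose under a fixed fractionation —
that hold the tumor at stasis.  Exposures above the curve predict shrinkage
and eventual eradication; below it, regrowth.  Three constructions are
provided:

* :func:`analytic_tse` — the closed form for the linear long-term
  inhibition, ``D_tot = dose_scale (1 - kk/kg) / (gamma (1 + b C))``,
  which ignores the short-term (per-fraction kill) effect;
* :func:`median_tse_curve` — simulation-based: the smallest ``C`` whose
  total-volume derivative at the evaluation time ``t*`` is at most
  ``epsilon``, solved per total dose for the median individual;
* :func:`percentile_tse_curve` — Monte-Carlo: the same search per virtual
  subject drawn from the population model, with the requested empirical
  percentile taken per dose.

All searches exploit the monotonicity of the stasis derivative in ``C`` and
in the total dose and run as lockstep bisection vectorized over subjects
(or over grid doses).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    ConfigurationError,
    ModelParameters,
    _Batch,
    _derivative_batch,
)
from .population import PopulationModel
from .schedules import weekday_fraction_times

__all__ = [
    "StasisProblem",
    "TSECurve",
    "UnsupportedVariantError",
    "UnboundedRequirementError",
    "analytic_tse",
    "stasis_concentration",
    "stasis_dose",
    "median_tse_curve",
    "percentile_tse_curve",
    "percentile_stasis_dose",
    "dose_at_concentration",
    "rank_compounds",
    "RankingResult",
    "default_dose_grid",
]


class UnsupportedVariantError(ConfigurationError):
    """The analytic curve exists only for the linear inhibition variant."""


class UnboundedRequirementError(RuntimeError):
    """No exposure within the configured bracket satisfies stasis."""


@dataclass(frozen=True)
class StasisProblem:
    """Configuration of the stasis search.

    The fractionation is fixed (default 5 fractions/week for 6 weeks; the
    total dose is split evenly over the fractions, weekend gaps preserved)
    and the stasis test is one-sided: total-volume derivative at ``t_star``
    at most ``epsilon`` [mm^3/day].
    """

    weeks: int = 6
    fractions_per_week: int = 5
    t_star: float = 60.0
    epsilon: float = 1e-4
    conc_upper: float = 1e4
    conc_tol: float = 1e-4
    dose_upper: float = 65536.0
    dose_tol: float = 0.01

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ConfigurationError("epsilon must be > 0")
        last = 7 * (self.weeks - 1) + self.fractions_per_week - 1
        if self.t_star <= last:
            raise ConfigurationError(
                f"t_star ({self.t_star}) must fall after the last fraction (day {last})"
            )

    @property
    def n_fractions(self) -> int:
        return self.weeks * self.fractions_per_week

    @property
    def fraction_times(self) -> np.ndarray:
        return weekday_fraction_times(self.weeks, self.fractions_per_week)


@dataclass(frozen=True)
class TSECurve:
    """Ordered stasis pairs tagged with a population percentile."""

    concentrations: np.ndarray
    total_doses: np.ndarray
    percentile: float | str  # fraction in (0, 1) or "median"
    method: str  # analytic | simulated_median | simulated_percentile
    t_star: float | None = None
    epsilon: float | None = None
    n_subjects: int | None = None
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        c = np.asarray(self.concentrations, float)
        d = np.asarray(self.total_doses, float)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "total_doses", d)
        if c.shape != d.shape or c.ndim != 1:
            raise ConfigurationError("curve needs matching 1-d arrays")
        if np.any(c < 0):
            raise ConfigurationError("concentrations must be >= 0")
        if np.any(np.diff(c) <= 0) or np.any(np.diff(d) >= 0):
            raise ConfigurationError(
                "total dose must be strictly decreasing in concentration"
            )

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.concentrations.tolist(), self.total_doses.tolist()))


def default_dose_grid() -> np.ndarray:
    """Total-dose grid 0-300 Gy in 5 Gy steps."""
    return np.arange(0.0, 305.0, 5.0)


# ---------------------------------------------------------------------------
# batched stasis searches


def _deriv(batch, problem, total_doses, concentrations):
    """Stasis derivative at t* for per-subject doses/concentrations."""
    times = problem.fraction_times
    m = len(times)
    doses = np.asarray(total_doses, float)[:, None] / m * np.ones(m)
    concs = np.asarray(concentrations, float)[:, None] * np.ones(m)
    return _derivative_batch(batch, (times, doses, concs), problem.t_star)


def _bisect(f, lo, hi, tol, max_iter=80):
    """Lockstep vector bisection for the smallest x with f(x) <= 0."""
    lo = lo.copy()
    hi = hi.copy()
    for _ in range(max_iter):
        if np.max(hi - lo) <= tol:
            break
        mid = 0.5 * (lo + hi)
        ok = f(mid) <= 0.0
        hi[ok] = mid[ok]
        lo[~ok] = mid[~ok]
    return hi


def _expand_bracket(f, start, upper, label, on_unbounded):
    """Per-subject upper bracket by doubling; inf where none exists."""
    hi = np.asarray(start, float).copy()
    active = f(hi) > 0.0
    while np.any(active & (hi < upper)):
        hi[active] = np.minimum(hi[active] * 2.0, upper)
        active = f(hi) > 0.0
    if np.any(active):
        if on_unbounded == "raise":
            raise UnboundedRequirementError(
                f"no {label} below {upper} reaches stasis for "
                f"{int(active.sum())} subject(s)"
            )
        hi[active] = np.inf
    return hi


def _stasis_conc_batch(batch, total_doses, problem, on_unbounded="raise"):
    """Smallest concentration with derivative <= epsilon, per subject."""
    total_doses = np.asarray(total_doses, float)
    f = lambda c: _deriv(batch, problem, total_doses, c) - problem.epsilon
    zero = np.zeros_like(total_doses)
    out = np.zeros_like(total_doses)
    need = f(zero) > 0.0
    if not np.any(need):
        return out
    hi = _expand_bracket(
        f, np.full_like(total_doses, 1.0), problem.conc_upper, "concentration",
        on_unbounded,
    )
    finite = np.isfinite(hi)
    sel = need & finite
    if np.any(sel):
        sub = _Batch(
            batch.template,
            gamma=batch.gamma[sel],
            alpha=batch.alpha[sel],
            v0=batch.v0[sel],
        )
        fsub = (
            lambda c: _deriv(sub, problem, total_doses[sel], c) - problem.epsilon
        )
        out[sel] = _bisect(
            fsub, np.zeros(sel.sum()), hi[sel], problem.conc_tol
        )
    out[~finite] = np.inf
    return out


def _stasis_dose_batch(batch, concentrations, problem, on_unbounded="raise"):
    """Smallest total dose with derivative <= epsilon, per subject."""
    concentrations = np.asarray(concentrations, float)
    f = lambda d: _deriv(batch, problem, d, concentrations) - problem.epsilon
    zero = np.zeros_like(concentrations)
    out = np.zeros_like(concentrations)
    need = f(zero) > 0.0
    if not np.any(need):
        return out
    hi = _expand_bracket(
        f, np.full_like(concentrations, 64.0), problem.dose_upper, "total dose",
        on_unbounded,
    )
    finite = np.isfinite(hi)
    sel = need & finite
    if np.any(sel):
        sub = _Batch(
            batch.template,
            gamma=batch.gamma[sel],
            alpha=batch.alpha[sel],
            v0=batch.v0[sel],
        )
        fsub = (
            lambda d: _deriv(sub, problem, d, concentrations[sel])
            - problem.epsilon
        )
        out[sel] = _bisect(
            fsub, np.zeros(sel.sum()), hi[sel], problem.dose_tol
        )
    out[~finite] = np.inf
    return out


# ---------------------------------------------------------------------------
# public operations


def analytic_tse(params: ModelParameters, concentration: float) -> float:
    """Total stasis dose [Gy] from the long-term-only closed form.

    Valid for the linear inhibition variant; the short-term (per-fraction)
    kill and hence the potency ``a`` do not enter.
    """
    if params.inhibition_kind != "linear":
        raise UnsupportedVariantError(
            "analytic TSE requires the linear inhibition variant"
        )
    denom = params.gamma * (1.0 + params.b * concentration)
    if denom <= 0:
        raise ConfigurationError("need gamma (1 + b C) > 0")
    return params.dose_scale * (1.0 - params.kk / params.kg) / denom


def stasis_concentration(
    params: ModelParameters, total_dose: float, problem: StasisProblem
) -> float:
    """Smallest concentration [ug/mL] giving stasis at ``total_dose``."""
    if total_dose < 0:
        raise ValueError("total_dose must be >= 0")
    batch = _Batch(params)
    return float(_stasis_conc_batch(batch, np.array([total_dose]), problem)[0])


def stasis_dose(
    params: ModelParameters, concentration: float, problem: StasisProblem
) -> float:
    """Smallest total dose [Gy] giving stasis at ``concentration``."""
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    batch = _Batch(params)
    return float(_stasis_dose_batch(batch, np.array([concentration]), problem)[0])


def _curve_from_pairs(conc, dose, **kw) -> TSECurve:
    """Assemble a curve from per-dose concentration requirements.

    Doses whose requirement is unbounded (inf) are dropped; ties in
    concentration (several doses already static drug-free) keep the lowest
    dose so the curve stays strictly monotone.
    """
    conc = np.asarray(conc, float)
    dose = np.asarray(dose, float)
    keep = np.isfinite(conc)
    conc, dose = conc[keep], dose[keep]
    order = np.argsort(dose)
    conc, dose = conc[order], dose[order]
    # walking up in dose, required concentration must not increase
    conc = np.minimum.accumulate(conc)
    uniq = np.ones(len(conc), dtype=bool)
    uniq[1:] = conc[1:] < conc[:-1]
    conc, dose = conc[uniq], dose[uniq]
    order = np.argsort(conc)
    return TSECurve(concentrations=conc[order], total_doses=dose[order], **kw)


def median_tse_curve(
    params: ModelParameters,
    dose_grid: np.ndarray | None = None,
    problem: StasisProblem | None = None,
) -> TSECurve:
    """Simulation-based TSE curve for the median individual."""
    problem = problem or StasisProblem()
    grid = default_dose_grid() if dose_grid is None else np.asarray(dose_grid, float)
    batch = _Batch(
        params,
        gamma=np.full(len(grid), params.gamma),
        alpha=np.full(len(grid), params.alpha),
        v0=np.full(len(grid), params.v0),
    )
    conc = _stasis_conc_batch(batch, grid, problem, on_unbounded="inf")
    return _curve_from_pairs(
        conc,
        grid,
        percentile="median",
        method="simulated_median",
        t_star=problem.t_star,
        epsilon=problem.epsilon,
    )


def _population_batch(pop, compound, n_subjects, seed, study):
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    eg, ea, ev = pop.sample_effects(rng, n_subjects)
    med = pop.median_parameters(study, compound)
    return _Batch(
        med, gamma=med.gamma * eg, alpha=med.alpha * ea, v0=med.v0 * ev
    )


def percentile_tse_curve(
    pop: PopulationModel,
    n_subjects: int,
    percentile: float,
    dose_grid: np.ndarray | None = None,
    problem: StasisProblem | None = None,
    seed: int = 0,
    compound: str | None = None,
    study: int = 3,
) -> TSECurve:
    """Monte-Carlo population-percentile TSE curve.

    Draws ``n_subjects`` virtual individuals (lognormal between-subject
    variability on gamma, alpha, v0 around the ``study`` covariate set) and
    takes the nearest-rank ``percentile`` of the per-subject concentration
    requirement at each grid dose.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if not 0.0 < percentile < 1.0:
        raise ValueError("percentile must be in (0, 1)")
    problem = problem or StasisProblem()
    grid = default_dose_grid() if dose_grid is None else np.asarray(dose_grid, float)
    batch = _population_batch(pop, compound, n_subjects, seed, study)
    conc_req = np.empty(len(grid))
    for j, dose in enumerate(grid):
        per_subject = _stasis_conc_batch(
            batch, np.full(batch.n, dose), problem, on_unbounded="inf"
        )
        conc_req[j] = np.quantile(per_subject, percentile, method="inverted_cdf")
    return _curve_from_pairs(
        conc_req,
        grid,
        percentile=percentile,
        method="simulated_percentile",
        t_star=problem.t_star,
        epsilon=problem.epsilon,
        n_subjects=n_subjects,
        seed=seed,
        metadata={"compound": compound, "study": study},
    )


def percentile_stasis_dose(
    pop: PopulationModel,
    concentration: float,
    percentile: float,
    n_subjects: int,
    problem: StasisProblem | None = None,
    seed: int = 0,
    compound: str | None = None,
    study: int = 3,
) -> float:
    """Dose covering ``percentile`` of the population at a concentration.

    Per virtual subject, the smallest total dose reaching stasis at the
    given constant concentration is found by bisection; the nearest-rank
    percentile of that dose distribution is returned.  At ``concentration
    = 0`` this is the radiation-alone requirement (the curve's axis
    crossing).
    """
    if not 0.0 < percentile < 1.0:
        raise ValueError("percentile must be in (0, 1)")
    problem = problem or StasisProblem()
    batch = _population_batch(pop, compound, n_subjects, seed, study)
    doses = _stasis_dose_batch(
        batch, np.full(batch.n, float(concentration)), problem
    )
    return float(np.quantile(doses, percentile, method="inverted_cdf"))


def dose_at_concentration(curve: TSECurve, concentration: float) -> float:
    """Interpolated total dose on the curve at a concentration."""
    c = curve.concentrations
    if not c[0] <= concentration <= c[-1]:
        raise ValueError(
            f"concentration {concentration} outside curve range [{c[0]}, {c[-1]}]"
        )
    return float(np.interp(concentration, c, curve.total_doses))


@dataclass(frozen=True)
class RankingResult:
    """Compounds ordered by required dose (ascending = most potent first)."""

    order: tuple[str, ...]
    doses: dict
    concentration: float
    tie: bool = False


def rank_compounds(
    curves: dict[str, TSECurve], concentration: float, tie_tol: float = 1e-6
) -> RankingResult:
    """Rank compounds by the dose their TSE curves require at ``C``.

    All curves must share percentile and method (a common population model
    and schedule is the caller's contract).  Ties within ``tie_tol`` Gy are
    flagged and reported in input order.
    """
    tags = {(c.percentile, c.method) for c in curves.values()}
    if len(tags) > 1:
        raise ConfigurationError(
            "curves must share percentile and method to be ranked"
        )
    doses = {
        name: dose_at_concentration(curve, concentration)
        for name, curve in curves.items()
    }
    names = list(curves)
    order = sorted(names, key=lambda n: (doses[n], names.index(n)))
    vals = sorted(doses.values())
    tie = any(b - a <= tie_tol for a, b in zip(vals, vals[1:]))
    return RankingResult(
        order=tuple(order), doses=doses, concentration=concentration, tie=tie
    )
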