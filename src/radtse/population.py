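"""Population model and synthetic xenograft-study generator.

The population structure is a nonlinear mixed-effects (NLME) model: the
long-term inhibition coefficient ``gamma`` and the initial proliferating
volume ``v0`` have study-specific medians (inter-study variability as fixed
study covariates), and ``gamma``, ``alpha`` and ``v0`` carry independent
lognormal between-subject variability:

    gamma_j = gamma_{study(j)} * exp(eta_j),   eta_j ~ N(0, omega_gamma^2)

Observations carry a combined residual error
``y = f (1 + e1) + e2`` with ``e1 ~ N(0, sigma_prop^2)`` (proportional,
fraction) and ``e2 ~ N(0, sigma_add^2)`` (additive, mm^3), truncated at zero.

The generator emulates the three xenograft studies the model family was
built for: groups of 9-10 animals, 2 Gy fractions Monday-Friday for 1 or 6
weeks, twice-weekly caliper volumes, and a constant per-application
radiosensitizer concentration per arm (the arm's mean C_max).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import ConfigurationError, ModelParameters, Regimen, _Batch, _simulate_batch
from .schedules import mon_fri_regimen

__all__ = [
    "PopulationModel",
    "Arm",
    "StudyDesign",
    "SyntheticDataset",
    "sample_subject",
    "apply_residual_error",
    "synthesize_study",
    "synthesize_studies",
    "eradication_fraction",
]


@dataclass(frozen=True)
class PopulationModel:
    """Medians, between-subject variability and residual error magnitudes."""

    kg: float
    kk: float
    alpha: float
    gamma_by_study: tuple[float, float, float]
    v0_by_study: tuple[float, float, float]
    potencies: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    omega_gamma: float = 0.0
    omega_alpha: float = 0.0
    omega_v0: float = 0.0
    sigma_prop: float = 0.0
    sigma_add: float = 0.0
    inhibition_kind: str = "linear"
    id50: float | None = None
    alpha_beta_ratio: float = 10.0
    dose_scale: float = 10.0

    def __post_init__(self):
        for name in ("omega_gamma", "omega_alpha", "omega_v0", "sigma_prop", "sigma_add"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.kg <= 0 or not 0 <= self.kk < self.kg:
            raise ConfigurationError("need kg > 0 and 0 <= kk < kg")
        if any(g <= 0 for g in self.gamma_by_study) or any(
            v <= 0 for v in self.v0_by_study
        ):
            raise ConfigurationError("study medians must be positive")

    def compound_potency(self, compound: str | None) -> tuple[float, float]:
        if compound is None:
            return (0.0, 0.0)
        try:
            return tuple(self.potencies[compound])
        except KeyError:
            raise ConfigurationError(f"unknown compound {compound!r}") from None

    def median_parameters(
        self, study: int, compound: str | None = None
    ) -> ModelParameters:
        """The median individual of ``study`` (1-based), optionally dosed."""
        a, b = self.compound_potency(compound)
        return ModelParameters(
            kg=self.kg,
            kk=self.kk,
            alpha=self.alpha,
            gamma=self.gamma_by_study[_study_index(study)],
            v0=self.v0_by_study[_study_index(study)],
            alpha_beta_ratio=self.alpha_beta_ratio,
            a=a,
            b=b,
            inhibition_kind=self.inhibition_kind,
            id50=self.id50,
            dose_scale=self.dose_scale,
        )

    def sample_effects(
        self, rng: np.random.Generator, size: int
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Lognormal multipliers ``exp(eta)`` for (gamma, alpha, v0)."""
        eg = np.exp(rng.normal(0.0, self.omega_gamma, size))
        ea = np.exp(rng.normal(0.0, self.omega_alpha, size))
        ev = np.exp(rng.normal(0.0, self.omega_v0, size))
        return eg, ea, ev


def _study_index(study: int) -> int:
    if study not in (1, 2, 3):
        raise ConfigurationError(f"study must be 1, 2 or 3, got {study}")
    return study - 1


def sample_subject(
    pop: PopulationModel,
    study: int,
    rng: np.random.Generator,
    compound: str | None = None,
) -> ModelParameters:
    """Draw one virtual subject from the population of ``study``."""
    eg, ea, ev = pop.sample_effects(rng, 1)
    med = pop.median_parameters(study, compound)
    return med.replace(
        gamma=med.gamma * float(eg[0]),
        alpha=med.alpha * float(ea[0]),
        v0=med.v0 * float(ev[0]),
    )


def apply_residual_error(
    true_volume, pop: PopulationModel, rng: np.random.Generator
):
    """Observed volume(s) under the combined error model, truncated at 0."""
    f = np.asarray(true_volume, dtype=float)
    if np.any(f < 0):
        raise ValueError("true volumes must be >= 0")
    e1 = rng.normal(0.0, pop.sigma_prop, f.shape)
    e2 = rng.normal(0.0, pop.sigma_add, f.shape)
    y = f * (1.0 + e1) + e2
    out = np.maximum(y, 0.0)
    return out if out.shape else float(out)


@dataclass(frozen=True)
class Arm:
    """One treatment group of a study design.

    ``concentration`` is the constant per-application radiosensitizer
    plasma level [ug/mL] (the arm's mean C_max); vehicle arms carry
    ``radiation=False``.
    """

    name: str
    compound: str | None
    concentration: float
    n_subjects: int
    radiation: bool = True
    dose_label: str = ""
    observation_days: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ConfigurationError("arm needs n_subjects >= 1")
        if self.concentration < 0:
            raise ConfigurationError("concentration must be >= 0")


@dataclass(frozen=True)
class StudyDesign:
    """Arms, fractionation and observation grid of one xenograft study."""

    study: int
    weeks: int
    fraction_dose: float
    arms: tuple[Arm, ...]
    observation_days: tuple[float, ...]

    def __post_init__(self):
        _study_index(self.study)
        if list(self.observation_days) != sorted(self.observation_days):
            raise ConfigurationError("observation days must be sorted")
        if len(self.observation_days) < 2:
            raise ConfigurationError("need at least two observation days")

    def arm_observation_days(self, arm: Arm) -> tuple[float, ...]:
        return arm.observation_days or self.observation_days

    def arm_regimen(self, arm: Arm) -> Regimen:
        days = self.arm_observation_days(arm)
        horizon = float(days[-1])
        if not arm.radiation:
            return Regimen.untreated(horizon)
        return mon_fri_regimen(
            self.weeks,
            self.fraction_dose,
            concentration=arm.concentration,
            horizon=horizon,
        )

    def get_arm(self, name: str) -> Arm:
        for arm in self.arms:
            if arm.name == name:
                return arm
        raise ConfigurationError(f"no arm named {name!r}")


def twice_weekly_days(horizon: float, start: float = 0.0) -> tuple[float, ...]:
    """Twice-weekly observation grid ``start, +3, +7, +10, ...``."""
    days = []
    week = start
    while week <= horizon:
        days.append(week)
        if week + 3 <= horizon:
            days.append(week + 3)
        week += 7
    return tuple(days)


@dataclass(frozen=True)
class SyntheticDataset:
    """Long-format synthetic observations plus the generating truth."""

    observations: pd.DataFrame  # study, arm, subject, time_day, volume_mm3
    true_parameters: pd.DataFrame  # per-subject structural parameters
    seed: int

    def __post_init__(self):
        if (self.observations["volume_mm3"] < 0).any():
            raise ConfigurationError("observed volumes must be >= 0")
        counts = self.observations.groupby("subject").size()
        if (counts < 2).any():
            raise ConfigurationError("every subject needs >= 2 observations")


def _synthesize_arm(pop, design, arm, rng_params, rng_resid, subject_offset):
    """Simulate one arm; returns (obs rows, truth rows)."""
    n = arm.n_subjects
    eg, ea, ev = pop.sample_effects(rng_params, n)
    med = pop.median_parameters(design.study, arm.compound)
    gamma = med.gamma * eg
    alpha = med.alpha * ea
    v0 = med.v0 * ev
    batch = _Batch(med, gamma=gamma, alpha=alpha, v0=v0)
    regimen = design.arm_regimen(arm)
    days = np.asarray(design.arm_observation_days(arm), float)
    states, _, _, _, _ = _simulate_batch(
        batch,
        np.asarray(regimen.times, float),
        np.asarray(regimen.doses, float),
        np.asarray(regimen.concentrations, float),
        days,
    )
    truth = states.sum(axis=2)  # (n, T)
    observed = apply_residual_error(truth, pop, rng_resid)

    obs_rows = pd.DataFrame(
        {
            "study": design.study,
            "arm": arm.name,
            "subject": np.repeat(
                [f"s{design.study}_{arm.name}_{subject_offset + i}" for i in range(n)],
                len(days),
            ),
            "time_day": np.tile(days, n),
            "volume_mm3": observed.ravel(),
        }
    )
    truth_rows = pd.DataFrame(
        {
            "study": design.study,
            "arm": arm.name,
            "subject": [
                f"s{design.study}_{arm.name}_{subject_offset + i}" for i in range(n)
            ],
            "gamma": gamma,
            "alpha": alpha,
            "v0": v0,
            "a": med.a,
            "b": med.b,
            "concentration": arm.concentration if arm.radiation else 0.0,
        }
    )
    return obs_rows, truth_rows


def synthesize_study(
    pop: PopulationModel, design: StudyDesign, seed: int
) -> SyntheticDataset:
    """Generate one fully synthetic study; bit-reproducible under ``seed``.

    The master seed is split into independent substreams per arm
    (parameter draws and residual draws separately), so individual arms can
    be regenerated without simulating the others.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * len(design.arms))
    obs_frames, truth_frames = [], []
    offset = 0
    for j, arm in enumerate(design.arms):
        rng_params = np.random.default_rng(children[2 * j])
        rng_resid = np.random.default_rng(children[2 * j + 1])
        obs, truth = _synthesize_arm(pop, design, arm, rng_params, rng_resid, offset)
        obs_frames.append(obs)
        truth_frames.append(truth)
        offset += arm.n_subjects
    return SyntheticDataset(
        observations=pd.concat(obs_frames, ignore_index=True),
        true_parameters=pd.concat(truth_frames, ignore_index=True),
        seed=seed,
    )


def synthesize_studies(
    pop: PopulationModel, designs: Sequence[StudyDesign], seed: int
) -> SyntheticDataset:
    """Generate several studies under one master seed."""
    sub_seeds = np.random.SeedSequence(seed).generate_state(len(designs))
    parts = [
        synthesize_study(pop, d, int(s)) for d, s in zip(designs, sub_seeds)
    ]
    return SyntheticDataset(
        observations=pd.concat(
            [p.observations for p in parts], ignore_index=True
        ),
        true_parameters=pd.concat(
            [p.true_parameters for p in parts], ignore_index=True
        ),
        seed=seed,
    )


def eradication_fraction(
    pop: PopulationModel,
    design: StudyDesign,
    arm: Arm | str,
    n: int,
    seed: int,
    threshold: float = 1.0,
) -> float:
    """Fraction of simulated subjects eradicated at study end.

    Eradication is a noise-free end-of-study total volume below
    ``threshold`` mm^3 (default 1 mm^3).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(arm, str):
        arm = design.get_arm(arm)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    eg, ea, ev = pop.sample_effects(rng, n)
    med = pop.median_parameters(design.study, arm.compound)
    batch = _Batch(
        med, gamma=med.gamma * eg, alpha=med.alpha * ea, v0=med.v0 * ev
    )
    regimen = design.arm_regimen(arm)
    end = design.arm_observation_days(arm)[-1]
    states, _, _, _, _ = _simulate_batch(
        batch,
        np.asarray(regimen.times, float),
        np.asarray(regimen.doses, float),
        np.asarray(regimen.concentrations, float),
        np.array([end], float),
    )
    return float(np.mean(states[:, 0, :].sum(axis=1) < threshold))
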