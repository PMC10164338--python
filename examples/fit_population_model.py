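"""Fit the population model to synthetic data and check recovery.

Generates a reduced two-study dataset from known parameters, refits it
with the FOCE-type Laplace estimator from deliberately perturbed starting
values, and prints estimate vs truth.  Run time is a minute or two.
"""

import dataclasses

import numpy as np

from radtse import FitSettings, fit_population, synthesize_studies, twice_weekly_days
from radtse.io import published_population
from radtse.population import Arm, StudyDesign

truth = dataclasses.replace(
    published_population(), potencies={}  # radiation-only arms below
)

designs = [
    StudyDesign(
        study=1, weeks=6, fraction_dose=2.0,
        observation_days=twice_weekly_days(84.0),
        arms=(
            Arm("vehicle", None, 0.0, 6, radiation=False,
                observation_days=twice_weekly_days(24.0)),
            Arm("rt", None, 0.0, 12),
        ),
    ),
    StudyDesign(
        study=3, weeks=6, fraction_dose=2.0,
        observation_days=twice_weekly_days(84.0),
        arms=(Arm("rt", None, 0.0, 12),),
    ),
]

dataset = synthesize_studies(truth, designs, seed=11)
init = dataclasses.replace(
    truth,
    kg=truth.kg * 1.3, kk=truth.kk * 1.3, alpha=truth.alpha * 0.7,
    gamma_by_study=tuple(g * 1.3 for g in truth.gamma_by_study),
    v0_by_study=tuple(v * 0.8 for v in truth.v0_by_study),
    omega_gamma=0.4, omega_alpha=0.4, omega_v0=0.3,
    sigma_prop=0.25, sigma_add=3.0,
)
result = fit_population(
    dataset, designs, init,
    FitSettings(fixed=("gamma_2", "v0_2")),  # study 2 absent from the data
)

print(f"-2 ln L (Laplace) = {result.objective:.1f}, AIC = {result.aic:.1f}\n")
ref = {
    "kg": truth.kg, "kk": truth.kk, "alpha": truth.alpha,
    "gamma_1": truth.gamma_by_study[0], "gamma_3": truth.gamma_by_study[2],
    "v0_1": truth.v0_by_study[0], "v0_3": truth.v0_by_study[2],
    "omega_gamma": truth.omega_gamma, "omega_alpha": truth.omega_alpha,
    "omega_v0": truth.omega_v0, "sigma_prop": truth.sigma_prop,
    "sigma_add": truth.sigma_add,
}
print("parameter     estimate     truth    error")
for name, est in result.estimates.items():
    t = ref[name]
    print(f"{name:12s} {est:9.4f} {t:9.4f} {100*(est/t-1):+7.1f}%")
print("\nShrinkage per random effect:", {
    k: round(v, 2) for k, v in result.shrinkage.items()
})
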