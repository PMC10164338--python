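"""File formats, bundled reference fixtures and run configuration.

Flat JSON documents hold parameters (single-subject or population),
delimited UTF-8 CSV tables hold regimens, trajectories, observations and
TSE curves (curves get a JSON metadata sidecar).  The published parameter
set and the three xenograft study designs ship with the package so nothing
needs downloading.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .model import ConfigurationError, ModelParameters, Regimen, Trajectory
from .population import Arm, PopulationModel, StudyDesign, SyntheticDataset, twice_weekly_days
from .tse import TSECurve

__all__ = [
    "RunConfig",
    "published_population",
    "default_study_designs",
    "load_parameters",
    "save_parameters",
    "load_regimen",
    "save_regimen",
    "save_trajectory",
    "save_curve",
    "load_curve",
    "save_dataset",
    "load_dataset",
]

log = logging.getLogger("radtse")

_POP_REQUIRED = ("kg", "kk", "alpha", "gamma1", "v0_1")
_SUBJ_REQUIRED = ("kg", "kk", "alpha", "gamma", "v0")


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of a reproducible run."""

    seed: int = 0
    t_star: float = 60.0
    epsilon: float = 1e-4
    n_subjects: int = 1000
    percentiles: tuple[float, ...] = (0.95,)
    dose_grid_max: float = 300.0
    dose_grid_step: float = 5.0
    output_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self):
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ConfigurationError("seed must be a non-negative integer")
        if any(not 0 < p < 1 for p in self.percentiles):
            raise ConfigurationError("percentiles must lie in (0, 1)")


def _read_json(path):
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)


def _population_from_dict(doc: dict) -> PopulationModel:
    for key in _POP_REQUIRED:
        if key not in doc:
            raise ConfigurationError(f"parameter file is missing field {key!r}")
    gammas = tuple(doc.get(f"gamma{k}", doc["gamma1"]) for k in (1, 2, 3))
    v0s = tuple(doc.get(f"v0_{k}", doc["v0_1"]) for k in (1, 2, 3))
    compounds = sorted(
        {k.split("_", 1)[1] for k in doc if k.startswith(("a_", "b_"))}
    )
    potencies = {
        c: (float(doc.get(f"a_{c}", 0.0)), float(doc.get(f"b_{c}", 0.0)))
        for c in compounds
    }
    sigma_prop = float(doc.get("sigma_prop", 0.0))
    if sigma_prop > 0:
        log.info(
            "sigma_prop=%.3g interpreted as a fraction (%.0f%% CV)",
            sigma_prop,
            100 * sigma_prop,
        )
    log.info(
        "gamma values are per %s Gy of accumulated dose (dose_scale)",
        doc.get("dose_scale", 10.0),
    )
    return PopulationModel(
        kg=float(doc["kg"]),
        kk=float(doc["kk"]),
        alpha=float(doc["alpha"]),
        gamma_by_study=tuple(float(g) for g in gammas),
        v0_by_study=tuple(float(v) for v in v0s),
        potencies=potencies,
        omega_gamma=float(doc.get("omega_gamma", 0.0)),
        omega_alpha=float(doc.get("omega_alpha", 0.0)),
        omega_v0=float(doc.get("omega_v0", 0.0)),
        sigma_prop=sigma_prop,
        sigma_add=float(doc.get("sigma_add", 0.0)),
        inhibition_kind=doc.get("inhibition_kind", "linear"),
        id50=doc.get("id50"),
        alpha_beta_ratio=float(doc.get("alpha_beta_ratio", 10.0)),
        dose_scale=float(doc.get("dose_scale", 10.0)),
    )


def _subject_from_dict(doc: dict) -> ModelParameters:
    for key in _SUBJ_REQUIRED:
        if key not in doc:
            raise ConfigurationError(f"parameter file is missing field {key!r}")
    return ModelParameters(
        kg=float(doc["kg"]),
        kk=float(doc["kk"]),
        alpha=float(doc["alpha"]),
        gamma=float(doc["gamma"]),
        v0=float(doc["v0"]),
        alpha_beta_ratio=float(doc.get("alpha_beta_ratio", 10.0)),
        a=float(doc.get("a", 0.0)),
        b=float(doc.get("b", 0.0)),
        inhibition_kind=doc.get("inhibition_kind", "linear"),
        id50=doc.get("id50"),
        dose_scale=float(doc.get("dose_scale", 10.0)),
    )


def load_parameters(path) -> ModelParameters | PopulationModel:
    """Load a flat JSON parameter document.

    Files with study-indexed medians (``gamma1``, ``v0_1``...) yield a
    :class:`PopulationModel`; files with plain ``gamma``/``v0`` yield a
    single-subject :class:`ModelParameters`.
    """
    doc = _read_json(path)
    if not isinstance(doc, dict):
        raise ConfigurationError("parameter file must hold a JSON object")
    if "gamma" in doc:
        return _subject_from_dict(doc)
    return _population_from_dict(doc)


def save_parameters(obj: ModelParameters | PopulationModel, path) -> None:
    if isinstance(obj, ModelParameters):
        doc = dataclasses.asdict(obj)
    else:
        doc = {
            "kg": obj.kg,
            "kk": obj.kk,
            "alpha": obj.alpha,
            "omega_gamma": obj.omega_gamma,
            "omega_alpha": obj.omega_alpha,
            "omega_v0": obj.omega_v0,
            "sigma_prop": obj.sigma_prop,
            "sigma_add": obj.sigma_add,
            "alpha_beta_ratio": obj.alpha_beta_ratio,
            "dose_scale": obj.dose_scale,
            "inhibition_kind": obj.inhibition_kind,
        }
        if obj.id50 is not None:
            doc["id50"] = obj.id50
        for k in (1, 2, 3):
            doc[f"gamma{k}"] = obj.gamma_by_study[k - 1]
            doc[f"v0_{k}"] = obj.v0_by_study[k - 1]
        for comp, (a, b) in obj.potencies.items():
            doc[f"a_{comp}"] = a
            doc[f"b_{comp}"] = b
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def published_population() -> PopulationModel:
    """The bundled reference parameter set (three-study population)."""
    with resources.files("radtse.data").joinpath("published_params.json").open() as fh:
        return _population_from_dict(json.load(fh))


def default_study_designs() -> list[StudyDesign]:
    """The three bundled xenograft study designs.

    Mon-Fri 2 Gy fractions for 1 or 6 weeks, twice-weekly observations,
    per-arm mean C_max as the constant radiosensitizer exposure; vehicle
    arms are followed for a shorter window (they grow unchecked).
    """
    with resources.files("radtse.data").joinpath("study_designs.json").open() as fh:
        doc = json.load(fh)
    designs = []
    for sd in doc["studies"]:
        default_days = twice_weekly_days(float(sd["observation_horizon_day"]))
        arms = []
        for a in sd["arms"]:
            days = None
            if "observation_horizon_day" in a:
                days = twice_weekly_days(float(a["observation_horizon_day"]))
            arms.append(
                Arm(
                    name=a["name"],
                    compound=a["compound"],
                    concentration=float(a["cmax_ug_ml"]),
                    n_subjects=int(a["n_subjects"]),
                    radiation=bool(a["radiation"]),
                    dose_label=f"{a['dose_mg_kg']} mg/kg",
                    observation_days=days,
                )
            )
        designs.append(
            StudyDesign(
                study=int(sd["study"]),
                weeks=int(sd["weeks"]),
                fraction_dose=float(sd["fraction_dose_gy"]),
                arms=tuple(arms),
                observation_days=default_days,
            )
        )
    return designs


# ---------------------------------------------------------------------------
# delimited tables


def save_regimen(regimen: Regimen, path) -> None:
    pd.DataFrame(
        {
            "time_day": regimen.times,
            "dose_gy": regimen.doses,
            "conc_ug_ml": regimen.concentrations,
        }
    ).to_csv(path, index=False)


def load_regimen(path, horizon: float | None = None) -> Regimen:
    df = pd.read_csv(path)
    for col in ("time_day", "dose_gy", "conc_ug_ml"):
        if col not in df.columns:
            raise ConfigurationError(f"regimen file is missing column {col!r}")
    if horizon is None:
        horizon = float(df["time_day"].max()) + 21.0 if len(df) else 21.0
    return Regimen(
        times=tuple(df["time_day"].astype(float)),
        doses=tuple(df["dose_gy"].astype(float)),
        concentrations=tuple(df["conc_ug_ml"].astype(float)),
        horizon=horizon,
    )


def save_trajectory(traj: Trajectory, path) -> None:
    df = pd.DataFrame(
        traj.states[:, [0, 3, 4, 5, 1, 2]],
        columns=["v1", "v2", "v3", "v4", "u1", "u2"],
    )
    df.insert(0, "time_day", traj.times)
    df["v_tot"] = traj.total_volume
    df.to_csv(path, index=False)


def save_curve(curve: TSECurve, path) -> None:
    """CSV of the stasis pairs plus a ``.meta.json`` sidecar."""
    path = Path(path)
    pd.DataFrame(
        {
            "conc_ug_ml": curve.concentrations,
            "total_dose_gy": curve.total_doses,
        }
    ).to_csv(path, index=False)
    meta = {
        "percentile": curve.percentile,
        "method": curve.method,
        "t_star": curve.t_star,
        "epsilon": curve.epsilon,
        "n_subjects": curve.n_subjects,
        "seed": curve.seed,
        "metadata": curve.metadata,
    }
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1)
        fh.write("\n")


def load_curve(path) -> TSECurve:
    path = Path(path)
    df = pd.read_csv(path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = _read_json(meta_path) if meta_path.exists() else {}
    return TSECurve(
        concentrations=df["conc_ug_ml"].to_numpy(float),
        total_doses=df["total_dose_gy"].to_numpy(float),
        percentile=meta.get("percentile", "median"),
        method=meta.get("method", "simulated_median"),
        t_star=meta.get("t_star"),
        epsilon=meta.get("epsilon"),
        n_subjects=meta.get("n_subjects"),
        seed=meta.get("seed"),
        metadata=meta.get("metadata") or {},
    )


def save_dataset(dataset: SyntheticDataset, path, truth_path=None) -> None:
    dataset.observations.to_csv(path, index=False)
    if truth_path is not None:
        dataset.true_parameters.to_csv(truth_path, index=False)


def load_dataset(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"study", "arm", "subject", "time_day", "volume_mm3"}
    missing = needed - set(df.columns)
    if missing:
        raise ConfigurationError(f"dataset is missing columns {sorted(missing)}")
    return df
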