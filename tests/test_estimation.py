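"""Individual and population fits, model selection, VPC and sensitivity."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from radtse import (
    FitSettings,
    ModelParameters,
    Regimen,
    fit_individual,
    fit_population,
    local_sensitivity,
    mon_fri_regimen,
    select_inhibition_variant,
    simulate,
    twice_weekly_days,
    vpc_summary,
)
from radtse.estimation import _predict_arm
from radtse.population import Arm, StudyDesign, synthesize_studies, synthesize_study


@pytest.fixture(scope="module")
def small_designs():
    """A reduced two-study layout used for fast estimator checks."""
    d1 = StudyDesign(
        study=1,
        weeks=6,
        fraction_dose=2.0,
        observation_days=twice_weekly_days(84.0),
        arms=(
            Arm("vehicle", None, 0.0, 4, radiation=False,
                observation_days=twice_weekly_days(24.0)),
            Arm("rt", None, 0.0, 6),
        ),
    )
    d3 = StudyDesign(
        study=3,
        weeks=6,
        fraction_dose=2.0,
        observation_days=twice_weekly_days(84.0),
        arms=(Arm("rt", None, 0.0, 6),),
    )
    return [d1, d3]


class TestFitIndividual:
    def test_noise_free_recovery(self, pop):
        """With additive-only error the likelihood optimum sits exactly at
        the generating parameters."""
        truth = pop.median_parameters(1).replace(gamma=0.035, alpha=0.08, v0=30.0)
        reg = mon_fri_regimen(6, 2.0, horizon=84.0)
        days = np.array(twice_weekly_days(84.0))
        f = _predict_arm(truth, truth.gamma, truth.alpha, truth.v0, reg, days)[0]
        obs = pd.DataFrame({"time_day": days, "volume_mm3": f})
        fit = fit_individual(obs, reg, pop.median_parameters(1), 0.0, 1.0)
        assert fit.parameters.gamma == pytest.approx(truth.gamma, rel=1e-3)
        assert fit.parameters.alpha == pytest.approx(truth.alpha, rel=1e-3)
        assert fit.parameters.v0 == pytest.approx(truth.v0, rel=1e-3)
        assert not fit.unidentifiable

    def test_vehicle_subject_flags_radiation_parameters(self, median1):
        reg = Regimen.untreated(24.0)
        days = np.array(twice_weekly_days(24.0))
        f = _predict_arm(median1, median1.gamma, median1.alpha, median1.v0, reg, days)[0]
        obs = pd.DataFrame({"time_day": days, "volume_mm3": f})
        fit = fit_individual(obs, reg, median1.replace(v0=40.0), 0.0, 1.0)
        assert set(fit.unidentifiable) == {"gamma", "alpha"}
        assert fit.parameters.v0 == pytest.approx(median1.v0, rel=1e-3)

    def test_objective_equals_hand_computed_gaussian_deviance(self, median1):
        reg = Regimen.untreated(15.0)
        days = np.array([0.0, 5.0, 10.0, 15.0])
        f = _predict_arm(median1, median1.gamma, median1.alpha, median1.v0, reg, days)[0]
        y = f * np.array([1.05, 0.97, 1.01, 0.97])
        obs = pd.DataFrame({"time_day": days, "volume_mm3": y})
        sp, sa = 0.2, 2.0
        fit = fit_individual(obs, reg, median1, sp, sa)
        fhat = _predict_arm(
            fit.parameters, fit.parameters.gamma, fit.parameters.alpha,
            fit.parameters.v0, reg, days,
        )[0]
        var = (sp * fhat) ** 2 + sa**2
        by_hand = float(np.sum(np.log(2 * np.pi * var) + (y - fhat) ** 2 / var))
        assert fit.objective == pytest.approx(by_hand, rel=1e-9)

    def test_too_few_observations_rejected(self, median1):
        obs = pd.DataFrame({"time_day": [0.0, 3.0, 7.0], "volume_mm3": [50.0] * 3})
        with pytest.raises(ValueError, match="4 observations"):
            fit_individual(obs, Regimen.untreated(10.0), median1, 0.1, 1.0)


class TestFitPopulation:
    def test_zero_bsv_reduces_to_pooled_fit(self, pop, small_designs):
        """With all omegas at zero the Laplace objective collapses to a
        pooled fixed-effects Gaussian deviance."""
        frozen = dataclasses.replace(
            pop, omega_gamma=0.0, omega_alpha=0.0, omega_v0=0.0,
            sigma_prop=0.1, sigma_add=1.0,
        )
        ds = synthesize_studies(frozen, small_designs, seed=21)
        settings = FitSettings(
            fixed=("sigma_prop", "sigma_add", "gamma_2", "v0_2"), max_iter=60
        )
        res = fit_population(ds, small_designs, frozen, settings)
        assert res.n_parameters == 7  # kg, kk, alpha, gamma_1/3, v0_1/3
        assert (res.ebes[["eta_gamma", "eta_alpha", "eta_v0"]] == 0).all().all()
        # pooled deviance by hand at the fitted point
        fitted = res.population_model(frozen)
        dev = 0.0
        for d in small_designs:
            for arm in d.arms:
                sel = ds.observations[
                    (ds.observations.study == d.study)
                    & (ds.observations.arm == arm.name)
                ]
                med = fitted.median_parameters(d.study, arm.compound)
                days = np.array(sorted(sel.time_day.unique()))
                f = _predict_arm(med, med.gamma, med.alpha, med.v0,
                                 d.arm_regimen(arm), days)[0]
                fmap = dict(zip(days, f))
                fh = sel.time_day.map(fmap).to_numpy()
                y = sel.volume_mm3.to_numpy()
                var = (0.1 * fh) ** 2 + 1.0
                dev += np.sum(np.log(2 * np.pi * var) + (y - fh) ** 2 / var)
        assert res.objective == pytest.approx(dev, rel=1e-6)

    def test_estimates_invariant_to_row_order(self, pop, small_designs):
        frozen = dataclasses.replace(
            pop, omega_alpha=0.0, omega_v0=0.0, sigma_prop=0.1, sigma_add=1.0
        )
        ds = synthesize_studies(frozen, small_designs, seed=22)
        settings = FitSettings(
            fixed=("sigma_prop", "sigma_add", "gamma_2", "v0_2",
                   "omega_gamma", "omega_alpha", "omega_v0"),
            max_iter=40,
        )
        a = fit_population(ds, small_designs, frozen, settings)
        shuffled = ds.observations.sample(frac=1.0, random_state=0).reset_index(
            drop=True
        )
        b = fit_population(shuffled, small_designs, frozen, settings)
        for k in a.estimates:
            assert a.estimates[k] == pytest.approx(b.estimates[k], rel=1e-9)

    def test_laplace_matches_quadrature_for_rich_data(self, pop, small_designs):
        """The reported quadrature deviance stays close to the Laplace one
        when the per-subject information is strong."""
        mild = dataclasses.replace(
            pop, omega_gamma=0.2, omega_alpha=0.1, omega_v0=0.1,
            sigma_prop=0.1, sigma_add=1.0,
        )
        ds = synthesize_studies(mild, small_designs, seed=23)
        settings = FitSettings(
            fixed=("sigma_prop", "sigma_add", "gamma_2", "v0_2",
                   "omega_gamma", "omega_alpha", "omega_v0"),
            max_iter=60,
        )
        res = fit_population(ds, small_designs, mild, settings)
        assert abs(res.objective_agq - res.objective) < 0.01 * abs(res.objective)


class TestModelSelection:
    def test_aic_definition_and_tie_break(self, pop, small_designs, monkeypatch):
        import radtse.estimation as est

        fakes = {
            "linear": est.FitResult({}, {}, pd.DataFrame(), 100.0, 100.0, 108.0,
                                    4, 10, True, {}),
            "saturating": est.FitResult({}, {}, pd.DataFrame(), 98.0, 98.0, 108.0,
                                        5, 10, True, {}),
        }

        def fake_fit(dataset, designs, init, settings=None):
            return fakes[init.inhibition_kind]

        monkeypatch.setattr(est, "fit_population", fake_fit)
        inits = {
            "linear": pop,
            "saturating": dataclasses.replace(
                pop, inhibition_kind="saturating", id50=50.0
            ),
        }
        best, table = est.select_inhibition_variant(None, small_designs, inits)
        # equal AIC: the variant with fewer parameters wins
        assert best == "linear"
        assert table.loc["linear", "aic"] == pytest.approx(2 * 4 + 100.0)

    def test_linear_recovered_without_variability(self, small_designs):
        """On clean data the generating (linear) inhibition shape wins the
        AIC comparison outright."""
        from radtse import published_population

        truth = dataclasses.replace(
            published_population(),
            omega_gamma=0.0, omega_alpha=0.0, omega_v0=0.0,
            sigma_prop=0.05, sigma_add=0.5,
        )
        ds = synthesize_studies(truth, small_designs, seed=31)
        fixed = ("omega_gamma", "omega_alpha", "omega_v0",
                 "sigma_prop", "sigma_add", "gamma_2", "v0_2")

        def init_for(kind):
            kw = dict(inhibition_kind=kind)
            if kind == "saturating":
                kw["id50"] = 50.0
            return dataclasses.replace(
                truth,
                gamma_by_study=(0.035,) * 3,
                v0_by_study=(30.0,) * 3,
                alpha=0.05,
                **kw,
            )

        inits = {k: init_for(k) for k in ("linear", "exponential", "saturating")}
        best, table = select_inhibition_variant(
            ds, small_designs, inits, FitSettings(fixed=fixed)
        )
        assert best == "linear"
        assert table.loc["linear", "aic"] < table.loc["exponential", "aic"]


class TestVPC:
    def test_zero_variability_bands_collapse(self, pop, small_designs):
        clean = dataclasses.replace(
            pop, omega_gamma=0.0, omega_alpha=0.0, omega_v0=0.0,
            sigma_prop=0.0, sigma_add=0.0,
        )
        ds = synthesize_studies(clean, small_designs, seed=5)
        out = vpc_summary(ds, clean, small_designs, n_replicates=20, seed=6)
        assert np.allclose(out.band_lo, out.band_hi)
        assert np.allclose(out.observed_median, out.simulated_median)
        assert out.within_band.all()

    def test_observed_median_covered_under_correct_model(self, pop, small_designs):
        """Each time point's observed median falls in the 90% band with
        probability ~0.9; the fraction over time points fluctuates around
        that (and the points are serially correlated within subjects), so
        the bound leaves room for that sampling noise."""
        ds = synthesize_studies(pop, small_designs, seed=7)
        out = vpc_summary(ds, pop, small_designs, n_replicates=120, seed=8)
        assert out.within_band.mean() >= 0.7
        # and the band is not vacuous: it excludes a shifted population
        assert (out.band_lo < out.observed_median).mean() > 0.8

    def test_bands_widen_with_gamma_variability(self, pop, small_designs):
        widths = []
        for omega in (0.2, 0.8):
            p = dataclasses.replace(
                pop, omega_gamma=omega, omega_alpha=0.0, omega_v0=0.0,
                sigma_prop=0.0, sigma_add=0.0,
            )
            ds = synthesize_studies(p, small_designs, seed=9)
            out = vpc_summary(ds, p, small_designs, n_replicates=60, seed=10)
            rt = out[(out.study == 1) & (out.arm == "rt")]
            late = rt[rt.time_day >= 42.0]
            widths.append((late.band_hi - late.band_lo).mean())
        assert widths[1] > widths[0]


@pytest.fixture(scope="module")
def groups():
    from radtse.io import default_study_designs

    return {
        f"s{d.study}_{arm.name}": (d.study, arm.compound, d.arm_regimen(arm))
        for d in default_study_designs()
        for arm in d.arms
        if d.arm_observation_days(arm)[-1] >= 60.0
    }


class TestSensitivity:

    def test_growth_and_kill_rates_dominate(self, pop, groups):
        table = local_sensitivity(pop, groups, t_star=60.0)
        assert set(table.top_parameters(2)) == {"kg", "kk"}

    def test_drug_potency_silent_in_radiation_only_group(self, pop, groups):
        table = local_sensitivity(pop, groups, t_star=60.0)
        assert table.per_group.loc["a", "s3_rt"] == 0.0
        assert table.per_group.loc["b", "s3_rt"] == 0.0
        assert table.per_group.loc["a", "s3_rt_rs1_100"] > 0.0

    def test_group_normalization_peaks_at_one(self, pop, groups):
        table = local_sensitivity(pop, groups, t_star=60.0)
        assert np.allclose(table.per_group.max(axis=0), 1.0)

    def test_finite_difference_matches_closed_form_untreated(self, median1):
        """Untreated tumors grow as V0_tot e^((kg-kk)t); the package's
        scaled central differences must match the same differences taken
        on the closed-form solution."""
        pop_like = {"vehicle": (1, None, Regimen.untreated(60.0))}
        from radtse import published_population

        step = 0.05
        table = local_sensitivity(
            published_population(), pop_like, t_star=60.0, rel_step=step
        )
        p = median1
        t = 60.0

        def vt(kg, kk, v0):
            tot = v0 * (1 - (kk / kg) ** 4) / (1 - kk / kg)
            return tot * np.exp((kg - kk) * t)

        base = dict(kg=p.kg, kk=p.kk, v0=p.v0)
        exact = {}
        for name in ("kg", "kk", "v0"):
            hi = dict(base); hi[name] *= 1 + step
            lo = dict(base); lo[name] *= 1 - step
            exact[name] = abs(vt(**hi) - vt(**lo)) / (2 * step)
        top = max(exact.values())
        for name in ("kg", "kk", "v0"):
            assert table.per_group.loc[name, "vehicle"] == pytest.approx(
                exact[name] / top, rel=1e-9
            )
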