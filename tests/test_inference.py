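"""Links, MLE fitting, derived abundance, bootstrap and AIC selection."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from transjs.data import (
    ORIGIN_TRANSLOCATED,
    CaptureData,
    CaptureHistory,
    StudyDesign,
)
from transjs.inference import (
    FitOptions,
    ModelSpec,
    ParameterMap,
    aic_select,
    bootstrap_ci,
    derive_abundance,
    expand_parameters,
    fit_mle,
    parse_spec,
)
from transjs.likelihood import ParameterSet
from transjs.simulate import ScenarioSpec, scenario, simulate_dataset

from conftest import random_dataset

QUICK = FitOptions(n_starts=2, maxiter=300, seed=0)


def design_for(T, tau=2, **kw):
    return StudyDesign(
        n_occasions=T, occasion_times=np.arange(T, dtype=float) * 6.0, tau=tau,
        **kw,
    )


class TestExpandParameters:
    def test_link_identities(self):
        design = design_for(4, tau=2)
        spec = ModelSpec(phi="constant", p="constant", phi_timescale="interval")
        pmap = ParameterMap(spec, design, "standard")
        theta = np.zeros(pmap.k)
        theta[pmap._slices["n"]] = np.log(500.0)
        params = pmap.expand(theta)["_all"]
        assert params.n_super == pytest.approx(500.0)
        np.testing.assert_allclose(params.phi, 0.5)
        np.testing.assert_allclose(params.p, 0.5)
        # multinomial logit with all-zero coefficients is uniform
        np.testing.assert_allclose(params.beta, 0.25)

    def test_monthly_survival_is_powered_by_interval_length(self):
        design = design_for(3, tau=2)  # 6-month spacing
        spec = ModelSpec(phi="constant", p="constant", phi_timescale="monthly")
        params = expand_parameters(
            np.zeros(ParameterMap(spec, design, "standard").k), spec, design,
            "standard",
        )["_all"]
        np.testing.assert_allclose(params.phi, 0.5 ** 6)

    def test_translocation_fixed_constraints(self):
        design = design_for(5, tau=3)
        spec = ModelSpec(phi="constant", p="time")
        pmap = ParameterMap(spec, design, "translocation")
        # p_1 fixed to 1 -> only 4 free p coefficients; beta free over
        # occasions 3..5 -> 2 coefficients
        assert pmap.k == 1 + 1 + 4 + 2
        params = pmap.expand(np.zeros(pmap.k))["_all"]
        assert params.p[0] == 1.0
        assert params.beta[0] == params.beta[1] == 0.0
        assert params.beta[2:].sum() == pytest.approx(1.0)

    def test_fixed_p_occasions_honored_exactly(self):
        design = design_for(4, tau=2)
        spec = ModelSpec(p="constant", p_fixed=((2, 0.25),))
        params = expand_parameters(
            np.ones(ParameterMap(spec, design, "standard").k), spec, design,
            "standard",
        )["_all"]
        assert params.p[1] == 0.25
        np.testing.assert_allclose(params.p[[0, 2, 3]], expit(1.0))

    def test_covariate_links(self):
        cov = pd.DataFrame(
            {"effort": [1.0, 2.0, 3.0, 4.0]}, index=pd.RangeIndex(1, 5)
        )
        design = design_for(4, tau=2, covariates=cov)
        spec = ModelSpec(p=("effort",), phi_timescale="interval")
        pmap = ParameterMap(spec, design, "standard")
        theta = np.zeros(pmap.k)
        theta[pmap._slices["p"]] = [0.5, -0.2]
        params = pmap.expand(theta)["_all"]
        np.testing.assert_allclose(
            params.p, expit(0.5 - 0.2 * cov["effort"].to_numpy())
        )

    def test_parse_spec_formulas(self):
        spec = parse_spec({"phi": "~time", "p": "~effort + moon", "n": "~group"})
        assert spec.phi == "time"
        assert spec.p == ("effort", "moon")
        assert spec.n == "group"

    def test_length_mismatch_rejected(self):
        design = design_for(3)
        spec = ModelSpec()
        with pytest.raises(ValueError, match="length"):
            expand_parameters(np.zeros(99), spec, design, "standard")


class TestDeriveAbundance:
    def test_recursion_step(self):
        design = design_for(2, tau=2)
        params = ParameterSet(
            n_super=100.0, phi=[0.9], p=[1.0, 0.5], beta=[0.0, 0.1]
        )
        nt = derive_abundance(params, design, "translocation", n0=30)
        assert nt[0] == 30.0
        assert nt[1] == pytest.approx(30 * 0.9 + 100 * 0.1)  # 37

    def test_no_entries_geometric_decline(self):
        design = design_for(4, tau=2)
        params = ParameterSet(
            n_super=0.0, phi=[0.5] * 3, p=[1.0] + [0.5] * 3,
            beta=[0.0, 1.0, 0.0, 0.0],
        )
        nt = derive_abundance(params, design, "translocation", n0=16)
        np.testing.assert_allclose(nt, [16, 8, 4, 2])

    def test_no_deaths_conserves_everyone(self):
        design = design_for(5, tau=2)
        beta = np.array([0.0, 0.4, 0.3, 0.2, 0.1])
        params = ParameterSet(
            n_super=50.0, phi=np.ones(4), p=np.full(5, 0.5), beta=beta
        )
        nt = derive_abundance(params, design, "translocation", n0=20)
        assert nt[-1] == pytest.approx(20 + 50)

    def test_standard_model_first_occasion(self):
        design = design_for(3, tau=2)
        params = ParameterSet(
            n_super=200.0, phi=[0.8, 0.8], p=np.full(3, 0.5),
            beta=[0.5, 0.25, 0.25],
        )
        nt = derive_abundance(params, design, "standard")
        assert nt[0] == pytest.approx(100.0)


class TestFitMle:
    def test_recovers_scenario5_parameters(self, scenario5_replicate):
        """Survival recovered within a few percent on one mid-p replicate."""
        data, truth = scenario5_replicate
        fit = fit_mle(
            data.histories, data.design,
            ModelSpec(phi="constant", p="constant"), "translocation", QUICK,
        )
        assert fit.converged
        phi_monthly_hat = next(iter(fit.params.values())).phi[0] ** (1 / 6)
        rel = abs(phi_monthly_hat - truth.phi_unit.mean()) / truth.phi_unit.mean()
        assert rel < 0.06
        # abundance trajectory starts exactly at the released count
        assert fit.abundance[0] == data.n_translocated

    def test_all_translocated_pushes_n_to_boundary(self, rng):
        data = random_dataset(rng, 5, n_wild=0, n_trans=12)
        fit = fit_mle(
            data.histories, data.design, ModelSpec(), "translocation", QUICK
        )
        assert fit.n_super_total < 1.0
        assert fit.boundary

    def test_covariate_rescaling_leaves_loglik_invariant(self, rng):
        data, _ = simulate_dataset(
            ScenarioSpec(scenario_id=1, n1=20, n_total=120,
                         p_range=(0.4, 0.6), n_occasions=6), 5
        )
        effort = np.array([2.0, 3.0, 1.0, 4.0, 2.0, 3.0])
        lls = []
        for scale in (1.0, 10.0):
            cov = pd.DataFrame(
                {"effort": effort * scale}, index=pd.RangeIndex(1, 7)
            )
            design = dataclasses.replace(data.design, covariates=cov)
            fit = fit_mle(
                data.histories, design, ModelSpec(p=("effort",)),
                "translocation", FitOptions(n_starts=3, seed=0),
            )
            lls.append(fit.loglik)
        assert lls[0] == pytest.approx(lls[1], abs=1e-4)

    def test_multistart_stability(self, scenario5_replicate):
        """Different start seeds land on the same optimum."""
        data, _ = scenario5_replicate
        spec = ModelSpec(phi="constant", p="constant")
        fits = [
            fit_mle(data.histories, data.design, spec, "standard",
                    FitOptions(n_starts=2, seed=s))
            for s in (0, 99)
        ]
        assert fits[0].loglik == pytest.approx(fits[1].loglik, abs=1e-4)

    def test_aic_formula(self, rng):
        data = random_dataset(rng, 4, n_wild=6, n_trans=3)
        fit = fit_mle(data.histories, data.design, ModelSpec(), "standard",
                      QUICK)
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik)

    def test_sparse_time_dependent_standard_fit_hits_boundaries(self):
        """Full time dependence on sparse data drives phi to the boundary.

        The constrained (translocation) fit with constant survival stays
        interior on the same data — the mechanism behind boundary
        estimates under over-parameterized standard fits.
        """
        spec_sim = ScenarioSpec(
            scenario_id=1, n1=15, n_total=80, p_range=(0.1, 0.3),
            n_occasions=8,
        )
        data, _ = simulate_dataset(spec_sim, 31)
        full = fit_mle(
            data.histories, data.design, ModelSpec(phi="time", p="time"),
            "standard", QUICK,
        )
        constrained = fit_mle(
            data.histories, data.design, ModelSpec(), "translocation", QUICK,
        )
        phi_hat = next(iter(full.params.values())).phi
        assert full.boundary and phi_hat.max() > 1 - 1e-3
        phi_c = next(iter(constrained.params.values())).phi
        assert (phi_c > 1e-3).all() and (phi_c < 1 - 1e-3).all()


class TestGroupFits:
    def test_group_n_sums_over_groups(self, rng):
        data = random_dataset(rng, 5, tau=2, n_wild=14, n_trans=6)
        labels = ("f", "m")
        for i, h in enumerate(data.histories):
            h.group = labels[i % 2]
        design = dataclasses.replace(data.design, groups=labels)
        data = CaptureData(design, data.histories)
        fit = fit_mle(
            data.histories, design, ModelSpec(n="group"), "translocation",
            QUICK,
        )
        assert set(fit.params) == {"f", "m"}
        assert fit.n_super_total == pytest.approx(
            sum(ps.n_super for ps in fit.params.values())
        )
        assert fit.abundance == pytest.approx(
            fit.abundance_by_group["f"] + fit.abundance_by_group["m"]
        )


class TestBootstrap:
    def test_degenerate_resampling_gives_zero_width(self):
        design = design_for(4, tau=2)
        histories = [
            CaptureHistory(f"t{i}", ORIGIN_TRANSLOCATED, [1, 0, 1, 0])
            for i in range(15)
        ]
        boot = bootstrap_ci(
            histories, design, ModelSpec(), "translocation", B=4, seed=1,
            options=QUICK,
        )
        lo, hi = boot.intervals["phi[1]"]
        assert hi - lo == pytest.approx(0.0, abs=1e-6)

    def test_reproducible_and_brackets_estimate(self, scenario5_replicate):
        data, _ = scenario5_replicate
        spec = ModelSpec(phi="constant", p="constant")
        kw = dict(B=8, seed=42, options=QUICK)
        b1 = bootstrap_ci(data.histories, data.design, spec, "translocation",
                          **kw)
        b2 = bootstrap_ci(data.histories, data.design, spec, "translocation",
                          **kw)
        assert b1.intervals == b2.intervals
        fit = fit_mle(data.histories, data.design, spec, "translocation",
                      QUICK)
        lo, hi = b1.intervals["N"]
        assert lo <= fit.n_super_total <= hi

    def test_rejects_tiny_b(self, rng):
        data = random_dataset(rng, 4)
        with pytest.raises(ValueError):
            bootstrap_ci(data.histories, data.design, ModelSpec(),
                         "translocation", B=1)


class TestAicSelect:
    def test_table_structure_and_ties(self, scenario5_replicate):
        data, _ = scenario5_replicate
        spec = ModelSpec(phi="constant", p="constant")
        table = aic_select([spec, spec], data.histories, data.design,
                           "translocation", QUICK)
        assert table["delta_aic"].iloc[0] == 0.0
        assert table["aic"].iloc[0] == pytest.approx(table["aic"].iloc[1])
        np.testing.assert_allclose(
            table["aic"], 2 * table["k"] - 2 * table["loglik"]
        )

    def test_single_candidate_trivial_delta(self, scenario5_replicate):
        data, _ = scenario5_replicate
        table = aic_select(
            [ModelSpec()], data.histories, data.design, "translocation", QUICK
        )
        assert len(table) == 1 and table["delta_aic"].iloc[0] == 0.0

    def test_nested_specs_prefer_true_smaller_model(self):
        """Data simulated with constant p: p~1 usually out-ranks p~time."""
        sim = ScenarioSpec(
            scenario_id=1, n1=25, n_total=150, p_range=(0.45, 0.55),
            n_occasions=7,
        )
        wins = 0
        n_rep = 7
        for r in range(n_rep):
            data, _ = simulate_dataset(sim, 600 + r)
            table = aic_select(
                [ModelSpec(name="const"), ModelSpec(p="time", name="time")],
                data.histories, data.design, "translocation", QUICK,
            )
            wins += table.iloc[0]["spec"] == "const"
        assert wins > n_rep / 2
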