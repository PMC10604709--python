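"""Empirical-Bayes estimation, Laplace marginal likelihood, population fits,
covariate selection and the individual bootstrap."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import integrate

from adapk.data import Cohort, DoseEvent, Observation, Subject
from adapk.estimation import (
    CovariateSpec,
    bootstrap_fit,
    covariate_lrt,
    estimate_ebe,
    fit_population,
    laplace_ofv,
    stepwise_covariate_search,
)
from adapk.population import (
    PopulationParameters,
    PriorEntry,
    PriorSpec,
    RandomEffects,
    final_parameters,
    individual_loglik,
)
from adapk.simulate import DesignSpec, generate_cohort
from adapk.structural import concentration, individual_params

from conftest import make_subject

pytestmark = pytest.mark.filterwarnings("ignore::RuntimeWarning")


class TestEstimateEbe:
    def test_no_usable_observations_shrinks_to_population(self, final_pop):
        s = Subject(id="Z", doses=(DoseEvent(0.0, 40.0),), observations=(),
                    albumin=3.77, aaa=0)
        eta = estimate_ebe(s, final_pop)
        assert eta.eta_cl == pytest.approx(0.0, abs=1e-9)
        assert eta.eta_v == pytest.approx(0.0, abs=1e-9)

    def test_recovers_known_eta_under_rich_low_noise_design(self, final_pop):
        pop = final_pop.with_values(err_prop=0.01)
        true_eta = RandomEffects(0.4, -0.3)
        params = individual_params(pop, true_eta, albumin=3.77, aaa=0)
        doses = tuple(DoseEvent(336.0 * k, 40.0) for k in range(10))
        times = np.linspace(50, 3300, 20)
        rng = np.random.default_rng(3)
        obs = []
        for t in times:
            f = concentration(params, doses, float(t))
            obs.append(Observation(float(t), f * (1 + 0.01 * rng.normal())))
        s = Subject(id="R", doses=doses, observations=tuple(obs), albumin=3.77, aaa=0)
        eta = estimate_ebe(s, pop)
        assert eta.eta_cl == pytest.approx(true_eta.eta_cl, abs=0.02)
        assert eta.eta_v == pytest.approx(true_eta.eta_v, abs=0.02)

    def test_low_trough_inflates_clearance(self, final_pop):
        typ = individual_params(final_pop, RandomEffects(0, 0), albumin=3.77, aaa=0)
        s_template = make_subject("L", obs_times=(672.0,), conc=(1.0,))
        f_typ = concentration(typ, s_template.doses, 672.0)
        s = make_subject("L", obs_times=(672.0,), conc=(f_typ / 5,))
        eta = estimate_ebe(s, final_pop)
        assert eta.eta_cl > 0

    def test_maximizes_individual_loglik(self, final_pop):
        s = make_subject("O", obs_times=(400.0, 700.0), conc=(3.0, 5.0))
        eta = estimate_ebe(s, final_pop)
        ll_hat = individual_loglik(s, final_pop, eta)
        rng = np.random.default_rng(0)
        for _ in range(50):
            probe = RandomEffects(
                eta.eta_cl + rng.normal(0, 0.2), eta.eta_v + rng.normal(0, 0.2)
            )
            assert individual_loglik(s, final_pop, probe) <= ll_hat + 1e-9


class TestLaplaceOfv:
    def test_matches_closed_form_in_conjugate_limit(self):
        # one observation, additive error, tiny IIV: the marginal density is
        # Gaussian and Laplace is exact up to O(omega^2) model curvature
        pop = PopulationParameters(
            cl_pop=0.03, v_pop=8.0, cov_alb=0.0, omega_cl=1e-4, omega_v=1e-4,
            err_add=1.0, err_prop=0.0,
            fixed=frozenset({"ka_pop", "cov_aaa", "cov_alb"}),
        )
        s = make_subject("C", obs_times=(672.0,), conc=(5.0,))
        cohort = Cohort(subjects=(s,), meta={})
        typ = individual_params(pop, RandomEffects(0, 0), albumin=3.77, aaa=0)
        f = concentration(typ, s.doses, 672.0)
        # delta-method variance of f through the two lognormal effects
        h = 1e-6
        df_cl = (
            concentration(replace(typ, cl=typ.cl * math.exp(h)), s.doses, 672.0) - f
        ) / h
        df_v = (
            concentration(replace(typ, v=typ.v * math.exp(h)), s.doses, 672.0) - f
        ) / h
        var = 1.0**2 + (df_cl * pop.omega_cl) ** 2 + (df_v * pop.omega_v) ** 2
        expected = -2 * (
            -0.5 * math.log(2 * math.pi * var) - 0.5 * (5.0 - f) ** 2 / var
        )
        assert laplace_ofv(cohort, pop) == pytest.approx(expected, rel=1e-6)

    def test_matches_quadrature_at_moderate_iiv(self, final_pop):
        # 2-d adaptive quadrature of the true marginal for one subject
        s = make_subject("Q", obs_times=(500.0, 900.0), conc=(4.0, 6.0))
        cohort = Cohort(subjects=(s,), meta={})

        def integrand(e_v, e_cl):
            return math.exp(
                individual_loglik(s, final_pop, RandomEffects(e_cl, e_v))
            )

        val, _ = integrate.dblquad(integrand, -4, 4, -3, 3, epsabs=1e-12, epsrel=1e-9)
        exact_ofv = -2 * math.log(val)
        # the default Hermite grid integrates the posterior's skewness; the
        # single-node (pure Laplace) approximation is markedly cruder
        assert laplace_ofv(cohort, final_pop) == pytest.approx(exact_ofv, rel=0.01)
        lap = laplace_ofv(cohort, final_pop)  # default grid
        from adapk._core import CohortArrays, laplace_terms

        one_node, _, _ = laplace_terms(CohortArrays(cohort), final_pop, n_quad=1)
        assert abs(lap - exact_ofv) < abs(float(one_node.sum()) - exact_ofv)

    def test_additive_over_subjects(self, final_pop, two_subject_cohort):
        total = laplace_ofv(two_subject_cohort, final_pop)
        parts = sum(
            laplace_ofv(Cohort(subjects=(s,), meta={}), final_pop)
            for s in two_subject_cohort
        )
        assert total == pytest.approx(parts, rel=1e-10)
        doubled = Cohort(
            subjects=tuple(two_subject_cohort.subjects)
            + tuple(replace(s, id=s.id + "bis") for s in two_subject_cohort),
            meta={},
        )
        assert laplace_ofv(doubled, final_pop) == pytest.approx(2 * total, rel=1e-10)

    def test_generating_parameters_are_a_local_minimum(self, final_pop):
        cohort, _ = generate_cohort(
            DesignSpec(n_subjects=150, seed=77, rich_design=True), final_pop
        )
        ofv0 = laplace_ofv(cohort, final_pop)
        for factor in (0.7, 1.4):
            assert laplace_ofv(cohort, final_pop.with_values(cl_pop=final_pop.cl_pop * factor)) > ofv0


class TestFitPopulation:
    def test_all_fixed_is_pure_evaluation(self, final_pop, study_cohort):
        cohort, _ = study_cohort
        all_fixed = frozenset(
            {"cl_pop", "v_pop", "ka_pop", "cov_aaa", "cov_alb",
             "omega_cl", "omega_v", "err_add", "err_prop"}
        )
        fit = fit_population(cohort, final_pop, fixed=all_fixed)
        assert fit.ofv == pytest.approx(laplace_ofv(cohort, final_pop), rel=1e-12)
        assert fit.rse == {} and fit.free_names == ()

    def test_refit_from_own_optimum_is_stable(self, final_pop, study_cohort):
        cohort, _ = study_cohort
        fit = fit_population(cohort, final_pop, seed=1)
        refit = fit_population(cohort, fit.estimates, seed=1)
        assert refit.ofv == pytest.approx(fit.ofv, abs=1e-4)

    def test_tight_prior_pins_to_prior_mean(self, final_pop, study_cohort):
        cohort, _ = study_cohort
        priors = PriorSpec(entries={"omega_cl": PriorEntry(0.58, 1e-6)})
        fit = fit_population(cohort, final_pop, priors, seed=1)
        assert fit.estimates.omega_cl == pytest.approx(0.58, rel=1e-3)

    def test_vague_prior_equals_plain_fit(self, final_pop, study_cohort):
        cohort, _ = study_cohort
        plain = fit_population(cohort, final_pop, seed=1)
        vague = PriorSpec(entries={"omega_cl": PriorEntry(0.58, 1e6)})
        mapped = fit_population(cohort, final_pop, vague, seed=1)
        assert abs(plain.ofv - mapped.ofv) < 1e-6

    def test_informative_priors_shrink_uncertainty(self, final_pop, study_cohort):
        # the study's rationale for the prior model: IIV RSEs collapse
        cohort, _ = study_cohort
        plain = fit_population(cohort, final_pop, seed=1)
        priors = PriorSpec(
            entries={
                "omega_cl": PriorEntry(0.65, 0.10),
                "omega_v": PriorEntry(0.48, 0.19),
            }
        )
        mapped = fit_population(cohort, final_pop, priors, seed=1)
        assert mapped.rse["omega_v"] < plain.rse["omega_v"]

    def test_estimation_error_shrinks_with_cohort_size(self, final_pop):
        # consistency at reduced scale: median |error| over replicates is
        # nonincreasing as the cohort grows
        sizes = (20, 80, 320)
        med_err = []
        for n in sizes:
            errs = []
            for rep in range(5):
                cohort, _ = generate_cohort(
                    DesignSpec(n_subjects=n, seed=1000 + rep, rich_design=True,
                               albumin_uniform=True),
                    final_pop,
                )
                fit = fit_population(cohort, final_pop, seed=1, compute_uncertainty=False)
                errs.append(abs(fit.estimates.cl_pop - final_pop.cl_pop))
            med_err.append(np.median(errs))
        assert med_err[0] >= med_err[1] >= med_err[2]


@pytest.fixture(scope="module")
def null_cohort_and_base(final_pop):
    pop0 = final_pop.with_values(cov_alb=0.0)
    cohort, _ = generate_cohort(DesignSpec(n_subjects=100, seed=41), pop0)
    base = fit_population(
        cohort,
        pop0.with_values(fixed=frozenset({"ka_pop", "cov_aaa", "err_add", "cov_alb"})),
        seed=1,
    )
    return cohort, base


class TestCovariateLrt:
    def test_candidate_fixed_at_null_gives_zero_delta(self, null_cohort_and_base):
        cohort, base = null_cohort_and_base
        delta, p, accepted = covariate_lrt(
            cohort, base, CovariateSpec("alb"), seed=1,
            fixed=frozenset({"ka_pop", "cov_aaa", "err_add", "cov_alb"}),
        )
        # two independent optimizer runs: the OFVs agree to optimizer noise
        assert delta == pytest.approx(0.0, abs=1e-4)
        assert p > 0.99
        assert not accepted

    def test_non_nested_candidate_rejected(self, final_pop, study_cohort):
        cohort, _ = study_cohort
        fit = fit_population(cohort, final_pop, seed=1)  # cov_alb already free
        with pytest.raises(ValueError, match="nest"):
            covariate_lrt(cohort, fit, CovariateSpec("alb"), seed=1)

    def test_detects_true_albumin_effect(self, final_pop):
        # power at the declared design: 150 subjects, sparse troughs
        n_accept = 0
        for seed in range(20):
            cohort, _ = generate_cohort(DesignSpec(seed=300 + seed, n_subjects=150), final_pop)
            base = fit_population(
                cohort,
                final_pop.with_values(
                    cov_alb=0.0,
                    fixed=frozenset({"ka_pop", "cov_aaa", "err_add", "cov_alb"}),
                ),
                seed=1,
                compute_uncertainty=False,
            )
            _, _, accepted = covariate_lrt(
                cohort, base, CovariateSpec("alb"), seed=1, compute_uncertainty=False
            )
            n_accept += accepted
        assert n_accept >= 19  # >= 95% of 20 cohorts

    def test_type_one_error_controlled_without_albumin_effect(self, final_pop):
        pop0 = final_pop.with_values(cov_alb=0.0)
        n_accept = 0
        for seed in range(20):
            cohort, _ = generate_cohort(DesignSpec(seed=400 + seed, n_subjects=100), pop0)
            base = fit_population(
                cohort,
                pop0.with_values(fixed=frozenset({"ka_pop", "cov_aaa", "err_add", "cov_alb"})),
                seed=1,
                compute_uncertainty=False,
            )
            _, _, accepted = covariate_lrt(
                cohort, base, CovariateSpec("alb"), threshold=0.05, seed=1,
                compute_uncertainty=False,
            )
            n_accept += accepted
        assert n_accept <= 3  # ~5% nominal, binomial tolerance at 20 trials


class TestStepwiseSearch:
    def _with_weight(self, cohort, seed):
        rng = np.random.default_rng(seed)
        subs = tuple(
            replace(s, covariates={"weight": float(rng.normal(70, 12))}) for s in cohort
        )
        return Cohort(subjects=subs, meta={})

    def test_empty_candidate_set_returns_base(self, final_pop, study_cohort):
        cohort, _ = study_cohort
        base = fit_population(cohort, final_pop, seed=1)
        result = stepwise_covariate_search(cohort, base, [], seed=1)
        assert result.fit is base and result.selected == ()

    def test_selects_true_effect_not_spurious_one(self, final_pop):
        n_alb = n_weight = 0
        for seed in range(20):
            cohort, _ = generate_cohort(DesignSpec(seed=500 + seed, n_subjects=100), final_pop)
            cohort = self._with_weight(cohort, 900 + seed)
            base = fit_population(
                cohort,
                final_pop.with_values(
                    cov_alb=0.0,
                    fixed=frozenset({"ka_pop", "cov_aaa", "err_add", "cov_alb"}),
                ),
                seed=1,
                compute_uncertainty=False,
            )
            result = stepwise_covariate_search(
                cohort, base,
                [CovariateSpec("alb"), CovariateSpec("weight", form="power")],
                seed=1, compute_uncertainty=False,
            )
            names = [c.covariate for c in result.selected]
            n_alb += "alb" in names
            n_weight += "weight" in names
        assert n_alb >= 18  # >= 90% of 20 cohorts
        assert n_weight <= 4

    def test_identical_candidates_tie_broken_by_declaration_order(self, final_pop):
        cohort, _ = generate_cohort(DesignSpec(seed=51, n_subjects=60), final_pop)
        cohort = self._with_weight(cohort, 52)
        base = fit_population(
            cohort,
            final_pop.with_values(fixed=frozenset({"ka_pop", "cov_aaa", "err_add"})),
            seed=1,
            compute_uncertainty=False,
        )
        first = CovariateSpec("weight", form="power")
        second = CovariateSpec("weight", form="power")
        result = stepwise_covariate_search(
            cohort, base, [first, second], alpha=0.999999, seed=1,
            compute_uncertainty=False,
        )
        assert result.selected and result.selected[0] is first


class TestBootstrapFit:
    def test_single_replicate_preserves_cohort_size(self, final_pop, study_cohort):
        cohort, _ = study_cohort
        all_fixed = frozenset(
            {"cl_pop", "v_pop", "ka_pop", "cov_aaa", "cov_alb",
             "omega_cl", "omega_v", "err_add", "err_prop"}
        )
        boot = bootstrap_fit(
            cohort, final_pop.with_values(fixed=all_fixed), n_reps=1, seed=9
        )
        assert boot.replicates[0].n_subjects == cohort.n_subjects

    def test_distinct_subject_fraction_near_0632(self, final_pop, study_cohort):
        # resampling n of n with replacement keeps ~1-1/e distinct subjects
        cohort, _ = study_cohort
        all_fixed = frozenset(
            {"cl_pop", "v_pop", "ka_pop", "cov_aaa", "cov_alb",
             "omega_cl", "omega_v", "err_add", "err_prop"}
        )
        boot = bootstrap_fit(
            cohort, final_pop.with_values(fixed=all_fixed), n_reps=200, seed=9
        )
        n = cohort.n_subjects
        fracs = [
            len({sid.split("~")[0] for sid in rep.ebes}) / n
            for rep in boot.replicates
        ]
        assert np.mean(fracs) == pytest.approx(1 - (1 - 1 / n) ** n, abs=0.05)

    def test_same_seed_reproduces_summary_bitwise(self, final_pop, study_cohort):
        cohort, _ = study_cohort
        fit = fit_population(cohort, final_pop, seed=1, compute_uncertainty=False)
        b1 = bootstrap_fit(cohort, fit.estimates, n_reps=5, seed=33)
        b2 = bootstrap_fit(cohort, fit.estimates, n_reps=5, seed=33)
        assert b1.summary.equals(b2.summary)

    def test_invalid_rep_count_rejected(self, final_pop, study_cohort):
        cohort, _ = study_cohort
        with pytest.raises(ValueError):
            bootstrap_fit(cohort, final_pop, n_reps=0, seed=1)
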