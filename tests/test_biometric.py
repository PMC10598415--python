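"""ACE-family ML estimation: likelihoods, fitting, comparisons, CIs."""

import math

import numpy as np
import pytest
from scipy import stats

from twinace.biometric import (BivariateACEParams, UnivariateACEParams,
                               bivariate_heritability, bivariate_minus2ll,
                               compare_nested,
                               fit_bivariate, fit_to_dict, fit_univariate,
                               likelihood_ci, profile_deviance,
                               univariate_minus2ll)
from twinace.simulate import (BivariateSimSpec, UnivariateSimSpec,
                              simulate_pairs)

from conftest import make_cohort


def brute_force_uni_m2ll(params, cohort, trait="y"):
    """Independent oracle: per-pair density summation via scipy."""
    total = 0.0
    for rec in cohort.records:
        k_a = 1.0 if rec.zygosity == "MZ" else 0.5
        v = params.a ** 2 + params.c ** 2 + params.e ** 2
        b = k_a * params.a ** 2 + params.c ** 2
        cov = np.array([[v, b], [b, v]])
        vals = np.array([t.phenotypes[trait] for t in rec.twins])
        obs = ~np.isnan(vals)
        if not obs.any():
            continue
        mu = np.full(obs.sum(), params.mean)
        total += -2.0 * stats.multivariate_normal.logpdf(
            vals[obs], mean=mu, cov=cov[np.ix_(obs, obs)])
    return total


class TestUnivariateLikelihood:
    def test_independence_closed_form(self, toy_cohort):
        """With a = c = 0, e = 1 the likelihood is a product of standard
        normal densities over all observed individual values."""
        params = UnivariateACEParams(a=0.0, c=0.0, e=1.0, mean=0.0)
        vals = toy_cohort.pair_matrix("y").ravel()
        vals = vals[~np.isnan(vals)]
        expected = float(-2.0 * stats.norm.logpdf(vals).sum())
        assert univariate_minus2ll(params, toy_cohort) == pytest.approx(
            expected, abs=1e-10)

    @pytest.mark.parametrize("a,c,e,mean", [
        (0.6, 0.3, 0.8, 0.1), (0.0, 0.5, 1.2, -0.4), (1.0, 0.0, 0.5, 0.0)])
    def test_matches_brute_force_oracle(self, toy_cohort, a, c, e, mean):
        params = UnivariateACEParams(a, c, e, mean)
        assert univariate_minus2ll(params, toy_cohort) == pytest.approx(
            brute_force_uni_m2ll(params, toy_cohort), abs=1e-10)

    def test_perturbing_e_at_optimum_worsens_fit(self, small_sim_cohort):
        fit = fit_univariate(small_sim_cohort, "y", model="AE", ci=())
        p = fit.params
        for eps in (0.02, -0.02):
            worse = UnivariateACEParams(p.a, p.c, p.e * (1 + eps), p.mean)
            assert univariate_minus2ll(worse, small_sim_cohort) > fit.minus2ll


class TestFitUnivariate:
    def test_recovers_generating_components(self):
        spec = UnivariateSimSpec(0.46, 0.0, 0.54, n_mz=658, n_dz=1473,
                                 seed=30, trait="y")
        fit = fit_univariate(simulate_pairs(spec), "y", model="AE",
                             ci=("A",))
        lo, hi = fit.ci95["A"]
        assert lo < 0.46 < hi
        assert fit.params.A == pytest.approx(0.46, abs=0.08)

    def test_null_data_estimates_near_zero(self):
        spec = UnivariateSimSpec(0.0, 0.0, 1.0, n_mz=25_000, n_dz=25_000,
                                 seed=31, trait="y")
        fit = fit_univariate(simulate_pairs(spec), "y", model="ACE", ci=())
        assert fit.params.A < 0.05 and fit.params.C < 0.05

    def test_nested_chain_is_monotone(self, small_sim_cohort):
        m2 = {m: fit_univariate(small_sim_cohort, "y", model=m, ci=()).minus2ll
              for m in ("ACE", "AE", "CE", "E")}
        assert m2["E"] >= m2["CE"] - 1e-6 >= m2["ACE"] - 2e-6
        assert m2["E"] >= m2["AE"] - 1e-6 >= m2["ACE"] - 2e-6

    def test_proportions_sum_to_one(self, small_sim_cohort):
        fit = fit_univariate(small_sim_cohort, "y", model="ACE", ci=())
        assert sum(fit.params.proportions().values()) == pytest.approx(
            1.0, abs=1e-9)


class TestCompareNested:
    def test_delta_df_and_p(self, small_sim_cohort):
        ace = fit_univariate(small_sim_cohort, "y", model="ACE", ci=())
        ae = fit_univariate(small_sim_cohort, "y", model="AE", ci=())
        comp = compare_nested(ace, ae)
        assert comp.delta_df == 1
        assert comp.delta_minus2ll >= 0
        assert comp.p_value_boundary == pytest.approx(comp.p_value / 2)

    def test_zero_delta_gives_p_one(self, small_sim_cohort):
        ace = fit_univariate(small_sim_cohort, "y", model="ACE", ci=())
        ae = fit_univariate(small_sim_cohort, "y", model="AE", ci=())
        ae.minus2ll = ace.minus2ll
        assert compare_nested(ace, ae).p_value == 1.0

    def test_detects_shared_environment_when_present(self):
        spec = UnivariateSimSpec(0.2, 0.3, 0.5, n_mz=5000, n_dz=5000,
                                 seed=32, trait="y")
        cohort = simulate_pairs(spec)
        ace = fit_univariate(cohort, "y", model="ACE", ci=())
        ae = fit_univariate(cohort, "y", model="AE", ci=())
        assert compare_nested(ace, ae).p_value < 0.01

    def test_non_nested_labels_rejected(self, small_sim_cohort):
        ae = fit_univariate(small_sim_cohort, "y", model="AE", ci=())
        ce = fit_univariate(small_sim_cohort, "y", model="CE", ci=())
        with pytest.raises(ValueError):
            compare_nested(ae, ce)


def _biv_cohort(n=300, seed=40, r_a=0.3, r_e=0.1):
    spec = BivariateSimSpec(0.46, 0.0, 0.54, 0.44, 0.0, 0.56,
                            r_a=r_a, r_c=0.0, r_e=r_e,
                            n_mz=n, n_dz=n, seed=seed)
    return simulate_pairs(spec)


def brute_force_biv_m2ll(params, cohort, traits):
    total = 0.0
    p1 = (params.a1, params.c1, params.e1)
    p2 = (params.a2, params.c2, params.e2)
    for rec in cohort.records:
        k_a = 1.0 if rec.zygosity == "MZ" else 0.5
        # build the 4x4 by explicit formulas, independent of the package
        a1, c1, e1 = p1
        a2, c2, e2 = p2
        w = np.array([
            [a1 * a1 + c1 * c1 + e1 * e1,
             a1 * a2 * params.r_a + c1 * c2 * params.r_c + e1 * e2 * params.r_e],
            [a1 * a2 * params.r_a + c1 * c2 * params.r_c + e1 * e2 * params.r_e,
             a2 * a2 + c2 * c2 + e2 * e2]])
        b = np.array([
            [k_a * a1 * a1 + c1 * c1,
             k_a * a1 * a2 * params.r_a + c1 * c2 * params.r_c],
            [k_a * a1 * a2 * params.r_a + c1 * c2 * params.r_c,
             k_a * a2 * a2 + c2 * c2]])
        cov = np.block([[w, b], [b, w]])
        vals = np.array([rec.twin1.phenotypes[traits[0]],
                         rec.twin1.phenotypes[traits[1]],
                         rec.twin2.phenotypes[traits[0]],
                         rec.twin2.phenotypes[traits[1]]])
        mu = np.array([params.mean1, params.mean2,
                       params.mean1, params.mean2])
        obs = ~np.isnan(vals)
        if not obs.any():
            continue
        total += -2.0 * stats.multivariate_normal.logpdf(
            vals[obs], mean=mu[obs], cov=cov[np.ix_(obs, obs)])
    return total


class TestBivariateLikelihood:
    PARAMS = BivariateACEParams(0.6, 0.2, 0.75, 0.5, 0.3, 0.8,
                                r_a=0.4, r_c=-0.2, r_e=0.1,
                                mean1=0.05, mean2=-0.1)

    def _toy(self):
        cohort = _biv_cohort(n=2, seed=41)
        # knock out one value to exercise FIML
        rec = cohort.records[0]
        rec.twin2.phenotypes["trait2"] = math.nan
        return cohort

    def test_matches_brute_force_oracle(self):
        cohort = self._toy()
        ours = bivariate_minus2ll(self.PARAMS, cohort)
        oracle = brute_force_biv_m2ll(self.PARAMS, cohort,
                                      ("trait1", "trait2"))
        assert ours == pytest.approx(oracle, abs=1e-10)

    def test_zero_correlations_decompose_into_univariate(self):
        cohort = _biv_cohort(n=50, seed=42)
        p = BivariateACEParams(0.6, 0.2, 0.75, 0.5, 0.3, 0.8,
                               r_a=0.0, r_c=0.0, r_e=0.0,
                               mean1=0.05, mean2=-0.1)
        u1 = UnivariateACEParams(p.a1, p.c1, p.e1, p.mean1)
        u2 = UnivariateACEParams(p.a2, p.c2, p.e2, p.mean2)
        total = bivariate_minus2ll(p, cohort)
        parts = (univariate_minus2ll(u1, cohort, "trait1")
                 + univariate_minus2ll(u2, cohort, "trait2"))
        assert total == pytest.approx(parts, abs=1e-9)

    def test_trait_permutation_symmetry(self):
        cohort = _biv_cohort(n=40, seed=43)
        p = self.PARAMS
        swapped = BivariateACEParams(p.a2, p.c2, p.e2, p.a1, p.c1, p.e1,
                                     r_a=p.r_a, r_c=p.r_c, r_e=p.r_e,
                                     mean1=p.mean2, mean2=p.mean1)
        direct = bivariate_minus2ll(p, cohort, ("trait1", "trait2"))
        flipped = bivariate_minus2ll(swapped, cohort, ("trait2", "trait1"))
        assert direct == pytest.approx(flipped, abs=1e-9)


class TestFitBivariate:
    def test_recovers_component_correlations(self):
        cohort = _biv_cohort(n=4000, seed=44, r_a=0.3, r_e=0.1)
        fit = fit_bivariate(cohort, model="AE", ci=())
        assert fit.params.r_a == pytest.approx(0.3, abs=0.06)
        assert fit.params.r_e == pytest.approx(0.1, abs=0.05)
        implied_rph = (math.sqrt(0.46 * 0.44) * 0.3
                       + math.sqrt(0.54 * 0.56) * 0.1)
        assert fit.params.r_ph == pytest.approx(implied_rph, abs=0.03)

    def test_rph_identity_at_optimizer_exit(self):
        cohort = _biv_cohort(n=500, seed=45)
        fit = fit_bivariate(cohort, model="AE", ci=())
        p = fit.params
        manual = ((p.a1 * p.a2 * p.r_a + p.e1 * p.e2 * p.r_e)
                  / math.sqrt(p.variance1 * p.variance2))
        assert p.r_ph == pytest.approx(manual, abs=1e-9)

    def test_shares_sum_to_one(self):
        cohort = _biv_cohort(n=500, seed=46)
        fit = fit_bivariate(cohort, model="AE", ci=())
        shares = fit.params.covariance_shares()
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-9)
        assert bivariate_heritability(fit.params) == pytest.approx(
            shares["A"])

    def test_near_duplicate_traits_drive_correlations_to_one(self):
        spec = UnivariateSimSpec(0.5, 0.0, 0.5, n_mz=300, n_dz=300,
                                 seed=47, trait="trait1")
        cohort = simulate_pairs(spec)
        X = cohort.pair_matrix("trait1")
        noise = 0.05 * np.random.default_rng(2).standard_normal(X.size)
        dup = cohort.with_transformed_trait("trait2", X.ravel() + noise)
        fit = fit_bivariate(dup, ["trait1", "trait2"], model="AE", ci=())
        assert fit.params.r_a > 0.95
        assert fit.params.r_ph > 0.95

    def test_ace_not_worse_than_ae(self):
        cohort = _biv_cohort(n=400, seed=48)
        ace = fit_bivariate(cohort, model="ACE", ci=())
        ae = fit_bivariate(cohort, model="AE", ci=())
        assert ae.minus2ll >= ace.minus2ll - 1e-6


class TestBivariateHeritability:
    def test_all_genetic_when_no_environmental_overlap(self):
        p = BivariateACEParams(0.7, 0.0, 0.71, 0.6, 0.0, 0.8,
                               r_a=0.5, r_c=0.0, r_e=0.0)
        assert bivariate_heritability(p) == pytest.approx(1.0)

    def test_equal_components_give_half(self):
        # a1*a2*rA == e1*e2*rE by construction
        p = BivariateACEParams(0.6, 0.0, 0.6, 0.6, 0.0, 0.6,
                               r_a=0.3, r_c=0.0, r_e=0.3)
        assert bivariate_heritability(p) == pytest.approx(0.5)

    def test_zero_phenotypic_covariance_is_an_error(self):
        p = BivariateACEParams(0.6, 0.0, 0.8, 0.6, 0.0, 0.8,
                               r_a=0.0, r_c=0.0, r_e=0.0)
        with pytest.raises(ZeroDivisionError):
            bivariate_heritability(p)


class TestLikelihoodCI:
    def test_mean_ci_matches_wald_in_quadratic_case(self, small_sim_cohort):
        """The profile of the mean is essentially quadratic, so the profile
        CI must agree with +-1.96 se."""
        from twinace.biometric import _delta_method_ci

        fit = fit_univariate(small_sim_cohort, "y", model="AE", ci=())
        lo, hi = likelihood_ci(fit, "mean")
        wlo, whi = _delta_method_ci(fit, "mean", 0.95)
        assert lo == pytest.approx(wlo, abs=2e-3)
        assert hi == pytest.approx(whi, abs=2e-3)

    def test_null_a_lower_bound_hits_boundary(self):
        spec = UnivariateSimSpec(0.0, 0.0, 1.0, n_mz=800, n_dz=800,
                                 seed=50, trait="y")
        fit = fit_univariate(simulate_pairs(spec), "y", model="AE",
                             ci=("A",))
        lo, hi = fit.ci95["A"]
        assert lo == 0.0
        assert fit.ci_flags.get("A") == "boundary"

    def test_deviance_zero_at_mle(self, small_sim_cohort):
        fit = fit_univariate(small_sim_cohort, "y", model="AE", ci=())
        assert profile_deviance(fit, "A", fit.params.A) == pytest.approx(
            0.0, abs=5e-3)

    def test_fit_dump_is_json_ready(self, small_sim_cohort):
        import json

        fit = fit_univariate(small_sim_cohort, "y", model="AE", ci=("A",))
        dump = json.loads(json.dumps(fit_to_dict(fit)))
        assert dump["model"] == "AE"
        assert "A" in dump["ci95"]


class TestFalconer:
    def test_formulas_on_exact_correlations(self):
        from twinace.biometric import FalconerEstimates

        f = FalconerEstimates(r_mz=0.48, r_dz=0.22)
        assert f.A == pytest.approx(0.52)
        assert f.C == pytest.approx(-0.04)
        assert f.E == pytest.approx(0.52)
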