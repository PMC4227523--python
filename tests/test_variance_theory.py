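"""Closed-form layer: derived variances, the five accuracies, response."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from ige.variance_theory import (
    GeneticParameterSet,
    GroupDesign,
    accuracy_classical_blup,
    accuracy_group,
    accuracy_individual,
    accuracy_multilevel,
    accuracy_relatives,
    derived_variances,
    intensity_from_selected_fraction,
    predict_response,
    total_breeding_variance,
)

from conftest import exact_accuracy_oracle, random_psd_params


class TestParameterSet:
    def test_non_psd_genetic_matrix_rejected_naming_matrix(self):
        with pytest.raises(ValueError, match="genetic"):
            GeneticParameterSet(1.0, 1.0, 1.5, 1.0, 1.0)

    def test_non_psd_residual_matrix_rejected(self):
        with pytest.raises(ValueError, match="residual"):
            GeneticParameterSet(1.0, 1.0, 0.0, 1.0, 0.1, 0.9)

    def test_negative_group_variance_rejected(self):
        with pytest.raises(ValueError, match="var_group_env"):
            GeneticParameterSet(1.0, 1.0, 0.0, 1.0, 1.0, 0.0, -0.1)

    def test_correlation_absent_when_a_variance_is_zero(self):
        p = GeneticParameterSet(1.0, 0.0, 0.0, 1.0, 0.0)
        assert p.genetic_correlation is None

    def test_degenerate_perfect_competition_accepted(self):
        # rA = -1 with (n-1) sigma_AS balancing sigma_AD: one winner, one
        # loser; total heritable variance collapses to ~0 but must load
        a_d = 0.9
        n = 4
        a_s = a_d / (n - 1) ** 2
        p = GeneticParameterSet(a_d, a_s, -math.sqrt(a_d * a_s), 1.0, 0.1)
        var_tbv = total_breeding_variance(p, n)
        assert abs(var_tbv) < 1e-9

    def test_group_size_below_two_rejected(self):
        with pytest.raises(ValueError, match="group_size"):
            GroupDesign(1)


class TestDerivedVariances:
    def test_social_terms_vanish(self, null_social_params):
        for n in (2, 4, 9):
            dv = derived_variances(null_social_params, GroupDesign(n, 0.3))
            assert dv.var_tbv == pytest.approx(0.4)

    def test_t2_can_exceed_one(self):
        # strong positive social variance in sizeable groups
        p = GeneticParameterSet(0.2, 0.3, 0.1, 0.6, 0.2)
        dv = derived_variances(p, GroupDesign(8, 0.0))
        assert dv.t2 > 1.0

    def test_footnote_group_mean_identity(self, rng):
        # sigma2_Pgrp written as {s2P + 2(n-1)Cov + (n-1)[s2P + (n-2)Cov]}/n^2
        for _ in range(50):
            p = random_psd_params(rng)
            n = int(rng.integers(2, 9))
            r = float(rng.uniform(0, 1))
            dv = derived_variances(p, GroupDesign(n, r))
            s2p, cov = dv.var_phenotype, dv.cov_groupmates
            direct = (
                s2p + 2 * (n - 1) * cov + (n - 1) * (s2p + (n - 2) * cov)
            ) / n**2
            assert dv.var_group_mean == pytest.approx(direct, rel=1e-12)

    def test_tpv_consistency_identity(self, rng):
        # sigma2_P + (n-1)Cov = sigma2_TPV + (n-1) r sigma2_TBV + n sigma2_g
        for _ in range(50):
            p = random_psd_params(rng)
            n = int(rng.integers(2, 9))
            r = float(rng.uniform(0, 1))
            dv = derived_variances(p, GroupDesign(n, r))
            lhs = dv.var_phenotype + (n - 1) * dv.cov_groupmates
            rhs = (
                dv.var_total_phenotypic
                + (n - 1) * r * dv.var_tbv
                + n * p.var_group_env
            )
            assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_var_tbv_nonnegative_for_psd(self, rng):
        for _ in range(200):
            p = random_psd_params(rng)
            n = int(rng.integers(2, 12))
            assert total_breeding_variance(p, n) >= -1e-9


class TestAccuraciesAgainstExactOracle:
    """Closed forms vs an independent joint-covariance computation."""

    @pytest.mark.parametrize("scheme", ["IS", "GS", "MS"])
    def test_group_schemes_match_oracle(self, scheme, rng):
        for _ in range(40):
            p = random_psd_params(rng)
            n = int(rng.integers(2, 8))
            r = float(rng.uniform(0, 1))
            g = float(rng.uniform(0, 1))
            design = GroupDesign(n, r, multilevel_weight=g)
            fn = {
                "IS": accuracy_individual,
                "GS": accuracy_group,
                "MS": accuracy_multilevel,
            }[scheme]
            got = fn(p, design)
            want = exact_accuracy_oracle(p, n, r, scheme, g=g)
            assert got == pytest.approx(want, rel=1e-9, abs=1e-12)

    @pytest.mark.parametrize("m", [1, 3, 10])
    def test_relatives_scheme_matches_oracle(self, m, rng):
        for _ in range(20):
            p = random_psd_params(rng)
            n = int(rng.integers(2, 6))
            r = float(rng.choice([0.25, 0.5]))
            design = GroupDesign(
                n, r, relatedness_candidate_to_relatives=r, groups_per_candidate=m
            )
            got = accuracy_relatives(p, design)
            want = exact_accuracy_oracle(p, n, r, "SR", m=m)
            assert got == pytest.approx(want, rel=1e-9, abs=1e-12)


class TestAccuracyProperties:
    def test_individual_negative_with_negative_covariance(self):
        p = GeneticParameterSet(0.3, 0.4, -0.33, 1.0, 0.3)
        rho = accuracy_individual(p, GroupDesign(4, 0.0))
        assert rho < 0  # sigma2_AD + (n-1) sigma_ADS = 0.3 - 0.99 < 0

    def test_group_accuracy_positive(self, rng):
        for _ in range(50):
            p = random_psd_params(rng)
            rho = accuracy_group(p, GroupDesign(4, float(rng.uniform(0, 1))))
            if rho is not None:
                assert 0 <= rho <= 1 + 1e-12

    def test_group_accuracy_two_mean_null_social(self, null_social_params):
        # with null social effects, selecting on a 2-member group mean has
        # classical accuracy sqrt(h^2 / 2) when members are unrelated
        p = null_social_params
        got = accuracy_group(p, GroupDesign(2, 0.0))
        h2 = 0.4 / (0.4 + 0.6)
        assert got == pytest.approx(math.sqrt(h2 / 2), rel=1e-12)

    def test_multilevel_endpoints(self, rng):
        # g=0 is individual selection, g=1 group selection: 1000 sets
        for _ in range(1000):
            p = random_psd_params(rng)
            n = int(rng.integers(2, 8))
            r = float(rng.uniform(0, 1))
            lo = accuracy_multilevel(p, GroupDesign(n, r, multilevel_weight=0.0))
            hi = accuracy_multilevel(p, GroupDesign(n, r, multilevel_weight=1.0))
            ind = accuracy_individual(p, GroupDesign(n, r))
            grp = accuracy_group(p, GroupDesign(n, r))
            assert lo == pytest.approx(ind, rel=1e-10, abs=1e-14)
            assert hi == pytest.approx(grp, rel=1e-10, abs=1e-14)

    def test_relatives_limit_full_sibs(self, hen_like_params):
        p = GeneticParameterSet(
            hen_like_params.var_direct_genetic,
            hen_like_params.var_social_genetic,
            hen_like_params.cov_direct_social_genetic,
            hen_like_params.var_direct_residual,
            hen_like_params.var_social_residual,
        )  # no group env so the mn -> inf limit is exactly sqrt(r_rel)
        design = GroupDesign(
            4, 0.5, relatedness_candidate_to_relatives=0.5,
            groups_per_candidate=10**7,
        )
        assert accuracy_relatives(p, design) == pytest.approx(
            math.sqrt(0.5), rel=1e-6
        )

    def test_relatives_monotone_in_groups(self, hen_like_params):
        accs = [
            accuracy_relatives(
                hen_like_params,
                GroupDesign(4, 0.5, relatedness_candidate_to_relatives=0.5,
                            groups_per_candidate=m),
            )
            for m in (1, 2, 10)
        ]
        assert accs[0] < accs[1] < accs[2]

    def test_classical_blup_null_social_equals_rho_mme(self, null_social_params):
        assert accuracy_classical_blup(
            null_social_params, GroupDesign(4), 0.6
        ) == pytest.approx(0.6)

    def test_classical_blup_sign_rule(self):
        p = GeneticParameterSet(0.3, 0.4, -0.33, 1.0, 0.3)
        rho = accuracy_classical_blup(p, GroupDesign(4, 0.0), 0.7)
        assert rho < 0

    def test_undefined_accuracy_reported_absent(self):
        p = GeneticParameterSet(0.0, 0.0, 0.0, 1.0, 0.0)
        assert accuracy_individual(p, GroupDesign(4)) is None
        assert accuracy_classical_blup(p, GroupDesign(4), 0.5) is None


class TestResponse:
    def test_delta_g_identity(self, rng):
        for _ in range(20):
            iota = float(rng.uniform(0, 3))
            rho = float(rng.uniform(-1, 1))
            sd = float(rng.uniform(0, 100))
            pred = predict_response(iota, rho, sd)
            assert pred.delta_g == iota * rho * sd

    def test_zero_accuracy_means_zero_response(self):
        assert predict_response(2.4, 0.0, 55.0).delta_g == 0.0

    def test_doubling_sd_tbv_doubles_response(self):
        a = predict_response(1.0, 0.3, 30.0).delta_g
        b = predict_response(1.0, 0.3, 60.0).delta_g
        assert b == pytest.approx(2 * a)

    def test_accuracy_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            predict_response(1.0, 1.2, 10.0)


class TestIntensity:
    def test_half_selected(self):
        assert intensity_from_selected_fraction(0.5) == pytest.approx(
            math.sqrt(2 / math.pi), rel=1e-12
        )

    def test_everything_selected_limit(self):
        assert intensity_from_selected_fraction(1 - 1e-12) < 1e-5

    def test_matches_truncated_normal_quadrature(self):
        p = 0.10
        z = stats.norm.isf(p)
        val, _ = integrate.quad(lambda x: x * stats.norm.pdf(x), z, 12.0)
        assert intensity_from_selected_fraction(p) == pytest.approx(
            val / p, abs=1e-6
        )

    def test_monotone_decreasing(self):
        vals = [intensity_from_selected_fraction(p) for p in (0.05, 0.2, 0.5, 0.9)]
        assert vals == sorted(vals, reverse=True)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.3, 2.0])
    def test_invalid_fraction_rejected(self, bad):
        with pytest.raises(ValueError):
            intensity_from_selected_fraction(bad)
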