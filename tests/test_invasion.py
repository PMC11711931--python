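"""Tests of the analytic invasion machinery against closed forms and the
independent diploid-recursion oracle."""

import numpy as np
import pytest

from chemevol import (
    BenefitParams,
    DominanceParams,
    ModelParams,
    dominance_scan,
    mutant_growth_rate,
    optimal_homozygote,
    polymorphism_possible,
    preset_params,
    simplified_condition,
)
from chemevol.invasion import log_geometric_mean_fitness
from conftest import dom
from oracles import per_env_log_growth_sd, recursion_invades


def _random_params(rng, theta=1.0) -> ModelParams:
    """Random single-herbivore parameter draw with exchangeable loci."""
    return ModelParams(
        L=10, theta=theta, p=rng.uniform(0.05, 0.95),
        M=rng.uniform(0.2, 1.5),
        dom=dom(rng.uniform(0, 1), rng.uniform(0, 1)),
        c=rng.uniform(0.0, 0.15),
        benefit=BenefitParams(b0=rng.uniform(0, 0.8),
                              ahalf=rng.uniform(-1, 4), s=rng.uniform(0.3, 3)),
    )


class TestOptimalHomozygote:
    def test_pure_cost_optimum_is_undefended(self):
        params = ModelParams(p=0.0, dom=dom(0.5, 0.5))
        presence, w = optimal_homozygote(params)
        assert presence.sum() == 0
        assert w == pytest.approx(1.0)

    def test_costless_benefit_optimum_is_fully_defended(self):
        params = ModelParams(c=0.0, p=0.5, dom=dom(0.5, 0.5))
        presence, _ = optimal_homozygote(params)
        assert presence.sum() == 10

    def test_matches_bruteforce_over_counts(self, defaults):
        params = defaults.replace(dom=dom(0.5, 0.5))
        presence, w = optimal_homozygote(params)
        # independent brute force over presence-allele counts
        wt = [np.exp(log_geometric_mean_fitness(
            np.r_[np.ones(r, int), np.zeros(10 - r, int)], params))
            for r in range(11)]
        assert presence.sum() == int(np.argmax(wt))
        assert w == pytest.approx(max(wt), abs=1e-12)

    def test_heterogeneous_effects_bruteforce(self, rng):
        params = ModelParams(L=6, M=rng.uniform(-0.5, 1.5, (6, 1)),
                             p=0.6, dom=dom(0.5, 0.5, 6))
        presence, w = optimal_homozygote(params)
        best = max(range(64), key=lambda b: log_geometric_mean_fitness(
            np.array([(b >> l) & 1 for l in range(6)]), params))
        expected = np.array([(best >> l) & 1 for l in range(6)])
        np.testing.assert_array_equal(presence, expected)


class TestMutantGrowthRate:
    def test_phenotypically_identical_mutant_is_neutral(self, defaults):
        params = defaults.replace(dom=dom(0.0, 0.0))
        res = mutant_growth_rate(np.zeros(10, int), 3, params)
        assert res.lambda_tilde == pytest.approx(1.0, abs=1e-12)
        assert not res.invades

    def test_pure_cost_mutant_closed_form(self):
        # neutral-effect locus with cost: lambda~ = exp(-c*dc) exactly (theta=1)
        params = ModelParams(M=0.0, c=0.05, dom=dom(0.8, 0.6))
        res = mutant_growth_rate(np.zeros(10, int), 0, params)
        assert res.lambda_tilde == pytest.approx(np.exp(-0.05 * 0.6), abs=1e-12)
        assert not res.invades

    def test_theta_one_reduces_to_fitness_ratio_product(self, defaults):
        # for theta=1 and one herbivore: lambda~ = (Wm/Wr)^p * (fm/fr)^(1-p)
        params = defaults.replace(dom=dom(0.9, 0.2))
        resident = np.r_[np.ones(2, int), np.zeros(8, int)]
        res = mutant_growth_rate(resident, 5, params)
        from chemevol import Genotype, fitness
        het = Genotype.from_dose(np.r_[2 * resident[:5], 1, 2 * resident[6:]])
        hom = Genotype.homozygous(resident)
        expected = ((fitness(het, [0], params) / fitness(hom, [0], params)) ** 0.2
                    * (fitness(het, [], params) / fitness(hom, [], params)) ** 0.8)
        assert res.lambda_tilde == pytest.approx(expected, abs=1e-12)

    def test_continuous_at_zero_dominance(self, defaults):
        lam = [mutant_growth_rate(np.zeros(10, int), 0,
                                  defaults.replace(dom=dom(eps, eps))).lambda_tilde
               for eps in (1e-9, 1e-6, 1e-3)]
        assert lam[0] == pytest.approx(1.0, abs=1e-6)
        assert abs(lam[2] - 1.0) < 1e-2


class TestPolymorphismPossible:
    def test_zero_dominance_never_polymorphic(self, defaults):
        assert not polymorphism_possible(defaults.replace(dom=dom(0, 0)))

    def test_costless_full_genotype_uninvadable(self):
        params = ModelParams(c=0.0, p=0.5, dom=dom(0.8, 0.2))
        assert not polymorphism_possible(params)

    def test_dominance_reversal_corner_polymorphic(self, defaults):
        assert polymorphism_possible(defaults.replace(dom=dom(1.0, 0.0)))

    def test_collapsed_matches_full_enumeration(self, rng):
        # exchangeable loci: count-collapsed residents agree with all 2^L
        for _ in range(5):
            params = _random_params(rng).replace(L=6, M=1.0,
                                                 dom=dom(rng.uniform(0, 1),
                                                         rng.uniform(0, 1), 6))
            collapsed = polymorphism_possible(params)
            full = polymorphism_possible(
                params.replace(M=np.ones((6, 1)) + 0.0,
                               dom=DominanceParams(
                                   params.dom.da + np.zeros(6),
                                   params.dom.dc + np.zeros(6))))
            assert collapsed == full


class TestSimplifiedCondition:
    def test_agrees_with_growth_rate_over_random_draws(self, rng):
        """Two independent code paths give identical invadability booleans."""
        from chemevol.invasion import _iter_residents, _resident_invadable
        for _ in range(100):
            params = _random_params(rng)
            for r, presence in enumerate(_iter_residents(params)):
                via_lambda = _resident_invadable(presence, params, collapsed=True)
                assert simplified_condition(r, params) == via_lambda

    def test_boundary_residents_check_one_mutant(self):
        # r=0: only the addition mutant exists; pure-cost addition never invades
        params = ModelParams(M=0.0, c=0.05, dom=dom(1.0, 1.0))
        assert not simplified_condition(0, params)

    def test_requires_simplifying_assumptions(self, defaults):
        with pytest.raises(ValueError):
            simplified_condition(0, defaults.replace(theta=0.5))


class TestDominanceScan:
    def test_no_herbivory_zero_scope(self):
        scan = dominance_scan(ModelParams(p=0.0), grid_step=0.25)
        assert scan.scope_percent == 0.0

    def test_costless_zero_scope(self):
        scan = dominance_scan(ModelParams(c=0.0, p=0.5), grid_step=0.25)
        assert scan.scope_percent == 0.0

    def test_scope_invariant_to_phase_length(self):
        params = preset_params("fluctuating")
        s1 = dominance_scan(params.replace(g=1), grid_step=0.25)
        s5 = dominance_scan(params.replace(g=5), grid_step=0.25)
        np.testing.assert_array_equal(s1.polymorphic, s5.polymorphic)

    def test_fluctuating_region_roughly_above_diagonal(self):
        scan = dominance_scan(preset_params("fluctuating"), grid_step=0.1)
        da, dc = np.meshgrid(scan.da_values, scan.dc_values, indexing="ij")
        # polymorphism requires activity dominance >= cost dominance (roughly)
        assert not scan.polymorphic[da + 0.05 < dc].any()
        assert scan.polymorphic[(da > 0.5) & (dc < 0.5)].all()


class TestRecursionOracle:
    def test_invasion_verdict_matches_recursion(self, rng):
        """Sign of log lambda~ agrees with the long-run fate of a rare allele
        in the deterministic diploid recursion (spot check; the full
        200-draw sweep runs in the acceptance suite)."""
        checked = 0
        while checked < 25:
            theta = 1.0 if checked % 2 == 0 else 0.3
            params = _random_params(rng, theta=theta)
            r = int(rng.integers(0, params.L + 1))
            presence = np.r_[np.ones(r, int), np.zeros(params.L - r, int)]
            locus = int(rng.integers(0, params.L))
            res = mutant_growth_rate(presence, locus, params)
            sd = per_env_log_growth_sd(presence, locus, params)
            if abs(np.log(res.lambda_tilde)) < max(6 * sd / np.sqrt(50_000 / params.g), 1e-9):
                continue  # indistinguishable from neutral at this sequence length
            assert recursion_invades(presence, locus, params, rng) == res.invades
            checked += 1
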