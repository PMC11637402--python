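"""Unit and property tests for the local background-selection theory."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bgsisland import (
    IslandParams,
    SelectionSegment,
    classic_B_region,
    classic_B_site_sum,
    decay_factor_Z,
    fixation_rate,
    heterozygosity_B,
    q_infinity_sq_point,
    q_infinity_sq_region,
    solve_local_equilibrium,
)


class TestClassicB:
    def test_empty_site_list_gives_no_reduction(self):
        assert classic_B_site_sum([], [], []) == 1.0

    def test_single_tightly_linked_site(self):
        b = classic_B_site_sum([1e-5], [0.015], [0.0])
        assert b == pytest.approx(math.exp(-1e-5 / 0.015), rel=1e-12)

    def test_site_sum_equals_region_formula_without_recombination(self):
        b_sites = classic_B_site_sum([1e-5] * 700, [0.015] * 700, [0.0] * 700)
        b_region = classic_B_region(7e-3, 0.015, 0.0)
        assert b_sites == pytest.approx(b_region, rel=1e-12)
        assert b_region == pytest.approx(0.6270890852, rel=1e-8)

    def test_region_formula_examples(self):
        assert classic_B_region(0.0, 0.015, 0.0) == 1.0
        assert classic_B_region(7e-3, 0.015, 0.01) == pytest.approx(
            math.exp(-0.014 / 0.04), rel=1e-12)

    def test_unselected_site_rejected(self):
        with pytest.raises(ValueError):
            classic_B_site_sum([1e-5], [0.0], [0.0])
        with pytest.raises(ValueError):
            classic_B_region(1e-3, 0.0, 0.0)

    def test_recombination_weakens_reduction(self):
        assert classic_B_region(7e-3, 0.015, 0.01) > classic_B_region(
            7e-3, 0.015, 0.0)


class TestDecayFactorZ:
    def test_strong_selection_limit_is_one_minus_t(self):
        z, clamped = decay_factor_Z(7e-3, 0.015, 0.0)
        assert z == pytest.approx(0.985, abs=1e-12)
        assert not clamped

    def test_weak_selection_value(self):
        z, clamped = decay_factor_Z(7e-3, 0.0005, 0.003)
        assert z == pytest.approx(1.0 - (7e-3 * 5e-4) / 1e-3, rel=1e-12)
        assert not clamped

    def test_fixation_dominated_segment_is_clamped_to_zero(self):
        z, clamped = decay_factor_Z(7e-3, 0.01, 3.5e-3)
        assert z == 0.0 and clamped
        z, clamped = decay_factor_Z(7e-3, 0.01, 5e-3)
        assert z == 0.0 and clamped


class TestLinkageInflation:
    def test_no_association_gives_unity(self):
        assert q_infinity_sq_point(0.0, 0.0, 0.0) == 1.0

    def test_tight_linkage_no_migration(self):
        q = q_infinity_sq_point(0.0, 1 - 0.015, 0.0)
        assert q == pytest.approx((1 / 0.015) ** 2, rel=1e-12)

    def test_migration_shrinks_inflation(self):
        q = q_infinity_sq_point(0.0, 1 - 0.015, 0.09)
        assert q == pytest.approx((1 / (1 - 0.985 * 0.91)) ** 2, rel=1e-9)
        assert q < q_infinity_sq_point(0.0, 1 - 0.015, 0.0)

    def test_divergent_geometric_sum_rejected(self):
        with pytest.raises(ValueError):
            q_infinity_sq_point(0.0, 1.0, 0.0)

    def test_region_average_reduces_to_point_at_zero_map_length(self):
        assert q_infinity_sq_region(0.0, 0.985, 0.0) == pytest.approx(
            q_infinity_sq_point(0.0, 0.985, 0.0), rel=1e-12)

    @pytest.mark.parametrize("M", [1e-4, 1e-3, 0.01, 0.1])
    @pytest.mark.parametrize("Z", [0.9, 0.985, 0.999, 0.9999])
    @pytest.mark.parametrize("m", [0.0, 0.00045, 0.009, 0.1])
    def test_region_average_matches_quadrature(self, M, Z, m):
        """Closed form equals the numerical average of the point formula
        over recombination fractions in [0, M/2] (adaptive quadrature)."""
        from scipy.integrate import quad
        integral, _ = quad(q_infinity_sq_point, 0.0, M / 2, args=(Z, m),
                           epsabs=0.0, epsrel=1e-11, limit=200)
        numeric = integral / (M / 2)
        assert q_infinity_sq_region(M, Z, m) == pytest.approx(numeric, rel=1e-6)


class TestFixationRate:
    def test_neutral_limit_equals_mutation_rate(self):
        assert fixation_rate(500, 7e-3, 0.0) == pytest.approx(7e-3, rel=1e-12)
        # continuity for tiny t
        assert fixation_rate(500, 7e-3, 1e-15) == pytest.approx(7e-3, rel=1e-9)

    def test_strong_selection_value(self):
        r = fixation_rate(500, 7e-3, 0.015)
        assert r == pytest.approx(0.21 / (math.exp(30) - 1), rel=1e-9)

    def test_vanishes_for_large_scaled_selection(self):
        assert fixation_rate(1e6, 7e-3, 0.015) < 1e-100

    @given(st.floats(0.1, 500.0), st.floats(1e-6, 0.05))
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing_in_scaled_selection(self, nf, t):
        assert fixation_rate(nf * 1.5, 7e-3, t) < fixation_rate(nf, 7e-3, t)

    @given(st.floats(1.0, 1e4), st.floats(0.0, 0.5))
    @settings(max_examples=50, deadline=None)
    def test_bounded_by_mutation_rate(self, nf, t):
        r = fixation_rate(nf, 7e-3, t)
        assert 0.0 <= r <= 7e-3


class TestLocalEquilibrium:
    def test_no_selection_gives_no_reduction(self):
        island = IslandParams(d=10, N_local=500, m=0.009)
        seg = SelectionSegment(t=0.015, mu_del=0.0, L=700, M=0.0)
        res = solve_local_equilibrium(island, [seg])
        assert res.B_local == 1.0
        assert res.R == 0.0

    def test_strong_selection_agrees_with_classic_theory(self, study_segment):
        """With N_local*t = 7.5 and no migration, the quantitative-genetic
        solution approaches the deterministic mutation-selection-balance B."""
        island = IslandParams(d=10, N_local=500, m=0.0)
        res = solve_local_equilibrium(island, [study_segment])
        classic = classic_B_region(7e-3, 0.015, 0.0)
        assert res.converged
        assert res.B_local == pytest.approx(classic, rel=0.10)

    def test_solution_is_self_consistent(self, study_segment):
        """The returned (B, R) satisfy both coupled equations."""
        island = IslandParams(d=10, N_local=500, m=0.009)
        res = solve_local_equilibrium(island, [study_segment])
        diag = res.diagnostics[0]
        assert diag.R == pytest.approx(
            fixation_rate(res.B_local * 500, study_segment.U, study_segment.t),
            rel=1e-8)
        theta = diag.V_A * diag.Q_inf_sq / 2.0
        assert res.B_local == pytest.approx(math.exp(-theta), rel=1e-8)

    @pytest.mark.parametrize("t", [0.0005, 0.005, 0.015])
    def test_migration_weakens_background_selection(self, t):
        """B_local is non-decreasing in the migration rate: emigration
        truncates a neutral lineage's association with deleterious
        backgrounds."""
        bs = []
        for m in (0.0, 0.001, 0.01, 0.09):
            isl = IslandParams(d=10, N_local=500, m=m)
            seg = SelectionSegment(t=t, mu_del=1e-5, L=700, M=0.0)
            bs.append(solve_local_equilibrium(isl, [seg]).B_local)
        assert all(b2 >= b1 for b1, b2 in zip(bs, bs[1:]))

    def test_mutation_pressure_strengthens_background_selection(self):
        island = IslandParams(d=10, N_local=500, m=0.001)
        bs = []
        for mu in (1e-6, 5e-6, 1e-5, 2e-5):
            seg = SelectionSegment(t=0.015, mu_del=mu, L=700, M=0.0)
            bs.append(solve_local_equilibrium(island, [seg]).B_local)
        assert all(b2 <= b1 for b1, b2 in zip(bs, bs[1:]))

    def test_migration_effect_flag_off_reproduces_panmictic_solution(
            self, study_segment):
        migr = IslandParams(d=10, N_local=500, m=0.09)
        pan = IslandParams(d=10, N_local=500, m=0.0)
        off = solve_local_equilibrium(migr, [study_segment],
                                      apply_migration_effect=False)
        ref = solve_local_equilibrium(pan, [study_segment])
        assert off.B_local == pytest.approx(ref.B_local, rel=1e-10)

    def test_recombination_weakens_reduction(self):
        island = IslandParams(d=10, N_local=500, m=0.0)
        b0 = solve_local_equilibrium(
            island, [SelectionSegment(0.015, 1e-5, 700, M=0.0)]).B_local
        b1 = solve_local_equilibrium(
            island, [SelectionSegment(0.015, 1e-5, 700, M=0.01)]).B_local
        assert b1 > b0


class TestHeterozygosityB:
    def test_neutral_limit_recovers_unity(self):
        island = IslandParams(d=10, N_local=200, m=0.009)
        seg = SelectionSegment(t=0.015, mu_del=0.0, L=700, M=0.0)
        res = solve_local_equilibrium(island, [seg])
        n_eh, b_het = heterozygosity_B(island, [seg], res)
        assert b_het == pytest.approx(1.0, abs=1e-10)
        assert n_eh == pytest.approx(200.0, abs=1e-6)

    @pytest.mark.parametrize("t,m", [(0.0005, 0.00045), (0.005, 0.001),
                                     (0.015, 0.0), (0.015, 0.009)])
    def test_ordering_between_fitness_and_census_size(self, t, m):
        """N_f <= N_eH <= N_local: equilibrium diversity reflects alleles
        of all ages, most of which have not reached the asymptotic
        association."""
        island = IslandParams(d=10, N_local=500, m=m)
        seg = SelectionSegment(t=t, mu_del=1e-5, L=700, M=0.0)
        res = solve_local_equilibrium(island, [seg])
        _, b_het = heterozygosity_B(island, [seg], res)
        assert res.B_local < b_het <= 1.0

    def test_time_dependent_factor_approaches_asymptote(self, study_segment):
        from bgsisland.bgs_theory import _q_sq_tau_region
        island = IslandParams(d=10, N_local=500, m=0.009)
        res = solve_local_equilibrium(island, [study_segment])
        diag = res.diagnostics[0]
        q_tau = _q_sq_tau_region(0.0, diag.Z, island.m,
                                 np.array([0.0, 1e6]))
        assert q_tau[0] == 0.0
        assert q_tau[1] == pytest.approx(
            q_infinity_sq_region(0.0, diag.Z, island.m), rel=1e-9)
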