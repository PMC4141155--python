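"""Equilibrium solver, constant estimation, and replicate statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gqbind.assign import SpeciesAbundanceTable
from gqbind.binding import (
    BindingConstants,
    EquilibriumState,
    SaturationError,
    affinity_ratio,
    concentrations_from_areas,
    estimate_constants,
    format_constant,
    fraction_bound,
    replicate_summary,
    solve_equilibrium,
)

DNA_K = BindingConstants(K1=1.87e6, K2=2.83e5)
RNA_K = BindingConstants(K1=5.62e7, K2=2.62e6)


def _table(areas):
    return SpeciesAbundanceTable(areas=areas)


class TestFractionBound:
    def test_free_only_is_zero(self):
        assert fraction_bound(_table({(0, 0): 5.0})) == 0.0

    def test_equal_free_and_bound_is_half(self):
        assert fraction_bound(_table({(0, 0): 3.0, (1, 0): 3.0})) == 0.5

    def test_equilibrium_proportional_areas(self):
        """Areas proportional to the solved equilibrium at the DNA constants."""
        state = solve_equilibrium(10e-6, 10e-6, DNA_K)
        table = _table({(0, 0): state.free_q, (1, 0): state.c11, (2, 0): state.c12})
        assert fraction_bound(table) == pytest.approx(0.7228, abs=0.002)

    def test_counterion_only_policy(self):
        table = _table({(0, 0): 2.0, (0, 1): 1.0, (1, 0): 1.0})
        assert fraction_bound(table) == pytest.approx(0.25)
        assert fraction_bound(table, counterion_only_is_bound=True) == pytest.approx(0.5)

    def test_scale_invariance(self):
        areas = {(0, 0): 1.0, (1, 0): 2.0, (2, 1): 0.5}
        f1 = fraction_bound(_table(areas))
        f2 = fraction_bound(_table({k: 137.5 * v for k, v in areas.items()}))
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            fraction_bound(_table({}))


class TestConcentrationsFromAreas:
    def test_even_split(self):
        state = concentrations_from_areas(_table({(0, 0): 50.0, (1, 0): 50.0}), 10e-6, 10e-6)
        assert state.free_q == pytest.approx(5e-6)
        assert state.c11 == pytest.approx(5e-6)
        assert state.free_l == pytest.approx(5e-6)

    def test_saturation_boundary_errors(self):
        table = _table({(0, 0): 25.0, (1, 0): 50.0, (2, 0): 25.0})
        with pytest.raises(SaturationError, match="mass balance"):
            concentrations_from_areas(table, 10e-6, 10e-6)

    def test_equilibrium_areas_close_ligand_balance(self):
        # by-difference arithmetic on the given (rounded) areas:
        # 10 - 5.547 - 2*1.6805 = 1.092 µM; the unrounded solver areas
        # at the DNA constants give 1.0745 µM (see solver round trip)
        table = _table({(0, 0): 27.725, (1, 0): 55.470, (2, 0): 16.805})
        state = concentrations_from_areas(table, 10e-6, 10e-6)
        assert state.free_l == pytest.approx(1.092e-6, rel=1e-9)
        exact = solve_equilibrium(10e-6, 10e-6, DNA_K)
        assert exact.free_l == pytest.approx(1.0745e-6, abs=0.001e-6)

    def test_counterion_adducts_collapse_into_their_ligand_class(self):
        split = concentrations_from_areas(
            _table({(0, 0): 30.0, (0, 2): 20.0, (1, 0): 25.0, (1, 1): 25.0}),
            10e-6, 10e-6,
        )
        merged = concentrations_from_areas(
            _table({(0, 0): 50.0, (1, 0): 50.0}), 10e-6, 10e-6
        )
        assert split == merged

    def test_higher_stoichiometry_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            concentrations_from_areas(_table({(0, 0): 1.0, (3, 0): 1.0}), 10e-6, 10e-6)


class TestEstimateConstants:
    def test_simple_arithmetic(self):
        state = EquilibriumState(free_q=2.5e-6, c11=2.5e-6, c12=0.0, free_l=7.5e-6)
        k = estimate_constants(state)
        assert k.K1 == pytest.approx(1 / 7.5e-6, rel=1e-12)
        assert k.K2 == 0.0
        assert not k.k2_estimable

    @pytest.mark.parametrize("truth", [DNA_K, RNA_K], ids=["DNA", "RNA"])
    def test_round_trip_recovers_table_constants(self, truth):
        state = solve_equilibrium(10e-6, 10e-6, truth)
        k = estimate_constants(state)
        assert k.K1 == pytest.approx(truth.K1, rel=1e-6)
        assert k.K2 == pytest.approx(truth.K2, rel=1e-6)

    def test_zero_components_rejected(self):
        with pytest.raises(ValueError):
            estimate_constants(EquilibriumState(0.0, 1e-6, 0.0, 1e-6))
        with pytest.raises(ValueError):
            estimate_constants(EquilibriumState(1e-6, 0.0, 0.0, 1e-6))


class TestSolveEquilibrium:
    def test_zero_constants_leave_everything_free(self):
        state = solve_equilibrium(10e-6, 10e-6, BindingConstants(0.0, 0.0))
        assert state.free_q == 10e-6
        assert state.free_l == 10e-6
        assert state.c11 == 0.0

    def test_dna_fraction_bound(self):
        state = solve_equilibrium(10e-6, 10e-6, DNA_K)
        assert 100 * state.fraction_bound == pytest.approx(72.28, abs=0.1)

    def test_mass_balances_conserved(self):
        state = solve_equilibrium(7e-6, 13e-6, RNA_K)
        assert state.total_q == pytest.approx(7e-6, rel=1e-12)
        assert state.total_l == pytest.approx(13e-6, rel=1e-12)

    @given(
        logk1=st.floats(4, 9),
        logk2=st.floats(3, 8),
        c_um=st.floats(1, 50),
    )
    @settings(max_examples=100, deadline=None)
    def test_estimate_inverts_solve(self, logk1, logk2, c_um):
        truth = BindingConstants(10**logk1, 10**logk2)
        c = c_um * 1e-6
        state = solve_equilibrium(c, c, truth)
        if state.free_l < 1e-12:  # saturated: estimator input degenerate
            return
        k = estimate_constants(state)
        assert k.K1 == pytest.approx(truth.K1, rel=1e-6)
        assert k.K2 == pytest.approx(truth.K2, rel=1e-6)

    def test_fraction_bound_monotone_in_k1(self):
        base = solve_equilibrium(10e-6, 10e-6, DNA_K).fraction_bound
        up_k1 = solve_equilibrium(10e-6, 10e-6, BindingConstants(2 * DNA_K.K1, DNA_K.K2))
        assert up_k1.fraction_bound >= base

    def test_fraction_bound_monotone_in_k2_under_ligand_excess(self):
        """With ligand in large excess, stronger second binding can only
        raise the bound fraction."""
        base = solve_equilibrium(10e-6, 100e-6, DNA_K).fraction_bound
        up_k2 = solve_equilibrium(10e-6, 100e-6, BindingConstants(DNA_K.K1, 2 * DNA_K.K2))
        assert up_k2.fraction_bound >= base

    def test_fraction_bound_can_drop_with_k2_when_ligand_limited(self):
        """At equimolar totals each 1:2 complex sequesters two ligands, so
        strengthening K2 depletes free ligand and can lower the fraction
        of quadruplex that is bound at all."""
        base = solve_equilibrium(10e-6, 10e-6, DNA_K).fraction_bound
        up_k2 = solve_equilibrium(10e-6, 10e-6, BindingConstants(DNA_K.K1, 2 * DNA_K.K2))
        assert up_k2.fraction_bound < base

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            solve_equilibrium(-1e-6, 1e-6, DNA_K)
        with pytest.raises(ValueError):
            solve_equilibrium(float("nan"), 1e-6, DNA_K)


class TestNoisyRecovery:
    def test_k1_recovery_within_three_sd(self):
        """5 % multiplicative area noise, n = 3: mean K1 within 3 SD of truth."""
        rng = np.random.default_rng(42)
        truth_state = solve_equilibrium(10e-6, 10e-6, DNA_K)
        k1s = []
        for _ in range(3):
            noisy = {
                (0, 0): truth_state.free_q * rng.lognormal(0, 0.05),
                (1, 0): truth_state.c11 * rng.lognormal(0, 0.05),
                (2, 0): truth_state.c12 * rng.lognormal(0, 0.05),
            }
            state = concentrations_from_areas(_table(noisy), 10e-6, 10e-6)
            k1s.append(estimate_constants(state).K1)
        stats = replicate_summary(k1s)
        assert abs(stats.mean - DNA_K.K1) < 3 * stats.sd


class TestReplicateStats:
    def test_table_style_triplet(self):
        stats = replicate_summary([1.68e6, 1.87e6, 2.06e6])
        assert stats.mean == pytest.approx(1.87e6)
        assert stats.sd == pytest.approx(1.9e5, rel=1e-6)
        assert stats.n == 3

    def test_single_value_has_no_sd(self):
        stats = replicate_summary([5.0])
        assert stats.mean == 5.0
        assert stats.sd is None
        assert "n=1" in stats.format()

    def test_constant_replicates_zero_sd(self):
        assert replicate_summary([2.0, 2.0, 2.0]).sd == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            replicate_summary([])


class TestAffinityComparison:
    def test_rna_vs_dna_ratios(self):
        r1, r2 = affinity_ratio(RNA_K, DNA_K)
        assert r1 == pytest.approx(30.05, abs=0.05)
        assert r2 == pytest.approx(9.258, abs=0.01)
        assert r1 >= 10 and r2 >= 9

    def test_identical_constants(self):
        assert affinity_ratio(DNA_K, DNA_K) == (1.0, 1.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            affinity_ratio(DNA_K, BindingConstants(0.0, 0.0))


class TestFormatting:
    def test_report_style(self):
        assert format_constant(1.87e6) == "1.87 × 10^6 M⁻¹"
        assert format_constant(5.62e7) == "5.62 × 10^7 M⁻¹"
        assert format_constant(0.0) == "not estimable"
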