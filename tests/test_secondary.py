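import numpy as np
import pytest

from simep.kinetics import bv_current, platinum_water, solve_1d_cell
from simep.secondary import (
    SecondaryCellSpec,
    centerline_profile,
    insulator_centre_field,
    power_input,
    solve_facing_cell,
    solve_secondary,
    sweep_secondary,
)


class TestSpecValidation:
    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SecondaryCellSpec(sigma=-1.0)
        with pytest.raises(ValueError):
            SecondaryCellSpec(V_app=0.0)


class TestEquilibriumAndNoDrive:
    def test_applied_equals_cell_equilibrium_gives_no_current(self):
        sol = solve_secondary(SecondaryCellSpec(sigma=0.005, V_app=2.06), n_base=16)
        assert abs(sol.I_total) < 1e-12
        assert abs(sol.P) < 1e-10
        assert insulator_centre_field(sol) < 1e-6  # kV/cm

    def test_below_open_circuit_flagged_no_drive(self):
        sol = solve_secondary(SecondaryCellSpec(sigma=0.005, V_app=1.5), n_base=16)
        assert sol.no_drive
        assert sol.I_total < 0


class TestConvergedSolutionInvariants:
    def test_charge_conservation_within_one_percent(self, secondary_reference_solution):
        sol = secondary_reference_solution
        Ia = sol.anode_current.total
        Ic = sol.cathode_current.total
        assert Ia > 0 > Ic
        assert abs(Ia + Ic) / abs(Ia) < 0.01

    def test_voltage_budget_closes_within_two_percent(self, secondary_reference_solution):
        d = secondary_reference_solution.diagnostics
        assert d["voltage_budget"] == pytest.approx(2.9, rel=0.02)
        assert d["eta_a_mean"] > 0 > d["eta_c_mean"]
        assert d["ohmic_drop"] > 0

    def test_field_current_consistency_at_anode(self, secondary_reference_solution):
        # sigma * normal field at the electrode equals the local kinetic
        # current density (the discrete boundary condition, re-extracted
        # from the potential by one-sided differences)
        sol = secondary_reference_solution
        spec = sol.spec
        seg = sol.phi.grid.segments["anode"]
        phi_s = sol.phi.values[0, seg.lo : seg.hi + 1]
        i_kin = bv_current(
            spec.V_app - phi_s - spec.kinetics.anode.E_eq, spec.kinetics.anode
        )
        density = sol.anode_current.density
        # compare away from the singular junction (current crowding makes
        # the one-sided extraction lose accuracy on the last few nodes)
        m = slice(0, seg.n_nodes - 5)
        assert density[m] == pytest.approx(i_kin[m], rel=0.02)

    def test_kinetic_total_matches_gradient_total(self, secondary_reference_solution):
        sol = secondary_reference_solution
        assert sol.I_total == pytest.approx(sol.anode_current.total, rel=0.01)


class TestOneDOracleAgreement:
    def test_facing_cell_matches_closed_form(self):
        k = platinum_water()
        for V in (2.5, 2.9):
            i2d = solve_facing_cell(1e-5, 1e-5, 0.005, V, k, n=21)
            ref = solve_1d_cell(1e-5, 0.005, V, k)
            assert i2d == pytest.approx(ref.current_density, rel=0.02)


@pytest.fixture(scope="module")
def small_sweep():
    return sweep_secondary([0.0005, 0.005, 0.05], [2.4, 2.7, 3.1, 3.5], n_base=16)


@pytest.fixture(scope="module")
def low_sigma_solution():
    return solve_secondary(SecondaryCellSpec(sigma=0.0005, V_app=2.9), n_base=32)


class TestTrends:
    def test_sweep_cardinality_and_convergence(self, small_sweep):
        assert len(small_sweep) == 12
        assert small_sweep.converged.all()

    def test_current_monotone_in_applied_voltage(self, small_sweep):
        for sigma, sub in small_sweep.groupby("sigma"):
            I = sub.sort_values("V_app").I_total.values
            assert all(b > a for a, b in zip(I, I[1:]))

    def test_field_decreases_with_conductivity_at_fixed_voltage(self, small_sweep):
        sub = small_sweep[small_sweep.V_app == 2.7].sort_values("sigma")
        E = sub.E_centre_kV_cm.values
        assert all(b < a for a, b in zip(E, E[1:]))

    def test_field_spread_across_conductivities_shrinks_at_high_voltage(self, small_sweep):
        # the sluggish anode limits the current, so at high voltage the
        # field distribution becomes nearly conductivity-independent
        def rel_spread(V):
            E = small_sweep[small_sweep.V_app == V].E_centre_kV_cm.values
            return (E.max() - E.min()) / E.mean()

        assert rel_spread(3.5) < rel_spread(2.7)

    def test_power_positive_above_open_circuit(self, small_sweep):
        assert (small_sweep.P_uW_cm2 > 0).all()


class TestProfileAndPower:
    @pytest.fixture()
    def sol(self, low_sigma_solution):
        return low_sigma_solution

    def test_profile_has_one_row_per_grid_row(self, sol):
        prof = centerline_profile(sol)
        assert len(prof) == sol.phi.grid.ny
        assert (np.diff(prof.y_um) > 0).all()

    def test_profile_decays_away_from_insulator(self, sol):
        prof = centerline_profile(sol)
        E = prof.E_kV_cm.values
        tail = E[3:]
        assert all(b <= a * (1 + 1e-9) for a, b in zip(tail, tail[1:]))
        assert E[0] == pytest.approx(E.max(), rel=1e-6)

    def test_reversible_field_reaches_into_the_channel(self, sol):
        # at 2.9 V in low-conductivity water the 1 kV/cm reversible
        # threshold is exceeded out to a few hundred nanometres
        prof = centerline_profile(sol)
        reach = prof[prof.E_kV_cm >= 1.0].y_um.max()
        assert 0.2 <= reach <= 1.2

    def test_power_input_consistent_with_current(self, sol):
        spec = sol.spec
        expect = spec.V_app * sol.I_total / spec.geometry.length * 100.0
        assert power_input(sol) == pytest.approx(expect, rel=1e-12)
        assert sol.P == pytest.approx(expect, rel=1e-12)


class TestSweepErrors:
    def test_empty_lists_rejected(self):
        with pytest.raises(ValueError):
            sweep_secondary([], [2.5])

    def test_caller_ordering_preserved(self):
        t = sweep_secondary([0.05, 0.005], [2.5, 2.3], n_base=16)
        assert list(t.sigma) == [0.05, 0.05, 0.005, 0.005]
        assert list(t.V_app) == [2.5, 2.3, 2.5, 2.3]
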