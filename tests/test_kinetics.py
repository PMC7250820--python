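"""Compartment-model dynamics, measurement operators and inhibitor gating."""

import dataclasses

import numpy as np
import pytest
from scipy.linalg import expm

import periphos as pp
from periphos.constants import AVOGADRO


def single_pulse_design(conc=1e-8, rho=2e10, times=(10, 30, 60, 120), **kw):
    return pp.ExperimentDesign(
        cell_density=rho,
        additions=(pp.Addition(0.0, "P33", conc),),
        sampling_times=times,
        protocols=(pp.Protocol.ASW,),
        replicates=1,
        **kw,
    )


class TestSimulateBasics:
    def test_zero_clearance_leaves_cells_empty(self):
        params = pp.KineticParameters(clearance_cl=0.0)
        traj = pp.simulate(params, single_pulse_design())
        for pool in ("adsorbed", "periplasm", "cyto_labile", "macromolecule"):
            assert np.all(traj.pool("P33", pool) == 0.0)
        assert np.all(traj.seawater_conc("P33") == pytest.approx(1e-8, rel=1e-12))

    def test_linear_chain_matches_matrix_exponential(self):
        """In the linear-import regime the model is a first-order chain whose
        exact solution is a matrix exponential."""
        # enormous Km keeps the importer far from saturation (P/K ~ 1e-10)
        params = pp.KineticParameters(
            clearance_cl=1.8e-13, import_vmax=1.2e11, import_km=1e6,
            assim_rate=0.05,
        )
        rho = 2e10
        design = single_pulse_design(rho=rho, times=(5, 15, 45, 90, 180))
        traj = pp.simulate(params, design, rtol=1e-12, atol=1e-9)

        k_acc = params.clearance_cl * rho
        k_imp = params.import_vmax / params.import_k_molecules
        ka = params.assim_rate
        A = np.array(
            [
                [-k_acc, 0, 0, 0],
                [k_acc, -k_imp, 0, 0],
                [0, k_imp, -ka, 0],
                [0, 0, ka, 0],
            ]
        )
        y0 = np.array([1e-8 * AVOGADRO / rho, 0, 0, 0])
        for t in (5, 15, 45, 90, 180):
            oracle = expm(A * t) @ y0
            idx = np.flatnonzero(traj.times == t)[0]
            got = traj.states[idx, 0, [0, 2, 3, 4]]
            assert got == pytest.approx(oracle, rel=1e-6)

    def test_mass_conserved_between_additions(self, fig3_trajectory):
        """Per-channel label totals stay constant to 1e-9 relative."""
        traj = fig3_trajectory
        tot33 = traj.total_label("P33")
        assert np.all(np.abs(tot33 / tot33[0] - 1) < 1e-9)
        post = traj.times >= 120
        tot32 = traj.total_label("P32")[post]
        assert np.all(np.abs(tot32 / tot32[0] - 1) < 1e-9)

    def test_macromolecules_nondecreasing_seawater_nonincreasing(self, fig3_trajectory):
        traj = fig3_trajectory
        for ch in pp.CHANNELS:
            assert np.all(np.diff(traj.pool(ch, "macromolecule")) >= -1e-9)
        sw33 = traj.pool("P33", "seawater")
        assert np.all(np.diff(sw33) <= 1e-9 * sw33[0])

    def test_depletion_matches_closed_form(self):
        """Seawater follows c0*exp(-CL rho t) even with import and
        assimilation running (no return flux exists)."""
        params = pp.fig3_default_parameters()
        rho = 2e10
        design = single_pulse_design(rho=rho, times=(15, 60, 240, 600))
        traj = pp.simulate(params, design)
        expected = pp.seawater_depletion_closed_form(params, rho, 1e-8, traj.times)
        assert traj.seawater_conc("P33") == pytest.approx(expected, rel=1e-3)

    def test_accumulation_proportional_to_concentration(self):
        """Accumulation rate scales linearly with seawater P_i over
        1e-13..1e-6 mol/l (log-log slope 1)."""
        params = pp.fig3_default_parameters()
        concs = 10.0 ** np.arange(-13, -5.9, 1.0)
        accumulated = []
        for c in concs:
            traj = pp.simulate(params, single_pulse_design(conc=c, rho=1e9, times=(10.0,)))
            cell = traj.total_label("P33") - traj.pool("P33", "seawater")
            accumulated.append(cell[traj.times == 10.0][0])
        slope = np.polyfit(np.log10(concs), np.log10(accumulated), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.01)


class TestClosedFormDepletion:
    def test_initial_value(self):
        p = pp.KineticParameters()
        assert pp.seawater_depletion_closed_form(p, 1e10, 1e-9, 0.0) == 1e-9

    def test_six_orders_of_depletion(self):
        """CL*rho*t = ln(1e6) takes a 1e-9 mol/l tracer to the 1e-15
        detection limit."""
        p = pp.KineticParameters(clearance_cl=1.8e-13)
        rho = 2e10
        t = np.log(1e6) / (p.clearance_cl * rho)
        assert pp.seawater_depletion_closed_form(p, rho, 1e-9, t) == pytest.approx(1e-15, rel=1e-9)


class TestMeasurementOperators:
    def test_zero_state_measures_zero(self, fig3_params):
        state = pp.CompartmentState.from_internal(np.zeros(10), 2e10)
        for proto in pp.Protocol:
            assert pp.apply_measurement(state, proto, fig3_params)["P33"] == 0.0

    def test_pool_sums_per_protocol(self):
        params = pp.KineticParameters(pfa_retained_fraction=0.0)
        y = np.zeros(10)
        y[2], y[3], y[4] = 100.0, 10.0, 5.0  # periplasm, cyto, macromolecule
        state = pp.CompartmentState.from_internal(y, 2e10)
        get = lambda proto: pp.apply_measurement(state, proto, params)["P33"]
        assert get("ASW") == 115.0
        assert get("DW") == 15.0
        assert get("PFA") == 5.0
        assert get("TCA") == 5.0

    def test_pfa_retains_fraction_of_periplasm(self):
        params = pp.KineticParameters(pfa_retained_fraction=0.2)
        y = np.zeros(10)
        y[2], y[4] = 50.0, 5.0
        state = pp.CompartmentState.from_internal(y, 2e10)
        assert pp.apply_measurement(state, "PFA", params)["P33"] == pytest.approx(15.0)

    def test_unknown_protocol_rejected(self, fig3_params):
        state = pp.CompartmentState.from_internal(np.zeros(10), 2e10)
        with pytest.raises(ValueError):
            pp.apply_measurement(state, "XYZ", fig3_params)

    def test_labile_pool_dwarfs_assimilated_at_three_hours(
        self, fig3_trajectory, fig3_params
    ):
        """At 3 h of the reference pulse-chase the labile pulse label is
        10-20x the macromolecule-assimilated pulse label."""
        state = fig3_trajectory.state_at(180.0)
        asw = pp.apply_measurement(state, "ASW", fig3_params)["P33"]
        pfa = pp.apply_measurement(state, "PFA", fig3_params)["P33"]
        assert 10 <= (asw - pfa) / pfa <= 20


class TestInhibitors:
    def test_no_inhibitor_is_identity(self, fig3_params):
        eff = pp.apply_inhibitor(fig3_params, "none", 0.0)
        for t in (0.0, 10.0, 1e3):
            assert eff.accumulation_gate(t) == 1.0
            assert eff.import_gate(t) == 1.0
            assert eff.clearance_factor(t) == 1.0

    def test_cccp_freezes_accumulation_after_delay(self, fig3_params):
        """Total cell label long after CCCP equals the label accumulated
        during the first 4 minutes."""
        design = single_pulse_design(
            rho=1e9, times=(4.0, 30.0, 60.0),
            inhibitor_events=(pp.InhibitorEvent(0.0, pp.InhibitorKind.CCCP),),
        )
        traj = pp.simulate(fig3_params, design)
        cell = traj.total_label("P33") - traj.pool("P33", "seawater")
        at4 = cell[traj.times == 4.0][0]
        at60 = cell[traj.times == 60.0][0]
        assert at60 == pytest.approx(at4, rel=1e-9)

    def test_dccd_onset_three_times_later_than_cccp(self, fig3_params):
        eff_cccp = pp.apply_inhibitor(fig3_params, "CCCP", 0.0)
        eff_dccd = pp.apply_inhibitor(fig3_params, "DCCD", 0.0)
        assert eff_dccd.accumulation_off_at == 3 * eff_cccp.accumulation_off_at

    def test_dccd_blocks_import_cccp_does_not(self, fig3_params):
        assert pp.apply_inhibitor(fig3_params, "DCCD", 0.0).import_gate(20.0) == 0.0
        assert pp.apply_inhibitor(fig3_params, "CCCP", 0.0).import_gate(20.0) == 1.0
        blocking = dataclasses.replace(fig3_params, cccp_blocks_import=True)
        assert pp.apply_inhibitor(blocking, "CCCP", 0.0).import_gate(20.0) == 0.0

    def test_ionophore_scales_clearance(self, fig3_params):
        eff = pp.apply_inhibitor(fig3_params, "ionophore", 10.0, factor=0.4)
        assert eff.clearance_factor(5.0) == 1.0
        assert eff.clearance_factor(15.0) == 0.4

    def test_ionophore_without_factor_rejected(self, fig3_params):
        with pytest.raises(ValueError):
            pp.apply_inhibitor(fig3_params, "ionophore", 0.0)


class TestBufferDecoupling:
    def test_chase_does_not_change_pulse_assimilation_slope(self, fig3_trajectory):
        """The periplasmic buffer decouples assimilation from the medium:
        the 100x chase leaves the pulse's macromolecular slope unchanged."""
        traj = fig3_trajectory
        m = traj.pool("P33", "macromolecule")
        pre = m[traj.times == 120][0] / 120.0
        post = (m[traj.times == 300][0] - m[traj.times == 120][0]) / 180.0
        assert post == pytest.approx(pre, rel=0.10)

    def test_bypassing_the_buffer_collapses_the_slope(self, fig3_params, fig3_design):
        """Without the buffer (conventional direct-uptake topology) the chase
        dilutes the pulse >10x out of the assimilation flux."""
        direct = dataclasses.replace(fig3_params, topology="direct")
        traj = pp.simulate(direct, fig3_design)
        m = traj.pool("P33", "macromolecule")
        pre = m[traj.times == 120][0] / 120.0
        post = (m[traj.times == 300][0] - m[traj.times == 120][0]) / 180.0
        assert pre / post > 10


class TestLightAndValidation:
    def test_light_factor_scales_accumulation(self):
        base = single_pulse_design(rho=1e9, times=(30.0,))
        p1 = pp.KineticParameters(light_factor=1.0, import_vmax=0.0)
        p2 = pp.KineticParameters(light_factor=2.0, import_vmax=0.0)
        acc = {}
        for key, p in (("dark", p1), ("light", p2)):
            traj = pp.simulate(p, base)
            acc[key] = traj.pool("P33", "periplasm")[traj.times == 30.0][0]
        # doubling the clearance roughly doubles early accumulation
        assert acc["light"] == pytest.approx(2 * acc["dark"], rel=5e-3)

    def test_light_schedule_gates_the_factor(self):
        design = single_pulse_design(
            rho=1e9, times=(10.0, 20.0), light_schedule=((0.0, 10.0),)
        )
        p = pp.KineticParameters(light_factor=3.0, import_vmax=0.0)
        traj = pp.simulate(p, design)
        peri = traj.pool("P33", "periplasm")
        first = peri[traj.times == 10.0][0]
        second = peri[traj.times == 20.0][0] - first
        # lights-off decade accumulates ~3x slower
        assert first / second == pytest.approx(3.0, rel=2e-2)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"clearance_cl": -1.0},
            {"pfa_retained_fraction": 1.5},
            {"import_km": 0.0},
            {"periplasm_volume": -1e-17},
            {"topology": "spiral"},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            pp.KineticParameters(**kwargs)

    def test_design_requires_positive_density_and_ordered_additions(self):
        with pytest.raises(ValueError):
            pp.ExperimentDesign(
                cell_density=0.0,
                additions=(pp.Addition(0.0, "P33", 1e-8),),
                sampling_times=(10.0,),
            )
        with pytest.raises(ValueError):
            pp.ExperimentDesign(
                cell_density=1e9,
                additions=(
                    pp.Addition(10.0, "P33", 1e-8),
                    pp.Addition(0.0, "P32", 1e-6),
                ),
                sampling_times=(10.0,),
            )
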