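"""Assembled-model integration: fixed points, conservation, convergence."""

import copy

import numpy as np
import pytest

from ca1ach.core import (AchPulse, AssembledModel, CurrentPulse, SP,
                         integrate, steady_state)
from ca1ach.metrics import exp_fit
from ca1ach.params import ModelParams
from ca1ach.reactions import mass_action_oracle


def conserved_totals(model, y):
    """Free + complexed totals for every buffer/enzyme, per compartment."""
    _, _, chem = model.split(y)
    pairs = {
        "calr": chem[SP["calr"]] + chem[SP["calr_ca"]],
        "cb": chem[SP["cb"]] + chem[SP["cb_ca"]],
        "ogb": chem[SP["ogb"]] + chem[SP["ogb_ca"]],
        "pmca": chem[SP["pmca"]] + chem[SP["pmca_ca"]],
        "ip5p": chem[SP["ip5p"]] + chem[SP["ip5p_ip3"]],
        "ip3k": (chem[SP["ip3k"]] + chem[SP["ip3k_2ca"]]
                 + chem[SP["ip3k_2ca_ip3"]]),
        "plc": (chem[SP["plc"]] + chem[SP["ga_gtp_plc"]]
                + chem[SP["ga_gdp_plc"]]),
        "galpha": (chem[SP["g"]] + chem[SP["rg"]] + chem[SP["rlg"]]
                   + chem[SP["ga_gtp"]] + chem[SP["ga_gdp"]]
                   + chem[SP["ga_gtp_plc"]] + chem[SP["ga_gdp_plc"]]),
        "receptor": (chem[SP["r"]] + chem[SP["rl"]] + chem[SP["rg"]]
                     + chem[SP["rlg"]]),
        "ip3r": (chem[SP["ir"]] + chem[SP["ir_i"]] + chem[SP["ir_o"]]
                 + chem[SP["ir_c"]]),
    }
    return pairs


class TestRestingState:
    def test_rest_is_a_fixed_point(self, model):
        dy = model.rhs(0.0, model.initial_state())
        assert np.abs(dy[: model.n_elec]).max() < 1e-9      # mV/ms

    def test_resting_model_is_stationary_over_60s(self, model):
        tr, y = integrate(model, 60e3, dt_out=1000.0, detect_spikes=False,
                          return_final_state=True,
                          record=["vm:soma", "vm:trunk10"])
        for name in ("vm:soma", "vm:trunk10"):
            assert np.abs(tr[name] - tr[name][0]).max() < 0.5
        y0 = model.initial_state()
        _, _, chem0 = model.split(y0)
        _, _, chem1 = model.split(y)
        scale = np.maximum(np.abs(chem0), 1e-7)
        drift = np.abs(chem1 - chem0) / scale
        assert drift.max() < 0.02

    def test_er_calcium_rests_at_175_uM(self, model, rest):
        ca_er = model.chem_view(rest, "ca_er")
        assert np.allclose(ca_er, 0.175, rtol=0.02)

    def test_steady_state_is_idempotent(self, model, rest):
        y2, _ = steady_state(model, settle=10e3, y0=rest)
        scale = np.maximum(np.abs(rest), 1e-7)
        assert (np.abs(y2 - rest) / scale).max() < 1e-3


class TestPassiveMembrane:
    def test_rc_relaxation_matches_membrane_time_constant(self, passive_params):
        """A -100 pA step on the passive soma relaxes with tau = Rm*Cm."""
        p = copy.deepcopy(passive_params)
        p.morphology.trunk.n_compartments = 1
        p.morphology.trunk.length = 1.0     # isolate the soma electrically
        p.morphology.trunk.diameter = 0.1
        p.morphology.axon.length = 1.0
        p.morphology.axon.diameter = 0.1
        model = AssembledModel(p)
        tr = integrate(model, 600.0,
                       stimuli=[CurrentPulse(-100.0, 50.0, 500.0)],
                       dt_out=0.5, detect_spikes=False, rtol=1e-7,
                       record=["vm:soma"])
        sel = (tr.times >= 50.0) & (tr.times <= 500.0)
        tau, asym, r2 = exp_fit(tr.times[sel], tr["vm:soma"][sel], t0=50.0)
        # tau = Rm*Cm = (1/g_leak)*cm; densities cancel the area
        g = p.morphology.soma.channels["leak"]          # mS/cm^2
        tau_theory = p.morphology.cm / g                # (uF/cm^2)/(mS/cm^2) = ms
        assert r2 > 0.999
        assert tau == pytest.approx(tau_theory, rel=0.01)

    def test_zero_amplitude_stimulus_is_identity(self, model, rest):
        tr0 = integrate(model, 500.0, y0=rest, dt_out=5.0, detect_spikes=False)
        tr1 = integrate(model, 500.0, y0=rest, dt_out=5.0, detect_spikes=False,
                        stimuli=[CurrentPulse(1e-12, 100.0, 100.0)])
        assert np.abs(tr0["vm:soma"] - tr1["vm:soma"]).max() < 1e-3


class TestConservation:
    def test_buffers_and_enzymes_conserved_through_phasic_stimulus(self, model, rest):
        totals0 = conserved_totals(model, rest)
        _, y = integrate(model, 4000.0,
                         stimuli=[AchPulse(0.1, start=500.0, duration=50.0)],
                         y0=rest, dt_out=5.0, return_final_state=True)
        totals1 = conserved_totals(model, y)
        for name, t0 in totals0.items():
            assert np.allclose(totals1[name], t0, rtol=1e-3), name

    def test_calcium_bookkeeping_closed_system(self, default_params):
        """With PMCA extrusion, VGCC influx and SOCE disabled, total calcium
        (free + bound, volume-weighted across cytosol and ER) is conserved."""
        p = default_params.copy()
        p.soce.enabled = False
        p.cytosol.k_pmca_rel = 0.0
        for sec in (p.morphology.soma, p.morphology.trunk):
            sec.channels["ca_hva"] = 0.0
            sec.channels["ca_t"] = 0.0
        model = AssembledModel(p)

        def total_ca(y):
            _, _, chem = model.split(y)
            cyt = (chem[SP["ca"]] + chem[SP["cb_ca"]] + chem[SP["ogb_ca"]]
                   + chem[SP["pmca_ca"]] + 2.0 * chem[SP["ip3k_2ca"]]
                   + 2.0 * chem[SP["ip3k_2ca_ip3"]]) * model.vol_cyt
            er = (chem[SP["ca_er"]] + chem[SP["calr_ca"]]) * model.vol_er
            return float(np.sum(cyt + er))

        y0 = model.initial_state()
        _, y1 = integrate(model, 60e3, y0=y0, dt_out=2000.0,
                          detect_spikes=False, return_final_state=True)
        assert total_ca(y1) == pytest.approx(total_ca(y0), rel=1e-3)

    def test_hydrolysis_converts_pip2_to_ip3_and_dag_one_to_one(self, model, rest):
        """Lost PIP2 (through the PLC path) reappears as DAG, and IP3
        production equals the DAG production times the membrane-to-volume
        conversion, after accounting for the lipid-cycle exchange."""
        _, y = integrate(model, 2500.0,
                         stimuli=[AchPulse(0.1, start=500.0, duration=50.0)],
                         y0=rest, dt_out=5.0, return_final_state=True)
        _, _, chem0 = model.split(rest)
        _, _, chem1 = model.split(y)
        dag_gain = chem1[SP["dag"]] - chem0[SP["dag"]]
        ip3_total = (chem1[SP["ip3"]] + chem1[SP["ip5p_ip3"]]
                     + chem1[SP["ip3k_2ca_ip3"]] + chem1[SP["ip2"]]
                     + chem1[SP["ip4"]])
        assert np.all(dag_gain > 0.1)   # the pulse genuinely hydrolysed PIP2
        # IP3 diffuses between compartments, so compare volume-weighted totals
        produced = float(np.sum(dag_gain * model.ip3_scale * model.vol_cyt))
        held = float(np.sum(ip3_total * model.vol_cyt))
        assert held == pytest.approx(produced, rel=1e-2)


class TestAssembledChemistryAgainstOracle:
    def test_network_derivatives_match_oracle_at_random_state(self, model):
        """The model's own mass-action subnetwork agrees with the naive
        oracle at an arbitrary (positive) concentration vector."""
        rng = np.random.default_rng(42)
        names = list(model.network.species_index)
        concs = {sp: float(rng.uniform(0.0, 0.5)) for sp in names}
        concs["ach"] = 0.05
        mat = np.array([[concs[sp]] for sp in names])
        deriv = model.network.derivatives(mat, {"ach": concs["ach"]})[:, 0]
        expected = mass_action_oracle(
            [r for r in model.reaction_specs],
            concs)
        for sp, i in model.network.species_index.items():
            assert deriv[i] == pytest.approx(expected[sp], rel=1e-10, abs=1e-12)


class TestSolverBehaviour:
    def test_output_interval_does_not_change_solution(self, model, rest):
        trA = integrate(model, 1000.0, y0=rest, dt_out=10.0, detect_spikes=False)
        trB = integrate(model, 1000.0, y0=rest, dt_out=50.0, detect_spikes=False)
        common = np.intersect1d(trA.times, trB.times)
        a = trA["vm:soma"][np.isin(trA.times, common)]
        b = trB["vm:soma"][np.isin(trB.times, common)]
        assert np.abs(a - b).max() < 1e-6

    def test_tolerance_convergence_on_subthreshold_response(self, model, rest):
        """Tightening tolerances converges: successive trace differences
        shrink, and the loose-default error stays below 0.1 mV sup-norm on a
        subthreshold cholinergic response."""
        stim = [AchPulse(1e-3, start=200.0, duration=50.0)]
        traces = {}
        for scale in (1.0, 0.2, 0.05):
            traces[scale] = integrate(
                model, 3000.0, stimuli=stim, y0=rest, dt_out=5.0,
                rtol=model.params.solver.rtol * scale,
                atol_scale=scale, detect_spikes=False)["vm:soma"]
        d10 = np.abs(traces[1.0] - traces[0.05]).max()
        d02 = np.abs(traces[0.2] - traces[0.05]).max()
        assert d02 <= d10 + 1e-12
        assert d10 < 0.1

    def test_duration_must_be_positive(self, model):
        with pytest.raises(ValueError):
            integrate(model, 0.0)
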