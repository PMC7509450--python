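"""Unit behaviour of the calcium-handling fluxes and laws."""

import numpy as np
import pytest

from ca1ach import calcium
from ca1ach.params import ERParams, IP3RParams, SOCEParams, CytosolParams


class TestSerca:
    def test_zero_calcium_gives_zero_flux(self):
        assert calcium.serca_flux(0.0, ERParams()) == 0.0

    def test_half_activation_at_1p3_uM_exactly(self):
        p = ERParams(g_serca=2.0)
        assert calcium.serca_flux(0.0013, p) == pytest.approx(1.0, rel=1e-12)

    def test_flux_at_half_of_half_activation(self):
        # ca = K/2 -> ca^2/(ca^2+K^2) = 1/5
        p = ERParams(g_serca=1.0)
        assert calcium.serca_flux(0.00065, p) == pytest.approx(0.2, rel=1e-12)


class TestLeak:
    def test_empty_store_no_leak(self):
        assert calcium.er_leak_flux(0.0, ERParams()) == 0.0

    def test_linearity(self):
        p = ERParams()
        assert calcium.er_leak_flux(0.35, p) == pytest.approx(
            2 * calcium.er_leak_flux(0.175, p))

    def test_rest_balance_defines_fixed_point(self):
        """At the calibrated rest the (volume-corrected) SERCA inflow equals
        the leak plus the small resting store-operated entry."""
        from ca1ach.params import ModelParams
        from ca1ach.calcium import soce_rate
        p = ModelParams()
        uptake = 9.0 * calcium.serca_flux(p.cytosol.ca_rest, p.er)
        leak = calcium.er_leak_flux(p.er.ca_er_rest, p.er)
        soce = soce_rate(p.morphology.v_init, p.er.ca_er_rest, p.soce)
        assert uptake + soce == pytest.approx(leak, rel=1e-3)


class TestIP3R:
    def test_closed_without_ip3(self):
        assert calcium.ip3r_open_probability(0.0, 1e-4) == 0.0

    def test_monotone_in_ip3(self):
        ip3 = np.logspace(-6, -1, 30)
        po = calcium.ip3r_open_probability(ip3, 3e-4)
        assert np.all(np.diff(po) > 0)

    def test_biphasic_in_calcium(self):
        ca = np.logspace(-6, -1, 60)
        po = calcium.ip3r_open_probability(0.01, ca)
        peak = int(np.argmax(po))
        assert 0 < peak < len(ca) - 1
        assert po[-1] < po[peak]
        # high calcium (>= 10 uM) below the value near 0.3 uM
        assert (calcium.ip3r_open_probability(0.01, 0.01)
                < calcium.ip3r_open_probability(0.01, 3e-4))

    def test_flux_zero_when_closed_or_empty(self):
        p = IP3RParams()
        assert calcium.ip3r_flux(0.175, 0.0, p) == 0.0
        assert calcium.ip3r_flux(0.0, 0.7, p) == 0.0

    def test_gating_states_conserve_total(self):
        p = IP3RParams()
        d = calcium.ip3r_gating_derivatives(0.4, 0.3, 0.2, 0.1, 1e-3, 5e-4, p)
        assert sum(d) == pytest.approx(0.0, abs=1e-15)


class TestSOCE:
    def test_value_at_reference_point(self):
        p = SOCEParams(g_soce=2.0)
        # vm = v_init and ca_er = ca_d -> softplus(0) * exp(0) = ln 2
        assert calcium.soce_rate(p.v_init, p.ca_d, p) == pytest.approx(
            2.0 * np.log(2.0), rel=1e-12)

    def test_requires_depolarisation(self):
        p = SOCEParams()
        assert calcium.soce_rate(-2000.0, p.ca_d, p) == pytest.approx(0.0, abs=1e-12)

    def test_deactivates_as_store_refills(self):
        p = SOCEParams()
        full = calcium.soce_rate(0.0, 10.0 * p.ca_d, p)
        depleted = calcium.soce_rate(0.0, 0.1 * p.ca_d, p)
        assert full < 1e-3 * depleted

    def test_never_negative(self):
        p = SOCEParams()
        vm = np.linspace(-120, 60, 50)
        assert np.all(calcium.soce_rate(vm, 0.05, p) >= 0)


class TestFluorescence:
    def test_unbound_only(self):
        assert calcium.fluorescence(1.0, 0.0) == 1.0

    def test_bound_fluoresces_fourteen_fold(self):
        assert calcium.fluorescence(0.0, 1.0) == 14.0

    def test_half_bound(self):
        assert calcium.fluorescence(0.5, 0.5) == 7.5

    def test_dff_requires_resting_fluorescence(self):
        with pytest.raises(ZeroDivisionError):
            calcium.delta_f_over_f(0.1, 0.1, f_rest=0.0)


class TestDiffusion:
    def test_uniform_profile_has_no_flux(self):
        vols = np.array([10.0, 5.0, 5.0])
        d = calcium.diffusion_terms(np.full(3, 0.7), 0.1, vols,
                                    np.array([1.0, 1.0]), np.array([2.0, 2.0]))
        assert np.allclose(d, 0.0)

    def test_step_profile_conserves_moles(self):
        vols = np.array([10.0, 2.0, 7.0, 1.0])
        conc = np.array([1.0, 0.0, 0.5, 2.0])
        d = calcium.diffusion_terms(conc, 0.2, vols,
                                    np.ones(3), np.full(3, 1.5))
        assert float(np.dot(d, vols)) == pytest.approx(0.0, abs=1e-10)
        # flux direction: high -> low between the first two compartments
        assert d[0] < 0 and d[1] > 0

    def test_two_compartments_relax_to_equality(self):
        # explicit Euler relaxation of the closed pair conserves total moles
        vols = np.array([3.0, 1.0])
        conc = np.array([1.0, 0.0])
        total0 = np.dot(conc, vols)
        for _ in range(20000):
            conc = conc + 0.05 * calcium.diffusion_terms(
                conc, 0.5, vols, np.array([1.0]), np.array([1.0]))
        assert conc[0] == pytest.approx(conc[1], rel=1e-6)
        assert np.dot(conc, vols) == pytest.approx(total0, rel=1e-10)


def test_negative_buffer_totals_rejected():
    from ca1ach.params import ERParams, CytosolParams
    with pytest.raises(ValueError):
        calcium.build_buffer_and_pump_reactions(
            ERParams(calr_total=-1.0), CytosolParams())


def test_pmca_cycle_reduces_to_michaelis_menten():
    """At constant calcium the pump cycle extrudes at
    k_rel*total*ca/(ca+K) with K=(kb+k_rel)/kf (quasi-steady reduction)."""
    cyt = CytosolParams()
    kf, kb, krel = cyt.kf_pmca_ca, cyt.kb_pmca_ca, cyt.k_pmca_rel
    total = 0.002
    ca = 2e-4
    # simulate the two-state cycle at clamped calcium until steady state
    pmca, pmca_ca = total, 0.0
    dt = 0.05
    for _ in range(200000):
        b = kf * ca * pmca - kb * pmca_ca
        r = krel * pmca_ca
        pmca += dt * (-b + r)
        pmca_ca += dt * (b - r)
    extrusion = krel * pmca_ca
    km = (kb + krel) / kf
    assert extrusion == pytest.approx(krel * total * ca / (ca + km), rel=1e-6)
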