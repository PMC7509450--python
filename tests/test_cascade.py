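"""M1 cascade: builders, fixed points, dose responses."""

import numpy as np
import pytest

from ca1ach import cascade
from ca1ach.core import AchPulse, SP, integrate
from ca1ach.params import M1Params, ModelParams


class TestBuilders:
    def test_ach_affinity_matches_configured_ec50(self):
        p = M1Params()
        assert p.koff_ach / p.kon_ach == pytest.approx(p.ach_ec50)

    def test_modification_factors_apply(self):
        p = M1Params()
        assert p.k_plc_assoc_eff == pytest.approx(10.0 * p.k_plc_assoc)
        assert p.k_plc_diss_eff == pytest.approx(10.0 * p.k_plc_diss)
        assert p.r_plc_eff == pytest.approx(100.0 * p.r_plc)

    def test_empty_pools_rejected(self):
        with pytest.raises(ValueError):
            cascade.build_receptor_gprotein_reactions(M1Params(r_total=0.0))

    def test_lipid_cycle_rest_is_fixed_point(self):
        p = M1Params()
        k5p, k4k = cascade.lipid_rest_rates(p)
        d_pip2 = p.k5k * p.pi4p_rest - k5p * p.pip2_rest
        d_pi4p = (k4k * p.pi_rest + k5p * p.pip2_rest
                  - (p.k4p + p.k5k) * p.pi4p_rest)
        assert d_pip2 == pytest.approx(0.0, abs=1e-15)
        assert d_pi4p == pytest.approx(0.0, abs=1e-15)

    def test_hydrolysis_rate_is_first_order_in_both(self):
        assert cascade.pip2_hydrolysis_rate(0.0, 1.0, 2.0) == 0.0
        assert cascade.pip2_hydrolysis_rate(0.5, 0.0, 2.0) == 0.0
        assert (cascade.pip2_hydrolysis_rate(1.0, 0.3, 2.0)
                == pytest.approx(2 * cascade.pip2_hydrolysis_rate(0.5, 0.3, 2.0)))


class TestCascadeDynamics:
    def test_no_ach_means_no_cascade_activity(self, model, rest):
        _, y = integrate(model, 60e3, y0=rest, dt_out=5000.0,
                         detect_spikes=False, return_final_state=True)
        for sp in ("ga_gtp_plc", "ip3", "rl"):
            assert np.abs(model.chem_view(y, sp)
                          - model.chem_view(rest, sp)).max() < 1e-6

    def test_saturating_ach_pulse_saturates_plc_response(self, model, rest):
        def peak_plc(conc):
            tr = integrate(model, 3000.0,
                           stimuli=[AchPulse(conc, 500.0, 50.0)], y0=rest,
                           dt_out=5.0, detect_spikes=False,
                           record=["ga_gtp_plc:soma"])
            return tr["ga_gtp_plc:soma"].max()

        p100 = peak_plc(0.1)
        p1000 = peak_plc(1.0)
        assert abs(p1000 - p100) / p100 < 0.05

    def test_peak_ip3_monotone_in_concentration(self, model, rest):
        peaks = []
        for conc in (1e-4, 1e-3, 1e-2):
            tr = integrate(model, 3000.0,
                           stimuli=[AchPulse(conc, 500.0, 50.0)], y0=rest,
                           dt_out=5.0, detect_spikes=False,
                           record=["ip3:soma"])
            peaks.append(tr["ip3:soma"].max())
        assert peaks[0] < peaks[1] < peaks[2]

    def test_plc_rate_multipliers_speed_activation(self, default_params, rest):
        """With the 10x association/dissociation factors removed the active
        PLC peak comes much later (the original-kinetics comparison)."""
        from ca1ach.core import AssembledModel

        def plc_peak_time(factor):
            p = default_params.copy()
            p.m1.plc_assoc_factor = factor
            p.m1.plc_diss_factor = factor
            m = AssembledModel(p)
            tr = integrate(m, 6000.0, stimuli=[AchPulse(0.1, 500.0, 50.0)],
                           dt_out=10.0, detect_spikes=False,
                           record=["ga_gtp_plc:soma"])
            return tr.times[int(np.argmax(tr["ga_gtp_plc:soma"]))] - 500.0

        assert plc_peak_time(10.0) < 0.7 * plc_peak_time(1.0)
        assert plc_peak_time(10.0) < 2000.0

    def test_ip3_returns_near_rest_within_3s(self, model, rest):
        tr = integrate(model, 5000.0, stimuli=[AchPulse(0.1, 500.0, 50.0)],
                       y0=rest, dt_out=10.0, detect_spikes=False,
                       record=["ip3:soma"])
        peak = tr["ip3:soma"].max()
        at3s = tr["ip3:soma"][np.argmin(np.abs(tr.times - 3500.0))]
        assert at3s < 0.1 * peak

    def test_receptor_dose_response_half_max_near_configured_ec50(
            self, model, rest):
        """Steady-state active G-alpha under sustained ACh has half-max
        within a factor-band of the configured receptor EC50."""
        def steady_active(conc):
            _, y = integrate(model, 60e3, stimuli=[AchPulse(conc, 0.0)],
                             y0=rest, dt_out=5000.0, detect_spikes=False,
                             return_final_state=True)
            chem = model.split(y)[2]
            return float((chem[SP["ga_gtp"]] + chem[SP["ga_gtp_plc"]]
                          + chem[SP["ga_gdp_plc"]])[0])

        sat = steady_active(0.1)
        ec50 = model.params.m1.ach_ec50
        low = steady_active(ec50 / 8)
        mid = steady_active(ec50)
        assert low < 0.35 * sat
        assert 0.2 * sat < mid < 0.9 * sat
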