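"""Cytosolic and ER calcium machinery.

Builders return :class:`~ca1ach.reactions.ReactionSpec` lists for the pure
mass-action parts (buffers, indicator, PMCA cycle) and plain functions for the
custom fluxes (SERCA, ER leak, IP3 receptor, SOCE) that move calcium between
the cytosolic and ER sub-volumes.  Cross-volume fluxes are volume-corrected:
a flux expressed as a cytosolic concentration change enters the ER multiplied
by cytosol_fraction/er_fraction, and vice versa.

The ER has no explicit membrane area -- SERCA, leak and IP3R are direct
volume-to-volume fluxes; SOCE adds calcium to the ER lumen only, bypassing the
cytosol entirely.
"""

from __future__ import annotations

import numpy as np

from .params import CytosolParams, ERParams, IP3RParams, SOCEParams
from .reactions import ReactionSpec


def build_buffer_and_pump_reactions(er: ERParams, cyt: CytosolParams) -> list[ReactionSpec]:
    """Calreticulin (ER lumen), calbindin, OGB-1 indicator and the PMCA cycle.

    The PMCA release step returns the pump to its free state while the bound
    calcium leaves the modelled system (extrusion to the extracellular space).
    """
    if er.calr_total < 0 or cyt.cb_total < 0 or cyt.ogb_total < 0:
        raise ValueError("buffer totals must be >= 0")
    return [
        ReactionSpec("calr_binding", [("calr", 1), ("ca_er", 1)], [("calr_ca", 1)],
                     kf=er.kf_calr, kb=er.kb_calr, region="er"),
        ReactionSpec("cb_binding", [("cb", 1), ("ca", 1)], [("cb_ca", 1)],
                     kf=cyt.kf_cb, kb=cyt.kb_cb),
        ReactionSpec("ogb_binding", [("ogb", 1), ("ca", 1)], [("ogb_ca", 1)],
                     kf=cyt.kf_ogb1, kb=cyt.kb_ogb1),
        ReactionSpec("pmca_binding", [("pmca", 1), ("ca", 1)], [("pmca_ca", 1)],
                     kf=cyt.kf_pmca_ca, kb=cyt.kb_pmca_ca),
        ReactionSpec("pmca_release", [("pmca_ca", 1)], [("pmca", 1)],
                     kf=cyt.k_pmca_rel),
    ]


def serca_flux(ca_cyt, params: ERParams):
    """SERCA uptake as a cytosolic concentration change (mM/ms, >= 0).

    flux = g_serca * ca^2 / (ca^2 + k_serca^2); half-activation at 1.3 uM.
    """
    ca = np.asarray(ca_cyt, dtype=float)
    ca2 = ca * ca
    return params.g_serca * ca2 / (ca2 + params.k_serca ** 2)


def er_leak_flux(ca_er, params: ERParams):
    """First-order ER leak, expressed as an ER concentration change (mM/ms)."""
    return params.kf_leak_er * np.asarray(ca_er, dtype=float)


def ip3r_flux(ca_er, r_open, params: IP3RParams):
    """IP3R release flux in ER concentration units (mM/ms).

    Proportional to ER free calcium so release ceases as the store empties
    (the mechanism that terminates regenerative release).
    """
    return params.g_ip3r * np.asarray(r_open) * np.asarray(ca_er)


def ip3r_gating_derivatives(ir, ir_i, ir_o, ir_c, ip3, ca, p: IP3RParams):
    """Sequential-binding receptor scheme; returns the four state derivatives.

    R --IP3--> R*IP3 --Ca--> open --Ca--> inactivated.  Binding steps do not
    consume measurable ligand (receptor density is negligible next to the
    ligand pools).
    """
    f_bind = p.kon_ip3 * ip3 * ir - p.koff_ip3 * ir_i
    f_act = p.kon_act * ca * ir_i - p.koff_act * ir_o
    f_inh = p.kon_inh * ca * ir_o - p.koff_inh * ir_c
    return (-f_bind, f_bind - f_act, f_act - f_inh, f_inh)


def ip3r_open_probability(ip3, ca_cyt, params: IP3RParams | None = None):
    """Steady-state open fraction of the receptor scheme.

    Biphasic in cytosolic calcium (activation then inhibition) and
    monotonically increasing in IP3.
    """
    p = params or IP3RParams()
    ip3 = np.asarray(ip3, dtype=float)
    ca = np.asarray(ca_cyt, dtype=float)
    if np.any(ip3 < 0) or np.any(ca < 0):
        raise ValueError("concentrations must be >= 0")
    # detailed-balance chain: RI/R = ip3/Kd_i ; RO/RI = ca/Kd_a ; RC/RO = ca/Kd_c
    kd_i = p.koff_ip3 / p.kon_ip3
    kd_a = p.koff_act / p.kon_act
    kd_c = p.koff_inh / p.kon_inh
    x = ip3 / kd_i
    a = ca / kd_a
    c = ca / kd_c
    return x * a / (1.0 + x * (1.0 + a * (1.0 + c)))


def soce_rate(vm, ca_er, params: SOCEParams):
    """Store-operated entry: d(ca_er)/dt contribution (mM/ms, never negative).

    rate = g_soce * ln(1 + exp(vm - v_init)) * exp(-(ca_er - ca_d) * k_soce).
    Requires depolarisation (softplus of the voltage above rest) and store
    depletion (the exponential vanishes as the store refills); it adds
    calcium to the ER only and never touches the cytosol.
    """
    if not params.enabled:
        return np.zeros_like(np.asarray(vm, dtype=float))
    dv = np.asarray(vm, dtype=float) - params.v_init
    softplus = np.logaddexp(0.0, dv)
    gate = np.exp(-(np.asarray(ca_er, dtype=float) - params.ca_d) * params.k_soce)
    return params.g_soce * softplus * gate


def diffusion_terms(conc, d_coef, volumes, cross_areas, distances):
    """Flux-conservative 1-D discrete Laplacian along the trunk-soma path.

    Parameters
    ----------
    conc : (n,) concentrations along the path (soma first)
    d_coef : diffusion coefficient, um^2/ms
    volumes : (n,) cytosolic volumes, um^3
    cross_areas : (n-1,) cross-sectional areas between neighbours, um^2
    distances : (n-1,) centre-to-centre distances, um

    Returns the per-compartment concentration derivative; total moles are
    conserved and the ends are zero-flux.
    """
    conc = np.asarray(conc, dtype=float)
    if conc.shape[0] < 2 or d_coef == 0.0:
        return np.zeros_like(conc)
    j = d_coef * cross_areas * (conc[1:] - conc[:-1]) / distances  # um^3*mM/ms
    dc = np.zeros_like(conc)
    dc[:-1] += j / volumes[:-1]
    dc[1:] -= j / volumes[1:]
    return dc


def fluorescence(ogb_free, ogb_bound, f_mult: float = 14.0):
    """Simulated OGB-1 fluorescence: F = f_mult * bound + free."""
    free = np.asarray(ogb_free, dtype=float)
    bound = np.asarray(ogb_bound, dtype=float)
    if np.any(free < -1e-12) or np.any(bound < -1e-12):
        raise ValueError("indicator concentrations must be >= 0")
    return f_mult * bound + free


def delta_f_over_f(ogb_free, ogb_bound, f_rest: float, f_mult: float = 14.0):
    """Relative fluorescence change (F(t) - F_rest) / F_rest."""
    if f_rest == 0:
        raise ZeroDivisionError("resting fluorescence is zero (indicator absent?)")
    return (fluorescence(ogb_free, ogb_bound, f_mult) - f_rest) / f_rest
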