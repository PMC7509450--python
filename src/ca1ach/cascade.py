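"""M1 muscarinic cascade: receptor, G protein, PLC, IP3 turnover, lipid cycle.

Topology follows the published Gq/PLC kinetic scheme for the M1 receptor
(receptor precoupling, nucleotide exchange on the receptor-bound G protein,
GTPase acceleration while PLC is bound) with three modifications carried as
explicit factors: the PLC association and dissociation rates are raised 10x
and the hydrolysis rate constant r_PLC 100x relative to the source kinetics,
which moves IP3 production from the ~2 s peak of the original model to being
largely complete within 2 s, as required for the fast regenerative calcium
release of CA1 cells.  ACh association/dissociation is parameterised directly
by the receptor EC50.

Membrane species are dimensionless densities (resting PIP2 = 1); IP3 and its
degradation enzymes are cytosolic (mM).  The hydrolysis step is a custom flux
because it crosses the unit boundary: one PIP2 unit yields ``ip3_scale`` mM of
IP3 (per-compartment, proportional to the surface-to-volume ratio) plus one
DAG unit, so hydrolysis conserves PIP2 -> IP3 + DAG one-to-one after the
conversion.
"""

from __future__ import annotations

import numpy as np

from .params import M1Params
from .reactions import ReactionSpec


def build_receptor_gprotein_reactions(p: M1Params) -> list[ReactionSpec]:
    """ACh binding, receptor/G-protein coupling, activation and recovery.

    ``ach`` is a clamped bath species (set by the stimulus, not consumed).
    """
    if p.r_total <= 0 or p.g_total <= 0:
        raise ValueError("receptor and G protein pools must be positive")
    return [
        ReactionSpec("ach_bind_r", [("r", 1), ("ach", 1)], [("rl", 1)],
                     kf=p.kon_ach, kb=p.koff_ach, region="membrane"),
        ReactionSpec("precouple", [("r", 1), ("g", 1)], [("rg", 1)],
                     kf=p.kon_rg, kb=p.koff_rg, region="membrane"),
        ReactionSpec("ach_bind_rg", [("rg", 1), ("ach", 1)], [("rlg", 1)],
                     kf=p.kon_ach, kb=p.koff_ach, region="membrane"),
        ReactionSpec("couple_rl", [("rl", 1), ("g", 1)], [("rlg", 1)],
                     kf=p.kon_rlg, kb=p.koff_rlg, region="membrane"),
        ReactionSpec("g_activate", [("rlg", 1)],
                     [("rl", 1), ("ga_gtp", 1), ("gbg", 1)],
                     kf=p.k_act, region="membrane"),
        ReactionSpec("ga_hydrolysis", [("ga_gtp", 1)], [("ga_gdp", 1)],
                     kf=p.k_hyd, region="membrane"),
        ReactionSpec("g_reassociate", [("ga_gdp", 1), ("gbg", 1)], [("g", 1)],
                     kf=p.k_reassoc, region="membrane"),
    ]


def build_plc_reactions(p: M1Params) -> list[ReactionSpec]:
    """PLC activation by Galpha-GTP and the GAP-accelerated shutoff."""
    return [
        ReactionSpec("plc_assoc", [("plc", 1), ("ga_gtp", 1)], [("ga_gtp_plc", 1)],
                     kf=p.k_plc_assoc_eff, region="membrane"),
        ReactionSpec("plc_gap", [("ga_gtp_plc", 1)], [("ga_gdp_plc", 1)],
                     kf=p.k_gap, region="membrane"),
        ReactionSpec("plc_diss", [("ga_gdp_plc", 1)], [("ga_gdp", 1), ("plc", 1)],
                     kf=p.k_plc_diss_eff, region="membrane"),
    ]


def build_ip3_degradation_reactions(p: M1Params) -> list[ReactionSpec]:
    """IP 5-phosphatase Michaelis path and the calcium-gated IP3 kinase path.

    IP3K must bind two calcium ions before it can bind IP3; IP2 and IP4 are
    terminal sinks.
    """
    return [
        ReactionSpec("ip5p_bind", [("ip5p", 1), ("ip3", 1)], [("ip5p_ip3", 1)],
                     kf=p.kf_ip5p, kb=p.kb_ip5p),
        ReactionSpec("ip5p_convert", [("ip5p_ip3", 1)], [("ip5p", 1), ("ip2", 1)],
                     kf=p.k_ip2),
        ReactionSpec("ip3k_ca_bind", [("ip3k", 1), ("ca", 2)], [("ip3k_2ca", 1)],
                     kf=p.kf_ip3k_ca, kb=p.kb_ip3k_ca),
        ReactionSpec("ip3k_ip3_bind", [("ip3k_2ca", 1), ("ip3", 1)],
                     [("ip3k_2ca_ip3", 1)],
                     kf=p.kf_ip3k_ip3, kb=p.kb_ip3k_ip3),
        ReactionSpec("ip3k_convert", [("ip3k_2ca_ip3", 1)],
                     [("ip3k_2ca", 1), ("ip4", 1)], kf=p.k_ip4),
    ]


def build_lipid_cycle_reactions(p: M1Params) -> list[ReactionSpec]:
    """Phosphoinositide resynthesis: PI <-> PI4P <-> PIP2.

    The pair (k4k, k5p) is re-derived from (k4p, k5k) and the resting pool
    sizes so the configured pools are an exact fixed point of the cycle.
    """
    k5p, k4k = lipid_rest_rates(p)
    return [
        ReactionSpec("pi_4k", [("pi", 1)], [("pi4p", 1)], kf=k4k, region="membrane"),
        ReactionSpec("pi4p_5k", [("pi4p", 1)], [("pip2", 1)], kf=p.k5k, region="membrane"),
        ReactionSpec("pi4p_4p", [("pi4p", 1)], [("pi", 1)], kf=p.k4p, region="membrane"),
        ReactionSpec("pip2_5p", [("pip2", 1)], [("pi4p", 1)], kf=k5p, region="membrane"),
    ]


def lipid_rest_rates(p: M1Params) -> tuple[float, float]:
    """(k5p, k4k) making the configured resting pools a fixed point.

    Rest balance with zero basal hydrolysis:
    k5k*PI4P = k5p*PIP2 and k4k*PI = k4p*PI4P + (k5k*PI4P - k5p*PIP2).
    """
    k5p = p.k5k * p.pi4p_rest / p.pip2_rest
    k4k = p.k4p * p.pi4p_rest / p.pi_rest
    return k5p, k4k


def pip2_hydrolysis_rate(pip2, active_plc, r_plc: float):
    """PIP2 consumption rate (units/ms): r_PLC * [Galpha-GTP-PLC] * PIP2."""
    return r_plc * np.asarray(active_plc, dtype=float) * np.asarray(pip2, dtype=float)


def build_cascade_reactions(p: M1Params) -> list[ReactionSpec]:
    return (build_receptor_gprotein_reactions(p) + build_plc_reactions(p)
            + build_ip3_degradation_reactions(p) + build_lipid_cycle_reactions(p))


def cascade_rest_concentrations(p: M1Params) -> dict[str, float]:
    """Stimulus-free fixed point of the cascade (everything inactive).

    Receptor precoupling equilibrates R + G <-> RG; lipids at configured rest.
    """
    # solve r + g <-> rg with totals r_total, g_total
    kd = p.koff_rg / p.kon_rg if p.kon_rg > 0 else np.inf
    if np.isfinite(kd):
        b = p.r_total + p.g_total + kd
        rg = (b - np.sqrt(b * b - 4.0 * p.r_total * p.g_total)) / 2.0
    else:
        rg = 0.0
    return {
        "r": p.r_total - rg, "rl": 0.0, "g": p.g_total - rg, "rg": rg,
        "rlg": 0.0, "gbg": 0.0, "ga_gtp": 0.0, "ga_gdp": 0.0,
        "plc": p.plc_total, "ga_gtp_plc": 0.0, "ga_gdp_plc": 0.0,
        "pi": p.pi_rest, "pi4p": p.pi4p_rest, "pip2": p.pip2_rest,
        "dag": 0.0, "ip3": 0.0,
        "ip5p": p.ip5p_total, "ip5p_ip3": 0.0,
        "ip3k": p.ip3k_total, "ip3k_2ca": 0.0, "ip3k_2ca_ip3": 0.0,
        "ip2": 0.0, "ip4": 0.0,
    }
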