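"""Parameter containers for every mechanism group.

All parameters live in small frozen-by-convention dataclasses grouped by the
region they act on (plasma membrane, cytosol, ER, M1 cascade).  The defaults
shipped here are the output of the staged calibration workflow in
:mod:`ca1ach.calibration`; re-running ``CholinergicCA1Model().fit()``
reproduces them.

Units follow :mod:`ca1ach.units` (ms, mV, mM, pA, nS, pF, um).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict, fields, is_dataclass
from typing import Any


@dataclass
class SectionParams:
    """Geometry and channel densities for one morphological section."""

    length: float            # um, total section length
    diameter: float          # um
    n_compartments: int
    channels: dict[str, float] = field(default_factory=dict)  # mS/cm^2

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError("section length and diameter must be positive")
        if self.n_compartments < 1:
            raise ValueError("n_compartments must be >= 1")
        for name, dens in self.channels.items():
            if dens < 0:
                raise ValueError(f"negative density for channel {name!r}")


@dataclass
class MorphologyParams:
    """Reduced CA1 morphology: soma, 200 um of apical trunk, axon.

    Chemistry (the expanded calcium/cascade model) is present in the soma and
    trunk only; the axon is electrical-only and provides spike initiation.
    """

    soma: SectionParams = field(default_factory=lambda: SectionParams(
        length=20.0, diameter=20.0, n_compartments=1,
        channels={
            "na": 56.7, "kdr": 10.0, "ka": 6.0, "kv7": 1.18, "h": 0.15,
            "sk": 1.0, "ca_hva": 0.3, "ca_t": 0.03, "leak": 0.035,
        },
    ))
    trunk: SectionParams = field(default_factory=lambda: SectionParams(
        length=200.0, diameter=2.0, n_compartments=10,
        channels={
            "na": 28.3, "kdr": 6.0, "ka": 6.0, "kv7": 1.18, "h": 0.15,
            "sk": 0.2, "ca_hva": 0.06, "ca_t": 0.05, "leak": 0.035,
        },
    ))
    axon: SectionParams = field(default_factory=lambda: SectionParams(
        length=40.0, diameter=1.0, n_compartments=1,
        channels={"na": 207.0, "kdr": 40.0, "leak": 0.035},
    ))
    cytosol_fraction: float = 0.9
    er_fraction: float = 0.1
    ra: float = 150.0        # ohm*cm axial resistivity
    cm: float = 1.0          # uF/cm^2
    v_init: float = -65.0    # mV resting potential


@dataclass
class ChannelKinetics:
    """Reversal potentials plus the PIP2 and calcium modulation laws."""

    e_na: float = 55.0
    e_k: float = -90.0
    e_ca: float = 120.0
    e_h: float = -30.0
    # Kv7 availability as a Hill function of membrane PIP2 relative to rest
    pip2_half: float = 0.64      # x resting PIP2
    pip2_hill: float = 5.0
    # SK activation: Hill in cytosolic free calcium
    sk_ca_half: float = 0.0007  # mM
    sk_hill: float = 4.8
    # pharmacology switch: force the Kv7 availability scale to zero (XE991-
    # like block) without re-deriving the resting balance
    kv7_block: bool = False


@dataclass
class ERParams:
    """SERCA pump, ER leak and calreticulin (ER lumen buffer)."""

    g_serca: float = 1.65420e-4  # mM/ms, maximal SERCA flux (stage 1)
    kf_leak_er: float = 5.005e-5 # 1/ms, first-order leak (stage 1)
    k_serca: float = 0.0013      # mM, SERCA half-activation (fixed)
    ca_er_rest: float = 0.175    # mM, resting ER free calcium
    calr_total: float = 3.6      # mM
    kf_calr: float = 0.1         # 1/(mM*ms)
    kb_calr: float = 0.2         # 1/ms  (Kd = 2 mM, low affinity / high capacity)


@dataclass
class CytosolParams:
    """Cytosolic buffers, the fluorescent indicator and the PMCA pump."""

    ca_rest: float = 1e-4        # mM resting free calcium
    cb_total: float = 0.045      # mM calbindin-D28k (regular value)
    kf_cb: float = 20.0          # 1/(mM*ms)
    kb_cb: float = 0.014         # 1/ms (Kd ~ 0.7 uM)
    cb_fluor_fraction: float = 0.2   # fraction of cb_total in imaging replications
    ogb_total: float = 0.0       # mM; indicator only present in imaging protocols
    ogb_default: float = 0.05    # mM used when the indicator is enabled
    kf_ogb1: float = 400.0       # 1/(mM*ms)
    kb_ogb1: float = 0.172       # 1/ms (Kd ~ 0.43 uM, intracellular)
    f_mult: float = 14.0         # bound/unbound fluorescence ratio
    pmca_density: float = 0.035  # mM*um; soma total = density * (S/V)_soma
    pmca_sv_exponent: float = 0.3  # sublinear S/V scaling of extrusion capacity
    kf_pmca_ca: float = 50.0     # 1/(mM*ms)
    kb_pmca_ca: float = 0.007    # 1/ms
    k_pmca_rel: float = 0.012    # 1/ms, calcium leaves the modelled system
    d_ca: float = 0.013          # um^2/ms effective (buffered) Ca diffusion
    d_ip3: float = 0.28          # um^2/ms IP3 diffusion


@dataclass
class IP3RParams:
    """Sequential-binding IP3 receptor scheme (IP3 then activating calcium,
    with a further calcium binding step that inactivates the open state).

    The open fraction is biphasic in cytosolic calcium and increasing in IP3.
    """

    g_ip3r: float = 5.2e-2       # 1/ms at the soma; flux = g * R_open * ca_er
    sv_exponent: float = 0.4     # flux capacity rises with surface-to-volume
                                 # (tubular ER packs more membrane per volume
                                 # in thin processes)
    kon_ip3: float = 4.0         # 1/(mM*ms)
    koff_ip3: float = 0.02       # 1/ms   (Kd ~ 2 uM)
    kon_act: float = 105.0       # 1/(mM*ms)
    koff_act: float = 0.028       # 1/ms   (Kd ~ 0.2 uM)
    kon_inh: float = 2.5         # 1/(mM*ms)
    koff_inh: float = 0.005      # 1/ms   (Kd ~ 2 uM)


@dataclass
class SOCEParams:
    """Store-operated calcium entry: depolarisation- and depletion-gated
    refilling of the ER that bypasses the cytosol entirely."""

    g_soce: float = 6.0e-6       # mM/ms
    v_init: float = -60.0        # mV; softplus reference slightly above the
                                 # resting potential, so activation genuinely
                                 # requires depolarisation
    ca_d: float = 0.0875         # mM reference (ca_er_rest / 2)
    k_soce: float = 40.0         # 1/mM
    enabled: bool = True


@dataclass
class M1Params:
    """M1 receptor / Gq / PLC cascade, IP3 degradation and lipid resynthesis.

    Membrane species are dimensionless densities (resting PIP2 = 1); IP3 and
    the degradation enzymes are cytosolic (mM).  The three modification
    factors relative to the source kinetics (x10 PLC association and
    dissociation, x100 hydrolysis rate) are exposed explicitly so the
    original-vs-recalibrated comparison is a config switch.
    """

    r_total: float = 1.0
    g_total: float = 1.0
    plc_total: float = 1.0
    # ACh binding; kon is set so koff/kon equals the receptor EC50 target
    ach_ec50: float = 6.5e-4     # mM (0.65 uM)
    koff_ach: float = 0.0055     # 1/ms
    # receptor/G-protein coupling
    kon_rg: float = 2e-4         # 1/(unit*ms) precoupling
    koff_rg: float = 1e-3        # 1/ms
    kon_rlg: float = 0.03        # 1/(unit*ms)
    koff_rlg: float = 1e-3       # 1/ms
    k_act: float = 0.004          # 1/ms, nucleotide exchange + dissociation
    k_hyd: float = 6e-4        # 1/ms, lone Galpha-GTP hydrolysis
    k_reassoc: float = 5e-3      # 1/(unit*ms)
    # PLC binding (base rates; the factors multiply them)
    k_plc_assoc: float = 0.002   # 1/(unit*ms)
    k_plc_diss: float = 0.001    # 1/ms
    plc_assoc_factor: float = 10.0
    plc_diss_factor: float = 10.0
    k_gap: float = 4.5e-3        # 1/ms, GTPase while PLC-bound
    # PIP2 hydrolysis
    r_plc: float = 1.55e-4          # 1/(unit*ms) base rate
    r_plc_factor: float = 100.0
    ip3_scale_soma: float = 0.0195  # mM IP3 per unit PIP2 hydrolysed, at soma S/V
    # lipid pools (normalised to resting PIP2 = 1) and cycle rates;
    # k4k and k5p are re-derived at build time so rest is an exact fixed point
    pi_rest: float = 28.0
    pi4p_rest: float = 0.8
    pip2_rest: float = 1.0
    k4k: float = 7.93e-5          # 1/ms PI -> PI4P          (stage 4)
    k5k: float = 7.67e-4         # 1/ms PI4P -> PIP2        (stage 4)
    k4p: float = 4.92e-4          # 1/ms PI4P -> PI          (stage 4)
    k5p: float = 6.14e-4         # 1/ms PIP2 -> PI4P        (stage 4)
    # IP3 degradation
    ip5p_total: float = 1.6e-3     # mM
    kf_ip5p: float = 10.0        # 1/(mM*ms)
    kb_ip5p: float = 0.005       # 1/ms
    k_ip2: float = 0.01          # 1/ms
    ip3k_total: float = 1e-4     # mM
    kf_ip3k_ca: float = 1000.0   # 1/(mM^2*ms), two calcium ions bind first
    kb_ip3k_ca: float = 2.5e-4   # 1/ms
    kf_ip3k_ip3: float = 50.0    # 1/(mM*ms)
    kb_ip3k_ip3: float = 0.01    # 1/ms
    k_ip4: float = 0.02          # 1/ms

    @property
    def kon_ach(self) -> float:
        return self.koff_ach / self.ach_ec50

    @property
    def k_plc_assoc_eff(self) -> float:
        return self.k_plc_assoc * self.plc_assoc_factor

    @property
    def k_plc_diss_eff(self) -> float:
        return self.k_plc_diss * self.plc_diss_factor

    @property
    def r_plc_eff(self) -> float:
        return self.r_plc * self.r_plc_factor


@dataclass
class SolverParams:
    """Integrator settings (the model is one stiff monolithic ODE system)."""

    method: str = "BDF"
    rtol: float = 1e-4
    atol_vm: float = 1e-3        # mV
    atol_gate: float = 1e-6
    atol_conc: float = 1e-9      # mM
    dt_out: float = 1.0          # ms default output interval
    settle_time: float = 120e3   # ms, steady-state relaxation
    max_negative_conc: float = 1e-6  # mM; sustained worse negativity aborts


@dataclass
class ModelParams:
    """Top-level parameter bundle (one per model instance)."""

    morphology: MorphologyParams = field(default_factory=MorphologyParams)
    channels: ChannelKinetics = field(default_factory=ChannelKinetics)
    er: ERParams = field(default_factory=ERParams)
    cytosol: CytosolParams = field(default_factory=CytosolParams)
    ip3r: IP3RParams = field(default_factory=IP3RParams)
    soce: SOCEParams = field(default_factory=SOCEParams)
    m1: M1Params = field(default_factory=M1Params)
    solver: SolverParams = field(default_factory=SolverParams)

    def copy(self) -> "ModelParams":
        return copy.deepcopy(self)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ModelParams":
        return _dataclass_from_dict(cls, data, path="")


def _dataclass_from_dict(cls, data: dict[str, Any], path: str):
    """Strictly build a dataclass tree, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise TypeError(f"expected mapping at {path or '<root>'}")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        key = sorted(unknown)[0]
        raise KeyError(f"unknown config key: {path}{key}")
    kwargs = {}
    for name, f in known.items():
        if name not in data:
            continue
        value = data[name]
        if is_dataclass(f.type) or (isinstance(f.type, str) and f.type in _TYPE_REGISTRY):
            sub = _TYPE_REGISTRY[f.type] if isinstance(f.type, str) else f.type
            kwargs[name] = _dataclass_from_dict(sub, value, path=f"{path}{name}.")
        else:
            kwargs[name] = value
    return cls(**kwargs)


_TYPE_REGISTRY = {
    "SectionParams": SectionParams,
    "MorphologyParams": MorphologyParams,
    "ChannelKinetics": ChannelKinetics,
    "ERParams": ERParams,
    "CytosolParams": CytosolParams,
    "IP3RParams": IP3RParams,
    "SOCEParams": SOCEParams,
    "M1Params": M1Params,
    "SolverParams": SolverParams,
    "ModelParams": ModelParams,
}
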