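"""State layout, right-hand-side assembly and time integration.

The electrical cable (membrane potential + channel gates) and the chemistry
(calcium, buffers, cascade) form one monolithic stiff ODE system integrated
with a BDF method; no operator splitting is used, which keeps the tight
vm <-> Ca <-> K-channel loop consistent.

State vector layout (stable, documented):

* ``y[0 : n_elec]`` -- membrane potential per electrical compartment (mV)
* ``y[n_elec : n_elec + n_gates*n_elec]`` -- channel gates, shape
  (n_gates, n_elec), row-major
* the remainder -- chemistry, shape (n_species, n_chem), row-major, in the
  order of :data:`SPECIES`

Chemistry compartments are the soma+trunk prefix of the electrical ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy import sparse

from . import calcium, cascade
from .channels import kv7_conductance_scale, make_channel_schemes, sk_activation
from .morphology import Morphology, build_reduced_morphology
from .params import ModelParams
from .reactions import ReactionNetwork, ReactionSpec
from .units import CA_CURRENT_TO_FLUX

#: fixed species ordering of the chemistry block
SPECIES: tuple[str, ...] = (
    # calcium side
    "ca", "ca_er", "calr", "calr_ca", "cb", "cb_ca", "ogb", "ogb_ca",
    "pmca", "pmca_ca",
    # M1 cascade (membrane densities + cytosolic IP3 branch)
    "r", "rl", "g", "rg", "rlg", "gbg", "ga_gtp", "ga_gdp",
    "plc", "ga_gtp_plc", "ga_gdp_plc",
    "pi", "pi4p", "pip2", "dag", "ip3",
    "ip5p", "ip5p_ip3", "ip3k", "ip3k_2ca", "ip3k_2ca_ip3", "ip2", "ip4",
    # IP3 receptor gating states (fractions, sum to 1 per compartment)
    "ir", "ir_i", "ir_o", "ir_c",
)
SP = {name: i for i, name in enumerate(SPECIES)}


class IntegrationError(RuntimeError):
    pass


class SteadyStateError(RuntimeError):
    pass


@dataclass
class CurrentPulse:
    """Square somatic current injection."""
    amplitude: float          # pA
    start: float              # ms
    duration: float           # ms
    compartment: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")

    kind = "current"

    def edges(self) -> list[float]:
        return [self.start, self.start + self.duration]


@dataclass
class AchPulse:
    """Clamped bath ACh applied uniformly to all chemistry compartments.

    ``duration=None`` means sustained to the end of the run.  ACh is not
    consumed by receptor binding.
    """
    concentration: float      # mM
    start: float              # ms
    duration: float | None = None

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")

    kind = "ach"

    def edges(self) -> list[float]:
        if self.duration is None:
            return [self.start]
        return [self.start, self.start + self.duration]

    def value(self, t: float) -> float:
        if t < self.start:
            return 0.0
        if self.duration is not None and t >= self.start + self.duration:
            return 0.0
        return self.concentration


@dataclass
class Trace:
    """Sampled time series of selected state variables."""

    times: np.ndarray                       # ms, strictly increasing
    variables: dict[str, np.ndarray]
    stimuli: list[tuple] = field(default_factory=list)
    spike_times: np.ndarray | None = None   # soma threshold crossings, ms

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        for name, v in self.variables.items():
            if len(v) != len(t):
                raise ValueError(f"series {name!r} length mismatch")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.variables[name]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_ms": self.times})
        for name, v in self.variables.items():
            df[name] = v
        return df


def write_trace(trace: Trace, path: str) -> None:
    """Lossless CSV round trip (full float precision)."""
    trace.to_dataframe().to_csv(path, index=False, float_format="%.17g")


def read_trace(path: str) -> Trace:
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_ms" not in df.columns:
        raise ValueError(f"{path}: not a trace file (no time_ms column)")
    times = df["time_ms"].to_numpy()
    variables = {c: df[c].to_numpy() for c in df.columns if c != "time_ms"}
    return Trace(times=times, variables=variables)


class AssembledModel:
    """Compiled model: geometry, channels, reaction network and fluxes."""

    def __init__(self, params: ModelParams, morphology: Morphology | None = None):
        self.params = params
        self.morph = morphology or build_reduced_morphology(params.morphology)
        m = self.morph
        self.n_elec = m.n_elec
        self.n_chem = m.n_chem
        self.chem_to_elec = m.chem_indices            # chem comp -> elec comp
        arr = m.arrays()
        self.area = arr["area"]
        self.vol_cyt = arr["volume_cyt"][self.chem_to_elec]
        self.vol_er = arr["volume_er"][self.chem_to_elec]
        self.sv = arr["sv_ratio"][self.chem_to_elec]
        self.vol_ratio = params.morphology.cytosol_fraction / params.morphology.er_fraction
        self.capacitance = m.capacitance()
        self.ax_i, self.ax_j, self.ax_g = m.axial_conductance()

        # compartment names
        names = []
        counters: dict[str, int] = {}
        for s in m.section_of:
            counters[s] = counters.get(s, 0) + 1
            names.append(s if m.section_of.count(s) == 1 else f"{s}{counters[s]}")
        self.comp_names = names
        self.comp_index = {n: i for i, n in enumerate(names)}

        # channels
        self.schemes = make_channel_schemes()
        self.active_channels = [ch for ch in m.channel_density if ch != "leak"]
        self.gbar = {ch: m.channel_density[ch] * self.area for ch in m.channel_density}
        self.gate_list: list[tuple[str, int]] = []     # (channel, gate index)
        for ch in self.active_channels:
            for gi in range(len(self.schemes[ch].gates)):
                self.gate_list.append((ch, gi))
        self.n_gates = len(self.gate_list)

        # chemistry network
        self.n_species = len(SPECIES)
        specs = (calcium.build_buffer_and_pump_reactions(params.er, params.cytosol)
                 + cascade.build_cascade_reactions(params.m1))
        self.reaction_specs = specs
        self.network = ReactionNetwork(specs, SP, clamped={"ach"})

        # per-compartment scales
        self.ip3_scale = params.m1.ip3_scale_soma * self.sv / self.sv[0]
        # extrusion capacity grows sublinearly with surface-to-volume: thin
        # dendrites clear calcium faster than the soma, but not in full
        # proportion to their membrane area
        q = params.cytosol.pmca_sv_exponent
        self.pmca_total = (params.cytosol.pmca_density * self.sv[0]
                           * (self.sv / self.sv[0]) ** q)
        self.g_ip3r_comp = (params.ip3r.g_ip3r
                            * (self.sv / self.sv[0]) ** params.ip3r.sv_exponent)

        # diffusion geometry along the chemistry path
        diam = arr["diameter"][self.chem_to_elec]
        pos = arr["position"][self.chem_to_elec]
        self.diff_cross = np.pi * (np.minimum(diam[:-1], diam[1:]) / 2.0) ** 2
        self.diff_dist = np.abs(np.diff(pos))

        # state offsets
        self.off_gates = self.n_elec
        self.off_chem = self.n_elec + self.n_gates * self.n_elec
        self.n_state = self.off_chem + self.n_species * self.n_chem

        self._rest_state = None
        self._e_leak = None
        self._j_bg = None
        self._finalise_rest()

    # ----- state helpers -------------------------------------------------
    def split(self, y: np.ndarray):
        vm = y[: self.n_elec]
        gates = y[self.off_gates: self.off_chem].reshape(self.n_gates, self.n_elec)
        chem = y[self.off_chem:].reshape(self.n_species, self.n_chem)
        return vm, gates, chem

    def chem_view(self, y: np.ndarray, species: str) -> np.ndarray:
        return self.split(y)[2][SP[species]]

    def initial_state(self) -> np.ndarray:
        return self._rest_state.copy()

    def _analytic_rest(self) -> np.ndarray:
        p = self.params
        v0 = p.morphology.v_init
        y = np.zeros(self.n_state)
        vm, gates, chem = self.split(y)
        vm[:] = v0
        for gi, (ch, k) in enumerate(self.gate_list):
            gates[gi, :] = self.schemes[ch].gates[k].inf(v0)

        ca = p.cytosol.ca_rest
        ca_er = p.er.ca_er_rest
        chem[SP["ca"]] = ca
        chem[SP["ca_er"]] = ca_er
        kd_calr = p.er.kb_calr / p.er.kf_calr
        chem[SP["calr_ca"]] = p.er.calr_total * ca_er / (ca_er + kd_calr)
        chem[SP["calr"]] = p.er.calr_total - chem[SP["calr_ca"]]
        kd_cb = p.cytosol.kb_cb / p.cytosol.kf_cb
        chem[SP["cb_ca"]] = p.cytosol.cb_total * ca / (ca + kd_cb)
        chem[SP["cb"]] = p.cytosol.cb_total - chem[SP["cb_ca"]]
        kd_ogb = p.cytosol.kb_ogb1 / p.cytosol.kf_ogb1
        chem[SP["ogb_ca"]] = p.cytosol.ogb_total * ca / (ca + kd_ogb)
        chem[SP["ogb"]] = p.cytosol.ogb_total - chem[SP["ogb_ca"]]
        km_pmca = (p.cytosol.kb_pmca_ca + p.cytosol.k_pmca_rel) / p.cytosol.kf_pmca_ca
        chem[SP["pmca_ca"]] = self.pmca_total * ca / (ca + km_pmca)
        chem[SP["pmca"]] = self.pmca_total - chem[SP["pmca_ca"]]

        rest = cascade.cascade_rest_concentrations(p.m1)
        for name, value in rest.items():
            chem[SP[name]] = value
        # IP3K calcium pre-binding equilibrium at resting calcium
        q = p.m1.kf_ip3k_ca * ca * ca / max(p.m1.kb_ip3k_ca, 1e-30)
        chem[SP["ip3k_2ca"]] = p.m1.ip3k_total * q / (1.0 + q)
        chem[SP["ip3k"]] = p.m1.ip3k_total - chem[SP["ip3k_2ca"]]
        # IP3R: no IP3 at rest -> all receptors unliganded
        chem[SP["ir"]] = 1.0
        return y

    def _finalise_rest(self) -> None:
        """Pin the resting potential and cytosolic calcium.

        The leak reversal absorbs the standing (small) channel currents at
        v_init, and a constant background calcium influx balances resting
        PMCA extrusion net of resting VGCC influx -- the standard way of
        making the configured rest an exact fixed point of the plasma
        membrane without touching the ER balance (which the stage-1
        calibration owns).
        """
        y = self._analytic_rest()
        vm, gates, chem = self.split(y)
        self._e_leak = np.zeros(self.n_elec)
        self._pinning = True
        i_other, i_ca = self._ionic_currents(vm, gates, chem)
        self._pinning = False
        g_leak = self.gbar["leak"]
        self._e_leak = vm + i_other / np.where(g_leak > 0, g_leak, np.inf)
        p = self.params
        pmca_rest_extrusion = p.cytosol.k_pmca_rel * chem[SP["pmca_ca"]]
        vgcc_rest_influx = -i_ca[self.chem_to_elec] * CA_CURRENT_TO_FLUX / self.vol_cyt
        self._j_bg = pmca_rest_extrusion - vgcc_rest_influx
        self._rest_state = y

    # ----- electrical ----------------------------------------------------
    def _ionic_currents(self, vm, gates, chem):
        """(non-leak ionic current, calcium current) per compartment, pA.

        Leak is handled separately because its reversal is the rest-pinning
        parameter.
        """
        p = self.params
        ck = p.channels
        rev = {"na": ck.e_na, "k": ck.e_k, "ca": ck.e_ca, "h": ck.e_h}
        gate_of = {}
        for gi, (ch, k) in enumerate(self.gate_list):
            gate_of[(ch, k)] = gates[gi]

        pip2_scale = np.ones(self.n_elec)
        if self.n_chem:
            rel = chem[SP["pip2"]] / max(p.m1.pip2_rest, 1e-30)
            pip2_scale[self.chem_to_elec] = kv7_conductance_scale(
                np.maximum(rel, 0.0), ck.pip2_half, ck.pip2_hill)
        if ck.kv7_block and not getattr(self, "_pinning", False):
            pip2_scale[:] = 0.0
        ca_elec = np.full(self.n_elec, p.cytosol.ca_rest)
        ca_elec[self.chem_to_elec] = np.maximum(chem[SP["ca"]], 0.0)

        i_total = np.zeros(self.n_elec)
        i_ca = np.zeros(self.n_elec)
        for ch in self.active_channels:
            scheme = self.schemes[ch]
            g = self.gbar[ch]
            if not np.any(g):
                continue
            if ch == "sk":
                act = sk_activation(ca_elec, ck.sk_ca_half, ck.sk_hill)
                cur = g * act * (vm - ck.e_k)
            else:
                open_frac = 1.0
                for k, power in enumerate(scheme.gate_powers):
                    gate = gate_of[(ch, k)]
                    open_frac = open_frac * (gate ** power if power != 1 else gate)
                if scheme.modulation == "pip2":
                    open_frac = open_frac * pip2_scale
                cur = g * open_frac * (vm - rev[scheme.reversal])
            i_total += cur
            if scheme.reversal == "ca":
                i_ca += cur
        return i_total, i_ca

    # ----- right-hand side ------------------------------------------------
    def rhs(self, t: float, y: np.ndarray,
            stimuli: Sequence = ()) -> np.ndarray:
        p = self.params
        vm, gates, chem = self.split(y)
        dy = np.zeros_like(y)
        dvm, dgates, dchem = self.split(dy)

        # gating kinetics
        for gi, (ch, k) in enumerate(self.gate_list):
            kin = self.schemes[ch].gates[k]
            dgates[gi] = (kin.inf(vm) - gates[gi]) / kin.tau(vm)

        chem_pos = np.maximum(chem, 0.0)
        i_ion, i_ca = self._ionic_currents(vm, gates, chem_pos)
        i_leak = self.gbar["leak"] * (vm - self._e_leak)
        i_inj = np.zeros(self.n_elec)
        ach_value = 0.0
        for stim in stimuli:
            if stim.kind == "current":
                if stim.start <= t < stim.start + stim.duration:
                    i_inj[stim.compartment] += stim.amplitude
            elif stim.kind == "ach":
                ach_value += stim.value(t)

        i_net = -(i_ion + i_leak) + i_inj
        np.add.at(i_net, self.ax_i, self.ax_g * (vm[self.ax_j] - vm[self.ax_i]))
        np.add.at(i_net, self.ax_j, self.ax_g * (vm[self.ax_i] - vm[self.ax_j]))
        dvm[:] = i_net / self.capacitance

        if self.n_chem == 0:
            return dy

        # mass-action chemistry
        self.network.derivatives(chem_pos, {"ach": ach_value}, out=dchem)

        ca = chem_pos[SP["ca"]]
        ca_er = chem_pos[SP["ca_er"]]
        vr = self.vol_ratio

        j_serca = calcium.serca_flux(ca, p.er)           # cytosol units
        dchem[SP["ca"]] -= j_serca
        dchem[SP["ca_er"]] += j_serca * vr

        j_leak = calcium.er_leak_flux(ca_er, p.er)       # ER units
        dchem[SP["ca_er"]] -= j_leak
        dchem[SP["ca"]] += j_leak / vr

        d_ir, d_iri, d_iro, d_irc = calcium.ip3r_gating_derivatives(
            chem_pos[SP["ir"]], chem_pos[SP["ir_i"]], chem_pos[SP["ir_o"]],
            chem_pos[SP["ir_c"]], chem_pos[SP["ip3"]], ca, p.ip3r)
        dchem[SP["ir"]] += d_ir
        dchem[SP["ir_i"]] += d_iri
        dchem[SP["ir_o"]] += d_iro
        dchem[SP["ir_c"]] += d_irc
        j_ip3r = self.g_ip3r_comp * chem_pos[SP["ir_o"]] * ca_er
        dchem[SP["ca_er"]] -= j_ip3r
        dchem[SP["ca"]] += j_ip3r / vr

        vm_chem = vm[self.chem_to_elec]
        dchem[SP["ca_er"]] += calcium.soce_rate(vm_chem, ca_er, p.soce)

        # PIP2 hydrolysis (membrane units -> IP3 in mM via per-compartment scale)
        h = cascade.pip2_hydrolysis_rate(chem_pos[SP["pip2"]],
                                         chem_pos[SP["ga_gtp_plc"]],
                                         p.m1.r_plc_eff)
        dchem[SP["pip2"]] -= h
        dchem[SP["dag"]] += h
        dchem[SP["ip3"]] += h * self.ip3_scale

        # VGCC influx into the full cytosolic sub-volume + background balance
        dchem[SP["ca"]] += (-i_ca[self.chem_to_elec] * CA_CURRENT_TO_FLUX
                            / self.vol_cyt) + self._j_bg

        # longitudinal diffusion of free calcium and IP3
        if self.n_chem >= 2:
            dchem[SP["ca"]] += calcium.diffusion_terms(
                ca, p.cytosol.d_ca, self.vol_cyt, self.diff_cross, self.diff_dist)
            dchem[SP["ip3"]] += calcium.diffusion_terms(
                chem_pos[SP["ip3"]], p.cytosol.d_ip3, self.vol_cyt,
                self.diff_cross, self.diff_dist)
        return dy

    # ----- jacobian sparsity ---------------------------------------------
    def jac_sparsity(self) -> sparse.csc_matrix:
        n = self.n_state
        rows: list[int] = []
        cols: list[int] = []

        def add(r, c):
            rows.append(r)
            cols.append(c)

        def vm_idx(e):
            return e

        def gate_idx(gi, e):
            return self.off_gates + gi * self.n_elec + e

        def chem_idx(sp_name, c):
            return self.off_chem + SP[sp_name] * self.n_chem + c

        neighbours: dict[int, set[int]] = {e: {e} for e in range(self.n_elec)}
        for a, b in zip(self.ax_i, self.ax_j):
            neighbours[a].add(b)
            neighbours[b].add(a)

        elec_of_chem = {c: e for c, e in enumerate(self.chem_to_elec)}
        chem_of_elec = {e: c for c, e in elec_of_chem.items()}

        for e in range(self.n_elec):
            for nb in neighbours[e]:
                add(vm_idx(e), vm_idx(nb))
            for gi in range(self.n_gates):
                add(vm_idx(e), gate_idx(gi, e))
                add(gate_idx(gi, e), vm_idx(e))
                add(gate_idx(gi, e), gate_idx(gi, e))
            if e in chem_of_elec:
                c = chem_of_elec[e]
                add(vm_idx(e), chem_idx("ca", c))
                add(vm_idx(e), chem_idx("pip2", c))

        pairs = set(self.network.dependency_pairs())
        custom = [
            ({"ca", "ca_er"}, {"ca"}),                        # SERCA
            ({"ca", "ca_er"}, {"ca_er"}),                     # leak + IP3R drive
            ({"ir", "ir_i", "ir_o", "ir_c", "ca", "ca_er"},
             {"ir", "ir_i", "ir_o", "ir_c", "ip3", "ca"}),    # IP3R
            ({"pip2", "dag", "ip3"}, {"pip2", "ga_gtp_plc"}),  # hydrolysis
        ]
        for affected, deps in custom:
            for a in affected:
                for b in deps:
                    pairs.add((a, b))
        for c in range(self.n_chem):
            for a, b in pairs:
                add(chem_idx(a, c), chem_idx(b, c))
            e = elec_of_chem[c]
            add(chem_idx("ca_er", c), vm_idx(e))              # SOCE
            add(chem_idx("ca", c), vm_idx(e))                 # VGCC influx
            for gi, (ch, _) in enumerate(self.gate_list):
                if self.schemes[ch].reversal == "ca":
                    add(chem_idx("ca", c), gate_idx(gi, e))
        for c in range(self.n_chem - 1):                      # diffusion
            for spn in ("ca", "ip3"):
                add(chem_idx(spn, c), chem_idx(spn, c + 1))
                add(chem_idx(spn, c + 1), chem_idx(spn, c))

        data = np.ones(len(rows))
        return sparse.csc_matrix((data, (rows, cols)), shape=(n, n))

    def _jac_groups(self):
        """Greedy structurally-orthogonal column groups for FD Jacobians."""
        if getattr(self, "_groups_cache", None) is not None:
            return self._groups_cache
        sp_csc = self.jac_sparsity().tocsc()
        n = self.n_state
        rows_of = [sp_csc.indices[sp_csc.indptr[j]: sp_csc.indptr[j + 1]]
                   for j in range(n)]
        group_rows: list[set[int]] = []
        group_of = np.empty(n, dtype=int)
        for j in range(n):
            rj = set(rows_of[j].tolist())
            for gi, gr in enumerate(group_rows):
                if not (gr & rj):
                    gr |= rj
                    group_of[j] = gi
                    break
            else:
                group_rows.append(set(rj))
                group_of[j] = len(group_rows) - 1
        self._groups_cache = (group_of, len(group_rows), rows_of)
        return self._groups_cache

    def _fd_floor(self) -> np.ndarray:
        floor = np.full(self.n_state, 1e-10)
        floor[: self.n_elec] = 1e-4
        floor[self.off_gates: self.off_chem] = 1e-7
        return floor

    def make_jacobian(self, fun) -> Callable:
        """Grouped finite-difference Jacobian on the known sparsity pattern.

        A fixed relative step avoids the pathologies of adaptive differencing
        on terminal-sink species whose columns are structurally zero.
        """
        group_of, n_groups, rows_of = self._jac_groups()
        floor = self._fd_floor()
        n = self.n_state
        members = [np.flatnonzero(group_of == g) for g in range(n_groups)]
        # flat (row, col) pattern in csc order and the group of each column
        cols_all = np.concatenate([np.full(len(rows_of[c]), c, dtype=np.intp)
                                   for c in range(n)])
        rows_all = np.concatenate([rows_of[c] for c in range(n)])
        indptr = np.zeros(n + 1, dtype=np.intp)
        indptr[1:] = np.cumsum([len(rows_of[c]) for c in range(n)])
        group_of_entry = group_of[cols_all]

        def jac(t, y):
            f0 = fun(t, y)
            h = 1e-6 * np.abs(y) + floor
            df = np.empty((n, n_groups))
            for g in range(n_groups):
                yp = y.copy()
                yp[members[g]] += h[members[g]]
                df[:, g] = fun(t, yp) - f0
            data = df[rows_all, group_of_entry] / h[cols_all]
            return sparse.csc_matrix((data, rows_all, indptr), shape=(n, n))

        return jac

    def atol(self) -> np.ndarray:
        s = self.params.solver
        a = np.full(self.n_state, s.atol_gate)
        a[: self.n_elec] = s.atol_vm
        a[self.off_chem:] = s.atol_conc
        return a


# --------------------------------------------------------------------------
def assemble_rhs(model: AssembledModel, stimuli: Sequence = ()) -> Callable:
    """Return the derivative function f(t, y) for a fixed stimulus schedule."""
    return lambda t, y: model.rhs(t, y, stimuli)


def integrate(model: AssembledModel, duration: float,
              stimuli: Sequence = (), y0: np.ndarray | None = None,
              record: Sequence[str] | None = None, dt_out: float | None = None,
              rtol: float | None = None, atol_scale: float = 1.0,
              t0: float = 0.0, detect_spikes: bool = True,
              spike_threshold: float = 0.0,
              return_final_state: bool = False):
    """Integrate the model and sample a :class:`Trace`.

    The time axis is split at every stimulus edge so the solver never steps
    across a discontinuity.  Soma spikes are located exactly with solver
    events (upward crossings of ``spike_threshold``).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    p = model.params.solver
    y = model.initial_state() if y0 is None else np.array(y0, dtype=float)
    dt = dt_out if dt_out is not None else p.dt_out
    rec = list(record) if record is not None else ["vm:soma", "ca:soma",
                                                   "ca_er:soma", "ip3:soma",
                                                   "pip2:soma"]

    edges = {t0, t0 + duration}
    for stim in stimuli:
        for e in stim.edges():
            if t0 < e < t0 + duration:
                edges.add(e)
    breakpoints = sorted(edges)

    fun = assemble_rhs(model, stimuli)
    jac = model.make_jacobian(fun)
    atol = model.atol() * atol_scale
    rt = rtol if rtol is not None else p.rtol

    soma = 0
    def spike_event(t, yy):
        return yy[soma] - spike_threshold
    spike_event.direction = 1.0

    times_parts, y_parts, spikes = [], [], []
    for a, b in zip(breakpoints[:-1], breakpoints[1:]):
        n_pts = max(2, int(math.ceil((b - a) / dt)) + 1)
        t_eval = np.linspace(a, b, n_pts)
        sol = solve_ivp(fun, (a, b), y, method=p.method, rtol=rt, atol=atol,
                        jac=jac, t_eval=t_eval, dense_output=False,
                        events=[spike_event] if detect_spikes else None)
        if not sol.success:
            raise IntegrationError(
                f"solver failed at t ~ {sol.t[-1] if sol.t.size else a:.3f} ms: "
                f"{sol.message}")
        y = sol.y[:, -1].copy()
        chem_min = y[model.off_chem:].min() if model.n_chem else 0.0
        if chem_min < -p.max_negative_conc:
            raise IntegrationError(
                f"sustained negative concentration ({chem_min:.3e} mM) at "
                f"t = {b:.1f} ms")
        skip = 1 if times_parts else 0
        times_parts.append(sol.t[skip:])
        y_parts.append(sol.y[:, skip:])
        if detect_spikes and sol.t_events and sol.t_events[0].size:
            spikes.append(sol.t_events[0])

    times = np.concatenate(times_parts)
    ys = np.concatenate(y_parts, axis=1)

    variables: dict[str, np.ndarray] = {}
    for name in rec:
        kind, comp = name.split(":")
        ci = model.comp_index[comp]
        if kind == "vm":
            variables[name] = ys[ci].copy()
        else:
            c = int(np.flatnonzero(model.chem_to_elec == ci)[0])
            variables[name] = ys[model.off_chem + SP[kind] * model.n_chem + c].copy()

    spike_times = np.concatenate(spikes) if spikes else np.array([])
    # refractory deduplication (2 ms)
    if spike_times.size:
        keep = [spike_times[0]]
        for t in spike_times[1:]:
            if t - keep[-1] >= 2.0:
                keep.append(t)
        spike_times = np.array(keep)

    annotations = [(s.kind, s.start, getattr(s, "duration", None),
                    getattr(s, "amplitude", getattr(s, "concentration", None)))
                   for s in stimuli]
    trace = Trace(times=times, variables=variables, stimuli=annotations,
                  spike_times=spike_times)
    if return_final_state:
        return trace, y
    return trace


def steady_state(model: AssembledModel, settle: float | None = None,
                 y0: np.ndarray | None = None,
                 residual_threshold: float = 1e-4) -> tuple[np.ndarray, float]:
    """Relax the stimulus-free model and return (state, residual norm).

    The residual is the maximum absolute state derivative scaled by the
    solver's absolute tolerances; values above ``residual_threshold`` (in
    tolerance units per ms, scaled by 1e-3) raise :class:`SteadyStateError`.
    """
    p = model.params.solver
    t_settle = settle if settle is not None else p.settle_time
    _, y = integrate(model, t_settle, y0=y0, dt_out=t_settle / 16,
                     detect_spikes=False, return_final_state=True)
    dy = model.rhs(0.0, y)
    residual = float(np.max(np.abs(dy) / (model.atol() * 1e3)))
    if residual > residual_threshold * 1e3:
        raise SteadyStateError(f"steady state not reached (residual {residual:.3e})")
    return y, residual
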