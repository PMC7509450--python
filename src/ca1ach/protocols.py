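"""Virtual experiments and their scalar metrics.

Each protocol runs the assembled model through a stimulus schedule and
returns a :class:`ProtocolResult` whose metrics carry (value, units) pairs.
Baselines for "peak hyperpolarization/depolarization" are the mean membrane
potential over the 500 ms before the stimulus.  Spike threshold is 0 mV with
a 2 ms refractory; the driven protocols first search for the somatic current
that produces steady 10 Hz firing (bisection, 0.2 Hz tolerance).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from . import metrics
from .core import (AchPulse, AssembledModel, CurrentPulse, SP, Trace,
                   integrate, steady_state)
from .params import ModelParams


@dataclass
class ProtocolResult:
    name: str
    metrics: dict[str, tuple[float, str]]
    config: dict[str, Any] = field(default_factory=dict)
    traces: dict[str, Trace] = field(default_factory=dict)

    def value(self, key: str) -> float:
        return self.metrics[key][0]


# --------------------------------------------------------------------- caches
def rest_state(model: AssembledModel, settle: float | None = None) -> np.ndarray:
    cache = getattr(model, "_proto_cache", None)
    if cache is None:
        cache = model._proto_cache = {}
    key = ("rest", settle)
    if key not in cache:
        y, _ = steady_state(model, settle=settle)
        cache[key] = y
    return cache[key].copy()


def tonic_steady_state(model: AssembledModel, conc: float,
                       settle: float = 90e3) -> np.ndarray:
    """State after prolonged bath ACh exposure (ACh still present)."""
    cache = getattr(model, "_proto_cache", None)
    if cache is None:
        cache = model._proto_cache = {}
    key = ("tonic", conc, settle)
    if key not in cache:
        y0 = rest_state(model)
        stim = [AchPulse(conc, start=0.0)]
        _, y = integrate(model, settle, stimuli=stim, y0=y0, dt_out=settle / 16,
                         detect_spikes=False, return_final_state=True)
        cache[key] = y
    return cache[key].copy()


def find_drive_current(model: AssembledModel, target_hz: float = 10.0,
                       tol_hz: float = 0.2, stimuli: Sequence = (),
                       y0: np.ndarray | None = None) -> float:
    """Bisection on sustained somatic current for a steady firing rate."""
    cache = getattr(model, "_proto_cache", None)
    if cache is None:
        cache = model._proto_cache = {}
    key = ("drive", target_hz, tuple((s.kind, getattr(s, "concentration", 0))
                                     for s in stimuli))
    if key in cache:
        return cache[key]
    y = rest_state(model) if y0 is None else y0

    def rate(amp: float) -> float:
        tr = integrate(model, 3000.0,
                       stimuli=list(stimuli) + [CurrentPulse(amp, 0.0, 3000.0)],
                       y0=y, dt_out=1.0)
        st = tr.spike_times[tr.spike_times > 1000.0]
        if st.size < 2:
            return 0.0
        return 1e3 * (st.size - 1) / (st[-1] - st[0])

    lo, hi = 0.0, 400.0
    r_hi = rate(hi)
    while r_hi < target_hz:
        lo, hi = hi, hi * 1.6
        r_hi = rate(hi)
        if hi > 5e3:
            raise RuntimeError("cannot reach target firing rate")
    r_lo = rate(lo) if lo > 0 else 0.0
    amp = None
    for _ in range(14):
        # secant step inside the bracket, falling back to bisection
        if r_hi > r_lo:
            guess = lo + (target_hz - r_lo) * (hi - lo) / (r_hi - r_lo)
            if not (lo < guess < hi):
                guess = 0.5 * (lo + hi)
        else:
            guess = 0.5 * (lo + hi)
        r = rate(guess)
        if abs(r - target_hz) <= tol_hz:
            amp = guess
            break
        if r < target_hz:
            lo, r_lo = guess, r
        else:
            hi, r_hi = guess, r
    cache[key] = amp if amp is not None else 0.5 * (lo + hi)
    return cache[key]


# ------------------------------------------------------------------ rheobase
def find_rheobase(model: AssembledModel, y0: np.ndarray | None = None,
                  stimuli: Sequence = (), pulse_ms: float = 200.0,
                  tol_pa: float = 1.0, upper: float = 800.0) -> float:
    """Minimum 200 ms pulse amplitude eliciting a spike, by binary search."""
    y = rest_state(model) if y0 is None else y0

    def spikes(amp: float) -> bool:
        tr = integrate(model, pulse_ms + 80.0,
                       stimuli=list(stimuli) + [CurrentPulse(amp, 20.0, pulse_ms)],
                       y0=y, dt_out=1.0)
        return tr.spike_times.size > 0

    lo = 0.0
    hi = upper
    if not spikes(hi):
        raise RuntimeError(f"upper bracket {hi} pA fails to spike")
    while hi - lo > tol_pa:
        mid = 0.5 * (lo + hi)
        if spikes(mid):
            hi = mid
        else:
            lo = mid
    return hi


def input_resistance(model: AssembledModel, y0: np.ndarray | None = None,
                     stimuli: Sequence = (),
                     amplitudes: Sequence[float] = (-100.0, 0.0, 100.0),
                     probe_ms: float = 800.0) -> float:
    """Input resistance (MOhm) from the regression of steady deflection on
    current over the given amplitudes."""
    y = rest_state(model) if y0 is None else y0
    vs = []
    for amp in amplitudes:
        stim = list(stimuli)
        if amp != 0.0:
            stim.append(CurrentPulse(amp, 20.0, probe_ms))
        tr = integrate(model, probe_ms + 40.0, stimuli=stim, y0=y, dt_out=2.0)
        if tr.spike_times.size:
            raise RuntimeError(f"spike during input-resistance probe at {amp} pA")
        sel = (tr.times > probe_ms - 200.0) & (tr.times < probe_ms)
        vs.append(tr["vm:soma"][sel].mean())
    slope = np.polyfit(list(amplitudes), vs, 1)[0]
    return float(slope * 1e3)  # mV/pA -> MOhm


# ----------------------------------------------------------------- protocols
def run_phasic_protocol(model: AssembledModel, conc: float,
                        mode: str = "rest", pulse_ms: float = 50.0,
                        post_window: float = 9e3, keep_traces: bool = False,
                        drive_amp: float | None = None) -> ProtocolResult:
    """50 ms bath ACh pulse, at rest or while driven to steady 10 Hz firing."""
    if mode not in ("rest", "driven_10hz"):
        raise ValueError(f"unknown mode {mode!r}")
    t_pulse = 1000.0 if mode == "rest" else 2000.0
    duration = t_pulse + post_window
    y0 = rest_state(model)
    stimuli: list = [AchPulse(conc, start=t_pulse, duration=pulse_ms)]
    if mode == "driven_10hz":
        amp = drive_amp if drive_amp is not None else find_drive_current(model)
        stimuli.append(CurrentPulse(amp, 0.0, duration))
    rec = ["vm:soma", "ca:soma", "ca_er:soma", "ip3:soma", "pip2:soma"]
    tr = integrate(model, duration, stimuli=stimuli, y0=y0, dt_out=1.0,
                   record=rec)
    out: dict[str, tuple[float, str]] = {}
    base_sel = (tr.times >= t_pulse - 500.0) & (tr.times < t_pulse)
    baseline = float(tr["vm:soma"][base_sel].mean())
    ca_rest = float(tr["ca:soma"][base_sel].mean())
    post = tr.times >= t_pulse
    out["peak_ca"] = (float(tr["ca:soma"][post].max() - ca_rest), "mM")

    if mode == "rest":
        vm_post = tr["vm:soma"][post]
        t_post = tr.times[post]
        hyper_sel = t_post <= t_pulse + 4000.0
        i_min = int(np.argmin(vm_post[hyper_sel]))
        hyper = float(vm_post[hyper_sel][i_min] - baseline)
        t_trough = t_post[hyper_sel][i_min]
        depol_sel = t_post >= t_trough
        depol = float(vm_post[depol_sel].max() - baseline)
        out["peak_hyperpolarization"] = (min(hyper, 0.0), "mV")
        out["peak_depolarization"] = (max(depol, 0.0), "mV")
    else:
        st = tr.spike_times
        pre = st[(st > 500.0) & (st < t_pulse)]
        if pre.size < 3:
            raise RuntimeError("no stable pre-pulse firing in driven mode")
        base_rate = 1e3 * (pre.size - 1) / (pre[-1] - pre[0])
        dur, censored = metrics.inhibition_duration(st, t_pulse, t_end=duration)
        out["inhibition_duration"] = (dur, "ms")
        out["inhibition_censored"] = (float(censored), "bool")
        # left endpoint of the inhibition gap, relative to pulse onset
        after = st[st >= t_pulse]
        edges = np.concatenate([st[st < t_pulse][-1:], after])
        if edges.size >= 2:
            isis = np.diff(edges)
            k = int(np.argmax(isis))
            out["inhibition_start"] = (float(edges[k] - t_pulse), "ms")
        t_ifr, ifr = metrics.instantaneous_firing_rate(st)
        sel = t_ifr > t_pulse
        if sel.any():
            peak_ifr = float(ifr[sel].max())
            k = int(np.argmax(ifr[sel]))
            out["peak_acceleration"] = (100.0 * (peak_ifr - base_rate) / base_rate, "%")
            out["ifr_peak_time"] = (float(t_ifr[sel][k] - t_pulse), "ms")
        out["baseline_rate"] = (base_rate, "Hz")
    result = ProtocolResult(
        "phasic", out, config={"conc_mM": conc, "mode": mode,
                               "pulse_ms": pulse_ms})
    if keep_traces:
        result.traces["main"] = tr
    return result


def run_tonic_protocol(model: AssembledModel, conc: float,
                       duration: float = 60e3,
                       measure_excitability: bool = True,
                       keep_traces: bool = False) -> ProtocolResult:
    """Sustained bath ACh: depolarization, transient hyperpolarization,
    rheobase, input resistance at the adapted steady state."""
    y0 = rest_state(model)
    t_on = 1000.0
    stim = [AchPulse(conc, start=t_on)]
    tr = integrate(model, t_on + duration, stimuli=stim, y0=y0, dt_out=5.0,
                   record=["vm:soma", "ca:soma", "ca_er:soma", "pip2:soma"])
    base_sel = (tr.times >= t_on - 500.0) & (tr.times < t_on)
    baseline = float(tr["vm:soma"][base_sel].mean())
    post = tr.times >= t_on
    vm_post = tr["vm:soma"][post]
    out: dict[str, tuple[float, str]] = {
        "steady_depolarization": (float(np.mean(vm_post[-200:]) - baseline), "mV"),
        "transient_hyperpolarization": (min(float(vm_post.min() - baseline), 0.0), "mV"),
    }
    if measure_excitability:
        y_tonic = tonic_steady_state(model, conc)
        tonic_stim = [AchPulse(conc, start=0.0)] if conc > 0 else []
        out["rheobase"] = (find_rheobase(model, y0=y_tonic, stimuli=tonic_stim), "pA")
        out["input_resistance"] = (
            input_resistance(model, y0=y_tonic, stimuli=tonic_stim), "MOhm")
    result = ProtocolResult("tonic", out, config={"conc_mM": conc,
                                                  "duration_ms": duration})
    if keep_traces:
        result.traces["main"] = tr
    return result


def deplete_er_state(model: AssembledModel, fraction: float = 0.2) -> np.ndarray:
    """Rest state with ER free calcium reset to ``fraction`` of rest and
    calreticulin re-equilibrated at the new free level (store depletion)."""
    y = rest_state(model)
    _, _, chem = model.split(y)
    er = model.params.er
    chem[SP["ca_er"]] *= fraction
    kd = er.kb_calr / er.kf_calr
    chem[SP["calr_ca"]] = er.calr_total * chem[SP["ca_er"]] / (chem[SP["ca_er"]] + kd)
    chem[SP["calr"]] = er.calr_total - chem[SP["calr_ca"]]
    return y


def run_er_refill_protocol(model: AssembledModel, duration: float = 180e3,
                           fraction: float = 0.2,
                           keep_traces: bool = False) -> ProtocolResult:
    """Deplete the ER, hold the cell at rest, fit the refill exponential."""
    y0 = deplete_er_state(model, fraction)
    tr = integrate(model, duration, y0=y0, dt_out=250.0, detect_spikes=False,
                   record=["vm:soma", "ca:soma", "ca_er:soma"])
    tau, asymptote, r2 = metrics.exp_fit(tr.times, tr["ca_er:soma"], t0=0.0)
    out = {
        "refill_tau": (tau / 1e3, "s"),
        "ca_er_asymptote": (asymptote, "mM"),
        "fit_r2": (r2, ""),
    }
    result = ProtocolResult("er_refill", out, config={"fraction": fraction})
    if keep_traces:
        result.traces["main"] = tr
    return result


def make_imaging_model(params: ModelParams) -> AssembledModel:
    """Model variant with the OGB-1 indicator present and calbindin at the
    diminished (20%) concentration used for fluorescence replication."""
    p = params.copy()
    p.cytosol.ogb_total = p.cytosol.ogb_default
    p.cytosol.cb_total = p.cytosol.cb_total * p.cytosol.cb_fluor_fraction
    return AssembledModel(p)


def run_ap_transient_protocol(model: AssembledModel | None = None,
                              params: ModelParams | None = None,
                              keep_traces: bool = False) -> ProtocolResult:
    """Single evoked action potential; indicator fluorescence per section."""
    if model is None:
        model = make_imaging_model(params or ModelParams())
    if model.params.cytosol.ogb_total <= 0:
        raise ValueError("indicator disabled: delta F/F undefined")
    y0 = rest_state(model)
    rec = ["vm:soma"]
    for comp in ("soma", "trunk5"):
        rec += [f"ogb:{comp}", f"ogb_ca:{comp}"]
    tr = integrate(model, 1600.0,
                   stimuli=[CurrentPulse(1500.0, 100.0, 3.0)],
                   y0=y0, dt_out=1.0, record=rec)
    if tr.spike_times.size < 1:
        raise RuntimeError("no action potential elicited")
    f_mult = model.params.cytosol.f_mult
    out: dict[str, tuple[float, str]] = {}
    from .calcium import fluorescence
    for comp, label in (("soma", "soma"), ("trunk5", "trunk")):
        f = fluorescence(tr[f"ogb:{comp}"], tr[f"ogb_ca:{comp}"], f_mult)
        f_rest = f[tr.times < 100.0].mean()
        dff = (f - f_rest) / f_rest
        peak = float(dff.max())
        i_pk = int(np.argmax(dff))
        tau, _, _ = metrics.exp_fit(tr.times, dff, t0=float(tr.times[i_pk]))
        out[f"peak_dff_{label}"] = (peak, "dF/F")
        out[f"decay_tau_{label}"] = (tau, "ms")
    result = ProtocolResult("ap_transient", out, config={})
    if keep_traces:
        result.traces["main"] = tr
    return result


def run_calcium_wave_protocol(model: AssembledModel, conc: float = 0.1,
                              keep_traces: bool = False) -> ProtocolResult:
    """Simultaneous phasic ACh on soma+trunk; per-compartment calcium peaks."""
    if model.n_chem < 3:
        raise ValueError("wave protocol needs >= 3 chemistry compartments")
    y0 = rest_state(model)
    chem_names = [model.comp_names[e] for e in model.chem_to_elec]
    rec = [f"ca:{c}" for c in chem_names]
    t_pulse = 500.0
    tr = integrate(model, t_pulse + 6000.0,
                   stimuli=[AchPulse(conc, start=t_pulse, duration=50.0)],
                   y0=y0, dt_out=2.0, record=rec, detect_spikes=False)
    out: dict[str, tuple[float, str]] = {}
    peaks, times_pk = {}, {}
    for c in chem_names:
        series = tr[f"ca:{c}"]
        i = int(np.argmax(series))
        peaks[c] = float(series[i])
        times_pk[c] = float(tr.times[i] - t_pulse)
        out[f"peak_ca_{c}"] = (peaks[c], "mM")
        out[f"peak_time_{c}"] = (times_pk[c], "ms")
    distal = chem_names[-1]
    out["soma_lag"] = (times_pk["soma"] - times_pk[distal], "ms")
    out["trunk_soma_peak_ratio"] = (peaks[distal] / peaks["soma"], "")
    result = ProtocolResult("calcium_wave", out, config={"conc_mM": conc})
    if keep_traces:
        result.traces["main"] = tr
    return result


def run_repeated_phasic_protocol(model: AssembledModel, conc: float = 0.1,
                                 interval: float = 15e3,
                                 depolarize_between: bool = False,
                                 keep_traces: bool = False) -> ProtocolResult:
    """Two phasic pulses; optional driven spiking between them.

    Probes the store-operated entry mechanism: without depolarization between
    the pulses the store stays depleted and the second hyperpolarization is
    much weaker; interposed spiking lets SOCE refill the store.
    """
    y0 = rest_state(model)
    t1 = 1000.0
    t2 = t1 + interval
    duration = t2 + 5000.0
    stimuli: list = [AchPulse(conc, start=t1, duration=50.0),
                     AchPulse(conc, start=t2, duration=50.0)]
    if depolarize_between:
        amp = find_drive_current(model)
        stimuli.append(CurrentPulse(amp, t1 + 5000.0, interval - 6000.0))
    tr = integrate(model, duration, stimuli=stimuli, y0=y0, dt_out=2.0,
                   record=["vm:soma", "ca:soma", "ca_er:soma"])

    def hyp(t_on: float) -> float:
        base = tr["vm:soma"][(tr.times >= t_on - 300.0) & (tr.times < t_on)].mean()
        sel = (tr.times >= t_on) & (tr.times <= t_on + 3000.0)
        return float(tr["vm:soma"][sel].min() - base)

    h1, h2 = hyp(t1), hyp(t2)
    out = {
        "hyp_first": (h1, "mV"),
        "hyp_second": (h2, "mV"),
        "second_to_first_ratio": (h2 / h1 if h1 != 0 else np.nan, ""),
    }
    result = ProtocolResult("repeated_phasic", out,
                            config={"conc_mM": conc, "interval_ms": interval,
                                    "depolarize_between": depolarize_between})
    if keep_traces:
        result.traces["main"] = tr
    return result


# -------------------------------------------------------------------- sweeps
def default_dose_grid(lo: float = 1e-6, hi: float = 0.1,
                      per_decade: int = 4) -> np.ndarray:
    """Log-spaced ACh concentrations in mM (default 1 nM .. 100 uM)."""
    n = int(round(np.log10(hi / lo) * per_decade)) + 1
    return np.logspace(np.log10(lo), np.log10(hi), n)


def phasic_dose_response(model: AssembledModel, concs: np.ndarray | None = None,
                         mode: str = "rest") -> dict[str, np.ndarray]:
    concs = default_dose_grid() if concs is None else np.asarray(concs)
    rows: dict[str, list[float]] = {"conc": []}
    drive = find_drive_current(model) if mode == "driven_10hz" else None
    for c in concs:
        res = run_phasic_protocol(model, float(c), mode=mode, drive_amp=drive)
        rows["conc"].append(float(c))
        for k, (v, _) in res.metrics.items():
            rows.setdefault(k, []).append(v)
    return {k: np.asarray(v) for k, v in rows.items()}


def tonic_excitability_sweep(model: AssembledModel,
                             concs: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Rheobase (and optionally more) across tonic ACh concentrations."""
    if concs is None:
        concs = np.array([1e-6, 3.16e-6, 1e-5, 3.16e-5, 1e-4, 3.16e-4,
                          1e-3, 1e-2, 0.1])
    out = {"conc": [], "rheobase": []}
    for c in concs:
        y = tonic_steady_state(model, float(c))
        stim = [AchPulse(float(c), start=0.0)]
        out["conc"].append(float(c))
        out["rheobase"].append(find_rheobase(model, y0=y, stimuli=stim))
    return {k: np.asarray(v) for k, v in out.items()}
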