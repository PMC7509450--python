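"""Scalar metrics computed from traces: spikes, rates, fits.

These are deliberately small, pure functions so every protocol metric has a
single documented definition.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import curve_fit


def detect_spikes(times, vm, threshold: float = 0.0,
                  refractory: float = 2.0) -> np.ndarray:
    """Upward threshold crossings with refractory deduplication (ms)."""
    times = np.asarray(times, dtype=float)
    vm = np.asarray(vm, dtype=float)
    if times.size == 0:
        raise ValueError("empty trace")
    above = vm >= threshold
    idx = np.flatnonzero(~above[:-1] & above[1:]) + 1
    # linear interpolation of the crossing time
    crossings = []
    for i in idx:
        t0, t1 = times[i - 1], times[i]
        v0, v1 = vm[i - 1], vm[i]
        crossings.append(t0 + (threshold - v0) / (v1 - v0) * (t1 - t0))
    out: list[float] = []
    for t in crossings:
        if not out or t - out[-1] >= refractory:
            out.append(t)
    return np.array(out)


def instantaneous_firing_rate(spike_times) -> tuple[np.ndarray, np.ndarray]:
    """IFR = 1/ISI (Hz), assigned at the right endpoint of each interval."""
    st = np.asarray(spike_times, dtype=float)
    if st.size < 2:
        return np.array([]), np.array([])
    isi = np.diff(st)
    return st[1:], 1e3 / isi


def inhibition_duration(spike_times, pulse_onset: float,
                        t_end: float | None = None) -> tuple[float, bool]:
    """Longest inter-spike interval starting at or after the pulse onset.

    Returns (duration_ms, censored).  If no spike follows the onset the
    duration runs from the last spike to ``t_end`` and is flagged censored.
    """
    st = np.asarray(spike_times, dtype=float)
    if st.size == 0:
        raise ValueError("no spikes in trace")
    after = st[st >= pulse_onset]
    before = st[st < pulse_onset]
    if after.size == 0:
        if t_end is None:
            raise ValueError("no spikes after onset and no t_end given")
        last = before[-1] if before.size else pulse_onset
        return float(t_end - last), True
    # intervals ending after the onset, including the one that brackets it
    edges = np.concatenate([before[-1:], after])
    isis = np.diff(edges)
    if isis.size == 0:
        if t_end is None:
            return 0.0, False
        return float(t_end - after[-1]), True
    return float(isis.max()), False


def exp_fit(times, series, t0: float = 0.0) -> tuple[float, float, float]:
    """Fit a + b*exp(-t/tau) after t0; returns (tau_ms, asymptote, r2)."""
    times = np.asarray(times, dtype=float)
    series = np.asarray(series, dtype=float)
    mask = times >= t0
    t = times[mask] - t0
    y = series[mask]
    if t.size < 4:
        raise ValueError("too few points for exponential fit")
    span = y.max() - y.min()
    if span <= 0 or span < 1e-12 * max(abs(y).max(), 1.0):
        raise ValueError("series is constant; exponential fit rejected")

    def f(t, a, b, tau):
        return a + b * np.exp(-t / tau)

    tau0 = (t[-1] - t[0]) / 3.0
    p0 = (y[-1], y[0] - y[-1], tau0)
    popt, _ = curve_fit(f, t, y, p0=p0,
                        bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
                        maxfev=20000)
    resid = y - f(t, *popt)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return float(popt[2]), float(popt[0]), r2


def hill_fit(dose, response) -> tuple[float, float, float, float]:
    """4-parameter Hill fit; returns (ec50, hill, floor, ceiling).

    Doses must span the transition (>= 5 points); non-sigmoidal (flat) data
    raises.
    """
    dose = np.asarray(dose, dtype=float)
    resp = np.asarray(response, dtype=float)
    if dose.size < 5:
        raise ValueError("need at least 5 doses for a Hill fit")
    span = resp.max() - resp.min()
    if span <= 0 or span < 1e-9 * max(abs(resp).max(), 1.0):
        raise ValueError("flat response; Hill fit rejected")

    def f(logc, logec50, n, lo, hi):
        return lo + (hi - lo) / (1.0 + np.exp(-n * (logc - logec50)))

    logd = np.log(np.maximum(dose, 1e-300))
    half = resp.min() + span / 2.0
    i = int(np.argmin(np.abs(resp - half)))
    p0 = (logd[i], 1.0, float(resp.min()), float(resp.max()))
    popt, _ = curve_fit(f, logd, resp, p0=p0, maxfev=40000)
    ec50 = float(np.exp(popt[0]))
    return ec50, float(popt[1]), float(popt[2]), float(popt[3])
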