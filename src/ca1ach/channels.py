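"""Voltage-gated channel kinetics and the two modulated conductances.

Gating uses first-order Hodgkin-Huxley relaxation dx/dt = (x_inf(V) - x)/tau(V)
with Boltzmann steady states and bell/sigmoid time constants.  The kinetics
are smooth re-parameterisations of standard hippocampal formulations; the
densities are free parameters constrained by the excitability calibration
(rheobase, steady 10 Hz drive), not copied from any particular morphology
file.

Two conductances carry the cholinergic modulation hooks:

* Kv7 (M-current): availability multiplied by a saturating Hill function of
  membrane PIP2 relative to rest (:func:`kv7_conductance_scale`), so full
  PIP2 depletion closes the channel and the resting membrane leaves it
  nearly fully available.
* SK: instantaneous Hill activation by cytosolic free calcium
  (:func:`sk_activation`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np


# Kv7 activation midpoint/slope (mV); module-level so the excitability
# calibration can adjust the subthreshold-vs-threshold balance of the
# M-current
KV7_VHALF = -48.0
KV7_SLOPE = 7.0


def _boltz(v, vhalf, k):
    x = np.clip(-(v - vhalf) / k, -60.0, 60.0)
    return 1.0 / (1.0 + np.exp(x))


@dataclass
class GateKinetics:
    name: str
    inf: Callable
    tau: Callable


@dataclass
class ChannelScheme:
    """One channel type: gates, reversal selector and modulation hook."""

    name: str
    gates: list[GateKinetics]
    reversal: str                 # 'na' | 'k' | 'ca' | 'leak'
    gate_powers: list[int]
    modulation: str = "none"      # 'none' | 'pip2' | 'calcium'


def make_channel_schemes() -> dict[str, ChannelScheme]:
    g = {}
    g["na"] = ChannelScheme(
        "na",
        gates=[
            GateKinetics("m", lambda v: _boltz(v, -43.0, 5.5),
                         lambda v: 0.05 + 0.15 / (1.0 + np.exp((v + 30.0) / 10.0))),
            GateKinetics("h", lambda v: _boltz(v, -50.0, -6.0),
                         lambda v: 0.5 + 8.0 / (1.0 + np.exp((v + 50.0) / 8.0))),
        ],
        reversal="na", gate_powers=[3, 1])
    g["kdr"] = ChannelScheme(
        "kdr",
        gates=[GateKinetics("n", lambda v: _boltz(v, -15.0, 8.0),
                            lambda v: 1.0 + 4.0 / (1.0 + np.exp((v + 25.0) / 10.0)))],
        reversal="k", gate_powers=[1])
    g["ka"] = ChannelScheme(
        "ka",
        gates=[
            GateKinetics("a", lambda v: _boltz(v, -50.0, 8.0), lambda v: 1.0 + 0.0 * v),
            GateKinetics("b", lambda v: 0.1 + 0.9 * _boltz(v, -68.0, -7.0),
                         lambda v: 150.0 + 0.0 * v),
        ],
        reversal="k", gate_powers=[1, 1])
    g["kv7"] = ChannelScheme(
        "kv7",
        gates=[GateKinetics("z", lambda v: _boltz(v, KV7_VHALF, KV7_SLOPE),
                            lambda v: 10.0 + 160.0 / (np.exp((v - KV7_VHALF) / 28.0)
                                                      + np.exp(-(v - KV7_VHALF) / 28.0)))],
        reversal="k", gate_powers=[1], modulation="pip2")
    g["sk"] = ChannelScheme("sk", gates=[], reversal="k", gate_powers=[],
                            modulation="calcium")
    g["ca_hva"] = ChannelScheme(
        "ca_hva",
        gates=[GateKinetics("m", lambda v: _boltz(v, -15.0, 6.0), lambda v: 1.5 + 0.0 * v)],
        reversal="ca", gate_powers=[2])
    g["ca_t"] = ChannelScheme(
        "ca_t",
        gates=[
            GateKinetics("m", lambda v: _boltz(v, -42.0, 5.0), lambda v: 1.5 + 0.0 * v),
            GateKinetics("h", lambda v: _boltz(v, -72.0, -5.0), lambda v: 25.0 + 0.0 * v),
        ],
        reversal="ca", gate_powers=[2, 1])
    # HCN: hyperpolarisation-activated mixed cation current; deactivation on
    # depolarisation carries part of the input-resistance rise seen when the
    # M-current is suppressed, while contributing nothing near spike threshold
    g["h"] = ChannelScheme(
        "h",
        gates=[GateKinetics("q", lambda v: _boltz(v, -80.0, -8.0),
                            lambda v: 40.0 + 50.0 / (1.0 + np.exp(-(v + 80.0) / 10.0)))],
        reversal="h", gate_powers=[1])
    g["leak"] = ChannelScheme("leak", gates=[], reversal="leak", gate_powers=[])
    return g


def kv7_conductance_scale(pip2_level, half: float = 0.2, hill: float = 1.8):
    """Kv7 availability in [0, 1] as a function of PIP2 relative to rest.

    Monotone, saturating; 0 at full depletion, >= 0.9 at the resting density.
    """
    p = np.asarray(pip2_level, dtype=float)
    if np.any(p < 0):
        raise ValueError("pip2_level must be >= 0")
    ph = np.power(p, hill)
    return ph / (ph + half ** hill)


def sk_activation(ca_cyt, half: float = 0.00035, hill: float = 4.0):
    """SK channel open fraction: Hill function of cytosolic calcium (mM)."""
    ca = np.asarray(ca_cyt, dtype=float)
    if np.any(ca < 0):
        raise ValueError("ca_cyt must be >= 0")
    ch = np.power(ca, hill)
    return ch / (ch + half ** hill)


def sk_current(ca_cyt, vm, gbar: float, e_k: float = -90.0,
               half: float = 0.00035, hill: float = 4.0):
    """SK current density (same units as gbar*(mV)); outward positive."""
    return gbar * sk_activation(ca_cyt, half, hill) * (vm - e_k)
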