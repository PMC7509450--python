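"""High-level modelling interface.

:class:`CholinergicCA1Model` wraps the assembled simulator behind a
statsmodels-like API: build the model from a parameter set (or a YAML
config), call :meth:`fit` to run the staged calibration, and receive a
:class:`CalibrationResult` carrying the fitted parameters, the achieved
versus target values per stage and a ``summary()`` table.  The virtual
experiments hang off the model object as :meth:`run_protocol`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from . import calibration, protocols
from .core import AchPulse, AssembledModel, CurrentPulse, Trace, integrate, steady_state
from .params import ModelParams


@dataclass
class CalibrationResult:
    """Outcome of the staged calibration (returned by ``fit``)."""

    params: ModelParams
    stages: list[calibration.StageResult]
    model: "CholinergicCA1Model" = None

    @property
    def converged(self) -> bool:
        return all(s.met for s in self.stages)

    def to_dict(self) -> dict[str, Any]:
        return {"converged": self.converged,
                "stages": [s.to_dict() for s in self.stages],
                "params": self.params.to_dict()}

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)

    def summary(self) -> str:
        lines = ["Staged calibration summary",
                 "=" * 66,
                 f"{'stage':<18}{'quantity':<22}{'achieved':>12}{'met':>6}",
                 "-" * 66]
        for s in self.stages:
            for k, v in s.achieved.items():
                lines.append(f"{s.name:<18}{k:<22}{v:>12.4g}"
                             f"{'yes' if s.met else 'NO':>6}")
        lines.append("-" * 66)
        lines.append(f"all stages met: {'yes' if self.converged else 'NO'}")
        return "\n".join(lines)


class CholinergicCA1Model:
    """CA1 pyramidal neuron with M1 muscarinic modulation.

    Parameters
    ----------
    params : ModelParams, optional
        Full parameter bundle; defaults to the shipped calibrated set.

    Examples
    --------
    >>> model = CholinergicCA1Model()
    >>> res = model.run_protocol("phasic", conc=0.1)     # 100 uM, 50 ms
    >>> res.value("peak_hyperpolarization")              # doctest: +SKIP
    """

    def __init__(self, params: ModelParams | None = None):
        self.params = params or ModelParams()
        self._assembled: AssembledModel | None = None

    # -- construction ------------------------------------------------------
    @classmethod
    def from_config(cls, path: str) -> "CholinergicCA1Model":
        from .config import load_config
        return cls(load_config(path).model)

    def build(self, rebuild: bool = False) -> AssembledModel:
        """Compile (and cache) the ODE system for the current parameters."""
        if self._assembled is None or rebuild:
            self._assembled = AssembledModel(self.params)
        return self._assembled

    # -- simulation --------------------------------------------------------
    def steady_state(self, settle: float | None = None):
        return steady_state(self.build(), settle=settle)

    def simulate(self, duration: float, stimuli: Sequence = (),
                 from_rest: bool = True, **kw) -> Trace:
        model = self.build()
        y0 = protocols.rest_state(model) if from_rest else None
        return integrate(model, duration, stimuli=stimuli, y0=y0, **kw)

    # -- fitting -----------------------------------------------------------
    def fit(self, stages: tuple[str, ...] = calibration.STAGE_ORDER,
            **stage_kwargs) -> CalibrationResult:
        """Run the staged calibration and adopt the fitted parameters."""
        fitted, report = calibration.staged_calibrate(
            self.params, stages=stages, stage_kwargs=stage_kwargs or None)
        self.params = fitted
        self._assembled = None
        return CalibrationResult(params=fitted, stages=report, model=self)

    # -- protocols ---------------------------------------------------------
    def run_protocol(self, name: str, **kw) -> protocols.ProtocolResult:
        model = self.build()
        if name == "phasic":
            conc = kw.pop("conc")
            return protocols.run_phasic_protocol(model, conc, **kw)
        if name == "tonic":
            conc = kw.pop("conc")
            return protocols.run_tonic_protocol(model, conc, **kw)
        if name == "er_refill":
            return protocols.run_er_refill_protocol(model, **kw)
        if name == "ap_transient":
            return protocols.run_ap_transient_protocol(params=self.params, **kw)
        if name == "wave":
            return protocols.run_calcium_wave_protocol(model, **kw)
        if name == "repeated_phasic":
            return protocols.run_repeated_phasic_protocol(model, **kw)
        if name == "rheobase":
            value = protocols.find_rheobase(model, **kw)
            return protocols.ProtocolResult("rheobase",
                                            {"rheobase": (value, "pA")})
        if name == "input_resistance":
            value = protocols.input_resistance(model, **kw)
            return protocols.ProtocolResult("input_resistance",
                                            {"input_resistance": (value, "MOhm")})
        raise ValueError(f"unknown protocol {name!r}")
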