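"""Acquisition protocols: which variable is stepped, and over what schedule.

The four default protocols reproduce the microimaging study conditions:

* ``cpmg``      — 64 echoes at TE = 5.3 ms spacing (T2 mapping)
* ``satrec``    — 12 repetition times from 0.1 s to 15 s (T1 mapping)
* ``mt``        — 8 off-resonance presaturation durations, 0.1 s to 4.6 s
                  at +6000 Hz offset (km and MTR mapping)
* ``diffusion`` — 9 gradient amplitudes from 0 to 900 mT/m with
                  delta = 5 ms, Delta = 10.25 ms (ADC mapping)

Schedules not fully pinned down by the acquisition description (TR and
saturation-time spacing) default to logarithmic spacing, the usual choice
for exponential-recovery sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import GAMMA_PROTON, stejskal_tanner_b

__all__ = ["AcquisitionProtocol", "default_protocol", "PROTOCOL_KINDS"]

PROTOCOL_KINDS = ("cpmg", "satrec", "mt", "diffusion")

#: units of the stepped acquisition variable, per protocol kind
SCHEDULE_UNITS = {
    "cpmg": "ms",       # echo time
    "satrec": "s",      # repetition time
    "mt": "s",          # presaturation duration
    "diffusion": "s/mm^2",  # b-value
}


@dataclass(frozen=True)
class AcquisitionProtocol:
    """One stepped-variable spin-echo acquisition.

    ``schedule`` holds the stepped variable: TE (ms) for cpmg, TR (s) for
    satrec, saturation time (s) for mt, and gradient amplitude (mT/m) for
    diffusion (the fit variable, b, is derived — see :meth:`fit_schedule`).
    ``extra`` carries acquisition metadata that the computation does not
    use (e.g. the presaturation offset and nominal B1).
    """

    kind: str
    schedule: tuple
    # diffusion timing (ms); unused for other kinds
    delta_ms: float = 5.0
    Delta_ms: float = 10.25
    gamma: float = GAMMA_PROTON
    b0: float = 0.0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in PROTOCOL_KINDS:
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        sched = np.asarray(self.schedule, dtype=float)
        if sched.size == 0:
            raise ValueError("schedule must be non-empty")
        if np.any(np.diff(sched) <= 0):
            raise ValueError("schedule must be strictly increasing")
        if self.kind == "diffusion":
            if not self.delta_ms < self.Delta_ms:
                raise ValueError("require delta < Delta")
            if self.b0 < 0:
                raise ValueError("b0 must be non-negative")
        object.__setattr__(self, "schedule", tuple(float(v) for v in sched))

    @property
    def fit_schedule(self) -> np.ndarray:
        """The acquisition-variable values the signal model is fit against.

        Identical to ``schedule`` except for diffusion, where gradient
        amplitudes are converted to b-values (s/mm^2).
        """
        sched = np.asarray(self.schedule, dtype=float)
        if self.kind == "diffusion":
            return stejskal_tanner_b(
                sched, self.delta_ms, self.Delta_ms, gamma=self.gamma, b0=self.b0
            )
        return sched

    @property
    def fit_units(self) -> str:
        return SCHEDULE_UNITS[self.kind]

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "schedule": list(self.schedule),
            "gamma": self.gamma,
            "extra": dict(self.extra),
        }
        if self.kind == "diffusion":
            d.update(delta_ms=self.delta_ms, Delta_ms=self.Delta_ms, b0=self.b0)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        return cls(
            kind=d["kind"],
            schedule=tuple(d["schedule"]),
            delta_ms=d.get("delta_ms", 5.0),
            Delta_ms=d.get("Delta_ms", 10.25),
            gamma=d.get("gamma", GAMMA_PROTON),
            b0=d.get("b0", 0.0),
            extra=d.get("extra", {}),
        )


def default_protocol(kind: str) -> AcquisitionProtocol:
    """The study-condition protocol for a contrast kind."""
    if kind == "cpmg":
        te = 5.3 * np.arange(1, 65)  # 64 echoes, 5.3 ms spacing
        return AcquisitionProtocol("cpmg", tuple(te))
    if kind == "satrec":
        tr = np.geomspace(0.1, 15.0, 12)
        return AcquisitionProtocol("satrec", tuple(tr))
    if kind == "mt":
        t_sat = np.geomspace(0.1, 4.6, 8)
        return AcquisitionProtocol(
            "mt",
            tuple(t_sat),
            extra={"offset_hz": 6000.0, "b1_nominal": "12 mT (as reported)",
                   "tr_s": 5.0, "te_ms": 7.2},
        )
    if kind == "diffusion":
        g = np.linspace(0.0, 900.0, 9)
        return AcquisitionProtocol(
            "diffusion", tuple(g), delta_ms=5.0, Delta_ms=10.25, b0=0.0,
            extra={"te_ms": 19.4, "tr_s": 1.0},
        )
    raise ValueError(f"unknown protocol kind {kind!r}")
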