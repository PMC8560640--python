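"""Containers for arterial input function (AIF) curves.

An AIF is a gadolinium concentration vs time curve measured in a cardiac
blood pool during first pass of a contrast bolus, sampled once per heartbeat
(one frame per R-R interval).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MIN_SAMPLES = 10


@dataclass
class AIFCurve:
    """Concentration-time curve for one cavity.

    Parameters
    ----------
    times : array of float
        Sample times in seconds, strictly increasing, roughly one per heartbeat.
    conc : array of float
        Gadolinium concentration in mmol/l, non-negative.
    cavity_label : {"RV", "LV"}
        Which blood pool the curve was sampled from.
    """

    times: np.ndarray
    conc: np.ndarray
    cavity_label: str = "RV"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.times.shape != self.conc.shape:
            raise ValueError("times and conc must have equal length")
        if self.times.size < MIN_SAMPLES:
            raise ValueError(f"AIF curve needs at least {MIN_SAMPLES} samples, got {self.times.size}")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.conc < 0):
            raise ValueError("concentrations must be non-negative (clip at 0 upstream)")
        if self.cavity_label not in ("RV", "LV"):
            raise ValueError("cavity_label must be 'RV' or 'LV'")

    @property
    def peak(self) -> float:
        return float(self.conc.max())

    @property
    def peak_time(self) -> float:
        return float(self.times[int(np.argmax(self.conc))])


@dataclass
class AIFCurvePair:
    """RV and LV AIF curves on a shared time base."""

    rv: AIFCurve
    lv: AIFCurve
    rr_interval: float
    qc_flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rr_interval <= 0:
            raise ValueError("rr_interval must be positive")
        if not np.allclose(self.rv.times, self.lv.times):
            raise ValueError("RV and LV curves must share a time base")
        if self.rv.cavity_label != "RV" or self.lv.cavity_label != "LV":
            raise ValueError("pair must hold an RV curve and an LV curve, in that order")

    @property
    def times(self) -> np.ndarray:
        return self.rv.times
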