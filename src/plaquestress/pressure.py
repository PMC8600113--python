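"""Position-specific cyclic pressure loading.

The load applied to each cross-section is derived from three inputs measured
in the catheterization lab: the resting aortic pressure tracing Pa(t), the
resting distal coronary pressure tracing Pd(t) (pressure-wire sensor parked
distal to the lesion), and the OFR pullback curve — an OCT-computed FFR
surrogate giving the fractional pressure ratio at every pullback position.

The pullback curve is normalized between the two tracings: a position whose
OFR equals the proximal-end value feels the full aortic waveform, a position
at the sensor feels the distal waveform, and intermediate positions are
interpolated linearly in OFR.  The solver is then driven by the *relative*
pressure — the cyclic waveform minus its own diastolic minimum — so the
imaged (diastolic) geometry is the stress-free reference configuration and no
zero-pressure-state estimation is needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "MMHG_TO_KPA",
    "PressureTracing",
    "OFRPullback",
    "PressureLoad",
    "extract_representative_beat",
    "position_pressure",
    "relative_pressure",
    "load_fractions",
]

MMHG_TO_KPA = 0.133322


@dataclass(frozen=True)
class PressureTracing:
    """Paired aortic / distal coronary pressure tracings, uniformly sampled."""

    time: np.ndarray  # s
    pa: np.ndarray    # mmHg, aortic
    pd: np.ndarray    # mmHg, distal coronary

    def __post_init__(self):
        t = np.asarray(self.time, float)
        pa = np.asarray(self.pa, float)
        pd_ = np.asarray(self.pd, float)
        if not (len(t) == len(pa) == len(pd_)):
            raise ValueError("time, pa and pd must have equal length")
        if len(t) < 4:
            raise ValueError("tracing too short")
        dt = np.diff(t)
        if dt.min() <= 0 or (dt.max() - dt.min()) > 0.01 * dt.mean():
            raise ValueError("time must be uniformly increasing (within 1%)")
        for name, p in (("pa", pa), ("pd", pd_)):
            if p.min() <= 10 or p.max() >= 300:
                raise ValueError(f"{name} outside the physiologic range (10, 300) mmHg")
        if np.any(pd_ > pa + 5.0):
            raise ValueError("distal pressure exceeds aortic pressure beyond tolerance")
        for arr, name in ((t, "time"), (pa, "pa"), (pd_, "pd")):
            arr.flags.writeable = False
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "pa", pa)
        object.__setattr__(self, "pd", pd_)

    @property
    def fs(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.time)))

    @classmethod
    def from_csv(cls, path) -> "PressureTracing":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(), df["pa_mmhg"].to_numpy(),
                   df["pd_mmhg"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time, "pa_mmhg": self.pa,
                      "pd_mmhg": self.pd}).to_csv(path, index=False)


@dataclass(frozen=True)
class OFRPullback:
    """OFR value along the pullback; position in mm increases distal→proximal."""

    position: np.ndarray
    value: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.position, float)
        v = np.asarray(self.value, float)
        if len(x) != len(v) or len(x) < 2:
            raise ValueError("position and value must be equal-length, n>=2")
        if np.any(np.diff(x) <= 0):
            raise ValueError("pullback positions must be strictly increasing")
        if v.min() <= 0 or v.max() > 1.0:
            raise ValueError("OFR values must lie in (0, 1]")
        x.flags.writeable = False
        v.flags.writeable = False
        object.__setattr__(self, "position", x)
        object.__setattr__(self, "value", v)

    def at(self, x: float) -> float:
        if not (self.position[0] <= x <= self.position[-1]):
            raise ValueError(f"position {x} mm outside the pullback range")
        return float(np.interp(x, self.position, self.value))

    @classmethod
    def from_csv(cls, path) -> "OFRPullback":
        df = pd.read_csv(path)
        return cls(df["position_mm"].to_numpy(), df["ofr"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"position_mm": self.position,
                      "ofr": self.value}).to_csv(path, index=False)


@dataclass(frozen=True)
class PressureLoad:
    """Relative (cyclic-minus-diastolic) pressure at one cross-section, kPa."""

    time: np.ndarray
    delta_p: np.ndarray  # kPa, >= 0, min exactly 0
    peak_index: int

    def __post_init__(self):
        t = np.asarray(self.time, float)
        dp = np.asarray(self.delta_p, float)
        if len(t) != len(dp):
            raise ValueError("time and delta_p must have equal length")
        if not np.all(np.isfinite(dp)) or dp.min() < 0 or dp.min() > 1e-12:
            raise ValueError("relative pressure must be finite, >=0, with min 0")
        t.flags.writeable = False
        dp.flags.writeable = False
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "delta_p", dp)

    @property
    def peak(self) -> float:
        return float(self.delta_p[self.peak_index])

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time,
                      "delta_p_kpa": self.delta_p}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def extract_representative_beat(tracing: PressureTracing) -> PressureTracing:
    """Cut one representative beat, foot to foot, from a multi-beat tracing.

    Feet are the diastolic minima of the aortic channel.  Among the complete
    beats found, the one with the largest pulse pressure is returned — a
    deterministic choice that avoids ensemble averaging.  A tracing already
    spanning a single beat is returned unchanged.
    """
    pa = tracing.pa
    rng = pa.max() - pa.min()
    if rng <= 0:
        raise ValueError("aortic tracing is constant; no beat to extract")
    # feet = prominent minima of pa
    feet, _ = find_peaks(-pa, prominence=0.4 * rng)
    if len(feet) < 2:
        return tracing  # at most one full beat present
    best, best_pp = None, -np.inf
    for a, b in zip(feet[:-1], feet[1:]):
        pp = pa[a:b + 1].max() - pa[a:b + 1].min()
        if pp > best_pp:
            best, best_pp = (a, b), pp
    a, b = best
    return PressureTracing(tracing.time[a:b + 1] - tracing.time[a],
                           tracing.pa[a:b + 1], tracing.pd[a:b + 1])


def position_pressure(tracing: PressureTracing, pullback: OFRPullback,
                      x: float) -> np.ndarray:
    """Estimate the pressure waveform (mmHg) at pullback position ``x``.

    The OFR pullback is normalized between the aortic and distal tracings:

        P(x,t) = Pd(t) + (Pa(t) - Pd(t)) * (OFR(x) - OFR_w) / (OFR_p - OFR_w)

    with OFR_p the proximal-end value and OFR_w the value at the distal
    pressure-sensor position (the distal end of the pullback).
    """
    ofr_p = float(pullback.value[-1])   # proximal end (largest position)
    ofr_w = float(pullback.value[0])    # distal sensor position
    if abs(ofr_p - ofr_w) < 1e-12:
        warnings.warn("flat OFR pullback: no gradient to distribute; using Pa(t)",
                      stacklevel=2)
        return tracing.pa.copy()
    frac = (pullback.at(x) - ofr_w) / (ofr_p - ofr_w)
    if frac == 1.0:   # proximal end: exactly the aortic tracing
        return tracing.pa.copy()
    if frac == 0.0:   # sensor position: exactly the distal tracing
        return tracing.pd.copy()
    return tracing.pd + (tracing.pa - tracing.pd) * frac


def relative_pressure(p_mmhg: np.ndarray,
                      time: np.ndarray | None = None) -> PressureLoad:
    """Convert a one-beat pressure waveform into the relative-pressure load.

    The estimated diastolic pressure (the beat minimum of the waveform at this
    position) is subtracted and the result converted to kPa, so the load is
    zero at the imaged diastolic configuration and peaks at systole.
    """
    p = np.asarray(p_mmhg, float)
    if time is None:
        time = np.arange(len(p), dtype=float)
    dp = (p - p.min()) * MMHG_TO_KPA
    if dp.max() == 0:
        warnings.warn("constant pressure: relative load is identically zero",
                      stacklevel=2)
    return PressureLoad(np.asarray(time, float), dp, int(np.argmax(dp)))


def load_fractions(n_steps: int = 10) -> np.ndarray:
    """Monotone load-fraction ladder 0..1 used by the quasi-static solver.

    The elastic, quasi-static model makes intermediate unloading redundant:
    only the ramp from diastole (0) to the peak load (1) needs solving, and
    the diastolic and peak states bracket the lumen-diameter extremes.
    """
    if n_steps < 1:
        raise ValueError("need at least one load step")
    return np.linspace(0.0, 1.0, n_steps + 1)
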