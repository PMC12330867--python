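"""Resampling of gated flow series onto the canonical 32-step cycle grid.

Prospectively gated acquisitions cover only part of the cardiac cycle, and
frame spacing varies with heart rate.  For cross-subject and arterio-venous
comparability every vessel's flow series is mapped onto a fixed grid of 32
steps, step k sitting at k x 3.125 %CC (so step 3 = 9.375 %CC, step 8 =
25 %CC, step 32 = 100 %CC, i.e. the next R-wave).  Steps inside the sampled
range are linear interpolations; steps beyond the last sample are linear
extrapolations from the final two samples (floored at zero for sinuses and at
the minimum observed flow for arteries, preventing unphysical negative or
sub-baseline diastolic values).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .flow import VesselTimeSeries
from .synthetic import VENOUS_VESSELS

__all__ = ["N_STEPS", "STEP_PCT", "FlowProfile32", "normalize_profile", "sum_profiles"]

N_STEPS = 32
#: step k (1-based) sits at k * 3.125 %CC
STEP_PCT = np.arange(1, N_STEPS + 1) * (100.0 / N_STEPS)


@dataclass
class FlowProfile32:
    """Flow waveform of one vessel on the canonical 32-step grid."""

    vessel: str
    flow_ul_s: np.ndarray  # 32 values
    rr_ms: float
    extrapolated: np.ndarray  # 32 bools, True where the step was extrapolated

    def __post_init__(self) -> None:
        self.flow_ul_s = np.asarray(self.flow_ul_s, dtype=float)
        self.extrapolated = np.asarray(self.extrapolated, dtype=bool)
        if self.flow_ul_s.shape != (N_STEPS,) or self.extrapolated.shape != (N_STEPS,):
            raise ValueError(f"profile must have exactly {N_STEPS} steps")

    @property
    def pct_cc(self) -> np.ndarray:
        return STEP_PCT.copy()

    @property
    def step_duration_s(self) -> float:
        return self.rr_ms / N_STEPS / 1000.0

    @property
    def extrapolated_fraction(self) -> float:
        return float(self.extrapolated.mean())

    def to_frame(self, subject_id: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame({
            "vessel": self.vessel,
            "step": np.arange(1, N_STEPS + 1),
            "pct_cc": STEP_PCT,
            "flow_ul_s": self.flow_ul_s,
            "extrapolated": self.extrapolated,
        })
        if subject_id is not None:
            df.insert(0, "subject_id", subject_id)
        return df


def normalize_profile(series: VesselTimeSeries, mode: str = "secant",
                      sinus_floor: float = 0.0) -> FlowProfile32:
    """Map a partially covering flow series onto the 32-step grid.

    ``mode='secant'`` (default) extrapolates beyond the sampled range along
    the secant of the two nearest samples; ``mode='periodic'`` instead wraps
    the samples with period 100 %CC and interpolates.  Sinus profiles are
    floored at ``sinus_floor`` (default 0 ul/s) in the forward-extrapolated
    region; arterial profiles at their minimum observed flow.
    """
    if mode not in ("secant", "periodic"):
        raise ValueError("mode must be 'secant' or 'periodic'")
    p = np.asarray(series.pct_cc, dtype=float)
    f = np.asarray(series.flow_ul_s, dtype=float)
    if p.size < 3:
        raise ValueError("cannot normalize a series with fewer than 3 samples")

    extrapolated = (STEP_PCT < p[0]) | (STEP_PCT > p[-1])
    if mode == "periodic":
        # wrap the samples: the first sample recurs one cycle later
        pw = np.concatenate([p - 100.0, p, p + 100.0])
        fw = np.concatenate([f, f, f])
        flow = np.interp(STEP_PCT, pw, fw)
    else:
        flow = np.interp(STEP_PCT, p, f)
        fwd = STEP_PCT > p[-1]
        if fwd.any():
            slope = (f[-1] - f[-2]) / (p[-1] - p[-2])
            flow[fwd] = f[-1] + slope * (STEP_PCT[fwd] - p[-1])
        back = STEP_PCT < p[0]
        if back.any():
            slope = (f[1] - f[0]) / (p[1] - p[0])
            flow[back] = f[0] + slope * (STEP_PCT[back] - p[0])
        # the diastolic floor applies to the forward (end-of-cycle) region;
        # backward extrapolation (rare: gating starts at the R-wave) is exact
        floor = sinus_floor if series.vessel in VENOUS_VESSELS else float(f.min())
        flow[fwd] = np.maximum(flow[fwd], floor)
    return FlowProfile32(vessel=series.vessel, flow_ul_s=flow, rr_ms=series.rr_ms,
                         extrapolated=extrapolated)


def sum_profiles(profiles: list[FlowProfile32], label: str | None = None) -> FlowProfile32:
    """Step-wise sum of same-subject profiles (e.g. Art = BT+RC+LC)."""
    if not profiles:
        raise ValueError("need at least one profile")
    rr = profiles[0].rr_ms
    if any(abs(pr.rr_ms - rr) > 1e-9 for pr in profiles):
        raise ValueError("profiles must share the same R-R interval")
    flow = np.sum([pr.flow_ul_s for pr in profiles], axis=0)
    extrap = np.any([pr.extrapolated for pr in profiles], axis=0)
    if label is None:
        label = "+".join(pr.vessel for pr in profiles)
    return FlowProfile32(vessel=label, flow_ul_s=flow, rr_ms=rr, extrapolated=extrap)
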