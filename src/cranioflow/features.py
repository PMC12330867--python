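"""Waveform features: peak M, dicrotic notch D, systolic upslope, PI/RI, lags.

All features are computed on 32-step normalized profiles.  The flow maximum
(point M) is reported with its arrival time in %CC; the dicrotic notch
(point D), the slope break separating the steep systolic descent from the
slow diastolic decay, is located as the largest positive discrete second
difference after the peak; the systolic upslope is the flow rise between the
start of the large arterial inflow (step 3 = 9.375 %CC) and the peak, per
unit time; pulsatility and resistive indices are PI = (max - min)/mean and
RI = (max - min)/max.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normalization import N_STEPS, STEP_PCT, FlowProfile32
from .synthetic import VENOUS_VESSELS

__all__ = [
    "ProfileFeatures",
    "find_peak",
    "find_dicrotic_notch",
    "upslope",
    "pulsatility_indices",
    "extract_features",
    "peak_lags",
    "LAG_PAIRS",
]

#: ordered vessel pairs for which peak lags are reported
LAG_PAIRS = (("BT", "RC"), ("BT", "LC"), ("BT", "SS"), ("LC", "SS"),
             ("StS", "SS"), ("Art", "Ven"))

_UPSLOPE_REF_STEP = 3  # step where the large arterial inflow starts
_NOTCH_WINDOW_END_PCT = 75.0


@dataclass
class ProfileFeatures:
    vessel: str
    peak_flow_ul_s: float
    peak_pct_cc: float
    peak_step: int
    notch_pct_cc: float | None
    upslope_ul_s2: float
    upslope_defined: bool
    pi: float
    ri: float

    def to_dict(self) -> dict:
        return {
            "vessel": self.vessel,
            "peak_flow_ul_s": self.peak_flow_ul_s,
            "peak_pct_cc": self.peak_pct_cc,
            "peak_step": self.peak_step,
            "notch_pct_cc": self.notch_pct_cc,
            "upslope_ul_s2": self.upslope_ul_s2,
            "upslope_defined": self.upslope_defined,
            "pi": self.pi,
            "ri": self.ri,
        }


def find_peak(profile: FlowProfile32) -> tuple[float, float]:
    """(peak flow, peak %CC); ties broken towards the earliest step."""
    idx = int(np.argmax(profile.flow_ul_s))  # argmax returns the first maximum
    return float(profile.flow_ul_s[idx]), float(STEP_PCT[idx])


def find_dicrotic_notch(profile: FlowProfile32) -> float | None:
    """Notch position in %CC, or None when no slope break exists.

    Defined for arterial profiles whose peak arrives before 50 %CC.  The
    notch is the step in (peak, 75 %CC] maximizing the discrete second
    difference of the flow; a notch requires that maximum to be positive
    (convex break in an otherwise concave descent).
    """
    if profile.vessel in VENOUS_VESSELS:
        raise ValueError("the dicrotic notch is not defined for venous profiles")
    _, peak_pct = find_peak(profile)
    if peak_pct >= 50.0:
        raise ValueError("notch detection requires an arterial peak before 50 %CC")
    f = profile.flow_ul_s
    # second difference at step index k (0-based) needs both neighbours
    d2 = f[2:] - 2.0 * f[1:-1] + f[:-2]  # d2[j] is curvature at step j+2 (1-based)
    steps = np.arange(2, N_STEPS)  # 1-based steps 2..31
    pct = steps * (100.0 / N_STEPS)
    window = (pct > peak_pct) & (pct <= _NOTCH_WINDOW_END_PCT)
    if not window.any() or np.max(d2[window]) <= 0:
        return None
    cand = np.where(window)[0]
    best = cand[np.argmax(d2[cand])]
    return float(pct[best])


def upslope(profile: FlowProfile32) -> tuple[float, bool]:
    """Systolic upslope in ul/s^2 and whether it is well defined.

    Slope = (peak flow - flow at step 3) / elapsed time.  A peak at or
    before step 3 leaves the slope undefined (0 is reported for a perfectly
    flat profile, NaN otherwise), with the ``defined`` flag cleared.
    """
    peak_flow, _ = find_peak(profile)
    peak_step = int(np.argmax(profile.flow_ul_s)) + 1
    if peak_step <= _UPSLOPE_REF_STEP:
        if np.ptp(profile.flow_ul_s) == 0:
            return 0.0, False
        return float("nan"), False
    f3 = profile.flow_ul_s[_UPSLOPE_REF_STEP - 1]
    dt_s = (peak_step - _UPSLOPE_REF_STEP) * profile.rr_ms / N_STEPS / 1000.0
    return float((peak_flow - f3) / dt_s), True


def pulsatility_indices(profile: FlowProfile32) -> tuple[float, float]:
    """(PI, RI) over the 32 steps; NaN where the denominator vanishes."""
    f = profile.flow_ul_s
    fmax, fmin, fmean = float(f.max()), float(f.min()), float(f.mean())
    pi = (fmax - fmin) / fmean if fmean > 0 else float("nan")
    ri = (fmax - fmin) / fmax if fmax > 0 else float("nan")
    return pi, ri


def extract_features(profile: FlowProfile32) -> ProfileFeatures:
    peak_flow, peak_pct = find_peak(profile)
    peak_step = int(np.argmax(profile.flow_ul_s)) + 1
    notch = None
    if profile.vessel not in VENOUS_VESSELS and peak_pct < 50.0:
        notch = find_dicrotic_notch(profile)
    slope, defined = upslope(profile)
    pi, ri = pulsatility_indices(profile)
    return ProfileFeatures(vessel=profile.vessel, peak_flow_ul_s=peak_flow,
                           peak_pct_cc=peak_pct, peak_step=peak_step,
                           notch_pct_cc=notch, upslope_ul_s2=slope,
                           upslope_defined=defined, pi=pi, ri=ri)


def peak_lags(features: dict[str, ProfileFeatures]) -> pd.DataFrame:
    """Pairwise peak-arrival lags (%CC) for the ordered vessel pairs.

    lag(v1 -> v2) = peak_pct_cc(v2) - peak_pct_cc(v1); pairs with a missing
    vessel are omitted (recorded by their absence).
    """
    rows = []
    for v1, v2 in LAG_PAIRS:
        if v1 in features and v2 in features:
            rows.append({"from": v1, "to": v2,
                         "lag_pct_cc": features[v2].peak_pct_cc - features[v1].peak_pct_cc})
    return pd.DataFrame(rows, columns=["from", "to", "lag_pct_cc"])
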