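"""Per-cycle volumes, perfusion/CBF, and arterio-venous volume coupling.

Per-cycle blood volume is the sum of elementary volumes delivered during each
of the 32 cycle steps (flow x step duration).  Perfusion normalises the
arterial input per minute; cerebral blood flow (CBF) further normalises by
brain tissue mass (grey + white matter volume x 1.05 g/ml tissue density).

Because peripheral venous pathways are not imaged, the measured venous
outflow underestimates the true drainage; a correction factor
CF = V_arterial / V_venous rescales the venous waveform so that arterial and
venous per-cycle volumes balance, as intracranial volume homeostasis
(Monro-Kellie) requires.  The step-wise balance Art - CF*Ven then alternates
between blood surplus and deficit over the cycle; the peak-to-peak range of
its running sum is the oscillating volume, i.e. the volume the craniospinal
system must buffer (e.g. by displacing CSF) within one heart beat.  The
closed trajectory of (arterial flow, venous flow) over the 32 steps forms a
hysteresis loop whose area indexes the arterio-venous phase lag and the
viscoelastic buffering of the system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString

from .normalization import N_STEPS, FlowProfile32
from .synthetic import ARTERIAL_VESSELS, VENOUS_VESSELS, SubjectSpec

__all__ = [
    "BRAIN_TISSUE_DENSITY_G_ML",
    "SubjectHaemodynamics",
    "cycle_volume",
    "perfusion_and_cbf",
    "seymour_prediction",
    "av_balance",
    "hysteresis_loop",
    "input_fractions",
]

BRAIN_TISSUE_DENSITY_G_ML = 1.05


@dataclass
class SubjectHaemodynamics:
    """Volume and coupling metrics of one subject."""

    subject_id: str
    volume_ul_cc: dict[str, float]  # per vessel
    total_arterial_ul_cc: float
    total_carotid_ul_cc: float
    total_venous_ul_cc: float
    fractions_pct: dict[str, float]
    perfusion_ml_min: float
    drainage_ml_min: float
    cbf_ml_min_100g: float
    cf: float
    balance_ul: np.ndarray  # 32 step-wise values
    cumulative_balance_ul: np.ndarray  # 32 running-sum values
    oscillating_volume_ul: float
    osc_pct_csf: float
    hysteresis_area: float  # (ul/s)^2
    hysteresis_self_intersecting: bool


def cycle_volume(profile: FlowProfile32) -> float:
    """Per-cycle volume (ul): sum of flow_k x step duration over 32 steps."""
    return float(profile.flow_ul_s.sum() * profile.step_duration_s)


def perfusion_and_cbf(volumes_ul_cc: dict[str, float], subject: SubjectSpec
                      ) -> tuple[float, float, float]:
    """(perfusion ml/min, CBF ml/min/100 g, drainage ml/min).

    perfusion = total arterial volume per cycle x heart rate; drainage the
    venous analogue; CBF = perfusion per 100 g of brain tissue, with tissue
    mass = (GM + WM volume) x 1.05 g/ml.
    """
    art = sum(volumes_ul_cc[v] for v in ARTERIAL_VESSELS if v in volumes_ul_cc)
    ven = sum(volumes_ul_cc[v] for v in VENOUS_VESSELS if v in volumes_ul_cc)
    perfusion = art * subject.heart_rate_bpm / 1000.0  # ul/min -> ml/min
    drainage = ven * subject.heart_rate_bpm / 1000.0
    mass_g = (subject.gm_ul + subject.wm_ul) / 1000.0 * BRAIN_TISSUE_DENSITY_G_ML
    if mass_g <= 0:
        raise ValueError("brain tissue mass must be positive")
    cbf = perfusion / mass_g * 100.0
    return perfusion, cbf, drainage


def seymour_prediction(brain_volume_ml: float) -> float:
    """Allometric perfusion prediction for primates: volume^0.95 (ml/min)."""
    if brain_volume_ml <= 0:
        raise ValueError("brain volume must be positive")
    return float(brain_volume_ml ** 0.95)


def av_balance(art: FlowProfile32, ven: FlowProfile32
               ) -> tuple[float, np.ndarray, np.ndarray, float]:
    """(CF, step-wise balance ul, cumulative balance ul, oscillating volume ul).

    balance_k = (art_k - CF * ven_k) x step duration; its running sum closes
    at zero by construction of CF, and the oscillating volume is the
    peak-to-peak range of that cumulative curve.
    """
    if abs(art.rr_ms - ven.rr_ms) > 1e-9:
        raise ValueError("arterial and venous profiles must share rr_ms")
    v_art = cycle_volume(art)
    v_ven = cycle_volume(ven)
    if v_ven <= 0:
        raise ValueError("venous per-cycle volume must be positive")
    cf = v_art / v_ven
    dt = art.step_duration_s
    balance = (art.flow_ul_s - cf * ven.flow_ul_s) * dt
    cumulative = np.cumsum(balance)
    oscillating = float(np.ptp(cumulative))
    return cf, balance, cumulative, oscillating


def hysteresis_loop(art: FlowProfile32, ven: FlowProfile32
                    ) -> tuple[np.ndarray, float, bool]:
    """(loop points (32, 2), |shoelace area|, self-intersection flag).

    The loop is the ordered polygon of (arterial flow, venous flow) at the 32
    steps, closed from step 32 back to step 1; its area is the absolute
    shoelace signed area.  Self-intersecting loops are flagged (their signed
    area mixes sub-loop orientations).
    """
    if abs(art.rr_ms - ven.rr_ms) > 1e-9:
        raise ValueError("arterial and venous profiles must share rr_ms")
    pts = np.column_stack([art.flow_ul_s, ven.flow_ul_s])
    x, y = pts[:, 0], pts[:, 1]
    area = 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
    ring = np.vstack([pts, pts[:1]])
    self_intersecting = not LineString(ring).is_simple
    return pts, area, self_intersecting


def input_fractions(volumes_ul_cc: dict[str, float]) -> dict[str, float]:
    """Per-subject percentage contributions to arterial input / venous output."""
    art = sum(volumes_ul_cc[v] for v in ARTERIAL_VESSELS if v in volumes_ul_cc)
    ven = sum(volumes_ul_cc[v] for v in VENOUS_VESSELS if v in volumes_ul_cc)
    out: dict[str, float] = {}
    if art > 0:
        for v in ARTERIAL_VESSELS:
            if v in volumes_ul_cc:
                out[f"pct_arterial_{v}"] = 100.0 * volumes_ul_cc[v] / art
        if "RC" in volumes_ul_cc and "LC" in volumes_ul_cc:
            out["pct_arterial_carotids"] = 100.0 * (
                volumes_ul_cc["RC"] + volumes_ul_cc["LC"]) / art
    elif any(v in volumes_ul_cc for v in ARTERIAL_VESSELS):
        raise ValueError("total arterial volume must be positive")
    if ven > 0:
        for v in VENOUS_VESSELS:
            if v in volumes_ul_cc:
                out[f"pct_venous_{v}"] = 100.0 * volumes_ul_cc[v] / ven
    elif any(v in volumes_ul_cc for v in VENOUS_VESSELS):
        raise ValueError("total venous volume must be positive")
    return out
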