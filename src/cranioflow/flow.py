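"""Velocity decoding and per-vessel flow time series.

Phase-contrast images encode through-plane velocity linearly in the voxel
phase: v = VENC * phi / pi, so a phase of pi maps to the velocity-encoding
limit.  Per frame, the vessel's mean velocity is the arithmetic mean of the
decoded velocities over the lumen voxels, and flow is mean velocity times
lumen cross-sectional area (1 cm/s x 1 mm^2 = 10 ul/s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import LumenMask
from .synthetic import CineDataset

__all__ = ["VesselTimeSeries", "decode_velocity", "vessel_series", "NEAR_VENC_FRACTION"]

#: |v| above this fraction of VENC is flagged as near-aliasing
NEAR_VENC_FRACTION = 0.95

_PHASE_TOL = 1e-9


@dataclass
class VesselTimeSeries:
    """Per-frame lumen area, mean velocity and flow for one vessel."""

    vessel: str
    rr_ms: float
    times_ms: np.ndarray
    pct_cc: np.ndarray  # 100 * t / RR, strictly increasing in [0, 100)
    area_mm2: np.ndarray
    mean_velocity_cm_s: np.ndarray
    flow_ul_s: np.ndarray
    near_aliasing: bool = False

    def __post_init__(self) -> None:
        for name in ("times_ms", "pct_cc", "area_mm2", "mean_velocity_cm_s", "flow_ul_s"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not np.all(np.diff(self.pct_cc) > 0):
            raise ValueError("pct_cc must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.times_ms)

    def to_frame(self, subject_id: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame({
            "vessel": self.vessel,
            "frame": np.arange(self.n_samples),
            "time_ms": self.times_ms,
            "pct_cc": self.pct_cc,
            "area_mm2": self.area_mm2,
            "mean_velocity_cm_s": self.mean_velocity_cm_s,
            "flow_ul_s": self.flow_ul_s,
        })
        if subject_id is not None:
            df.insert(0, "subject_id", subject_id)
        return df


def decode_velocity(phase: np.ndarray | float, venc_cm_s: float) -> np.ndarray | float:
    """Decode phase (radians, in (-pi, pi]) into velocity (cm/s)."""
    phase = np.asarray(phase, dtype=float)
    if np.any(phase > np.pi + _PHASE_TOL) or np.any(phase <= -np.pi - _PHASE_TOL):
        raise ValueError("phase values must lie in (-pi, pi]")
    v = venc_cm_s * phase / np.pi
    return float(v) if v.ndim == 0 else v


def vessel_series(dataset: CineDataset, masks: list[LumenMask | None],
                  vessel: str | None = None) -> VesselTimeSeries:
    """Assemble the per-frame flow series of one vessel from its lumen masks.

    ``masks`` holds one entry per dataset frame (``None`` marks frames on
    which the vessel was not detected; these become missing samples).
    """
    if len(masks) != dataset.n_frames:
        raise ValueError("need one mask entry per frame")
    present = [m for m in masks if m is not None]
    if not present:
        raise ValueError("vessel has no detected frames")
    if vessel is None:
        vessel = present[0].vessel
    times, areas, vels, flows = [], [], [], []
    near = False
    for k, mask in enumerate(masks):
        if mask is None:
            continue
        phases = dataset.phase[k][mask.pixels[:, 0], mask.pixels[:, 1]]
        v = decode_velocity(phases, dataset.venc_cm_s)
        if np.max(np.abs(v)) > NEAR_VENC_FRACTION * dataset.venc_cm_s:
            near = True
        v_mean = float(np.mean(v))
        times.append(float(dataset.frame_times_ms[k]))
        areas.append(mask.area_mm2)
        vels.append(v_mean)
        flows.append(v_mean * 10.0 * mask.area_mm2)  # cm/s * mm^2 -> ul/s
    times = np.asarray(times)
    return VesselTimeSeries(
        vessel=vessel, rr_ms=dataset.rr_ms, times_ms=times,
        pct_cc=100.0 * times / dataset.rr_ms, area_mm2=np.asarray(areas),
        mean_velocity_cm_s=np.asarray(vels), flow_ul_s=np.asarray(flows),
        near_aliasing=near)
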