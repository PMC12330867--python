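"""Synthetic cardiac-gated cine phase-contrast MRI datasets with known ground truth.

This module generates everything the downstream analysis consumes: per-subject
biology (age group, sex, weight, heart rate, tissue volumes), per-vessel flow
waveforms over the cardiac cycle, and gated magnitude/phase image stacks for an
arterial slice (basilar trunk BT, right/left internal carotids RC/LC) and a
venous slice (superior sagittal sinus SS, straight sinus StS).

The rendering model is deliberately simple but physically honest:

* each vessel is a filled disk of constant signal amplitude on a dark
  background;
* the within-lumen velocity profile is parabolic (Poiseuille: zero at the
  wall, twice the mean at the centre), rescaled per frame so that
  lumen-mean velocity x lumen area reproduces the waveform flow exactly;
* through-plane velocity is encoded linearly into the image phase,
  phi = pi * v / VENC;
* complex Gaussian noise is added to the real and imaginary channels before
  magnitude/phase extraction, so magnitude noise is Rician and background
  magnitude is Rayleigh, as in real MR magnitude images;
* prospective gating: frame times start at the R-wave (t = 0) and cover only
  a fraction (default 75%) of the R-R interval.

Group defaults are calibrated to the published young-adult / old-adult
marmoset cohort means (per-vessel per-cycle volumes, heart rates, peak-flow
arrival times, tissue volumes), so that synthetic cohorts reproduce the
study's group-level structure while every quantity remains exactly known.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ARTERIAL_VESSELS",
    "VENOUS_VESSELS",
    "ALL_VESSELS",
    "AliasingError",
    "SubjectSpec",
    "WaveformParams",
    "CineDataset",
    "GroundTruth",
    "CohortSubject",
    "make_waveform",
    "render_cine",
    "make_cohort",
    "young_defaults",
    "old_defaults",
    "write_subject",
    "read_cine",
    "write_cohort",
    "COHORT_VOLUMES_UL",
]

ARTERIAL_VESSELS = ("BT", "RC", "LC")
VENOUS_VESSELS = ("SS", "StS")
ALL_VESSELS = ARTERIAL_VESSELS + VENOUS_VESSELS

#: in-plane pixel size (dy, dx) in mm and acquisition matrix (rows, cols)
PIXEL_MM = (0.15, 0.15)
GRID_SHAPE = (200, 160)
SLICE_THICKNESS_MM = 1.0

#: one-sided velocity-encoding limits (cm/s)
VENC_ARTERIAL_CM_S = 50.0
VENC_VENOUS_CM_S = 20.0

#: lumen signal amplitude (arbitrary units) and default complex-noise SD
LUMEN_SIGNAL = 1.0
DEFAULT_NOISE_SD = 0.06

#: fixed vessel-seed layout (row, col) per slice; vessels are well separated
ARTERIAL_SEEDS = {"BT": (118, 80), "RC": (70, 48), "LC": (70, 112)}
VENOUS_SEEDS = {"SS": (60, 80), "StS": (130, 80)}

#: published young/old group-mean per-cycle blood volumes (ul/cardiac cycle)
COHORT_VOLUMES_UL = {
    "YA": {"BT": 19.0, "RC": 13.2, "LC": 15.5, "SS": 6.2, "StS": 6.8},
    "OA": {"BT": 30.3, "RC": 19.3, "LC": 19.5, "SS": 5.6, "StS": 5.7},
}

_DENSE_N = 4096


class AliasingError(ValueError):
    """Raised when an encoded velocity exceeds the VENC limit."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectSpec:
    """Biology of one synthetic subject."""

    subject_id: str
    age_group: str  # "YA" or "OA"
    sex: str  # "M" or "F"
    weight_g: float
    heart_rate_bpm: float
    gm_ul: float
    wm_ul: float
    csf_ul: float
    rng_seed: int

    def __post_init__(self) -> None:
        if self.age_group not in ("YA", "OA"):
            raise ValueError(f"age_group must be YA or OA, got {self.age_group!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be M or F, got {self.sex!r}")
        if self.heart_rate_bpm <= 0:
            raise ValueError("heart_rate_bpm must be positive")
        for name in ("weight_g", "gm_ul", "wm_ul", "csf_ul"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def rr_ms(self) -> float:
        return 60000.0 / self.heart_rate_bpm


@dataclass(frozen=True)
class WaveformParams:
    """Ground-truth waveform description for one vessel.

    ``volume_per_cc_ul`` is the per-cycle blood volume the waveform integrates
    to; ``peak_pct_cc`` the arrival time of the flow maximum (point M);
    ``pulse_width_pct`` the systolic rise width (onset-to-peak, %CC);
    ``baseline_fraction`` the diastolic floor as a fraction of the peak;
    ``notch_pct_cc`` the dicrotic-notch position (arterial waveforms only).
    """

    vessel: str
    volume_per_cc_ul: float
    peak_pct_cc: float
    pulse_width_pct: float
    baseline_fraction: float
    lumen_radius_mm: float
    notch_pct_cc: float | None = None

    def __post_init__(self) -> None:
        if self.vessel not in ALL_VESSELS:
            raise ValueError(f"unknown vessel {self.vessel!r}")
        if not 0.0 < self.peak_pct_cc < 100.0:
            raise ValueError("peak_pct_cc must lie strictly inside (0, 100)")
        if self.volume_per_cc_ul <= 0:
            raise ValueError("volume_per_cc_ul must be positive")
        if not 0.0 <= self.baseline_fraction < 1.0:
            raise ValueError("baseline_fraction must lie in [0, 1)")
        if self.pulse_width_pct <= 0:
            raise ValueError("pulse_width_pct must be positive")
        if self.peak_pct_cc - self.pulse_width_pct < -100.0 or self.peak_pct_cc > 100.0:
            raise ValueError("pulse lies entirely outside [0, 100]")
        if self.is_venous and self.notch_pct_cc is not None:
            raise ValueError("notch_pct_cc is an arterial-only parameter")

    @property
    def is_venous(self) -> bool:
        return self.vessel in VENOUS_VESSELS


@dataclass
class CineDataset:
    """One gated cine PC-MRI slice: magnitude/phase stacks plus metadata."""

    slice_kind: str  # "arterial" or "venous"
    magnitude: np.ndarray  # (n_frames, rows, cols), a.u., >= 0
    phase: np.ndarray  # (n_frames, rows, cols), radians in (-pi, pi]
    venc_cm_s: float
    frame_times_ms: np.ndarray  # strictly increasing, < rr_ms
    rr_ms: float
    pixel_mm: tuple[float, float]
    slice_thickness_mm: float
    vessel_seeds: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if self.slice_kind not in ("arterial", "venous"):
            raise ValueError("slice_kind must be 'arterial' or 'venous'")
        t = np.asarray(self.frame_times_ms, dtype=float)
        if t.size < 3:
            raise ValueError("need at least 3 frames")
        if not np.all(np.diff(t) > 0):
            raise ValueError("frame_times_ms must be strictly increasing")
        if t.max() >= self.rr_ms:
            raise ValueError("frame times must stay inside one R-R interval")
        if np.any(np.asarray(self.magnitude) < 0):
            raise ValueError("magnitude must be non-negative")

    @property
    def n_frames(self) -> int:
        return len(self.frame_times_ms)

    @property
    def vessels(self) -> tuple[str, ...]:
        return tuple(self.vessel_seeds)


@dataclass
class GroundTruth:
    """Simulation truth for parameter-recovery tests."""

    rr_ms: float
    dense_pct: np.ndarray  # dense %CC grid, [0, 100)
    flow_ul_s: dict[str, np.ndarray]  # per-vessel dense true waveform
    lumen_area_mm2: dict[str, float]  # per-vessel pixelated lumen area
    volume_ul_cc: dict[str, float]  # per-vessel true per-cycle volume
    peak_pct_cc: dict[str, float]  # per-vessel true peak arrival
    area_series_mm2: dict[str, np.ndarray] = field(default_factory=dict)

    def flow_at(self, vessel: str, t_pct: np.ndarray | float) -> np.ndarray:
        """True flow (ul/s) at arbitrary %CC positions (periodic)."""
        grid = np.append(self.dense_pct, 100.0)
        f = self.flow_ul_s[vessel]
        return np.interp(np.asarray(t_pct, dtype=float) % 100.0, grid,
                         np.append(f, f[0]))


@dataclass
class CohortSubject:
    subject: SubjectSpec
    arterial: CineDataset
    venous: CineDataset
    truth: GroundTruth


# ---------------------------------------------------------------------------
# waveform construction
# ---------------------------------------------------------------------------


def _gamma_pulse(t_pct: np.ndarray, onset: float, peak: float, alpha: float) -> np.ndarray:
    """Periodic gamma-variate pulse with unit amplitude at ``peak`` %CC."""
    rise = peak - onset
    x = ((t_pct - onset) % 100.0) / rise
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] ** alpha * np.exp(alpha * (1.0 - x[pos]))
    return out


def _unit_shape(params: WaveformParams) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalised periodic waveform shape (peak value 1) on a dense grid."""
    t = np.linspace(0.0, 100.0, _DENSE_N, endpoint=False)
    if params.is_venous:
        # venous: smoothed (circular convolution with a causal exponential
        # kernel) copy of a systolic pulse, shifted so the maximum lands at
        # the requested peak position
        base = _gamma_pulse(t, onset=0.0, peak=params.pulse_width_pct, alpha=2.0)
        tau = 0.6 * params.pulse_width_pct
        kern = np.exp(-t / tau)
        kern /= kern.sum()
        smooth = np.real(np.fft.ifft(np.fft.fft(base) * np.fft.fft(kern)))
        shift = int(round(params.peak_pct_cc / 100.0 * _DENSE_N)) - int(np.argmax(smooth))
        shape = np.roll(smooth, shift)
    else:
        onset = params.peak_pct_cc - params.pulse_width_pct
        main = _gamma_pulse(t, onset=onset, peak=params.peak_pct_cc, alpha=2.5)
        if params.notch_pct_cc is not None:
            # small secondary (post-notch) bump: its onset at the notch
            # position creates the slope break between the steep systolic
            # descent and the slow diastolic decay
            bump_rise = 0.45 * params.pulse_width_pct
            bump = _gamma_pulse(t, onset=params.notch_pct_cc,
                                peak=params.notch_pct_cc + bump_rise, alpha=2.0)
            main = main + 0.22 * bump
        shape = main
    shape = shape / shape.max()
    unit = params.baseline_fraction + (1.0 - params.baseline_fraction) * shape
    return t, unit


def make_waveform(params: WaveformParams, t_pct: Sequence[float] | np.ndarray,
                  rr_ms: float) -> np.ndarray:
    """Evaluate the true flow waveform (ul/s) at positions ``t_pct`` (%CC).

    The waveform is periodic with period 100 %CC, non-negative, has a single
    dominant systolic peak at ``params.peak_pct_cc``, and is scaled so its
    integral over one cycle of duration ``rr_ms`` equals
    ``params.volume_per_cc_ul``.
    """
    t_pct = np.asarray(t_pct, dtype=float)
    if np.any(t_pct < 0.0) or np.any(t_pct > 100.0):
        raise ValueError("t_pct must lie within [0, 100]")
    if t_pct.size > 1 and np.any(np.diff(t_pct) <= 0):
        raise ValueError("t_pct grid must be strictly increasing")
    grid, unit = _unit_shape(params)
    rr_s = rr_ms / 1000.0
    # mean over the cycle x cycle duration = volume
    scale = params.volume_per_cc_ul / (unit.mean() * rr_s)
    flow = scale * unit
    wrapped = np.append(grid, 100.0)
    return np.interp(t_pct, wrapped, np.append(flow, flow[0]))


# ---------------------------------------------------------------------------
# cine rendering
# ---------------------------------------------------------------------------


def _disk_pixels(centre: tuple[int, int], radius_mm: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pixel coordinates of the lumen disk and normalised parabolic weights.

    Pixels whose centres fall strictly inside ``radius_mm`` of the seed belong
    to the lumen.  Weights follow a Poiseuille profile 2*(1 - (r/R)^2),
    renormalised to have mean exactly 1 over the pixelated disk so that the
    pixel-mean velocity equals the prescribed lumen-mean velocity.
    """
    r_px_y = radius_mm / PIXEL_MM[0]
    r_px_x = radius_mm / PIXEL_MM[1]
    span = int(np.ceil(max(r_px_y, r_px_x))) + 1
    dy, dx = np.mgrid[-span:span + 1, -span:span + 1]
    r2 = (dy / r_px_y) ** 2 + (dx / r_px_x) ** 2
    inside = r2 < 1.0
    rows = centre[0] + dy[inside]
    cols = centre[1] + dx[inside]
    w = 2.0 * (1.0 - r2[inside])
    w = w / w.mean()
    return rows, cols, w


def lumen_pixel_count(radius_mm: float) -> int:
    """Number of pixels in a pixelated lumen disk of the given radius."""
    rows, _, _ = _disk_pixels((0, 0), radius_mm)
    return int(rows.size)


def render_cine(subject: SubjectSpec, waveforms: Sequence[WaveformParams],
                noise_sd: float = DEFAULT_NOISE_SD, coverage_fraction: float = 0.75,
                n_frames: int = 16, rng: np.random.Generator | None = None,
                area_pulsation: float = 0.0) -> tuple[CineDataset, GroundTruth]:
    """Render one gated cine PC-MRI slice for ``subject``.

    All ``waveforms`` must belong to the same compartment (all arterial or
    all venous); the slice kind, VENC and vessel-seed layout follow from it.
    ``area_pulsation`` optionally modulates each lumen radius over the cycle
    so the cross-sectional area tracks the flow waveform by +/- that fraction.
    Raises :class:`AliasingError` if any encoded voxel velocity would exceed
    the VENC.
    """
    if not 0.5 <= coverage_fraction <= 1.0:
        raise ValueError("coverage_fraction must lie in [0.5, 1]")
    if n_frames < 3:
        raise ValueError("need at least 3 frames")
    vessels = [p.vessel for p in waveforms]
    if len(set(vessels)) != len(vessels):
        raise ValueError("duplicate vessels in waveform list")
    venous_flags = {p.is_venous for p in waveforms}
    if len(venous_flags) != 1:
        raise ValueError("waveforms must all belong to one slice compartment")
    is_venous = venous_flags.pop()
    slice_kind = "venous" if is_venous else "arterial"
    venc = VENC_VENOUS_CM_S if is_venous else VENC_ARTERIAL_CM_S
    seeds_all = VENOUS_SEEDS if is_venous else ARTERIAL_SEEDS
    seeds = {v: seeds_all[v] for v in vessels}
    if rng is None:
        rng = np.random.default_rng(subject.rng_seed)

    rr_ms = subject.rr_ms
    # prospective gating: acquisition starts at the R-wave onset
    if coverage_fraction >= 1.0:  # keep the last frame inside the cycle
        frame_times = np.linspace(0.0, rr_ms, n_frames, endpoint=False)
    else:
        frame_times = np.linspace(0.0, coverage_fraction * rr_ms, n_frames)
    frame_pct = 100.0 * frame_times / rr_ms

    dense_pct = np.linspace(0.0, 100.0, _DENSE_N, endpoint=False)
    truth = GroundTruth(rr_ms=rr_ms, dense_pct=dense_pct, flow_ul_s={},
                        lumen_area_mm2={}, volume_ul_cc={}, peak_pct_cc={})
    pix_area = PIXEL_MM[0] * PIXEL_MM[1]

    mags = np.zeros((n_frames, *GRID_SHAPE))
    phases = np.zeros((n_frames, *GRID_SHAPE))
    complex_stack = np.zeros((n_frames, *GRID_SHAPE), dtype=complex)

    for params in waveforms:
        dense_flow = make_waveform(params, dense_pct, rr_ms)
        truth.flow_ul_s[params.vessel] = dense_flow
        truth.volume_ul_cc[params.vessel] = params.volume_per_cc_ul
        truth.peak_pct_cc[params.vessel] = float(dense_pct[np.argmax(dense_flow)])
        base_rows, base_cols, base_w = _disk_pixels(seeds[params.vessel], params.lumen_radius_mm)
        truth.lumen_area_mm2[params.vessel] = base_rows.size * pix_area
        flows = np.interp(frame_pct, np.append(dense_pct, 100.0),
                          np.append(dense_flow, dense_flow[0]))
        fmin, fmax = dense_flow.min(), dense_flow.max()
        areas = np.empty(n_frames)
        for k in range(n_frames):
            if area_pulsation:
                rel = (flows[k] - fmin) / max(fmax - fmin, 1e-12)
                factor = np.sqrt(1.0 + area_pulsation * (2.0 * rel - 1.0))
                rows, cols, w = _disk_pixels(seeds[params.vessel],
                                             params.lumen_radius_mm * factor)
            else:
                rows, cols, w = base_rows, base_cols, base_w
            area_mm2 = rows.size * pix_area
            areas[k] = area_mm2
            v_mean_mm_s = flows[k] / area_mm2  # ul/s / mm^2 = mm/s
            v_cm_s = w * v_mean_mm_s / 10.0
            if np.max(np.abs(v_cm_s)) > venc:
                raise AliasingError(
                    f"{params.vessel}: voxel velocity {np.max(np.abs(v_cm_s)):.1f} cm/s "
                    f"exceeds VENC {venc:.0f} cm/s at frame {k}")
            phi = np.pi * v_cm_s / venc
            complex_stack[k, rows, cols] = LUMEN_SIGNAL * np.exp(1j * phi)
        truth.area_series_mm2[params.vessel] = areas

    if noise_sd > 0:
        noise = rng.normal(scale=noise_sd, size=(2, n_frames, *GRID_SHAPE))
        complex_stack = complex_stack + noise[0] + 1j * noise[1]
    mags = np.abs(complex_stack)
    phases = np.angle(complex_stack)
    # np.angle returns [-pi, pi]; fold the closed endpoint onto +pi
    phases[phases == -np.pi] = np.pi

    dataset = CineDataset(slice_kind=slice_kind, magnitude=mags, phase=phases,
                          venc_cm_s=venc, frame_times_ms=frame_times, rr_ms=rr_ms,
                          pixel_mm=PIXEL_MM, slice_thickness_mm=SLICE_THICKNESS_MM,
                          vessel_seeds=seeds)
    return dataset, truth


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

# group defaults calibrated to the published cohort means: per-vessel
# per-cycle volumes and heart rates from the study's summary table; peak
# arrival times from the reported flow-peak chronology (composite arterial
# peak at ~31 %CC young / ~25 %CC old, venous peaks at ~38-44 %CC young /
# ~29-34 %CC old, basilar trunk slightly leading the carotids); dicrotic
# notch at step 17 (53.1 %CC); lumen radii sized to the reported 13-31 voxel
# cross-sections at 150 um pixels.  Baseline fractions and pulse widths are
# free shape parameters tuned so arterial pulsatility indices land near the
# reported ~1.0-1.5 range and old waveforms are steeper and less damped.
_R13, _R21, _R25, _R29, _R37 = 0.315, 0.375, 0.435, 0.462, 0.50  # mm -> 13..37 px

_YA_HR = 189.0
_OA_HR = 152.0

_YA_BIOLOGY = dict(weight_g=373.0, gm_ul=4084.0, wm_ul=2669.0, csf_ul=941.0)
_OA_BIOLOGY = dict(weight_g=391.0, gm_ul=4256.0, wm_ul=2831.0, csf_ul=1119.0)

_NOTCH = 53.125  # %CC, step 17 of the 32-step grid


def young_defaults() -> dict[str, WaveformParams]:
    """Per-vessel waveform defaults for the young-adult group."""
    return {
        "BT": WaveformParams("BT", 19.0, 30.0, 21.0, 0.30, _R29, _NOTCH),
        "RC": WaveformParams("RC", 13.2, 32.5, 21.0, 0.34, _R21, _NOTCH),
        "LC": WaveformParams("LC", 15.5, 31.5, 21.0, 0.32, _R25, _NOTCH),
        "SS": WaveformParams("SS", 6.2, 44.2, 24.0, 0.62, _R21),
        "StS": WaveformParams("StS", 6.8, 38.4, 24.0, 0.60, _R25),
    }


def old_defaults() -> dict[str, WaveformParams]:
    """Per-vessel waveform defaults for the old-adult group."""
    return {
        "BT": WaveformParams("BT", 30.3, 24.0, 15.0, 0.29, _R37, _NOTCH),
        "RC": WaveformParams("RC", 19.3, 26.5, 15.0, 0.32, _R25, _NOTCH),
        "LC": WaveformParams("LC", 19.5, 26.0, 15.0, 0.31, _R25, _NOTCH),
        "SS": WaveformParams("SS", 5.6, 33.5, 13.0, 0.56, _R13),
        "StS": WaveformParams("StS", 5.7, 28.6, 13.0, 0.54, _R13),
    }


#: between-subject variability (coefficients of variation of multiplicative
#: lognormal jitter).  The global flow scale and per-vessel idiosyncratic
#: jitter combine to roughly the published per-vessel volume CVs (~0.2);
#: the heart-rate CV is kept moderate so encoded velocities stay within the
#: VENC limits, as in the acquired cohort where no aliasing occurred.
JITTER = {
    "flow_scale_cv": 0.13,
    "vessel_cv": 0.12,
    "hr_cv": 0.13,
    "tissue_cv": 0.08,
    # peak-time variability: a subject-level shift moves all vessels together
    # (systolic timing co-varies within a subject), plus smaller independent
    # per-vessel jitter (all additive %CC)
    "timing_shift_sd": 2.5,
    "peak_sd_art": {"YA": 1.5, "OA": 1.2},
    "peak_sd_ven": {"YA": 2.0, "OA": 1.5},
}


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    sigma = np.sqrt(np.log(1.0 + cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def _jittered_subject(group: str, index: int, sex: str, seed: int,
                      rng: np.random.Generator) -> tuple[SubjectSpec, dict[str, WaveformParams]]:
    base = young_defaults() if group == "YA" else old_defaults()
    bio = _YA_BIOLOGY if group == "YA" else _OA_BIOLOGY
    hr0 = _YA_HR if group == "YA" else _OA_HR
    hr = hr0 * _lognormal_factor(rng, JITTER["hr_cv"])
    gscale = _lognormal_factor(rng, JITTER["flow_scale_cv"])
    spec = SubjectSpec(
        subject_id=f"{group}{index + 1:02d}",
        age_group=group,
        sex=sex,
        weight_g=float(np.clip(rng.normal(bio["weight_g"], 35.0), 300.0, 470.0)),
        heart_rate_bpm=hr,
        gm_ul=bio["gm_ul"] * _lognormal_factor(rng, JITTER["tissue_cv"]),
        wm_ul=bio["wm_ul"] * _lognormal_factor(rng, JITTER["tissue_cv"]),
        csf_ul=bio["csf_ul"] * _lognormal_factor(rng, JITTER["tissue_cv"]),
        rng_seed=seed,
    )
    params: dict[str, WaveformParams] = {}
    shift = rng.normal(0.0, JITTER["timing_shift_sd"])
    for vessel, p in base.items():
        vol = p.volume_per_cc_ul * gscale * _lognormal_factor(rng, JITTER["vessel_cv"])
        sd = JITTER["peak_sd_ven" if p.is_venous else "peak_sd_art"][group]
        peak = float(np.clip(p.peak_pct_cc + shift + rng.normal(0.0, sd),
                             10.0, 48.0 if not p.is_venous else 70.0))
        params[vessel] = replace(p, volume_per_cc_ul=vol, peak_pct_cc=peak)
    return spec, params


def _would_alias(spec: SubjectSpec, params: Mapping[str, WaveformParams]) -> bool:
    """Analytic pre-check of the VENC bound for the centre-of-lumen voxel."""
    pix_area = PIXEL_MM[0] * PIXEL_MM[1]
    for p in params.values():
        venc = VENC_VENOUS_CM_S if p.is_venous else VENC_ARTERIAL_CM_S
        _, _, w = _disk_pixels((0, 0), p.lumen_radius_mm)
        area = lumen_pixel_count(p.lumen_radius_mm) * pix_area
        dense = make_waveform(p, np.linspace(0, 99.9, 512), spec.rr_ms)
        v_max = w.max() * dense.max() / area / 10.0
        if v_max > 0.98 * venc:
            return True
    return False


def make_cohort(n_young: int, n_old: int, seed: int,
                noise_sd: float = DEFAULT_NOISE_SD, coverage_fraction: float = 0.75,
                n_frames: int = 16) -> list[CohortSubject]:
    """Generate a reproducible two-group cohort of synthetic subjects.

    Subjects whose jittered flows would exceed the velocity-encoding limit
    are redrawn (the acquired cohort, by construction of its VENC settings,
    contained no aliased series), so every returned dataset renders cleanly.
    """
    if n_young < 1 or n_old < 1:
        raise ValueError("need at least one subject per group")
    master = np.random.default_rng(seed)
    cohort: list[CohortSubject] = []
    # sex balance mirroring the study cohort (~60/40 males/females)
    for group, n in (("YA", n_young), ("OA", n_old)):
        for i in range(n):
            sex = "M" if i % 5 in (0, 2, 4) else "F"
            for _attempt in range(100):
                sub_seed = int(master.integers(0, 2**31 - 1))
                rng = np.random.default_rng(sub_seed)
                spec, params = _jittered_subject(group, i, sex, sub_seed, rng)
                if not _would_alias(spec, params):
                    break
            else:  # pragma: no cover - defensive
                raise RuntimeError("could not draw a VENC-compatible subject")
            art_params = [params[v] for v in ARTERIAL_VESSELS]
            ven_params = [params[v] for v in VENOUS_VESSELS]
            art, truth_a = render_cine(spec, art_params, noise_sd=noise_sd,
                                       coverage_fraction=coverage_fraction,
                                       n_frames=n_frames, rng=rng)
            ven, truth_v = render_cine(spec, ven_params, noise_sd=noise_sd,
                                       coverage_fraction=coverage_fraction,
                                       n_frames=n_frames, rng=rng)
            truth = GroundTruth(
                rr_ms=spec.rr_ms, dense_pct=truth_a.dense_pct,
                flow_ul_s={**truth_a.flow_ul_s, **truth_v.flow_ul_s},
                lumen_area_mm2={**truth_a.lumen_area_mm2, **truth_v.lumen_area_mm2},
                volume_ul_cc={**truth_a.volume_ul_cc, **truth_v.volume_ul_cc},
                peak_pct_cc={**truth_a.peak_pct_cc, **truth_v.peak_pct_cc},
                area_series_mm2={**truth_a.area_series_mm2, **truth_v.area_series_mm2},
            )
            cohort.append(CohortSubject(spec, art, ven, truth))
    return cohort


# ---------------------------------------------------------------------------
# file I/O (NIfTI + JSON sidecars, CSV manifest)
# ---------------------------------------------------------------------------


def write_cine(dataset: CineDataset, out_dir: Path, stem: str) -> dict[str, str]:
    """Write magnitude/phase NIfTI volumes (frames on the 4th axis) + sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag([dataset.pixel_mm[0], dataset.pixel_mm[1],
                      dataset.slice_thickness_mm, 1.0])
    files = {}
    for kind, stack in (("mag", dataset.magnitude), ("phase", dataset.phase)):
        arr = np.transpose(stack, (1, 2, 0))[:, :, np.newaxis, :]  # x,y,z,t
        img = nib.Nifti1Image(arr.astype(np.float32), affine)
        path = out_dir / f"{stem}_{kind}.nii.gz"
        nib.save(img, path)
        files[kind] = path.name
    sidecar = {
        "slice_kind": dataset.slice_kind,
        "venc_cm_s": dataset.venc_cm_s,
        "frame_times_ms": list(map(float, dataset.frame_times_ms)),
        "rr_ms": dataset.rr_ms,
        "pixel_mm": list(dataset.pixel_mm),
        "slice_thickness_mm": dataset.slice_thickness_mm,
        "vessel_seeds": {v: list(map(int, s)) for v, s in dataset.vessel_seeds.items()},
    }
    side_path = out_dir / f"{stem}.json"
    side_path.write_text(json.dumps(sidecar, indent=1))
    files["sidecar"] = side_path.name
    return files


def read_cine(out_dir: Path, stem: str) -> CineDataset:
    out_dir = Path(out_dir)
    meta = json.loads((out_dir / f"{stem}.json").read_text())
    stacks = {}
    for kind in ("mag", "phase"):
        arr = np.asarray(nib.load(out_dir / f"{stem}_{kind}.nii.gz").dataobj)
        stacks[kind] = np.transpose(arr[:, :, 0, :], (2, 0, 1)).astype(float)
    return CineDataset(
        slice_kind=meta["slice_kind"], magnitude=stacks["mag"], phase=stacks["phase"],
        venc_cm_s=meta["venc_cm_s"], frame_times_ms=np.array(meta["frame_times_ms"]),
        rr_ms=meta["rr_ms"], pixel_mm=tuple(meta["pixel_mm"]),
        slice_thickness_mm=meta["slice_thickness_mm"],
        vessel_seeds={v: tuple(s) for v, s in meta["vessel_seeds"].items()},
    )


def write_subject(item: CohortSubject, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    sid = item.subject.subject_id
    write_cine(item.arterial, out_dir, f"{sid}_arterial")
    write_cine(item.venous, out_dir, f"{sid}_venous")
    truth = {
        "rr_ms": item.truth.rr_ms,
        "dense_pct": list(map(float, item.truth.dense_pct[::8])),
        "flow_ul_s": {v: list(map(float, f[::8])) for v, f in item.truth.flow_ul_s.items()},
        "lumen_area_mm2": item.truth.lumen_area_mm2,
        "volume_ul_cc": item.truth.volume_ul_cc,
        "peak_pct_cc": item.truth.peak_pct_cc,
    }
    (out_dir / f"{sid}_truth.json").write_text(json.dumps(truth))


def write_cohort(cohort: Sequence[CohortSubject], out_dir: Path) -> pd.DataFrame:
    """Write every subject plus a cohort manifest CSV; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for item in cohort:
        write_subject(item, out_dir)
        s = item.subject
        rows.append({
            "subject_id": s.subject_id, "age_group": s.age_group, "sex": s.sex,
            "weight_g": s.weight_g, "heart_rate_bpm": s.heart_rate_bpm,
            "gm_ul": s.gm_ul, "wm_ul": s.wm_ul, "csf_ul": s.csf_ul,
            "rng_seed": s.rng_seed,
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "cohort.csv", index=False)
    return manifest
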