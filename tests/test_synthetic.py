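"""Waveform construction, cine rendering, and cohort generation."""

import numpy as np
import pytest

from cranioflow.synthetic import (AliasingError, SubjectSpec, WaveformParams,
                                  lumen_pixel_count, make_cohort, make_waveform,
                                  old_defaults, render_cine, young_defaults)

RR_YA = 60000.0 / 189.0
DENSE = np.linspace(0.0, 100.0, 2000, endpoint=False)


def _bt(**kw) -> WaveformParams:
    base = dict(vessel="BT", volume_per_cc_ul=19.0, peak_pct_cc=31.0,
                pulse_width_pct=21.0, baseline_fraction=0.30,
                lumen_radius_mm=0.462, notch_pct_cc=53.125)
    base.update(kw)
    return WaveformParams(**base)


class TestMakeWaveform:
    def test_volume_contract(self):
        """Trapezoidal integral over one cycle reproduces the per-cycle volume."""
        f = make_waveform(_bt(), DENSE, RR_YA)
        grid_s = np.append(DENSE, 100.0) / 100.0 * RR_YA / 1000.0
        vol = np.trapezoid(np.append(f, f[0]), grid_s)
        assert vol == pytest.approx(19.0, rel=0.01)

    def test_peak_position(self):
        """The waveform maximum lands at the requested %CC (within the grid)."""
        f = make_waveform(_bt(peak_pct_cc=31.0), DENSE, RR_YA)
        assert DENSE[np.argmax(f)] == pytest.approx(31.0, abs=100.0 / 2000 + 1e-9)

    def test_periodicity(self):
        f = make_waveform(_bt(), DENSE, RR_YA)
        assert abs(f[0] - make_waveform(_bt(), np.array([100.0]), RR_YA)[0]) \
            <= 0.01 * f.max()

    def test_degenerate_pulse_is_nearly_constant(self):
        """baseline_fraction -> 1 collapses the pulse; PI -> 0."""
        f = make_waveform(_bt(baseline_fraction=0.999), DENSE, RR_YA)
        pi = (f.max() - f.min()) / f.mean()
        assert pi < 0.005
        assert np.all(f > 0)

    def test_venous_is_delayed_smooth_copy(self):
        p = WaveformParams("SS", 6.2, 44.2, 24.0, 0.62, 0.375)
        f = make_waveform(p, DENSE, RR_YA)
        assert DENSE[np.argmax(f)] == pytest.approx(44.2, abs=0.1)
        art = make_waveform(_bt(), DENSE, RR_YA)
        assert (f.max() - f.min()) / f.mean() < (art.max() - art.min()) / art.mean()

    def test_non_negative(self):
        for params in (*young_defaults().values(), *old_defaults().values()):
            assert np.all(make_waveform(params, DENSE, RR_YA) >= 0)

    def test_rejects_bad_grid(self):
        with pytest.raises(ValueError):
            make_waveform(_bt(), np.array([10.0, 5.0, 20.0]), RR_YA)
        with pytest.raises(ValueError):
            make_waveform(_bt(), np.array([-5.0, 10.0]), RR_YA)

    def test_rejects_pulse_outside_cycle(self):
        with pytest.raises(ValueError):
            _bt(peak_pct_cc=120.0)
        with pytest.raises(ValueError):
            _bt(peak_pct_cc=0.0)


class TestRenderCine:
    def test_noiseless_decode_is_exact(self, young_subject):
        """With zero noise the encoded lumen-mean velocity is exact per frame."""
        p = _bt(baseline_fraction=0.999)  # nearly constant flow
        ds, truth = render_cine(young_subject, [p], noise_sd=0.0)
        area = truth.lumen_area_mm2["BT"]
        rows, cols = np.nonzero(ds.magnitude[0] > 0.5)
        for k in range(ds.n_frames):
            v = ds.venc_cm_s * ds.phase[k, rows, cols] / np.pi
            flow_true = truth.flow_at("BT", 100.0 * ds.frame_times_ms[k] / ds.rr_ms)
            v_true = flow_true / area / 10.0
            assert np.mean(v) == pytest.approx(float(v_true), rel=1e-9)

    def test_lumen_voxel_counts_match_reported_range(self):
        """Defaults give 13-37 voxel cross-sections at 150 um pixels."""
        for params in (*young_defaults().values(), *old_defaults().values()):
            n = lumen_pixel_count(params.lumen_radius_mm)
            assert 13 <= n <= 37
        # a ~0.45 mm^2 lumen covers ~20 voxels (pixelated-disk oracle)
        r = 0.375
        oracle = sum(1 for dy in range(-4, 5) for dx in range(-4, 5)
                     if (dy * 0.15) ** 2 + (dx * 0.15) ** 2 < r * r)
        assert lumen_pixel_count(r) == oracle == 21

    def test_frame_times_span_coverage(self, young_subject):
        ds, _ = render_cine(young_subject, [_bt()], noise_sd=0.0,
                            coverage_fraction=0.75, n_frames=16)
        assert ds.n_frames == 16
        assert ds.frame_times_ms[0] == 0.0
        assert ds.frame_times_ms[-1] < 0.76 * ds.rr_ms

    def test_aliasing_raises(self, young_subject):
        huge = _bt(volume_per_cc_ul=500.0)
        with pytest.raises(AliasingError):
            render_cine(young_subject, [huge], noise_sd=0.0)

    def test_phase_range_and_magnitude_sign(self, noisy_arterial):
        ds, _ = noisy_arterial
        assert np.all(ds.magnitude >= 0)
        assert np.all(ds.phase > -np.pi)
        assert np.all(ds.phase <= np.pi)

    def test_mixed_compartments_rejected(self, young_subject):
        with pytest.raises(ValueError):
            render_cine(young_subject,
                        [_bt(), WaveformParams("SS", 6.0, 40.0, 24.0, 0.6, 0.375)])


class TestMakeCohort:
    def test_determinism(self):
        a = make_cohort(1, 1, seed=12, n_frames=6)
        b = make_cohort(1, 1, seed=12, n_frames=6)
        for x, y in zip(a, b):
            assert x.subject == y.subject
            assert np.array_equal(x.arterial.magnitude, y.arterial.magnitude)
            assert np.array_equal(x.venous.phase, y.venous.phase)

    def test_counts_and_structure(self, small_noiseless_cohort):
        cohort = small_noiseless_cohort
        assert len(cohort) == 4
        assert sum(c.subject.age_group == "YA" for c in cohort) == 2
        for c in cohort:
            assert set(c.arterial.vessel_seeds) == {"BT", "RC", "LC"}
            assert set(c.venous.vessel_seeds) == {"SS", "StS"}
            assert set(c.truth.volume_ul_cc) == {"BT", "RC", "LC", "SS", "StS"}

    def test_truth_volume_conservation(self, small_noiseless_cohort):
        """Each true waveform integrates to its per-cycle volume within 1%."""
        for c in small_noiseless_cohort:
            grid_s = np.append(c.truth.dense_pct, 100.0) / 100.0 * c.truth.rr_ms / 1000.0
            for v, f in c.truth.flow_ul_s.items():
                vol = np.trapezoid(np.append(f, f[0]), grid_s)
                assert vol == pytest.approx(c.truth.volume_ul_cc[v], rel=0.01)

    def test_group_means_near_calibration_targets(self):
        """Cohort-mean true BT volumes sit near the young/old calibration values."""
        cohort = make_cohort(7, 7, seed=97, noise_sd=0.0, n_frames=5)
        bt_ya = [c.truth.volume_ul_cc["BT"] for c in cohort if c.subject.age_group == "YA"]
        bt_oa = [c.truth.volume_ul_cc["BT"] for c in cohort if c.subject.age_group == "OA"]
        # within ~3 SEM of the 19.0 / 30.3 ul calibration means (CV ~ 0.18, n=7)
        assert np.mean(bt_ya) == pytest.approx(19.0, abs=4.0)
        assert np.mean(bt_oa) == pytest.approx(30.3, abs=6.5)
        hr_ya = [c.subject.heart_rate_bpm for c in cohort if c.subject.age_group == "YA"]
        hr_oa = [c.subject.heart_rate_bpm for c in cohort if c.subject.age_group == "OA"]
        assert np.mean(hr_ya) > np.mean(hr_oa)

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            make_cohort(0, 3, seed=1)


class TestSubjectSpec:
    @pytest.mark.parametrize("field,value", [
        ("heart_rate_bpm", 0.0), ("gm_ul", -1.0), ("age_group", "MIDDLE"),
        ("sex", "X"),
    ])
    def test_validation(self, field, value, young_subject):
        kw = dict(subject_id="s", age_group="YA", sex="F", weight_g=375.0,
                  heart_rate_bpm=189.0, gm_ul=4084.0, wm_ul=2669.0,
                  csf_ul=941.0, rng_seed=0)
        kw[field] = value
        with pytest.raises(ValueError):
            SubjectSpec(**kw)
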