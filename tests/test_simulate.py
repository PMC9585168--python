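"""Simulator: waveform kinematics, analytic oracle, rendering, cohorts."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import find_peaks

from zfcardio import (CanvasOverflowError, CohortSpec, DEFAULT_MODEL_EFFECT,
                      GroupEffectSpec, HeartSimParams, axis_waveform,
                      cohort_manifest, expected_indicators, generate_cohort,
                      render_sequence, segment_heart_frame, SegmentationConfig)


class TestAxisWaveform:
    def test_diastolic_identity_at_cycle_start(self, default_params):
        a, b = axis_waveform(default_params, 0.0)
        assert a == pytest.approx(default_params.a_ed_um)
        assert b == pytest.approx(default_params.b_ed_um)

    def test_peak_systole_shortening(self):
        p = HeartSimParams(a_ed_um=100.0, contraction_long=0.2)
        t_peak = p.systole_fraction / (2.0 * p.beat_freq_hz)
        a, _ = axis_waveform(p, t_peak)
        assert a == pytest.approx(80.0, rel=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(t=st.floats(min_value=0.0, max_value=10.0),
           freq=st.floats(min_value=0.5, max_value=5.0))
    def test_periodicity(self, t, freq):
        p = HeartSimParams(beat_freq_hz=freq)
        a0, b0 = axis_waveform(p, t)
        a1, b1 = axis_waveform(p, t + 1.0 / freq)
        assert a0 == pytest.approx(a1, rel=1e-6)
        assert b0 == pytest.approx(b1, rel=1e-6)

    @settings(max_examples=50, deadline=None)
    @given(t=st.floats(min_value=0.0, max_value=10.0))
    def test_axes_bounded_by_diastole_and_systole(self, t):
        p = HeartSimParams()
        a, b = axis_waveform(p, t)
        assert p.a_ed_um * (1 - p.contraction_long) - 1e-9 <= a <= p.a_ed_um + 1e-9
        assert p.b_ed_um * (1 - p.contraction_short) - 1e-9 <= b <= p.b_ed_um + 1e-9


class TestExpectedIndicators:
    def test_heart_rate_unit_conversion(self):
        ind = expected_indicators(HeartSimParams(beat_freq_hz=2.5))
        assert ind.hr_bpm == pytest.approx(150.0)

    def test_zero_contraction_zeroes_all_contraction_indicators(self):
        p = HeartSimParams(contraction_long=0.0, contraction_short=0.0)
        ind = expected_indicators(p)
        assert ind.fac == ind.fs == ind.sv_um3 == ind.ef == ind.co_um3_min == 0

    def test_hand_evaluated_fac_and_fs(self):
        p = HeartSimParams(a_ed_um=100, b_ed_um=60,
                           contraction_long=0.2, contraction_short=0.3)
        ind = expected_indicators(p)
        assert ind.fs == pytest.approx(0.3, rel=1e-12)
        assert ind.fac == pytest.approx(1 - 0.8 * 0.7, rel=1e-12)

    def test_invariant_to_imaging_and_noise_settings(self, default_params):
        noisy = dataclasses.replace(default_params, pixel_size_um=1.0,
                                    frame_interval_s=0.01, noise_sd=50.0,
                                    poisson_noise=True, psf_sigma_px=3.0)
        assert expected_indicators(noisy) == expected_indicators(default_params)


class TestRenderSequence:
    def test_determinism_bit_identical(self):
        p = HeartSimParams(noise_sd=20.0, poisson_noise=True, n_frames=10)
        seq1, _ = render_sequence(p, seed=42)
        seq2, _ = render_sequence(p, seed=42)
        assert seq1.frames.tobytes() == seq2.frames.tobytes()

    def test_noiseless_raster_area_within_2pct_of_analytic(self):
        p = HeartSimParams(noise_sd=0.0, psf_sigma_px=0.0, n_frames=2)
        seq, truth = render_sequence(p, seed=0)
        mask = segment_heart_frame(
            seq.frames[0], SegmentationConfig(threshold_method="fixed",
                                              fixed_threshold=550.0))
        area_um2 = mask.sum() * p.pixel_size_um ** 2
        assert area_um2 == pytest.approx(truth[0].area_um2, rel=0.02)

    def test_ground_truth_trace_has_one_maximum_per_cycle_start(self):
        # 2 Hz over the half-open 3 s record: cycle starts 0.0 .. 2.5 -> 6
        p = HeartSimParams(beat_freq_hz=2.0, n_frames=90,
                           frame_interval_s=1 / 30)
        _, truth = render_sequence(p, seed=0)
        areas = np.array([g.area_um2 for g in truth])
        interior = find_peaks(areas)[0]
        n_maxima = len(interior) + int(areas[0] > areas[1])
        assert n_maxima == 6

    def test_canvas_overflow_raises(self, default_params):
        with pytest.raises(CanvasOverflowError):
            render_sequence(default_params, seed=0, shape=(32, 32))

    def test_validation_rejects_inverted_axes(self):
        with pytest.raises(ValueError):
            render_sequence(HeartSimParams(a_ed_um=50, b_ed_um=60), seed=0)


class TestCohorts:
    @staticmethod
    def _grid_spec(rhos, n=1, cv=0.0):
        groups = {"control": GroupEffectSpec(), "model": DEFAULT_MODEL_EFFECT}
        for rho in rhos:
            groups[f"rho{rho:g}"] = GroupEffectSpec(recovery=rho)
        return CohortSpec(n_per_group=n, groups=groups, seed=5,
                          inter_fish_cv=cv)

    def test_full_recovery_reproduces_control_truth(self):
        fishes = generate_cohort(self._grid_spec([1.0]))
        by_group = {f.group: f for f in fishes}
        ctrl, treat = by_group["control"].truth, by_group["rho1"].truth
        for k, v in ctrl.as_dict().items():
            assert treat.as_dict()[k] == pytest.approx(v, rel=1e-9), k

    def test_zero_recovery_reproduces_model_truth(self):
        fishes = generate_cohort(self._grid_spec([0.0]))
        by_group = {f.group: f for f in fishes}
        model, treat = by_group["model"].truth, by_group["rho0"].truth
        for k, v in model.as_dict().items():
            assert treat.as_dict()[k] == pytest.approx(v, rel=1e-9), k

    def test_manifest_row_count(self):
        fishes = generate_cohort(self._grid_spec([0.25, 0.5, 0.75], n=2))
        assert len(cohort_manifest(fishes)) == 2 * 5

    def test_jitter_is_reproducible_and_mean_one(self):
        spec = self._grid_spec([], n=6, cv=0.10)
        hrs1 = [f.truth.hr_bpm for f in generate_cohort(spec)]
        hrs2 = [f.truth.hr_bpm for f in generate_cohort(spec)]
        assert hrs1 == hrs2
        assert len(set(hrs1)) > 1  # jitter actually varies between fish

    def test_missing_model_group_rejected(self):
        spec = CohortSpec(groups={"control": GroupEffectSpec()})
        with pytest.raises(Exception, match="model"):
            generate_cohort(spec)
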