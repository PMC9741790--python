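"""WHOLE/SEGM/NORM/ZERO contracts."""

import numpy as np
import pytest

from gaitent.errors import (
    DegenerateCycleError,
    LengthError,
    ParameterError,
    SegmentationError,
    StructureError,
    VariableError,
)
from gaitent.preprocess import (
    ProcessedSignal,
    make_whole,
    normalize_spatial,
    segment_resample,
    zero_cycles,
)
from gaitent.segmentation import StrideSegmentation, segment_strides, trim_first_last
from gaitent.synthetic import GaitParams, generate_recording


@pytest.fixture
def segmented(noisy_params):
    rec = generate_recording(noisy_params)
    seg = segment_strides(rec)
    return trim_first_last(rec, seg)


def _segm(values, spc, n_cyc, variable="copap"):
    return ProcessedSignal(
        values=np.asarray(values, float), type_tag="SEGM", variable=variable,
        samples_per_cycle=spc, n_cycles=n_cyc,
    )


class TestWhole:
    def test_truncates_to_n_points(self, segmented):
        rec, _ = segmented
        sig = make_whole(rec, "copap", 2200)
        assert len(sig.values) == 2200
        np.testing.assert_array_equal(sig.values, rec.copap[:2200])

    def test_full_length_is_identity(self, segmented):
        rec, _ = segmented
        sig = make_whole(rec, "vgrf", rec.n_samples)
        np.testing.assert_array_equal(sig.values, rec.vgrf)

    def test_too_short_reports_both_lengths(self, segmented):
        rec, _ = segmented
        with pytest.raises(LengthError) as exc:
            make_whole(rec, "copml", rec.n_samples + 1)
        assert exc.value.needed == rec.n_samples + 1
        assert exc.value.available == rec.n_samples

    def test_zero_points_rejected(self, segmented):
        rec, _ = segmented
        with pytest.raises(ParameterError):
            make_whole(rec, "copap", 0)


class TestSegmResample:
    def test_length_contract(self, segmented):
        rec, seg = segmented
        sig = segment_resample(rec, seg, "copap", samples_per_cycle=100, n_cycles=8)
        assert len(sig.values) == 800
        assert sig.samples_per_cycle == 100 and sig.n_cycles == 8

    def test_exact_length_cycle_is_unchanged(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=300)
        seg = StrideSegmentation(
            boundaries=np.array([0, 100, 200, 300]),
            stride_durations=np.array([1.0, 1.0, 1.0]),
            source_rate=100.0,
        )
        from gaitent.synthetic import GaitRecording

        rec = GaitRecording(sampling_rate=100.0, copap=x, copml=x, vgrf=np.abs(x))
        sig = segment_resample(rec, seg, "copap", samples_per_cycle=100, n_cycles=3)
        np.testing.assert_allclose(sig.values, x, atol=1e-9)

    def test_linear_ramp_stays_linear(self):
        from gaitent.synthetic import GaitRecording

        ramp = np.arange(73, dtype=float)
        rec = GaitRecording(sampling_rate=100.0, copap=ramp, copml=ramp, vgrf=ramp)
        seg = StrideSegmentation(
            boundaries=np.array([0, 73]), stride_durations=np.array([0.73]), source_rate=100.0
        )
        sig = segment_resample(rec, seg, "copap", samples_per_cycle=100, n_cycles=1)
        expected = np.linspace(0.0, 72.0, 100)
        np.testing.assert_allclose(sig.values, expected, atol=1e-9)

    def test_too_few_cycles_errors(self, segmented):
        rec, seg = segmented
        with pytest.raises(SegmentationError):
            segment_resample(rec, seg, "copap", n_cycles=seg.n_strides + 1)


class TestNorm:
    def test_every_cycle_spans_unit_interval(self, segmented):
        rec, seg = segmented
        sig = segment_resample(rec, seg, "copap")
        norm = normalize_spatial(sig)
        cyc = norm.cycles()
        np.testing.assert_allclose(cyc.min(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(cyc.max(axis=1), 1.0, atol=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=100)
        sig = _segm(np.concatenate([base, 2.5 * base + 7.0]), 100, 2)
        norm = normalize_spatial(sig)
        cyc = norm.cycles()
        np.testing.assert_allclose(cyc[0], cyc[1], atol=1e-12)

    def test_constant_cycle_identified(self):
        sig = _segm(np.concatenate([np.arange(50.0), np.full(50, 3.0)]), 50, 2)
        with pytest.raises(DegenerateCycleError) as exc:
            normalize_spatial(sig)
        assert exc.value.cycle_index == 1

    def test_vgrf_rejected(self, segmented):
        rec, seg = segmented
        sig = segment_resample(rec, seg, "vgrf")
        with pytest.raises(VariableError):
            normalize_spatial(sig)


class TestZero:
    def test_cycles_translated_to_origin(self, segmented):
        rec, seg = segmented
        ap = segment_resample(rec, seg, "copap")
        ml = segment_resample(rec, seg, "copml")
        z_ap, z_ml = zero_cycles(ap, ml)
        assert np.all(z_ap.cycles()[:, 0] == 0.0)
        assert np.all(z_ml.cycles()[:, 0] == 0.0)

    def test_first_differences_preserved(self, segmented):
        rec, seg = segmented
        ap = segment_resample(rec, seg, "copap")
        ml = segment_resample(rec, seg, "copml")
        z_ap, _ = zero_cycles(ap, ml)
        before = np.diff(ap.cycles(), axis=1)
        after = np.diff(z_ap.cycles(), axis=1)
        np.testing.assert_allclose(after, before, atol=1e-12)

    def test_drift_only_signal_zeroes_to_identical_cycles(self):
        """Equal-duration cycles on a pure linear trend translate onto the
        same segment, so ZERO removes the drift exactly."""
        params = GaitParams(
            stride_time_cv=0.0, waveform_noise_sd=0.0, within_cycle_shape_jitter=0.0,
            drift_rate=1.0, n_strides=10,
        )
        rec = generate_recording(params)
        seg = segment_strides(rec)
        rec_t, seg_t = trim_first_last(rec, seg)
        ap = segment_resample(rec_t, seg_t, "copap")
        ml = segment_resample(rec_t, seg_t, "copml")
        z_ap, z_ml = zero_cycles(ap, ml)
        for z in (z_ap, z_ml):
            cyc = z.cycles()
            assert np.max(np.abs(cyc - cyc[0])) < 1e-9

    def test_mismatched_structure_errors(self):
        ap = _segm(np.arange(200.0), 100, 2, "copap")
        ml = _segm(np.arange(100.0), 100, 1, "copml")
        with pytest.raises(StructureError):
            zero_cycles(ap, ml)

    def test_vgrf_rejected(self, segmented):
        rec, seg = segmented
        v = segment_resample(rec, seg, "vgrf")
        ml = segment_resample(rec, seg, "copml")
        with pytest.raises((VariableError, StructureError)):
            zero_cycles(v, ml)
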