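"""SVM computation, noise filtering, and per-recording normalisation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gaitwalk as gw
from gaitwalk.preprocess import SvmSeries

finite = st.floats(min_value=-50, max_value=50, allow_nan=False, allow_infinity=False)


@pytest.mark.parametrize("axes, expected", [
    ((3, 4, 0), 5.0),
    ((0, 0, 0), 0.0),
    ((1, 2, 2), 3.0),
])
def test_svm_worked_examples(axes, expected):
    assert gw.compute_svm(*axes) == pytest.approx(expected)


@settings(derandomize=True, max_examples=200, deadline=None)
@given(ax=finite, ay=finite, az=finite)
def test_svm_invariant_under_axis_permutation_and_sign(ax, ay, az):
    base = gw.compute_svm(ax, ay, az)
    assert gw.compute_svm(az, ax, ay) == pytest.approx(base)
    assert gw.compute_svm(-ax, ay, -az) == pytest.approx(base)
    assert base >= 0


def test_svm_elementwise_and_nonfinite():
    out = gw.compute_svm([3, 0], [4, 0], [0, 0])
    assert np.allclose(out, [5, 0])
    with pytest.raises(gw.ValidationError):
        gw.compute_svm(np.nan, 1, 2)


def _series(values, fs=100.0, normalized=False):
    return SvmSeries(values=np.asarray(values, float), source="accel",
                     sample_rate_hz=fs, normalized=normalized)


class TestFilter:
    def test_constant_series_preserved(self):
        x = _series(np.full(200, 7.0))
        for spec in (gw.FilterSpec(), gw.FilterSpec(kind="moving_average", window=5)):
            y = gw.filter_svm(x, spec)
            assert np.allclose(y.values, 7.0)
            assert len(y) == len(x)

    def test_impulse_through_moving_average(self):
        x = np.zeros(51)
        x[25] = 1.0
        y = gw.filter_svm(_series(x), gw.FilterSpec(kind="moving_average", window=5))
        assert np.allclose(y.values[23:28], 0.2)
        assert np.allclose(y.values[:23], 0.0) and np.allclose(y.values[28:], 0.0)

    def test_lowpass_attenuates_spike_noise(self):
        # 2 Hz gait-band sinusoid plus spike noise; 6 Hz low-pass must get
        # closer to the clean signal than the noisy input is
        rng = np.random.default_rng(0)
        t = np.arange(0, 10, 0.01)
        clean = 10 + np.sin(2 * np.pi * 2 * t)
        noisy = clean + rng.normal(0, 1.0, t.size) * (rng.random(t.size) < 0.1)
        filtered = gw.filter_svm(_series(noisy), gw.FilterSpec(cutoff_hz=6.0))
        rms_noisy = np.sqrt(np.mean((noisy - clean) ** 2))
        rms_filtered = np.sqrt(np.mean((filtered.values - clean) ** 2))
        assert rms_filtered < rms_noisy

    def test_too_short_series_rejected(self):
        with pytest.raises(gw.ValidationError):
            gw.filter_svm(_series(np.ones(10)))
        with pytest.raises(gw.ValidationError):
            gw.filter_svm(_series(np.ones(4)), gw.FilterSpec(kind="moving_average", window=5))

    def test_length_never_increases(self, sim_recording):
        raw = gw.svm_series(sim_recording)
        assert len(gw.filter_svm(raw)) == len(raw)


class TestNormalize:
    def test_zscore_definition(self, sim_recording):
        y = gw.normalize_svm(gw.svm_series(sim_recording))
        assert abs(float(np.mean(y.values))) < 1e-9
        assert float(np.std(y.values)) == pytest.approx(1.0, abs=1e-9)
        assert y.normalized

    def test_idempotent_on_standardized_input(self):
        x = np.array([10.0, 20.0, 30.0])
        z = (x - x.mean()) / x.std()
        out = gw.normalize_svm(_series(z, normalized=True))
        assert np.allclose(out.values, z, atol=1e-9)

    def test_hand_computed_population_zscore(self):
        out = gw.normalize_svm(_series([10.0, 20.0, 30.0]))
        expected = np.array([-1.22474487, 0.0, 1.22474487])
        assert np.allclose(out.values, expected, atol=1e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(gw.ValidationError):
            gw.normalize_svm(_series(np.full(10, 3.0)))


def test_filter_normalize_order_is_fixed_and_commutes_for_linear_filter():
    # the moving average is linear, so filter-then-normalize equals
    # normalize-then-filter; this justifies but does not replace the
    # fixed filter -> normalize pipeline order
    rng = np.random.default_rng(1)
    x = 10 + np.abs(rng.normal(2, 1, 300))
    spec = gw.FilterSpec(kind="moving_average", window=5)
    a = gw.normalize_svm(gw.filter_svm(_series(x), spec))
    b = gw.filter_svm(gw.normalize_svm(_series(x)), spec)
    # same shape up to the affine rescaling the order changes
    corr = np.corrcoef(a.values, b.values)[0, 1]
    assert corr > 0.9999


def test_negative_raw_svm_rejected():
    with pytest.raises(gw.ValidationError):
        _series([-1.0, 2.0])


def test_svm_series_source_validation(sim_recording):
    with pytest.raises(gw.ValidationError):
        gw.svm_series(sim_recording, source="magnetometer")
    gyro = gw.svm_series(sim_recording, source="gyro")
    assert len(gyro) == sim_recording.n_samples
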