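"""Simulator: block structure, noise moments, HRF shape, trimming."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mvpasim as m
from mvpasim.sim_core import hrf_kernel


class TestDesign:
    def test_volume_arithmetic(self, design160, design480):
        assert design160.total_volumes == 160
        assert design160.retained_volumes == 80
        assert design480.total_volumes == 480
        assert design480.retained_volumes == 240

    @pytest.mark.parametrize("kwargs", [
        dict(tr_seconds=-1), dict(volumes_per_block=0),
        dict(block_seconds=30.0),                 # 16 * 2 != 30
        dict(trim_volumes=16), dict(trim_volumes=-1),
        dict(reps_per_class=0),
    ])
    def test_invalid_designs_rejected(self, kwargs):
        with pytest.raises(m.ConfigurationError):
            m.ExperimentDesign(**kwargs)


class TestBlockLabels:
    def test_smallest_design(self):
        design = m.ExperimentDesign(reps_per_class=1, trim_volumes=0)
        labels, block_ids = m.build_block_labels(design)
        assert list(labels) == ["A"] * 16 + ["B"] * 16
        assert set(block_ids) == {0, 1}

    @settings(deadline=None, derandomize=True)
    @given(reps=st.integers(1, 6), vpb=st.sampled_from([2, 4, 8, 16]))
    def test_structure_properties(self, reps, vpb):
        design = m.ExperimentDesign(block_seconds=2.0 * vpb,
                                    volumes_per_block=vpb,
                                    reps_per_class=reps, trim_volumes=0)
        labels, block_ids = m.build_block_labels(design)
        assert labels.size == design.total_volumes
        assert np.sum(labels == "A") == np.sum(labels == "B")
        assert np.unique(block_ids).size == 2 * reps
        # strict ABAB alternation of block classes
        per_block = [labels[block_ids == b][0] for b in np.unique(block_ids)]
        assert per_block == ["A", "B"] * reps
        # labels constant within each block
        for b in np.unique(block_ids):
            assert np.unique(labels[block_ids == b]).size == 1


class TestNullNeural:
    def test_shape_and_determinism(self, design160):
        ts1 = m.sample_null_neural(design160, 64, seed=7)
        ts2 = m.sample_null_neural(design160, 64, seed=7)
        assert ts1.data.shape == (160, 64)
        assert ts1.stage == "neural"
        np.testing.assert_array_equal(ts1.data, ts2.data)
        ts3 = m.sample_null_neural(design160, 64, seed=8)
        assert not np.array_equal(ts1.data, ts3.data)

    def test_standard_normal_moments(self, design160):
        ts = m.sample_null_neural(design160, 625, seed=1)  # 1e5 entries
        x = ts.data.ravel()
        n = x.size
        assert abs(x.mean()) < 4 / np.sqrt(n)
        assert abs(x.var() - 1) < 4 * np.sqrt(2 / n)

    def test_data_independent_of_labels(self, design160):
        # per-voxel correlation with a +/-1 label code, pooled over
        # 200 independent null datasets, centres on zero
        corrs = []
        for seed in range(200):
            ts = m.sample_null_neural(design160, 8, seed=seed)
            code = np.where(ts.labels == "A", 1.0, -1.0)
            z = (ts.data - ts.data.mean(0)) / ts.data.std(0)
            corrs.extend(z.T @ (code - code.mean()) / ts.n_timepoints)
        corrs = np.asarray(corrs)
        se = corrs.std(ddof=1) / np.sqrt(corrs.size)
        assert abs(corrs.mean()) < 4 * se


class TestClassPatterns:
    def test_zero_signal_gives_zero_patterns(self):
        pa, pb = m.make_class_patterns(50, m.SignalSpec(s=0.0), seed=3)
        assert not pa.any() and not pb.any()

    def test_pattern_standard_deviation(self):
        pa, _ = m.make_class_patterns(100_000, m.SignalSpec(s=0.1), seed=4)
        se = 0.1 * np.sqrt(0.5 / pa.size)  # SE of a normal sd estimate
        assert abs(pa.std() - 0.1) < 4 * se

    def test_smoothing_induces_gaussian_autocorrelation(self):
        # white noise through a Gaussian kernel of sd sigma has lag-d
        # autocorrelation exp(-d^2 / (4 sigma^2))
        sigma = 3.0
        pa, _ = m.make_class_patterns(100_000,
                                      m.SignalSpec(s=1.0, spatial_sigma=sigma),
                                      seed=5)
        z = (pa - pa.mean()) / pa.std()
        for d in (1, 2, 4, 6):
            r = np.mean(z * np.roll(z, d))
            assert r == pytest.approx(np.exp(-d ** 2 / (4 * sigma ** 2)),
                                      abs=0.02)

    def test_negative_parameters_rejected(self):
        with pytest.raises(m.ConfigurationError):
            m.SignalSpec(s=-0.1)
        with pytest.raises(m.ConfigurationError):
            m.SignalSpec(s=0.1, spatial_sigma=-1.0)


class TestInjectSignal:
    def test_zero_pattern_is_identity(self, design160):
        neural = m.sample_null_neural(design160, 5, seed=9)
        out = m.inject_signal(neural, (np.zeros(5), np.zeros(5)))
        np.testing.assert_array_equal(out.data, neural.data)

    def test_single_voxel_offsets(self):
        design = m.ExperimentDesign(reps_per_class=1, trim_volumes=0)
        labels, block_ids = m.build_block_labels(design)
        neural = m.LabeledTimeseries(data=np.zeros((32, 1)), labels=labels,
                                     block_ids=block_ids, stage="neural",
                                     tr_seconds=2.0)
        out = m.inject_signal(neural, (np.array([1.0]), np.array([-1.0])))
        np.testing.assert_array_equal(out.data[labels == "A", 0], 1.0)
        np.testing.assert_array_equal(out.data[labels == "B", 0], -1.0)

    def test_class_mean_difference_recovers_pattern(self):
        design = m.ExperimentDesign(reps_per_class=100)  # 1600/class
        neural = m.sample_null_neural(design, 4, seed=10)
        pa = np.array([0.5, -0.2, 0.0, 1.0])
        pb = np.array([-0.5, 0.1, 0.3, 0.0])
        out = m.inject_signal(neural, (pa, pb))
        diff = (out.data[out.labels == "A"].mean(0)
                - out.data[out.labels == "B"].mean(0))
        n_per_class = 1600
        tol = 4 * np.sqrt(2 / n_per_class)
        np.testing.assert_allclose(diff, pa - pb, atol=tol)

    def test_dimension_mismatch(self, design160):
        neural = m.sample_null_neural(design160, 5, seed=9)
        with pytest.raises(ValueError):
            m.inject_signal(neural, (np.zeros(4), np.zeros(5)))


class TestHRFKernel:
    def test_zero_at_origin_and_unit_peak(self):
        k = m.hrf_kernel(m.HRFSpec(), tr_seconds=2.0)
        assert k[0] == 0.0
        assert k.max() == 1.0
        assert np.all(k >= 0)

    def test_peak_location_is_w_a_b(self):
        # continuous-time maximum of t^a exp(-t/b) sits at t = a*b
        for w in (0.5, 1.0, 1.5):
            spec = m.HRFSpec(width_scale=w)
            k = m.hrf_kernel(spec, tr_seconds=0.002)
            assert np.argmax(k) * 0.002 == pytest.approx(w * 8.6 * 0.547,
                                                         abs=0.005)

    def test_width_scale_stretches_fwhm(self):
        def fwhm(w):
            k = m.hrf_kernel(m.HRFSpec(width_scale=w), tr_seconds=0.01)
            above = np.nonzero(k >= 0.5)[0]
            return (above[-1] - above[0]) * 0.01

        widths = [fwhm(w) for w in (0.5, 1.0, 1.5)]
        assert widths[0] < widths[1] < widths[2]
        # time-axis stretch scales the FWHM proportionally
        assert widths[2] / widths[1] == pytest.approx(1.5, rel=0.02)

    def test_support_too_short_rejected(self):
        with pytest.raises(m.ConfigurationError):
            m.hrf_kernel(m.HRFSpec(support_seconds=2.0), tr_seconds=2.0)

    def test_boxcar_duration(self):
        k = m.hrf_kernel(m.HRFSpec(family="boxcar", width_scale=1.0),
                         tr_seconds=2.0)
        assert np.sum(k == 1.0) == 8  # 16 s at TR 2


class TestConvolution:
    def test_impulse_reproduces_kernel(self, design160):
        kernel = hrf_kernel(m.HRFSpec(), 2.0)
        labels, block_ids = m.build_block_labels(design160)
        data = np.zeros((160, 1))
        data[0, 0] = 1.0
        neural = m.LabeledTimeseries(data=data, labels=labels,
                                     block_ids=block_ids, stage="neural",
                                     tr_seconds=2.0)
        bold = m.convolve_with_hrf(neural, m.HRFSpec())
        np.testing.assert_allclose(bold.data[: kernel.size, 0], kernel,
                                   atol=1e-12)
        np.testing.assert_allclose(bold.data[kernel.size:, 0], 0, atol=1e-12)

    def test_linearity(self, design160):
        x = m.sample_null_neural(design160, 3, seed=11)
        y = m.sample_null_neural(design160, 3, seed=12)
        both = m.LabeledTimeseries(data=x.data + y.data, labels=x.labels,
                                   block_ids=x.block_ids, stage="neural",
                                   tr_seconds=2.0)
        spec = m.HRFSpec()
        np.testing.assert_allclose(
            m.convolve_with_hrf(both, spec).data,
            m.convolve_with_hrf(x, spec).data
            + m.convolve_with_hrf(y, spec).data, atol=1e-10)

    def test_constant_input_steady_state(self, design160):
        kernel = hrf_kernel(m.HRFSpec(), 2.0)
        labels, block_ids = m.build_block_labels(design160)
        neural = m.LabeledTimeseries(data=np.full((160, 1), 3.0),
                                     labels=labels, block_ids=block_ids,
                                     stage="neural", tr_seconds=2.0)
        bold = m.convolve_with_hrf(neural, m.HRFSpec())
        np.testing.assert_allclose(bold.data[kernel.size:, 0],
                                   3.0 * kernel.sum(), rtol=1e-10)

    def test_temporal_autocorrelation_by_stage(self, design160):
        neural = m.sample_null_neural(design160, 200, seed=13)
        bold = m.convolve_with_hrf(neural, m.HRFSpec())

        def mean_lag1(data):
            z = (data - data.mean(0)) / data.std(0)
            return np.mean(np.sum(z[1:] * z[:-1], axis=0) / data.shape[0])

        n_eff = 159 * 200
        assert abs(mean_lag1(neural.data)) < 4 / np.sqrt(n_eff)
        assert mean_lag1(bold.data) > 0.2


class TestTrimming:
    def test_retained_counts(self, design160):
        ts = m.simulate_dataset(design160, 4, seed=14)
        assert ts.n_timepoints == 80
        assert np.sum(ts.labels == "A") == np.sum(ts.labels == "B") == 40
        for b in ts.block_list():
            assert np.sum(ts.block_ids == b) == design160.retained_per_block

    def test_trim_zero_is_identity(self):
        design = m.ExperimentDesign(trim_volumes=0)
        neural = m.sample_null_neural(design, 3, seed=15)
        bold = m.convolve_with_hrf(neural, m.HRFSpec())
        trimmed = m.trim_initial_volumes(bold, design)
        np.testing.assert_array_equal(trimmed.data, bold.data)
        assert trimmed.stage == "bold_trimmed"

    def test_trimming_requires_bold_stage(self, design160):
        neural = m.sample_null_neural(design160, 3, seed=16)
        with pytest.raises(ValueError):
            m.trim_initial_volumes(neural, design160)


def test_simulate_dataset_is_pure_function_of_seed(design160):
    a = m.simulate_dataset(design160, 8, signal=m.SignalSpec(s=0.1), seed=17)
    b = m.simulate_dataset(design160, 8, signal=m.SignalSpec(s=0.1), seed=17)
    c = m.simulate_dataset(design160, 8, signal=m.SignalSpec(s=0.1), seed=18)
    np.testing.assert_array_equal(a.data, b.data)
    assert not np.array_equal(a.data, c.data)
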