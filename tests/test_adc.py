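import math

import numpy as np
import pytest

from adcfmri import (
    AcquisitionScheme,
    VolumeSeries,
    compute_adc,
    highpass_filter,
    interpolate_pairwise_adc,
    split_interleaved,
)
from adcfmri.adc import reinterleave


def make_dw(data, scheme=None, n=None):
    scheme = scheme or AcquisitionScheme()
    n = n if n is not None else data.shape[-1]
    return VolumeSeries(
        data=data, tr_s=1.0, contrast="dw_interleaved", bvals=scheme.bval_vector(n)
    )


@pytest.fixture
def scheme():
    return AcquisitionScheme()


class TestSplit:
    def test_paper_series_splits_into_252_at_2s(self, scheme, rng):
        dw = make_dw(rng.uniform(500, 1500, size=(4, 4, 2, 504)))
        low, high = split_interleaved(dw, scheme)
        assert low.n_volumes == high.n_volumes == 252
        assert low.tr_s == high.tr_s == 2.0
        assert set(low.bvals) == {200.0} and set(high.bvals) == {1000.0}

    def test_index_bookkeeping(self, scheme, rng):
        dw = make_dw(rng.uniform(500, 1500, size=(2, 2, 1, 4)))
        low, high = split_interleaved(dw, scheme)
        np.testing.assert_array_equal(low.source_volume_indices, [0, 2])
        np.testing.assert_array_equal(high.source_volume_indices, [1, 3])
        np.testing.assert_array_equal(low.data, dw.data[..., [0, 2]])

    def test_non_alternating_vector_rejected_at_first_offense(self, rng):
        with pytest.raises(ValueError, match="index 1"):
            VolumeSeries(
                data=rng.uniform(1, 2, size=(2, 2, 1, 4)),
                tr_s=1.0,
                contrast="dw_interleaved",
                bvals=[200, 200, 1000, 1000],
            )

    def test_odd_length_rejected(self, scheme, rng):
        dw = VolumeSeries(
            data=rng.uniform(1, 2, size=(2, 2, 1, 5)),
            tr_s=1.0,
            contrast="dw_interleaved",
            bvals=[200, 1000, 200, 1000, 200],
        )
        with pytest.raises(ValueError, match="even"):
            split_interleaved(dw, scheme)

    def test_split_reinterleave_round_trip(self, scheme, rng):
        dw = make_dw(rng.uniform(500, 1500, size=(3, 3, 2, 20)))
        low, high = split_interleaved(dw, scheme)
        back = reinterleave(low, high)
        np.testing.assert_array_equal(back.data, dw.data)
        np.testing.assert_array_equal(back.bvals, dw.bvals)


class TestComputeADC:
    def test_equal_signals_give_zero(self, scheme):
        low = VolumeSeries(np.full((2, 2, 1, 4), 1000.0), 2.0, "dw_single",
                           bvals=np.full(4, 200.0))
        high = VolumeSeries(np.full((2, 2, 1, 4), 1000.0), 2.0, "dw_single",
                            bvals=np.full(4, 1000.0))
        adc = compute_adc(low, high, (200.0, 1000.0))
        np.testing.assert_array_equal(adc.data, 0.0)

    def test_monoexponential_recovers_planted_diffusivity(self):
        low = VolumeSeries(np.full((2, 2, 1, 4), 1000.0), 2.0, "dw_single",
                           bvals=np.full(4, 200.0))
        high = VolumeSeries(np.full((2, 2, 1, 4), 1000.0 * math.exp(-0.8)), 2.0,
                            "dw_single", bvals=np.full(4, 1000.0))
        adc = compute_adc(low, high, (200.0, 1000.0))
        np.testing.assert_allclose(adc.data, 1.0e-3, rtol=1e-14)

    def test_biexponential_matches_scalar_oracle(self):
        s0, d0, f0, ds = 1000.0, 0.7e-3, 0.1, 1e-2
        s_lo = s0 * ((1 - f0) * math.exp(-200 * d0) + f0 * math.exp(-200 * ds))
        s_hi = s0 * ((1 - f0) * math.exp(-1000 * d0) + f0 * math.exp(-1000 * ds))
        expected = math.log(s_lo / s_hi) / 800.0
        low = VolumeSeries(np.full((1, 1, 1, 2), s_lo), 2.0, "dw_single",
                           bvals=np.full(2, 200.0))
        high = VolumeSeries(np.full((1, 1, 1, 2), s_hi), 2.0, "dw_single",
                            bvals=np.full(2, 1000.0))
        adc = compute_adc(low, high, (200.0, 1000.0))
        np.testing.assert_allclose(adc.data, expected, rtol=1e-14)

    def test_common_multiplicative_factor_cancels(self, rng):
        base_low = rng.uniform(800, 1200, size=(3, 3, 1, 10))
        base_high = base_low * math.exp(-0.5)
        gain = rng.uniform(0.9, 1.1, size=10)  # shared time-varying factor
        low = VolumeSeries(base_low * gain, 2.0, "dw_single", bvals=np.full(10, 200.0))
        high = VolumeSeries(base_high * gain, 2.0, "dw_single", bvals=np.full(10, 1000.0))
        low0 = VolumeSeries(base_low, 2.0, "dw_single", bvals=np.full(10, 200.0))
        high0 = VolumeSeries(base_high, 2.0, "dw_single", bvals=np.full(10, 1000.0))
        a1 = compute_adc(low, high, (200.0, 1000.0)).data
        a0 = compute_adc(low0, high0, (200.0, 1000.0)).data
        np.testing.assert_allclose(a1, a0, atol=1e-15)

    def test_nonpositive_signal_flags_voxel_invalid(self):
        data = np.full((2, 1, 1, 4), 1000.0)
        data[0, 0, 0, 2] = 0.0
        low = VolumeSeries(data, 2.0, "dw_single", bvals=np.full(4, 200.0))
        high = VolumeSeries(np.full((2, 1, 1, 4), 500.0), 2.0, "dw_single",
                            bvals=np.full(4, 1000.0))
        adc = compute_adc(low, high, (200.0, 1000.0))
        assert not adc.valid_mask[0, 0, 0]
        assert adc.valid_mask[1, 0, 0]
        assert np.isnan(adc.data[0, 0, 0]).all()

    def test_mismatched_lengths_raise(self):
        low = VolumeSeries(np.ones((2, 2, 1, 4)), 2.0, "dw_single", bvals=np.full(4, 200.0))
        high = VolumeSeries(np.ones((2, 2, 1, 6)), 2.0, "dw_single", bvals=np.full(6, 1000.0))
        with pytest.raises(ValueError, match="length"):
            compute_adc(low, high, (200.0, 1000.0))


class TestInterpolatedADC:
    def test_constant_signals_equal_native_value(self, scheme, rng):
        dw = make_dw(np.full((2, 2, 1, 20), 0.0) + np.array(
            [1000.0 * math.exp(-0.2 * 0.7) if i % 2 == 0 else 1000.0 * math.exp(-0.7)
             for i in range(20)]))
        low, high = split_interleaved(dw, scheme)
        native = compute_adc(low, high, (200.0, 1000.0))
        interp = interpolate_pairwise_adc(low, high, (200.0, 1000.0))
        assert interp.interpolated and interp.tr_s == 1.0
        assert interp.n_volumes == 2 * native.n_volumes - 1
        np.testing.assert_allclose(interp.data, native.data[0, 0, 0, 0], rtol=1e-12)

    def test_linear_high_series_uses_exact_midpoint(self, scheme):
        n = 10
        lo_val = 1000.0
        hi_t = 500.0 + 5.0 * np.arange(n)  # linear in original volume index
        data = np.empty((1, 1, 1, n))
        data[..., 0::2] = lo_val
        data[..., 1::2] = hi_t[1::2]
        dw = make_dw(data)
        low, high = split_interleaved(dw, scheme)
        interp = interpolate_pairwise_adc(low, high, (200.0, 1000.0))
        # at interior b_low times (even t >= 2) the interpolated S_high is the
        # midpoint of its neighbors, which for a linear series is its own value
        for t in range(2, n - 1, 2):
            expected = math.log(lo_val / hi_t[t]) / 800.0
            assert interp.data[0, 0, 0, t] == pytest.approx(expected, rel=1e-12)

    def test_paper_defaults_give_503_samples(self, scheme, rng):
        dw = make_dw(rng.uniform(500, 1500, size=(2, 2, 1, 504)))
        low, high = split_interleaved(dw, scheme)
        interp = interpolate_pairwise_adc(low, high, (200.0, 1000.0))
        assert interp.n_volumes == 503


class TestHighpass:
    def test_long_period_drift_removed(self):
        # residual fluctuation; the drift's DC offset stays in the restored mean
        t = np.arange(252) * 2.0
        drift = np.sin(2 * np.pi * t / 200.0)
        out = highpass_filter(drift[None, None, None, :], 2.0, 100.0)
        assert np.abs(out - out.mean()).max() <= 0.10 * 1.0

    def test_epoch_frequency_preserved(self):
        t = np.arange(252) * 2.0
        task = np.sin(2 * np.pi * t / 40.0)
        out = highpass_filter(task[None, None, None, :], 2.0, 100.0)
        assert np.abs(out - out.mean()).max() >= 0.95

    def test_constant_series_unchanged(self):
        const = np.full((2, 2, 1, 100), 7.0)
        out = highpass_filter(const, 2.0, 100.0)
        np.testing.assert_allclose(out, 7.0, rtol=1e-12)

    def test_short_series_warns_and_passes_through(self):
        data = np.random.default_rng(0).normal(size=(1, 1, 1, 20))
        with pytest.warns(UserWarning, match="skipped"):
            out = highpass_filter(data, 2.0, 100.0)
        np.testing.assert_array_equal(out, data)

    def test_cutoff_must_exceed_nyquist_period(self):
        with pytest.raises(ValueError):
            highpass_filter(np.ones((1, 1, 1, 100)), 2.0, 3.0)


def test_noisefree_phantom_adc_recovers_planted_diffusivity(
    msc_noisefree_adc, label_map
):
    """The full generator->split->ADC chain returns the planted D(t)."""
    adc, truth = msc_noisefree_adc
    d_t = truth.region_waveforms["mSC"]["d"][::2]  # pair-resolution truth
    vox = adc.data[label_map.mask("mSC")]
    np.testing.assert_allclose(
        vox, np.broadcast_to(d_t, vox.shape), rtol=1e-12
    )
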