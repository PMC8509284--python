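"""Forward signal models and Rician noise tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from renalqmri import phantom as ph
from renalqmri import synthesis as syn


class TestSignalModels:
    def test_ir_long_ti_recovers_equilibrium(self):
        # TI >> T1 with TR >> T1: full recovery to ~m0
        s = syn.signal_ir(1000.0, 1e7, tr_ms=1e7, m0=2.0)
        assert s == pytest.approx(2.0, rel=1e-6)

    def test_ir_null_point(self):
        # ideal inversion, infinite TR: signal vanishes at TI = T1*ln 2
        t1 = 1304.0
        s = syn.signal_ir(t1, t1 * math.log(2), tr_ms=1e9, m0=1.0, inv_eff=1.0)
        assert s == pytest.approx(0.0, abs=1e-9)

    def test_ir_closed_form_value(self):
        # independent evaluation of the magnitude recovery formula
        expected = abs(1 - 2 * math.exp(-1000 / 1304) + math.exp(-18000 / 1304))
        s = syn.signal_ir(1304.0, 1000.0, tr_ms=18000.0, m0=1.0, inv_eff=1.0)
        assert s == pytest.approx(expected, rel=1e-12)

    def test_ir_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            syn.signal_ir(-5.0, 100.0)
        with pytest.raises(ValueError):
            syn.signal_ir(1000.0, 100.0, inv_eff=1.5)

    def test_t2_trivial_points(self):
        assert syn.signal_t2(42.0, 0.0, m0=3.0) == 3.0
        assert syn.signal_t2(42.0, 42.0, m0=1.0) == pytest.approx(1 / math.e)
        vals = syn.signal_t2(42.0, np.arange(11.0, 78.0, 11.0))
        assert np.all(np.diff(vals) < 0) and vals.size == 7

    def test_dwi_trivial_points(self):
        assert syn.signal_dwi(1.72e-3, 0.0, s0=5.0) == 5.0
        assert syn.signal_dwi(1.72e-3, 800.0) == pytest.approx(math.exp(-1.376), rel=1e-12)
        assert np.all(syn.signal_dwi(0.0, np.array([0.0, 400.0, 800.0])) == 1.0)

    @given(rate=st.floats(5.0, 500.0))
    @settings(max_examples=25, deadline=None)
    def test_decay_strictly_monotone(self, rate):
        te = np.linspace(1.0, 100.0, 12)
        assert np.all(np.diff(syn.signal_t2(rate, te)) < 0)
        b = np.linspace(0.0, 800.0, 8)
        assert np.all(np.diff(syn.signal_dwi(rate * 1e-5, b)) < 0)


class TestRicianNoise:
    def _series(self, value, n=20000):
        data = np.full((n, 1, 1, 1), float(value))
        return syn.AcquisitionSeries("DWI", data, np.array([0.0]), None, 1000.0, np.inf)

    def test_infinite_snr_is_identity(self):
        s = self._series(500.0, n=10)
        out = syn.add_rician_noise(s, np.inf, 0)
        assert np.array_equal(out.data, s.data)

    def test_zero_signal_gives_rayleigh_mean(self):
        s = self._series(0.0)
        out = syn.add_rician_noise(s, 40.0, seed=1)
        sigma = 1000.0 / 40.0
        assert out.data.mean() == pytest.approx(sigma * math.sqrt(math.pi / 2), rel=0.02)

    def test_high_snr_second_moment(self):
        # s/sigma = 40: E[magnitude] ~ sqrt(s^2 + 2 sigma^2) to o(1)
        s = self._series(1000.0, n=1_000_000)
        out = syn.add_rician_noise(s, 40.0, seed=2)
        sigma = 25.0
        assert out.data.mean() == pytest.approx(math.sqrt(1000.0**2 + 2 * sigma**2), rel=1e-3)

    def test_deterministic_given_seed(self):
        s = self._series(100.0, n=50)
        a = syn.add_rician_noise(s, 10.0, seed=3)
        b = syn.add_rician_noise(s, 10.0, seed=3)
        c = syn.add_rician_noise(s, 10.0, seed=4)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_rejects_nonpositive_snr(self):
        with pytest.raises(ValueError):
            syn.add_rician_noise(self._series(1.0, 2), 0.0, 0)


class TestAcquisitionSeries:
    def test_validation(self):
        data = np.zeros((4, 4, 1, 3))
        with pytest.raises(ValueError):
            syn.AcquisitionSeries("DWI", data, np.array([0.0, 2.0, 1.0]), None, 1.0, 40.0)
        with pytest.raises(ValueError):
            syn.AcquisitionSeries("DWI", data, np.array([0.0, 1.0]), None, 1.0, 40.0)
        with pytest.raises(ValueError):
            syn.AcquisitionSeries("DWI", -np.ones((4, 4, 1, 3)), np.array([0.0, 1.0, 2.0]), None, 1.0, 40.0)
        with pytest.raises(ValueError):
            syn.AcquisitionSeries("BOLD", data, np.array([0.0, 1.0, 2.0]), None, 1.0, 40.0)


class TestSynthesizeSubject:
    def test_noiseless_matches_closed_forms(self, control_params):
        phantom = ph.make_phantom(control_params, (64, 64), seed=0)
        proto = syn.Protocol(snr=np.inf)
        series = syn.synthesize_subject(phantom, proto, seed=0)
        i, j = map(int, np.argwhere(phantom.label_map == ph.ISOM)[0])
        np.testing.assert_allclose(
            series["t1"].data[i, j, 0],
            syn.signal_ir(1808.0, np.array(proto.ti_ms), proto.tr_ms, proto.s0_scale),
        )
        np.testing.assert_allclose(
            series["t2"].data[i, j, 0],
            syn.signal_t2(54.0, np.array(proto.te_ms), proto.s0_scale),
        )
        np.testing.assert_allclose(
            series["dwi"].data[i, j, 0],
            syn.signal_dwi(1.72e-3, np.array(proto.b_s_per_mm2), proto.s0_scale),
        )
        assert np.all(series["t1"].data[~phantom.tissue_mask] == 0)

    def test_default_protocol_axes(self, control_params):
        phantom = ph.make_phantom(control_params, (64, 64), seed=0)
        series = syn.synthesize_subject(phantom, syn.Protocol(), seed=0)
        assert series["t1"].param_axis.tolist() == list(syn.DEFAULT_TI_MS)
        assert series["t1"].tr_ms == 18000.0
        assert series["t2"].param_axis.tolist() == [11, 22, 33, 44, 55, 66, 77]
        assert series["dwi"].param_axis.tolist() == [0, 100, 200, 300, 400, 600, 800]

    def test_reproducible_and_noise_scale(self, control_params):
        phantom = ph.make_phantom(control_params, (64, 64), seed=0)
        proto = syn.Protocol(snr=40.0)
        a = syn.synthesize_subject(phantom, proto, seed=5)
        b = syn.synthesize_subject(phantom, proto, seed=5)
        assert all(np.array_equal(a[k].data, b[k].data) for k in a)
        # relative signal deviation at b=0 is ~1/SNR = 2.5%
        clean = syn.synthesize_subject(phantom, syn.Protocol(snr=np.inf), seed=5)
        dev = (a["dwi"].data[phantom.tissue_mask, 0, 0] - clean["dwi"].data[phantom.tissue_mask, 0, 0])
        assert dev.std() / proto.s0_scale == pytest.approx(1 / 40, rel=0.1)
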