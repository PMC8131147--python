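"""Wavelet denoising, segmentation, band energy, and scalp topography."""

import numpy as np
import pytest
import pywt
from hypothesis import given, settings, strategies as st

from emofuse import preprocessing as pp
from emofuse import synthetic as sy
from emofuse.montage import electrode_positions, frontal_mask


def make_raw(samples, fs=256.0):
    return pp.RawEEG(samples, fs)


def white_raw(rng, n=512, fs=256.0, sd=1.0):
    return make_raw(rng.normal(0, sd, size=(32, n)), fs)


class TestDenoise:
    def test_zero_threshold_is_identity_up_to_round_off(self, rng):
        raw = white_raw(rng)
        out = pp.denoise_wavelet_soft(raw, threshold_rule="none")
        err = np.abs(out.samples - raw.samples).max() / np.abs(raw.samples).max()
        assert err <= 1e-8

    def test_all_zero_signal_stays_zero(self):
        out = pp.denoise_wavelet_soft(make_raw(np.zeros((32, 256))))
        assert np.allclose(out.samples, 0.0)

    def test_noise_energy_reduced_at_0db_snr(self, rng):
        """DWT-coefficient oracle: soft thresholding removes more noise
        energy than signal energy on a 6 Hz tone at 0 dB SNR."""
        fs, n = 256.0, 1024
        t = np.arange(n) / fs
        clean = np.sqrt(2.0) * np.sin(2 * np.pi * 6.0 * t)  # power 1
        noise = rng.normal(0, 1.0, size=(32, n))  # power 1 -> SNR 0 dB
        raw = make_raw(clean[None] + noise, fs)
        out = pp.denoise_wavelet_soft(raw)
        resid_in = np.mean(noise**2)
        resid_out = np.mean((out.samples - clean[None]) ** 2)
        assert resid_out < resid_in
        # oracle cross-check: universal-threshold shrinkage of the DWT
        # details reduces coefficient noise energy
        coeffs = pywt.wavedec(raw.samples[0], "db4", level=4)
        sigma = np.median(np.abs(coeffs[-1])) / 0.6745
        lam = sigma * np.sqrt(2 * np.log(n))
        shrunk = [coeffs[0]] + [pywt.threshold(c, lam, "soft") for c in coeffs[1:]]
        oracle = pywt.waverec(shrunk, "db4")[:n]
        assert np.mean((oracle - clean) ** 2) < resid_in

    def test_too_deep_level_rejected(self, rng):
        with pytest.raises(ValueError, match="level"):
            pp.denoise_wavelet_soft(white_raw(rng, n=64), level=12)


class TestSegment:
    def test_counts_and_remainder(self):
        raw = make_raw(np.zeros((32, 2560)), fs=256.0)  # 10 s
        assert len(pp.segment(raw, 0.5)) == 20
        raw = make_raw(np.zeros((32, int(10.3 * 256))), fs=256.0)
        assert len(pp.segment(raw, 0.5)) == 20

    def test_concatenation_round_trip(self, rng):
        raw = white_raw(rng, n=2560)
        segs = pp.segment(raw, 0.5)
        rebuilt = np.concatenate([s.samples for s in segs], axis=1)
        assert np.array_equal(rebuilt, raw.samples[:, : rebuilt.shape[1]])
        assert [s.index for s in segs] == list(range(len(segs)))

    def test_invalid_durations_rejected(self, rng):
        raw = white_raw(rng)
        with pytest.raises(ValueError):
            pp.segment(raw, 0.0)
        with pytest.raises(ValueError):
            pp.segment(raw, 0.05)  # under 32 samples


class TestBandPower:
    def test_zero_signal_zero_power(self):
        seg = pp.EEGSegment(np.zeros((32, 256)), 1.0, 0, 256.0)
        assert np.allclose(pp.band_power(seg, "alpha"), 0.0)

    def test_parseval_alpha_concentration(self):
        """A unit-amplitude 10 Hz sinusoid (total power 0.5) puts its
        energy in the alpha band: alpha within 5% of total, beta and
        theta below 2% of total."""
        fs, dur = 128.0, 2.0
        t = np.arange(int(fs * dur)) / fs
        x = np.tile(np.sin(2 * np.pi * 10.0 * t), (32, 1))
        seg = pp.EEGSegment(x, dur, 0, fs)
        total = 0.5
        alpha = pp.band_power(seg, "alpha")[0]
        assert abs(alpha - total) / total < 0.05
        assert pp.band_power(seg, "beta")[0] < 0.02 * total
        assert pp.band_power(seg, "theta")[0] < 0.02 * total

    @settings(deadline=None, max_examples=20)
    @given(k=st.floats(0.1, 10.0))
    def test_quadratic_amplitude_scaling(self, k):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(32, 256))
        a = pp.band_power(pp.EEGSegment(x, 1.0, 0, 256.0), "beta")
        b = pp.band_power(pp.EEGSegment(k * x, 1.0, 0, 256.0), "beta")
        np.testing.assert_allclose(b, k**2 * a, rtol=1e-6)

    def test_band_beyond_nyquist_rejected(self):
        seg = pp.EEGSegment(np.zeros((32, 256)), 1.0, 0, 256.0)
        with pytest.raises(ValueError):
            pp.band_power(seg, (100.0, 140.0))


class TestTopoImage:
    def test_constant_field_gives_constant_image(self):
        img, mask = pp.topo_image(np.full(32, 3.7))
        assert np.allclose(img[mask], 3.7)
        assert np.allclose(img[~mask], 0.0)

    def test_single_hot_electrode_peaks_at_its_pixel(self):
        pos = electrode_positions()
        for e in (0, 13, 22):
            v = np.zeros(32)
            v[e] = 5.0
            img, mask = pp.topo_image(v)
            iy, ix = np.unravel_index(np.argmax(img), img.shape)
            grid = np.linspace(-1, 1, img.shape[0])
            px, py = grid[ix], grid[iy]
            d = np.hypot(px - pos[e, 0], py - pos[e, 1])
            assert d < 2.5 / img.shape[0]  # within ~one pixel of electrode

    def test_nearest_pixel_reproduces_electrode_value(self, rng):
        v = rng.uniform(1.0, 9.0, size=32)
        mapper = pp.TopoMapper(resolution=32)
        img = mapper(v)
        pos = mapper.positions
        grid = np.linspace(-1, 1, 32)
        for e in range(32):
            ix = np.argmin(np.abs(grid - pos[e, 0]))
            iy = np.argmin(np.abs(grid - pos[e, 1]))
            assert abs(img[iy, ix] - v[e]) < 1e-6

    def test_image_bounded_by_electrode_range(self, rng):
        v = rng.uniform(0.0, 4.0, size=32)
        img, mask = pp.topo_image(v)
        assert img[mask].min() >= v.min() - 1e-9
        assert img[mask].max() <= v.max() + 1e-9

    def test_duplicate_positions_rejected(self):
        pos = electrode_positions().copy()
        pos[1] = pos[0]
        with pytest.raises(ValueError, match="duplicate"):
            pp.TopoMapper(pos)

    def test_linear_mapper_matches_direct_interpolation_oracle(self, rng):
        """The precomputed basis map agrees with scipy's direct linear
        interpolant away from the snapped electrode pixels (the linear
        interpolant is exactly linear in the electrode values)."""
        from scipy.interpolate import LinearNDInterpolator

        v = rng.uniform(1.0, 3.0, size=32)
        mapper = pp.TopoMapper(resolution=24, method="linear")
        img = mapper(v)
        grid = np.linspace(-1, 1, 24)
        gx, gy = np.meshgrid(grid, grid, indexing="xy")
        direct = LinearNDInterpolator(mapper.positions, v)(
            np.column_stack([gx.ravel(), gy.ravel()])
        ).reshape(24, 24)
        ok = np.isfinite(direct)
        diff = np.abs(img - direct)[ok]
        # all but the 32 snapped electrode pixels agree to round-off
        assert (diff > 1e-9).sum() <= 32

    def test_cubic_mapper_is_linear_in_values(self, rng):
        """The precomputed cubic map is linear in the electrode vector
        (before clipping), so superposition holds."""
        mapper = pp.TopoMapper(resolution=16)
        a = rng.uniform(1.0, 2.0, size=32)
        b = rng.uniform(1.0, 2.0, size=32)
        lhs = (a + b) @ mapper.weights
        rhs = a @ mapper.weights + b @ mapper.weights
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)


class TestPipelineComposition:
    def test_frontal_beta_exceeds_alpha_at_high_arousal(self):
        """On synthetic trials the frontal beta image outshines the alpha
        image at high activation, and the reverse at low (>=80% of 50)."""
        cfg = sy.SynthConfig(n_trials=1, seed=31)
        mapper = pp.TopoMapper()
        pos = mapper.positions
        grid = np.linspace(-1, 1, mapper.resolution)
        fm = frontal_mask()
        fpix = [
            (np.argmin(np.abs(grid - y)), np.argmin(np.abs(grid - x)))
            for (x, y), f in zip(pos, fm) if f
        ]

        def frontal_mean(img):
            return np.mean([img[iy, ix] for iy, ix in fpix])

        hits = {0: 0, 2: 0}
        n = 25
        for lvl in (0, 2):
            for ts in range(n):
                raw = sy.generate_eeg_trial(cfg, sy.EmotionLabel(lvl, 1), ts)
                images = pp.trial_to_band_images(raw, T=0.2, mapper=mapper)
                alpha = np.mean([frontal_mean(im) for im in images[:, 0]])
                beta = np.mean([frontal_mean(im) for im in images[:, 1]])
                if lvl == 2 and beta > alpha:
                    hits[2] += 1
                if lvl == 0 and alpha > beta:
                    hits[0] += 1
        assert hits[2] >= 0.8 * n
        assert hits[0] >= 0.8 * n


class TestEDFReader:
    @staticmethod
    def _write_minimal_edf(path, data_uv, fs, names):
        """Hand-assembled EDF: ASCII headers + int16 little-endian records."""
        n_ch, n_samp = data_uv.shape
        phys_min, phys_max = -200.0, 200.0
        dig_min, dig_max = -32768, 32767

        def field(text, width):
            return f"{text:<{width}}"[:width].encode("ascii")

        hdr = b"".join([
            field("0", 8), field("X", 80), field("X", 80),
            field("01.01.20", 8), field("00.00.00", 8),
            field(str(256 + 256 * n_ch), 8), field("", 44),
            field("1", 8), field(str(n_samp / fs), 8), field(str(n_ch), 4),
        ])
        sig = b"".join([
            b"".join(field(n, 16) for n in names),
            b"".join(field("AgAgCl", 80) for _ in names),
            b"".join(field("uV", 8) for _ in names),
            b"".join(field(str(phys_min), 8) for _ in names),
            b"".join(field(str(phys_max), 8) for _ in names),
            b"".join(field(str(dig_min), 8) for _ in names),
            b"".join(field(str(dig_max), 8) for _ in names),
            b"".join(field("", 80) for _ in names),
            b"".join(field(str(n_samp), 8) for _ in names),
            b"".join(field("", 32) for _ in names),
        ])
        gain = (dig_max - dig_min) / (phys_max - phys_min)
        digital = np.round((data_uv - phys_min) * gain + dig_min).astype("<i2")
        with open(path, "wb") as fh:
            fh.write(hdr + sig + digital.tobytes())

    def test_round_trips_signals_and_rate(self, tmp_path, rng):
        from emofuse.montage import CHANNEL_NAMES

        fs, n = 128.0, 256
        t = np.arange(n) / fs
        data = 50.0 * np.sin(2 * np.pi * 10.0 * t)[None] + rng.normal(
            0, 5.0, size=(32, n)
        )
        path = tmp_path / "trial.edf"
        self._write_minimal_edf(path, data, fs, CHANNEL_NAMES)
        raw = pp.read_raw_edf(path)
        assert raw.sampling_rate == fs
        assert raw.electrode_names == CHANNEL_NAMES
        # int16 quantisation of a 400 uV physical span: ~0.006 uV steps
        assert np.abs(raw.samples - data).max() < 0.05

    def test_unknown_channel_names_rejected(self, tmp_path, rng):
        names = ["XX" + str(i) for i in range(32)]
        path = tmp_path / "bad.edf"
        self._write_minimal_edf(path, rng.normal(size=(32, 128)), 128.0, names)
        with pytest.raises(ValueError, match="unsupported electrode"):
            pp.read_raw_edf(path)
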