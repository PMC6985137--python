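"""FCD extraction against brute-force and closed-form oracles."""

import numpy as np
import pytest
from scipy import signal as scipy_signal
from scipy import stats as sps

from conftest import make_series
from fcdstrat.fcd import (FWHM_TO_SIGMA, FcdMap, MotionSummary, bandpass,
                          compute_fcd, discard_initial_frames, motion_qc,
                          read_bold_nifti, read_motion_trace, smooth_map,
                          tcompcor_denoise, write_map_csv, write_map_nifti)


def brute_force_fcd(data, threshold=0.7, normalize=True):
    """O(V^2) oracle: pairwise pearsonr, strict threshold, log1p degree,
    divided by the lower-median log-degree."""
    V = data.shape[0]
    degree = np.zeros(V)
    for i in range(V):
        for j in range(i + 1, V):
            r = sps.pearsonr(data[i], data[j]).statistic
            if r > threshold:
                degree[i] += 1
                degree[j] += 1
    values = np.log1p(degree)
    if not normalize:
        return values
    return values / np.percentile(values, 50, method="lower")


class TestFrameTrimming:
    def test_165_minus_5_is_160(self, rng):
        s = make_series(rng.normal(size=(4, 165)))
        assert discard_initial_frames(s, 5).n_frames == 160

    def test_zero_is_identity(self, rng):
        s = make_series(rng.normal(size=(4, 30)))
        np.testing.assert_array_equal(discard_initial_frames(s, 0).data, s.data)

    def test_empty_result_forbidden(self, rng):
        s = make_series(rng.normal(size=(4, 5)))
        with pytest.raises(ValueError):
            discard_initial_frames(s, 5)


class TestTcompcor:
    def test_zero_components_is_linear_detrend(self, rng):
        X = rng.normal(size=(10, 50))
        out = tcompcor_denoise(make_series(X), n_components=0).data
        t = np.linspace(-1, 1, 50)
        D = np.column_stack([np.ones(50), t])
        beta, *_ = np.linalg.lstsq(D, X.T, rcond=None)
        np.testing.assert_allclose(out, X - (D @ beta).T, atol=1e-10)

    def test_planted_nuisance_removed_from_clean_voxels(self, rng):
        V, T = 100, 120
        nuisance = rng.normal(size=T)
        X = rng.normal(size=(V, T))
        X[:5] += 8.0 * nuisance          # high-variance nuisance voxels
        X[5:] += 0.8 * nuisance          # moderate leak into clean voxels
        out = tcompcor_denoise(make_series(X), mask_fraction=0.05,
                               n_components=3).data
        for v in range(5, V):
            r = np.corrcoef(out[v], nuisance)[0, 1]
            assert abs(r) < 0.1

    def test_tie_case_deterministic(self):
        # identical variance everywhere: mask is a reproducible subset
        X = np.tile(np.sin(np.linspace(0, 10, 40)), (10, 1))
        X += np.ones((10, 1)) * 0.0
        out1 = tcompcor_denoise(make_series(X.copy()), n_components=1).data
        out2 = tcompcor_denoise(make_series(X.copy()), n_components=1).data
        np.testing.assert_array_equal(out1, out2)

    def test_too_many_components_rejected(self, rng):
        s = make_series(rng.normal(size=(10, 20)))
        with pytest.raises(ValueError):
            tcompcor_denoise(s, n_components=20)


class TestBandpass:
    def test_inband_tone_preserved(self):
        t = np.arange(600) * 3.0
        x = np.sin(2 * np.pi * 0.05 * t)
        out = bandpass(make_series(np.tile(x, (2, 1)))).data[0]
        mid = slice(100, -100)
        gain = np.sqrt((out[mid] ** 2).mean() / (x[mid] ** 2).mean())
        assert gain == pytest.approx(1.0, abs=0.05)

    def test_constant_series_zeroed(self):
        out = bandpass(make_series(np.full((3, 100), 7.0))).data
        assert np.abs(out).max() < 1e-10

    def test_above_nyquist_rejected(self):
        s = make_series(np.random.default_rng(0).normal(size=(2, 50)), tr=3.0)
        with pytest.raises(ValueError):
            bandpass(s, high=0.3)  # Nyquist at TR=3 s is 0.167 Hz

    def test_stopband_attenuation_via_fft(self):
        # 0.3 Hz tone at TR=1 s: measure the gain spectrally on the
        # steady-state section; must be attenuated by >= 20 dB
        t = np.arange(4000) * 1.0
        x = np.sin(2 * np.pi * 0.3 * t)
        out = bandpass(make_series(np.tile(x, (2, 1)), tr=1.0)).data[0]
        seg = slice(1000, 3000)
        f = np.fft.rfftfreq(2000, d=1.0)
        gain = (np.abs(np.fft.rfft(out[seg]))[np.argmin(np.abs(f - 0.3))]
                / np.abs(np.fft.rfft(x[seg]))[np.argmin(np.abs(f - 0.3))])
        assert 20 * np.log10(gain) < -20

    def test_design_attenuation_at_band_edges(self):
        # forward-backward (squared-magnitude) response: >= 20 dB down at
        # 0.5 x low and 2 x high, < 1 dB ripple mid-band
        sos = scipy_signal.butter(4, [0.01, 0.16], btype="bandpass",
                                  fs=1.0, output="sos")
        _, h = scipy_signal.sosfreqz(sos, worN=[0.005, 0.05, 0.32], fs=1.0)
        db = 40 * np.log10(np.abs(h))
        assert db[0] < -20 and db[2] < -20
        assert abs(db[1]) < 1.0


class TestComputeFcd:
    def test_complete_clique_all_ones(self, rng):
        x = np.sin(np.linspace(0, 20, 80)) + 0.0
        data = np.tile(x, (5, 1))
        fcd = compute_fcd(make_series(data))
        np.testing.assert_allclose(fcd.values, np.ones(5))

    def test_six_voxel_worked_example(self, rng):
        T = 200
        a = np.sin(np.linspace(0, 12 * np.pi, T))
        b = np.cos(np.linspace(0, 12 * np.pi, T))   # orthogonal to a
        noise = rng.normal(size=T)
        assert abs(sps.pearsonr(a, noise).statistic) < 0.7
        data = np.vstack([a, a, a, b, b, noise])
        fcd = compute_fcd(make_series(data))
        log2, log3 = np.log(2), np.log(3)
        expected = np.array([log3, log3, log3, log2, log2, 0.0]) / log2
        np.testing.assert_allclose(fcd.values, expected, atol=1e-12)

    def test_threshold_is_strict(self, rng):
        # a correlation exactly equal to the threshold must not form a link;
        # feed the implementation's own correlation value back as threshold
        data = rng.normal(size=(2, 100))
        Z = (data - data.mean(axis=1, keepdims=True)) / data.std(axis=1,
                                                                 keepdims=True)
        r_exact = float((Z @ Z.T)[0, 1] / data.shape[1])
        fcd = compute_fcd(make_series(data), threshold=r_exact,
                          normalization="none")
        assert fcd.values[0] == 0.0 and fcd.values[1] == 0.0

    def test_matches_brute_force_oracle(self, rng):
        data = rng.normal(size=(40, 60))
        data += 2.0 * rng.normal(size=60)        # global links
        data[:10] += 2.0 * rng.normal(size=60)   # plus a denser cluster
        fcd = compute_fcd(make_series(data))
        np.testing.assert_allclose(fcd.values, brute_force_fcd(data),
                                   atol=1e-10)

    def test_affine_invariance(self, rng):
        data = rng.normal(size=(20, 50))
        data += 2.0 * rng.normal(size=50)
        scaled = data * rng.uniform(0.5, 3, size=(20, 1)) + \
            rng.normal(size=(20, 1))
        f1 = compute_fcd(make_series(data))
        f2 = compute_fcd(make_series(scaled))
        np.testing.assert_allclose(f1.values, f2.values, atol=1e-10)

    def test_permutation_equivariance(self, rng):
        data = rng.normal(size=(15, 40))
        data += 2.0 * rng.normal(size=40)
        data[:6] += 1.5 * rng.normal(size=40)
        perm = rng.permutation(15)
        f1 = compute_fcd(make_series(data))
        f2 = compute_fcd(make_series(data[perm]))
        np.testing.assert_allclose(f2.values, f1.values[perm], atol=1e-12)

    def test_median_is_one_with_default_normalization(self, rng):
        data = rng.normal(size=(21, 50))
        data += 1.5 * rng.normal(size=50)  # global component links everyone
        fcd = compute_fcd(make_series(data))
        assert np.median(fcd.values) == pytest.approx(1.0)

    def test_no_links_raises(self, rng):
        data = rng.normal(size=(10, 2000))  # long series: all r near 0
        with pytest.raises(ValueError, match="median"):
            compute_fcd(make_series(data))

    def test_constant_voxel_degree_zero_with_warning(self, rng):
        x = np.sin(np.linspace(0, 20, 60))
        data = np.vstack([x, x, x, np.zeros(60)])
        with pytest.warns(RuntimeWarning, match="constant"):
            fcd = compute_fcd(make_series(data), normalization="none")
        assert fcd.values[3] == 0.0


class TestSmoothing:
    @staticmethod
    def grid_map(values, shape):
        coords = np.argwhere(np.ones(shape, bool))
        return FcdMap(values=values, coords=coords, shape=shape)

    def test_constant_map_unchanged(self):
        m = self.grid_map(np.full(7 * 7 * 7, 3.3), (7, 7, 7))
        out = smooth_map(m, fwhm_voxels=2.5)
        np.testing.assert_allclose(out.values, m.values)

    def test_impulse_matches_closed_form_kernel(self):
        shape = (15, 15, 15)
        vals = np.zeros(15**3)
        center = np.ravel_multi_index((7, 7, 7), shape)
        vals[center] = 1.0
        out = smooth_map(self.grid_map(vals, shape), fwhm_voxels=2.5)
        vol = np.zeros(shape)
        vol[tuple(out.coords.T)] = out.values
        sigma = 2.5 * FWHM_TO_SIGMA
        assert sigma == pytest.approx(2.5 / 2.3548, abs=1e-4)
        # ratios to the center value follow exp(-d^2 / (2 sigma^2))
        for offset in [(1, 0, 0), (0, 2, 0), (1, 1, 1)]:
            d2 = sum(o**2 for o in offset)
            ratio = vol[7 + offset[0], 7 + offset[1], 7 + offset[2]] / vol[7, 7, 7]
            assert ratio == pytest.approx(np.exp(-d2 / (2 * sigma**2)), rel=1e-3)

    def test_tiny_fwhm_is_identity(self, rng):
        m = self.grid_map(rng.normal(size=5**3), (5, 5, 5))
        out = smooth_map(m, fwhm_voxels=1e-6)
        np.testing.assert_allclose(out.values, m.values, atol=1e-8)

    def test_masked_renormalization_preserves_constants(self):
        # half-masked grid: a constant map must stay constant at the border
        shape = (8, 8, 8)
        mask = np.zeros(shape, bool)
        mask[:4] = True
        coords = np.argwhere(mask)
        m = FcdMap(values=np.full(len(coords), 2.0), coords=coords, shape=shape)
        out = smooth_map(m, fwhm_voxels=2.5)
        np.testing.assert_allclose(out.values, 2.0, rtol=1e-10)

    def test_nonpositive_fwhm_rejected(self, rng):
        m = self.grid_map(rng.normal(size=27), (3, 3, 3))
        with pytest.raises(ValueError):
            smooth_map(m, fwhm_voxels=0.0)


class TestMotionQc:
    def test_eleven_frames_above_excludes(self):
        fd = np.concatenate([np.full(11, 0.7), np.full(100, 0.1)])
        assert motion_qc(MotionSummary(fd)) == "exclude"

    def test_exactly_ten_retains(self):
        fd = np.concatenate([np.full(10, 0.7), np.full(100, 0.1)])
        assert motion_qc(MotionSummary(fd)) == "retain"

    def test_zero_motion_retains(self):
        m = MotionSummary(np.zeros(100))
        assert motion_qc(m) == "retain"
        assert m.fd_mean == 0.0

    def test_negative_displacement_rejected(self):
        with pytest.raises(ValueError):
            MotionSummary(np.array([0.1, -0.2]))


class TestIo:
    def test_nifti_roundtrip(self, tmp_path, rng):
        import nibabel as nib

        shape = (6, 5, 4)
        mask = rng.random(shape) > 0.3
        n_frames = 30
        vol4d = rng.normal(size=shape + (n_frames,))
        img = nib.Nifti1Image(vol4d, np.eye(4))
        img.header.set_zooms((1.0, 1.0, 1.0, 3.0))
        nib.save(img, tmp_path / "bold.nii.gz")
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), np.eye(4)),
                 tmp_path / "mask.nii.gz")
        series = read_bold_nifti(tmp_path / "bold.nii.gz",
                                 tmp_path / "mask.nii.gz")
        assert series.tr == pytest.approx(3.0)
        assert series.n_voxels == mask.sum()
        np.testing.assert_allclose(series.data, vol4d[mask])

        fmap = FcdMap(values=rng.random(mask.sum()),
                      coords=np.argwhere(mask), shape=shape)
        write_map_nifti(fmap, tmp_path / "map.nii.gz")
        back = np.asarray(nib.load(tmp_path / "map.nii.gz").dataobj)
        np.testing.assert_allclose(back[mask], fmap.values)
        write_map_csv(fmap, tmp_path / "map.csv")
        assert (tmp_path / "map.csv").read_text().startswith("voxel_id,value")

    def test_motion_trace_roundtrip(self, tmp_path):
        fd = np.array([0.05, 0.7, 0.12])
        (tmp_path / "fd.txt").write_text("\n".join(f"{v}" for v in fd))
        m = read_motion_trace(tmp_path / "fd.txt")
        np.testing.assert_allclose(m.fd_per_frame, fd)
        assert m.n_frames_above == 1
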