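"""NUFFT operators, noise calibration and data simulation."""

import numpy as np
import pytest

from qrfthermo import (
    GreParams,
    NoiseModel,
    SequenceParams,
    calibrate_noise,
    ernst_angle,
    make_spiral_trajectory,
    render_tr_images,
    simulate_2dft_pair,
    spiral_forward,
    spoiled_gre_signal,
)
from qrfthermo.dictionary import (
    DictionaryGrid,
    build_dictionary,
    default_frequency_grid,
)
from qrfthermo.nufft import NufftPlan
from qrfthermo.phantom import add_gaussian_hotspot, make_disc_phantom, prf_shift
from qrfthermo.sequence import sweep_frequency


class TestNufft:
    def test_forward_matches_direct_dft(self):
        """Gridding NUFFT agrees with the exact non-uniform DFT on a 16x16
        random image to 1e-6 relative error."""
        rng = np.random.default_rng(0)
        n = 16
        p = SequenceParams(n_tr=24)
        traj = make_spiral_trajectory(p, matrix=n)
        plan = NufftPlan(traj, matrix=n)
        img = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
        x = np.arange(n) - n // 2
        gx, gy = np.meshgrid(x, x, indexing="ij")
        for l in (0, 7):
            k = traj.coords[l]
            ref = (
                np.array(
                    [
                        (img * np.exp(-2j * np.pi * (kx * gx + ky * gy))).sum()
                        for kx, ky in k
                    ]
                )
                / n
            )
            got = plan.forward(img, l)
            assert np.abs(got - ref).max() / np.abs(ref).max() < 1e-6

    def test_adjoint_identity(self):
        """<Ax, y> == <x, A^H y> to near machine precision (the adjoint is
        the exact transpose of the forward)."""
        rng = np.random.default_rng(1)
        p = SequenceParams(n_tr=24)
        traj = make_spiral_trajectory(p, matrix=32)
        plan = NufftPlan(traj)
        img = rng.standard_normal((32, 32)) + 1j * rng.standard_normal((32, 32))
        y = rng.standard_normal(traj.n_samples) + 1j * rng.standard_normal(
            traj.n_samples
        )
        lhs = np.vdot(y, plan.forward(img, 3))
        rhs = np.vdot(plan.adjoint(y, 3), img)
        assert abs(lhs - rhs) / abs(lhs) < 1e-6

    def test_batched_equals_sequential(self):
        rng = np.random.default_rng(2)
        p = SequenceParams(n_tr=24)
        traj = make_spiral_trajectory(p, matrix=16)
        plan = NufftPlan(traj)
        imgs = rng.standard_normal((40, 16, 16)) + 1j * rng.standard_normal((40, 16, 16))
        il = np.arange(40) % 12
        batched = plan.forward(imgs, il)
        for i in (0, 13, 39):
            assert np.allclose(batched[i], plan.forward(imgs[i], il[i]), atol=1e-12)


class TestSpoiledGre:
    def test_saturation_free_limit(self):
        # TR >> T1, TE = 0, 90 degrees: full magnetization
        assert spoiled_gre_signal(1.0, 0.1, 0.05, 90.0, 10.0, 0.0) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_ernst_angle_maximizes_signal(self):
        t1, tr = 0.825, 0.017
        ae = ernst_angle(t1, tr)
        flips = np.linspace(1, 90, 400)
        vals = [spoiled_gre_signal(1.0, t1, 0.046, f, tr, 0.012) for f in flips]
        assert abs(flips[int(np.argmax(vals))] - ae) < 0.5

    def test_closed_form_value(self):
        t1, t2s, tr, te, a = 0.825, 0.046, 0.017, 0.012, 11.6
        e1 = np.exp(-tr / t1)
        ar = np.radians(a)
        ref = np.sin(ar) * (1 - e1) / (1 - np.cos(ar) * e1) * np.exp(-te / t2s)
        assert spoiled_gre_signal(1.0, t1, t2s, a, tr, te) == pytest.approx(
            ref, abs=1e-12
        )


class TestNoiseCalibration:
    def test_infinite_snr_gives_zero_noise(self):
        s2, sq = calibrate_noise(NoiseModel(snr_target=1e12), 1.0)
        assert s2 < 1e-11 and sq < 1e-10

    def test_linearity_in_snr(self):
        a = calibrate_noise(NoiseModel(snr_target=100), 1.0)
        b = calibrate_noise(NoiseModel(snr_target=200), 1.0)
        assert a[0] == pytest.approx(2 * b[0])
        assert a[1] == pytest.approx(2 * b[1])

    def test_dwell_ratio_scaling(self):
        """Spiral per-sample noise exceeds the 2DFT std by the square root
        of the dwell-time ratio (25 us / 2 us)."""
        s2, sq = calibrate_noise(NoiseModel(), 1.0)
        assert sq / s2 == pytest.approx(np.sqrt(12.5), rel=1e-12)


class TestSpiralForward:
    def test_delta_image_gives_coil_weighted_exponentials(self):
        """Zero noise, off-center delta image: samples are the analytic
        complex exponentials (times the coil weight at the delta)."""
        n = 16
        p = SequenceParams(n_tr=12)
        traj = make_spiral_trajectory(p, matrix=n)
        plan = NufftPlan(traj)
        img = np.zeros((1, n, n), dtype=complex)
        ix, iy = 10, 5
        img[0, ix, iy] = 1.0
        coil = (np.arange(n * n).reshape(n, n) / (n * n) + 0.5).astype(complex)
        ks = spiral_forward(img, plan, p, coil_maps=coil[None], noise_std=0.0)
        k = traj.coords[0]
        ref = (
            coil[ix, iy]
            * np.exp(-2j * np.pi * (k[:, 0] * (ix - n // 2) + k[:, 1] * (iy - n // 2)))
            / n
        )
        assert np.abs(ks.samples[0, 0] - ref).max() < 1e-6

    def test_seed_reproducibility(self, phantom32, plan64, params_short):
        img = np.repeat(phantom32.m0[None].astype(complex), 4, axis=0)
        a = spiral_forward(img, plan64, params_short, noise_std=0.1, rng=5)
        b = spiral_forward(img, plan64, params_short, noise_std=0.1, rng=5)
        assert np.array_equal(a.samples, b.samples)

    def test_noise_level_and_whiteness(self, plan64, params_short):
        """Added noise has the requested complex std and is uncorrelated
        across TRs and samples."""
        img = np.zeros((24, 64, 64), dtype=complex)
        sigma = 0.05
        ks = spiral_forward(img, plan64, params_short, noise_std=sigma, rng=0)
        z = ks.samples[:, 0, :]
        assert np.sqrt(np.mean(np.abs(z) ** 2)) == pytest.approx(sigma, rel=0.02)
        # correlation between different TRs at matched sample positions
        c = np.abs(np.mean(z[:-1] * np.conj(z[1:])))
        assert c < 5 * sigma**2 / np.sqrt(z[0].size * (z.shape[0] - 1))


class TestRenderTrImages:
    def test_uniform_disc_shares_one_timecourse(self, phantom32, small_dictionary):
        imgs = render_tr_images(phantom32, small_dictionary)
        vox = np.where(phantom32.mask)
        tcs = imgs[:, vox[0], vox[1]]
        assert np.abs(tcs - tcs[:, :1]).max() < 1e-12

    def test_zero_m0_gives_zero_images(self, phantom32, small_dictionary):
        maps = phantom32.copy()
        maps.m0[:] = 0.0
        imgs = render_tr_images(maps, small_dictionary)
        assert np.abs(imgs).max() == 0.0

    def test_out_of_range_frequency_raises(self, phantom32, small_dictionary):
        maps = phantom32.copy()
        maps.freq_hz[maps.mask] = 80.0
        with pytest.raises(ValueError):
            render_tr_images(maps, small_dictionary)

    def test_heated_voxel_peak_trs_shift_with_frequency(self, params_short):
        """A heated voxel's signal peaks at the TRs where the sweep crosses
        its shifted frequency, distinct from an unheated voxel's peaks."""
        from scipy.signal import find_peaks

        grid = DictionaryGrid(
            freqs_hz=default_frequency_grid(512),
            linewidths_hz=np.array([1.0]),
            t1t2_pairs_s=((0.25, 0.01),),
        )
        d = build_dictionary(grid, params_short)
        maps = add_gaussian_hotspot(
            make_disc_phantom(grid=64, diameter_vox=32), peak_c=25.0, fwhm_vox=10
        )
        imgs = render_tr_images(maps, d)
        hot = np.unravel_index(np.argmax(maps.temp_c), maps.shape)
        cold = (20, 32)
        assert maps.mask[cold] and maps.temp_c[cold] < 0.5
        period = 180.0 / params_short.quad_coeff_deg
        lo = int(np.ceil(period)) + 1
        for vox, f0 in ((hot, maps.freq_hz[hot]), (cold, 0.0)):
            mag = np.abs(imgs[:, vox[0], vox[1]])
            peaks, _ = find_peaks(mag[lo:], height=0.5 * mag[lo:].max())
            peaks += lo
            n = np.arange(params_short.n_tr)
            sw = sweep_frequency(n, params_short)
            dist = np.abs(((sw - f0) + 50) % 100 - 50)
            crossings = n[dist < 1.17]
            # snapped frequency is on the grid, so use generous +-3 TRs
            for pk in peaks:
                assert np.min(np.abs(crossings - pk)) <= 3


class Test2dftPair:
    def test_zero_frequency_zero_phase_difference(self, phantom32):
        gre = GreParams()
        base, heat = simulate_2dft_pair(
            phantom32, gre, NoiseModel(snr_target=1e12), rng=0
        )
        dphi = np.angle(heat * np.conj(base))[phantom32.mask]
        assert np.abs(dphi).max() < 1e-6

    def test_measured_snr_matches_target(self, phantom32):
        """Empirical image SNR (mean masked magnitude over complex noise
        std) hits the 112 target within 2%."""
        gre = GreParams()
        noise = NoiseModel(snr_target=112)
        mags, noises = [], []
        clean, _ = simulate_2dft_pair(phantom32, gre, NoiseModel(snr_target=1e12), rng=0)
        for r in range(20):
            base, _ = simulate_2dft_pair(phantom32, gre, noise, rng=r)
            noises.append(base - clean)
        resid = np.stack(noises)[:, phantom32.mask]
        sigma = np.sqrt(np.mean(np.abs(resid) ** 2))
        snr = np.abs(clean[phantom32.mask]).mean() / sigma
        assert snr == pytest.approx(112, rel=0.02)

    def test_hotspot_phase_difference_closed_form(self):
        maps = make_disc_phantom(grid=64, diameter_vox=32)
        heated = add_gaussian_hotspot(maps, peak_c=25.0, fwhm_vox=10)
        gre = GreParams()
        base, dyn = simulate_2dft_pair(
            maps, gre, NoiseModel(snr_target=1e12), heated_maps=heated, rng=0
        )
        peak = np.unravel_index(np.argmax(heated.temp_c), maps.shape)
        dphi = np.angle(dyn * np.conj(base))[peak]
        expected = 2 * np.pi * prf_shift(25.0, 3.0) * gre.te_s
        # expected is outside (-pi, pi]: compare wrapped
        expected = (expected + np.pi) % (2 * np.pi) - np.pi
        assert dphi == pytest.approx(expected, abs=1e-6)
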