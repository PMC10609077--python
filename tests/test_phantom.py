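"""Phantom synthesis: signal rendering, ice field, deterministic frames,
Poisson dose sampling, and gain/dark references."""

import numpy as np
import pytest

import cryophantom as cp
from cryophantom.metrics import radial_psd


class TestRenderSignal:
    def test_grid_matches_brute_force_classification(self):
        spec = cp.PhantomSpec(dims=(300, 300), n_frames=1, grid_step=150, line_width=5)
        img = cp.render_signal(spec)
        expect = np.zeros((300, 300))
        for row in range(300):
            for col in range(300):
                if row % 150 < 5 or col % 150 < 5:
                    expect[row, col] = 1.0
        np.testing.assert_array_equal(img, expect)
        # phase convention: line starts at multiples of the step
        line_cols = np.nonzero(img[200] == 1.0)[0]
        np.testing.assert_array_equal(line_cols, [0, 1, 2, 3, 4, 150, 151, 152, 153, 154])

    def test_zero_line_width_rejected(self):
        with pytest.raises(cp.InvalidParameterError):
            cp.PhantomSpec(dims=(300, 300), n_frames=1, line_width=0)

    def test_disc_area(self):
        spec = cp.PhantomSpec(
            dims=(300, 300), n_frames=1, signal_kind="disc", disc_radius=50
        )
        img = cp.render_signal(spec)
        count = (img > 0).sum()
        assert count == pytest.approx(np.pi * 50**2, rel=0.02)

    def test_cross_is_centred_and_symmetric(self):
        spec = cp.PhantomSpec(dims=(101, 101), n_frames=1, signal_kind="cross")
        img = cp.render_signal(spec)
        np.testing.assert_array_equal(img, img.T)
        assert img[50, 50] == spec.signal_amplitude


class TestSimulateIce:
    def test_rescale_bounds_exact(self):
        ice = cp.simulate_ice((128, 128), cp.IceSpec(), pixel_size=1.0, seed=4)
        assert ice.min() == 0.0
        assert ice.max() == 2.0

    def test_seed_determinism(self):
        a = cp.simulate_ice((64, 64), cp.IceSpec(), seed=11)
        b = cp.simulate_ice((64, 64), cp.IceSpec(), seed=11)
        np.testing.assert_array_equal(a, b)
        c = cp.simulate_ice((64, 64), cp.IceSpec(), seed=12)
        assert not np.array_equal(a, c)

    @pytest.mark.parametrize("shape", ["gaussian", "raised-cosine"])
    def test_power_above_cutoff_negligible(self, shape):
        ice = cp.simulate_ice(
            (256, 256), cp.IceSpec(filter_shape=shape), pixel_size=1.0, seed=7
        )
        psd = radial_psd(ice)
        cutoff = 1.0 / 3.0  # cycles/px for a 3 Å low-pass at 1 Å pixels
        half = psd.power[np.argmin(np.abs(psd.freq - cutoff / 2))]
        above = psd.power[psd.freq > cutoff]
        assert above.max() <= 0.01 * half

    def test_beyond_nyquist_rejected(self):
        with pytest.raises(cp.InvalidParameterError):
            cp.simulate_ice((64, 64), cp.IceSpec(lowpass_resolution=3.0), pixel_size=2.0)


class TestRenderMovie:
    def test_zero_motion_frames_equal_base_signal(self):
        spec = cp.PhantomSpec(dims=(64, 64), n_frames=3, grid_step=20, line_width=3)
        truth = cp.MotionGroundTruth(
            shifts=np.zeros((3, 2)), k_coeffs=np.zeros((3, 2)), dims=(64, 64)
        )
        stack = cp.render_movie(spec, truth)
        base = cp.render_signal(spec)
        for t in range(3):
            np.testing.assert_allclose(stack.frames[t], base, atol=1e-6)

    def test_frame_count_mismatch_rejected(self):
        spec = cp.PhantomSpec(dims=(64, 64), n_frames=3, grid_step=20, line_width=3)
        truth = cp.MotionGroundTruth(
            shifts=np.zeros((2, 2)), k_coeffs=np.zeros((2, 2)), dims=(64, 64)
        )
        with pytest.raises(cp.InvalidParameterError):
            cp.render_movie(spec, truth)

    def test_translation_recoverable_by_registration(self):
        """Frame t cross-correlates with frame 0 at the true relative shift."""
        dims = (256, 256)
        n = 4
        shifts = np.array([[0, 0], [2, 0], [4, 0], [6, 0]], dtype=float)
        truth = cp.MotionGroundTruth(
            shifts=shifts, k_coeffs=np.zeros((n, 2)), dims=dims
        )
        spec = cp.PhantomSpec(dims=dims, n_frames=n, grid_step=40, line_width=3,
                              ice=cp.IceSpec(), seed=9)
        stack = cp.render_movie(spec, truth)
        for t in range(1, n):
            est = cp.cc_shift_pair(stack.frames[0], stack.frames[t], max_shift=12)
            assert abs(est[0] - shifts[t, 0]) < 0.1
            assert abs(est[1] - shifts[t, 1]) < 0.1

    def test_doming_degrades_corners_more_than_center(self, doming_movie):
        """Last frame still matches the first at the centre but not in the
        corner — the radial deformation grows with radius."""
        first, last = doming_movie.frames[0], doming_movie.frames[-1]

        def corr(a, b):
            a = a - a.mean()
            b = b - b.mean()
            return (a * b).sum() / np.sqrt((a**2).sum() * (b**2).sum())

        w = 128
        c0 = corr(first[192:320, 192:320], last[192:320, 192:320])
        c_corner = corr(first[:w, :w], last[:w, :w])
        assert c0 > c_corner


class TestApplyDose:
    def test_zero_frame_stays_zero(self):
        stack = cp.FrameStack(frames=np.zeros((2, 16, 16)))
        out = cp.apply_dose(stack, seed=1)
        np.testing.assert_array_equal(out.frames, 0)

    def test_poisson_moments(self):
        lam = 4.0
        stack = cp.FrameStack(frames=np.full((1, 512, 512), lam))
        out = cp.apply_dose(stack, seed=2)
        n = 512 * 512
        se_mean = np.sqrt(lam / n)
        # SE of the sample variance of a Poisson: sqrt((mu4 - var^2)/n),
        # mu4 = lam(1 + 3lam) for Poisson
        se_var = np.sqrt((lam * (1 + 3 * lam) - lam**2) / n)
        assert abs(out.frames.mean() - lam) < 3 * se_mean
        assert abs(out.frames.var() - lam) < 3 * se_var

    def test_seed_determinism(self):
        stack = cp.FrameStack(frames=np.full((2, 32, 32), 3.0))
        a = cp.apply_dose(stack, seed=5)
        b = cp.apply_dose(stack, seed=5)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_replicate_average_converges_to_deterministic_frame(self):
        rng = np.random.default_rng(0)
        det = rng.uniform(0.5, 4.0, size=(1, 64, 64))
        stack = cp.FrameStack(frames=det)
        reps = np.stack(
            [cp.apply_dose(stack, seed=s).frames[0] for s in range(200)]
        )
        err = np.abs(reps.mean(axis=0) - det[0]).max()
        # 200-replicate mean of Poisson(lam<=4): SE <= sqrt(4/200) ~ 0.14
        assert err < 5 * np.sqrt(4.0 / 200)


class TestGainDark:
    def test_values_and_dims(self):
        gain, dark = cp.generate_gain_dark((256, 128))
        assert gain.shape == (128, 256)
        assert gain.sum() == 256 * 128
        assert dark.sum() == 0

    def test_degenerate_single_pixel(self):
        gain, dark = cp.generate_gain_dark((1, 1))
        assert gain[0, 0] == 1.0
        assert dark[0, 0] == 0.0


class TestDeterminism:
    def test_same_spec_same_movie(self, fixed_step_truth):
        spec = cp.PhantomSpec(
            dims=(512, 512), n_frames=10, seed=3,
            ice=cp.IceSpec(), dose_sampling=True,
        )
        a = cp.simulate_movie(spec, fixed_step_truth)
        b = cp.simulate_movie(spec, fixed_step_truth)
        np.testing.assert_array_equal(a.frames, b.frames)
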