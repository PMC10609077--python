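"""Reference aligner: sub-pixel cross-correlation, least-squares global
consensus, patch-based local motion, and micrograph synthesis."""

import numpy as np
import pytest

import cryophantom as cp
from cryophantom.phantom import FrameStack


class TestCcShiftPair:
    def test_autocorrelation_peak_at_origin(self, band_limited_image):
        est = cp.cc_shift_pair(band_limited_image, band_limited_image, 10)
        assert est == pytest.approx((0.0, 0.0), abs=1e-9)

    def test_integer_circular_shift_exact(self, band_limited_image):
        b = np.roll(band_limited_image, (3, 5), axis=(0, 1))  # y+3, x+5
        est = cp.cc_shift_pair(band_limited_image, b, 10)
        assert est == pytest.approx((5.0, 3.0), abs=1e-9)

    def test_fourier_subpixel_shift(self, band_limited_image):
        fy = np.fft.fftfreq(256)[:, None]
        fx = np.fft.fftfreq(256)[None, :]
        ramp = np.exp(-2j * np.pi * (fx * 2.5 + fy * 1.5))
        b = np.fft.ifft2(np.fft.fft2(band_limited_image) * ramp).real
        est = cp.cc_shift_pair(band_limited_image, b, 10)
        assert est[0] == pytest.approx(2.5, abs=0.1)
        assert est[1] == pytest.approx(1.5, abs=0.1)

    def test_flat_input_degenerate(self):
        flat = np.ones((64, 64))
        with pytest.raises(cp.DegenerateInputError):
            cp.cc_shift_pair(flat, flat, 8)

    def test_oversized_max_shift_rejected(self):
        img = np.random.default_rng(0).normal(size=(64, 64))
        with pytest.raises(cp.InvalidParameterError):
            cp.cc_shift_pair(img, img, 20)


class TestSolveGlobal:
    def test_identical_frames_give_zero_shifts(self):
        rng = np.random.default_rng(2)
        frame = rng.normal(size=(128, 128))
        stack = FrameStack(frames=np.stack([frame] * 4))
        ga = cp.solve_global(stack, cp.AlignConfig(max_shift=10))
        np.testing.assert_allclose(ga.shifts, 0, atol=1e-9)

    def test_reference_frame_shift_is_exactly_zero(self, noiseless_movie):
        ga = cp.solve_global(noiseless_movie, cp.AlignConfig(max_shift=20))
        assert ga.reference_frame == 5
        np.testing.assert_array_equal(ga.shifts[5], 0.0)

    def test_noiseless_fixed_step_recovery(self, noiseless_movie, fixed_step_truth):
        ga = cp.solve_global(noiseless_movie, cp.AlignConfig(max_shift=20))
        assert cp.shift_rmse(ga, fixed_step_truth) <= 0.2

    def test_pairwise_transitivity(self, noiseless_movie):
        f = noiseless_movie.frames
        s01 = np.array(cp.cc_shift_pair(f[0], f[1], 20))
        s12 = np.array(cp.cc_shift_pair(f[1], f[2], 20))
        s02 = np.array(cp.cc_shift_pair(f[0], f[2], 20))
        assert np.linalg.norm(s02 - (s01 + s12)) < 0.3

    def test_small_bound_fails_large_bound_succeeds(self):
        """An under-estimated expected-shift bound aborts alignment of a
        120 px total-drift movie; raising the bound recovers it."""
        dims = (640, 640)
        n = 10
        model = cp.FixedStepModel(total_shift=120, n_frames=n, direction=(1.0, 0.0))
        truth = cp.MotionGroundTruth.from_models(model, None, n, dims)
        spec = cp.PhantomSpec(dims=dims, n_frames=n, seed=3, ice=cp.IceSpec())
        stack = cp.simulate_movie(spec, truth)
        with pytest.raises(cp.AlignmentFailureError):
            cp.solve_global(stack, cp.AlignConfig(max_shift=50))
        ga = cp.solve_global(stack, cp.AlignConfig(max_shift=150))
        assert cp.shift_rmse(ga, truth) <= 0.5


class TestLocalAlign:
    def test_pure_global_motion_leaves_no_local_residual(
        self, noiseless_movie, global_alignment
    ):
        lm = cp.local_align(noiseless_movie, global_alignment, cp.AlignConfig(max_shift=20))
        assert np.abs(lm.patch_shifts).max() <= 0.3

    def test_doming_residuals_grow_with_radius(self, doming_movie):
        cfg = cp.AlignConfig(max_shift=20)
        ga = cp.solve_global(doming_movie, cfg)
        lm = cp.local_align(doming_movie, ga, cfg)
        mag = np.linalg.norm(lm.patch_shifts, axis=2).mean(axis=1).reshape(5, 5)
        corner = (mag[0, 0] + mag[0, -1] + mag[-1, 0] + mag[-1, -1]) / 4
        assert corner > mag[2, 2]

    def test_spline_reproduces_patch_shifts(self, doming_movie):
        cfg = cp.AlignConfig(max_shift=20)
        ga = cp.solve_global(doming_movie, cfg)
        lm = cp.local_align(doming_movie, ga, cfg)
        xs = lm.patch_centers[:, 0]
        ys = lm.patch_centers[:, 1]
        for t in range(doming_movie.n_frames):
            pred = lm.evaluate(xs, ys, float(t))
            np.testing.assert_allclose(
                pred.T, lm.patch_shifts[:, t, :], atol=0.1
            )

    def test_too_small_patches_rejected(self):
        stack = FrameStack(frames=np.random.default_rng(0).normal(size=(3, 96, 96)))
        ga = cp.GlobalAlignment(
            shifts=np.zeros((3, 2)), reference_frame=1,
            residual_norm=0.0, n_pairs=3, n_flagged=0,
        )
        with pytest.raises(cp.InvalidParameterError):
            cp.local_align(stack, ga, cp.AlignConfig(max_shift=5, patch_grid=(2, 2)))


class TestRenderMicrograph:
    @staticmethod
    def _zero_alignment(n):
        return cp.GlobalAlignment(
            shifts=np.zeros((n, 2)), reference_frame=n // 2,
            residual_norm=0.0, n_pairs=n * (n - 1) // 2, n_flagged=0,
        )

    def test_zero_motion_average_is_frame_mean(self):
        rng = np.random.default_rng(3)
        frames = rng.normal(size=(4, 64, 64))
        stack = FrameStack(frames=frames)
        mic = cp.render_micrograph(stack, self._zero_alignment(4))
        np.testing.assert_allclose(mic, frames.mean(axis=0), atol=1e-9)

    def test_sum_equals_average_times_frames(self, noiseless_movie, global_alignment):
        avg = cp.render_micrograph(
            noiseless_movie, global_alignment,
            cfg=cp.AlignConfig(output_convention="average"),
        )
        total = cp.render_micrograph(
            noiseless_movie, global_alignment,
            cfg=cp.AlignConfig(output_convention="sum"),
        )
        np.testing.assert_allclose(total, avg * noiseless_movie.n_frames, rtol=1e-6)

    def test_constant_movie_average_and_sum(self):
        stack = FrameStack(frames=np.full((5, 64, 64), 2.5))
        mic = cp.render_micrograph(stack, self._zero_alignment(5))
        np.testing.assert_allclose(mic, 2.5, atol=1e-12)
        mic_sum = cp.render_micrograph(
            stack, self._zero_alignment(5),
            cfg=cp.AlignConfig(output_convention="sum"),
        )
        np.testing.assert_allclose(mic_sum, 12.5, atol=1e-12)

    def test_true_shift_alignment_keeps_grid_edges_sharp(
        self, noiseless_movie, fixed_step_truth, global_alignment
    ):
        """Micrograph aligned with recovered shifts has grid-line edge
        profiles within a pixel of the unmoved base signal's."""
        mic = cp.render_micrograph(noiseless_movie, global_alignment)
        base = cp.render_signal(
            cp.PhantomSpec(dims=(512, 512), n_frames=10, signal_kind="grid", seed=3)
        )

        def line_fwhm(row, near_col):
            """Width at half maximum of the grid line closest to near_col.

            The micrograph is referenced to the middle frame, so the line may
            sit a few pixels from its base position; centre the window on the
            local maximum first.
            """
            seg = row[near_col - 20 : near_col + 25]
            peak = near_col - 20 + int(np.argmax(seg))
            profile = row[peak - 10 : peak + 15]
            return np.count_nonzero(profile > 0.5 * profile.max())

        # profile across the x=150 vertical grid line, centre row
        assert abs(line_fwhm(mic[256], 150) - line_fwhm(base[256], 150)) <= 1

    def test_fourier_interpolation_supported(self, noiseless_movie, global_alignment):
        mic = cp.render_micrograph(
            noiseless_movie, global_alignment,
            cfg=cp.AlignConfig(interpolation="fourier-crop"),
        )
        assert np.isfinite(mic).all()

    def test_linear_interpolation_damps_high_frequencies(
        self, noiseless_movie, global_alignment
    ):
        mic_lin = cp.render_micrograph(
            noiseless_movie, global_alignment,
            cfg=cp.AlignConfig(interpolation="linear"),
        )
        mic_cub = cp.render_micrograph(
            noiseless_movie, global_alignment,
            cfg=cp.AlignConfig(interpolation="cubic-bspline"),
        )
        p_lin = cp.radial_psd(mic_lin)
        p_cub = cp.radial_psd(mic_cub)
        k = int(0.9 * p_lin.power.size)
        assert p_lin.power[k:].mean() < p_cub.power[k:].mean()

    def test_unknown_interpolation_rejected(self):
        with pytest.raises(cp.InvalidParameterError):
            cp.AlignConfig(interpolation="sinc")
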