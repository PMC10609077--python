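"""Shared fixtures: small phantom movies reused across the suite."""

import numpy as np
import pytest

import cryophantom as cp

DIMS = (512, 512)
N_FRAMES = 10


@pytest.fixture(scope="session")
def fixed_step_truth():
    model = cp.FixedStepModel(total_shift=10, n_frames=N_FRAMES, direction=(1.0, 0.0))
    return cp.MotionGroundTruth.from_models(model, None, N_FRAMES, DIMS)


@pytest.fixture(scope="session")
def noiseless_movie(fixed_step_truth):
    spec = cp.PhantomSpec(dims=DIMS, n_frames=N_FRAMES, signal_kind="grid", seed=3)
    return cp.render_movie(spec, fixed_step_truth)


@pytest.fixture(scope="session")
def noisy_movie(fixed_step_truth):
    spec = cp.PhantomSpec(
        dims=DIMS, n_frames=N_FRAMES, signal_kind="grid", seed=3,
        ice=cp.IceSpec(), dose_sampling=True,
    )
    return cp.simulate_movie(spec, fixed_step_truth)


@pytest.fixture(scope="session")
def doming_truth():
    schedule = cp.DeformationSchedule(n_frames=N_FRAMES)
    return cp.MotionGroundTruth.from_models(cp.ShiftModel(), schedule, N_FRAMES, DIMS)


@pytest.fixture(scope="session")
def doming_movie(doming_truth):
    spec = cp.PhantomSpec(
        dims=DIMS, n_frames=N_FRAMES, signal_kind="grid", seed=5,
        ice=cp.IceSpec(), dose_sampling=True,
    )
    return cp.simulate_movie(spec, doming_truth)


@pytest.fixture(scope="session")
def global_alignment(noiseless_movie):
    return cp.solve_global(noiseless_movie, cp.AlignConfig(max_shift=20))


@pytest.fixture
def band_limited_image():
    """Smooth random image suitable for sub-pixel registration fixtures."""
    rng = np.random.default_rng(0)
    img = rng.normal(size=(256, 256))
    fy = np.fft.fftfreq(256)[:, None]
    fx = np.fft.fftfreq(256)[None, :]
    soft = np.exp(-(fx**2 + fy**2) * 800)
    return np.fft.ifft2(np.fft.fft2(img) * soft).real
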