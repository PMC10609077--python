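"""Phantom movie synthesis: deterministic signal + ice content, per-frame
deformation, and optional Poisson electron-counting noise.

The generation pipeline mirrors how a direct-detector exposure is formed:

1. build one static content image — simulated amorphous ice (a low-pass
   filtered Gaussian random field rescaled to a physical intensity range)
   with a geometric signal (grid / disc / cross) added on top;
2. warp that single content by the per-frame displacement field (global
   drift composed with doming), so every frame shows the *same* specimen
   under different motion — frames are deterministic given the spec;
3. optionally treat each deterministic pixel value as the mean of a Poisson
   distribution and sample integer electron counts per pixel.

Gain and dark references (all-ones / all-zeros) are generated at movie size
for testing correction pipelines.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError
from .motion import MotionGroundTruth, displacement_field

__all__ = [
    "IceSpec",
    "PhantomSpec",
    "FrameStack",
    "render_signal",
    "simulate_ice",
    "render_movie",
    "apply_dose",
    "generate_gain_dark",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IceSpec:
    """Simulated amorphous-ice background.

    A white Gaussian field N(mean, sd^2) is low-pass filtered so it carries
    no content finer than ``lowpass_resolution`` (Å), then linearly rescaled
    so its minimum and maximum hit ``rescale_min`` and ``rescale_max``
    exactly. Defaults give a [0, 2] mean-electron background, matching
    typical per-pixel doses.

    ``filter_shape`` selects the spectral attenuation: ``gaussian`` (default;
    amplitude falls to 1% at the cutoff so out-of-band energy is negligible)
    or ``raised-cosine`` (cosine roll-off ending at the cutoff).
    """

    mean: float = 0.0
    sd: float = 1.0
    lowpass_resolution: float = 3.0
    rescale_min: float = 0.0
    rescale_max: float = 2.0
    filter_shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise InvalidParameterError("ice sd must be > 0")
        if self.rescale_min >= self.rescale_max:
            raise InvalidParameterError("rescale_min must be < rescale_max")
        if self.filter_shape not in ("gaussian", "raised-cosine"):
            raise InvalidParameterError(
                f"unknown filter_shape {self.filter_shape!r}"
            )


@dataclass(frozen=True)
class PhantomSpec:
    """Full recipe for one phantom movie.

    ``dims`` is (width, height) in pixels; ``signal_kind`` one of
    {"grid", "disc", "cross"}. The grid has lines every ``grid_step`` pixels,
    ``line_width`` pixels wide; disc/cross stamps use ``disc_radius`` /
    ``cross_arm`` (pixels). ``signal_amplitude`` is the mean-electron count
    the signal adds on top of the background, keeping Poisson means in a
    realistic range. ``dose_sampling`` toggles Poisson counting; ``seed``
    fixes all randomness.
    """

    dims: tuple[int, int] = (4096, 4096)
    n_frames: int = 70
    pixel_size: float = 1.0
    signal_kind: str = "grid"
    grid_step: int = 150
    line_width: int = 5
    disc_radius: float = 50.0
    cross_arm: float = 75.0
    signal_amplitude: float = 1.0
    ice: IceSpec | None = None
    dose_sampling: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.dims
        if w < 16 or h < 16:
            raise InvalidParameterError("dims must be >= 16 per axis")
        if self.n_frames < 1:
            raise InvalidParameterError("n_frames must be >= 1")
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be > 0")
        if self.signal_kind not in ("grid", "disc", "cross"):
            raise InvalidParameterError(
                f"unknown signal_kind {self.signal_kind!r}"
            )
        if not (self.grid_step > self.line_width > 0):
            raise InvalidParameterError("need grid_step > line_width > 0")
        if self.ice is not None and self.ice.lowpass_resolution < 2 * self.pixel_size:
            raise InvalidParameterError(
                "ice lowpass_resolution below Nyquist (2 * pixel_size)"
            )


@dataclass
class FrameStack:
    """Ordered movie frames with pixel size.

    ``frames`` has shape (n_frames, H, W); values are mean electron counts
    per pixel before dose sampling and integer counts after.
    """

    frames: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise InvalidParameterError("frames must be a (n, H, W) array")
        if not np.isfinite(self.frames).all():
            raise InvalidParameterError("frame values must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def dims(self) -> tuple[int, int]:
        """(width, height) in pixels."""
        return (self.frames.shape[2], self.frames.shape[1])


def render_signal(spec: PhantomSpec) -> np.ndarray:
    """Base signal image (H, W): grid lines, a centred disc, or a centred
    cross, of amplitude ``signal_amplitude`` on a zero background.

    Grid phase convention: lines start at pixel rows/columns congruent to 0
    modulo ``grid_step`` and span ``[c, c + line_width)``.
    """
    w, h = spec.dims
    img = np.zeros((h, w), dtype=np.float64)
    if spec.signal_kind == "grid":
        cols = np.arange(w) % spec.grid_step < spec.line_width
        rows = np.arange(h) % spec.grid_step < spec.line_width
        img[:, cols] = spec.signal_amplitude
        img[rows, :] = spec.signal_amplitude
    elif spec.signal_kind == "disc":
        yy, xx = np.mgrid[0:h, 0:w]
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= spec.disc_radius**2
        img[mask] = spec.signal_amplitude
    else:  # cross
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        half = spec.line_width / 2.0
        yy, xx = np.mgrid[0:h, 0:w]
        horiz = (np.abs(yy - cy) <= half) & (np.abs(xx - cx) <= spec.cross_arm)
        vert = (np.abs(xx - cx) <= half) & (np.abs(yy - cy) <= spec.cross_arm)
        img[horiz | vert] = spec.signal_amplitude
    return img


def _lowpass_transfer(
    fr: np.ndarray, cutoff: float, shape: str
) -> np.ndarray:
    """Spectral attenuation H(f) for radial frequency fr (cycles/px)."""
    if shape == "gaussian":
        # amplitude 1% at the cutoff -> power 1e-4; band edge effectively dark
        return np.exp(-math.log(100.0) * (fr / cutoff) ** 2)
    # raised-cosine: flat to 0.5*cutoff, cosine roll-off to zero at cutoff
    lo = 0.5 * cutoff
    h = np.ones_like(fr)
    ramp = (fr >= lo) & (fr < cutoff)
    h[ramp] = 0.5 * (1.0 + np.cos(math.pi * (fr[ramp] - lo) / (cutoff - lo)))
    h[fr >= cutoff] = 0.0
    return h


def simulate_ice(
    dims: tuple[int, int],
    ice: IceSpec,
    pixel_size: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Simulated ice image (H, W): filtered, rescaled Gaussian random field.

    Deterministic given ``seed``: same seed, bit-identical field. The output
    minimum and maximum equal ``rescale_min`` / ``rescale_max`` exactly.
    """
    if ice.lowpass_resolution < 2 * pixel_size:
        raise InvalidParameterError(
            "lowpass_resolution below Nyquist (2 * pixel_size)"
        )
    w, h = dims
    rng = np.random.default_rng(seed)
    white = rng.normal(ice.mean, ice.sd, size=(h, w))

    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    fr = np.sqrt(fx**2 + fy**2)
    cutoff = pixel_size / ice.lowpass_resolution  # cycles per pixel
    transfer = _lowpass_transfer(fr, cutoff, ice.filter_shape)
    smooth = np.fft.ifft2(np.fft.fft2(white) * transfer).real

    lo, hi = smooth.min(), smooth.max()
    if hi == lo:
        raise InvalidParameterError("degenerate ice field: constant after filtering")
    scaled = (smooth - lo) / (hi - lo)
    return ice.rescale_min + scaled * (ice.rescale_max - ice.rescale_min)


def render_content(spec: PhantomSpec) -> np.ndarray:
    """Static undeformed content: ice (if enabled) plus the signal."""
    content = np.zeros((spec.dims[1], spec.dims[0]), dtype=np.float64)
    if spec.ice is not None:
        content += simulate_ice(spec.dims, spec.ice, spec.pixel_size, spec.seed)
    content += render_signal(spec)
    return content


def render_movie(
    spec: PhantomSpec,
    truth: MotionGroundTruth,
    interpolation_order: int = 3,
) -> FrameStack:
    """Deterministic phantom frames: the static content warped per frame.

    The content (ice + signal) is built once and deformed by the frame's
    displacement field, so consecutive frames differ only by motion. Warping
    is bicubic by default; samples falling outside the content are filled
    with its mean to avoid spurious edges that would bias alignment.
    Output values are mean electron counts (dose sampling is a separate,
    optional step — see :func:`apply_dose`).
    """
    if truth.n_frames != spec.n_frames:
        raise InvalidParameterError("truth frame count != spec.n_frames")
    if tuple(truth.dims) != tuple(spec.dims):
        raise InvalidParameterError("truth dims != spec dims")
    content = render_content(spec)
    fill = float(content.mean())
    frames = np.empty((spec.n_frames, spec.dims[1], spec.dims[0]))
    for t in range(spec.n_frames):
        coords = displacement_field(truth, t)
        frames[t] = ndimage.map_coordinates(
            content, coords, order=interpolation_order,
            mode="constant", cval=fill,
        )
    return FrameStack(frames=frames, pixel_size=spec.pixel_size)


def apply_dose(stack: FrameStack, seed: int = 0) -> FrameStack:
    """Sample Poisson electron counts: each pixel's deterministic value is
    the mean of an independent Poisson draw.

    Negative means (possible after interpolation overshoot) are clipped to
    zero; the number of clipped pixels is logged. Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    means = stack.frames
    n_neg = int((means < 0).sum())
    if n_neg:
        logger.info("apply_dose: clipped %d negative Poisson means to 0", n_neg)
        means = np.clip(means, 0, None)
    counts = rng.poisson(means).astype(np.float64)
    return FrameStack(frames=counts, pixel_size=stack.pixel_size)


def simulate_movie(
    spec: PhantomSpec, truth: MotionGroundTruth
) -> FrameStack:
    """Full pipeline: deterministic rendering plus optional dose sampling."""
    stack = render_movie(spec, truth)
    if spec.dose_sampling:
        stack = apply_dose(stack, seed=spec.seed)
    return stack


def generate_gain_dark(dims: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """All-ones gain and all-zeros dark reference images at movie dims."""
    w, h = dims
    if w < 1 or h < 1:
        raise InvalidParameterError("dims must be positive")
    return np.ones((h, w), dtype=np.float32), np.zeros((h, w), dtype=np.float32)
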