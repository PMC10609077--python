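"""Ground-truth motion models for phantom cryo-EM movies.

Two ingredients make up the per-frame motion of a phantom movie:

* a **global drift** common to every pixel of a frame, produced either by a
  smooth parametric trajectory (linear + quadratic polynomial plus small
  trigonometric wobble) or by a fixed step per frame along a constant
  direction, and
* a **doming deformation** — the dome-like bulging of the specimen support
  under the beam — modelled as a barrel/pincushion radial transform whose
  coefficients grow linearly over the exposure so the deformation is more
  prominent in later frames.

Both are composed into a per-pixel *displacement field*: the map from each
output pixel of a frame to the source coordinate in the undeformed content.
Because the truth is parametric, an aligner's estimates can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "ShiftModel",
    "FixedStepModel",
    "DeformationSchedule",
    "MotionGroundTruth",
    "eval_shift",
    "fixed_step_shifts",
    "interp_k",
    "radial_deform",
    "displacement_field",
]


@dataclass(frozen=True)
class ShiftModel:
    """Parametric global drift trajectory.

    The shift of frame ``t`` (integer index, ``t >= 0``) is

    .. math::

        x(t) = a_1 t + a_2 t^2 + \\cos(t)/10, \\qquad
        y(t) = b_1 t + b_2 t^2 + \\sin(t^2)/5

    with trigonometric arguments in radians. The defaults emulate drift
    magnitudes commonly seen in cryo-EM exposures: the linear terms set the
    drift rate, the quadratic terms bend the trajectory, and the trig terms
    add sub-pixel wobble.
    """

    a1: float = -0.039
    a2: float = 0.002
    b1: float = -0.02
    b2: float = 0.002

    def __post_init__(self) -> None:
        for name in ("a1", "a2", "b1", "b2"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"{name} must be finite")

    def shifts(self, n_frames: int) -> np.ndarray:
        """Per-frame (x, y) shifts for frames 0..n_frames-1, shape (n, 2)."""
        if n_frames < 1:
            raise InvalidParameterError("n_frames must be >= 1")
        return np.array([eval_shift(self, t) for t in range(n_frames)])


@dataclass(frozen=True)
class FixedStepModel:
    """Constant per-frame step drift: frame 0 at rest, last frame displaced
    by ``total_shift`` pixels along ``direction`` (a unit 2-vector)."""

    total_shift: float
    n_frames: int
    direction: tuple[float, float] = (1.0 / math.sqrt(2), 1.0 / math.sqrt(2))

    def __post_init__(self) -> None:
        if self.total_shift < 0:
            raise InvalidParameterError("total_shift must be >= 0")
        if self.n_frames < 2:
            raise InvalidParameterError("n_frames must be >= 2")
        norm = math.hypot(*self.direction)
        if not math.isclose(norm, 1.0, rel_tol=0, abs_tol=1e-9):
            raise InvalidParameterError(
                f"direction must be a unit vector (norm {norm!r})"
            )

    def shifts(self) -> np.ndarray:
        return fixed_step_shifts(self)


@dataclass(frozen=True)
class DeformationSchedule:
    """Barrel/pincushion coefficients interpolated linearly across frames.

    ``k1``/``k2`` are the cubic and quintic radial-distortion coefficients of
    :func:`radial_deform`; they run from ``*_start`` at frame 0 to ``*_end``
    at the last frame, making the doming grow over the exposure.
    """

    n_frames: int
    k1_start: float = 0.01
    k1_end: float = 0.015
    k2_start: float = 0.01
    k2_end: float = 0.015

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise InvalidParameterError("n_frames must be >= 1")
        for name in ("k1_start", "k1_end", "k2_start", "k2_end"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"{name} must be finite")

    def coefficients(self) -> np.ndarray:
        """(n_frames, 2) array of (k1, k2) per frame."""
        return np.array([interp_k(self, t) for t in range(self.n_frames)])


@dataclass(frozen=True)
class MotionGroundTruth:
    """Exact per-frame motion of a simulated movie.

    ``shifts[t]`` is the (x, y) global drift of frame ``t`` in pixels;
    ``k_coeffs[t]`` the (k1, k2) doming coefficients. ``dims`` is
    (width, height) in pixels. ``normalization`` tags the radius convention
    used by the doming transform ("per-axis": each axis mapped linearly to
    [-1, 1] about the geometric frame centre).
    """

    shifts: np.ndarray
    k_coeffs: np.ndarray
    dims: tuple[int, int]
    normalization: str = "per-axis"

    def __post_init__(self) -> None:
        shifts = np.asarray(self.shifts, dtype=float)
        ks = np.asarray(self.k_coeffs, dtype=float)
        object.__setattr__(self, "shifts", shifts)
        object.__setattr__(self, "k_coeffs", ks)
        if shifts.ndim != 2 or shifts.shape[1] != 2:
            raise InvalidParameterError("shifts must have shape (n_frames, 2)")
        if ks.shape != shifts.shape:
            raise InvalidParameterError("k_coeffs must match shifts in shape")
        if not (np.isfinite(shifts).all() and np.isfinite(ks).all()):
            raise InvalidParameterError("motion entries must be finite")

    @property
    def n_frames(self) -> int:
        return self.shifts.shape[0]

    @classmethod
    def from_models(
        cls,
        shift_model: "ShiftModel | FixedStepModel",
        schedule: DeformationSchedule | None,
        n_frames: int,
        dims: tuple[int, int],
    ) -> "MotionGroundTruth":
        """Evaluate shift model + doming schedule into explicit per-frame truth."""
        if isinstance(shift_model, FixedStepModel):
            if shift_model.n_frames != n_frames:
                raise InvalidParameterError("FixedStepModel.n_frames mismatch")
            shifts = shift_model.shifts()
        else:
            shifts = shift_model.shifts(n_frames)
        if schedule is None:
            ks = np.zeros((n_frames, 2))
        else:
            if schedule.n_frames != n_frames:
                raise InvalidParameterError("DeformationSchedule.n_frames mismatch")
            ks = schedule.coefficients()
        return cls(shifts=shifts, k_coeffs=ks, dims=tuple(dims))


def eval_shift(model: ShiftModel, t: float) -> tuple[float, float]:
    """Global drift (x, y) in pixels of frame ``t``.

    Total function for t >= 0; trig arguments are radians.
    """
    if t < 0:
        raise InvalidParameterError("frame index t must be >= 0")
    x = model.a1 * t + model.a2 * t * t + math.cos(t) / 10.0
    y = model.b1 * t + model.b2 * t * t + math.sin(t * t) / 5.0
    return (x, y)


def fixed_step_shifts(model: FixedStepModel) -> np.ndarray:
    """Per-frame shifts of a fixed-step drift, shape (n_frames, 2).

    Frame 0 is at (0, 0); each frame advances total_shift/(n_frames-1)
    pixels along ``direction``; the final shift magnitude equals
    ``total_shift`` exactly (up to floating point).
    """
    step = model.total_shift / (model.n_frames - 1)
    d = np.asarray(model.direction, dtype=float)
    t = np.arange(model.n_frames, dtype=float)[:, None]
    return t * step * d[None, :]


def interp_k(schedule: DeformationSchedule, t: float) -> tuple[float, float]:
    """Doming coefficients (k1, k2) of frame ``t`` by linear interpolation."""
    n = schedule.n_frames
    if not (0 <= t <= n - 1):
        raise InvalidParameterError(f"frame index {t} outside [0, {n - 1}]")
    if n == 1:
        return (schedule.k1_start, schedule.k2_start)
    frac = t / (n - 1)
    k1 = schedule.k1_start + frac * (schedule.k1_end - schedule.k1_start)
    k2 = schedule.k2_start + frac * (schedule.k2_end - schedule.k2_start)
    return (k1, k2)


def radial_deform(r_in, k1: float, k2: float):
    """Barrel/pincushion radial transform on normalized radii.

    ``r_out = r_in * (1 + k1*r_in**2 + k2*r_in**4)``. The origin is a fixed
    point; for k1, k2 >= 0 the map is strictly increasing in r (no fold-over
    at the coefficient scale used here). Accepts scalars or arrays.
    """
    r = np.asarray(r_in, dtype=float)
    if np.any(r < 0):
        raise InvalidParameterError("radius must be >= 0")
    out = r * (1.0 + k1 * r**2 + k2 * r**4)
    if np.isscalar(r_in) or out.ndim == 0:
        return float(out)
    return out


def _normalized_grid(dims: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Per-axis normalized coordinates in [-1, 1] about the geometric centre.

    dims is (width, height); returns (nx, ny) meshgrids indexed [row, col].
    Uses the (N-1)/2 pixel-centre convention so the first and last pixel of
    each axis sit exactly at -1 and +1 (corners reach radius sqrt(2)).
    """
    w, h = dims
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    sx = cx if cx > 0 else 1.0
    sy = cy if cy > 0 else 1.0
    xs = (np.arange(w) - cx) / sx
    ys = (np.arange(h) - cy) / sy
    nx, ny = np.meshgrid(xs, ys)
    return nx, ny


def displacement_field(
    truth: MotionGroundTruth, t: int, dims: tuple[int, int] | None = None
) -> np.ndarray:
    """Output→source coordinate map for frame ``t``, shape (2, H, W).

    Composes the global shift (applied first to the content) with the doming
    transform of frame ``t``. For each output pixel the map gives the (row,
    col) coordinate in the undeformed content at which the frame samples —
    the inverse-mapping convention used for warping, which avoids scattering
    artifacts. The doming acts on per-axis normalized coordinates, pushing
    the sampling point radially outward by Eq.-of-motion factor
    ``1 + k1*r^2 + k2*r^4``; the shift is then undone by subtracting the
    frame's (x, y) drift.
    """
    if not (0 <= t < truth.n_frames):
        raise InvalidParameterError(f"frame index {t} outside movie")
    if dims is None:
        dims = truth.dims
    w, h = dims
    if w < 1 or h < 1:
        raise InvalidParameterError("dims must be positive")
    k1, k2 = truth.k_coeffs[t]
    sx_shift, sy_shift = truth.shifts[t]

    nx, ny = _normalized_grid((w, h))
    scale = 1.0 + k1 * (nx**2 + ny**2) + k2 * (nx**2 + ny**2) ** 2
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    half_w = cx if cx > 0 else 1.0
    half_h = cy if cy > 0 else 1.0
    # sampling position after doming, in pixel coordinates
    src_x = nx * scale * half_w + cx
    src_y = ny * scale * half_h + cy
    # undo the global shift (content was moved by (+x, +y) before doming)
    src_x -= sx_shift
    src_y -= sy_shift
    return np.stack([src_y, src_x])
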