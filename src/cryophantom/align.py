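"""Reference movie aligner: FFT cross-correlation with sub-pixel peaks,
all-pairs least-squares global alignment, patch-based local motion with a
cubic B-spline model in space and time, and micrograph synthesis.

This is deliberately a *reference* method of the cross-correlation family —
simple, deterministic and fully inspectable — not a re-implementation of any
particular production aligner. Global drift is estimated from every frame
pair and reconciled by least squares (which makes the estimate testable via
transitivity); residual local motion is measured on a grid of patches and
smoothed by a tensor-product cubic B-spline over (x, y, t), the
interpolation family used by several production tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import ndimage
from scipy.interpolate import BSpline

from .errors import (
    AlignmentFailureError,
    DegenerateInputError,
    InvalidParameterError,
)
from .phantom import FrameStack

__all__ = [
    "AlignConfig",
    "GlobalAlignment",
    "LocalMotionModel",
    "cc_shift_pair",
    "solve_global",
    "local_align",
    "render_micrograph",
    "align_movie",
]


@dataclass(frozen=True)
class AlignConfig:
    """Aligner settings.

    ``max_shift`` bounds the expected per-pair shift (pixels); the
    correlation peak is searched only within it, so an under-estimated bound
    reproduces the alignment failures seen when drift exceeds a tool's
    expectations. ``patch_grid`` is (px, py) or "auto" (5x5 below 5000 px
    frame width, 7x5 above). ``cc_smooth_px`` is the wavelength (pixels) of
    the Gaussian low-pass applied to correlation surfaces before peak search
    to suppress shot noise. ``consistency_tol_px`` flags pairwise
    measurements inconsistent with the least-squares consensus.
    """

    max_shift: float = 50.0
    patch_grid: tuple[int, int] | str = "auto"
    reference_frame: int | str = "middle"
    cc_smooth_px: float = 4.0
    interpolation: str = "cubic-bspline"
    output_convention: str = "average"
    consistency_tol_px: float = 5.0
    patch_max_shift: float = 16.0

    def __post_init__(self) -> None:
        if self.max_shift <= 0:
            raise InvalidParameterError("max_shift must be > 0")
        if self.interpolation not in ("cubic-bspline", "linear", "fourier-crop"):
            raise InvalidParameterError(
                f"unknown interpolation {self.interpolation!r}"
            )
        if self.output_convention not in ("average", "sum"):
            raise InvalidParameterError(
                f"unknown output_convention {self.output_convention!r}"
            )
        if isinstance(self.patch_grid, str):
            if self.patch_grid != "auto":
                raise InvalidParameterError("patch_grid must be (px, py) or 'auto'")
        elif min(self.patch_grid) < 1:
            raise InvalidParameterError("patch counts must be >= 1")

    def resolve_patch_grid(self, dims: tuple[int, int]) -> tuple[int, int]:
        """5x5 for frame widths below 5000 px, 7x5 for bigger frames."""
        if self.patch_grid != "auto":
            return tuple(self.patch_grid)  # type: ignore[return-value]
        return (5, 5) if dims[0] < 5000 else (7, 5)

    def resolve_reference(self, n_frames: int) -> int:
        if self.reference_frame == "middle":
            return n_frames // 2
        ref = int(self.reference_frame)
        if not (0 <= ref < n_frames):
            raise InvalidParameterError("reference_frame outside movie")
        return ref


@dataclass
class GlobalAlignment:
    """Per-frame rigid shift estimates referenced to ``reference_frame``.

    ``shifts[t]`` is the estimated (x, y) content drift of frame ``t``
    relative to the reference frame (whose shift is exactly (0, 0)).
    ``residual_norm`` is the RMS inconsistency of the pairwise measurements
    against the least-squares consensus; ``n_flagged``/``n_pairs`` summarise
    how many measurements were rejected.
    """

    shifts: np.ndarray
    reference_frame: int
    residual_norm: float
    n_pairs: int
    n_flagged: int

    @property
    def n_frames(self) -> int:
        return self.shifts.shape[0]


@dataclass
class LocalMotionModel:
    """Residual (post-global) motion on a patch grid, smoothed by a
    tensor-product cubic B-spline over (x, y, t)."""

    patch_centers: np.ndarray        # (P, 2) as (x, y)
    patch_shifts: np.ndarray         # (P, n_frames, 2) as (dx, dy)
    knots_x: np.ndarray
    knots_y: np.ndarray
    knots_t: np.ndarray
    coeffs: np.ndarray               # (2, ncx, ncy, nct) for (dx, dy)

    def evaluate(self, x, y, t) -> np.ndarray:
        """Local (dx, dy) at coordinates (x, y, t); broadcasts over arrays.

        Returns shape (2,) + broadcast shape.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        t = np.atleast_1d(np.asarray(t, dtype=float))
        bx = _design_matrix(x.ravel(), self.knots_x)
        by = _design_matrix(y.ravel(), self.knots_y)
        bt = _design_matrix(t.ravel(), self.knots_t)
        out = np.empty((2, x.size))
        for c in range(2):
            # sum_ijk bx_i by_j bt_k coef_ijk per data point
            tmp = np.einsum("pi,ijk->pjk", bx, self.coeffs[c])
            tmp = np.einsum("pj,pjk->pk", by, tmp)
            out[c] = np.einsum("pk,pk->p", bt, tmp)
        return out.reshape((2,) + x.shape)


def _smooth_sigma(cc_smooth_px: float) -> float:
    """Spatial Gaussian sigma for a low-pass of the given wavelength."""
    return cc_smooth_px / math.pi if cc_smooth_px > 0 else 0.0


def cc_shift_pair(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    max_shift: float,
    cc_smooth_px: float = 4.0,
) -> tuple[float, float]:
    """Sub-pixel shift of ``frame_b`` relative to ``frame_a`` by FFT
    cross-correlation.

    The correlation surface is optionally Gaussian low-pass filtered, the
    integer peak is searched within ±max_shift, and refined by fitting a 2-D
    parabola to its 3x3 neighbourhood. Returns (sx, sy) such that
    ``frame_b(p) ≈ frame_a(p - s)`` — i.e. the content of b sits ``s``
    pixels further along than in a. Ties in the integer peak break toward
    the smaller |shift|.
    """
    a = np.asarray(frame_a, dtype=np.float64)
    b = np.asarray(frame_b, dtype=np.float64)
    if a.shape != b.shape:
        raise InvalidParameterError("frames must share dims")
    if max_shift >= min(a.shape) / 4:
        raise InvalidParameterError("max_shift must be < min(dims)/4")
    a = a - a.mean()
    b = b - b.mean()
    if not (a.any() and b.any()):
        raise DegenerateInputError("zero-variance input: flat correlation surface")

    cc = np.fft.ifft2(np.fft.fft2(b) * np.conj(np.fft.fft2(a))).real
    sigma = _smooth_sigma(cc_smooth_px)
    if sigma > 0:
        cc = ndimage.fourier_gaussian(np.fft.fft2(cc), sigma)
        cc = np.fft.ifft2(cc).real
    cc = np.fft.fftshift(cc)
    if cc.max() == cc.min():
        raise DegenerateInputError("flat correlation surface")

    h, w = cc.shape
    cy, cx = h // 2, w // 2
    m = int(math.floor(max_shift))
    window = cc[cy - m : cy + m + 1, cx - m : cx + m + 1]
    # argmax with ties broken toward the smaller displacement
    peak_val = window.max()
    ties = np.argwhere(window == peak_val)
    d2 = ((ties - m) ** 2).sum(axis=1)
    py, px = ties[np.argmin(d2)]
    iy, ix = py - m, px - m

    def parabola_offset(cm, c0, cp):
        denom = cm - 2 * c0 + cp
        if denom >= 0:  # not a maximum; keep integer peak
            return 0.0
        off = 0.5 * (cm - cp) / denom
        return float(np.clip(off, -0.5, 0.5))

    gy, gx = cy + iy, cx + ix
    dx = dy = 0.0
    if 0 < gx < w - 1:
        dx = parabola_offset(cc[gy, gx - 1], cc[gy, gx], cc[gy, gx + 1])
    if 0 < gy < h - 1:
        dy = parabola_offset(cc[gy - 1, gx], cc[gy, gx], cc[gy + 1, gx])
    return (ix + dx, iy + dy)


def _lstsq_shifts(
    n: int, pairs: list[tuple[int, int]], measured: np.ndarray
) -> np.ndarray:
    """Solve per-frame shifts from pairwise differences s_ij = x_j - x_i."""
    rows = len(pairs)
    a_mat = np.zeros((rows + 1, n))
    for r, (i, j) in enumerate(pairs):
        a_mat[r, i] = -1.0
        a_mat[r, j] = 1.0
    a_mat[rows, 0] = 1.0  # gauge: pin frame 0 (re-referenced later)
    rhs = np.vstack([measured, np.zeros((1, 2))])
    sol, *_ = np.linalg.lstsq(a_mat, rhs, rcond=None)
    return sol


def solve_global(frames: FrameStack, cfg: AlignConfig) -> GlobalAlignment:
    """All-pairs global alignment with least-squares consensus.

    Every frame pair (i < j) is measured by :func:`cc_shift_pair`;
    measurements whose peak saturates the search bound, or that disagree
    with the consensus by more than ``consistency_tol_px``, are flagged and
    excluded. If more than half of all measurements — or more than half of
    any single frame's measurements — are flagged, the movie cannot be
    reliably aligned under the given ``max_shift`` and an
    :class:`AlignmentFailureError` is raised (mirroring the failures real
    aligners show when drift exceeds the expected-shift bound).
    """
    data = frames.frames
    n = data.shape[0]
    if n < 2:
        raise InvalidParameterError("need at least 2 frames")
    pairs = list(combinations(range(n), 2))
    measured = np.array(
        [
            cc_shift_pair(data[i], data[j], cfg.max_shift, cfg.cc_smooth_px)
            for i, j in pairs
        ]
    )
    # flag measurements that saturate the search window (true peak outside)
    boundary = np.abs(measured).max(axis=1) >= cfg.max_shift - 1.0
    flagged = boundary.copy()

    def check_failure(flag_mask: np.ndarray) -> None:
        if flag_mask.sum() > 0.5 * len(pairs):
            raise AlignmentFailureError(
                f"{int(flag_mask.sum())}/{len(pairs)} pairwise shifts exceed "
                f"max_shift={cfg.max_shift}; increase the expected-shift bound"
            )
        per_frame = np.zeros(n)
        per_frame_tot = np.zeros(n)
        for (i, j), f in zip(pairs, flag_mask):
            per_frame_tot[i] += 1
            per_frame_tot[j] += 1
            if f:
                per_frame[i] += 1
                per_frame[j] += 1
        worst = int(np.argmax(per_frame / per_frame_tot))
        if per_frame[worst] > 0.5 * per_frame_tot[worst]:
            raise AlignmentFailureError(
                f"frame {worst}: {int(per_frame[worst])}/{int(per_frame_tot[worst])} "
                f"pairwise shifts exceed max_shift={cfg.max_shift}"
            )

    check_failure(flagged)
    keep = [p for p, f in zip(pairs, flagged) if not f]
    sol = _lstsq_shifts(n, keep, measured[~flagged])

    # consistency pass: reject measurements that disagree with the consensus
    pred = np.array([sol[j] - sol[i] for i, j in pairs])
    resid = np.linalg.norm(measured - pred, axis=1)
    flagged |= resid > cfg.consistency_tol_px
    check_failure(flagged)
    if flagged.any():
        keep = [p for p, f in zip(pairs, flagged) if not f]
        sol = _lstsq_shifts(n, keep, measured[~flagged])
        pred = np.array([sol[j] - sol[i] for i, j in pairs])
        resid = np.linalg.norm(measured - pred, axis=1)

    ref = cfg.resolve_reference(n)
    shifts = sol - sol[ref]
    shifts[ref] = 0.0
    rms = float(np.sqrt(np.mean(resid[~flagged] ** 2))) if (~flagged).any() else 0.0
    return GlobalAlignment(
        shifts=shifts,
        reference_frame=ref,
        residual_norm=rms,
        n_pairs=len(pairs),
        n_flagged=int(flagged.sum()),
    )


def _clamped_knots(lo: float, hi: float, ncoef: int) -> np.ndarray:
    """Clamped cubic knot vector with ``ncoef`` basis functions on [lo, hi]."""
    if hi <= lo:
        hi = lo + 1.0
    interior = np.linspace(lo, hi, ncoef - 2)[1:-1]
    return np.concatenate([[lo] * 4, interior, [hi] * 4])


def _design_matrix(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    x = np.clip(x, knots[0], knots[-1])
    # keep the right domain edge inside the last span
    eps = 1e-9 * max(1.0, abs(knots[-1]))
    x = np.minimum(x, knots[-1] - eps)
    return BSpline.design_matrix(x, knots, 3).toarray()


def _patch_boxes(
    dims: tuple[int, int],
    grid: tuple[int, int],
    patch_size: int,
    margin: int = 0,
) -> list[tuple[int, int, int, int]]:
    """(x0, y0, size, size) boxes with centres on a uniform grid.

    Patches may overlap; boxes are clamped inside the frame, inset by
    ``margin`` pixels (the drift border, where compensated frames carry
    fill values rather than specimen content) where room allows.
    """
    w, h = dims
    px, py = grid
    mx = margin if w - 2 * margin >= patch_size else max((w - patch_size) // 2, 0)
    my = margin if h - 2 * margin >= patch_size else max((h - patch_size) // 2, 0)
    boxes = []
    for gy in range(py):
        cy = (gy + 0.5) * h / py
        y0 = int(round(np.clip(cy - patch_size / 2, my, h - patch_size - my)))
        for gx in range(px):
            cx = (gx + 0.5) * w / px
            x0 = int(round(np.clip(cx - patch_size / 2, mx, w - patch_size - mx)))
            boxes.append((x0, y0, patch_size, patch_size))
    return boxes


def local_align(
    frames: FrameStack, global_alignment: GlobalAlignment, cfg: AlignConfig
) -> LocalMotionModel:
    """Patch-based residual motion after global compensation.

    Frames are first shifted back by the estimated global drift, the frame
    is divided into the patch grid, and each patch's per-frame residual
    shift is measured against the patch's temporal average. A tensor-product
    cubic B-spline over (x, y, t) — (patch count + 3) coefficients per
    spatial axis, n_frames/2 temporal coefficients — is least-squares fitted
    to all patch shifts.
    """
    data = frames.frames
    n, h, w = data.shape
    grid = cfg.resolve_patch_grid((w, h))
    patch_size = max(min(h, w) // max(grid), 128)
    patch_size = min(patch_size, min(h, w))
    if patch_size < 128:
        raise InvalidParameterError(
            f"patch size {patch_size} px < 128 px; reduce the patch grid"
        )

    compensated = np.empty_like(data)
    for t in range(n):
        sx, sy = global_alignment.shifts[t]
        compensated[t] = ndimage.shift(
            data[t], (-sy, -sx), order=3, mode="nearest"
        )

    margin = int(np.ceil(np.abs(global_alignment.shifts).max())) + 2
    boxes = _patch_boxes((w, h), grid, patch_size, margin)
    centers = np.array(
        [(x0 + s / 2.0, y0 + s / 2.0) for x0, y0, s, s in boxes]
    )
    patch_shifts = np.zeros((len(boxes), n, 2))
    bound = min(cfg.patch_max_shift, patch_size / 4 - 1)
    for p, (x0, y0, sz, _) in enumerate(boxes):
        stackp = compensated[:, y0 : y0 + sz, x0 : x0 + sz]
        refp = stackp.mean(axis=0)
        for t in range(n):
            try:
                patch_shifts[p, t] = cc_shift_pair(
                    refp, stackp[t], bound, cfg.cc_smooth_px
                )
            except DegenerateInputError:
                patch_shifts[p, t] = 0.0

    ncx = grid[0] + 3
    ncy = grid[1] + 3
    nct = max(4, n // 2 + 4)  # n/2 interior temporal knots + clamped ends
    kx = _clamped_knots(0.0, w - 1.0, ncx)
    ky = _clamped_knots(0.0, h - 1.0, ncy)
    kt = _clamped_knots(0.0, n - 1.0, nct)

    xs = np.repeat(centers[:, 0], n)
    ys = np.repeat(centers[:, 1], n)
    ts = np.tile(np.arange(n, dtype=float), len(boxes))
    bx = _design_matrix(xs, kx)
    by = _design_matrix(ys, ky)
    bt = _design_matrix(ts, kt)
    design = np.einsum("pi,pj,pk->pijk", bx, by, bt).reshape(len(xs), -1)
    coeffs = np.empty((2, ncx, ncy, nct))
    for c in range(2):
        rhs = patch_shifts[:, :, c].reshape(-1)
        sol, *_ = np.linalg.lstsq(design, rhs, rcond=None)
        coeffs[c] = sol.reshape(ncx, ncy, nct)
    return LocalMotionModel(
        patch_centers=centers,
        patch_shifts=patch_shifts,
        knots_x=kx,
        knots_y=ky,
        knots_t=kt,
        coeffs=coeffs,
    )


def render_micrograph(
    frames: FrameStack,
    global_alignment: GlobalAlignment,
    local: LocalMotionModel | None = None,
    cfg: AlignConfig | None = None,
) -> np.ndarray:
    """Combine motion-compensated frames into a micrograph.

    Each frame is warped by the inverse of its estimated motion (global
    drift plus, if available, the B-spline local field) using the configured
    interpolation, then frames are combined as their average (default) or
    sum. ``fourier-crop`` applies the global shift as an exact Fourier phase
    ramp; any local field is applied on top with cubic interpolation.
    """
    cfg = cfg or AlignConfig()
    data = frames.frames
    n, h, w = data.shape
    if global_alignment.n_frames != n:
        raise InvalidParameterError("alignment frame count != movie frames")
    order = {"cubic-bspline": 3, "linear": 1}.get(cfg.interpolation)

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    acc = np.zeros((h, w))
    for t in range(n):
        sx, sy = global_alignment.shifts[t]
        frame = data[t]
        if cfg.interpolation == "fourier-crop":
            spec = np.fft.fft2(frame)
            frame = np.fft.ifft2(ndimage.fourier_shift(spec, (-sy, -sx))).real
            if local is not None:
                loc = local.evaluate(xx.ravel(), yy.ravel(), float(t))
                lx = loc[0].reshape(h, w)
                ly = loc[1].reshape(h, w)
                frame = ndimage.map_coordinates(
                    frame, [yy + ly, xx + lx], order=3, mode="nearest"
                )
            acc += frame
            continue
        ux = np.full((h, w), sx)
        uy = np.full((h, w), sy)
        if local is not None:
            loc = local.evaluate(xx.ravel(), yy.ravel(), float(t))
            ux = ux + loc[0].reshape(h, w)
            uy = uy + loc[1].reshape(h, w)
        acc += ndimage.map_coordinates(
            frame, [yy + uy, xx + ux], order=order, mode="nearest"
        )
    if cfg.output_convention == "average":
        return acc / n
    return acc


def align_movie(
    frames: FrameStack, cfg: AlignConfig | None = None, with_local: bool = True
) -> tuple[GlobalAlignment, LocalMotionModel | None, np.ndarray]:
    """Convenience pipeline: global + optional local alignment + micrograph."""
    cfg = cfg or AlignConfig()
    global_alignment = solve_global(frames, cfg)
    local = local_align(frames, global_alignment, cfg) if with_local else None
    micrograph = render_micrograph(frames, global_alignment, local, cfg)
    return global_alignment, local, micrograph
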