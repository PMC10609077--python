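"""Per-micrograph quality measures: window crops, trimmed-CV histogram,
radially averaged power spectral density, the PSD-drop resolution limit,
and shift-recovery error against the simulator's ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, InvalidParameterError, UndefinedCVError
from .motion import MotionGroundTruth

__all__ = [
    "WindowTriplet",
    "RadialPSD",
    "extract_windows",
    "histogram_cv",
    "radial_psd",
    "psd_resolution_limit",
    "shift_rmse",
]

WINDOW = 512


@dataclass
class WindowTriplet:
    """512x512 crops from the top-left corner, centre, and bottom-right
    corner of a micrograph, plus a mean-0 / sd-1 normalized centre window."""

    top_left: np.ndarray
    center: np.ndarray
    bottom_right: np.ndarray
    center_normalized: np.ndarray
    offsets: dict


@dataclass
class RadialPSD:
    """Azimuthally averaged power spectrum.

    ``freq`` is in cycles/pixel (bin 0 is DC); ``power`` the mean |FFT|^2
    per radial bin (linear scale — use :attr:`log_power` for plotting);
    ``total_power`` is the full unnormalized spectral energy (Parseval).
    """

    freq: np.ndarray
    power: np.ndarray
    pixel_size: float
    total_power: float

    @property
    def log_power(self) -> np.ndarray:
        return np.log10(np.maximum(self.power, np.finfo(float).tiny))

    @property
    def resolution_A(self) -> np.ndarray:
        """Per-bin resolution in Å (inf at DC)."""
        with np.errstate(divide="ignore"):
            return self.pixel_size / self.freq


def extract_windows(micrograph: np.ndarray, window: int = WINDOW) -> WindowTriplet:
    """Crop the three diagnostic windows and normalize the centre one."""
    img = np.asarray(micrograph, dtype=np.float64)
    h, w = img.shape
    if h < window or w < window:
        raise InvalidParameterError(
            f"micrograph {w}x{h} smaller than the {window}x{window} window"
        )
    oy, ox = (h - window) // 2, (w - window) // 2
    tl = img[:window, :window].copy()
    ct = img[oy : oy + window, ox : ox + window].copy()
    br = img[h - window :, w - window :].copy()
    sd = ct.std()
    if sd == 0:
        raise DegenerateInputError("centre window has zero sd; cannot normalize")
    return WindowTriplet(
        top_left=tl,
        center=ct,
        bottom_right=br,
        center_normalized=(ct - ct.mean()) / sd,
        offsets={
            "top_left": (0, 0),
            "center": (oy, ox),
            "bottom_right": (h - window, w - window),
        },
    )


def histogram_cv(
    micrograph: np.ndarray,
    iqr_fraction: float = 0.80,
    fence: float = 1.5,
    bins: int = 256,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Histogram of raw pixel values and outlier-trimmed CV (%).

    The coefficient of variation is 100*sd/mean computed after removing
    values outside ``[Q_lo - fence*IQR, Q_hi + fence*IQR]`` where Q_lo/Q_hi
    bound the central ``iqr_fraction`` of the distribution (Q10/Q90 for the
    default 80% IQR). Returns (counts, bin_edges, cv_percent).
    """
    vals = np.asarray(micrograph, dtype=np.float64).ravel()
    if vals.size == 0:
        raise InvalidParameterError("empty image")
    counts, edges = np.histogram(vals, bins=bins)
    lo_q = (1.0 - iqr_fraction) / 2.0
    q_lo, q_hi = np.quantile(vals, [lo_q, 1.0 - lo_q])
    iqr = q_hi - q_lo
    kept = vals[(vals >= q_lo - fence * iqr) & (vals <= q_hi + fence * iqr)]
    mean = kept.mean()
    if mean == 0:
        raise UndefinedCVError("trimmed mean is zero; CV undefined")
    cv = 100.0 * kept.std() / abs(mean)
    return counts, edges, float(cv)


def radial_psd(micrograph: np.ndarray, pixel_size: float = 1.0) -> RadialPSD:
    """Azimuthally averaged |FFT|^2 in ⌊min(dims)/2⌋ radial bins.

    Binning rounds each pixel's radial frequency to the nearest bin centre
    ``i / min(dims)`` cycles/px; frequencies beyond the last bin (square
    corners) are excluded from the profile but included in
    :attr:`RadialPSD.total_power`.
    """
    img = np.asarray(micrograph, dtype=np.float64)
    h, w = img.shape
    if min(h, w) < 64:
        raise InvalidParameterError("image must be at least 64 px per axis")
    spec = np.abs(np.fft.fft2(img)) ** 2
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    fr = np.sqrt(fx**2 + fy**2)
    nmin = min(h, w)
    nbins = nmin // 2
    idx = np.rint(fr * nmin).astype(int)
    mask = idx < nbins
    sums = np.bincount(idx[mask].ravel(), weights=spec[mask].ravel(), minlength=nbins)
    cnts = np.bincount(idx[mask].ravel(), minlength=nbins)
    power = sums / np.maximum(cnts, 1)
    freq = np.arange(nbins) / nmin
    return RadialPSD(
        freq=freq, power=power, pixel_size=pixel_size,
        total_power=float(spec.sum()),
    )


def psd_resolution_limit(
    psd: RadialPSD, drop: float = 100.0, origin: str = "dc"
) -> float:
    """Resolution (Å) where the radial PSD first drops below 1/``drop`` of
    its value at the origin; falls back to the Nyquist resolution
    (2 * pixel size) when the profile never drops below the threshold.

    ``origin`` selects the reference power: ``"dc"`` uses the true zero-
    frequency bin; ``"first-band"`` uses the first non-DC bin instead, which
    is the practical choice for untapered micrographs whose mean offset
    concentrates an arbitrarily large power at exact DC.
    """
    if psd.power.size < 2:
        raise InvalidParameterError("PSD must have a DC bin and at least one more")
    if origin == "dc":
        ref, start = psd.power[0], 1
    elif origin == "first-band":
        ref, start = psd.power[1], 2
    else:
        raise InvalidParameterError(f"unknown origin {origin!r}")
    threshold = ref / drop
    below = np.nonzero(psd.power[start:] < threshold)[0]
    if below.size == 0:
        return 2.0 * psd.pixel_size
    f = psd.freq[below[0] + start]
    return float(psd.pixel_size / f)


def shift_rmse(estimated: np.ndarray, truth: "MotionGroundTruth | np.ndarray",
               reference_frame: int | None = None) -> float:
    """RMSE (pixels) between estimated and true per-frame global shifts.

    Both trajectories are re-referenced to the estimator's reference frame
    (so the arbitrary gauge of either trajectory cancels), then the root
    mean square of the per-frame Euclidean shift error is returned.

    ``estimated`` may be a GlobalAlignment (its reference frame is used) or
    an (n, 2) array with ``reference_frame`` given.
    """
    if hasattr(estimated, "shifts") and hasattr(estimated, "reference_frame"):
        est = np.asarray(estimated.shifts, dtype=float)
        ref = estimated.reference_frame
    else:
        est = np.asarray(estimated, dtype=float)
        ref = reference_frame if reference_frame is not None else 0
    true = truth.shifts if isinstance(truth, MotionGroundTruth) else np.asarray(truth)
    true = np.asarray(true, dtype=float)
    if est.shape != true.shape:
        raise InvalidParameterError(
            f"frame-count mismatch: estimated {est.shape} vs truth {true.shape}"
        )
    est = est - est[ref]
    true = true - true[ref]
    err = np.linalg.norm(est - true, axis=1)
    return float(np.sqrt(np.mean(err**2)))
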