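"""Particle localization and frame-to-frame linking for brightfield movies.

Detection follows the cross-correlation approach of the tracking pipeline:
frames are matched against a particle reference image (normalized
cross-correlation), correlation maxima are refined to subpixel precision by
a 2D Gaussian fit, and detections are linked into trajectories by greedy
nearest-neighbor assignment.  A radial-symmetry localizer is provided for
the internalization videos, and the rolling time-median filter suppresses
moving particles ahead of the shear-phase analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from skimage.feature import match_template, peak_local_max

__all__ = [
    "ImageStack",
    "Detection",
    "Trajectory",
    "gaussian_template",
    "detect_particles",
    "localize_radial_symmetry",
    "link_detections",
    "static_filter",
]


@dataclass
class ImageStack:
    """Grayscale movie: frames x rows x cols, with pixel size (um/px) and dt (s)."""

    pixels: np.ndarray
    pixel_size: float
    dt: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise ValueError("expected a frames x rows x cols array")
        if self.pixel_size <= 0 or self.dt <= 0:
            raise ValueError("pixel size and frame interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]


@dataclass
class Detection:
    """One localized particle in one frame.  Positions are in pixels (subpixel)."""

    frame: int
    x: float
    y: float
    amplitude: float = np.nan
    width: float = np.nan
    score: float = np.nan


@dataclass
class Trajectory:
    """Ordered detections of one particle; at most one detection per frame."""

    track_id: int
    detections: list[Detection] = field(default_factory=list)

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame for d in self.detections], dtype=int)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) in pixels."""
        return np.array([[d.x, d.y] for d in self.detections], dtype=float)

    @property
    def start_frame(self) -> int:
        return self.detections[0].frame

    @property
    def end_frame(self) -> int:
        return self.detections[-1].frame

    def __len__(self) -> int:
        return len(self.detections)


def gaussian_template(radius_px: float, size: int | None = None) -> np.ndarray:
    """Synthetic bright-spot reference image: isotropic Gaussian of sigma ~ radius/2."""
    if size is None:
        size = int(2 * round(2 * radius_px) + 1)
    ax = np.arange(size) - (size - 1) / 2.0
    xx, yy = np.meshgrid(ax, ax)
    sigma = max(radius_px / 2.0, 0.8)
    return np.exp(-(xx**2 + yy**2) / (2 * sigma**2))


def _gauss2d(params, xx, yy):
    a, x0, y0, s, b = params
    return a * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * s**2)) + b


def _fit_gaussian(patch: np.ndarray, x0: float, y0: float) -> tuple[float, float, float, float]:
    """Least-squares 2D Gaussian refinement inside a window; returns x, y, amp, sigma."""
    ny, nx = patch.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    b0 = float(patch.min())
    a0 = float(patch.max() - b0)
    p0 = np.array([a0 if a0 > 0 else 1.0, x0, y0, max(nx / 6.0, 1.0), b0])

    def resid(p):
        return (_gauss2d(p, xx, yy) - patch).ravel()

    sol = optimize.least_squares(resid, p0, method="lm", max_nfev=200)
    a, xf, yf, s, _ = sol.x
    return float(xf), float(yf), float(a), float(abs(s))


def detect_particles(frame: np.ndarray, template: np.ndarray,
                     peak_threshold: float = 0.5,
                     min_correlation: float = 0.4,
                     fit_window: int = 11,
                     merge_radius: float | None = None) -> list[Detection]:
    """Detect bright particles in one frame by normalized cross-correlation.

    Local correlation maxima above ``peak_threshold`` (as a fraction of the
    correlation maximum) and above the absolute floor ``min_correlation``
    (which keeps particle-free noise frames empty) are refined by a 2D
    Gaussian fit in an ``fit_window`` x ``fit_window`` neighborhood;
    detections closer than ``merge_radius`` pixels (default: half the
    template size) are merged.
    """
    frame = np.asarray(frame, dtype=float)
    if template.shape[0] >= frame.shape[0] or template.shape[1] >= frame.shape[1]:
        raise ValueError("template must be smaller than the frame")
    if frame.std() == 0:
        return []
    corr = match_template(frame, template, pad_input=True)
    cmax = corr.max()
    if cmax <= 0:
        return []
    min_dist = max(int(template.shape[0] // 2), 1)
    peaks = peak_local_max(corr, min_distance=min_dist,
                           threshold_abs=max(peak_threshold * cmax, min_correlation))
    if merge_radius is None:
        merge_radius = template.shape[0] / 2.0

    half = fit_window // 2
    detections: list[Detection] = []
    for py, px in peaks:
        y0, y1 = max(py - half, 0), min(py + half + 1, frame.shape[0])
        x0, x1 = max(px - half, 0), min(px + half + 1, frame.shape[1])
        patch = frame[y0:y1, x0:x1]
        try:
            xf, yf, amp, sig = _fit_gaussian(patch, px - x0, py - y0)
        except Exception:
            xf, yf, amp, sig = px - x0, py - y0, np.nan, np.nan
        x, y = x0 + xf, y0 + yf
        # reject fits that ran away from the correlation peak or collapsed to
        # an implausible width (flat texture can absorb the Gaussian)
        if not (abs(x - px) <= half and abs(y - py) <= half
                and 0.3 <= sig <= fit_window):
            x, y = float(px), float(py)
            amp = float(patch.max() - patch.min())
            sig = np.nan
        if not (0 <= x < frame.shape[1] and 0 <= y < frame.shape[0]):
            continue
        detections.append(Detection(frame=0, x=x, y=y, amplitude=amp, width=sig,
                                    score=float(corr[py, px])))

    # merge duplicates within one particle radius, keeping the higher score
    detections.sort(key=lambda d: -(d.score if np.isfinite(d.score) else 0.0))
    kept: list[Detection] = []
    for det in detections:
        if all((det.x - k.x) ** 2 + (det.y - k.y) ** 2 > merge_radius**2 for k in kept):
            kept.append(det)
    return kept


def localize_radial_symmetry(roi: np.ndarray, smooth_sigma: float = 1.0,
                             grad_quantile: float = 0.9) -> tuple[float, float]:
    """Subpixel center of a radially symmetric spot via gradient-line least squares.

    Every pixel's intensity gradient defines a line through the pixel along the
    gradient direction; for a radially symmetric pattern all such lines pass
    through the center.  The center is the point minimizing a weighted sum of
    squared distances to these lines, which is a 2x2 linear solve.  Weights are
    the squared gradient magnitude (pixels below the ``grad_quantile`` of it
    are dropped — flat background carries no radial information) divided by
    the distance to the gradient-magnitude centroid; the image is lightly
    smoothed first.  Exact for noise-free symmetric input; returns (x, y) in
    pixel coordinates of ``roi``.
    """
    img = np.asarray(roi, dtype=float)
    if smooth_sigma > 0:
        img = ndimage.gaussian_filter(img, smooth_sigma)
    gy, gx = np.gradient(img)
    w = gx**2 + gy**2
    if w.sum() == 0:
        raise ValueError("zero-gradient patch: center undefined")
    ny, nx = img.shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    if grad_quantile is not None:
        w = np.where(w >= np.quantile(w, grad_quantile), w, 0.0)
        if w.sum() == 0:
            raise ValueError("zero-gradient patch: center undefined")
    cx0 = (w * xx).sum() / w.sum()
    cy0 = (w * yy).sum() / w.sum()
    w = w / (np.hypot(xx - cx0, yy - cy0) + 1.0)
    # unit gradient directions where defined
    mag = np.sqrt(gx**2 + gy**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(mag > 0, gx / mag, 0.0)
        uy = np.where(mag > 0, gy / mag, 0.0)
    # distance of point c to the line through (x, y) with direction u:
    # |(c - r)|^2 - ((c - r).u)^2  ->  normal projector P = I - u u^T
    # minimize sum w * (c - r)^T P (c - r)  ->  (sum w P) c = sum w P r
    pxx = w * (1.0 - ux * ux)
    pxy = w * (-ux * uy)
    pyy = w * (1.0 - uy * uy)
    a11, a12, a22 = pxx.sum(), pxy.sum(), pyy.sum()
    b1 = (pxx * xx + pxy * yy).sum()
    b2 = (pxy * xx + pyy * yy).sum()
    det = a11 * a22 - a12 * a12
    if det == 0:
        raise ValueError("degenerate gradient structure: center undefined")
    cx = (a22 * b1 - a12 * b2) / det
    cy = (a11 * b2 - a12 * b1) / det
    return float(cx), float(cy)


def link_detections(detections_by_frame: dict[int, list[Detection]],
                    max_step: float, max_gap: int = 0,
                    pixel_size: float = 1.0) -> list[Trajectory]:
    """Greedy nearest-neighbor linking of per-frame detections into trajectories.

    ``max_step`` is the largest allowed displacement in micrometers per frame
    transition (scaled by ``max_gap + 1`` across bridged gaps); detections are
    assigned in ascending-distance order, each to at most one track.
    """
    tracks: list[Trajectory] = []
    active: list[Trajectory] = []
    next_id = 0
    frames = sorted(detections_by_frame)
    for f in frames:
        dets = list(detections_by_frame[f])
        for d in dets:
            d.frame = f
        # candidate pairs (distance, track, detection)
        pairs = []
        for tr in active:
            last = tr.detections[-1]
            gap = f - last.frame
            if gap < 1 or gap > max_gap + 1:
                continue
            limit = max_step * gap / pixel_size
            for d in dets:
                dist = np.hypot(d.x - last.x, d.y - last.y)
                if dist <= limit:
                    pairs.append((dist, tr, d))
        pairs.sort(key=lambda p: p[0])
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for dist, tr, d in pairs:
            if id(tr) in used_tracks or id(d) in used_dets:
                continue
            tr.detections.append(d)
            used_tracks.add(id(tr))
            used_dets.add(id(d))
        for d in dets:
            if id(d) not in used_dets:
                tracks.append(Trajectory(track_id=next_id, detections=[d]))
                active.append(tracks[-1])
                next_id += 1
        active = [tr for tr in active if f - tr.detections[-1].frame <= max_gap]
    return tracks


def static_filter(stack: ImageStack, window: float) -> ImageStack:
    """Per-pixel rolling median over a time window (seconds).

    Suppresses moving particles while preserving static ones; applied to the
    shear-phase movie before counting attached particles.
    """
    if window < stack.dt:
        raise ValueError("window must be at least one frame interval")
    n = int(round(window / stack.dt))
    n = max(n, 1)
    if n % 2 == 0:
        n += 1
    if stack.n_frames < n:
        raise ValueError("stack has fewer frames than the filter window")
    filtered = ndimage.median_filter(stack.pixels, size=(n, 1, 1), mode="nearest")
    return ImageStack(filtered, stack.pixel_size, stack.dt)
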