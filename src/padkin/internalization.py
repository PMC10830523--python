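"""Cell masking, particle-cell-interaction standardization, internalization
probabilities, and ring-ROI fluorescence time series.

The cell mask is the product of a DIC local-contrast mask and a thresholded
fluorescence maximum projection, post-processed by hole filling, Gaussian
smoothing and small-object removal.  Particle-cell interaction (PCI) counts
are standardized for coverslip-to-coverslip variation in cell area and
particle load.  The conditional internalization probability is the fraction
of internalized particles among particle-cell interactions; multiplying by
the shear-assay remaining fraction gives the absolute probability that a
particle encountering a cell ends up internalized.

Engulfment dynamics are read out from ring-shaped ROIs around each tracked
particle: the mean intensity in a surface ring [r-3, r+2] px normalized by a
reference ring [r+9, r+12] px, per frame and channel.  The normalization
cancels global intensity drift such as photobleaching.  An actin (LifeAct)
peak preceding the acidification (LysoTracker) onset is the signature of
actin-driven engulfment followed by phagosome maturation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "CellMask",
    "PCIRecord",
    "RingIntensityTrace",
    "cell_mask_dic",
    "cell_mask_fluorescence",
    "combine_masks",
    "standardize_pci",
    "internalization_probabilities",
    "ring_intensity_trace",
    "choose_ring_radius",
    "detect_peak_then_acidification",
]


@dataclass
class CellMask:
    mask: np.ndarray
    pixel_size_um: float

    @property
    def area_um2(self) -> float:
        return float(np.count_nonzero(self.mask)) * self.pixel_size_um**2

    def extrapolated_area_um2(self, roi_area_um2: float, target_area_um2: float) -> float:
        """Scale the covered area from the imaged ROI to a larger target area."""
        return self.area_um2 * target_area_um2 / roi_area_um2


@dataclass(frozen=True)
class PCIRecord:
    """Per-coverslip particle-cell interaction bookkeeping."""

    pci_cs: float                 # interactions extrapolated to the coverslip
    area_cells_um2: float         # A_CS, cell-covered area on the coverslip
    area_single_cell_um2: float   # mean area of one cell
    n_particles_cs: float         # particles added to this coverslip
    n_cells_standard: float       # cells on the standard coverslip
    n_particles_standard: float   # particles on the standard coverslip


@dataclass
class RingIntensityTrace:
    lifeact: np.ndarray
    lysotracker: np.ndarray
    radius_px: int
    times: np.ndarray | None = None


def _disk_footprint(radius: int) -> np.ndarray:
    ax = np.arange(-radius, radius + 1)
    xx, yy = np.meshgrid(ax, ax)
    return xx**2 + yy**2 <= radius**2


def cell_mask_dic(dic_image: np.ndarray, threshold: float, radius_px: int = 3) -> np.ndarray:
    """Local-contrast mask: 1 where the intensity range (max - min) within a
    circular window of ``radius_px`` exceeds ``threshold``."""
    img = np.asarray(dic_image, dtype=float)
    fp = _disk_footprint(radius_px)
    local_range = (ndimage.maximum_filter(img, footprint=fp)
                   - ndimage.minimum_filter(img, footprint=fp))
    return local_range > threshold


def cell_mask_fluorescence(stack: np.ndarray, threshold: float) -> np.ndarray:
    """Threshold of the maximum projection of an axial fluorescence stack."""
    arr = np.asarray(stack, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    return arr.max(axis=0) > threshold


def combine_masks(m_dic: np.ndarray, m_f: np.ndarray, pixel_size_um: float,
                  fill_hole_um2: float = 40.0, smooth_radius_px: float = 3.0,
                  min_object_um2: float = 80.0) -> CellMask:
    """Pixelwise product of the DIC and fluorescence masks, post-processed.

    Holes up to ``fill_hole_um2`` are filled, the mask is Gaussian-smoothed
    and re-binarized, and objects below ``min_object_um2`` are removed.
    """
    m_dic = np.asarray(m_dic, dtype=bool)
    m_f = np.asarray(m_f, dtype=bool)
    if m_dic.shape != m_f.shape:
        raise ValueError("mask shapes differ")
    mask = m_dic & m_f

    px_area = pixel_size_um**2
    # fill holes up to the size limit: label background components fully
    # enclosed by the mask and absorb the small ones
    holes = ndimage.binary_fill_holes(mask) & ~mask
    lab, n = ndimage.label(holes)
    if n:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        small = np.isin(lab, np.nonzero(sizes * px_area <= fill_hole_um2)[0] + 1)
        mask = mask | small

    if smooth_radius_px > 0:
        mask = ndimage.gaussian_filter(mask.astype(float), smooth_radius_px) > 0.5

    lab, n = ndimage.label(mask)
    if n:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        keep = np.nonzero(sizes * px_area >= min_object_um2)[0] + 1
        mask = np.isin(lab, keep)
    return CellMask(mask=mask, pixel_size_um=pixel_size_um)


def standardize_pci(rec: PCIRecord) -> float:
    """Standardized interaction count:

    PCI_stand = PCI_CS * (N_cells,std / (A_CS / A_singleCell)) * (N_particles,std / N_particles,CS)
    """
    if rec.area_single_cell_um2 <= 0 or rec.n_particles_cs <= 0 or rec.area_cells_um2 <= 0:
        raise ValueError("areas and particle counts must be positive")
    n_cells_cs = rec.area_cells_um2 / rec.area_single_cell_um2
    return (rec.pci_cs * (rec.n_cells_standard / n_cells_cs)
            * (rec.n_particles_standard / rec.n_particles_cs))


def internalization_probabilities(n_internalized: float, n_interactions: float,
                                  remaining_fraction: float,
                                  sem_conditional: float | None = None,
                                  sem_remaining: float | None = None,
                                  ) -> dict:
    """Conditional and absolute internalization probabilities.

    conditional = internalized / interactions; absolute = conditional *
    remaining fraction.  When both uncertainties are supplied, the absolute
    probability's error combines the relative errors in quadrature.
    """
    if n_interactions <= 0:
        return {"conditional": None, "absolute": None,
                "flags": ["no interactions: probabilities undefined"]}
    conditional = n_internalized / n_interactions
    absolute = conditional * remaining_fraction
    out = {"conditional": conditional, "absolute": absolute, "flags": []}
    if sem_conditional is not None and sem_remaining is not None:
        rel = 0.0
        if conditional > 0:
            rel += (sem_conditional / conditional) ** 2
        if remaining_fraction > 0:
            rel += (sem_remaining / remaining_fraction) ** 2
        out["sem_absolute"] = absolute * float(np.sqrt(rel))
    return out


def _ring_means(frame: np.ndarray, cx: float, cy: float,
                inner: tuple[float, float], outer: tuple[float, float],
                ) -> tuple[float, float, float]:
    ny, nx = frame.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    d = np.hypot(xx - cx, yy - cy)
    ring = (d >= inner[0]) & (d <= inner[1])
    ref = (d >= outer[0]) & (d <= outer[1])
    if not ref.any():
        raise ValueError("reference ring is empty (particle too close to the edge)")
    ref_vals = frame[ref]
    return float(frame[ring].mean()), float(ref_vals.mean()), float(ref_vals.std())


def choose_ring_radius(frame: np.ndarray, cx: float, cy: float, r_nominal: float) -> int:
    """Integer ring radius maximizing (surface-ring mean - reference mean) / reference SD.

    Searched over [0.5, 1.5] x nominal radius to absorb particle-size dispersity.
    """
    best_r, best_score = int(round(r_nominal)), -np.inf
    lo = max(int(np.floor(0.5 * r_nominal)), 4)
    hi = int(np.ceil(1.5 * r_nominal))
    for r in range(lo, hi + 1):
        try:
            ring_mean, ref_mean, ref_sd = _ring_means(frame, cx, cy,
                                                      (r - 3, r + 2), (r + 9, r + 12))
        except ValueError:
            continue
        score = (ring_mean - ref_mean) / ref_sd if ref_sd > 0 else -np.inf
        if score > best_score:
            best_r, best_score = r, score
    return best_r


def ring_intensity_trace(lifeact_stack: np.ndarray, lysotracker_stack: np.ndarray,
                         centers: np.ndarray, radius_px: int | None = None,
                         r_nominal: float | None = None,
                         times: np.ndarray | None = None) -> RingIntensityTrace:
    """Normalized per-frame ring intensities around a tracked particle.

    ``centers`` is an (n_frames, 2) array of (x, y) pixel positions.  Each
    frame's surface-ring mean ([r-3, r+2] px) is divided by the reference-ring
    mean ([r+9, r+12] px); the ratio of a spatially uniform frame is exactly 1
    and any global multiplicative drift cancels.
    """
    la = np.asarray(lifeact_stack, dtype=float)
    ly = np.asarray(lysotracker_stack, dtype=float)
    centers = np.asarray(centers, dtype=float)
    if radius_px is None:
        if r_nominal is None:
            raise ValueError("either radius_px or r_nominal must be given")
        mid = len(la) // 2
        radius_px = choose_ring_radius(la[mid], centers[mid, 0], centers[mid, 1],
                                       r_nominal)
    out_la = np.empty(len(la))
    out_ly = np.empty(len(ly))
    for i in range(len(la)):
        cx, cy = centers[i]
        for stack, out in ((la, out_la), (ly, out_ly)):
            ring_mean, ref_mean, _ = _ring_means(stack[i], cx, cy,
                                                 (radius_px - 3, radius_px + 2),
                                                 (radius_px + 9, radius_px + 12))
            if ref_mean == 0:
                raise ValueError("reference ring mean is zero")
            out[i] = ring_mean / ref_mean
    return RingIntensityTrace(lifeact=out_la, lysotracker=out_ly,
                              radius_px=int(radius_px), times=times)


def detect_peak_then_acidification(trace: RingIntensityTrace, peak_threshold: float,
                                   onset_threshold: float, sustain_frames: int = 5,
                                   ) -> dict:
    """Does an actin peak precede the acidification onset?

    The LifeAct peak is the time of the maximal normalized intensity, provided
    it exceeds ``peak_threshold``.  The LysoTracker onset is the first frame
    from which the signal stays above ``onset_threshold`` for at least
    ``sustain_frames`` frames.  A particle with no detected acidification is
    excluded (``acidified=False``) and does not enter the denominator of the
    peak-before-onset fraction.
    """
    la, ly = trace.lifeact, trace.lysotracker
    idx = np.arange(len(la)) if trace.times is None else np.asarray(trace.times)

    onset = None
    above = ly >= onset_threshold
    for i in range(len(ly) - sustain_frames + 1):
        if above[i: i + sustain_frames].all():
            onset = idx[i]
            break
    if onset is None:
        return {"acidified": False, "peak_before_onset": None,
                "peak_time": None, "onset_time": None}

    peak_i = int(np.argmax(la))
    peak_time = idx[peak_i] if la[peak_i] >= peak_threshold else None
    return {
        "acidified": True,
        "peak_time": peak_time,
        "onset_time": onset,
        "peak_before_onset": bool(peak_time is not None and peak_time < onset),
    }
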