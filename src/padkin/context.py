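"""Near-cell vs near-coverslip classification of particle neighborhoods.

Each particle-frame gets a 52 x 52 um^2 subimage centered on the particle;
a pluggable classifier maps the patch to a ``cell`` or ``coverslip`` label
with a confidence.  Three classifiers are provided: a ground-truth
passthrough (synthetic data), a texture-energy baseline, and a hook for any
external model implementing the same callable interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "PATCH_SIDE_UM",
    "ContextPatch",
    "ContextLabel",
    "crop_patches",
    "classify_context",
    "TextureBaselineClassifier",
    "PassthroughClassifier",
]

#: Side length of the context subimage (um).
PATCH_SIDE_UM = 52.0


@dataclass
class ContextPatch:
    image: np.ndarray
    track_id: int
    frame: int


@dataclass
class ContextLabel:
    label: str               # "cell" | "coverslip"
    confidence: float
    track_id: int = -1
    frame: int = -1


class ContextModel(Protocol):
    def __call__(self, patch: np.ndarray) -> tuple[str, float]: ...


def crop_patches(stack, trajectories: Sequence, patch_side_um: float = PATCH_SIDE_UM,
                 ) -> list[ContextPatch]:
    """One zero-padded patch per (track, frame), particle centered.

    ``stack`` is a :class:`~padkin.detection.ImageStack`; trajectory positions
    are in pixels.
    """
    side = int(round(patch_side_um / stack.pixel_size))
    half = side // 2
    patches: list[ContextPatch] = []
    n_rows, n_cols = stack.pixels.shape[1:]
    for tr in trajectories:
        for det in tr.detections:
            cy, cx = int(round(det.y)), int(round(det.x))
            patch = np.zeros((side, side), dtype=float)
            y0, y1 = cy - half, cy - half + side
            x0, x1 = cx - half, cx - half + side
            sy0, sy1 = max(y0, 0), min(y1, n_rows)
            sx0, sx1 = max(x0, 0), min(x1, n_cols)
            if sy1 > sy0 and sx1 > sx0:
                patch[sy0 - y0: sy1 - y0, sx0 - x0: sx1 - x0] = \
                    stack.pixels[det.frame, sy0:sy1, sx0:sx1]
            patches.append(ContextPatch(image=patch, track_id=tr.track_id,
                                        frame=det.frame))
    return patches


class TextureBaselineClassifier:
    """Texture-energy heuristic: cells are textured, bare coverslip is flat.

    Feature: the standard deviation of the Gaussian-smoothed patch divided by
    the standard deviation of the raw patch.  Pixel-scale noise is averaged
    away by the smoothing while cell-scale texture survives, so the ratio is
    near zero over bare glass and near one over a cell.  Both standard
    deviations scale identically under affine intensity rescaling
    ``I -> a*I + b``, making the feature contrast-invariant.
    """

    def __init__(self, threshold: float = 0.5, smooth_sigma: float = 2.0) -> None:
        self.threshold = threshold
        self.smooth_sigma = smooth_sigma

    def feature(self, patch: np.ndarray) -> float:
        patch = np.asarray(patch, dtype=float)
        raw_std = patch.std()
        if raw_std == 0:
            return 0.0
        smooth = ndimage.gaussian_filter(patch, self.smooth_sigma)
        return float(smooth.std() / raw_std)

    def __call__(self, patch: np.ndarray) -> tuple[str, float]:
        f = self.feature(patch)
        label = "cell" if f > self.threshold else "coverslip"
        # distance from the threshold, squashed to (0.5, 1)
        conf = 0.5 + 0.5 * float(np.tanh(4.0 * abs(f - self.threshold)))
        return label, conf


class PassthroughClassifier:
    """Returns pre-computed ground-truth labels (synthetic data), confidence 1."""

    def __init__(self, labels: dict[tuple[int, int], str]) -> None:
        self.labels = labels
        self._patch_meta: tuple[int, int] | None = None

    def for_patch(self, patch: ContextPatch) -> tuple[str, float]:
        return self.labels[(patch.track_id, patch.frame)], 1.0

    def __call__(self, patch: np.ndarray) -> tuple[str, float]:
        raise TypeError("PassthroughClassifier needs patch metadata; "
                        "use classify_context, which dispatches to for_patch")


def classify_context(patches: Sequence[ContextPatch],
                     model: ContextModel | PassthroughClassifier | Callable,
                     ) -> list[ContextLabel]:
    """Apply a classifier to every patch.

    A model failure on a patch yields the conservative label ``coverslip``
    with confidence 0 plus a warning, so downstream kinetics never crash on a
    single bad patch.
    """
    out: list[ContextLabel] = []
    for p in patches:
        try:
            if isinstance(model, PassthroughClassifier):
                label, conf = model.for_patch(p)
            else:
                label, conf = model(p.image)
            if label not in ("cell", "coverslip"):
                raise ValueError(f"model returned unknown label {label!r}")
        except Exception as exc:  # conservative default on model failure
            warnings.warn(f"context model failed on track {p.track_id} frame "
                          f"{p.frame}: {exc}; labeling coverslip with confidence 0")
            label, conf = "coverslip", 0.0
        out.append(ContextLabel(label=label, confidence=float(conf),
                                track_id=p.track_id, frame=p.frame))
    return out
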