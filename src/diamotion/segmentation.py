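"""Reference lung segmenter for synthetic intensity volumes.

Threshold-based: lungs are the dark voxels (Otsu threshold by default), the
two largest 26-connected components above a minimum size are kept and their
internal cavities filled.  This is a deliberately simple, deterministic
segmenter for phantom data; masks from any external segmenter can instead be
supplied directly through :mod:`diamotion.volumes`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .volumes import MaskVolume, ScalarVolume

#: Structuring element for 26-connectivity in 3D.
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)

#: Components smaller than this fraction of the grid are ignored.
MIN_COMPONENT_FRACTION = 0.01


class SegmentationError(ValueError):
    """Raised when a volume cannot be segmented into two lungs."""


@dataclass
class LungPair:
    """Right and left lung masks; right = smaller mean axis-0 coordinate."""

    right: MaskVolume
    left: MaskVolume

    def __post_init__(self) -> None:
        if (self.right.data & self.left.data).any():
            raise SegmentationError("lung masks overlap")


def segment_lungs(volume: ScalarVolume, threshold: float | None = None) -> MaskVolume:
    """Segment the two lungs from a grayscale volume.

    Parameters
    ----------
    volume
        Grayscale 3D volume (lungs dark, body bright).
    threshold
        Fixed intensity threshold; voxels strictly below it are lung
        candidates.  Default: Otsu's threshold.

    Returns the union mask of the two largest dark components (26-connected,
    each at least 1% of the grid), with internal cavities filled.
    """
    data = np.asarray(volume.data, dtype=float)
    if data.size == 0 or not np.isfinite(data).any():
        raise SegmentationError("empty intensity volume")
    if threshold is None:
        if np.ptp(data) == 0:
            raise SegmentationError("constant intensity volume: no threshold separates lung from body")
        threshold = float(threshold_otsu(data))
    candidates = data < threshold
    labels, n = ndimage.label(candidates, structure=CONNECTIVITY_26)
    if n < 2:
        raise SegmentationError(f"found {n} candidate component(s); need two lungs")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    min_size = MIN_COMPONENT_FRACTION * labels.size
    keep = np.argsort(sizes)[::-1][:2]
    if sizes[keep].min() < min_size:
        raise SegmentationError(
            f"fewer than two components above the minimum size ({min_size:.0f} voxels)"
        )
    mask = np.isin(labels, keep + 1)
    mask = ndimage.binary_fill_holes(mask)
    return MaskVolume(mask, volume.spacing)


def split_sides(mask: MaskVolume) -> LungPair:
    """Split a two-lung mask into right and left lungs.

    Sides are assigned by mean axis-0 coordinate under the package
    convention (axis 0 runs right → left), so the right lung is the
    component with the smaller mean index.
    """
    labels, n = ndimage.label(mask.data, structure=CONNECTIVITY_26)
    if n != 2:
        raise SegmentationError(
            f"expected exactly two connected components, found {n}; "
            "erosion-based splitting of merged lungs is not attempted"
        )
    centers = ndimage.center_of_mass(mask.data, labels, index=[1, 2])
    right_label, left_label = (1, 2) if centers[0][0] < centers[1][0] else (2, 1)
    right = MaskVolume(labels == right_label, mask.spacing)
    left = MaskVolume(labels == left_label, mask.spacing)
    return LungPair(right=right, left=left)
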