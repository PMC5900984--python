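"""Semi-automated phantom segmentation from the b = 0 image.

Step 1 separates the NMR tubes from the background by intensity thresholding
(Otsu on the b = 0 histogram); step 2 removes high-signal free-water voxels,
thresholding at the midpoint between the phantom-material and free-water
intensity modes.  The original workflow finished with minor manual ROI
adjustment; the automatable analogue here is an optional manual mask that
overrides (or intersects) the automatic phantom label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .phantom import LABELS

__all__ = ["PhantomSegmentation", "segment_phantom"]


@dataclass(frozen=True)
class PhantomSegmentation:
    """Label map {0: background, 1: phantom, >=2: free water} with provenance."""

    label_map: np.ndarray
    foreground_threshold: float
    water_threshold: float
    manual_override: bool

    def mask(self, name: str) -> np.ndarray:
        if name == "water":
            return self.label_map >= 2
        return self.label_map == LABELS[name]


def segment_phantom(
    b0_volume: np.ndarray,
    foreground_threshold: float | None = None,
    water_threshold: float | None = None,
    manual_mask: np.ndarray | None = None,
    manual_mode: str = "override",
) -> PhantomSegmentation:
    """Segment phantom material vs free water on a b = 0 magnitude image.

    Parameters
    ----------
    b0_volume : 3D non-negative magnitude image.
    foreground_threshold : tube-vs-background threshold; default Otsu on the
        whole image.
    water_threshold : phantom-vs-water threshold; default the midpoint between
        the phantom-mode and water-mode intensities (modes estimated as class
        medians after an Otsu split of the foreground).
    manual_mask : optional boolean phantom mask standing in for manual ROI
        adjustment; ``manual_mode`` selects whether it replaces ("override")
        or intersects ("intersect") the automatic phantom label.
    """
    vol = np.asarray(b0_volume, dtype=float)
    if np.any(vol < 0):
        raise ValueError("b0 volume must be non-negative")
    if not np.any(vol > 0):
        raise ValueError("b0 volume is identically zero; nothing to segment")
    if manual_mode not in ("override", "intersect"):
        raise ValueError(f"unknown manual_mode {manual_mode!r}")

    if foreground_threshold is None:
        # flatten: Otsu needs intensities only, and 3-slice volumes otherwise
        # trip skimage's RGB-shape heuristic
        foreground_threshold = float(threshold_otsu(vol.ravel()))
    foreground = vol > foreground_threshold
    if not foreground.any():
        raise ValueError("no voxels survive the foreground threshold")

    if water_threshold is None:
        fg_vals = vol[foreground]
        split = float(threshold_otsu(fg_vals))
        low = fg_vals[fg_vals < split]
        high = fg_vals[fg_vals >= split]
        if low.size == 0 or high.size == 0:
            raise ValueError("foreground intensities have a single mode; "
                             "cannot separate phantom from water")
        phantom_mode = float(np.median(low))
        water_mode = float(np.median(high))
        water_threshold = 0.5 * (phantom_mode + water_mode)
    if water_threshold <= foreground_threshold:
        raise ValueError(
            f"water threshold {water_threshold} must exceed foreground "
            f"threshold {foreground_threshold}"
        )

    labels = np.zeros(vol.shape, dtype=np.int8)
    water = foreground & (vol >= water_threshold)
    phantom = foreground & ~water
    manual_override = manual_mask is not None
    if manual_override:
        manual_mask = np.asarray(manual_mask, dtype=bool)
        if manual_mask.shape != vol.shape:
            raise ValueError("manual mask shape mismatch")
        phantom = manual_mask if manual_mode == "override" else (phantom & manual_mask)
        water = water & ~phantom
    labels[water] = 2
    labels[phantom] = LABELS["phantom"]
    if not phantom.any():
        raise ValueError("segmentation produced an empty phantom label")
    return PhantomSegmentation(
        label_map=labels,
        foreground_threshold=float(foreground_threshold),
        water_threshold=float(water_threshold),
        manual_override=manual_override,
    )
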