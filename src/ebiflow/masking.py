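"""Object and per-channel masks and their boundaries.

Every downstream feature (area, mean pixel, circularity, similarity) is
evaluated over a mask produced here.  Conventions, fixed once for all
distance computations:

* pixel centres sit at integer ``(row, col)``, origin top-left;
* foreground is 8-connected, background 4-connected;
* the automatic threshold is Otsu's criterion on the channel histogram;
* the centroid of a mask is the unweighted mean of its pixel coordinates.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk

from .types import Mask, ObjectImage

__all__ = ["object_mask", "channel_mask", "mask_combine", "boundary"]

#: structuring element for the radius-1 morphological closing
_CLOSE_SE = disk(1)
#: 8-connectivity structure for foreground labelling
_STRUCT8 = np.ones((3, 3), dtype=bool)


def _segment(arr: np.ndarray, threshold: float | None) -> tuple[np.ndarray, bool]:
    """Threshold, close (radius 1) and hole-fill one channel.

    Returns (binary image, zero_variance flag).  A flat channel cannot be
    thresholded automatically; it yields an empty, flagged mask rather than
    an exception because flat channels occur routinely (unstained markers).
    """
    if threshold is None:
        if np.ptp(arr) == 0:
            return np.zeros(arr.shape, dtype=bool), True
        threshold = threshold_otsu(arr)
    fg = arr > threshold
    if fg.any():
        fg = closing(fg, _CLOSE_SE)  # skimage closing is border-safe
        fg = ndi.binary_fill_holes(fg)
    return fg, False


def object_mask(img: ObjectImage, channel: str, min_area_px: int = 0) -> Mask:
    """Whole-object mask from one channel (normally brightfield).

    Foreground is Otsu-thresholded, morphologically closed with a radius-1
    disk, hole-filled and restricted to the largest 8-connected component;
    components smaller than ``min_area_px`` are discarded first.  A
    zero-variance channel returns an empty mask flagged ``"empty"`` and
    ``"zero_variance"``.
    """
    arr = img.channel(channel)
    fg, flat = _segment(arr, None)
    flags: set[str] = set()
    if flat:
        flags.add("zero_variance")
    if fg.any():
        labels, n = ndi.label(fg, structure=_STRUCT8)
        sizes = ndi.sum_labels(fg, labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_area_px) + 1
        if keep.size:
            largest = keep[np.argmax(sizes[keep - 1])]
            fg = labels == largest
        else:
            fg = np.zeros_like(fg)
    if not fg.any():
        flags.add("empty")
    return Mask(img.object_id, channel, fg, flags)


def channel_mask(img: ObjectImage, channel: str, method: str = "auto",
                 threshold: float | None = None) -> Mask:
    """Per-marker mask; multi-blob foreground is kept (patchy staining).

    ``method`` is ``"auto"`` (Otsu) or ``"fixed"`` with an explicit
    ``threshold``; fixed masks keep every pixel strictly above it.
    """
    arr = img.channel(channel)
    if method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        fg, flat = _segment(arr, float(threshold))
    elif method == "auto":
        fg, flat = _segment(arr, None)
    else:
        raise ValueError(f"unknown method {method!r}")
    flags: set[str] = set()
    if flat:
        flags.add("zero_variance")
    if not fg.any():
        flags.add("empty")
    return Mask(img.object_id, channel, fg, flags)


def mask_combine(a: Mask, b: Mask, mode: str = "intersect") -> Mask:
    """Set union or intersection of two same-shape masks (commutative)."""
    if a.pixels.shape != b.pixels.shape:
        raise ValueError("mask shapes differ")
    if mode == "union":
        px = a.pixels | b.pixels
    elif mode == "intersect":
        px = a.pixels & b.pixels
    else:
        raise ValueError(f"unknown mode {mode!r}")
    flags = set()
    if not px.any():
        flags.add("empty")
    return Mask(a.object_id, f"{a.channel}*{b.channel}", px, flags)


def boundary(mask: Mask) -> tuple[np.ndarray, np.ndarray]:
    """Outer contour pixels of the largest component, plus the mask centroid.

    The boundary is the set of foreground pixels of the largest 8-connected
    component that are 4- or 8-adjacent to background (or touch the frame
    edge).  The centroid is computed over the *full* mask, so that boundary
    distances are measured from the object centre.

    Returns
    -------
    coords : (n, 2) int array of (row, col) boundary pixels
    centroid : (2,) float array

    Raises
    ------
    ValueError
        If the mask is empty.
    """
    if mask.is_empty:
        raise ValueError(f"object {mask.object_id}: boundary of empty mask")
    px = mask.pixels
    centroid = np.argwhere(px).mean(axis=0)
    labels, n = ndi.label(px, structure=_STRUCT8)
    if n > 1:
        sizes = ndi.sum_labels(px, labels, index=np.arange(1, n + 1))
        comp = labels == (1 + int(np.argmax(sizes)))
    else:
        comp = px
    interior = ndi.binary_erosion(comp, structure=_STRUCT8, border_value=0)
    coords = np.argwhere(comp & ~interior)
    return coords, centroid
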