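"""Per-object scalar features: area, intensity, mean pixel, circularity, similarity.

Circularity
    The average distance of the mask boundary from the mask centroid divided
    by the variation (population standard deviation) of that distance.  A
    circle has nearly constant boundary distance, hence a high value; a
    stellate shape has a highly variable one, hence a low value.

Similarity
    The log-transformed Pearson correlation of two channels' pixels over a
    masked region, ``S = ln((1 + rho) / (1 - rho))`` (twice the Fisher
    z-transform).  Identical staining patterns drive S to +S_cap, mutually
    exclusive ones to -S_cap, unrelated ones to ~0.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .masking import boundary, mask_combine, object_mask
from .types import Mask, ObjectImage

__all__ = [
    "circularity",
    "similarity",
    "intensity_features",
    "compute_feature_row",
    "compute_feature_table",
    "S_CAP",
    "C_CAP",
]

#: correlation clip; ln((1 + (1-1e-6)) / 1e-6) ~= 14.5
RHO_CLIP = 1.0 - 1e-6
S_CAP = math.log((1 + RHO_CLIP) / (1 - RHO_CLIP))
#: returned when the boundary-distance SD underflows (analytically a circle)
C_CAP = 100.0
_SD_EPS = 1e-9


def circularity(mask: Mask) -> float:
    """Boundary-distance shape statistic; higher means rounder.

    Requires at least 8 boundary pixels so the distance SD is meaningful.
    If the SD underflows (all boundary pixels equidistant from the centroid)
    the capped value ``C_CAP`` is returned.
    """
    coords, centroid = boundary(mask)  # raises on empty mask
    if len(coords) < 8:
        raise ValueError(
            f"object {mask.object_id}: {len(coords)} boundary pixels (< 8)"
        )
    d = np.hypot(coords[:, 0] - centroid[0], coords[:, 1] - centroid[1])
    sd = float(d.std())  # population SD
    if sd < _SD_EPS:
        return C_CAP
    return float(d.mean()) / sd


def similarity(img: ObjectImage, ch_a: str, ch_b: str, region: Mask) -> float:
    """Masked-correlation colocalization score for two channels.

    Symmetric in the channel pair and invariant under positive affine
    rescaling of either channel.  Returns NaN (caller should flag and
    exclude) when either channel has zero variance over the region.
    """
    if region.is_empty or region.area_px < 8:
        raise ValueError(
            f"object {img.object_id}: similarity region has "
            f"{region.area_px} pixels (< 8)"
        )
    a = img.channel(ch_a)[region.pixels].astype(float)
    b = img.channel(ch_b)[region.pixels].astype(float)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    rho = float(np.corrcoef(a, b)[0, 1])
    rho = min(max(rho, -RHO_CLIP), RHO_CLIP)
    return math.log((1 + rho) / (1 - rho))


def intensity_features(img: ObjectImage, channel: str, region: Mask,
                       object_region: Mask | None = None) -> tuple[float, float]:
    """(background-subtracted integrated intensity, mean pixel) over a mask.

    Background is the median of pixels outside ``object_region`` (defaults
    to ``region``); the integrated intensity subtracts background x area.
    Mean pixel is the plain mean over the region, no subtraction — it is
    the quantity used for positivity calls on patchy stains.
    """
    arr = img.channel(channel).astype(float)
    if region.is_empty:
        return 0.0, float("nan")
    outside = ~(object_region or region).pixels
    bg = float(np.median(arr[outside])) if outside.any() else 0.0
    vals = arr[region.pixels]
    intensity = float(vals.sum() - bg * region.area_px)
    return intensity, float(vals.mean())


# ---------------------------------------------------------------------------
# feature-table assembly

DEFAULT_SIMILARITY_PAIRS = (("VCAM1", "F480"), ("CD169", "F480"), ("CD11b", "F480"))


def compute_feature_row(img: ObjectImage,
                        marker_channels: tuple[str, ...] = (
                            "CD71", "Ter119", "F480", "VCAM1",
                            "CD169", "CD11b", "CD163"),
                        similarity_pairs=DEFAULT_SIMILARITY_PAIRS,
                        bf_channel: str = "BF",
                        min_area_px: int = 0) -> dict:
    """All scalar features for one object, as a flat dict (one CSV row).

    The similarity region is the whole-object (brightfield) mask: the least
    biased choice when comparing staining patterns across the event, and
    the region every marker shares.
    """
    omask = object_mask(img, bf_channel, min_area_px=min_area_px)
    row: dict = {
        "object_id": img.object_id,
        "area_bf_px": omask.area_px,
        "area_bf_um2": omask.area_um2(img.pixel_size_um),
        "flag_empty_object": omask.is_empty,
    }
    for ch in marker_channels:
        if ch not in img.channels:
            continue
        if omask.is_empty:
            row[f"intensity_{ch}"] = 0.0
            row[f"mean_pixel_{ch}"] = float("nan")
        else:
            inten, mp = intensity_features(img, ch, omask)
            row[f"intensity_{ch}"] = inten
            row[f"mean_pixel_{ch}"] = mp
    # circularity of the object mask and of the macrophage-marker masks
    for ch, mask in (("BF", omask),):
        try:
            row[f"circularity_{ch}"] = circularity(mask)
        except ValueError:
            row[f"circularity_{ch}"] = float("nan")
    for ch_a, ch_b in similarity_pairs:
        key = f"similarity_{ch_a}_{ch_b}"
        if ch_a not in img.channels or ch_b not in img.channels or omask.is_empty:
            row[key] = float("nan")
            continue
        try:
            row[key] = similarity(img, ch_a, ch_b, omask)
        except ValueError:
            row[key] = float("nan")
    return row


def compute_feature_table(images, **kwargs) -> pd.DataFrame:
    """Feature rows for an iterable of objects, ordered by object_id."""
    rows = [compute_feature_row(img, **kwargs) for img in images]
    return pd.DataFrame(rows).sort_values("object_id").reset_index(drop=True)
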