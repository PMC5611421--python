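"""Rule-based classification of gated events.

The analyst's manual inspection step — looking at each double-positive
event and deciding whether it is a genuine erythroblastic island — is
replaced here by an explicit, deterministic rule set:

* cells are segmented from the DNA channel (smoothed regional maxima
  seeding a watershed constrained to the object mask);
* a candidate central macrophage must be macrophage-marker positive by
  mean pixel, touch at least three CD71+ nucleated cells, and sit near the
  cluster centroid (centrality score >= theta_c);
* the same geometry with a VCAM-1+ / F4/80-negative centre is called a
  VCAM-1+;F4/80lo cluster;
* everything else falls through to loose cluster / singlet / debris by
  cell count and area.

Positivity is a mean-pixel threshold (background median + k * background
MAD by default) because patchy stains need not produce a clean image;
co-expression is judged on the Similarity score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .features import circularity, similarity
from .masking import channel_mask, object_mask
from .types import Mask, ObjectImage

__all__ = ["CellRecord", "ClassifyConfig", "ClusterCall", "segment_cells",
           "classify_cluster", "count_cd11b_cells", "positivity",
           "positivity_threshold", "coexpression_call", "classify_cohort"]

CALLS = ("EBI", "VCAM1pos_F480lo_cluster", "loose_cluster", "singlet", "debris")


@dataclass
class CellRecord:
    label: int
    centroid: tuple[float, float]
    nucleus: np.ndarray
    footprint: np.ndarray


@dataclass
class ClassifyConfig:
    """Thresholds and conventions of the classifier; all configurable."""

    species: str = "mouse"          # mouse: F4/80 axis; rat: CD163
    positivity_k: float = 6.0       # threshold = bg median + k * bg MAD
    fixed_thresholds: dict[str, float] = field(default_factory=dict)
    theta_c: float = 0.5            # minimum centrality of the central cell
    s_thresh: float = 1.0           # Similarity cut for co-expression
    min_object_area_um2: float = 4.0   # below this (or no nuclei): debris
    dna_sigma_px: float = 2.0
    nucleus_min_distance_px: int = 5
    count_reticulocytes: bool = False  # CD71+/DNA- cells never count to >= 3

    @property
    def mac_channel(self) -> str:
        return {"mouse": "F480", "rat": "CD163"}[self.species]


@dataclass
class ClusterCall:
    """Final per-object call with constituent-cell accounting."""

    object_id: str
    call: str
    n_nuclei: int
    n_erythroblasts: int
    n_cd11b_cells: int | None
    central_present: bool
    central_markers: dict[str, str]       # channel -> positive/negative/undefined
    central_circularity: float
    central_centrality: float
    central_cd11b_positive: bool | None
    similarity_to_mac: dict[str, float]   # channel -> S vs macrophage marker
    flags: set[str] = field(default_factory=set)

    def as_row(self) -> dict:
        row = {
            "object_id": self.object_id,
            "call": self.call,
            "n_nuclei": self.n_nuclei,
            "n_erythroblasts": self.n_erythroblasts,
            "n_cd11b_cells": self.n_cd11b_cells,
            "central_present": self.central_present,
            "central_circularity": self.central_circularity,
            "central_centrality": self.central_centrality,
            "central_cd11b_positive": self.central_cd11b_positive,
            "flags": ";".join(sorted(self.flags)),
        }
        for ch, state in self.central_markers.items():
            row[f"central_{ch}"] = state
        for ch, s in self.similarity_to_mac.items():
            row[f"similarity_{ch}"] = s
        return row


# ---------------------------------------------------------------------------
# positivity

def positivity_threshold(img: ObjectImage, channel: str, omask: Mask,
                         cfg: ClassifyConfig) -> float:
    """Mean-pixel positivity cut: fixed override, else background median
    plus ``k`` background MADs, estimated from off-object pixels."""
    if channel in cfg.fixed_thresholds:
        return cfg.fixed_thresholds[channel]
    arr = img.channel(channel).astype(float)
    bg = arr[~omask.pixels] if (~omask.pixels).any() else arr.ravel()
    med = float(np.median(bg))
    mad = float(np.median(np.abs(bg - med)))
    return med + cfg.positivity_k * mad


def positivity(mean_pixel: float, threshold: float) -> str:
    """Inclusive mean-pixel call: >= threshold is positive."""
    if np.isnan(mean_pixel):
        return "undefined"
    return "positive" if mean_pixel >= threshold else "negative"


def coexpression_call(s: float, s_thresh: float = 1.0) -> str:
    """Is a marker's staining pattern consistent with the reference marker?"""
    if np.isnan(s):
        return "undefined"
    return "consistent" if s >= s_thresh else "inconsistent"


# ---------------------------------------------------------------------------
# segmentation

def segment_cells(img: ObjectImage, omask: Mask | None = None,
                  cfg: ClassifyConfig | None = None) -> list[CellRecord]:
    """Nucleus-seeded cell segmentation inside the object mask.

    Nuclei are regional maxima of the Gaussian-smoothed DNA channel above
    its positivity threshold; each seeds a watershed basin (grown on
    distance from the seeds) which becomes the cell footprint.  An object
    with no detectable nuclei returns no cells — downstream that means
    debris, never an exception.
    """
    cfg = cfg or ClassifyConfig()
    omask = omask or object_mask(img, "BF")
    if omask.is_empty:
        return []
    dna = ndi.gaussian_filter(img.channel("DNA").astype(float),
                              cfg.dna_sigma_px)
    thr = positivity_threshold(img, "DNA", omask, cfg)
    peaks = peak_local_max(dna, min_distance=cfg.nucleus_min_distance_px,
                           threshold_abs=thr, labels=omask.pixels)
    if len(peaks) == 0:
        return []
    markers = np.zeros(omask.pixels.shape, dtype=int)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    # grow basins by proximity to the seeds (cells are compact blobs)
    dist = ndi.distance_transform_edt(markers == 0)
    basins = watershed(dist, markers=markers, mask=omask.pixels)
    # nucleus extent: smoothed DNA above an in-object Otsu cut
    in_obj = dna[omask.pixels]
    nuc_thr = threshold_otsu(in_obj) if np.ptp(in_obj) > 0 else np.inf
    nuclei = dna > nuc_thr
    cells = []
    for lab in range(1, len(peaks) + 1):
        fp = basins == lab
        if not fp.any():
            continue
        cells.append(CellRecord(
            label=lab,
            centroid=tuple(np.argwhere(fp).mean(axis=0)),
            nucleus=nuclei & fp,
            footprint=fp,
        ))
    return cells


def _adjacent(a: np.ndarray, b: np.ndarray) -> bool:
    """Footprints touch: overlap, or 8-adjacency after 1-px dilation."""
    if (a & b).any():
        return True
    grown = ndi.binary_dilation(a, structure=np.ones((3, 3), bool))
    return bool((grown & b).any())


def _band_mean(img: ObjectImage, channel: str, footprint: np.ndarray,
               width: int = 2) -> float:
    """Mean pixel over a cell's perimeter band (membrane staining)."""
    band = footprint & ~ndi.binary_erosion(footprint, iterations=width,
                                           border_value=0)
    if not band.any():
        band = footprint
    return float(img.channel(channel)[band].mean())


# ---------------------------------------------------------------------------
# classification

def count_cd11b_cells(img: ObjectImage, cells: list[CellRecord],
                      cfg: ClassifyConfig, omask: Mask,
                      central: CellRecord | None) -> tuple[int | None, bool | None]:
    """(number of CD11b+ cells excluding the centre, is the centre CD11b+).

    A cell is CD11b+ when the mean pixel over its 2-px perimeter band
    exceeds the positivity threshold — CD11b is a membrane stain.  Returns
    ``(None, None)`` when the channel is absent.
    """
    if "CD11b" not in img.channels:
        return None, None
    thr = positivity_threshold(img, "CD11b", omask, cfg)
    n = 0
    central_pos: bool | None = None
    for cell in cells:
        pos = _band_mean(img, "CD11b", cell.footprint) >= thr
        if central is not None and cell.label == central.label:
            central_pos = pos
        elif pos:
            n += 1
    return n, central_pos


def classify_cluster(img: ObjectImage, cells: list[CellRecord],
                     cfg: ClassifyConfig | None = None,
                     omask: Mask | None = None) -> ClusterCall:
    """Apply the island rule set to one segmented object."""
    cfg = cfg or ClassifyConfig()
    omask = omask or object_mask(img, "BF")
    flags: set[str] = set()
    area_um2 = omask.area_um2(img.pixel_size_um)
    mac_ch = cfg.mac_channel

    thresholds = {ch: positivity_threshold(img, ch, omask, cfg)
                  for ch in ("CD71", "F480", "VCAM1", "CD169", "CD11b",
                             "CD163") if ch in img.channels}

    # per-cell marker means over the footprint
    def mean_over(cell: CellRecord, ch: str) -> float:
        return float(img.channel(ch)[cell.footprint].mean())

    def marker_state(cell: CellRecord, ch: str) -> str:
        """Positive on the footprint mean, the 2-px perimeter-band mean, or
        the mean over a 3-px shell just outside the footprint.  Surface
        markers may be membrane-confined, and when cells overlap, a central
        cell's true boundary — where the ring stain sits — lies largely
        outside its own watershed basin, in the neighbours' territory."""
        if positivity(mean_over(cell, ch), thresholds[ch]) == "positive":
            return "positive"
        if positivity(_band_mean(img, ch, cell.footprint),
                      thresholds[ch]) == "positive":
            return "positive"
        shell = ndi.binary_dilation(cell.footprint, iterations=3) \
            & ~cell.footprint
        if shell.any() and positivity(
                float(img.channel(ch)[shell].mean()),
                thresholds[ch]) == "positive":
            return "positive"
        return "negative"

    nucleated = [c for c in cells if c.nucleus.any()]
    erythroblasts = [c for c in nucleated
                     if marker_state(c, "CD71") == "positive"]

    # centrality relative to the whole-cluster centroid
    if omask.is_empty:
        cluster_centroid = np.array(img.shape) / 2.0
        r_eq = 1.0
    else:
        cluster_centroid = np.argwhere(omask.pixels).mean(axis=0)
        r_eq = float(np.sqrt(omask.area_px / np.pi))

    def centrality(cell: CellRecord) -> float:
        d = float(np.hypot(cell.centroid[0] - cluster_centroid[0],
                           cell.centroid[1] - cluster_centroid[1]))
        return 1.0 - d / r_eq

    def island_geometry(cell: CellRecord) -> int:
        """Number of CD71+ nucleated cells contacting this cell."""
        return sum(1 for e in erythroblasts if e.label != cell.label
                   and _adjacent(cell.footprint, e.footprint))

    def pick(cands: list[CellRecord], key_ch: str) -> CellRecord | None:
        if not cands:
            return None
        if len(cands) > 1:
            flags.add("ambiguous_central")
        return max(cands, key=lambda c: (centrality(c), mean_over(c, key_ch)))

    mac_cands = [
        c for c in nucleated
        if marker_state(c, mac_ch) == "positive"
        and centrality(c) >= cfg.theta_c and island_geometry(c) >= 3]
    central = pick(mac_cands, mac_ch)
    call = None
    if central is not None:
        call = "EBI"
    elif "VCAM1" in img.channels and "F480" in img.channels:
        vcam_cands = [
            c for c in nucleated
            if marker_state(c, "VCAM1") == "positive"
            and marker_state(c, "F480") == "negative"
            and centrality(c) >= cfg.theta_c and island_geometry(c) >= 3]
        central = pick(vcam_cands, "VCAM1")
        if central is not None:
            call = "VCAM1pos_F480lo_cluster"
    if call is None:
        if len(nucleated) == 0 or area_um2 < cfg.min_object_area_um2:
            call = "debris"
        elif len(nucleated) == 1:
            call = "singlet"
        else:
            call = "loose_cluster"

    # central-macrophage phenotype
    marker_states: dict[str, str] = {}
    sim_scores: dict[str, float] = {}
    circ = float("nan")
    cent_score = float("nan")
    if central is not None:
        cent_score = centrality(central)
        for ch in ("F480", "VCAM1", "CD169", "CD163"):
            if ch in img.channels:
                marker_states[ch] = marker_state(central, ch)
        try:
            mac_mask = channel_mask(img, mac_ch, method="auto")
            circ = circularity(mac_mask)
        except (ValueError, KeyError):
            flags.add("circularity_undefined")
        for ch in ("VCAM1", "CD169", "CD11b"):
            if ch in img.channels and ch != mac_ch and not omask.is_empty:
                try:
                    sim_scores[ch] = similarity(img, ch, mac_ch, omask)
                except ValueError:
                    sim_scores[ch] = float("nan")

    n_cd11b, central_cd11b = count_cd11b_cells(img, cells, cfg, omask, central)
    if n_cd11b is None:
        flags.add("no_cd11b_channel")
    # the centre is not an erythroblast even if CD71 bleeds onto it
    n_ery = sum(1 for e in erythroblasts
                if central is None or e.label != central.label)
    return ClusterCall(
        object_id=img.object_id,
        call=call,
        n_nuclei=len(nucleated),
        n_erythroblasts=n_ery,
        n_cd11b_cells=n_cd11b,
        central_present=central is not None,
        central_markers=marker_states,
        central_circularity=circ,
        central_centrality=cent_score,
        central_cd11b_positive=central_cd11b,
        similarity_to_mac=sim_scores,
        flags=flags,
    )


def classify_cohort(images, cfg: ClassifyConfig | None = None) -> pd.DataFrame:
    """Segment and classify every object; one row per object, id-ordered."""
    cfg = cfg or ClassifyConfig()
    rows = []
    for img in images:
        omask = object_mask(img, "BF")
        cells = segment_cells(img, omask, cfg)
        rows.append(classify_cluster(img, cells, cfg, omask).as_row())
    return pd.DataFrame(rows).sort_values("object_id").reset_index(drop=True)
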