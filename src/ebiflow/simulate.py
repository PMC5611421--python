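"""Seeded synthetic cohorts of per-event multichannel images with ground truth.

Emulates what a 60x imaging flow cytometer records from dissociated
hematopoietic tissue: small registered frames containing single cells,
debris, loose cell chains, and true erythroblastic islands (EBIs) — a
central macrophage whose footprint overlaps at least three CD71+ nucleated
erythroblasts, optionally with CD11b+ satellite cells attached to the
island's periphery.

Tissue presets encode the biology the analysis is meant to recover:

``BM``
    mouse bone marrow — mostly stellate macrophages, CD169 patchy-positive,
    frequent CD11b+ satellites;
``FL``
    mouse E13.5 fetal liver — round macrophages, CD169-negative, very few
    satellites, frequent VCAM-1+/F4/80-low central cells;
``SP_stress``
    phlebotomized mouse spleen — stellate macrophages, elevated
    VCAM-1+/F4/80-low cluster frequency;
``ratBM``
    rat bone marrow — CD163+ / CD169- central macrophages.

Cell geometry is deliberately simple (disks; stellate macrophages are a
disk core with tapered radial arms), each marker is painted as a uniform,
membranous (2-px perimeter band) or patchy (random blob subset) pattern,
and the camera model is Poisson shot noise on signal plus additive Gaussian
read noise plus a constant background, each term independently switchable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .types import CHANNELS, ObjectImage

__all__ = [
    "MarkerSpec",
    "NoiseModel",
    "MacrophageShape",
    "SimulationConfig",
    "preset_config",
    "simulate_object",
    "simulate_cohort",
    "CLASSES",
    "TRUTH_COLUMNS",
]

CLASSES = (
    "singlet_erythroblast",
    "singlet_myeloid",
    "singlet_macrophage",
    "debris",
    "loose_cluster",
    "EBI",
    "VCAM1pos_F480lo_cluster",
)

TRUTH_COLUMNS = [
    "object_id", "true_class", "n_cells", "n_nuclei", "n_erythroblasts",
    "n_cd11b_cells", "macrophage_shape_class", "n_ery_contacting_central",
    "mac_pos_F480", "mac_pos_VCAM1", "mac_pos_CD169", "mac_pos_CD11b",
    "mac_pos_CD163",
]


@dataclass(frozen=True)
class MarkerSpec:
    """Staining model for one (cell class, channel) pair."""
    mean_level: float
    cv: float = 0.15
    pattern: str = "uniform"  # uniform | membranous | patchy
    patch_fraction: float = 0.4


@dataclass(frozen=True)
class NoiseModel:
    gaussian_sd: float = 2.0
    poisson_scale: float = 1.0  # 0 disables shot noise
    background_level: float = 4.0


@dataclass(frozen=True)
class MacrophageShape:
    p_round: float = 0.1
    n_extensions: tuple[int, int] = (4, 7)
    extension_len_px: tuple[int, int] = (12, 26)
    core_radius_px: tuple[int, int] = (9, 14)


@dataclass
class SimulationConfig:
    """Full description of one synthetic cohort.

    ``class_mix`` must sum to 1; ``erythroblasts_per_EBI`` must start at 3
    or more, because an island is defined by at least three attached
    erythroblasts.  ``marker_model`` maps cell class -> channel ->
    :class:`MarkerSpec`.
    """

    tissue_preset: str = "BM"
    n_objects: int = 100
    class_mix: dict[str, float] = field(default_factory=dict)
    frame_px: int = 128
    pixel_size_um: float = 0.33
    macrophage_shape: MacrophageShape = field(default_factory=MacrophageShape)
    erythroblasts_per_EBI: tuple[int, int] = (4, 8)
    cd11b_satellites_per_EBI: tuple[int, int] = (1, 3)
    p_cd11b_satellite: float = 0.8
    erythroblast_radius_px: tuple[int, int] = (5, 8)
    myeloid_radius_px: tuple[int, int] = (4, 6)
    marker_model: dict[str, dict[str, MarkerSpec]] = field(default_factory=dict)
    noise: NoiseModel = field(default_factory=NoiseModel)
    include_reticulocytes: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_mix:
            total = sum(self.class_mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"class_mix sums to {total}, not 1")
            unknown = set(self.class_mix) - set(CLASSES)
            if unknown:
                raise ValueError(f"unknown classes in class_mix: {unknown}")
        for name in ("erythroblasts_per_EBI", "cd11b_satellites_per_EBI",
                     "erythroblast_radius_px", "myeloid_radius_px"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name}: invalid range ({lo}, {hi})")
        if self.erythroblasts_per_EBI[0] < 3:
            raise ValueError(
                "erythroblasts_per_EBI: an EBI requires >= 3 erythroblasts")
        # the largest configured EBI must fit the frame
        reach = (self.macrophage_shape.core_radius_px[1]
                 + self.macrophage_shape.extension_len_px[1]
                 + 2 * self.erythroblast_radius_px[1]
                 + self.myeloid_radius_px[1] + 2)
        if reach > self.frame_px // 2:
            raise ValueError(
                f"frame_px={self.frame_px} too small for configured geometry "
                f"(max reach {reach} px from centre; reduce core_radius_px, "
                f"extension_len_px or erythroblast_radius_px)")


# ---------------------------------------------------------------------------
# presets

def _mouse_markers(cd169: bool) -> dict[str, dict[str, MarkerSpec]]:
    mac = {
        "F480": MarkerSpec(120.0, pattern="uniform"),
        "VCAM1": MarkerSpec(110.0, pattern="uniform"),
    }
    if cd169:
        mac["CD169"] = MarkerSpec(100.0, pattern="patchy", patch_fraction=0.4)
    return {
        "erythroblast": {
            "CD71": MarkerSpec(130.0, pattern="membranous"),
            "Ter119": MarkerSpec(90.0, pattern="membranous"),
        },
        "myeloid": {"CD11b": MarkerSpec(130.0, pattern="membranous")},
        "macrophage": mac,
        "vcam_central": {
            "VCAM1": MarkerSpec(120.0, pattern="uniform"),
            "F480": MarkerSpec(5.0, pattern="uniform"),
        },
    }


def _rat_markers() -> dict[str, dict[str, MarkerSpec]]:
    return {
        "erythroblast": {
            "CD71": MarkerSpec(130.0, pattern="membranous"),
            "Ter119": MarkerSpec(90.0, pattern="membranous"),
        },
        "myeloid": {"CD11b": MarkerSpec(130.0, pattern="membranous")},
        "macrophage": {
            # CD163 images the rat island macrophage as a broad,
            # cell-filling stain, much like F4/80 in the mouse
            "CD163": MarkerSpec(120.0, pattern="uniform"),
            "VCAM1": MarkerSpec(100.0, pattern="uniform"),
        },
        "vcam_central": {
            "VCAM1": MarkerSpec(120.0, pattern="uniform"),
        },
    }


_PRESETS: dict[str, dict] = {
    "BM": dict(
        class_mix={"singlet_erythroblast": 0.28, "singlet_myeloid": 0.14,
                   "singlet_macrophage": 0.05, "debris": 0.10,
                   "loose_cluster": 0.15, "EBI": 0.25,
                   "VCAM1pos_F480lo_cluster": 0.03},
        macrophage_shape=MacrophageShape(p_round=0.10),
        p_cd11b_satellite=0.8,
        marker_model=_mouse_markers(cd169=True),
    ),
    "FL": dict(
        class_mix={"singlet_erythroblast": 0.34, "singlet_myeloid": 0.06,
                   "singlet_macrophage": 0.05, "debris": 0.10,
                   "loose_cluster": 0.12, "EBI": 0.18,
                   "VCAM1pos_F480lo_cluster": 0.15},
        macrophage_shape=MacrophageShape(p_round=0.85),
        p_cd11b_satellite=0.05,
        marker_model=_mouse_markers(cd169=False),
    ),
    "SP_stress": dict(
        class_mix={"singlet_erythroblast": 0.30, "singlet_myeloid": 0.12,
                   "singlet_macrophage": 0.05, "debris": 0.10,
                   "loose_cluster": 0.14, "EBI": 0.21,
                   "VCAM1pos_F480lo_cluster": 0.08},
        macrophage_shape=MacrophageShape(p_round=0.15),
        p_cd11b_satellite=0.10,
        marker_model=_mouse_markers(cd169=True),
    ),
    "ratBM": dict(
        class_mix={"singlet_erythroblast": 0.28, "singlet_myeloid": 0.14,
                   "singlet_macrophage": 0.05, "debris": 0.10,
                   "loose_cluster": 0.16, "EBI": 0.25,
                   "VCAM1pos_F480lo_cluster": 0.02},
        macrophage_shape=MacrophageShape(p_round=0.20),
        p_cd11b_satellite=0.30,
        marker_model=_rat_markers(),
    ),
}


def preset_config(tissue_preset: str, n_objects: int = 100, seed: int = 0,
                  **overrides) -> SimulationConfig:
    """A ready-to-run :class:`SimulationConfig` for one tissue preset."""
    if tissue_preset not in _PRESETS:
        raise ValueError(f"unknown preset {tissue_preset!r}; "
                         f"choose from {sorted(_PRESETS)}")
    kwargs = dict(_PRESETS[tissue_preset])
    kwargs.update(tissue_preset=tissue_preset, n_objects=n_objects, seed=seed)
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


# ---------------------------------------------------------------------------
# geometry primitives

def _disk(shape: tuple[int, int], center: tuple[float, float],
          radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _wobbly_disk(shape, center, radius, rng, amp: float = 0.06,
                 harmonics=(2, 3, 4)) -> np.ndarray:
    """Disk with low-order radial boundary irregularity — real rounded cells
    are never perfect circles."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dy, dx = rr - center[0], cc - center[1]
    theta = np.arctan2(dy, dx)
    r_of_theta = np.ones_like(theta, dtype=float)
    for k in harmonics:
        r_of_theta += rng.normal(0.0, amp) * np.cos(
            k * theta + rng.uniform(0, 2 * np.pi))
    return dy**2 + dx**2 <= (radius * r_of_theta) ** 2


def _stellate(shape, center, core_r, n_arms, arm_len, rng) -> np.ndarray:
    """Disk core plus tapered radial arms with jittered angles."""
    fp = _disk(shape, center, core_r)
    base_w = max(2.0, core_r * 0.35)
    angles = (np.arange(n_arms) * 2 * np.pi / n_arms
              + rng.uniform(-0.35, 0.35, n_arms) + rng.uniform(0, 2 * np.pi))
    for th in angles:
        length = arm_len * rng.uniform(0.7, 1.0)
        for t in np.arange(0.0, length, 1.0):
            r = base_w * (1.0 - t / length) + 1.0
            cy = center[0] + (core_r - 1 + t) * np.sin(th)
            cx = center[1] + (core_r - 1 + t) * np.cos(th)
            fp |= _disk(shape, (cy, cx), r)
    return fp


def _perimeter_band(footprint: np.ndarray, width: int = 2) -> np.ndarray:
    eroded = ndi.binary_erosion(footprint, iterations=width, border_value=0)
    return footprint & ~eroded


def _patchy(footprint: np.ndarray, patch_fraction: float, rng) -> np.ndarray:
    """Random blob subset of a footprint covering ~patch_fraction of it."""
    target = patch_fraction * footprint.sum()
    patches = np.zeros_like(footprint)
    fg = np.argwhere(footprint)
    guard = 0
    while patches.sum() < target and guard < 200:
        cy, cx = fg[rng.integers(len(fg))]
        patches |= _disk(footprint.shape, (cy, cx), rng.uniform(2.0, 4.0))
        guard += 1
    return patches & footprint


@dataclass
class _Cell:
    cell_class: str            # erythroblast | myeloid | macrophage | vcam_central | reticulocyte
    footprint: np.ndarray
    nucleus: np.ndarray | None
    center: tuple[float, float]


def _make_cell(cfg: SimulationConfig, cell_class: str, center, rng,
               shape_class: str | None = None) -> tuple[_Cell, str]:
    """Build a cell's footprint and nucleus; returns (cell, shape_class)."""
    shp = (cfg.frame_px, cfg.frame_px)
    if cell_class in ("macrophage", "vcam_central"):
        ms = cfg.macrophage_shape
        core_r = rng.uniform(*ms.core_radius_px)
        if shape_class is None:
            shape_class = "round" if rng.random() < ms.p_round else "stellate"
        if shape_class == "round":
            fp = _wobbly_disk(shp, center, core_r * 1.25, rng)
        else:
            n_arms = rng.integers(ms.n_extensions[0], ms.n_extensions[1] + 1)
            arm_len = rng.uniform(*ms.extension_len_px)
            fp = _stellate(shp, center, core_r, n_arms, arm_len, rng)
        nucleus = _disk(shp, center, core_r * 0.55)
    else:
        if cell_class == "myeloid":
            r = rng.uniform(*cfg.myeloid_radius_px)
        else:
            r = rng.uniform(*cfg.erythroblast_radius_px)
        fp = _disk(shp, center, r)
        nucleus = None if cell_class == "reticulocyte" else _disk(
            shp, center, r * 0.55)
        shape_class = "none"
    return _Cell(cell_class, fp, nucleus, center), shape_class


# ---------------------------------------------------------------------------
# object assembly

def _layout_island(cfg: SimulationConfig, rng, central_class: str,
                   n_ery: int, n_sat: int) -> tuple[list[_Cell], str]:
    """Central cell at the frame centre, erythroblasts ringed around the
    core so every footprint overlaps it, satellites attached outside."""
    c0 = (cfg.frame_px / 2 + rng.uniform(-3, 3),
          cfg.frame_px / 2 + rng.uniform(-3, 3))
    central, shape_class = _make_cell(cfg, central_class, c0, rng)
    core_r = np.sqrt(central.nucleus.sum() / np.pi) / 0.55
    cells = [central]
    ery_pos = []
    base = rng.uniform(0, 2 * np.pi)
    for i in range(n_ery):
        th = base + 2 * np.pi * i / n_ery + rng.uniform(-0.2, 0.2) / max(n_ery, 1)
        r_e = rng.uniform(*cfg.erythroblast_radius_px)
        dist = core_r + r_e - rng.uniform(2.5, 4.0)  # overlap the core
        cy = c0[0] + dist * np.sin(th)
        cx = c0[1] + dist * np.cos(th)
        cell, _ = _make_cell(cfg, "erythroblast", (cy, cx), rng)
        cells.append(cell)
        ery_pos.append((th, dist, r_e))
    for _ in range(n_sat):
        th, dist, r_e = ery_pos[rng.integers(len(ery_pos))]
        r_s = rng.uniform(*cfg.myeloid_radius_px)
        th_s = th + rng.uniform(-0.25, 0.25)
        d_s = dist + r_e + r_s - 2.0
        cell, _ = _make_cell(
            cfg, "myeloid",
            (c0[0] + d_s * np.sin(th_s), c0[1] + d_s * np.cos(th_s)), rng)
        cells.append(cell)
    if cfg.include_reticulocytes and rng.random() < 0.3:
        th, dist, r_e = ery_pos[rng.integers(len(ery_pos))]
        r_r = rng.uniform(*cfg.erythroblast_radius_px) * 0.8
        d_r = dist + r_e + r_r - 2.0
        cell, _ = _make_cell(
            cfg, "reticulocyte",
            (c0[0] + d_r * np.sin(th + 0.4), c0[1] + d_r * np.cos(th + 0.4)),
            rng)
        cells.append(cell)
    return cells, shape_class


def _layout_loose(cfg: SimulationConfig, rng) -> tuple[list[_Cell], str]:
    """Bent chain: macrophage at one end touching one erythroblast, the rest
    chained on — connected in brightfield but failing island geometry."""
    n_ery = int(rng.integers(3, 5))
    core_r = rng.uniform(*cfg.macrophage_shape.core_radius_px)
    radii = [rng.uniform(*cfg.erythroblast_radius_px) for _ in range(n_ery)]
    th = rng.uniform(0, 2 * np.pi)
    pos = [(0.0, 0.0)]
    prev_r = core_r
    for r in radii:
        th += rng.uniform(-0.7, 0.7)
        step = prev_r + r - 2.0
        pos.append((pos[-1][0] + step * np.sin(th),
                    pos[-1][1] + step * np.cos(th)))
        prev_r = r
    ys, xs = zip(*pos)
    off = (cfg.frame_px / 2 - (min(ys) + max(ys)) / 2,
           cfg.frame_px / 2 - (min(xs) + max(xs)) / 2)
    pos = [(y + off[0], x + off[1]) for y, x in pos]
    # stellate arms would bridge the chain; keep the end macrophage compact
    mac, shape_class = _make_cell(cfg, "macrophage", pos[0], rng,
                                  shape_class="round")
    cells = [mac]
    for (cy, cx), _r in zip(pos[1:], radii):
        cell, _ = _make_cell(cfg, "erythroblast", (cy, cx), rng)
        cells.append(cell)
    return cells, shape_class


def _paint(cfg: SimulationConfig, cells: list[_Cell], rng) -> dict[str, np.ndarray]:
    shp = (cfg.frame_px, cfg.frame_px)
    clean = {ch: np.zeros(shp) for ch in CHANNELS}
    for cell in cells:
        level_bf = 60.0 if cell.cell_class == "debris" else 100.0
        np.maximum(clean["BF"], level_bf * cell.footprint, out=clean["BF"])
        if cell.nucleus is not None:
            np.maximum(clean["DNA"], 150.0 * cell.nucleus, out=clean["DNA"])
        model = cfg.marker_model.get(
            "erythroblast" if cell.cell_class == "reticulocyte"
            else cell.cell_class, {})
        for ch, spec in model.items():
            if cell.cell_class == "reticulocyte" and ch != "CD71":
                continue
            level = max(0.0, rng.normal(spec.mean_level,
                                        spec.cv * spec.mean_level))
            if spec.pattern == "uniform":
                region = cell.footprint
            elif spec.pattern == "membranous":
                region = _perimeter_band(cell.footprint, 2)
            elif spec.pattern == "patchy":
                region = _patchy(cell.footprint, spec.patch_fraction, rng)
            else:
                raise ValueError(f"unknown pattern {spec.pattern!r}")
            np.maximum(clean[ch], level * region, out=clean[ch])
    return clean


def _apply_noise(clean: dict[str, np.ndarray], noise: NoiseModel,
                 rng) -> dict[str, np.ndarray]:
    out = {}
    for ch, sig in clean.items():
        if noise.poisson_scale > 0:
            sig = rng.poisson(sig * noise.poisson_scale) / noise.poisson_scale
        sig = sig + noise.background_level
        if noise.gaussian_sd > 0:
            sig = sig + rng.normal(0.0, noise.gaussian_sd, sig.shape)
        out[ch] = np.clip(sig, 0.0, None)
    return out


def simulate_object(cfg: SimulationConfig, class_label: str, rng,
                    object_id: str = "obj") -> tuple[ObjectImage, dict]:
    """One event: a registered multichannel frame plus its ground-truth row.

    The truth dict carries the per-object counts, the central cell's shape
    class and true marker positivity, and the macrophage's pixel mask
    (``macrophage_mask``, dropped when truth tables are written to CSV).
    """
    if class_label not in CLASSES:
        raise ValueError(f"unknown class {class_label!r}")
    shp = (cfg.frame_px, cfg.frame_px)
    center = (cfg.frame_px / 2 + rng.uniform(-3, 3),
              cfg.frame_px / 2 + rng.uniform(-3, 3))
    shape_class = "none"
    n_sat = 0

    if class_label == "EBI":
        n_ery = int(rng.integers(cfg.erythroblasts_per_EBI[0],
                                 cfg.erythroblasts_per_EBI[1] + 1))
        if rng.random() < cfg.p_cd11b_satellite:
            n_sat = int(rng.integers(cfg.cd11b_satellites_per_EBI[0],
                                     cfg.cd11b_satellites_per_EBI[1] + 1))
        cells, shape_class = _layout_island(cfg, rng, "macrophage", n_ery, n_sat)
    elif class_label == "VCAM1pos_F480lo_cluster":
        n_ery = int(rng.integers(cfg.erythroblasts_per_EBI[0],
                                 cfg.erythroblasts_per_EBI[1] + 1))
        cells, shape_class = _layout_island(cfg, rng, "vcam_central", n_ery, 0)
    elif class_label == "loose_cluster":
        cells, shape_class = _layout_loose(cfg, rng)
    elif class_label == "debris":
        cells = []
        for _ in range(int(rng.integers(1, 4))):
            c = (center[0] + rng.uniform(-8, 8), center[1] + rng.uniform(-8, 8))
            fp = _disk(shp, c, rng.uniform(2.0, 4.0))
            cells.append(_Cell("debris", fp, None, c))
    else:  # singlets
        kind = {"singlet_erythroblast": "erythroblast",
                "singlet_myeloid": "myeloid",
                "singlet_macrophage": "macrophage"}[class_label]
        cell, shape_class = _make_cell(cfg, kind, center, rng)
        cells = [cell]

    clean = _paint(cfg, cells, rng)
    img = ObjectImage(object_id, _apply_noise(clean, cfg.noise, rng),
                      cfg.pixel_size_um)

    central = next((c for c in cells
                    if c.cell_class in ("macrophage", "vcam_central")), None)
    model = cfg.marker_model.get(central.cell_class, {}) if central else {}
    truth = {
        "object_id": object_id,
        "true_class": class_label,
        "n_cells": len(cells) if class_label != "debris" else 0,
        "n_nuclei": sum(1 for c in cells if c.nucleus is not None),
        "n_erythroblasts": sum(1 for c in cells
                               if c.cell_class == "erythroblast"),
        "n_cd11b_cells": sum(1 for c in cells if c.cell_class == "myeloid"),
        "macrophage_shape_class": (shape_class if central is not None
                                   and central.cell_class == "macrophage"
                                   else "none"),
        "macrophage_mask": central.footprint.copy() if central else None,
        "n_ery_contacting_central": (
            sum(1 for c in cells if c.cell_class == "erythroblast"
                and (c.footprint & central.footprint).any())
            if central is not None else 0),
    }
    for ch in ("F480", "VCAM1", "CD169", "CD11b", "CD163"):
        truth[f"mac_pos_{ch}"] = bool(
            central is not None and model.get(ch, MarkerSpec(0)).mean_level
            >= 50.0)
    return img, truth


def simulate_cohort(cfg: SimulationConfig) -> tuple[list[ObjectImage], pd.DataFrame]:
    """``cfg.n_objects`` events drawn from ``class_mix``, fully reproducible.

    Each object gets its own child RNG spawned from ``cfg.seed``, so cohorts
    are byte-identical across runs and object k is unaffected by how the
    others are drawn.
    """
    if not cfg.class_mix:
        raise ValueError("class_mix is empty")
    root = np.random.SeedSequence(cfg.seed)
    labels_rng = np.random.default_rng(root.spawn(1)[0])
    classes = sorted(cfg.class_mix)
    probs = np.array([cfg.class_mix[c] for c in classes])
    labels = labels_rng.choice(classes, size=cfg.n_objects, p=probs)
    children = root.spawn(1 + cfg.n_objects)[1:]
    width = len(str(max(cfg.n_objects - 1, 1)))
    images, rows = [], []
    for k, (label, child) in enumerate(zip(labels, children)):
        rng = np.random.default_rng(child)
        img, truth = simulate_object(cfg, label, rng,
                                     object_id=f"obj{k:0{width}d}")
        images.append(img)
        rows.append(truth)
    return images, pd.DataFrame(rows)


def config_to_dict(cfg: SimulationConfig) -> dict:
    """YAML-serialisable form of a config (inverse of :func:`config_from_dict`)."""
    d = dataclasses.asdict(cfg)
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if "noise" in d and isinstance(d["noise"], dict):
        d["noise"] = NoiseModel(**d["noise"])
    if "macrophage_shape" in d and isinstance(d["macrophage_shape"], dict):
        ms = dict(d["macrophage_shape"])
        for key in ("n_extensions", "extension_len_px", "core_radius_px"):
            if key in ms:
                ms[key] = tuple(ms[key])
        d["macrophage_shape"] = MacrophageShape(**ms)
    for key in ("erythroblasts_per_EBI", "cd11b_satellites_per_EBI",
                "erythroblast_radius_px", "myeloid_radius_px"):
        if key in d:
            d[key] = tuple(d[key])
    if "marker_model" in d:
        mm = {}
        for cls, chans in d["marker_model"].items():
            mm[cls] = {ch: (spec if isinstance(spec, MarkerSpec)
                            else MarkerSpec(**spec))
                       for ch, spec in chans.items()}
        d["marker_model"] = mm
    return SimulationConfig(**d)
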