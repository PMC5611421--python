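"""Hierarchical gating over the per-object feature table.

Mirrors the analyst's strategy: multiplets (large brightfield area) are
gated first, then the CD71 x macrophage-marker double-positive "EBI gate".
Gates form a tree; an object belongs to a gate iff it belongs to the parent
and falls inside the gate's region.  Interval bounds are half-open
``[lo, hi)`` so that adjacent gates partition an axis exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GateSpec", "PopulationTable", "apply_gates", "default_ebi_gates",
           "derive_intensity_thresholds"]

#: brightfield-area lower limit for the multiplet gate, in um^2
DEFAULT_AREA_LOWER_UM2 = 50.0


@dataclass(frozen=True)
class GateSpec:
    """One node of the gate tree.

    ``axes`` names one or two feature columns; ``region`` gives, per axis,
    a ``(lo, hi)`` pair where ``None`` means unbounded on that side.
    Membership on each axis is ``lo <= x < hi``.
    """

    name: str
    parent: str | None  # None = root
    axes: tuple[str, ...]
    region: tuple[tuple[float | None, float | None], ...]

    def __post_init__(self) -> None:
        if len(self.axes) not in (1, 2) or len(self.region) != len(self.axes):
            raise ValueError(f"gate {self.name!r}: axes/region mismatch")

    def contains(self, row) -> bool:
        for ax, (lo, hi) in zip(self.axes, self.region):
            x = row[ax]
            if np.isnan(x):
                return False
            if lo is not None and x < lo:
                return False
            if hi is not None and x >= hi:
                return False
        return True


@dataclass
class PopulationTable:
    """Gate membership, counts and parent-relative frequencies."""

    membership: pd.DataFrame       # object_id x gate name -> bool
    counts: pd.Series              # gate name -> count
    frequencies: pd.Series         # gate name -> count / parent count
    gate_paths: pd.Series          # object_id -> ordered list of gates passed

    def members(self, gate: str) -> pd.Index:
        return self.membership.index[self.membership[gate]]


def _check_tree(gates: list[GateSpec]) -> list[GateSpec]:
    names = [g.name for g in gates]
    if len(set(names)) != len(names):
        raise ValueError("duplicate gate names")
    roots = [g for g in gates if g.parent is None]
    if len(roots) != 1:
        raise ValueError(f"need exactly one root gate, found {len(roots)}")
    byname = {g.name: g for g in gates}
    order: list[GateSpec] = []
    seen: set[str] = set()

    def visit(g: GateSpec, stack: tuple[str, ...]) -> None:
        if g.name in stack:
            raise ValueError(f"gate cycle through {g.name!r}")
        if g.name in seen:
            return
        if g.parent is not None:
            if g.parent not in byname:
                raise ValueError(f"gate {g.name!r}: unknown parent {g.parent!r}")
            visit(byname[g.parent], stack + (g.name,))
        seen.add(g.name)
        order.append(g)

    for g in gates:
        visit(g, ())
    return order  # topological: parents before children


def apply_gates(features: pd.DataFrame, gates: list[GateSpec]) -> PopulationTable:
    """Evaluate a gate tree top-down over a feature table.

    Raises ``KeyError`` naming the gate and the missing column if a gate
    references a feature the table does not have.
    """
    order = _check_tree(gates)
    feats = features.set_index("object_id")
    membership = pd.DataFrame(index=feats.index)
    for g in order:
        for ax in g.axes:
            if ax not in feats.columns:
                raise KeyError(f"gate {g.name!r}: feature column {ax!r} missing")
        if g.parent is None:
            inside = pd.Series(True, index=feats.index)
        else:
            inside = membership[g.parent].copy()
        sel = inside[inside].index
        ok = feats.loc[sel].apply(g.contains, axis=1) if len(sel) else pd.Series(dtype=bool)
        inside.loc[sel] = ok
        membership[g.name] = inside.astype(bool)
    counts = membership.sum(axis=0)
    freqs = {}
    byname = {g.name: g for g in gates}
    for name in membership.columns:
        parent = byname[name].parent
        denom = len(feats) if parent is None else counts[parent]
        freqs[name] = counts[name] / denom if denom else np.nan
    paths = membership.apply(
        lambda row: [g.name for g in order if row[g.name]], axis=1)
    return PopulationTable(membership, counts.astype(int),
                           pd.Series(freqs), paths)


def derive_intensity_thresholds(features: pd.DataFrame,
                                channels: tuple[str, ...],
                                truth: pd.DataFrame | None = None,
                                q: float = 0.99,
                                area_lower_um2: float = DEFAULT_AREA_LOWER_UM2,
                                ) -> dict[str, float]:
    """Data-driven intensity cut per channel: the ``q`` quantile of a
    negative-control pool's integrated intensity.

    With a truth table the controls are the planted singlets and debris that
    genuinely lack the marker; without one, all objects below the multiplet
    area cut stand in (they are overwhelmingly single cells and debris).
    A cohort with no controls at all (e.g. clusters only) gets the column
    minimum — no usable cut can be estimated, so the gate keeps everything
    and a warning is logged.
    """
    import logging
    log = logging.getLogger("ebiflow")
    negatives = {
        "CD71": ("singlet_myeloid", "singlet_macrophage", "debris"),
        "Ter119": ("singlet_myeloid", "singlet_macrophage", "debris"),
        "F480": ("singlet_erythroblast", "singlet_myeloid", "debris"),
        "CD163": ("singlet_erythroblast", "singlet_myeloid", "debris"),
        "VCAM1": ("singlet_erythroblast", "singlet_myeloid", "debris"),
        "CD11b": ("singlet_erythroblast", "singlet_macrophage", "debris"),
    }
    out = {}
    for ch in channels:
        col = f"intensity_{ch}"
        pool = pd.Series(dtype=float)
        if truth is not None:
            merged = features.merge(truth[["object_id", "true_class"]],
                                    on="object_id")
            pool = merged.loc[merged["true_class"].isin(negatives[ch]), col]
        if pool.empty:
            pool = features.loc[features["area_bf_um2"] < area_lower_um2, col]
        if pool.empty:
            if truth is None and features.empty:
                raise ValueError(
                    f"no negative-control objects for channel {ch!r}")
            log.warning("no negative controls for %s; gate keeps everything",
                        ch)
            out[ch] = float(features[col].min())
        else:
            out[ch] = float(pool.quantile(q))
    return out


def default_ebi_gates(species: str = "mouse",
                      area_lower_um2: float = DEFAULT_AREA_LOWER_UM2,
                      t_cd71: float | None = None,
                      t_mac: float | None = None,
                      features: pd.DataFrame | None = None,
                      truth: pd.DataFrame | None = None) -> list[GateSpec]:
    """The standard tree: root -> multiplets (area) -> double-positive EBI gate.

    The macrophage axis is F4/80 for mouse and CD163 for rat.  Intensity
    cuts may be fixed, or derived from the data via
    :func:`derive_intensity_thresholds` when a feature table is supplied.
    """
    mac_channel = {"mouse": "F480", "rat": "CD163"}.get(species)
    if mac_channel is None:
        raise ValueError(f"unknown species {species!r}")
    if t_cd71 is None or t_mac is None:
        if features is None:
            raise ValueError("either fixed thresholds or a feature table "
                             "(for data-driven cuts) is required")
        t = derive_intensity_thresholds(features, ("CD71", mac_channel),
                                        truth=truth,
                                        area_lower_um2=area_lower_um2)
        t_cd71 = t["CD71"] if t_cd71 is None else t_cd71
        t_mac = t[mac_channel] if t_mac is None else t_mac
    return [
        GateSpec("all", None, ("area_bf_um2",), ((None, None),)),
        GateSpec("multiplets", "all", ("area_bf_um2",),
                 ((area_lower_um2, None),)),
        GateSpec("ebi_gate", "multiplets",
                 ("intensity_CD71", f"intensity_{mac_channel}"),
                 ((t_cd71, None), (t_mac, None))),
    ]
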