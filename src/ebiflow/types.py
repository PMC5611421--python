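"""Core containers shared by every pipeline stage.

An imaging flow cytometer records one small, spatially registered
multichannel image per event ("object").  :class:`ObjectImage` holds that
frame; :class:`Mask` is a boolean pixel set tied to one of its channels and
is the region on which every scalar feature is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical channel order used by the simulator, the TIFF writer and the CLI.
CHANNELS = (
    "BF",
    "DNA",
    "CD71",
    "Ter119",
    "F480",
    "VCAM1",
    "CD169",
    "CD11b",
    "CD163",
)


@dataclass
class ObjectImage:
    """One event's registered multichannel pixel frame.

    Parameters
    ----------
    object_id : str
        Unique identifier within a cohort.
    channels : dict of str -> ndarray
        Named 2-D float arrays of identical shape with finite,
        non-negative intensities.
    pixel_size_um : float
        Physical pixel pitch in micrometres per pixel.
    """

    object_id: str
    channels: dict[str, np.ndarray]
    pixel_size_um: float

    def __post_init__(self) -> None:
        shapes = {ch: a.shape for ch, a in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for name, arr in self.channels.items():
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2-D")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"channel {name!r} has non-finite or negative pixels")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(
                f"object {self.object_id}: channel {name!r} not present "
                f"(have {sorted(self.channels)})"
            )
        return self.channels[name]


@dataclass
class Mask:
    """Boolean pixel set tied to an :class:`ObjectImage` channel.

    ``flags`` records non-fatal conditions (e.g. ``empty`` when a
    zero-variance channel produced no foreground).
    """

    object_id: str
    channel: str
    pixels: np.ndarray
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    @property
    def is_empty(self) -> bool:
        return not self.pixels.any()

    def area_um2(self, pixel_size_um: float) -> float:
        return self.area_px * pixel_size_um**2
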