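"""Readers and writers: multipage TIFF objects, channel maps, CSV tables.

A cohort on disk is a directory of one multipage TIFF per object (page
order given by ``channels.yaml``), the channel map itself, and a
``truth.csv`` when the cohort is synthetic.  CSVs are deterministic:
object-id row order, floats at 6 significant digits.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import CHANNELS, ObjectImage

__all__ = ["write_cohort", "read_object_dir", "read_channel_map",
           "write_table", "write_feature_table", "write_calls",
           "write_summary", "FLOAT_FORMAT"]

log = logging.getLogger("ebiflow")

FLOAT_FORMAT = "%.6g"
CHANNELS_YAML = "channels.yaml"
TRUTH_CSV = "truth.csv"


def write_cohort(images: list[ObjectImage], truth: pd.DataFrame | None,
                 outdir: str | Path,
                 channels: tuple[str, ...] = CHANNELS) -> Path:
    """Write one TIFF per object plus channels.yaml (+ truth.csv if given)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if images:
        pixel_size = images[0].pixel_size_um
    else:
        pixel_size = float("nan")
    channel_map = {"pixel_size_um": float(pixel_size),
                   "channels": {ch: i for i, ch in enumerate(channels)}}
    (outdir / CHANNELS_YAML).write_text(yaml.safe_dump(channel_map))
    for img in images:
        # float64 pages so a write->read round trip is lossless
        stack = np.stack([img.channel(ch) for ch in channels]).astype(np.float64)
        tifffile.imwrite(outdir / f"{img.object_id}.tif", stack)
    if truth is not None:
        cols = [c for c in truth.columns if c != "macrophage_mask"]
        write_table(truth[cols], outdir / TRUTH_CSV)
    return outdir


def read_channel_map(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if "channels" not in cfg or "pixel_size_um" not in cfg:
        raise ValueError(f"malformed channel map {path}")
    return cfg


def read_object_dir(path: str | Path, channels: tuple[str, ...] | None = None):
    """Lazily yield validated ObjectImages from a cohort directory.

    Malformed files (unreadable, wrong page count, missing channel) are
    logged and skipped; a terminal log line reports how many were dropped.
    Streaming keeps the memory footprint constant per object.
    """
    path = Path(path)
    cmap = read_channel_map(path / CHANNELS_YAML)
    page_of = cmap["channels"]
    wanted = channels or tuple(page_of)
    pixel_size = float(cmap["pixel_size_um"])
    skipped = 0
    for tif in sorted(path.glob("*.tif")):
        try:
            stack = tifffile.imread(tif)
            if stack.ndim == 2:
                stack = stack[None]
            chans = {}
            for ch in wanted:
                if ch not in page_of or page_of[ch] >= len(stack):
                    raise ValueError(f"channel {ch!r} missing")
                chans[ch] = np.asarray(stack[page_of[ch]], dtype=float)
            yield ObjectImage(tif.stem, chans, pixel_size)
        except Exception as exc:  # malformed file: skip, keep streaming
            skipped += 1
            log.warning("skipping %s: %s", tif.name, exc)
    if skipped:
        log.warning("%d malformed object file(s) skipped", skipped)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Deterministic CSV: object_id-sorted where present, 6-sig-digit floats."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    if "object_id" in out.columns:
        out = out.sort_values("object_id").reset_index(drop=True)
    out.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


# stage-specific aliases keep call sites self-describing
write_feature_table = write_table
write_calls = write_table
write_summary = write_table
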