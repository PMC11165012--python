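"""Readers and writers for images, tables, spike lists and configs.

Images travel as multi-page 16-bit TIFF; each page is one Z-plane holding
all channels stacked along the first axis, with the channel map, pixel
size and identity stored as JSON in the TIFF description. Tables are plain
CSV. Configs are hierarchical YAML with a single global seed.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import FieldImage, FormatError, PlateMap, SpikeTrainSet, ZStack

WELL_TABLE_KEY_COLUMNS = ["plate", "well", "compound", "dose", "role", "replicate"]
SPIKE_LIST_COLUMNS = ["electrode_id", "spike_time_s"]


# ---------------------------------------------------------------- images

def write_image_stack(path, stack: ZStack) -> None:
    """Write a Z-stack as a multi-page TIFF (uint16, bit-exact round trip)."""
    path = Path(path)
    ref = stack.planes[0]
    meta = {
        "channels": {str(k): int(v) for k, v in ref.channels.items()},
        "pixel_size_um": float(ref.pixel_size_um),
        "well_id": ref.well_id,
        "field_index": int(ref.field_index),
    }
    pages = [np.clip(np.round(p.pixels), 0, 65535).astype(np.uint16) for p in stack.planes]
    tifffile.imwrite(path, np.stack(pages), description=json.dumps(meta))


def read_image_stack(path, required_channels=None) -> ZStack:
    """Read a single- or multi-page TIFF into a :class:`ZStack`.

    Channel names are resolved from the JSON sidecar metadata embedded in
    the TIFF description (or a ``<path>.json`` sidecar file). Intensities
    are preserved bit-exact.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    meta = None
    if desc:
        try:
            meta = json.loads(desc)
        except (TypeError, json.JSONDecodeError):
            meta = None
    sidecar = path.with_suffix(path.suffix + ".json")
    if meta is None and sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if not isinstance(meta, dict) or "channels" not in meta:
        raise FormatError(f"{path}: no channel metadata in TIFF description or sidecar")
    channels = {str(k): int(v) for k, v in meta["channels"].items()}
    if data.ndim == 3:  # single page: (C, H, W)
        data = data[None]
    if data.ndim != 4:
        raise FormatError(f"{path}: expected pages of shape (C, H, W)")
    if data.shape[1] != len(channels):
        raise FormatError(f"{path}: {data.shape[1]} planes per page but {len(channels)} channel names")
    planes = [
        FieldImage(
            page,
            channels,
            float(meta.get("pixel_size_um", 1.0)),
            meta.get("well_id", ""),
            int(meta.get("field_index", 0)),
        )
        for page in data
    ]
    stack = ZStack(planes)
    if required_channels:
        for name in required_channels:
            if not planes[0].has_channel(name):
                raise FormatError(f"{path}: required channel {name!r} missing")
    return stack


# ---------------------------------------------------------------- plate maps

def write_plate_map(path, pm: PlateMap) -> None:
    rows = [{"plate_id": pm.plate_id, **w} for w in pm.wells]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_plate_map(path) -> PlateMap:
    df = pd.read_csv(path)
    for col in ("plate_id", "well_id", "role"):
        if col not in df.columns:
            raise FormatError(f"plate map missing column {col!r}")
    plates = df["plate_id"].unique()
    if len(plates) != 1:
        raise FormatError("one plate map file per plate")
    wells = []
    for _, r in df.iterrows():
        w = {
            "well_id": str(r["well_id"]),
            "role": str(r["role"]),
            "compound_id": None if pd.isna(r.get("compound_id")) else str(r["compound_id"]),
            "dose": None if pd.isna(r.get("dose")) else float(r["dose"]),
            "cell_line": "" if pd.isna(r.get("cell_line")) else str(r.get("cell_line")),
        }
        wells.append(w)
    return PlateMap(str(plates[0]), wells)


# ---------------------------------------------------------------- well tables

def write_well_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_well_table(path) -> pd.DataFrame:
    """Read a long-format well table; validates keys and uniqueness."""
    df = pd.read_csv(path)
    for col in ("plate", "well"):
        if col not in df.columns:
            raise FormatError(f"well table missing column {col!r}")
    keys = [c for c in WELL_TABLE_KEY_COLUMNS if c in df.columns]
    if df.duplicated(subset=keys).any():
        raise FormatError("duplicate well rows in table")
    return df


# ---------------------------------------------------------------- spike lists

def write_spike_list(path, trains: SpikeTrainSet) -> None:
    rows = []
    for eid, times in trains.electrodes.items():
        for t in times:
            rows.append((eid, float(t)))
    df = pd.DataFrame(rows, columns=SPIKE_LIST_COLUMNS)
    header = f"# duration_s={trains.duration_s} well_id={trains.well_id}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_spike_list(path, duration_s: float | None = None, well_id: str = "") -> SpikeTrainSet:
    """Read an (electrode_id, spike_time_s) CSV; times are sorted per electrode."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("#"):
        skip = 1
        for tok in first[1:].split():
            if tok.startswith("duration_s=") and duration_s is None:
                duration_s = float(tok.split("=", 1)[1])
            elif tok.startswith("well_id=") and not well_id:
                well_id = tok.split("=", 1)[1]
    df = pd.read_csv(path, skiprows=skip)
    for col in SPIKE_LIST_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"spike list missing column {col!r}")
    if (df["spike_time_s"] < 0).any():
        raise FormatError("negative spike times")
    if duration_s is None:
        duration_s = float(df["spike_time_s"].max()) if len(df) else 1.0
    electrodes = {
        str(eid): np.sort(grp["spike_time_s"].to_numpy(float))
        for eid, grp in df.groupby("electrode_id")
    }
    return SpikeTrainSet(electrodes, float(duration_s), well_id)


# ---------------------------------------------------------------- configs

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def fixture_path(name: str) -> Path:
    """Path of a packaged fixture config, e.g. ``fixture_path('screen_sim.yaml')``."""
    return Path(resources.files("neuroscreen") / "fixtures" / name)


def load_fixture(name: str) -> dict:
    return load_config(fixture_path(name))
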