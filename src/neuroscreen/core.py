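"""Core containers shared across the pipeline.

Conventions: pixel coordinates are 0-based ``(row, col)``; areas are in
pixels unless an explicit ``pixel_size_um`` conversion is requested; well
ids are row letter + 2-digit column ("A01".."P24" on 384-well plates,
"A1".."F8" on 48-well MEA plates). Channel names are free text and matched
case-insensitively.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np


class FormatError(ValueError):
    """Raised when an input file or in-memory object violates the format contract."""


class ConfigError(ValueError):
    """Raised when a simulation or analysis configuration is inconsistent."""


def rng_for(seed: int, stage: str) -> np.random.Generator:
    """Return a generator seeded from ``(global seed, stage name)``.

    Every stochastic operation draws from its own stage stream so that
    adding a stage never perturbs the others.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())])
    )


@dataclass
class FieldImage:
    """One imaging field: a stack of 2-D channels with a channel-name map."""

    pixels: np.ndarray  # (n_channels, H, W), non-negative
    channels: Mapping[str, int]
    pixel_size_um: float
    well_id: str = ""
    field_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise FormatError("pixels must be (n_channels, H, W)")
        if len(self.channels) != self.pixels.shape[0]:
            raise FormatError("channel map does not cover all planes")
        if self.pixel_size_um <= 0:
            raise FormatError("pixel_size_um must be positive")
        self._lower = {str(k).lower(): v for k, v in self.channels.items()}

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]

    def has_channel(self, name: str) -> bool:
        return name.lower() in self._lower

    def channel(self, name: str) -> np.ndarray:
        """Return one channel by case-insensitive name."""
        key = name.lower()
        if key not in self._lower:
            raise FormatError(f"channel {name!r} not present (have {sorted(self.channels)})")
        return self.pixels[self._lower[key]]

    def with_pixels(self, pixels: np.ndarray) -> "FieldImage":
        return FieldImage(pixels, dict(self.channels), self.pixel_size_um,
                          self.well_id, self.field_index)


@dataclass
class ZStack:
    """Ordered Z-planes with identical geometry and channel maps."""

    planes: Sequence[FieldImage]

    def __post_init__(self) -> None:
        if len(self.planes) == 0:
            raise FormatError("a Z-stack needs at least one plane")
        ref = self.planes[0]
        for p in self.planes[1:]:
            if p.shape != ref.shape or set(k.lower() for k in p.channels) != set(
                k.lower() for k in ref.channels
            ):
                raise FormatError("planes differ in shape or channel map")

    def __len__(self) -> int:
        return len(self.planes)


def max_project(stack: ZStack) -> FieldImage:
    """Per-pixel, per-channel maximum-intensity projection across Z-planes.

    A single-plane stack is returned unchanged.
    """
    if len(stack) == 1:
        return stack.planes[0]
    ref = stack.planes[0]
    out = np.max(np.stack([p.pixels for p in stack.planes]), axis=0)
    return ref.with_pixels(out)


@dataclass
class WellRole:
    DMSO = "dmso"
    POSITIVE = "positive_control"
    COMPOUND = "compound"
    EMPTY = "empty"


def well_name(row: int, col: int, pad: int = 2) -> str:
    """0-based (row, col) -> instrument-style well id, e.g. (0, 0) -> 'A01'."""
    return f"{chr(ord('A') + row)}{col + 1:0{pad}d}"


@dataclass
class PlateMap:
    """Layout of one plate: role, compound and dose per well."""

    plate_id: str
    wells: "list[dict]" = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [w["well_id"] for w in self.wells]
        if len(ids) != len(set(ids)):
            raise FormatError(f"duplicate well ids on plate {self.plate_id}")
        for w in self.wells:
            role = w.get("role")
            if role in (WellRole.COMPOUND, WellRole.POSITIVE):
                if w.get("dose") is None:
                    raise FormatError(f"well {w['well_id']}: {role} wells need a dose")
            elif role in (WellRole.DMSO, WellRole.EMPTY):
                if w.get("dose") is not None:
                    raise FormatError(f"well {w['well_id']}: {role} wells carry no dose")
            else:
                raise FormatError(f"well {w['well_id']}: unknown role {role!r}")


@dataclass
class SpikeTrainSet:
    """Per-electrode sorted spike timestamps for one well."""

    electrodes: "dict[str, np.ndarray]"
    duration_s: float
    well_id: str = ""

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise FormatError("duration_s must be positive")
        clean = {}
        for eid, t in self.electrodes.items():
            t = np.asarray(t, dtype=float)
            if t.size and (t.min() < 0 or t.max() > self.duration_s):
                raise FormatError(f"electrode {eid}: spike times outside [0, duration]")
            if t.size and np.any(np.diff(t) < 0):
                raise FormatError(f"electrode {eid}: spike times not sorted")
            clean[str(eid)] = t
        self.electrodes = clean

    @property
    def n_electrodes(self) -> int:
        return len(self.electrodes)

    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.electrodes.values()))
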