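"""Section images, masks, boundary contours and tabular result I/O.

Conventions
-----------
Coordinates are ``(row, col)``, 0-based, referring to pixel centers.  All
physical distances are reported in micrometres: ``µm = pixels × pixel_size``.
Channels are held as float arrays internally; 8/16-bit unsigned and float32
TIFF inputs are accepted.

Sections are stored as 3-page TIFFs in the fixed page order
``nuclei, antibody, vessel`` with a JSON sidecar carrying pixel size, seed and
generation parameters.  Masks are single-page 8-bit TIFFs (0/255).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .exceptions import FormatError, UsageError

CHANNEL_ORDER = ("nuclei", "antibody", "vessel")


@dataclass
class SectionImage:
    """One tissue section: three co-registered channels plus pixel size.

    Channels: ``nuclei`` (DAPI), ``antibody`` (anti-HER2 mAb, Cy5-type
    fluorophore), ``vessel`` (perfused-vessel lectin stain, Cy3-type).
    """

    nuclei: np.ndarray
    antibody: np.ndarray
    vessel: np.ndarray
    pixel_size: float
    section_id: str = ""
    tumor_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.nuclei = np.asarray(self.nuclei, dtype=float)
        self.antibody = np.asarray(self.antibody, dtype=float)
        self.vessel = np.asarray(self.vessel, dtype=float)
        if not (self.nuclei.shape == self.antibody.shape == self.vessel.shape):
            raise FormatError("channel shapes differ: "
                              f"{self.nuclei.shape}, {self.antibody.shape}, {self.vessel.shape}")
        if self.nuclei.ndim != 2:
            raise FormatError("channels must be 2-D arrays")
        if not (np.isfinite(self.pixel_size) and self.pixel_size > 0):
            raise FormatError(f"pixel_size must be finite and > 0, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.nuclei.shape

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNEL_ORDER:
            raise UsageError(f"unknown channel {name!r}")
        return getattr(self, name)


@dataclass
class Mask:
    """Binary region (tumor foreground or vessel lumen) on the section grid."""

    pixels: np.ndarray
    kind: str = "tumor"  # {"tumor", "vessel"}

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise FormatError("mask must be a 2-D array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area_pixels(self) -> int:
        return int(self.pixels.sum())

    def area_um2(self, pixel_size: float) -> float:
        return self.area_pixels * pixel_size ** 2


def signed_area(coords: np.ndarray) -> float:
    """Shoelace signed area of a closed (row, col) polygon.

    The x-axis is taken as ``col`` and the y-axis as ``row``; with this
    convention a positive signed area is defined as counter-clockwise in the
    array frame (which appears clockwise when the image is displayed with the
    row axis pointing down).
    """
    c = np.asarray(coords, dtype=float)
    x, y = c[:, 1], c[:, 0]
    return 0.5 * float(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))


@dataclass
class BoundaryContour:
    """Closed, counter-clockwise sub-pixel trace of the tumor border.

    ``coords`` is an (N, 2) float array of (row, col) points with
    ``coords[0] == coords[-1]``; points lie on the 0.5-level of the binary
    tumor mask, i.e. halfway between foreground and background pixel centers.
    """

    coords: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 2 or c.shape[1] != 2 or len(c) < 4:
            raise FormatError("contour must be an (N>=4, 2) coordinate array")
        if not np.allclose(c[0], c[-1]):
            raise FormatError("contour must be closed (first point == last point)")
        if signed_area(c) < 0:
            c = c[::-1].copy()
        self.coords = c

    @property
    def n_points(self) -> int:
        return len(self.coords) - 1  # closing vertex not counted twice

    @property
    def is_counter_clockwise(self) -> bool:
        return signed_area(self.coords) > 0

    def arclength(self) -> np.ndarray:
        """Cumulative arclength (pixels) at each vertex, starting at 0."""
        seg = np.linalg.norm(np.diff(self.coords, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])


# ---------------------------------------------------------------------------
# TIFF I/O

def write_section(section: SectionImage, path: str | Path,
                  metadata: Mapping[str, Any] | None = None) -> Path:
    """Write a section as a 3-page float32 TIFF plus a JSON sidecar."""
    path = Path(path)
    stack = np.stack([section.nuclei, section.antibody, section.vessel]).astype(np.float32)
    tifffile.imwrite(path, stack, photometric="minisblack")
    sidecar = {
        "pixel_size_um": section.pixel_size,
        "channel_order": list(CHANNEL_ORDER),
        "section_id": section.section_id,
        "tumor_id": section.tumor_id,
        "group": section.group,
    }
    if metadata:
        sidecar.update(dict(metadata))
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_section(path: str | Path | Sequence[str | Path],
                 channel_order: Sequence[str] = CHANNEL_ORDER,
                 pixel_size: float | None = None,
                 section_id: str = "", tumor_id: str = "", group: str = "") -> SectionImage:
    """Read a section from a 3-page TIFF (or three single-page TIFFs).

    ``channel_order`` names each page/file.  ``pixel_size`` may be omitted
    when a JSON sidecar written by :func:`write_section` sits next to the
    (first) TIFF.
    """
    if set(channel_order) != set(CHANNEL_ORDER) or len(channel_order) != 3:
        raise UsageError(f"channel_order must be a permutation of {CHANNEL_ORDER}")

    if isinstance(path, (str, Path)):
        p = Path(path)
        if not p.exists():
            raise FormatError(f"section file not found: {p}")
        pages = tifffile.imread(p)
        if pages.ndim == 2:
            pages = pages[None]
        if pages.ndim != 3 or pages.shape[0] != 3:
            raise FormatError(f"{p}: expected a 3-page TIFF, got shape {pages.shape}")
        sidecar_path = p.with_suffix(".json")
    else:
        paths = [Path(q) for q in path]
        if len(paths) != 3:
            raise FormatError(f"expected 3 per-channel files, got {len(paths)}")
        for q in paths:
            if not q.exists():
                raise FormatError(f"section file not found: {q}")
        arrays = [tifffile.imread(q) for q in paths]
        shapes = {a.shape for a in arrays}
        if len(shapes) != 1 or arrays[0].ndim != 2:
            raise FormatError(f"per-channel shapes differ or are not 2-D: {shapes}")
        pages = np.stack(arrays)
        sidecar_path = paths[0].with_suffix(".json")

    meta: dict[str, Any] = {}
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
    if pixel_size is None:
        pixel_size = meta.get("pixel_size_um")
    if pixel_size is None:
        raise UsageError("pixel_size not given and no JSON sidecar found")

    channels = {name: pages[i] for i, name in enumerate(channel_order)}
    return SectionImage(
        nuclei=channels["nuclei"], antibody=channels["antibody"], vessel=channels["vessel"],
        pixel_size=float(pixel_size),
        section_id=section_id or meta.get("section_id", ""),
        tumor_id=tumor_id or meta.get("tumor_id", ""),
        group=group or meta.get("group", ""),
    )


def write_mask(mask: Mask, path: str | Path) -> Path:
    """Write a mask as a single-page 8-bit TIFF (foreground = 255)."""
    path = Path(path)
    tifffile.imwrite(path, (mask.pixels.astype(np.uint8) * 255))
    return path


def read_mask(path: str | Path, kind: str = "tumor") -> Mask:
    arr = tifffile.imread(Path(path))
    if arr.ndim != 2:
        raise FormatError(f"{path}: mask TIFF must be single-page 2-D")
    return Mask(pixels=arr > 0, kind=kind)


# ---------------------------------------------------------------------------
# Tabular results

def _record_to_dict(record: Any) -> dict[str, Any]:
    if dataclasses.is_dataclass(record) and not isinstance(record, type):
        return {k: v for k, v in dataclasses.asdict(record).items()
                if np.isscalar(v) or isinstance(v, (str, bool, int, float)) or v is None}
    if isinstance(record, Mapping):
        return dict(record)
    raise UsageError(f"cannot serialize record of type {type(record).__name__}")


def write_results(records: Iterable[Any], path: str | Path,
                  metadata_comment: str | None = None) -> Path:
    """Write homogeneous records (dataclasses or dicts) to CSV.

    Numbers are serialized at full repr precision so a read-back reproduces
    the values to <=1e-9 relative.  An optional ``metadata_comment`` line is
    prepended as a ``#`` comment (ignored by :func:`read_results`).
    """
    rows = [_record_to_dict(r) for r in records]
    if not rows:
        raise UsageError("write_results: empty record list")
    keys = list(rows[0].keys())
    for r in rows[1:]:
        if list(r.keys()) != keys:
            raise UsageError("write_results: records have mixed schemas")
    frame = pd.DataFrame(rows, columns=keys)
    path = Path(path)
    with open(path, "w") as fh:
        if metadata_comment:
            fh.write(f"# {metadata_comment}\n")
        frame.to_csv(fh, index=False, float_format="%.17g")
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), comment="#")
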