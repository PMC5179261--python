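"""Image and table I/O for the tubule-quantification pipeline.

Reads two-channel TIFF images (a whole-cell stain plus an endosomal
marker such as SNX1) into :class:`MultiChannelImage`, and reads/writes
the pipeline's tabular outputs: the per-image skeleton-branch CSV and
the per-image summary text file.

Conventions
-----------
* Coordinates are 0-based ``(row, col)``, row-major, origin top-left.
* Default pixel size is 0.1 um/px, so a 20 px length corresponds to 2 um.
* Floats are serialised with 6 significant digits, so writers are
  byte-deterministic and round-trips are stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

__all__ = [
    "MultiChannelImage",
    "BranchRecord",
    "ImageSummaryRow",
    "ChannelError",
    "TableFormatError",
    "DEFAULT_PIXEL_SIZE_UM",
    "read_two_channel_image",
    "write_branch_csv",
    "read_branch_csv",
    "write_summary_text",
    "read_summary_text",
]

DEFAULT_PIXEL_SIZE_UM = 0.1

#: fixed significant digits for serialised floats
_FLOAT_FMT = "{:.6g}"


class ChannelError(ValueError):
    """Raised when a TIFF does not provide the two required channels."""


class TableFormatError(ValueError):
    """Raised when a CSV/TSV table does not match the expected schema."""


@dataclass(frozen=True)
class MultiChannelImage:
    """A registered pair of 2-D intensity grids plus pixel calibration.

    Parameters
    ----------
    cell_channel :
        Whole-cell stain intensities ("red"); used only for masking.
    marker_channel :
        Endosomal-marker intensities ("green", e.g. SNX1); the channel
        in which tubules are detected.
    pixel_size_um :
        Physical size of one pixel in micrometres.
    source_id :
        Identifier for provenance (usually the file stem).
    """

    cell_channel: np.ndarray
    marker_channel: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    source_id: str = ""

    def __post_init__(self) -> None:
        cell = np.asarray(self.cell_channel)
        marker = np.asarray(self.marker_channel)
        if cell.ndim != 2 or marker.ndim != 2:
            raise ChannelError("channels must be 2-D intensity grids")
        if cell.shape != marker.shape:
            raise ChannelError(
                f"channel shapes differ: {cell.shape} vs {marker.shape}"
            )
        if not (np.isfinite(cell).all() and np.isfinite(marker).all()):
            raise ValueError("channel intensities must be finite")
        if (cell < 0).any() or (marker < 0).any():
            raise ValueError("channel intensities must be non-negative")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "cell_channel", cell)
        object.__setattr__(self, "marker_channel", marker)

    @property
    def shape(self) -> tuple[int, int]:
        return self.cell_channel.shape


@dataclass(frozen=True)
class BranchRecord:
    """One measured skeleton branch, as exported to the per-image CSV."""

    image_id: str
    component_id: int
    branch_id: int
    length_px: float
    endpoints: tuple[tuple[int, int], tuple[int, int]]
    n_junction_contacts: int

    def __post_init__(self) -> None:
        if self.length_px < 0:
            raise ValueError("length_px must be >= 0")
        if self.n_junction_contacts < 0:
            raise ValueError("n_junction_contacts must be >= 0")


@dataclass(frozen=True)
class ImageSummaryRow:
    """One line of the per-image summary text file (the three metrics)."""

    image_id: str
    n_tubules: int
    has_tubule: bool
    longest_excess_px: float


def read_two_channel_image(
    path: str | Path,
    channel_order: Mapping[str, int] | None = None,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> MultiChannelImage:
    """Read a two-plane (or RGB) TIFF into a :class:`MultiChannelImage`.

    Parameters
    ----------
    path :
        TIFF file with >= 2 planes, or an RGB image. For RGB input the
        default role mapping is ``{"cell": 0, "marker": 1}`` — red is
        the whole-cell stain and green the marker, matching common
        staining conventions.
    channel_order :
        Mapping from role (``"cell"``, ``"marker"``) to plane index.
    pixel_size_um :
        Physical pixel size; defaults to 0.1 um/px.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    data = tifffile.imread(path)
    data = np.asarray(data)
    if data.ndim == 2:
        raise ChannelError(
            f"{path.name}: requires two channels, got a single plane"
        )
    if data.ndim != 3:
        raise ChannelError(f"{path.name}: unsupported TIFF dimensionality {data.ndim}")
    # Accept planar (C, H, W) or interleaved RGB(A) (H, W, C).
    if data.shape[-1] in (3, 4) and data.shape[0] not in (2, 3, 4):
        data = np.moveaxis(data, -1, 0)
    n_planes = data.shape[0]
    if n_planes < 2:
        raise ChannelError(f"{path.name}: requires two channels, got {n_planes}")
    order = dict(channel_order) if channel_order is not None else {"cell": 0, "marker": 1}
    for role in ("cell", "marker"):
        if role not in order:
            raise ChannelError(f"channel_order must map role {role!r} to a plane index")
        if not 0 <= order[role] < n_planes:
            raise ChannelError(
                f"{path.name}: plane {order[role]} for role {role!r} out of range "
                f"(file has {n_planes} planes)"
            )
    cell = data[order["cell"]]
    marker = data[order["marker"]]
    if cell.shape != marker.shape:
        raise ChannelError(f"{path.name}: plane shapes differ")
    return MultiChannelImage(
        cell_channel=cell.astype(np.float64, copy=False),
        marker_channel=marker.astype(np.float64, copy=False),
        pixel_size_um=pixel_size_um,
        source_id=path.stem,
    )


_BRANCH_COLUMNS = [
    "image_id",
    "component_id",
    "branch_id",
    "length_px",
    "end0_row",
    "end0_col",
    "end1_row",
    "end1_col",
    "n_junction_contacts",
]


def write_branch_csv(records: Sequence[BranchRecord], path: str | Path) -> None:
    """Write one CSV row per skeleton branch (header always present).

    All records must share one ``image_id``; the writer is deterministic
    (fixed column order, 6-significant-digit floats).
    """
    records = list(records)
    image_ids = {r.image_id for r in records}
    if len(image_ids) > 1:
        raise ValueError(f"records span multiple images: {sorted(image_ids)}")
    lines = [",".join(_BRANCH_COLUMNS)]
    for r in records:
        (r0, c0), (r1, c1) = r.endpoints
        lines.append(
            ",".join(
                [
                    r.image_id,
                    str(int(r.component_id)),
                    str(int(r.branch_id)),
                    _FLOAT_FMT.format(r.length_px),
                    str(int(r0)),
                    str(int(c0)),
                    str(int(r1)),
                    str(int(c1)),
                    str(int(r.n_junction_contacts)),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_branch_csv(path: str | Path) -> list[BranchRecord]:
    """Read a branch CSV written by :func:`write_branch_csv`."""
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise TableFormatError(f"{path.name}: empty file, expected a header row")
    header = lines[0].split(",")
    missing = [c for c in _BRANCH_COLUMNS if c not in header]
    if missing:
        raise TableFormatError(f"{path.name}: missing required column(s) {missing}")
    idx = {c: header.index(c) for c in _BRANCH_COLUMNS}
    records: list[BranchRecord] = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split(",")
        if len(parts) < len(header):
            raise TableFormatError(f"{path.name}: row {lineno} has too few fields")

        def _num(col: str, cast, _parts=parts, _lineno=lineno):
            raw = _parts[idx[col]]
            try:
                return cast(float(raw)) if cast is int else cast(raw)
            except ValueError:
                raise TableFormatError(
                    f"{path.name}: row {_lineno}, column {col!r}: "
                    f"non-numeric value {raw!r}"
                ) from None

        records.append(
            BranchRecord(
                image_id=parts[idx["image_id"]],
                component_id=_num("component_id", int),
                branch_id=_num("branch_id", int),
                length_px=_num("length_px", float),
                endpoints=(
                    (_num("end0_row", int), _num("end0_col", int)),
                    (_num("end1_row", int), _num("end1_col", int)),
                ),
                n_junction_contacts=_num("n_junction_contacts", int),
            )
        )
    return records


_SUMMARY_COLUMNS = ["image_id", "n_tubules", "has_tubule", "longest_excess_px"]


def write_summary_text(rows: Sequence[ImageSummaryRow], path: str | Path) -> None:
    """Write the per-image summary: tab-delimited, one line per image.

    Columns: image id, tubule count, has-tubule flag (0/1), and the
    length in pixels by which the longest qualifying tubule exceeds the
    threshold (0 when the image has no qualifying tubule).
    """
    lines = ["\t".join(_SUMMARY_COLUMNS)]
    for row in rows:
        lines.append(
            "\t".join(
                [
                    row.image_id,
                    str(int(row.n_tubules)),
                    str(int(row.has_tubule)),
                    _FLOAT_FMT.format(row.longest_excess_px),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_summary_text(path: str | Path) -> list[ImageSummaryRow]:
    """Read a summary file written by :func:`write_summary_text`."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise TableFormatError(f"{path.name}: empty file, expected a header row")
    header = lines[0].split("\t")
    missing = [c for c in _SUMMARY_COLUMNS if c not in header]
    if missing:
        raise TableFormatError(f"{path.name}: missing required column(s) {missing}")
    idx = {c: header.index(c) for c in _SUMMARY_COLUMNS}
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        try:
            rows.append(
                ImageSummaryRow(
                    image_id=parts[idx["image_id"]],
                    n_tubules=int(float(parts[idx["n_tubules"]])),
                    has_tubule=bool(int(float(parts[idx["has_tubule"]]))),
                    longest_excess_px=float(parts[idx["longest_excess_px"]]),
                )
            )
        except (ValueError, IndexError):
            raise TableFormatError(
                f"{path.name}: row {lineno} is malformed: {line!r}"
            ) from None
    return rows


def write_two_channel_tiff(image: MultiChannelImage, path: str | Path) -> None:
    """Write a :class:`MultiChannelImage` as a 2-plane float32 TIFF.

    float32 keeps synthetic scenes bit-identical through a round trip.
    """
    stack = np.stack(
        [
            image.cell_channel.astype(np.float32),
            image.marker_channel.astype(np.float32),
        ]
    )
    tifffile.imwrite(Path(path), stack)


__all__.append("write_two_channel_tiff")
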