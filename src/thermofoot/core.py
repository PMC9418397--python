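"""Thermogram I/O, foot segmentation and network input encoding.

A thermogram is a per-pixel plantar temperature matrix in degrees Celsius.
Row 0 is at the toes, rows run anterior to posterior.  Columns run medial to
lateral for a right foot and are mirrored for a left foot.  Background pixels
are stored as ambient temperature values (not NaN); a :class:`FootMask`
distinguishes foot from background.
"""

from __future__ import annotations

import csv
import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.transform import resize as _sk_resize

__all__ = [
    "Side",
    "Group",
    "Thermogram",
    "FootMask",
    "EncodedInput",
    "EncodeMode",
    "ThermogramFormatError",
    "DEFAULT_WINDOW",
    "read_temperature_matrix",
    "write_temperature_matrix",
    "export_png",
    "segment_foot",
    "encode_for_network",
]

#: Default temperature normalization window in degC.  Acquisition systems use
#: different ranges; this one comfortably spans ambient room background and
#: plantar skin temperature and is configurable everywhere it is used.
DEFAULT_WINDOW: tuple[float, float] = (18.0, 40.0)

MIN_HEIGHT = 4
MIN_WIDTH = 2


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class Group(str, enum.Enum):
    CONTROL = "control"
    DIABETIC = "diabetic"


class EncodeMode(str, enum.Enum):
    RESIZED = "resized"  # interpolated to 227x227
    PADDED = "padded"  # foot bbox centered on a 227x227 zero canvas
    RECTANGULAR = "rectangular"  # interpolated to 180x80

    @property
    def target_shape(self) -> tuple[int, int]:
        if self is EncodeMode.RECTANGULAR:
            return (180, 80)
        return (227, 227)


class ThermogramFormatError(ValueError):
    """Raised for ragged or non-numeric temperature matrix files."""


@dataclass
class Thermogram:
    """One foot's temperature matrix plus subject metadata."""

    temperatures: np.ndarray
    subject_id: str = ""
    side: Side = Side.RIGHT
    group: Group = Group.DIABETIC

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        if t.ndim != 2:
            raise ValueError(f"temperature matrix must be 2-D, got ndim={t.ndim}")
        if t.shape[0] < MIN_HEIGHT or t.shape[1] < MIN_WIDTH:
            raise ValueError(
                f"matrix {t.shape} too small to partition; need at least "
                f"{MIN_HEIGHT}x{MIN_WIDTH}"
            )
        if not np.all(np.isfinite(t)):
            raise ValueError("temperature matrix contains non-finite values")
        self.temperatures = t
        self.side = Side(self.side)
        self.group = Group(self.group)

    @property
    def height(self) -> int:
        return self.temperatures.shape[0]

    @property
    def width(self) -> int:
        return self.temperatures.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.temperatures.shape


@dataclass
class FootMask:
    """Boolean matrix marking foot pixels, same shape as its thermogram."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        self.mask = m.astype(bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def any_foot(self) -> bool:
        return bool(self.mask.any())

    def bounding_box(self) -> tuple[int, int, int, int]:
        """Return (row0, row1, col0, col1), half-open, of the foot extent."""
        if not self.any_foot:
            raise ValueError("empty mask has no bounding box")
        rows = np.flatnonzero(self.mask.any(axis=1))
        cols = np.flatnonzero(self.mask.any(axis=0))
        return int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1


@dataclass
class EncodedInput:
    """Normalized intensity array in [0, 1] ready for the network."""

    values: np.ndarray
    mode: EncodeMode
    window: tuple[float, float] = DEFAULT_WINDOW
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def read_temperature_matrix(
    path: str | Path,
    *,
    delimiter: str = ",",
    subject_id: str = "",
    side: Side | str = Side.RIGHT,
    group: Group | str = Group.DIABETIC,
) -> Thermogram:
    """Parse a headerless CSV matrix of degC values into a :class:`Thermogram`.

    Raises :class:`ThermogramFormatError` naming the offending row (1-based)
    for ragged files, and the row/column for non-numeric cells.
    """
    path = Path(path)
    rows: list[list[float]] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        for i, raw in enumerate(reader, start=1):
            if not raw:
                continue
            if rows and len(raw) != len(rows[0]):
                raise ThermogramFormatError(
                    f"{path}: ragged matrix, row {i} has {len(raw)} fields, "
                    f"expected {len(rows[0])}"
                )
            parsed = []
            for j, cell in enumerate(raw, start=1):
                try:
                    parsed.append(float(cell))
                except ValueError as exc:
                    raise ThermogramFormatError(
                        f"{path}: non-numeric cell at row {i}, column {j}: {cell!r}"
                    ) from exc
            rows.append(parsed)
    if not rows:
        raise ThermogramFormatError(f"{path}: empty matrix")
    return Thermogram(
        np.array(rows, dtype=float), subject_id=subject_id, side=side, group=group
    )


def write_temperature_matrix(t: Thermogram, path: str | Path) -> Path:
    """Write the matrix as headerless CSV at full float round-trip precision."""
    path = Path(path)
    np.savetxt(path, t.temperatures, fmt="%.17g", delimiter=",")
    return path


def export_png(
    t: Thermogram, path: str | Path, *, window: tuple[float, float] = DEFAULT_WINDOW
) -> Path:
    """Export an 8-bit grayscale PNG mapping `window` to [0, 255]."""
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"window low must be < high, got {window}")
    scaled = np.clip((t.temperatures - lo) / (hi - lo), 0.0, 1.0)
    img = np.rint(scaled * 255.0).astype(np.uint8)
    path = Path(path)
    Image.fromarray(img, mode="L").save(path)
    return path


def segment_foot(t: Thermogram, ambient_ceiling: float = 22.0) -> FootMask:
    """Threshold out ambient background and keep the largest blob, holes filled.

    The foot is assumed warmer than the surroundings; pixels strictly above
    `ambient_ceiling` are candidate foot pixels.  Returns an all-false mask
    (with a warning) when nothing exceeds the ceiling.
    """
    if not np.isfinite(ambient_ceiling):
        raise ValueError("ambient_ceiling must be finite")
    raw = t.temperatures > ambient_ceiling
    if not raw.any():
        warnings.warn(
            f"no pixel above ambient ceiling {ambient_ceiling} degC; empty mask",
            stacklevel=2,
        )
        return FootMask(np.zeros(t.shape, dtype=bool))
    labels, n = ndimage.label(raw)
    if n > 1:
        sizes = ndimage.sum_labels(raw, labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        raw = labels == keep
    filled = ndimage.binary_fill_holes(raw)
    return FootMask(filled)


def _normalize(temps: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"window low must be < high, got {window}")
    return np.clip((temps - lo) / (hi - lo), 0.0, 1.0)


def _interp(values: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if values.shape == shape:
        return values.copy()
    out = _sk_resize(
        values, shape, order=1, anti_aliasing=False, preserve_range=True, mode="edge"
    )
    return np.clip(out, 0.0, 1.0)


def encode_for_network(
    t: Thermogram,
    mask: FootMask | None = None,
    mode: EncodeMode | str = EncodeMode.RECTANGULAR,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> EncodedInput:
    """Clip to `window`, map affinely to [0, 1] and shape for the network.

    resized
        whole image bilinearly interpolated to 227x227.
    padded
        the foot bounding box is placed, centered and at native scale, on a
        227x227 canvas of pad value 0 (coldest); boxes that exceed the canvas
        are downscaled to fit with a warning.
    rectangular
        whole image bilinearly interpolated to 180x80.

    Background pixels (mask false) are forced to intensity 0 so the pad value
    and the ambient background look alike.
    """
    mode = EncodeMode(mode)
    norm = _normalize(t.temperatures, window)
    if mask is not None:
        if mask.shape != t.shape:
            raise ValueError(f"mask shape {mask.shape} != thermogram shape {t.shape}")
        norm = np.where(mask.mask, norm, 0.0)

    meta: dict = {"source_shape": t.shape}
    if mode is EncodeMode.PADDED:
        target = mode.target_shape
        if mask is not None and mask.any_foot:
            r0, r1, c0, c1 = mask.bounding_box()
        else:
            r0, r1, c0, c1 = 0, t.height, 0, t.width
        block = norm[r0:r1, c0:c1]
        bh, bw = block.shape
        if bh > target[0] or bw > target[1]:
            scale = min(target[0] / bh, target[1] / bw)
            new_shape = (max(1, int(bh * scale)), max(1, int(bw * scale)))
            warnings.warn(
                f"foot bounding box {bh}x{bw} exceeds padded canvas {target}; "
                f"downscaled to {new_shape}",
                stacklevel=2,
            )
            block = _interp(block, new_shape)
            bh, bw = block.shape
        canvas = np.zeros(target, dtype=float)
        top = (target[0] - bh) // 2
        left = (target[1] - bw) // 2
        canvas[top : top + bh, left : left + bw] = block
        meta["placement"] = (top, left, bh, bw)
        values = canvas
    else:
        values = _interp(norm, mode.target_shape)

    return EncodedInput(values=values.astype(np.float64), mode=mode, window=window, meta=meta)
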