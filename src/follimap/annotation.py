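"""Annotation-image I/O and mark extraction.

A *clean annotation image* encodes one skin section with one colour per
mark class: green dots for primary hair follicles, blue dots for
secondary hair follicles, white blocks for hair-follicle-group (HFG)
regions and black for interstitial tissue.  This module recovers the
follicle centroids and the labelled HFG mask from such an image, and
round-trips both through plain-text/PNG artifacts.

Coordinate convention: continuous millimetres, origin at the top-left
corner of the section, x increasing rightward, y increasing downward.
Pixel ``(row, col)`` covers the square
``[col*s, (col+1)*s) x [row*s, (row+1)*s)`` for scale ``s`` in mm/pixel,
so the pixel centre sits at ``((col+0.5)*s, (row+0.5)*s)``.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field, replace
from functools import cached_property
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, PngImagePlugin
from skimage import measure

from .errors import PointTableFormatError

PRIMARY = "P"
SECONDARY = "S"

#: PNG text-chunk key used to persist the physical scale of a label mask.
_SCALE_KEY = "follimap:mm_per_pixel"


@dataclass(frozen=True)
class Palette:
    """RGB colours of the four annotation classes."""

    primary: tuple[int, int, int] = (0, 255, 0)
    secondary: tuple[int, int, int] = (0, 0, 255)
    hfg: tuple[int, int, int] = (255, 255, 255)
    background: tuple[int, int, int] = (0, 0, 0)

    def colors(self) -> dict[str, tuple[int, int, int]]:
        return {
            "primary": self.primary,
            "secondary": self.secondary,
            "hfg": self.hfg,
            "background": self.background,
        }


DEFAULT_PALETTE = Palette()


@dataclass(frozen=True)
class ExtractionQC:
    """Quality-control counters from a dot-extraction pass."""

    dropped_small: int = 0
    unknown_color_px: int = 0


@dataclass
class FolliclePointSet:
    """Marked follicle centroids of one section, in millimetres.

    ``cls`` holds ``"P"`` (primary) or ``"S"`` (secondary); ``group_id``
    is the HFG label a point belongs to, or ``-1`` when unknown (e.g.
    points recovered from an image before mask assignment).
    """

    x: np.ndarray
    y: np.ndarray
    cls: np.ndarray
    group_id: np.ndarray
    width_mm: float
    height_mm: float
    qc: ExtractionQC | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.cls = np.asarray(self.cls, dtype="<U1")
        self.group_id = np.asarray(self.group_id, dtype=np.int64)
        n = self.x.size
        if not (self.y.size == self.cls.size == self.group_id.size == n):
            raise ValueError("point arrays must have equal length")
        if n:
            bad = set(np.unique(self.cls)) - {PRIMARY, SECONDARY}
            if bad:
                raise ValueError(f"unknown follicle classes: {sorted(bad)}")
            if (
                self.x.min() < 0
                or self.y.min() < 0
                or self.x.max() > self.width_mm
                or self.y.max() > self.height_mm
            ):
                raise ValueError("point coordinates fall outside section bounds")

    def __len__(self) -> int:
        return int(self.x.size)

    @property
    def n_primary(self) -> int:
        return int(np.count_nonzero(self.cls == PRIMARY))

    @property
    def n_secondary(self) -> int:
        return int(np.count_nonzero(self.cls == SECONDARY))

    def subset(self, mask: np.ndarray) -> "FolliclePointSet":
        return replace(
            self,
            x=self.x[mask],
            y=self.y[mask],
            cls=self.cls[mask],
            group_id=self.group_id[mask],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_mm": self.x,
                "y_mm": self.y,
                "class": self.cls,
                "group_id": self.group_id,
            }
        )


@dataclass
class HFGMask:
    """Labelled hair-follicle-group raster.

    ``labels[r, c]`` is 0 for interstitial tissue and ``k > 0`` for
    pixels of group ``k``.  Areas are in mm² via ``mm_per_pixel``.
    """

    labels: np.ndarray
    mm_per_pixel: float

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int32)
        if self.labels.ndim != 2:
            raise ValueError("mask labels must be a 2-D array")
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def width_mm(self) -> float:
        return self.labels.shape[1] * self.mm_per_pixel

    @property
    def height_mm(self) -> float:
        return self.labels.shape[0] * self.mm_per_pixel

    @property
    def total_area(self) -> float:
        """Section area in mm² (all pixels)."""
        return self.labels.size * self.mm_per_pixel**2

    @cached_property
    def group_areas(self) -> dict[int, float]:
        counts = np.bincount(self.labels.ravel())
        px_area = self.mm_per_pixel**2
        return {
            int(g): float(counts[g] * px_area)
            for g in range(1, counts.size)
            if counts[g] > 0
        }

    @property
    def group_ids(self) -> list[int]:
        return sorted(self.group_areas)

    @property
    def n_groups(self) -> int:
        return len(self.group_areas)

    @property
    def hfg_area(self) -> float:
        """Total HFG-occupied area in mm²."""
        return float(sum(self.group_areas.values()))

    @property
    def coverage(self) -> float:
        """Area fraction occupied by HFG regions (Ratio-HFG of the mask)."""
        return self.hfg_area / self.total_area

    def label_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Group label under each (x, y) mm coordinate (0 = outside)."""
        h, w = self.labels.shape
        col = np.clip((np.asarray(x) / self.mm_per_pixel).astype(int), 0, w - 1)
        row = np.clip((np.asarray(y) / self.mm_per_pixel).astype(int), 0, h - 1)
        return self.labels[row, col]


def _color_mask(image: np.ndarray, color, tolerance: int) -> np.ndarray:
    img = image.astype(np.int32)
    c = np.asarray(color, dtype=np.int32)
    if tolerance <= 0:
        return np.all(img == c, axis=-1)
    return np.all(np.abs(img - c) <= tolerance, axis=-1)


def _check_unknown(image, palette: Palette, tolerance: int, warn_px: int) -> int:
    known = np.zeros(image.shape[:2], dtype=bool)
    for color in palette.colors().values():
        known |= _color_mask(image, color, tolerance)
    n_unknown = int(np.count_nonzero(~known))
    if n_unknown > warn_px:
        warnings.warn(
            f"{n_unknown} pixels match no palette colour; the image may not "
            "be a clean annotation or may need a colour tolerance",
            stacklevel=3,
        )
    return n_unknown


def extract_dots(
    image: np.ndarray,
    mm_per_pixel: float,
    palette: Palette = DEFAULT_PALETTE,
    *,
    min_component_px: int = 3,
    color_tolerance: int = 0,
    unknown_color_warn_px: int = 50,
) -> FolliclePointSet:
    """Recover follicle centroids from a clean annotation image.

    Each 8-connected component of the primary (resp. secondary) colour
    becomes one point at its pixel centroid, converted to mm.
    Components smaller than ``min_component_px`` are dropped and counted
    in the returned set's ``qc``.  An all-background image yields an
    empty point set.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError("expected an RGB image array (H, W, 3)")
    n_unknown = _check_unknown(image, palette, color_tolerance, unknown_color_warn_px)

    xs, ys, cls = [], [], []
    dropped = 0
    for klass, color in ((PRIMARY, palette.primary), (SECONDARY, palette.secondary)):
        mask = _color_mask(image, color, color_tolerance)
        labels = measure.label(mask, connectivity=2)
        for prop in measure.regionprops(labels):
            if prop.num_pixels < min_component_px:
                dropped += 1
                continue
            r, c = prop.centroid
            xs.append((c + 0.5) * mm_per_pixel)
            ys.append((r + 0.5) * mm_per_pixel)
            cls.append(klass)

    h, w = image.shape[:2]
    return FolliclePointSet(
        x=np.array(xs, dtype=float),
        y=np.array(ys, dtype=float),
        cls=np.array(cls, dtype="<U1"),
        group_id=np.full(len(xs), -1, dtype=np.int64),
        width_mm=w * mm_per_pixel,
        height_mm=h * mm_per_pixel,
        qc=ExtractionQC(dropped_small=dropped, unknown_color_px=n_unknown),
    )


def extract_mask(
    image: np.ndarray,
    mm_per_pixel: float,
    palette: Palette = DEFAULT_PALETTE,
    *,
    color_tolerance: int = 0,
) -> HFGMask:
    """Recover the labelled HFG mask from a clean annotation image.

    4-connected components of the block colour become labelled groups.
    Because follicle dots are drawn on top of the blocks, dot-coloured
    pixels connected to a block are counted as block area; dot
    components with no block pixel (a follicle drawn on background) are
    not groups.
    """
    image = np.asarray(image)
    block = _color_mask(image, palette.hfg, color_tolerance)
    dots = _color_mask(image, palette.primary, color_tolerance) | _color_mask(
        image, palette.secondary, color_tolerance
    )
    candidate = block | dots
    labels = measure.label(candidate, connectivity=1)
    # keep only components containing at least one true block pixel
    keep = np.unique(labels[block])
    keep = keep[keep > 0]
    lut = np.zeros(labels.max() + 1, dtype=np.int32)
    lut[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
    return HFGMask(labels=lut[labels], mm_per_pixel=mm_per_pixel)


# ---------------------------------------------------------------------------
# plain-text / PNG round-trip I/O

_POINT_COLUMNS = ["x_mm", "y_mm", "class", "group_id"]


def write_points_csv(points: FolliclePointSet, path: str | Path) -> None:
    """Write a point table: a `# section:` header line then CSV columns
    ``x_mm,y_mm,class,group_id`` (group_id blank when unknown)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(
            f"# section: width_mm={points.width_mm!r} height_mm={points.height_mm!r}\n"
        )
        writer = csv.writer(fh)
        writer.writerow(_POINT_COLUMNS)
        for x, y, k, g in zip(points.x, points.y, points.cls, points.group_id):
            writer.writerow([repr(float(x)), repr(float(y)), k, "" if g < 0 else int(g)])


def read_points_csv(
    path: str | Path,
    *,
    width_mm: float | None = None,
    height_mm: float | None = None,
) -> FolliclePointSet:
    """Read a point table written by :func:`write_points_csv`.

    Section bounds come from the ``# section:`` header line unless
    overridden.  Malformed rows raise :class:`PointTableFormatError`
    naming the 1-based line number.
    """
    path = Path(path)
    xs: list[float] = []
    ys: list[float] = []
    cls: list[str] = []
    gids: list[int] = []
    with path.open(newline="") as fh:
        lines = fh.read().splitlines()
    lineno = 0
    header_seen = False
    for raw in lines:
        lineno += 1
        if not raw.strip():
            continue
        if raw.startswith("#"):
            if raw.lstrip("# ").startswith("section:"):
                for tok in raw.split("section:", 1)[1].split():
                    key, _, val = tok.partition("=")
                    if key == "width_mm" and width_mm is None:
                        width_mm = float(val)
                    elif key == "height_mm" and height_mm is None:
                        height_mm = float(val)
            continue
        row = next(csv.reader(io.StringIO(raw)))
        if not header_seen:
            if [c.strip() for c in row] != _POINT_COLUMNS:
                raise PointTableFormatError(
                    f"expected header {_POINT_COLUMNS}, got {row}", line=lineno
                )
            header_seen = True
            continue
        if len(row) != 4:
            raise PointTableFormatError(f"expected 4 fields, got {len(row)}", lineno)
        try:
            xs.append(float(row[0]))
            ys.append(float(row[1]))
        except ValueError as exc:
            raise PointTableFormatError(str(exc), lineno) from None
        if row[2] not in (PRIMARY, SECONDARY):
            raise PointTableFormatError(
                f"class must be {PRIMARY!r} or {SECONDARY!r}, got {row[2]!r}", lineno
            )
        cls.append(row[2])
        gids.append(int(row[3]) if row[3].strip() else -1)
    if not header_seen:
        raise PointTableFormatError("missing column header row")
    if width_mm is None or height_mm is None:
        raise PointTableFormatError(
            "section bounds not found in header; pass width_mm/height_mm"
        )
    return FolliclePointSet(
        x=np.array(xs),
        y=np.array(ys),
        cls=np.array(cls, dtype="<U1"),
        group_id=np.array(gids, dtype=np.int64),
        width_mm=width_mm,
        height_mm=height_mm,
    )


def write_mask_png(mask: HFGMask, path: str | Path) -> None:
    """Write the label raster as a 16-bit greyscale PNG; the physical
    scale is stored in a PNG text chunk for lossless round trip."""
    if mask.labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many groups for a 16-bit label PNG")
    if mask.labels.min() < 0:
        raise ValueError("negative labels cannot be serialised")
    img = Image.fromarray(mask.labels.astype(np.uint16))
    info = PngImagePlugin.PngInfo()
    info.add_text(_SCALE_KEY, repr(float(mask.mm_per_pixel)))
    img.save(Path(path), format="PNG", pnginfo=info)


def read_mask_png(path: str | Path, mm_per_pixel: float | None = None) -> HFGMask:
    """Read a label mask written by :func:`write_mask_png`."""
    img = Image.open(Path(path))
    if mm_per_pixel is None:
        text = getattr(img, "text", {})
        if _SCALE_KEY not in text:
            raise ValueError(
                "mask PNG carries no scale metadata; pass mm_per_pixel explicitly"
            )
        mm_per_pixel = float(text[_SCALE_KEY])
    return HFGMask(labels=np.asarray(img, dtype=np.int32), mm_per_pixel=mm_per_pixel)


def save_annotation_png(image: np.ndarray, path: str | Path) -> None:
    """Write a rendered RGB annotation image."""
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(Path(path), format="PNG")


def load_annotation_png(path: str | Path) -> np.ndarray:
    """Read an RGB annotation image as a (H, W, 3) uint8 array."""
    return np.asarray(Image.open(Path(path)).convert("RGB"))
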