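"""Data model and I/O for retinal mosaic maps.

A retinal mosaic map records, for one dissected *Drosophila* retina, the
type of every ommatidium on a hexagonal grid together with its pixel
centroid on a standardised canvas (1400 x 1400 px by default).  Four
ommatidium types are distinguished:

``P_OC``
    pale and odd-coupled ommatidia combined (Rh3 in R7),
``Y``
    yellow ommatidia, including dorsal-yellow scored conservatively as
    yellow (Rh4 in R7),
``DRA``
    dorsal rim area ommatidia (Rh3 in both R7 and R8),
``UNKNOWN``
    ommatidia that could not be assigned.

Hex coordinates follow the *odd-row offset* ("odd-r") convention: rows are
horizontal, odd rows are shifted half a column to the right in pixel space.
``col`` increases anterior to posterior, ``row`` increases ventral to
dorsal (row 0 at the ventral rim).  The equator -- the mirror line between
the dorsal and ventral ommatidial fields -- is stored as a non-integer row
coordinate lying strictly between two rows, and the centre-most
dorso-ventral column is stored as an integer column index.  Both are used
by the region-partition tests.

On disk a map is a UTF-8 TSV (columns ``id col row x y type``) plus a JSON
sidecar carrying the canvas size, equator row, midline column and specimen
metadata.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Point, Polygon

P_OC = "P_OC"
Y = "Y"
DRA = "DRA"
UNKNOWN = "UNKNOWN"
#: The four admissible ommatidium type tokens, in canonical order.
TYPES = (P_OC, Y, DRA, UNKNOWN)

TSV_COLUMNS = ("id", "col", "row", "x", "y", "type")


class MosaicFormatError(ValueError):
    """A mosaic file does not conform to the TSV+JSON format."""


class MosaicValidationError(ValueError):
    """A mosaic map violates a structural invariant."""


class GeometryError(ValueError):
    """A geometric construction is degenerate (too few / collinear points)."""


class UndefinedValueError(ValueError):
    """A requested statistic has an empty denominator."""


@dataclass(frozen=True)
class OmmatidiumRecord:
    """One scored ommatidium: hex-grid position, pixel centroid and type."""

    id: int
    col: int
    row: int
    x: float
    y: float
    type: str

    def __post_init__(self) -> None:
        if self.type not in TYPES:
            raise MosaicValidationError(
                f"unknown ommatidium type {self.type!r}; expected one of {TYPES}"
            )


@dataclass
class RetinalMosaicMap:
    """A whole-retina ommatidium-type map with equator and midline annotations.

    Parameters
    ----------
    ommatidia
        The scored ommatidia.  ``(col, row)`` must be unique.
    canvas
        ``(width, height)`` of the standardised pixel canvas.
    equator_boundary
        Real-valued row coordinate of the equator.  Must be non-integer:
        the equator is a mirror line *between* ommatidial rows, so no
        ommatidium can sit on it.
    midline_col
        Integer column index of the centre-most dorso-ventral row.
    metadata
        Free-form specimen metadata; conventionally ``species``, ``strain``,
        ``sex`` ("F"/"M") and ``retina_id``.
    pixel_pitch
        Horizontal centre-to-centre distance of the hex lattice in pixels
        (stored so pixel positions can be regenerated from grid positions).
    """

    ommatidia: list[OmmatidiumRecord]
    equator_boundary: float
    midline_col: int
    canvas: tuple[float, float] = (1400.0, 1400.0)
    metadata: dict = field(default_factory=dict)
    pixel_pitch: float | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.ommatidia) < 1:
            raise MosaicValidationError("a mosaic map needs at least one ommatidium")
        seen: set[tuple[int, int]] = set()
        w, h = self.canvas
        for rec in self.ommatidia:
            key = (rec.col, rec.row)
            if key in seen:
                raise MosaicValidationError(f"duplicate hex position (col,row)={key}")
            seen.add(key)
            if not (0 <= rec.x <= w and 0 <= rec.y <= h):
                raise MosaicValidationError(
                    f"ommatidium {rec.id}: centroid ({rec.x},{rec.y}) outside canvas {self.canvas}"
                )
        if float(self.equator_boundary) == int(self.equator_boundary):
            raise MosaicValidationError(
                "equator_boundary must lie strictly between two integer rows "
                f"(got {self.equator_boundary})"
            )

    # -- convenience views ------------------------------------------------
    def __len__(self) -> int:
        return len(self.ommatidia)

    def types(self) -> np.ndarray:
        return np.array([o.type for o in self.ommatidia])

    def grid_positions(self) -> np.ndarray:
        return np.array([(o.col, o.row) for o in self.ommatidia], dtype=int)

    def centroids(self) -> np.ndarray:
        return np.array([(o.x, o.y) for o in self.ommatidia], dtype=float)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RetinalMosaicMap):
            return NotImplemented
        return (
            self.ommatidia == other.ommatidia
            and self.canvas == other.canvas
            and self.equator_boundary == other.equator_boundary
            and self.midline_col == other.midline_col
            and self.metadata == other.metadata
        )


@dataclass
class MarkedPointPattern:
    """Pixel centroids with type marks inside a convex observation window."""

    points: np.ndarray  # (n, 2) float
    marks: np.ndarray  # (n,) str
    window: Polygon

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.marks = np.asarray(self.marks)
        if len(self.points) != len(self.marks):
            raise MosaicValidationError("points and marks differ in length")

    def __len__(self) -> int:
        return len(self.points)

    def subset(self, type_filter: str | Sequence[str]) -> "MarkedPointPattern":
        """Restrict to one or more mark types, keeping the window."""
        if isinstance(type_filter, str):
            type_filter = (type_filter,)
        keep = np.isin(self.marks, list(type_filter))
        return MarkedPointPattern(self.points[keep], self.marks[keep], self.window)


@dataclass(frozen=True)
class TypeCounts:
    """Ommatidium tallies per type for a single retina."""

    n_p_oc: int
    n_y: int
    n_dra: int
    n_unknown: int

    @property
    def n_total(self) -> int:
        return self.n_p_oc + self.n_y + self.n_dra + self.n_unknown


def sidecar_path(path: str | Path) -> Path:
    """JSON sidecar path for a mosaic TSV (``foo.tsv`` -> ``foo.json``)."""
    return Path(path).with_suffix(".json")


def read_mosaic_map(path: str | Path) -> RetinalMosaicMap:
    """Read a retinal mosaic map from a TSV file + JSON sidecar.

    Raises
    ------
    MosaicFormatError
        Missing columns or an unparseable sidecar.
    MosaicValidationError
        Duplicate hex positions, bad type tokens, integer equator.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error paths
        raise MosaicFormatError(f"cannot parse mosaic TSV {path}: {exc}") from exc
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise MosaicFormatError(f"{path}: missing required column(s) {missing}")
    side = sidecar_path(path)
    if not side.exists():
        raise MosaicFormatError(f"missing JSON sidecar {side}")
    meta = json.loads(side.read_text())
    for key in ("canvas", "equator_boundary", "midline_col"):
        if key not in meta:
            raise MosaicFormatError(f"{side}: missing sidecar key {key!r}")
    recs = [
        OmmatidiumRecord(
            id=int(r.id), col=int(r.col), row=int(r.row),
            x=float(r.x), y=float(r.y), type=str(r.type),
        )
        for r in df.itertuples(index=False)
    ]
    extra = {
        k: v
        for k, v in meta.items()
        if k not in ("canvas", "equator_boundary", "midline_col", "pixel_pitch")
    }
    return RetinalMosaicMap(
        ommatidia=recs,
        canvas=tuple(meta["canvas"]),
        equator_boundary=float(meta["equator_boundary"]),
        midline_col=int(meta["midline_col"]),
        metadata=extra,
        pixel_pitch=meta.get("pixel_pitch"),
    )


def write_mosaic_map(mosaic: RetinalMosaicMap, path: str | Path) -> Path:
    """Write a map as TSV + JSON sidecar; round-trips through read_mosaic_map.

    x,y are serialised to 3 decimals, which is loss-free for maps produced
    by the synthetic generator and far below one pixel.
    """
    path = Path(path)
    df = pd.DataFrame(
        {
            "id": [o.id for o in mosaic.ommatidia],
            "col": [o.col for o in mosaic.ommatidia],
            "row": [o.row for o in mosaic.ommatidia],
            "x": [round(o.x, 3) for o in mosaic.ommatidia],
            "y": [round(o.y, 3) for o in mosaic.ommatidia],
            "type": [o.type for o in mosaic.ommatidia],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    meta = {
        "canvas": list(mosaic.canvas),
        "equator_boundary": mosaic.equator_boundary,
        "midline_col": mosaic.midline_col,
    }
    if mosaic.pixel_pitch is not None:
        meta["pixel_pitch"] = mosaic.pixel_pitch
    meta.update(mosaic.metadata)
    sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def to_point_pattern(mosaic: RetinalMosaicMap) -> MarkedPointPattern:
    """Convert a map to a marked point pattern in its convex-hull window.

    Raises :class:`GeometryError` for fewer than 3 or collinear centroids.
    """
    pts = mosaic.centroids()
    if len(pts) < 3:
        raise GeometryError("need at least 3 ommatidia to build a convex window")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise GeometryError(f"degenerate (collinear?) centroids: {exc}") from exc
    window = Polygon(pts[hull.vertices])
    return MarkedPointPattern(points=pts, marks=mosaic.types(), window=window)


def count_types(mosaic: RetinalMosaicMap) -> TypeCounts:
    """Exact per-type tallies of a map."""
    t = mosaic.types()
    return TypeCounts(
        n_p_oc=int(np.sum(t == P_OC)),
        n_y=int(np.sum(t == Y)),
        n_dra=int(np.sum(t == DRA)),
        n_unknown=int(np.sum(t == UNKNOWN)),
    )


def percent_p_oc(counts: TypeCounts) -> float:
    """Percentage of p+OC ommatidia relative to p+OC and y combined.

    DRA and UNKNOWN ommatidia are excluded from the denominator: the
    headline frequency statistic is taken relative to the total of
    non-DRA, typed ommatidia.
    """
    denom = counts.n_p_oc + counts.n_y
    if denom == 0:
        raise UndefinedValueError("no p+OC or y ommatidia: percentage undefined")
    return 100.0 * counts.n_p_oc / denom


def percent_y(counts: TypeCounts) -> float:
    """Complement of :func:`percent_p_oc`; the two sum to exactly 100."""
    denom = counts.n_p_oc + counts.n_y
    if denom == 0:
        raise UndefinedValueError("no p+OC or y ommatidia: percentage undefined")
    return 100.0 * counts.n_y / denom


def hex_to_pixels(
    col: np.ndarray,
    row: np.ndarray,
    pitch: float,
    origin: tuple[float, float] = (0.0, 0.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Map odd-r offset hex coordinates to pixel centres.

    Odd rows are shifted +pitch/2 in x; row spacing is ``pitch * sqrt(3)/2``.
    """
    col = np.asarray(col)
    row = np.asarray(row)
    x = origin[0] + pitch * (col + 0.5 * (row % 2))
    y = origin[1] + pitch * (math.sqrt(3.0) / 2.0) * row
    return x, y
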