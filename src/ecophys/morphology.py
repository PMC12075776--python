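"""Capsule (spherocylinder) morphometrics from segmented-cell measurements.

Scanning-electron micrographs of small pleomorphic cells are measured by
hand: the cell outline is segmented to a projected area S (pixel^2) and the
cell width is probed with circles at several sections, each recorded as a
radius r (pixels). The cell body is modelled as a capsule — a cylinder of
height h capped by two hemispheres of radius r — whose 2-D projection is a
stadium of area

    S = 2 r (l - 2 r) + pi r^2,      l = total length, h = l - 2 r.

Inverting the stadium area gives the length for each measured radius, and
the closed capsule formulas give the corresponding volume and surface area:

    V  = pi r^2 h + (4/3) pi r^3
    SA = 2 pi r h + 4 pi r^2

Radii measured at local bulges can exceed what the area allows
(S < pi r^2); such radii are flagged invalid and excluded from the per-cell
summaries rather than failing the cell. Curvature of bent rods is ignored:
a curved tube of the same axis length has the same volume, and no curvature
parameter is recoverable from (S, r) alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import AllRadiiInvalidError, EmptyInputError, RadiusAreaError

__all__ = [
    "CellMeasurement",
    "RadiusRecord",
    "CellGeometry",
    "PopulationMorphology",
    "stadium_area",
    "length_from_area",
    "capsule_volume",
    "capsule_surface_area",
    "per_cell_geometry",
    "population_summary",
]

PARAMETERS = ("radius", "length", "height", "surface_area", "volume")


@dataclass(frozen=True)
class CellMeasurement:
    """Raw per-cell measurements in pixel units plus the image scale."""

    cell_id: str
    area_px2: float
    radii_px: tuple[float, ...]
    scale_um_per_px: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "radii_px", tuple(float(r) for r in self.radii_px))
        if self.area_px2 <= 0:
            raise ValueError("segmented area must be > 0")
        if len(self.radii_px) < 1:
            raise ValueError("need at least one measured radius")
        if any(r <= 0 for r in self.radii_px):
            raise ValueError("radii must be > 0")
        if self.scale_um_per_px <= 0:
            raise ValueError("scale must be > 0")


@dataclass(frozen=True)
class RadiusRecord:
    """Geometry derived from one measured radius (um units)."""

    radius: float
    length: float
    height: float
    surface_area: float
    volume: float
    valid: bool


@dataclass(frozen=True)
class CellGeometry:
    """Per-radius geometry records and cell-level mean/median summaries."""

    cell_id: str
    records: tuple[RadiusRecord, ...]
    mean: dict[str, float]
    median: dict[str, float]

    def representative(self, which: Literal["mean", "median"] = "median") -> dict[str, float]:
        return self.median if which == "median" else self.mean


@dataclass(frozen=True)
class PopulationMorphology:
    """Population-level distributions of per-cell representative values."""

    per_cell: pd.DataFrame  # one row per cell, one column per parameter
    summary: pd.DataFrame  # mean/median/sd per parameter
    representative: str

    def to_long(self) -> pd.DataFrame:
        """Violin-plot-ready long format: cell_id, parameter, value."""
        return self.per_cell.reset_index().melt(
            id_vars="cell_id", var_name="parameter", value_name="value"
        )


def stadium_area(l: float, r: float) -> float:
    """Projected area of a capsule of length l and radius r (forward model)."""
    if r <= 0 or l < 2 * r:
        raise ValueError("need l >= 2r > 0")
    return 2.0 * r * (l - 2.0 * r) + math.pi * r * r


def length_from_area(S: float, r: float) -> float:
    """Invert the stadium projection: total length from area and radius.

    Raises :class:`RadiusAreaError` when S < pi r^2, i.e. the projection is
    smaller than a circle of the measured radius.
    """
    if r <= 0:
        raise ValueError("radius must be > 0")
    if S < math.pi * r * r:
        raise RadiusAreaError(
            f"area {S:g} is below pi*r^2 = {math.pi * r * r:g}; "
            "radius inconsistent with segmented area"
        )
    return (S - math.pi * r * r) / (2.0 * r) + 2.0 * r


def capsule_volume(l: float, r: float) -> float:
    """Volume of a capsule: cylinder of height l - 2r plus two hemispheres."""
    if r <= 0 or l < 2 * r:
        raise ValueError("need l >= 2r > 0")
    h = l - 2.0 * r
    return math.pi * r * r * h + (4.0 / 3.0) * math.pi * r**3


def capsule_surface_area(l: float, r: float) -> float:
    """Surface area of a capsule: open cylinder plus a full sphere."""
    if r <= 0 or l < 2 * r:
        raise ValueError("need l >= 2r > 0")
    h = l - 2.0 * r
    return 2.0 * math.pi * r * h + 4.0 * math.pi * r * r


def per_cell_geometry(m: CellMeasurement) -> CellGeometry:
    """Convert one cell's (S, radii) to per-radius capsule geometry in um.

    Each radius is combined with the cell's single segmented area; radii
    with S < pi r^2 are kept in the record list but flagged invalid and
    excluded from the mean/median summaries. Raises
    :class:`AllRadiiInvalidError` when no radius is consistent with the area.
    """
    scale = m.scale_um_per_px
    S = m.area_px2 * scale * scale
    records: list[RadiusRecord] = []
    for r_px in m.radii_px:
        r = r_px * scale
        try:
            l = length_from_area(S, r)
        except RadiusAreaError:
            records.append(
                RadiusRecord(
                    radius=r,
                    length=float("nan"),
                    height=float("nan"),
                    surface_area=float("nan"),
                    volume=float("nan"),
                    valid=False,
                )
            )
            continue
        records.append(
            RadiusRecord(
                radius=r,
                length=l,
                height=l - 2.0 * r,
                surface_area=capsule_surface_area(l, r),
                volume=capsule_volume(l, r),
                valid=True,
            )
        )
    valid = [rec for rec in records if rec.valid]
    if not valid:
        raise AllRadiiInvalidError(
            f"cell {m.cell_id}: every radius violates S >= pi*r^2"
        )
    arrays = {
        "radius": np.array([rec.radius for rec in valid]),
        "length": np.array([rec.length for rec in valid]),
        "height": np.array([rec.height for rec in valid]),
        "surface_area": np.array([rec.surface_area for rec in valid]),
        "volume": np.array([rec.volume for rec in valid]),
    }
    return CellGeometry(
        cell_id=m.cell_id,
        records=tuple(records),
        mean={k: float(v.mean()) for k, v in arrays.items()},
        median={k: float(np.median(v)) for k, v in arrays.items()},
    )


def population_summary(
    cells: Sequence[CellGeometry],
    representative: Literal["mean", "median"] = "median",
) -> PopulationMorphology:
    """Aggregate per-cell representative values into population statistics."""
    if len(cells) == 0:
        raise EmptyInputError("no cells to summarize")
    if representative not in ("mean", "median"):
        raise ValueError("representative must be 'mean' or 'median'")
    per_cell = pd.DataFrame(
        [c.representative(representative) for c in cells],
        index=pd.Index([c.cell_id for c in cells], name="cell_id"),
    )[list(PARAMETERS)]
    summary = pd.DataFrame(
        {
            "mean": per_cell.mean(),
            "median": per_cell.median(),
            "sd": per_cell.std(ddof=1).fillna(0.0),
        }
    )
    return PopulationMorphology(
        per_cell=per_cell, summary=summary, representative=representative
    )
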