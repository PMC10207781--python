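"""Tumor growth kinetics.

Converts between tumor diameter and accumulated cell count under a
spherical-volume model with constant cell-packing density, grows tumors
exponentially with a fixed volume-doubling time, and locates the two sizes
that bracket the usefulness of mammographic screening:

* the *detection threshold* Td — the smallest mammographically visible
  tumor, about 3 mm in diameter (~1e7 cells);
* the *palpability threshold* Tp — the size at which a tumor becomes
  self-detectable, 25–30 mm (~1e10 cells), beyond which screening no
  longer delivers early diagnosis.

The time a tumor spends growing from Td to Tp (the *sojourn window*,
about 4.6 years at the default doubling time) is the upper bound a
screening interval must stay below to be useful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "DEFAULT_CELL_DENSITY_PER_CM3",
    "DEFAULT_DOUBLING_TIME_DAYS",
    "DAYS_PER_YEAR",
    "DAYS_PER_MONTH",
    "GrowthModel",
    "TumorState",
    "Thresholds",
    "cells_from_diameter",
    "diameter_from_cells",
    "grow",
    "advance_cells",
    "sojourn_time_days",
    "sojourn_time_years",
]

#: Cell-packing density (cells per cm^3) — the standard oncology convention
#: that makes a 1 cm^3 tumor hold ~1e9 cells.  With a spherical tumor this
#: places ~1.4e7 cells at 3 mm and ~1.4e10 cells at 30 mm, consistent with
#: the detection and palpability anchors above.
DEFAULT_CELL_DENSITY_PER_CM3 = 1.0e9

#: Volume-doubling time in days, calibrated so that growing from the
#: detection threshold (1e7 cells) to the palpability threshold (1e10
#: cells) takes about 4.6 years.
DEFAULT_DOUBLING_TIME_DAYS = 168.5

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = DAYS_PER_YEAR / 12.0

_SPHERE_FACTOR = math.pi / 6.0  # volume of a sphere of diameter d is (pi/6) d^3


def cells_from_diameter(diameter_mm: float, density: float = DEFAULT_CELL_DENSITY_PER_CM3) -> float:
    """Number of cells in a spherical tumor of the given diameter.

    Parameters
    ----------
    diameter_mm : float
        Maximum tumor dimension in millimetres (TNM T-size convention).
    density : float
        Cell-packing density in cells per cm^3.

    Returns
    -------
    float
        Accumulated cell count N = (pi/6) * (d_cm)^3 * density.
    """
    if diameter_mm < 0:
        raise ValueError(f"diameter must be non-negative, got {diameter_mm}")
    if density <= 0:
        raise ValueError(f"density must be positive, got {density}")
    d_cm = diameter_mm / 10.0
    return _SPHERE_FACTOR * d_cm**3 * density


def diameter_from_cells(cells: float, density: float = DEFAULT_CELL_DENSITY_PER_CM3) -> float:
    """Diameter in mm of a spherical tumor holding ``cells`` cells.

    Exact inverse of :func:`cells_from_diameter` at the same density.
    """
    if cells < 0:
        raise ValueError(f"cell count must be non-negative, got {cells}")
    if density <= 0:
        raise ValueError(f"density must be positive, got {density}")
    d_cm = (cells / (_SPHERE_FACTOR * density)) ** (1.0 / 3.0)
    return d_cm * 10.0


@dataclass(frozen=True)
class GrowthModel:
    """Exponential growth with constant doubling time.

    The growth law between the detection and palpability thresholds is
    modelled as pure exponential volume growth; both parameters are
    configuration-overridable.
    """

    doubling_time_days: float = DEFAULT_DOUBLING_TIME_DAYS
    cell_density_per_cm3: float = DEFAULT_CELL_DENSITY_PER_CM3

    def __post_init__(self) -> None:
        if self.doubling_time_days <= 0:
            raise ValueError("doubling_time_days must be positive")
        if self.cell_density_per_cm3 <= 0:
            raise ValueError("cell_density_per_cm3 must be positive")


@dataclass(frozen=True)
class TumorState:
    """Tumor size expressed both as diameter and accumulated cell count."""

    diameter_mm: float
    cells: float
    time_offset_days: float = 0.0

    def __post_init__(self) -> None:
        if self.diameter_mm < 0 or self.cells < 0:
            raise ValueError("diameter and cell count must be non-negative")

    @classmethod
    def from_diameter(
        cls, diameter_mm: float, density: float = DEFAULT_CELL_DENSITY_PER_CM3
    ) -> "TumorState":
        return cls(diameter_mm=diameter_mm, cells=cells_from_diameter(diameter_mm, density))

    @classmethod
    def from_cells(
        cls, cells: float, density: float = DEFAULT_CELL_DENSITY_PER_CM3
    ) -> "TumorState":
        return cls(diameter_mm=diameter_from_cells(cells, density), cells=cells)


@dataclass(frozen=True)
class Thresholds:
    """Detection (Td) and palpability (Tp) thresholds, in cells and mm.

    The cell counts are primary; the diameters are derived from them under
    the module's density convention and must stay mutually consistent.
    """

    detection_cells: float
    detection_diameter_mm: float
    palpability_cells: float
    palpability_diameter_mm: float

    def __post_init__(self) -> None:
        if not 0 < self.detection_cells < self.palpability_cells:
            raise ValueError("need 0 < detection_cells < palpability_cells")

    @classmethod
    def from_cells(
        cls,
        detection_cells: float = 1.0e7,
        palpability_cells: float = 1.0e10,
        density: float = DEFAULT_CELL_DENSITY_PER_CM3,
    ) -> "Thresholds":
        return cls(
            detection_cells=detection_cells,
            detection_diameter_mm=diameter_from_cells(detection_cells, density),
            palpability_cells=palpability_cells,
            palpability_diameter_mm=diameter_from_cells(palpability_cells, density),
        )


def advance_cells(cells: float, elapsed_days: float, model: GrowthModel) -> float:
    """Cell count after growing (or, for negative elapsed time, rewinding)
    exponential growth for ``elapsed_days``."""
    return cells * 2.0 ** (elapsed_days / model.doubling_time_days)


def grow(state: TumorState, elapsed_days: float, model: GrowthModel) -> TumorState:
    """Advance a tumor state by ``elapsed_days`` of exponential growth.

    Cell count multiplies by ``2**(elapsed_days / doubling_time_days)``;
    the diameter is updated consistently under the model's density.
    """
    if elapsed_days < 0:
        raise ValueError(f"elapsed_days must be non-negative, got {elapsed_days}")
    new_cells = advance_cells(state.cells, elapsed_days, model)
    return replace(
        state,
        cells=new_cells,
        diameter_mm=diameter_from_cells(new_cells, model.cell_density_per_cm3),
        time_offset_days=state.time_offset_days + elapsed_days,
    )


def sojourn_time_days(thresholds: Thresholds, model: GrowthModel) -> float:
    """Growth time from the detection to the palpability threshold, in days.

    Equals ``doubling_time * log2(Tp_cells / Td_cells)``; depends only on
    the cell-count ratio, not on the packing density.
    """
    if thresholds.palpability_cells <= thresholds.detection_cells:
        raise ValueError("palpability threshold must exceed detection threshold")
    return model.doubling_time_days * math.log2(
        thresholds.palpability_cells / thresholds.detection_cells
    )


def sojourn_time_years(thresholds: Thresholds, model: GrowthModel) -> float:
    """Sojourn window in years (365.25-day years)."""
    return sojourn_time_days(thresholds, model) / DAYS_PER_YEAR
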