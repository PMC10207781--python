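"""Poisson metastasis-risk model.

Distant metastases are modelled as a Poisson seeding process: while a tumor
accumulates N(t) cells, the expected number of successful metastatic events
is mu = N(t)/P, where P is the average number of tumor cells needed to
produce one metastasis.  The probability that at least one metastasis has
formed by the time the tumor holds N cells is therefore

    pr_met(N) = 1 - exp(-N / P).

P is never observed directly; it is calibrated by least squares against
stage-specific metastasis probabilities observed under a reference
waiting-list strategy, evaluated at a representative diameter per TNM
T-band.  Shorter waiting lists are mapped to smaller sizes at diagnosis
through the exponential growth model, which yields strategy-specific
per-stage probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.stats.proportion import proportion_confint

from .kinetics import (
    DAYS_PER_MONTH,
    GrowthModel,
    Thresholds,
    advance_cells,
    cells_from_diameter,
)

__all__ = [
    "MetastasisModel",
    "StageBand",
    "CalibrationResult",
    "pr_met",
    "default_stage_bands",
    "calibrate_P",
    "stage_probabilities",
    "probability_interval",
    "read_stage_probabilities",
    "write_stage_probabilities",
]

#: Cohort size behind the observed stage probabilities; used as the default
#: effective n for the Wilson confidence intervals.
DEFAULT_N_EFFECTIVE = 242

#: Marker used in stage-probability tables for bands beyond the palpability
#: threshold, where screening no longer works as an early-diagnosis tool.
BEYOND_PALPABILITY = "beyond palpability threshold"


@dataclass(frozen=True)
class MetastasisModel:
    """Poisson seeding model with parameter P (cells per expected metastasis)."""

    P: float

    def __post_init__(self) -> None:
        if not self.P > 0:
            raise ValueError("P must be positive")

    def mu(self, cells: float) -> float:
        """Expected number of metastatic events after accumulating ``cells``."""
        return cells / self.P

    def pr_met(self, cells: float) -> float:
        return pr_met(cells, self)


def pr_met(cells: float, model: MetastasisModel) -> float:
    """Probability that a tumor of ``cells`` cells has metastasized.

    ``1 - exp(-cells / P)``: the Poisson probability of at least one
    seeding event.  Strictly increasing in ``cells``, zero at zero,
    bounded below 1 for any finite count.
    """
    if cells < 0:
        raise ValueError(f"cell count must be non-negative, got {cells}")
    return -math.expm1(-cells / model.P)


@dataclass(frozen=True)
class StageBand:
    """A TNM T-category mapped to a diameter band in millimetres."""

    label: str
    diameter_lo_mm: float
    diameter_hi_mm: float

    def __post_init__(self) -> None:
        if not 0 <= self.diameter_lo_mm < self.diameter_hi_mm:
            raise ValueError(f"invalid band {self.label}: need 0 <= lo < hi")

    @property
    def representative_diameter_mm(self) -> float:
        # Geometric midpoint: cell count scales with d^3, so the geometric
        # mean is less biased than the arithmetic mean within a band.
        return math.sqrt(self.diameter_lo_mm * self.diameter_hi_mm)

    def contains(self, diameter_mm: float) -> bool:
        return self.diameter_lo_mm <= diameter_mm < self.diameter_hi_mm


def default_stage_bands(thresholds: Thresholds | None = None) -> list[StageBand]:
    """TNM T-size bands, with T2 truncated at the palpability threshold.

    Beyond the palpability diameter the tumor is self-detectable and the
    screening model stops applying; the remainder of T2 and all of T3 are
    carried as explicit bands so tables can mark them with a sentinel.
    """
    if thresholds is None:
        thresholds = Thresholds.from_cells()
    tp = thresholds.palpability_diameter_mm
    bands = [
        StageBand("T1A", 1.0, 5.0),
        StageBand("T1B", 5.0, 10.0),
        StageBand("T1C", 10.0, 20.0),
    ]
    if tp < 50.0:
        bands.append(StageBand("T2", 20.0, tp))
        bands.append(StageBand("T2+", tp, 50.0))
    else:
        bands.append(StageBand("T2", 20.0, 50.0))
    bands.append(StageBand("T3", 50.0, 100.0))
    return bands


def validate_bands(bands: Sequence[StageBand]) -> list[str]:
    """Return one issue string per ordering violation or overlap."""
    issues: list[str] = []
    for a, b in zip(bands, bands[1:]):
        if b.diameter_lo_mm < a.diameter_hi_mm:
            issues.append(
                f"stage bands {a.label} and {b.label} overlap "
                f"({a.diameter_lo_mm}-{a.diameter_hi_mm} vs {b.diameter_lo_mm}-{b.diameter_hi_mm} mm)"
            )
    return issues


@dataclass(frozen=True)
class CalibrationResult:
    """Calibrated model plus per-stage fit residuals (model minus observed)."""

    model: MetastasisModel
    residuals: Mapping[str, float]
    rmse: float


def _band_cells(bands: Iterable[StageBand], density: float) -> dict[str, float]:
    return {
        b.label: cells_from_diameter(b.representative_diameter_mm, density) for b in bands
    }


def calibrate_P(
    observed: Mapping[str, float],
    bands: Sequence[StageBand],
    kinetics: GrowthModel,
) -> CalibrationResult:
    """Fit the seeding parameter P to observed per-stage probabilities.

    Least squares on the probability scale (the observed table contains
    exact zeros, which a log-odds objective could not hold).  A zero
    observation contributes a one-sided penalty: any positive model
    probability at that stage is penalized.  With a single informative
    pair (0 < p < 1) the closed form ``P = -N / log(1 - p)`` is used.

    Raises
    ------
    ValueError
        If every observed probability is 0 or 1 (no information about P).
    """
    cells_by_stage = _band_cells(bands, kinetics.cell_density_per_cm3)
    pairs = []
    for stage, p in observed.items():
        if stage not in cells_by_stage:
            raise KeyError(f"observed stage {stage!r} not among bands")
        if not 0 <= p <= 1:
            raise ValueError(f"probability for {stage} outside [0, 1]: {p}")
        pairs.append((stage, cells_by_stage[stage], float(p)))

    informative = [(s, n, p) for s, n, p in pairs if 0.0 < p < 1.0]
    if not informative:
        raise ValueError("calibration failure: all observed probabilities are 0 or 1")

    if len(informative) == 1:
        _, n0, p0 = informative[0]
        p_hat = -n0 / math.log1p(-p0)
    else:
        def loss(log10_p: float) -> float:
            model = MetastasisModel(P=10.0**log10_p)
            return sum((model.pr_met(n) - p) ** 2 for _, n, p in pairs if p < 1.0)

        counts = [n for _, n, p in informative]
        lo = math.log10(min(counts)) - 4.0
        hi = math.log10(max(counts)) + 4.0
        res = optimize.minimize_scalar(
            loss, bounds=(lo, hi), method="bounded", options={"xatol": 1e-12}
        )
        p_hat = 10.0**res.x

    model = MetastasisModel(P=p_hat)
    residuals = {s: model.pr_met(n) - p for s, n, p in pairs}
    rmse = math.sqrt(sum(r * r for r in residuals.values()) / len(residuals))
    return CalibrationResult(model=model, residuals=residuals, rmse=rmse)


def probability_interval(
    point: float, n_effective: float, method: str = "wilson"
) -> tuple[float, float]:
    """95% confidence interval for a proportion at an effective sample size.

    Wilson score interval by default; the interval always contains the
    point estimate and shrinks as ``n_effective`` grows.
    """
    if not 0 <= point <= 1:
        raise ValueError(f"point must lie in [0, 1], got {point}")
    if n_effective <= 0:
        raise ValueError("n_effective must be positive")
    lo, hi = proportion_confint(point * n_effective, n_effective, alpha=0.05, method=method)
    return float(lo), float(hi)


def stage_probabilities(
    waiting_months: float,
    model: MetastasisModel,
    bands: Sequence[StageBand],
    kinetics: GrowthModel,
    reference_waiting_months: float,
    thresholds: Thresholds | None = None,
    months_scale: float = 1.0,
    n_effective: float = DEFAULT_N_EFFECTIVE,
    strategy_label: str | None = None,
) -> pd.DataFrame:
    """Per-stage metastasis probabilities under one waiting-list duration.

    The size detected in a band under the reference strategy is rewound (or
    advanced) by ``(waiting_months - reference_waiting_months) * months_scale``
    months of exponential growth, then fed through ``pr_met``.  At the
    reference waiting time the table reproduces the calibration inputs by
    construction.  Bands at or beyond the palpability threshold get a NaN
    probability and a sentinel note: a palpable tumor defeats the purpose
    of screening as an early-diagnosis tool.

    Returns a DataFrame with columns
    ``strategy, stage, point, lo, hi, note``; probabilities are fractions.
    """
    if waiting_months <= 0:
        raise ValueError(f"waiting time must be positive, got {waiting_months}")
    if reference_waiting_months <= 0:
        raise ValueError("reference waiting time must be positive")
    if thresholds is None:
        thresholds = Thresholds.from_cells(density=kinetics.cell_density_per_cm3)

    elapsed_days = (waiting_months - reference_waiting_months) * months_scale * DAYS_PER_MONTH
    rows = []
    for band in bands:
        if band.diameter_lo_mm >= thresholds.palpability_diameter_mm - 1e-9:
            rows.append(
                {
                    "strategy": strategy_label or f"{waiting_months:g}-month",
                    "stage": band.label,
                    "point": math.nan,
                    "lo": math.nan,
                    "hi": math.nan,
                    "note": BEYOND_PALPABILITY,
                }
            )
            continue
        cells_ref = cells_from_diameter(
            band.representative_diameter_mm, kinetics.cell_density_per_cm3
        )
        cells = advance_cells(cells_ref, elapsed_days, kinetics)
        point = min(model.pr_met(cells), 1.0 - 1e-15)
        lo, hi = probability_interval(point, n_effective)
        rows.append(
            {
                "strategy": strategy_label or f"{waiting_months:g}-month",
                "stage": band.label,
                "point": point,
                "lo": lo,
                "hi": hi,
                "note": "",
            }
        )
    return pd.DataFrame(rows)


def write_stage_probabilities(table: pd.DataFrame, path) -> None:
    """Write a stage-probability table as CSV (probabilities as fractions)."""
    table.to_csv(path, index=False)


def read_stage_probabilities(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=True)
    if "note" in df.columns:
        df["note"] = df["note"].fillna("")
    return df
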