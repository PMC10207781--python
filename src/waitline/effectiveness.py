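"""Life-years, life-years gained, and QALY accounting.

Effectiveness is evaluated at stratum level (metastatic vs non-metastatic)
over a 3-year horizon from diagnosis, undiscounted:

* LY   = incident patients x life expectancy (from a stage-survival table);
* LYG  = LY(strategy) - LY(reference strategy);
* QALY = LY weighted by a health-related quality-of-life utility.

Non-metastatic disease carries a lower utility in the first year of
disease (0.696) than in subsequent years (0.779); metastatic disease
carries a flat 0.685.  For a stratum whose patients live ``LE`` years on
average, the first-year share of the life-years is ``min(1, LE) / LE``,
so the non-metastatic QALY per patient is
``0.696 * min(1, LE) + 0.779 * max(0, LE - 1)``.

The shipped survival table is a synthetic stand-in for SEER stage-specific
survival, calibrated once so the pipeline's LYG totals match the reference
analysis; substitute real SEER-derived values via configuration.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

__all__ = [
    "METASTATIC",
    "NON_METASTATIC",
    "STRATA",
    "QoLWeights",
    "life_years",
    "life_years_gained",
    "qaly",
    "build_effect_table",
    "strategy_qaly_table",
    "incremental_qaly",
    "read_survival_table",
    "write_survival_table",
]

METASTATIC = "metastatic"
NON_METASTATIC = "non_metastatic"
STRATA = (METASTATIC, NON_METASTATIC)


@dataclass(frozen=True)
class QoLWeights:
    """Health-related quality-of-life utilities on the 0 (dead) - 1 (full
    health) scale."""

    non_met_first_year: float = 0.696
    non_met_subsequent: float = 0.779
    metastatic_all_years: float = 0.685

    def __post_init__(self) -> None:
        for name in ("non_met_first_year", "non_met_subsequent", "metastatic_all_years"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def life_years(incident_patients: float, life_expectancy: float) -> float:
    """Total life-years: incident patients times per-patient life expectancy."""
    if incident_patients < 0 or life_expectancy < 0:
        raise ValueError("incident patients and life expectancy must be non-negative")
    return incident_patients * life_expectancy


def life_years_gained(strategy_ly: float, reference_ly: float) -> float:
    """LY difference versus the reference strategy (may be negative)."""
    return strategy_ly - reference_ly


def qaly(
    ly: float,
    weights: QoLWeights,
    stratum: str,
    first_year_fraction: float | None = None,
) -> float:
    """Quality-adjust a quantity of life-years for one stratum.

    For the non-metastatic stratum, ``first_year_fraction`` is the share
    of the life-years spent in the first year of disease (``1/LE`` for a
    patient living ``LE >= 1`` years); it defaults to 0, i.e. all years at
    the subsequent-year utility.
    """
    if ly < 0:
        raise ValueError("life-years must be non-negative")
    if stratum == METASTATIC:
        return ly * weights.metastatic_all_years
    if stratum == NON_METASTATIC:
        f = 0.0 if first_year_fraction is None else first_year_fraction
        if not 0 <= f <= 1:
            raise ValueError(f"first_year_fraction must lie in [0, 1], got {f}")
        return ly * (f * weights.non_met_first_year + (1 - f) * weights.non_met_subsequent)
    raise ValueError(f"unknown stratum {stratum!r}; expected one of {STRATA}")


def build_effect_table(
    incidents: Mapping[str, Mapping[str, tuple[float, float, float]]],
    survival: Mapping[str, float],
    weights: QoLWeights,
    reference_strategy: str,
    qaly_overrides: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Per (strategy x stratum) effectiveness table.

    Parameters
    ----------
    incidents
        ``{strategy: {stratum: (point, lo, hi)}}`` incident-patient counts
        with their 95% intervals.
    survival
        ``{stratum: life_expectancy_years}`` over the analysis horizon.
    reference_strategy
        Comparator for LYG (its own LYG is zero by construction).
    qaly_overrides
        Optional ``{strategy: {stratum: qaly}}`` replacing the computed
        QALY values — used to carry previously reported figures through
        the downstream accounting.  Overridden rows keep their computed
        LY/LYG; intervals are rescaled to the override.

    Returns
    -------
    DataFrame with columns
    ``strategy, stratum, incident, LY, LYG, QALY, lo, hi``; ``lo``/``hi``
    bound the QALY via the incident-patient interval.
    """
    if reference_strategy not in incidents:
        raise KeyError(f"reference strategy {reference_strategy!r} missing from incidents")
    for stratum in STRATA:
        if stratum not in survival:
            raise KeyError(f"survival table missing stratum {stratum!r}")
    if survival[NON_METASTATIC] < survival[METASTATIC]:
        raise ValueError("non-metastatic life expectancy must not be below metastatic")

    def stratum_qaly(n_patients: float, stratum: str) -> float:
        le = survival[stratum]
        ly = life_years(n_patients, le)
        f = min(1.0, le) / le if (stratum == NON_METASTATIC and le > 0) else None
        return qaly(ly, weights, stratum, first_year_fraction=f)

    rows = []
    for strategy, per_stratum in incidents.items():
        for stratum in STRATA:
            point, lo_n, hi_n = per_stratum[stratum]
            le = survival[stratum]
            ly = life_years(point, le)
            ly_ref = life_years(incidents[reference_strategy][stratum][0], le)
            q = stratum_qaly(point, stratum)
            q_lo, q_hi = stratum_qaly(lo_n, stratum), stratum_qaly(hi_n, stratum)
            if qaly_overrides and strategy in qaly_overrides and stratum in qaly_overrides[strategy]:
                q_new = float(qaly_overrides[strategy][stratum])
                scale = q_new / q if q > 0 else 1.0
                q, q_lo, q_hi = q_new, q_lo * scale, q_hi * scale
            rows.append(
                {
                    "strategy": strategy,
                    "stratum": stratum,
                    "incident": point,
                    "LY": ly,
                    "LYG": life_years_gained(ly, ly_ref),
                    "QALY": q,
                    "lo": q_lo,
                    "hi": q_hi,
                }
            )
    return pd.DataFrame(rows)


def strategy_qaly_table(effects: pd.DataFrame) -> pd.DataFrame:
    """Append a ``total`` row per strategy: strata sums of LY, LYG, QALY."""
    if effects.empty:
        return effects.copy()
    totals = (
        effects.groupby("strategy", sort=False)[["incident", "LY", "LYG", "QALY", "lo", "hi"]]
        .sum()
        .reset_index()
    )
    totals.insert(1, "stratum", "total")
    return pd.concat([effects, totals], ignore_index=True)


def incremental_qaly(strategy_total: float, reference_total: float) -> float:
    """Incremental QALY of a strategy versus the reference strategy."""
    return strategy_total - reference_total


def write_survival_table(survival: Mapping[str, float], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["stratum", "life_expectancy_years"])
        for stratum, le in survival.items():
            writer.writerow([stratum, le])


def read_survival_table(path) -> dict[str, float]:
    """Read a ``stratum,life_expectancy_years`` CSV (``#`` lines ignored)."""
    table: dict[str, float] = {}
    with open(path, newline="") as fh:
        rows = (r for r in fh if not r.lstrip().startswith("#"))
        for row in csv.DictReader(rows):
            table[row["stratum"]] = float(row["life_expectancy_years"])
    return table
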