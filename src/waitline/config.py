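"""Scenario configuration: loading, parsing and validation.

A single YAML file holds one block per pipeline stage (``tumor_model``,
``costs``, ``tariffs``, ``strategies``, ``metastasis``, ``qol``,
``effects``, ``cohort``, ``report``).  :func:`load_config` parses it into
typed domain objects; :func:`validate_config` returns a list of issue
strings (empty means runnable) without side effects.
"""

from __future__ import annotations

import copy
import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .costs import CostComponents, Strategy, Tariffs, eur
from .effectiveness import STRATA, QoLWeights, read_survival_table
from .kinetics import GrowthModel, Thresholds
from .metastasis import StageBand, default_stage_bands, validate_bands

__all__ = [
    "RunConfig",
    "load_config",
    "default_config",
    "validate_config",
    "config_hash",
]

_DATA = resources.files("waitline.data")


def _packaged_survival_path() -> Path:
    return Path(str(_DATA / "survival_synthetic.csv"))


@dataclass
class RunConfig:
    """Parsed scenario configuration plus the raw mapping it came from."""

    raw: dict[str, Any]
    source: str  # path or "<packaged default>"
    growth: GrowthModel
    thresholds: Thresholds
    components: CostComponents
    tariffs: Tariffs
    strategies: list[Strategy]
    bands: list[StageBand]
    observed_reference: dict[str, float]
    reference_strategy: str
    n_effective: int
    months_scale: float
    qol: QoLWeights
    survival: dict[str, float]
    incident_patients: dict[str, dict[str, tuple[float, float, float]]]
    reported_qaly: dict[str, dict[str, float]]
    cohort_spec_raw: dict[str, Any]
    use_printed_overrides: bool
    willingness_to_pay: Any = None

    def strategy(self, name: str) -> Strategy:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(f"no strategy named {name!r}")


def default_config() -> RunConfig:
    """The packaged default scenario."""
    with (_DATA / "default_scenario.yaml").open("r") as fh:
        raw = yaml.safe_load(fh)
    return _parse(raw, source="<packaged default>")


def load_config(path: str | Path | None = None, overrides: Mapping[str, Any] | None = None) -> RunConfig:
    """Load a scenario YAML (or the packaged default) into a RunConfig.

    ``overrides`` maps dotted keys (e.g. ``"metastasis.months_scale"``)
    to replacement values applied on the raw mapping before parsing.
    """
    if path is None:
        with (_DATA / "default_scenario.yaml").open("r") as fh:
            raw = yaml.safe_load(fh)
        source = "<packaged default>"
    else:
        raw = yaml.safe_load(Path(path).read_text())
        source = str(path)
    if overrides:
        raw = copy.deepcopy(raw)
        for dotted, value in overrides.items():
            _set_dotted(raw, dotted, value)
    return _parse(raw, source=source)


def _set_dotted(raw: dict, dotted: str, value: Any) -> None:
    parts = dotted.split(".")
    node = raw
    for part in parts[:-1]:
        node = node.setdefault(part, {})
    node[parts[-1]] = yaml.safe_load(str(value))


def _parse(raw: dict[str, Any], source: str) -> RunConfig:
    tm = raw.get("tumor_model", {})
    growth = GrowthModel(
        doubling_time_days=float(tm.get("doubling_time_days", 168.5)),
        cell_density_per_cm3=float(tm.get("cell_density_per_cm3", 1e9)),
    )
    thresholds = Thresholds.from_cells(
        detection_cells=float(tm.get("detection_cells", 1e7)),
        palpability_cells=float(tm.get("palpability_cells", 1e10)),
        density=growth.cell_density_per_cm3,
    )

    c = raw.get("costs", {})
    components = CostComponents(
        staff_annual=eur(c.get("staff_annual", "856825.94")),
        goods_services_annual=eur(c.get("goods_services_annual", "225288.23")),
        overheads_annual=eur(c.get("overheads_annual", "162317.13")),
        equipment_annual=eur(c.get("equipment_annual", "54000.00")),
        staff_daily_per_team=eur(c.get("staff_daily_per_team", "608.28")),
        goods_services_daily=eur(c.get("goods_services_daily", "128.59")),
        overheads_daily=eur(c.get("overheads_daily", "92.65")),
        equipment_daily=eur(c.get("equipment_daily", "30.82")),
        working_hours_per_day=eur(c.get("working_hours_per_day", 5)),
    )

    t = raw.get("tariffs", {})
    tariffs = Tariffs(
        paying_exam_fee=eur(t.get("paying_exam_fee", "87.00")),
        ticket_fee=eur(t.get("ticket_fee", "36.15")),
        paying_fraction=eur(t.get("paying_fraction", "0.35")),
    )

    strategies = []
    for s in raw.get("strategies", []) or []:
        strategies.append(
            Strategy(
                name=str(s["name"]),
                teams_day=int(s.get("teams_day", 0)),
                teams_afternoon=int(s.get("teams_afternoon", 0)),
                mammographs=int(s.get("mammographs", 0)),
                ultrasounds=int(s.get("ultrasounds", 0)),
                reporting_stations=int(s.get("reporting_stations", 0)),
                exams_per_day=int(s["exams_per_day"]),
                waiting_months=float(s["waiting_months"]),
                patients_3y=int(s.get("patients_3y", 0)),
                overrides={k: eur(v) for k, v in (s.get("overrides") or {}).items()},
            )
        )

    m = raw.get("metastasis", {})
    if "bands" in m:
        bands = [
            StageBand(str(b["label"]), float(b["lo_mm"]), float(b["hi_mm"]))
            for b in m["bands"]
        ]
    else:
        bands = default_stage_bands(thresholds)
    observed = {str(k): float(v) for k, v in (m.get("observed_reference") or {}).items()}

    e = raw.get("effects", {})
    survival_path = e.get("survival_table") or _packaged_survival_path()
    survival = read_survival_table(survival_path)

    incidents: dict[str, dict[str, tuple[float, float, float]]] = {}
    for strat, per_stratum in (e.get("incident_patients") or {}).items():
        incidents[str(strat)] = {}
        for stratum, v in per_stratum.items():
            if isinstance(v, (int, float)):
                point = lo = hi = float(v)
            else:
                point, lo, hi = (float(x) for x in v)
            incidents[str(strat)][str(stratum)] = (point, lo, hi)

    reported = {
        str(strat): {str(stratum): float(v) for stratum, v in per_stratum.items()}
        for strat, per_stratum in (e.get("reported_qaly") or {}).items()
    }

    q = raw.get("qol", {})
    qol = QoLWeights(
        non_met_first_year=float(q.get("non_met_first_year", 0.696)),
        non_met_subsequent=float(q.get("non_met_subsequent", 0.779)),
        metastatic_all_years=float(q.get("metastatic_all_years", 0.685)),
    )

    rep = raw.get("report", {})
    return RunConfig(
        raw=raw,
        source=source,
        growth=growth,
        thresholds=thresholds,
        components=components,
        tariffs=tariffs,
        strategies=strategies,
        bands=bands,
        observed_reference=observed,
        reference_strategy=str(m.get("reference_strategy", "current")),
        n_effective=int(m.get("n_effective", 242)),
        months_scale=float(m.get("months_scale", 1.0)),
        qol=qol,
        survival=survival,
        incident_patients=incidents,
        reported_qaly=reported,
        cohort_spec_raw=dict(raw.get("cohort", {})),
        use_printed_overrides=bool(rep.get("use_printed_overrides", True)),
        willingness_to_pay=rep.get("willingness_to_pay"),
    )


def validate_config(config: RunConfig) -> list[str]:
    """Collect every configuration violation; an empty list means runnable."""
    issues: list[str] = []

    if not config.strategies:
        issues.append("strategies: block is empty — at least one strategy is required")
    names = [s.name for s in config.strategies]
    if len(set(names)) != len(names):
        issues.append("strategies: duplicate strategy names")
    if config.strategies and config.reference_strategy not in names:
        issues.append(
            f"metastasis.reference_strategy: {config.reference_strategy!r} "
            f"is not among strategies {names}"
        )

    issues.extend(config.tariffs.issues())
    issues.extend(config.components.issues())
    for s in config.strategies:
        issues.extend(s.issues())

    issues.extend(f"metastasis.bands: {msg}" for msg in validate_bands(config.bands))
    band_labels = {b.label for b in config.bands}
    for stage, p in config.observed_reference.items():
        if stage not in band_labels:
            issues.append(f"metastasis.observed_reference: unknown stage {stage!r}")
        if not 0 <= p <= 1:
            issues.append(f"metastasis.observed_reference.{stage}: probability {p} outside [0, 1]")

    for stratum in STRATA:
        if stratum not in config.survival:
            issues.append(f"effects.survival_table: missing stratum {stratum!r}")
        elif config.survival[stratum] < 0:
            issues.append(f"effects.survival_table.{stratum}: negative life expectancy")
    if (
        all(s in config.survival for s in STRATA)
        and config.survival["non_metastatic"] < config.survival["metastatic"]
    ):
        issues.append("effects.survival_table: non-metastatic life expectancy below metastatic")

    for strat in names:
        if config.incident_patients and strat not in config.incident_patients:
            issues.append(f"effects.incident_patients: missing strategy {strat!r}")
    for strat, per_stratum in config.incident_patients.items():
        for stratum in STRATA:
            if stratum not in per_stratum:
                issues.append(f"effects.incident_patients.{strat}: missing stratum {stratum!r}")

    cohort = config.cohort_spec_raw
    for key in ("stage_counts", "node_counts", "histology_counts", "grade_counts"):
        counts = cohort.get(key)
        if counts is None:
            continue
        if any(v < 0 for v in counts.values()):
            issues.append(f"cohort.{key}: negative frequency")
        if sum(counts.values()) <= 0:
            issues.append(f"cohort.{key}: frequencies sum to zero")

    return issues


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the raw configuration (stamped on outputs)."""
    canonical = yaml.safe_dump(config.raw, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
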