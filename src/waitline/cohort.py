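"""Synthetic patient-cohort generator.

Emulates the department's 2019 breast-cancer registry (242 patients) so
every downstream stage can run without patient-level hospital data.  A
cohort is sampled from marginal frequency tables — TNM T-stage, nodal
status, histological subtype, histological grade — with a diameter drawn
log-uniformly inside each T-stage band.  Attributes are sampled
independently: the registry summary publishes only marginals, so joint
stage x grade x histology structure is deliberately not modelled.

Grade frequencies are renormalized over the reported categories (the
registry reports 235 graded patients of 242; the remainder are ungraded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kinetics import GrowthModel, cells_from_diameter
from .metastasis import MetastasisModel, StageBand, default_stage_bands

__all__ = [
    "TABLE_STAGE_COUNTS",
    "CohortSpec",
    "registry_spec",
    "generate_cohort",
    "assign_metastasis",
    "scale_to_strategy",
    "write_cohort_csv",
    "read_cohort_csv",
]

COHORT_COLUMNS = [
    "patient_id",
    "t_stage",
    "diameter_mm",
    "node_status",
    "histology",
    "grade",
    "metastatic",
]

#: 2019 registry marginals (absolute frequencies, n = 242).
TABLE_STAGE_COUNTS = {"T1A": 20, "T1B": 65, "T1C": 95, "T2": 59, "T3": 3}
TABLE_NODE_COUNTS = {"N0": 154, "N+": 88}
TABLE_HISTOLOGY_COUNTS = {"ductal": 189, "lobular": 44, "tubular": 5, "mucinous": 2}
TABLE_GRADE_COUNTS = {1: 79, 2: 109, 3: 47}  # 235 graded of 242

#: Diameter bands (mm) used for sampling, keyed by T-stage.  The full TNM
#: extents are used here (T2 up to 50 mm, T3 50-100 mm): the generator
#: produces tumors as recorded at diagnosis, not truncated at palpability.
SAMPLING_BANDS = {
    "T1A": (1.0, 5.0),
    "T1B": (5.0, 10.0),
    "T1C": (10.0, 20.0),
    "T2": (20.0, 50.0),
    "T3": (50.0, 100.0),
}


def _normalize(freqs: Mapping, what: str) -> dict:
    total = float(sum(freqs.values()))
    if not freqs or total <= 0:
        raise ValueError(f"{what}: frequencies must be positive")
    if any(v < 0 for v in freqs.values()):
        raise ValueError(f"{what}: negative frequency")
    if abs(total - 1.0) < 1e-9:  # already normalized; keep exact values
        return dict(freqs)
    return {k: v / total for k, v in freqs.items()}


@dataclass(frozen=True)
class CohortSpec:
    """Sampling specification: cohort size plus marginal frequencies.

    Frequencies may be given as counts; they are renormalized to sum to 1.
    """

    n: int
    stage_freqs: Mapping[str, float]
    node_freqs: Mapping[str, float]
    histology_freqs: Mapping[str, float]
    grade_freqs: Mapping[int, float]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("cohort size must be non-negative")
        object.__setattr__(self, "stage_freqs", _normalize(self.stage_freqs, "stage_freqs"))
        object.__setattr__(self, "node_freqs", _normalize(self.node_freqs, "node_freqs"))
        object.__setattr__(
            self, "histology_freqs", _normalize(self.histology_freqs, "histology_freqs")
        )
        object.__setattr__(self, "grade_freqs", _normalize(self.grade_freqs, "grade_freqs"))
        unknown = set(self.stage_freqs) - set(SAMPLING_BANDS)
        if unknown:
            raise ValueError(f"unknown T-stages in spec: {sorted(unknown)}")


def registry_spec(n: int = 242, seed: int = 0) -> CohortSpec:
    """Spec matching the 2019 registry marginals."""
    return CohortSpec(
        n=n,
        stage_freqs=TABLE_STAGE_COUNTS,
        node_freqs=TABLE_NODE_COUNTS,
        histology_freqs=TABLE_HISTOLOGY_COUNTS,
        grade_freqs=TABLE_GRADE_COUNTS,
        seed=seed,
    )


def _choice(rng: np.random.Generator, freqs: Mapping, size: int) -> np.ndarray:
    keys = list(freqs.keys())
    probs = np.asarray([freqs[k] for k in keys], dtype=float)
    idx = rng.choice(len(keys), size=size, p=probs)
    return np.asarray(keys, dtype=object)[idx]


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Sample a patient cohort; reproducible given ``spec.seed``.

    Diameters are drawn uniformly on the log scale within each stage band,
    reflecting exponential growth through the band.  The ``metastatic``
    flag starts False; see :func:`assign_metastasis`.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.n == 0:
        return pd.DataFrame(columns=COHORT_COLUMNS)

    stages = _choice(rng, spec.stage_freqs, spec.n)
    lo = np.asarray([SAMPLING_BANDS[s][0] for s in stages])
    hi = np.asarray([SAMPLING_BANDS[s][1] for s in stages])
    diameters = np.exp(rng.uniform(np.log(lo), np.log(hi)))

    return pd.DataFrame(
        {
            "patient_id": np.arange(spec.n),
            "t_stage": stages,
            "diameter_mm": diameters,
            "node_status": _choice(rng, spec.node_freqs, spec.n),
            "histology": _choice(rng, spec.histology_freqs, spec.n),
            "grade": _choice(rng, spec.grade_freqs, spec.n).astype(int),
            "metastatic": np.zeros(spec.n, dtype=bool),
        }
    )


def assign_metastasis(
    cohort: pd.DataFrame,
    model: MetastasisModel,
    rng_seed: int,
    kinetics: GrowthModel | None = None,
) -> pd.DataFrame:
    """Draw each patient's metastatic flag Bernoulli(pr_met(N(diameter))).

    Returns a copy; the expected metastatic count within a stage equals
    the stage's patient count times its metastasis probability.
    """
    if kinetics is None:
        kinetics = GrowthModel()
    rng = np.random.default_rng(rng_seed)
    out = cohort.copy()
    if out.empty:
        return out
    cells = np.asarray(
        [cells_from_diameter(d, kinetics.cell_density_per_cm3) for d in out["diameter_mm"]]
    )
    probs = -np.expm1(-cells / model.P)
    out["metastatic"] = rng.random(len(out)) < probs
    return out


def scale_to_strategy(
    spec: CohortSpec,
    patients_3y: int,
    waiting_months: float | None = None,
    reference_waiting_months: float | None = None,
    kinetics: GrowthModel | None = None,
    shift_stage_mix: bool = False,
) -> CohortSpec:
    """Rescale a cohort spec to a strategy's 3-year screened volume.

    Frequencies are kept as-is unless ``shift_stage_mix`` is set, in which
    case each stage band's probability mass is moved to the band that
    contains its representative diameter after rewinding the growth model
    over the waiting-time difference — shorter waits shift mass toward
    smaller stages.
    """
    if patients_3y <= 0:
        raise ValueError("patients_3y must be positive")
    new_freqs = dict(spec.stage_freqs)
    if shift_stage_mix:
        if waiting_months is None or reference_waiting_months is None:
            raise ValueError("stage-mix shift needs both waiting times")
        if kinetics is None:
            kinetics = GrowthModel()
        from .kinetics import DAYS_PER_MONTH, advance_cells, diameter_from_cells

        elapsed = (waiting_months - reference_waiting_months) * DAYS_PER_MONTH
        shifted: dict[str, float] = {s: 0.0 for s in spec.stage_freqs}
        for stage, mass in spec.stage_freqs.items():
            lo, hi = SAMPLING_BANDS[stage]
            d_rep = math.sqrt(lo * hi)
            cells = cells_from_diameter(d_rep, kinetics.cell_density_per_cm3)
            d_new = diameter_from_cells(
                advance_cells(cells, elapsed, kinetics), kinetics.cell_density_per_cm3
            )
            target = stage
            for label, (blo, bhi) in SAMPLING_BANDS.items():
                if blo <= d_new < bhi:
                    target = label
                    break
            else:
                # Below the smallest band: attribute to the smallest stage.
                target = min(SAMPLING_BANDS, key=lambda s: SAMPLING_BANDS[s][0])
            shifted[target] = shifted.get(target, 0.0) + mass
        new_freqs = {s: m for s, m in shifted.items() if m > 0}
    return replace(spec, n=patients_3y, stage_freqs=new_freqs)


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False, float_format="%.6f")


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
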