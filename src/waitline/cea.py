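"""Incremental cost-effectiveness ratios and strategy ranking.

Each candidate strategy is compared pairwise against the current
(comparator) strategy:

    ICER = (C_strategy - C_comparator) / (QALY_strategy - QALY_comparator)

in euros per QALY gained.  A strategy that saves money while gaining
QALYs is *dominant*; one that costs more while losing QALYs is
*dominated*; otherwise the ICER quantifies the trade-off, optionally
judged against a willingness-to-pay threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

from .costs import eur

__all__ = ["ICERResult", "RankedStrategy", "icer", "classify_dominance", "rank_strategies"]

_CENT = Decimal("0.01")


@dataclass(frozen=True)
class ICERResult:
    """Pairwise comparison of one strategy against the comparator."""

    strategy: str
    delta_cost: Decimal
    delta_qaly: float
    icer: Decimal | None  # None when delta_qaly == 0 (undefined ratio)
    dominance: str  # "dominant" | "dominated" | "trade-off"


def icer(delta_cost: Decimal, delta_qaly: float) -> Decimal:
    """Cost per QALY gained, reported to the cent.

    Raises
    ------
    ZeroDivisionError
        When ``delta_qaly`` is zero — the ratio is undefined, not a number.
    """
    if delta_qaly == 0:
        raise ZeroDivisionError("ICER undefined: zero QALY difference")
    value = eur(delta_cost) / Decimal(str(delta_qaly))
    return value.quantize(_CENT, rounding=ROUND_HALF_UP)


def classify_dominance(delta_cost: Decimal, delta_qaly: float) -> str:
    """Dominance from the signs of the cost and effect deltas."""
    dc = eur(delta_cost)
    if dc <= 0 and delta_qaly >= 0 and not (dc == 0 and delta_qaly == 0):
        return "dominant"
    if dc >= 0 and delta_qaly <= 0 and not (dc == 0 and delta_qaly == 0):
        return "dominated"
    return "trade-off"


def compare(strategy: str, delta_cost: Decimal, delta_qaly: float) -> ICERResult:
    """Build an :class:`ICERResult`, leaving the ratio undefined at zero
    QALY difference."""
    ratio = icer(delta_cost, delta_qaly) if delta_qaly != 0 else None
    return ICERResult(
        strategy=strategy,
        delta_cost=eur(delta_cost),
        delta_qaly=delta_qaly,
        icer=ratio,
        dominance=classify_dominance(delta_cost, delta_qaly),
    )


@dataclass(frozen=True)
class RankedStrategy:
    result: ICERResult
    rank: int
    verdict: str  # vs willingness-to-pay threshold, or "" when none given
    tied: bool


def rank_strategies(
    results: list[ICERResult],
    threshold: Decimal | None = None,
) -> list[RankedStrategy]:
    """Order strategies by favourability.

    Dominant strategies come first, then trade-offs by ascending ICER
    (lower cost per QALY ranks higher), then dominated and
    undefined-ratio strategies.  The sort is stable, so equal ICERs keep
    their input order and are flagged as ties.  With a willingness-to-pay
    threshold, each strategy gets a verdict: dominant strategies and
    trade-offs at or under the threshold are "cost-effective".
    """
    if not results:
        raise ValueError("need at least one strategy comparison")

    def sort_key(item: tuple[int, ICERResult]):
        idx, r = item
        group = {"dominant": 0, "trade-off": 1, "dominated": 2}[r.dominance]
        ratio = r.icer if r.icer is not None else Decimal("Infinity")
        return (group, ratio, idx)

    ordered = sorted(enumerate(results), key=sort_key)
    icers = [r.icer for _, r in ordered]
    ranked = []
    for rank, (_, result) in enumerate(ordered, start=1):
        if threshold is None:
            verdict = ""
        elif result.dominance == "dominant":
            verdict = "cost-effective"
        elif result.icer is not None and result.icer <= eur(threshold):
            verdict = "cost-effective"
        else:
            verdict = "not cost-effective"
        tied = result.icer is not None and icers.count(result.icer) > 1
        ranked.append(RankedStrategy(result=result, rank=rank, verdict=verdict, tied=tied))
    return ranked
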