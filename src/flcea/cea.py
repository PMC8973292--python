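"""Base-case cost-utility comparison: ICER, dominance, and net monetary benefit.

Incremental quantities are always PET/CT minus no-PET/CT, so a negative
incremental cost and a positive incremental QALY mean the scan both saves
money and improves outcomes (strong dominance).  The ICER is reported only
in the trade-off quadrants; in the dominance quadrants a sentinel label is
returned instead, and the net monetary benefit NMB = WTP * dQALY - dCost
carries the decision.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import CohortTrace, run_cohort
from .params import ParameterError, ParameterSet
from .tree import allocate_no_petct, allocate_petct

__all__ = [
    "CEResult",
    "run_base_case",
    "classify_dominance",
    "icer_or_sentinel",
    "compute_nmb",
    "is_cost_effective",
]


def classify_dominance(delta_cost: float, delta_qaly: float) -> str:
    """Quadrant classification of an incremental (cost, QALY) pair.

    ``strongly_dominant``: PET/CT no more costly and no less effective (and
    not a tie); ``dominated``: the reverse; ``tradeoff_ne``: more costly and
    more effective; ``tradeoff_sw``: cheaper and less effective; exact zeros
    in both dimensions are a ``tie``.
    """
    if delta_cost == 0.0 and delta_qaly == 0.0:
        return "tie"
    if delta_cost <= 0.0 and delta_qaly >= 0.0:
        return "strongly_dominant"
    if delta_cost >= 0.0 and delta_qaly <= 0.0:
        return "dominated"
    return "tradeoff_ne" if delta_qaly > 0.0 else "tradeoff_sw"


def icer_or_sentinel(delta_cost: float, delta_qaly: float):
    """Incremental cost-effectiveness ratio, or a dominance sentinel.

    Returns ``"dominant"`` / ``"dominated"`` in the dominance quadrants,
    ``None`` for an exact tie, and the ratio otherwise.  The ratio is never
    formed with a zero QALY difference.
    """
    label = classify_dominance(delta_cost, delta_qaly)
    if label == "strongly_dominant":
        return "dominant"
    if label == "dominated":
        return "dominated"
    if label == "tie":
        return None
    return delta_cost / delta_qaly


def compute_nmb(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """Net monetary benefit of the PET/CT strategy at a WTP threshold."""
    if wtp < 0:
        raise ParameterError("willingness-to-pay must be nonnegative")
    return wtp * delta_qaly - delta_cost


def is_cost_effective(delta_cost: float, delta_qaly: float, wtp: float) -> bool:
    """Cost-saving, or ICER below the WTP threshold in the NE quadrant."""
    if delta_cost < 0.0:
        return True
    return delta_qaly > 0.0 and delta_cost / delta_qaly < wtp


@dataclass(frozen=True)
class CEResult:
    """Per-strategy totals and the incremental comparison."""

    cost_no_petct: float
    qalys_no_petct: float
    cost_petct: float
    qalys_petct: float
    wtp: float

    @property
    def delta_cost(self) -> float:
        return self.cost_petct - self.cost_no_petct

    @property
    def delta_qaly(self) -> float:
        return self.qalys_petct - self.qalys_no_petct

    @property
    def classification(self) -> str:
        return classify_dominance(self.delta_cost, self.delta_qaly)

    @property
    def icer(self):
        return icer_or_sentinel(self.delta_cost, self.delta_qaly)

    @property
    def nmb(self) -> float:
        return compute_nmb(self.delta_cost, self.delta_qaly, self.wtp)

    def to_dict(self) -> dict:
        return {
            "no_petct": {"cost": self.cost_no_petct, "qalys": self.qalys_no_petct},
            "petct": {"cost": self.cost_petct, "qalys": self.qalys_petct},
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "classification": self.classification,
            "icer": self.icer,
            "wtp": self.wtp,
            "nmb": self.nmb,
        }


def run_base_case(ps: ParameterSet, return_traces: bool = False):
    """Run tree + cohort for both strategies on the set's base values."""
    trace_no = run_cohort(allocate_no_petct(ps), ps)
    trace_pet = run_cohort(allocate_petct(ps), ps)
    result = CEResult(
        cost_no_petct=trace_no.total_cost,
        qalys_no_petct=trace_no.total_qalys,
        cost_petct=trace_pet.total_cost,
        qalys_petct=trace_pet.total_qalys,
        wtp=ps.settings.wtp,
    )
    if return_traces:
        return result, {"no_petct": trace_no, "petct": trace_pet}
    return result
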