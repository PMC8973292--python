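"""Probabilistic sensitivity analysis.

Repeatedly draws a full parameter set from the per-parameter distributions,
runs both strategies through tree + cohort, and keeps the incremental
(cost, QALY) pair of each draw.  Summaries report the share of draws where
PET/CT is strongly dominant and the share where it is cost-effective, and a
cost-effectiveness acceptability curve (CEAC) gives the probability of a
positive net monetary benefit as a function of the willingness-to-pay.

Two senses of "cost-effective" coexist in this field and both are exposed:
``rule="nmb"`` counts draws with NMB > 0 (the CEAC definition), while the
default ``rule="cost-saving-or-icer"`` counts draws that save costs or have
an ICER below the threshold — the two differ only for cost-saving draws
with a large QALY loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cea import classify_dominance, is_cost_effective, run_base_case
from .params import ParameterError, ParameterSet, sample_parameter_set

__all__ = ["PSAResult", "run_psa", "ceac_curve"]


@dataclass(frozen=True)
class PSAResult:
    """Per-draw incremental pairs (PET/CT minus no-PET/CT) and summaries."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    seed: int
    wtp: float

    @property
    def n(self) -> int:
        return self.delta_cost.size

    def classifications(self) -> list[str]:
        return [classify_dominance(dc, dq)
                for dc, dq in zip(self.delta_cost, self.delta_qaly)]

    @property
    def proportion_dominant(self) -> float:
        """Share of draws where PET/CT is strongly dominant."""
        return sum(c == "strongly_dominant" for c in self.classifications()) / self.n

    def proportion_cost_effective(self, wtp: float | None = None,
                                  rule: str = "cost-saving-or-icer") -> float:
        """Share of cost-effective draws at a WTP threshold (default: the set's)."""
        w = self.wtp if wtp is None else float(wtp)
        if rule == "nmb":
            return float(np.mean(w * self.delta_qaly - self.delta_cost > 0.0))
        if rule == "cost-saving-or-icer":
            return float(np.mean([is_cost_effective(dc, dq, w)
                                  for dc, dq in zip(self.delta_cost, self.delta_qaly)]))
        raise ParameterError(f"unknown cost-effectiveness rule {rule!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "draw": np.arange(self.n),
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "classification": self.classifications(),
        })

    def summary(self) -> dict:
        return {
            "n": self.n,
            "seed": self.seed,
            "wtp": self.wtp,
            "mean_delta_cost": float(self.delta_cost.mean()),
            "mean_delta_qaly": float(self.delta_qaly.mean()),
            "proportion_strongly_dominant": self.proportion_dominant,
            "proportion_cost_effective": self.proportion_cost_effective(),
            "proportion_nmb_positive": self.proportion_cost_effective(rule="nmb"),
        }


def run_psa(ps: ParameterSet, n: int, seed: int) -> PSAResult:
    """n probabilistic draws, each evaluated through tree + cohort + CEA.

    Per-draw sub-seeds are spawned from a counter-based ``SeedSequence`` of
    the master seed, so draw i is identical regardless of evaluation order
    and the whole run is reproducible bit-for-bit for the same (n, seed).
    A draw that violates the parameter domains is a hard error.
    """
    if n < 1:
        raise ParameterError("n must be at least 1")
    children = np.random.SeedSequence(seed).spawn(n)
    dc = np.empty(n)
    dq = np.empty(n)
    for i, child in enumerate(children):
        draw = sample_parameter_set(ps, child)
        res = run_base_case(draw)
        dc[i] = res.delta_cost
        dq[i] = res.delta_qaly
    return PSAResult(dc, dq, seed=seed, wtp=ps.settings.wtp)


def ceac_curve(result: PSAResult, wtp_grid: Sequence[float]) -> np.ndarray:
    """Cost-effectiveness acceptability curve.

    For each WTP in the grid: the fraction of draws with positive net
    monetary benefit, WTP * dQALY - dCost > 0.  Returns (len(grid), 2)
    pairs of (wtp, fraction).
    """
    if result.n == 0:
        raise ParameterError("empty PSA result")
    grid = np.asarray(list(wtp_grid), dtype=float)
    if np.any(grid < 0):
        raise ParameterError("WTP grid values must be nonnegative")
    frac = [float(np.mean(w * result.delta_qaly - result.delta_cost > 0.0)) for w in grid]
    return np.column_stack([grid, frac])
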