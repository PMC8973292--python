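"""Deterministic sensitivity analyses.

One-way analyses vary a single parameter across its admissible range while
holding everything else at base, tracking the net monetary benefit (NMB) of
the PET/CT strategy; a sign change in NMB marks a preference threshold,
located by bisection after a 101-point pre-scan.  A tornado analysis ranks
parameters by the NMB spread over their ranges, and a two-way analysis maps
the preferred strategy over a grid of the two new-finding probabilities.

Varying one member of the management-mix Dirichlet group rescales the other
members proportionally so the mix keeps summing to one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .cea import run_base_case
from .params import ParameterError, ParameterSet

__all__ = [
    "ThresholdResult",
    "TwoWayFrontier",
    "TornadoEntry",
    "with_parameter_value",
    "default_range",
    "one_way_nmb_curve",
    "find_threshold",
    "two_way_frontier",
    "tornado",
]

#: default scan ranges by role: probabilities and proportions over the full
#: unit interval, utilities 0-1, costs 0-500,000 CAD
_DEFAULT_RANGES = {
    "probability-per-cycle": (0.0, 1.0),
    "proportion": (0.0, 1.0),
    "diagnostic-probability": (0.0, 1.0),
    "utility": (0.0, 1.0),
    "cost-CAD-2019": (0.0, 500_000.0),
}


def default_range(ps: ParameterSet, name: str) -> tuple[float, float]:
    if name not in ps.parameters:
        raise ParameterError(f"unknown parameter {name!r}")
    return _DEFAULT_RANGES[ps.parameters[name].role]


def with_parameter_value(ps: ParameterSet, name: str, value: float,
                         rebalance_group: bool = True) -> ParameterSet:
    """Set one parameter, proportionally rebalancing its Dirichlet group.

    When ``name`` belongs to a Dirichlet group, the remaining members are
    rescaled by (1 - value) / (their current sum); if the others currently
    sum to zero, the remainder is split equally.
    """
    if name not in ps.parameters:
        raise ParameterError(f"unknown parameter {name!r}")
    p = ps.parameters[name]
    lo, hi = _DEFAULT_RANGES[p.role]
    if not lo <= value <= hi:
        raise ParameterError(f"{name}: value {value} outside admissible domain [{lo}, {hi}]")
    updates = {name: float(value)}
    if rebalance_group and p.dist.kind == "dirichlet-group":
        others = [m for m in ps.dirichlet_members(p.dist.group) if m != name]
        total = sum(ps[m] for m in others)
        if total > 0.0:
            scale = (1.0 - value) / total
            updates.update({m: ps[m] * scale for m in others})
        elif others:
            share = (1.0 - value) / len(others)
            updates.update({m: share for m in others})
    return ps.with_values(updates)


def _nmb_at(ps: ParameterSet, name: str, value: float) -> float:
    return run_base_case(with_parameter_value(ps, name, value)).nmb


def one_way_nmb_curve(ps: ParameterSet, name: str,
                      value_range: tuple[float, float] | None = None,
                      n_points: int = 21) -> np.ndarray:
    """NMB of the PET/CT strategy on a grid of one parameter's values.

    Returns an (n_points, 2) array of (value, NMB) pairs.
    """
    if n_points < 2:
        raise ParameterError("n_points must be at least 2")
    lo, hi = value_range if value_range is not None else default_range(ps, name)
    dlo, dhi = default_range(ps, name)
    if not (dlo <= lo <= hi <= dhi):
        raise ParameterError(f"{name}: range ({lo}, {hi}) outside admissible domain")
    xs = np.linspace(lo, hi, n_points)
    return np.column_stack([xs, [_nmb_at(ps, name, x) for x in xs]])


@dataclass(frozen=True)
class ThresholdResult:
    """Preference thresholds of one parameter over a scanned range.

    ``thresholds`` lists every value where the NMB of the PET/CT strategy
    crosses zero (located to |NMB| < ``nmb_tol``); an empty tuple means the
    preferred strategy never flips in range.  ``direction`` states which side
    of the (first) threshold prefers PET/CT; it is ``None`` without a
    threshold and ``"mixed"`` with several.
    """

    parameter: str
    low: float
    high: float
    thresholds: tuple[float, ...]
    nmb_low: float
    nmb_high: float
    nmb_tol: float = 1e-3

    @property
    def direction(self) -> str | None:
        if not self.thresholds:
            return None
        if len(self.thresholds) > 1:
            return "mixed"
        return "petct_preferred_below" if self.nmb_low > 0 else "petct_preferred_above"


def find_threshold(ps: ParameterSet, name: str,
                   value_range: tuple[float, float] | None = None,
                   n_scan: int = 101, tol: float = 1e-3,
                   max_iter: int = 100) -> ThresholdResult:
    """Locate every NMB sign change of one parameter by pre-scan + bisection.

    The range is scanned at ``n_scan`` points; each bracket with a strict
    sign change is bisected until |NMB| < ``tol`` (in CAD) or ``max_iter``
    iterations.  The absence of a threshold is a valid result.
    """
    lo, hi = value_range if value_range is not None else default_range(ps, name)
    xs = np.linspace(lo, hi, n_scan)
    fs = np.array([_nmb_at(ps, name, x) for x in xs])
    thresholds: list[float] = []
    for i in range(n_scan - 1):
        a, b = xs[i], xs[i + 1]
        fa, fb = fs[i], fs[i + 1]
        if fa == 0.0:
            if not thresholds or abs(thresholds[-1] - a) > 1e-12:
                thresholds.append(float(a))
            continue
        if fa * fb >= 0.0:
            continue
        for _ in range(max_iter):
            m = 0.5 * (a + b)
            fm = _nmb_at(ps, name, m)
            if abs(fm) < tol:
                break
            if fa * fm < 0.0:
                b = m
            else:
                a, fa = m, fm
        thresholds.append(float(0.5 * (a + b) if abs(fm) >= tol else m))
    if fs[-1] == 0.0:
        thresholds.append(float(xs[-1]))
    return ThresholdResult(name, float(lo), float(hi), tuple(thresholds),
                           float(fs[0]), float(fs[-1]), tol)


@dataclass(frozen=True)
class TwoWayFrontier:
    """Preferred strategy over a two-parameter grid.

    ``preferred[i, j]`` is +1 where PET/CT is preferred (NMB > 0), -1 where
    no-PET/CT is preferred, 0 on exact ties, at (``xs[i]``, ``ys[j]``).
    """

    name_x: str
    name_y: str
    xs: np.ndarray
    ys: np.ndarray
    nmb: np.ndarray

    @property
    def preferred(self) -> np.ndarray:
        return np.sign(self.nmb).astype(int)


def two_way_frontier(ps: ParameterSet, name_x: str, name_y: str,
                     grid: tuple[int, int] = (51, 51),
                     range_x: tuple[float, float] | None = None,
                     range_y: tuple[float, float] | None = None) -> TwoWayFrontier:
    """Evaluate the preferred strategy on an (nx, ny) grid of two parameters."""
    nx, ny = grid
    if nx < 2 or ny < 2:
        raise ParameterError("grid must be at least 2x2")
    lo_x, hi_x = range_x if range_x is not None else default_range(ps, name_x)
    lo_y, hi_y = range_y if range_y is not None else default_range(ps, name_y)
    xs = np.linspace(lo_x, hi_x, nx)
    ys = np.linspace(lo_y, hi_y, ny)
    nmb = np.empty((nx, ny))
    for i, x in enumerate(xs):
        ps_x = with_parameter_value(ps, name_x, x)
        for j, y in enumerate(ys):
            nmb[i, j] = run_base_case(with_parameter_value(ps_x, name_y, y)).nmb
    return TwoWayFrontier(name_x, name_y, xs, ys, nmb)


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low: float
    high: float
    nmb_low: float
    nmb_high: float

    @property
    def spread(self) -> float:
        return abs(self.nmb_high - self.nmb_low)


def tornado(ps: ParameterSet,
            ranges: Mapping[str, tuple[float, float]] | None = None,
            parameters: Sequence[str] | None = None) -> list[TornadoEntry]:
    """NMB spread of each parameter over its range, largest first.

    ``ranges`` overrides the default role-based ranges; ``parameters``
    restricts the analysis (default: every required model parameter).  Ties
    break alphabetically, so the ranking is independent of processing order.
    """
    if parameters is None:
        parameters = [n for n in ps.parameters if "__" not in n]
    entries = []
    for name in parameters:
        lo, hi = (ranges or {}).get(name) or default_range(ps, name)
        entries.append(TornadoEntry(name, float(lo), float(hi),
                                    _nmb_at(ps, name, lo), _nmb_at(ps, name, hi)))
    return sorted(entries, key=lambda e: (-e.spread, e.parameter))
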