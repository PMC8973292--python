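"""Individual-patient Monte Carlo simulation.

A brute-force counterpart of the cohort engine: patients are sampled one by
one through the decision tree's branch probabilities and then stepped
cycle-by-cycle using exactly the same per-cycle transition probabilities and
reward accounting as the cohort model.  Because both engines consume the
same probabilities, the sample mean cost and QALYs converge to the cohort
totals, which makes the pair a mutual cross-check: any disagreement beyond
Monte Carlo error isolates a defect in one propagation scheme.

The strategy's upfront cost is a cohort-level expectation (it already
averages over the tree branches), so it is added to every patient as a
constant and contributes no variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import (
    DEAD_OTHER,
    LIVING,
    N_STATES,
    S,
    STATES,
    SUCCESSOR_IDX,
    Stratum,
    _ENTRY_COST_PARAM,
    _STATE_COST_PARAM,
    _UTILITY_PARAM,
    cycle_background_mortality,
    event_probabilities,
)
from .params import ParameterError, ParameterSet
from .tree import allocate_no_petct, allocate_petct

__all__ = ["PatientRecord", "MicrosimResult", "simulate_patients"]


@dataclass(frozen=True)
class PatientRecord:
    """One simulated disease course."""

    truth: str
    path: tuple[tuple[int, str], ...]  # (cycle, state) from entry to horizon
    total_cost: float
    total_qaly: float


@dataclass(frozen=True)
class MicrosimResult:
    strategy: str
    n: int
    seed: int
    mean_cost: float
    mean_qaly: float
    se_cost: float
    se_qaly: float
    #: fraction of patients in each state at the start of each cycle
    occupancy: np.ndarray
    records: tuple[PatientRecord, ...] | None = None

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy, "n": self.n, "seed": self.seed,
            "mean_cost": self.mean_cost, "mean_qaly": self.mean_qaly,
            "se_cost": self.se_cost, "se_qaly": self.se_qaly,
        }


def simulate_patients(ps: ParameterSet, strategy: str, n: int, seed: int,
                      return_records: bool = False) -> MicrosimResult:
    """Simulate n patients under one strategy; seeded and reproducible.

    ``strategy`` is ``"petct"`` or ``"no_petct"``.  Patient records are kept
    only on request (intended for small n).
    """
    if n < 1:
        raise ParameterError("n must be at least 1")
    st = ps.settings
    if st.half_cycle_correction or st.rewards_at_cycle_end:
        raise ParameterError("microsimulation supports the default reward accounting only")
    ps.validate()
    alloc = {"petct": allocate_petct, "no_petct": allocate_no_petct}.get(strategy)
    if alloc is None:
        raise ParameterError(f"unknown strategy {strategy!r}")
    alloc = alloc(ps)

    entries = sorted(alloc.fractions.items())
    probs = np.array([f for _, f in entries])
    probs = probs / probs.sum()
    strata: list[Stratum] = []
    stratum_index: dict[Stratum, int] = {}
    entry_state = np.empty(len(entries), dtype=int)
    entry_stratum = np.empty(len(entries), dtype=int)
    for e, ((state, truth), _) in enumerate(entries):
        covered = alloc.out_of_field_covered if truth == "early_out_of_field" else False
        key = Stratum(truth, covered)
        if key not in stratum_index:
            stratum_index[key] = len(strata)
            strata.append(key)
        entry_state[e] = S[state]
        entry_stratum[e] = stratum_index[key]

    D = np.array([event_probabilities(ps, s) for s in strata])  # (P, n_states)
    values = ps.values
    cost_vec = np.array([values[p] if p else 0.0 for p in _STATE_COST_PARAM])
    util_vec = np.array([values[p] if p else 0.0 for p in _UTILITY_PARAM])
    entry_cost_vec = np.zeros(N_STATES)
    for idx, pname in _ENTRY_COST_PARAM.items():
        entry_cost_vec[idx] = values[pname]

    bg = cycle_background_mortality(ps)
    n_cycles = st.n_cycles
    cy = st.cycle_years
    df = (1.0 + st.discount_rate) ** (-cy * np.arange(n_cycles + 1))

    rng = np.random.default_rng(seed)
    pick = rng.choice(len(entries), size=n, p=probs)
    state = entry_state[pick]
    stratum = entry_stratum[pick]

    cost = np.full(n, alloc.upfront_cost)
    qaly = np.full(n, alloc.upfront_qaly_adjust)
    occupancy = np.zeros((n_cycles + 1, N_STATES))
    paths = np.empty((n, n_cycles + 1), dtype=np.int8) if return_records else None

    living = LIVING.astype(bool)
    succ = SUCCESSOR_IDX
    for k in range(n_cycles):
        occupancy[k] = np.bincount(state, minlength=N_STATES)
        if paths is not None:
            paths[:, k] = state
        cost += cost_vec[state] * df[k]
        qaly += util_vec[state] * cy * df[k]
        alive = living[state]
        u_bg = rng.random(n)
        u_ev = rng.random(n)
        die_other = alive & (u_bg < bg[k])
        event = alive & ~die_other & (u_ev < D[stratum, state])
        new_state = np.where(die_other, DEAD_OTHER, np.where(event, succ[state], state))
        moved = new_state != state
        cost += entry_cost_vec[new_state] * moved * df[k + 1]
        state = new_state
    occupancy[n_cycles] = np.bincount(state, minlength=N_STATES)
    if paths is not None:
        paths[:, n_cycles] = state
    occupancy /= n

    records = None
    if return_records:
        truths = [entries[p][0][1] for p in pick]
        records = tuple(
            PatientRecord(
                truth=truths[i],
                path=tuple((k, STATES[paths[i, k]]) for k in range(n_cycles + 1)),
                total_cost=float(cost[i]),
                total_qaly=float(qaly[i]),
            )
            for i in range(n)
        )

    se_cost = float(cost.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    se_qaly = float(qaly.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return MicrosimResult(
        strategy=strategy, n=n, seed=seed,
        mean_cost=float(cost.mean()), mean_qaly=float(qaly.mean()),
        se_cost=se_cost, se_qaly=se_qaly,
        occupancy=occupancy, records=records,
    )
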