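"""State-transition cohort engine.

Twelve health states describe the disease course after the staging decision:
a post-RT remission state, the four noncurative management states for
advanced disease, bendamustine-rituximab plus maintenance at first relapse,
three salvage-chemotherapy lines, a palliative state, and two absorbing
death states (lymphoma death, death from other causes).

Within each 6-month cycle, background mortality (from the life table,
converted to a per-cycle probability under a constant hazard) and the
state's disease event (relapse, progression, or — from the palliative state
— lymphoma death) are applied as independent competing risks, with death
from other causes taking precedence when both occur.  The disease pathway is
a chain: each living state has exactly one disease-event successor.

The cohort is stratified by truth category (and, for remission, by whether
the RT field covers the disease); each stratum keeps its own event
probabilities, so false-positive upstaged patients can be given a different
natural history through ``<parameter>__<truth>`` overrides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .params import ParameterError, ParameterSet, annual_to_cycle_prob
from .tree import EntryAllocation

__all__ = [
    "STATES",
    "Stratum",
    "CohortTrace",
    "build_transition_matrix",
    "run_cohort",
    "discount_factor",
]

STATES = (
    "PostRT_Remission",
    "Adv_Rmono",
    "Adv_WW",
    "Adv_PallRT",
    "Adv_BR_line",
    "BR_plus_maintenance",
    "Salvage_1",
    "Salvage_2",
    "Salvage_3",
    "Palliative",
    "Dead_lymphoma",
    "Dead_other",
)
S = {name: i for i, name in enumerate(STATES)}
N_STATES = len(STATES)
DEAD_LYMPHOMA = S["Dead_lymphoma"]
DEAD_OTHER = S["Dead_other"]
LIVING = np.array([1.0] * 10 + [0.0, 0.0])

#: disease-event successor of each state (dead states map to themselves)
SUCCESSOR_IDX = np.array([
    S["BR_plus_maintenance"],  # PostRT_Remission relapse
    S["BR_plus_maintenance"],  # Adv_Rmono progression (BR not yet received)
    S["BR_plus_maintenance"],  # Adv_WW
    S["BR_plus_maintenance"],  # Adv_PallRT
    S["Salvage_1"],            # Adv_BR_line (BR already received)
    S["Salvage_1"],            # BR_plus_maintenance
    S["Salvage_2"],
    S["Salvage_3"],
    S["Palliative"],           # salvage lines exhausted
    S["Dead_lymphoma"],        # palliative state: lymphoma death
    DEAD_LYMPHOMA,
    DEAD_OTHER,
])

#: per-cycle disease-event parameter per state; remission is profile-dependent
_EVENT_PARAM = (
    None,  # PostRT_Remission: resolved per stratum
    "p_prog_rmono",
    "p_prog_ww",
    "p_prog_pallRT",
    "p_prog_br_firstline",
    "p_prog_br_maintenance",
    "p_prog_salvage1",
    "p_prog_salvage2",
    "p_prog_salvage3",
    "p_death_palliative",
    None,
    None,
)

#: one-off cost charged on *entering* a state mid-run (treatment initiation)
_ENTRY_COST_PARAM = {
    S["BR_plus_maintenance"]: "c_br_course",
    S["Salvage_1"]: "c_salvage_course",
    S["Salvage_2"]: "c_salvage_course",
    S["Salvage_3"]: "c_salvage_course",
}

_STATE_COST_PARAM = (
    "c_followup_cycle", "c_followup_cycle", "c_followup_cycle", "c_followup_cycle",
    "c_followup_cycle", "c_followup_cycle", "c_followup_cycle", "c_followup_cycle",
    "c_followup_cycle", "c_palliative_cycle", None, None,
)

_UTILITY_PARAM = (
    "u_first_remission", "u_adv_rmono", "u_adv_ww", "u_adv_pallRT", "u_adv_br",
    "u_br_maintenance", "u_salvage", "u_salvage", "u_salvage", "u_palliative",
    None, None,
)

# scatter matrix for the disease-event move (living states only)
_MOVE = np.zeros((N_STATES, N_STATES))
for _s in range(N_STATES):
    if LIVING[_s]:
        _MOVE[_s, SUCCESSOR_IDX[_s]] = 1.0


class Stratum(NamedTuple):
    """One truth category, plus whether the RT field covers the disease."""

    truth: str
    field_covers_disease: bool = False


def _relapse_param(stratum: Stratum) -> str:
    if stratum.truth == "advanced":
        return "p_relapse_rt_advanced"
    if stratum.truth == "early_out_of_field" and not stratum.field_covers_disease:
        return "p_relapse_rt_outfield"
    return "p_relapse_rt_infield"


def _lookup(values: dict[str, float], name: str, truth: str) -> float:
    return values.get(f"{name}__{truth}", values[name])


def event_probabilities(ps: ParameterSet, stratum: Stratum) -> np.ndarray:
    """Per-cycle disease-event probability of every state, for one stratum."""
    values = ps.values
    d = np.zeros(N_STATES)
    for i, pname in enumerate(_EVENT_PARAM):
        if pname is not None:
            d[i] = _lookup(values, pname, stratum.truth)
    d[S["PostRT_Remission"]] = _lookup(values, _relapse_param(stratum), stratum.truth)
    if np.any((d < 0) | (d > 1)):
        raise ParameterError(f"event probabilities out of [0, 1] for stratum {stratum}")
    return d


def build_transition_matrix(ps: ParameterSet, stratum: Stratum, age: float) -> np.ndarray:
    """One-cycle transition matrix for a stratum at a given attained age.

    Composition per living state s with background per-cycle mortality ``bg``
    and disease-event probability ``d_s``: P(s -> Dead_other) = bg,
    P(s -> successor) = (1 - bg) * d_s, P(s -> s) = (1 - bg) * (1 - d_s).
    Dead states are absorbing.  Rows sum to one by construction; a negative
    residual signals an inconsistent parameter set and raises.
    """
    if ps.life_table is None:
        raise ParameterError("ParameterSet has no life table attached")
    bg = annual_to_cycle_prob(ps.life_table.q(age), ps.settings.cycle_months)
    d = event_probabilities(ps, stratum)
    P = np.zeros((N_STATES, N_STATES))
    for s in range(N_STATES):
        if not LIVING[s]:
            P[s, s] = 1.0
            continue
        stay = (1.0 - bg) * (1.0 - d[s])
        if stay < -1e-12:
            raise ParameterError(f"negative residual self-transition in state {STATES[s]}")
        P[s, DEAD_OTHER] += bg
        P[s, SUCCESSOR_IDX[s]] += (1.0 - bg) * d[s]
        P[s, s] += stay
    rows = P.sum(axis=1)
    if np.any(np.abs(rows - 1.0) > 1e-10):
        raise ParameterError("transition-matrix rows do not sum to 1")
    return P


def discount_factor(cycle_index: int, cycle_years: float, rate: float) -> float:
    """(1 + rate)^(-cycle_index * cycle_years); equals 1 at cycle 0."""
    if rate < 0:
        raise ParameterError("discount rate must be nonnegative")
    return float((1.0 + rate) ** (-(cycle_index * cycle_years)))


@dataclass(frozen=True)
class CohortTrace:
    """Occupancy and discounted reward streams for one strategy.

    ``occupancy`` has ``n_cycles + 1`` rows: the cohort distribution at the
    start of each cycle, plus the terminal distribution.  Stream index k
    carries the state rewards accrued during cycle k plus any treatment
    initiation costs incurred on the transition landing at cycle k (the
    latter discounted at the end-of-cycle factor).  The upfront strategy cost
    sits undiscounted at index 0.
    """

    strategy: str
    ages: np.ndarray
    occupancy: np.ndarray
    discounted_cost_stream: np.ndarray
    discounted_qaly_stream: np.ndarray

    @property
    def total_cost(self) -> float:
        return float(self.discounted_cost_stream.sum())

    @property
    def total_qalys(self) -> float:
        return float(self.discounted_qaly_stream.sum())

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        df.insert(1, "age", self.ages)
        df["cycle_cost_disc"] = self.discounted_cost_stream
        df["cycle_qaly_disc"] = self.discounted_qaly_stream
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _profiles_of(alloc: EntryAllocation) -> tuple[list[Stratum], np.ndarray]:
    """Group the entry allocation into strata and their entry vectors."""
    groups: dict[Stratum, np.ndarray] = {}
    for (state, truth), f in alloc.fractions.items():
        covered = alloc.out_of_field_covered if truth == "early_out_of_field" else False
        key = Stratum(truth, covered)
        if key not in groups:
            groups[key] = np.zeros(N_STATES)
        if state not in S:
            raise ParameterError(f"unknown entry state {state!r}")
        groups[key][S[state]] += f
    strata = sorted(groups)
    return strata, np.array([groups[k] for k in strata])


def cycle_background_mortality(ps: ParameterSet) -> np.ndarray:
    """Per-cycle other-cause death probability for cycles 0..n_cycles-1."""
    st = ps.settings
    if ps.life_table is None:
        raise ParameterError("ParameterSet has no life table attached")
    ages = st.start_age + np.arange(st.n_cycles) * st.cycle_years
    return annual_to_cycle_prob(ps.life_table.q(ages), st.cycle_months)


def run_cohort(alloc: EntryAllocation, ps: ParameterSet) -> CohortTrace:
    """Propagate the cohort over the full horizon and accrue rewards.

    Per cycle k (k = 0..N-1): state rewards are occupancy x per-cycle cost
    and x utility x cycle length in years, discounted at the cycle-k factor
    (cycle-k+1 with ``rewards_at_cycle_end``; boundary-averaged occupancy
    with ``half_cycle_correction``).  Treatment-initiation costs attach to
    the transition's landing cycle, discounted there.
    """
    st = ps.settings
    ps.validate()
    n = st.n_cycles
    cy = st.cycle_years
    bg = cycle_background_mortality(ps)
    strata, occ = _profiles_of(alloc)  # occ: (P, n_states), mass-weighted
    D = np.array([event_probabilities(ps, s) for s in strata])

    values = ps.values
    cost_vec = np.array([values[p] if p else 0.0 for p in _STATE_COST_PARAM])
    util_vec = np.array([values[p] if p else 0.0 for p in _UTILITY_PARAM])
    entry_vec = np.zeros(N_STATES)
    for idx, pname in _ENTRY_COST_PARAM.items():
        entry_vec[idx] = values[pname]

    occupancy = np.zeros((n + 1, N_STATES))
    cost_stream = np.zeros(n + 1)
    qaly_stream = np.zeros(n + 1)
    bgv_mask = LIVING

    df_pow = (1.0 + st.discount_rate) ** (-cy)  # per-cycle discount multiplier
    df_k = 1.0

    for k in range(n):
        occupancy[k] = occ.sum(axis=0)
        bgv = bg[k] * bgv_mask
        surv = occ * (1.0 - bgv)
        moved = surv * D
        occ_next = surv - moved + moved @ _MOVE
        occ_next[:, DEAD_OTHER] += (occ * bgv).sum(axis=1)

        reward_occ = occupancy[k]
        if st.half_cycle_correction:
            reward_occ = 0.5 * (occupancy[k] + occ_next.sum(axis=0))
        df_next = df_k * df_pow
        df_reward = df_next if st.rewards_at_cycle_end else df_k
        cost_stream[k] += (reward_occ @ cost_vec) * df_reward
        qaly_stream[k] += (reward_occ @ util_vec) * cy * df_reward
        cost_stream[k + 1] += ((moved @ _MOVE).sum(axis=0) @ entry_vec) * df_next

        occ = occ_next
        df_k = df_next

    occupancy[n] = occ.sum(axis=0)
    cost_stream[0] += alloc.upfront_cost
    qaly_stream[0] += alloc.upfront_qaly_adjust

    sums = occupancy.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-9):
        raise ParameterError("cohort mass not conserved beyond tolerance")

    ages = st.start_age + np.arange(n + 1) * cy
    return CohortTrace(alloc.strategy, ages, occupancy, cost_stream, qaly_stream)
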