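"""Decision tree: entry-state allocation for the two staging strategies.

The modelled population is conventionally (CT-) staged early-stage follicular
lymphoma planned for curative-intent radiotherapy.  Underneath the CT stage,
each patient belongs to one of three *truth categories*: disease genuinely
confined to the planned RT field (``early_in_field``), early-stage disease
partly outside the planned field (``early_out_of_field``), or occult
advanced-stage disease (``advanced``).

The PET/CT arm resolves some of that truth before treatment, via two nested
chance nodes: with probability ``p_newfinding_adv`` the scan shows
advanced-stage disease (true positive with probability ``p_tp_adv``), and the
patient is diverted to noncurative management (rituximab monotherapy,
watchful waiting, palliative RT, or bendamustine-rituximab, in proportions
``p_rmono``/``p_ww``/``p_pallRT``/``p_BR``); otherwise, with probability
``p_newfinding_outfield`` the scan shows early-stage disease outside the
planned field (true positive with probability ``p_tp_outfield``) and the
field is enlarged; otherwise treatment proceeds as planned.

Both arms describe the same underlying population.  Assuming a near-perfect
false-negative rate for PET/CT in this disease, the truth prevalences are
derived from the PET-side parameters (finding probability x true-positive
probability) and applied identically — undetected — in the no-PET/CT arm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .params import ParameterError, ParameterSet, TRUTH_CATEGORIES

__all__ = [
    "EntryAllocation",
    "truth_prevalence",
    "allocate_no_petct",
    "allocate_petct",
]

_MASS_TOL = 1e-12

#: management-mix proportion -> entry state of the state-transition model
_MIX_STATES = {
    "p_rmono": "Adv_Rmono",
    "p_ww": "Adv_WW",
    "p_pallRT": "Adv_PallRT",
    "p_BR": "Adv_BR_line",
}

#: one-off cost incurred when a patient *starts* in the given state
_MIX_ENTRY_COST = {
    "Adv_Rmono": "c_rmono_course",
    "Adv_WW": None,
    "Adv_PallRT": "c_rt_palliative",
    "Adv_BR_line": "c_br_course",
}


@dataclass(frozen=True)
class EntryAllocation:
    """How one strategy distributes the cohort over entry states.

    ``fractions`` maps ``(entry state, truth category)`` to the fraction of
    the cohort starting there; the fractions sum to one.
    ``out_of_field_covered`` records whether, in this arm, the RT field of
    out-of-field-truth patients in remission covers their disease (true after
    PET/CT-guided field enlargement, false when staging stops at CT).
    ``upfront_cost`` bundles the strategy's diagnostics and first-line
    treatment initiation, charged undiscounted at cycle 0.
    """

    strategy: str
    fractions: dict[tuple[str, str], float]
    out_of_field_covered: bool
    upfront_cost: float
    upfront_qaly_adjust: float = 0.0

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > _MASS_TOL:
            raise ParameterError(f"{self.strategy}: entry fractions sum to {total!r}, not 1")
        if any(f < -_MASS_TOL for f in self.fractions.values()):
            raise ParameterError(f"{self.strategy}: negative entry fraction")
        if self.upfront_cost < 0:
            raise ParameterError(f"{self.strategy}: negative upfront cost")

    def truth_marginal(self) -> dict[str, float]:
        out = dict.fromkeys(TRUTH_CATEGORIES, 0.0)
        for (_, truth), f in self.fractions.items():
            out[truth] += f
        return out

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "out_of_field_covered": self.out_of_field_covered,
            "upfront_cost": self.upfront_cost,
            "upfront_qaly_adjust": self.upfront_qaly_adjust,
            "fractions": [
                {"state": s, "truth": t, "fraction": f}
                for (s, t), f in sorted(self.fractions.items())
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def _mix(ps: ParameterSet) -> dict[str, float]:
    mix = {name: ps[name] for name in _MIX_STATES}
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ParameterError(f"management mix sums to {total!r}, expected 1")
    return mix


def truth_prevalence(ps: ParameterSet) -> dict[str, float]:
    """Prevalence of the three truth categories in the staged population.

    Derived from the PET-side parameters under a sensitivity-of-one
    assumption: every truly advanced or out-of-field patient produces the
    corresponding PET/CT finding.  The chance nodes are nested (the
    out-of-field node is reached only without an advanced finding), so the
    prevalences are valid for any probabilities in [0, 1].
    """
    ps.validate()
    a = ps["p_newfinding_adv"] * ps["p_tp_adv"]
    o = (1.0 - ps["p_newfinding_adv"]) * ps["p_newfinding_outfield"] * ps["p_tp_outfield"]
    return {
        "early_in_field": 1.0 - a - o,
        "early_out_of_field": o,
        "advanced": a,
    }


def allocate_no_petct(ps: ParameterSet) -> EntryAllocation:
    """CT-only staging: everyone proceeds to planned curative-intent RT.

    The whole cohort enters post-RT remission, stratified by truth: in-field
    patients carry the curative relapse profile, out-of-field patients an
    elevated one (their disease was missed by the planned field), and
    advanced patients the no-curative-potential profile.  Upfront cost is the
    curative RT course; no scan, no biopsy.
    """
    prev = truth_prevalence(ps)
    fractions = {("PostRT_Remission", truth): p for truth, p in prev.items() if p > 0.0}
    if not fractions:  # all-zero prevalence cannot occur, but keep mass explicit
        fractions = {("PostRT_Remission", "early_in_field"): 1.0}
    return EntryAllocation(
        strategy="no_petct",
        fractions=fractions,
        out_of_field_covered=False,
        upfront_cost=ps["c_rt_curative"],
    )


def allocate_petct(ps: ParameterSet) -> EntryAllocation:
    """PET/CT staging: findings may divert or enlarge treatment.

    Branches: (i) advanced finding (``p_newfinding_adv``) -> the management
    mix, split into true positives (advanced truth) and false positives
    (in-field truth, managed noncuratively); (ii) otherwise an out-of-field
    finding (``p_newfinding_outfield``) -> enlarged-field curative RT, true
    positives now fully covered, false positives in-field truth; (iii)
    otherwise planned RT.  Upfront cost adds the scan for everyone, a biopsy
    for ``p_biopsy_on_new_finding`` of patients with any new finding, and the
    first-line treatment of each branch.  Enlarging the field carries no
    extra cost or QALY penalty by default.
    """
    ps.validate()
    a = ps["p_newfinding_adv"]
    o = (1.0 - a) * ps["p_newfinding_outfield"]
    tp_a, tp_o = ps["p_tp_adv"], ps["p_tp_outfield"]
    mix = _mix(ps)

    fractions: dict[tuple[str, str], float] = {}

    def add(state: str, truth: str, f: float) -> None:
        if f > 0.0:
            fractions[(state, truth)] = fractions.get((state, truth), 0.0) + f

    # branch (i): upstaged to advanced, managed per the mix
    for name, share in mix.items():
        add(_MIX_STATES[name], "advanced", a * share * tp_a)
        add(_MIX_STATES[name], "early_in_field", a * share * (1.0 - tp_a))
    # branch (ii): enlarged-field curative RT
    add("PostRT_Remission", "early_out_of_field", o * tp_o)
    add("PostRT_Remission", "early_in_field", o * (1.0 - tp_o))
    # branch (iii): treatment as planned
    add("PostRT_Remission", "early_in_field", 1.0 - a - o)
    if not fractions:
        fractions = {("PostRT_Remission", "early_in_field"): 1.0}

    mix_cost = sum(
        share * (ps[_MIX_ENTRY_COST[_MIX_STATES[name]]] if _MIX_ENTRY_COST[_MIX_STATES[name]] else 0.0)
        for name, share in mix.items()
    )
    upfront = (
        ps["c_petct"]
        + (a + o) * ps["p_biopsy_on_new_finding"] * ps["c_biopsy"]
        + (1.0 - a) * ps["c_rt_curative"]  # branches (ii) and (iii)
        + a * mix_cost
    )
    return EntryAllocation(
        strategy="petct",
        fractions=fractions,
        out_of_field_covered=True,
        upfront_cost=upfront,
    )
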