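"""Parameter schema, validation, PSA sampling, and synthetic reference inputs.

The model is driven by a :class:`ParameterSet`: a named collection of scalar
inputs (per-cycle transition probabilities, management-mix proportions,
health-state utilities, and unit costs in 2019 Canadian dollars), each with a
per-parameter uncertainty distribution used by the probabilistic sensitivity
analysis, plus the run settings (cohort start age, cycle length, horizon,
discount rate, willingness-to-pay threshold) and a life table of age-specific
background mortality.

Because the original supplementary parameter tables are not redistributed
here, :func:`generate_reference_parameters` builds a complete synthetic
reference set.  Values that are documented in the primary literature are
tagged ``[literature]`` in their ``source_note``; all other values are
plausible synthetic stand-ins tagged ``[synthetic]`` so the two are never
conflated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DistributionSpec",
    "Parameter",
    "Settings",
    "ParameterSet",
    "LifeTable",
    "REQUIRED_PARAMETERS",
    "TRUTH_CATEGORIES",
    "ParameterError",
    "load_parameters",
    "save_parameters",
    "sample_parameter_set",
    "generate_reference_parameters",
    "generate_synthetic_life_table",
    "annual_to_cycle_prob",
    "beta_from_mean_sd",
]


class ParameterError(ValueError):
    """Raised for schema, range, or completeness violations in model inputs."""


#: The three underlying disease-extent categories of a conventionally staged
#: early-stage cohort.  Used both by the decision tree and by the per-truth
#: override naming convention ``<parameter>__<truth>``.
TRUTH_CATEGORIES = ("early_in_field", "early_out_of_field", "advanced")

_ROLES = (
    "probability-per-cycle",
    "proportion",
    "diagnostic-probability",
    "utility",
    "cost-CAD-2019",
)
_UNIT_ROLES = frozenset(_ROLES[:4])  # roles whose values live in [0, 1]
_DIST_KINDS = ("fixed", "beta", "gamma", "uniform", "dirichlet-group")


@dataclass(frozen=True)
class DistributionSpec:
    """Uncertainty distribution attached to one parameter.

    ``params`` by kind: beta ``(alpha, beta)``; gamma ``(shape, scale)``;
    uniform ``(low, high)``; dirichlet-group ``(concentration,)`` with the
    group label in ``group``; fixed ``()``.
    """

    kind: str
    params: tuple[float, ...] = ()
    group: str | None = None

    def validate(self, name: str, role: str) -> None:
        if self.kind not in _DIST_KINDS:
            raise ParameterError(f"{name}: unknown distribution kind {self.kind!r}")
        p = self.params
        if self.kind == "fixed":
            return
        if self.kind == "beta":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise ParameterError(f"{name}: beta needs positive (alpha, beta), got {p}")
            if role not in _UNIT_ROLES:
                raise ParameterError(f"{name}: beta distribution on a non-[0,1] role {role!r}")
        elif self.kind == "gamma":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise ParameterError(f"{name}: gamma needs positive (shape, scale), got {p}")
            if role != "cost-CAD-2019":
                raise ParameterError(f"{name}: gamma distribution is reserved for cost parameters")
        elif self.kind == "uniform":
            if len(p) != 2 or p[0] > p[1]:
                raise ParameterError(f"{name}: uniform needs (low, high) with low <= high, got {p}")
            if role in _UNIT_ROLES and (p[0] < 0.0 or p[1] > 1.0):
                raise ParameterError(f"{name}: uniform support {p} outside [0, 1] for role {role!r}")
            if role == "cost-CAD-2019" and p[0] < 0.0:
                raise ParameterError(f"{name}: uniform support {p} allows negative costs")
        elif self.kind == "dirichlet-group":
            if self.group is None:
                raise ParameterError(f"{name}: dirichlet-group member without a group label")
            if len(p) != 1 or p[0] <= 0:
                raise ParameterError(f"{name}: dirichlet-group needs a positive concentration, got {p}")
            if role != "proportion":
                raise ParameterError(f"{name}: dirichlet-group is reserved for proportions")


@dataclass(frozen=True)
class Parameter:
    """One scalar model input with its uncertainty distribution."""

    name: str
    role: str
    base: float
    dist: DistributionSpec = DistributionSpec("fixed")
    source_note: str = ""

    def validate(self) -> None:
        if self.role not in _ROLES:
            raise ParameterError(f"{self.name}: unknown role {self.role!r}")
        if self.role in _UNIT_ROLES and not (0.0 <= self.base <= 1.0):
            raise ParameterError(
                f"{self.name}: value {self.base} out of range [0, 1] for role {self.role!r}"
            )
        if self.role == "cost-CAD-2019" and self.base < 0.0:
            raise ParameterError(f"{self.name}: cost {self.base} is negative")
        self.dist.validate(self.name, self.role)


@dataclass(frozen=True)
class Settings:
    """Run settings shared by every analysis stage.

    ``half_cycle_correction`` averages cycle-boundary occupancies when
    accruing rewards; ``rewards_at_cycle_end`` discounts the cycle-k reward
    with the end-of-cycle factor instead of the start-of-cycle one.  Both
    default to off.
    """

    start_age: float = 60.0
    cycle_months: float = 6.0
    horizon_years: float = 30.0
    discount_rate: float = 0.015
    wtp: float = 100_000.0
    half_cycle_correction: bool = False
    rewards_at_cycle_end: bool = False

    @property
    def cycle_years(self) -> float:
        return self.cycle_months / 12.0

    @property
    def n_cycles(self) -> int:
        n = self.horizon_years / self.cycle_years
        if abs(n - round(n)) > 1e-9:
            raise ParameterError(
                f"horizon of {self.horizon_years} y is not a whole number of "
                f"{self.cycle_months}-month cycles"
            )
        return int(round(n))

    def validate(self) -> None:
        if self.start_age < 0:
            raise ParameterError("start_age must be nonnegative")
        if self.cycle_months <= 0 or self.cycle_months > 12:
            raise ParameterError("cycle_months must lie in (0, 12]")
        if self.horizon_years <= 0:
            raise ParameterError("horizon_years must be positive")
        if self.discount_rate < 0:
            raise ParameterError("discount_rate must be nonnegative")
        if self.wtp < 0:
            raise ParameterError("wtp must be nonnegative")
        self.n_cycles  # divisibility check


# --------------------------------------------------------------------------
# Life table
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LifeTable:
    """Age (whole years) -> annual probability of death from other causes.

    Lookups clamp to the table's age range, so a cohort aged past the last
    row keeps the terminal mortality probability.
    """

    ages: np.ndarray
    annual_q: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        q = np.asarray(self.annual_q, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "annual_q", q)
        if ages.ndim != 1 or ages.shape != q.shape or ages.size == 0:
            raise ParameterError("life table needs matching 1-D age and probability columns")
        if np.any(np.diff(ages) != 1):
            raise ParameterError("life-table ages must be consecutive whole years")
        if np.any((q < 0) | (q > 1)):
            raise ParameterError("life-table probabilities must lie in [0, 1]")

    def q(self, age):
        """Annual other-cause mortality at ``floor(age)``, clamped to the table."""
        idx = np.clip(np.floor(np.asarray(age, dtype=float)).astype(int) - self.ages[0],
                      0, self.ages.size - 1)
        out = self.annual_q[idx]
        return float(out) if np.isscalar(age) or np.ndim(age) == 0 else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "annual_q": self.annual_q})

    def to_csv(self, path: str | Path) -> None:
        # .17g keeps the float round trip bit-exact
        self.to_frame().to_csv(path, index=False, float_format=lambda x: format(x, ".17g"))

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path, float_precision="round_trip")
        missing = {"age", "annual_q"} - set(df.columns)
        if missing:
            raise ParameterError(f"life table {path}: missing columns {sorted(missing)}")
        return cls(df["age"].to_numpy(), df["annual_q"].to_numpy())


def generate_synthetic_life_table(
    start_age: float = 60,
    end_age: float = 110,
    gompertz_params: tuple[float, float] = (0.008, math.log(2) / 7.5),
) -> LifeTable:
    """Gompertz-style synthetic background mortality.

    q(a) = min(1, b * exp(c * (a - start_age))) — an exponential rise in the
    annual death probability, the classical shape of adult all-cause
    mortality.  The defaults (b = 0.008 at age 60, doubling every 7.5 years)
    give hazards of the magnitude seen in recent national period life tables
    for a mixed-sex cohort.
    """
    b, c = gompertz_params
    if b <= 0:
        raise ParameterError("Gompertz rate at start_age must be positive")
    if c < 0:
        raise ParameterError("Gompertz slope must be nonnegative")
    if not start_age < end_age:
        raise ParameterError("start_age must be below end_age")
    ages = np.arange(int(start_age), int(end_age) + 1)
    q = np.minimum(1.0, b * np.exp(c * (ages - int(start_age))))
    return LifeTable(ages, q)


def annual_to_cycle_prob(q_annual, cycle_months: float = 6.0):
    """Convert an annual event probability to a per-cycle one.

    Uses the constant-hazard complement formula 1 - (1 - q)^(t/12), which
    composes exactly across cycles: two 6-month cycles reproduce the annual
    probability.
    """
    q = np.asarray(q_annual, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ParameterError(f"annual probability {q_annual} out of [0, 1]")
    if cycle_months <= 0:
        raise ParameterError("cycle_months must be positive")
    out = 1.0 - (1.0 - q) ** (cycle_months / 12.0)
    return float(out) if np.ndim(q_annual) == 0 else out


# --------------------------------------------------------------------------
# Required schema
# --------------------------------------------------------------------------

#: Every parameter the decision tree and cohort engine consume, with its role.
REQUIRED_PARAMETERS: dict[str, str] = {
    # diagnostic pathway
    "p_newfinding_adv": "diagnostic-probability",
    "p_newfinding_outfield": "diagnostic-probability",
    "p_tp_adv": "diagnostic-probability",
    "p_tp_outfield": "diagnostic-probability",
    "p_biopsy_on_new_finding": "proportion",
    # management mix after upstaging to advanced disease
    "p_rmono": "proportion",
    "p_ww": "proportion",
    "p_pallRT": "proportion",
    "p_BR": "proportion",
    # disease-course probabilities per 6-month cycle
    "p_relapse_rt_infield": "probability-per-cycle",
    "p_relapse_rt_outfield": "probability-per-cycle",
    "p_relapse_rt_advanced": "probability-per-cycle",
    "p_prog_rmono": "probability-per-cycle",
    "p_prog_ww": "probability-per-cycle",
    "p_prog_pallRT": "probability-per-cycle",
    "p_prog_br_firstline": "probability-per-cycle",
    "p_prog_br_maintenance": "probability-per-cycle",
    "p_prog_salvage1": "probability-per-cycle",
    "p_prog_salvage2": "probability-per-cycle",
    "p_prog_salvage3": "probability-per-cycle",
    "p_death_palliative": "probability-per-cycle",
    # utilities
    "u_first_remission": "utility",
    "u_adv_rmono": "utility",
    "u_adv_ww": "utility",
    "u_adv_pallRT": "utility",
    "u_adv_br": "utility",
    "u_br_maintenance": "utility",
    "u_salvage": "utility",
    "u_palliative": "utility",
    # unit costs, 2019 CAD
    "c_petct": "cost-CAD-2019",
    "c_biopsy": "cost-CAD-2019",
    "c_rt_curative": "cost-CAD-2019",
    "c_rt_palliative": "cost-CAD-2019",
    "c_rmono_course": "cost-CAD-2019",
    "c_br_course": "cost-CAD-2019",
    "c_salvage_course": "cost-CAD-2019",
    "c_followup_cycle": "cost-CAD-2019",
    "c_palliative_cycle": "cost-CAD-2019",
}


def _is_override_name(name: str) -> bool:
    if "__" not in name:
        return False
    stem, _, truth = name.rpartition("__")
    return stem in REQUIRED_PARAMETERS and truth in TRUTH_CATEGORIES


def is_known_name(name: str) -> bool:
    """A schema name: a required parameter or a per-truth override of one."""
    return name in REQUIRED_PARAMETERS or _is_override_name(name)


# --------------------------------------------------------------------------
# ParameterSet
# --------------------------------------------------------------------------


@dataclass
class ParameterSet:
    """A complete, validated set of model inputs plus run settings."""

    parameters: dict[str, Parameter]
    settings: Settings = field(default_factory=Settings)
    life_table: LifeTable | None = None

    @property
    def values(self) -> dict[str, float]:
        return {name: p.base for name, p in self.parameters.items()}

    @property
    def dists(self) -> dict[str, DistributionSpec]:
        return {name: p.dist for name, p in self.parameters.items()}

    def __getitem__(self, name: str) -> float:
        return self.parameters[name].base

    def __contains__(self, name: str) -> bool:
        return name in self.parameters

    def with_values(self, updates: Mapping[str, float]) -> "ParameterSet":
        """Return a copy with the given base values replaced (dists kept)."""
        params = dict(self.parameters)
        for name, value in updates.items():
            if name not in params:
                raise ParameterError(f"unknown parameter {name!r}")
            params[name] = replace(params[name], base=float(value))
        return ParameterSet(params, self.settings, self.life_table)

    def dirichlet_members(self, group: str) -> list[str]:
        return [n for n, p in self.parameters.items()
                if p.dist.kind == "dirichlet-group" and p.dist.group == group]

    def validate(self, require_complete: bool = True) -> None:
        unknown = [n for n in self.parameters if not is_known_name(n)]
        if unknown:
            raise ParameterError(f"unknown parameter names: {sorted(unknown)}")
        for name, p in self.parameters.items():
            if p.name != name:
                raise ParameterError(f"parameter keyed {name!r} is named {p.name!r}")
            p.validate()
        if require_complete:
            missing = [n for n in REQUIRED_PARAMETERS if n not in self.parameters]
            if missing:
                raise ParameterError(f"missing required parameters: {missing}")
            for name in self.parameters:
                want = REQUIRED_PARAMETERS.get(name.rpartition("__")[0] if _is_override_name(name)
                                               else name)
                if want is not None and self.parameters[name].role != want:
                    raise ParameterError(
                        f"{name}: role {self.parameters[name].role!r}, expected {want!r}"
                    )
            # the two nested chance nodes must be probabilities (guaranteed by
            # the range checks); dirichlet groups must sum to one
        groups: dict[str, float] = {}
        for p in self.parameters.values():
            if p.dist.kind == "dirichlet-group":
                groups[p.dist.group] = groups.get(p.dist.group, 0.0) + p.base
        for g, total in groups.items():
            if abs(total - 1.0) > 1e-9:
                raise ParameterError(f"dirichlet group {g!r} sums to {total!r}, expected 1")
        self.settings.validate()

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "settings": {
                "start_age": self.settings.start_age,
                "cycle_months": self.settings.cycle_months,
                "horizon_years": self.settings.horizon_years,
                "discount_rate": self.settings.discount_rate,
                "wtp": self.settings.wtp,
                "half_cycle_correction": self.settings.half_cycle_correction,
                "rewards_at_cycle_end": self.settings.rewards_at_cycle_end,
            },
            "parameters": [
                {
                    "name": p.name,
                    "role": p.role,
                    "base": p.base,
                    "dist": {
                        "kind": p.dist.kind,
                        "params": list(p.dist.params),
                        **({"group": p.dist.group} if p.dist.group else {}),
                    },
                    "source_note": p.source_note,
                }
                for p in self.parameters.values()
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping, life_table: LifeTable | None = None) -> "ParameterSet":
        if "parameters" not in data:
            raise ParameterError("parameter file lacks a 'parameters' section")
        try:
            settings = Settings(**data.get("settings", {}))
        except TypeError as exc:
            raise ParameterError(f"bad settings section: {exc}") from exc
        params: dict[str, Parameter] = {}
        for entry in data["parameters"]:
            try:
                dist_raw = entry.get("dist", {"kind": "fixed"})
                dist = DistributionSpec(
                    kind=dist_raw.get("kind", "fixed"),
                    params=tuple(float(x) for x in dist_raw.get("params", ())),
                    group=dist_raw.get("group"),
                )
                p = Parameter(
                    name=entry["name"],
                    role=entry["role"],
                    base=float(entry["base"]),
                    dist=dist,
                    source_note=entry.get("source_note", ""),
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise ParameterError(f"malformed parameter entry {entry!r}: {exc}") from exc
            if p.name in params:
                raise ParameterError(f"duplicate parameter {p.name!r}")
            params[p.name] = p
        ps = cls(params, settings, life_table)
        ps.validate()
        return ps


def _csv_to_dict(df: pd.DataFrame) -> dict:
    required_cols = {"name", "role", "base", "dist_kind"}
    missing = required_cols - set(df.columns)
    if missing:
        raise ParameterError(f"CSV parameter file missing columns {sorted(missing)}")
    entries = []
    for row in df.itertuples(index=False):
        params = [getattr(row, c) for c in ("dist_p1", "dist_p2") if hasattr(row, c)]
        params = [float(x) for x in params if pd.notna(x)]
        group = getattr(row, "group", None)
        note = getattr(row, "source_note", "")
        entries.append({
            "name": row.name, "role": row.role, "base": float(row.base),
            "dist": {"kind": row.dist_kind, "params": params,
                     **({"group": group} if isinstance(group, str) and group else {})},
            "source_note": note if isinstance(note, str) else "",
        })
    return {"parameters": entries}


def load_parameters(path: str | Path, fmt: str | None = None,
                    life_table: LifeTable | None = None) -> ParameterSet:
    """Load and validate a ParameterSet from JSON, YAML, or the CSV dialect."""
    path = Path(path)
    if fmt is None:
        fmt = {".json": "json", ".yaml": "yaml", ".yml": "yaml", ".csv": "csv"}.get(
            path.suffix.lower())
        if fmt is None:
            raise ParameterError(f"cannot infer format from suffix of {path}")
    if fmt == "json":
        data = json.loads(path.read_text())
    elif fmt == "yaml":
        data = yaml.safe_load(path.read_text())
    elif fmt == "csv":
        data = _csv_to_dict(pd.read_csv(path, float_precision="round_trip"))
    else:
        raise ParameterError(f"unknown parameter file format {fmt!r}")
    if not isinstance(data, Mapping):
        raise ParameterError(f"{path}: expected a mapping at top level")
    return ParameterSet.from_dict(data, life_table=life_table)


def save_parameters(ps: ParameterSet, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    if fmt is None:
        fmt = {".json": "json", ".yaml": "yaml", ".yml": "yaml", ".csv": "csv"}.get(
            path.suffix.lower())
        if fmt is None:
            raise ParameterError(f"cannot infer format from suffix of {path}")
    data = ps.to_dict()
    if fmt == "json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    elif fmt == "yaml":
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    elif fmt == "csv":
        rows = []
        for e in data["parameters"]:
            p = e["dist"]["params"]
            rows.append({
                "name": e["name"], "role": e["role"], "base": e["base"],
                "dist_kind": e["dist"]["kind"],
                "dist_p1": p[0] if len(p) > 0 else np.nan,
                "dist_p2": p[1] if len(p) > 1 else np.nan,
                "group": e["dist"].get("group", ""),
                "source_note": e["source_note"],
            })
        pd.DataFrame(rows).to_csv(path, index=False, float_format=lambda x: format(x, ".17g"))
    else:
        raise ParameterError(f"unknown parameter file format {fmt!r}")


# --------------------------------------------------------------------------
# PSA sampling
# --------------------------------------------------------------------------


def sample_parameter_set(ps: ParameterSet, seed) -> ParameterSet:
    """Draw one parameter set from the per-parameter distributions.

    Fixed parameters are unchanged; dirichlet-group members are drawn jointly
    and renormalized to sum to one; all other kinds are drawn independently.
    ``seed`` may be an int, a :class:`numpy.random.SeedSequence`, or a
    Generator; the same seed reproduces the draw exactly.
    """
    rng = np.random.default_rng(seed)
    updates: dict[str, float] = {}
    done_groups: set[str] = set()
    for name, p in ps.parameters.items():
        kind = p.dist.kind
        if kind == "fixed":
            continue
        if kind == "dirichlet-group":
            g = p.dist.group
            if g in done_groups:
                continue
            members = ps.dirichlet_members(g)
            alphas = np.array([ps.parameters[m].dist.params[0] for m in members])
            draw = rng.dirichlet(alphas)
            draw = draw / draw.sum()
            updates.update(zip(members, draw))
            done_groups.add(g)
        elif kind == "beta":
            updates[name] = float(rng.beta(*p.dist.params))
        elif kind == "gamma":
            updates[name] = float(rng.gamma(*p.dist.params))
        elif kind == "uniform":
            updates[name] = float(rng.uniform(*p.dist.params))
    out = ps.with_values(updates)
    out.validate(require_complete=False)
    return out


def beta_from_mean_sd(mean: float, sd: float) -> DistributionSpec:
    """Beta distribution moment-matched to a mean and standard deviation."""
    if not 0.0 < mean < 1.0:
        raise ParameterError(f"beta mean {mean} must lie strictly inside (0, 1)")
    var = min(sd * sd, 0.95 * mean * (1.0 - mean))
    if var <= 0:
        raise ParameterError("beta sd must be positive")
    nu = mean * (1.0 - mean) / var - 1.0
    return DistributionSpec("beta", (mean * nu, (1.0 - mean) * nu))


def _gamma_cv(base: float, cv: float = 0.25) -> DistributionSpec:
    shape = 1.0 / (cv * cv)
    return DistributionSpec("gamma", (shape, base / shape))


# --------------------------------------------------------------------------
# Synthetic reference set
# --------------------------------------------------------------------------


def generate_reference_parameters(seed: int | None = None) -> ParameterSet:
    """Build the synthetic reference ParameterSet (with its life table).

    The reference values are fixed constants, so the result is identical for
    every ``seed``; the argument exists for interface symmetry with the other
    generators.  Literature-documented values ([literature]) are: the biopsy
    proportion after a new finding (16%), the watchful-waiting (17.7%) and
    palliative-RT (5.6%) shares of the advanced-management mix, and the
    uniform distributions on the two true-positive probabilities
    (0.62-0.92 and 0.0-1.0).  Everything else is a plausible synthetic
    stand-in ([synthetic]) chosen once to be internally consistent with the
    qualitative behaviour reported for this treatment pathway.
    """
    del seed  # deterministic by design

    def par(name, base, dist, note):
        return Parameter(name, REQUIRED_PARAMETERS[name], base, dist, note)

    def beta_par(name, base, note="[synthetic]"):
        return par(name, base, beta_from_mean_sd(base, 0.1 * base), note)

    def cost_par(name, base, note="[synthetic]"):
        return par(name, base, _gamma_cv(base), note)

    def mix_par(name, base, note):
        return par(name, base,
                   DistributionSpec("dirichlet-group", (100.0 * base,), "management_mix"),
                   note)

    plist = [
        # diagnostic pathway -------------------------------------------------
        beta_par("p_newfinding_adv", 0.15,
                 "[synthetic] probability PET/CT reveals advanced-stage disease"),
        beta_par("p_newfinding_outfield", 0.06,
                 "[synthetic] probability PET/CT reveals early-stage disease outside "
                 "the planned RT field, given no advanced finding"),
        par("p_tp_adv", 10.0 / 13.0, DistributionSpec("uniform", (0.62, 0.92)),
            "[literature] true-positive probability of an advanced-stage finding; "
            "uniform 8/13..12/13"),
        par("p_tp_outfield", 1.0, DistributionSpec("uniform", (0.0, 1.0)),
            "[literature] true-positive probability of an out-of-field finding; "
            "uniform 0/6..6/6, base 6/6"),
        beta_par("p_biopsy_on_new_finding", 0.16,
                 "[literature] biopsy performed in ~16% of patients with new findings"),
        # management mix -----------------------------------------------------
        mix_par("p_rmono", 0.667, "[synthetic] residual of the literature mix shares"),
        mix_par("p_ww", 0.177, "[literature] watchful waiting share 17.7%"),
        mix_par("p_pallRT", 0.056, "[literature] palliative-intent RT share 5.6%"),
        mix_par("p_BR", 0.100, "[synthetic] bendamustine-rituximab share"),
        # disease course per 6-month cycle ------------------------------------
        beta_par("p_relapse_rt_infield", 0.035,
                 "[synthetic] relapse after curative RT with covered disease"),
        beta_par("p_relapse_rt_outfield", 0.10,
                 "[synthetic] relapse when disease lies outside the treated field"),
        beta_par("p_relapse_rt_advanced", 0.10,
                 "[synthetic] progression after curative-intent RT of truly advanced disease"),
        beta_par("p_prog_rmono", 0.03, "[synthetic] progression on rituximab monotherapy"),
        beta_par("p_prog_ww", 0.085, "[synthetic] progression under watchful waiting"),
        beta_par("p_prog_pallRT", 0.085, "[synthetic] progression after palliative RT"),
        beta_par("p_prog_br_firstline", 0.025, "[synthetic] progression on first-line BR"),
        beta_par("p_prog_br_maintenance", 0.035,
                 "[synthetic] progression on BR plus rituximab maintenance"),
        beta_par("p_prog_salvage1", 0.08, "[synthetic] progression on salvage line 1"),
        beta_par("p_prog_salvage2", 0.10, "[synthetic] progression on salvage line 2"),
        beta_par("p_prog_salvage3", 0.12, "[synthetic] progression on salvage line 3"),
        beta_par("p_death_palliative", 0.25, "[synthetic] lymphoma death in palliative care"),
        # utilities ------------------------------------------------------------
        beta_par("u_first_remission", 0.88, "[synthetic] first remission"),
        beta_par("u_adv_rmono", 0.80, "[synthetic] advanced disease on rituximab monotherapy"),
        beta_par("u_adv_ww", 0.80, "[synthetic] advanced disease under watchful waiting"),
        beta_par("u_adv_pallRT", 0.78, "[synthetic] advanced disease after palliative RT"),
        beta_par("u_adv_br", 0.74, "[synthetic] advanced disease on first-line BR"),
        beta_par("u_br_maintenance", 0.74, "[synthetic] BR plus maintenance after relapse"),
        beta_par("u_salvage", 0.68, "[synthetic] salvage chemotherapy"),
        beta_par("u_palliative", 0.55, "[synthetic] palliative state"),
        # unit costs, 2019 CAD -------------------------------------------------
        cost_par("c_petct", 1542.0, "[synthetic] PET/CT scan"),
        cost_par("c_biopsy", 900.0, "[synthetic] image-guided core biopsy"),
        cost_par("c_rt_curative", 12383.0, "[synthetic] 12-fraction IMRT course"),
        cost_par("c_rt_palliative", 2820.0, "[synthetic] 2-fraction palliative RT (4 Gy)"),
        cost_par("c_rmono_course", 22000.0, "[synthetic] rituximab monotherapy induction"),
        cost_par("c_br_course", 74000.0,
                 "[synthetic] bendamustine-rituximab plus rituximab maintenance"),
        cost_par("c_salvage_course", 31000.0, "[synthetic] one salvage chemotherapy line"),
        cost_par("c_followup_cycle", 250.0, "[synthetic] follow-up appointment per cycle"),
        cost_par("c_palliative_cycle", 6200.0, "[synthetic] palliative care per cycle"),
    ]
    ps = ParameterSet({p.name: p for p in plist}, Settings(),
                      generate_synthetic_life_table(60, 110))
    ps.validate()
    return ps
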