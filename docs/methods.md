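# Methods

This note records the model structure, the conventions the engine commits
to, the reasoning behind the synthetic reference inputs, and what the test
suite does and does not demonstrate.

## Population and decision problem

The cohort is 60-year-old patients with low-grade follicular lymphoma,
staged early (Ann Arbor I–II) on conventional CT and planned for
curative-intent radiotherapy (RT). Underneath that CT stage each patient
truly belongs to one of three categories: disease confined to the planned
RT field (`early_in_field`), early-stage disease partly outside the planned
field (`early_out_of_field`), or occult advanced disease (`advanced`). The
decision is whether to add a staging PET/CT before treatment.

## Decision tree

The PET/CT arm is two nested chance nodes:

1. with probability `p_newfinding_adv` the scan shows advanced disease; the
   patient moves to noncurative management, split over rituximab
   monotherapy / watchful waiting / palliative RT / bendamustine–rituximab
   (BR) by the management mix, and is a true positive with probability
   `p_tp_adv`;
2. otherwise, with probability `p_newfinding_outfield`, the scan shows
   early-stage disease outside the planned field; the field is enlarged
   (same RT course cost, no extra QALY penalty), a true positive with
   probability `p_tp_outfield`;
3. otherwise treatment proceeds as planned.

Nesting the second node under "no advanced finding" keeps every
(probability, probability) pair in the unit square admissible, which the
0–100 % one-way and two-way scans require; at realistic base values the
nesting correction `(1 - p_newfinding_adv)` is a second-order effect.

A biopsy cost applies to a fixed share (16 %) of *all* patients with a new
finding, in either branch. Biopsy contributes cost only: the model does not
re-route biopsy-identified false positives back to curative RT, since that
pathway is not well characterized — false-positive upstaged patients stay
on noncurative management, which is exactly the harm that makes the
advanced true-positive rate matter.

**Truth prevalence.** The tree is parameterized on the PET side, so the
underlying prevalences are derived assuming the scan's false-negative rate
is negligible in this disease: prevalence(advanced) =
`p_newfinding_adv * p_tp_adv`, prevalence(out-of-field) =
`(1 - p_newfinding_adv) * p_newfinding_outfield * p_tp_outfield`. The
no-PET/CT arm inherits the same prevalences undetected — everyone receives
the planned RT, with a relapse profile determined by their truth category.
Tests assert the truth marginal is identical across arms for any inputs.

## State space and transitions

Twelve states: `PostRT_Remission`, the four advanced-management states,
`BR_plus_maintenance` (first relapse, BR-naïve patients), `Salvage_1..3`,
`Palliative`, and the absorbing `Dead_lymphoma` / `Dead_other`. The disease
pathway is a chain — each living state has a single disease-event
successor: remission and the three non-BR management states relapse into
BR + maintenance; BR states progress into salvage; the third salvage line
exhausts into palliation; the palliative state carries a per-cycle lymphoma
death probability. Every living state therefore has a path to palliation
and to both deaths.

Cycles are 6 months (the natural unit of the published per-cycle
probabilities); the 30-year horizon gives 60 cycles. Per cycle and living
state, background mortality `bg` (life-table annual probability at the
floor of current age, converted by the constant-hazard complement
`1 - (1 - q)^(1/2)`) and the state's disease-event probability `d` compose
as independent competing risks with other-cause death taking precedence:
P(→Dead_other) = `bg`, P(→successor) = `(1 - bg)·d`, P(stay) =
`(1 - bg)·(1 - d)`. Rows sum to one by construction. Age advances 0.5 years
per cycle; life-table lookups clamp at the table ends.

Event probabilities are constant per state (no tunnel states), matching the
level of detail the published probabilities support. Transformation to
high-grade disease and hematopoietic cell transplantation are out of scope.

## Rewards, discounting, accounting

- State rewards for cycle k use the cycle-*start* occupancy, discounted at
  `(1 + r)^(-k/2)` with r = 1.5 %/year; cycle 0 is undiscounted.
- One-off treatment-initiation costs (BR course, each salvage line) attach
  to the transition's landing cycle and are discounted there.
- The strategy's upfront cost (diagnostics plus first-line treatment
  initiation from the tree) is charged undiscounted at cycle 0.
- Per-cycle state costs are a follow-up appointment for all living states
  except palliation, which carries a per-cycle palliative-care cost.
- No half-cycle correction by default; `Settings.half_cycle_correction`
  enables boundary-averaged rewards, and `Settings.rewards_at_cycle_end`
  shifts reward discounting by one cycle, so either convention of the
  original implementation can be reproduced. Both flags are off in every
  reported result, and the closed-form QALY tests pin the default exactly.

## Synthetic reference parameters

The reference set is a complete stand-in for the unpublished supplementary
tables. Values documented in the primary literature are used verbatim and
tagged `[literature]`: the watchful-waiting (17.7 %) and palliative-RT
(5.6 %) mix shares, the 16 % biopsy share, and the two true-positive
uncertainty distributions — uniform(0.62, 0.92) for advanced findings
(base 10/13) and uniform(0, 1) for out-of-field findings (base 6/6). All
other values are `[synthetic]`, chosen once by two rules and not revisited:

1. magnitudes a practitioner would recognize (e.g. ≈3.5 %/cycle relapse
   after curative RT, consistent with ~45 % 10-year event-free survival;
   progression slower on rituximab monotherapy than under watchful
   waiting; costs of the right order for Canadian RT courses, rituximab
   and BR programs);
2. consistency with the *direction* of every published one-way threshold
   (each base value lies on the reported preferred side of its threshold).

Under these inputs the base case reproduces the qualitative published
structure — PET/CT strongly dominant, preference robust except at extreme
mix shares, scan prices, or progression rates — but absolute costs, QALYs
and PSA proportions are illustrative, not a reproduction of the original
supplement-dependent numbers.

Uncertainty distributions follow field convention: beta for probabilities
and utilities (moment-matched, sd = 10 % of the mean, i.e. a ±20 % relative
range at ±2 sd); gamma for costs (CV 0.25); uniform only where the
literature states one; a Dirichlet over the 4-way management mix with
concentration 100 × share. PSA draws renormalize the mix exactly to one.

The synthetic life table is Gompertz: q(a) = min(1, 0.008·e^{(ln2/7.5)(a−60)}),
ages 60–110 — annual other-cause mortality of 0.8 % at 60 doubling every
7.5 years, the magnitude of recent national period life tables for a
mixed-sex cohort. It emulates only smooth adult mortality; cause
elimination, cohort effects and sex stratification are absent, so tests
passing under it say nothing about those features of real tables (any real
table can be supplied as a 2-column CSV).

## Sensitivity analyses

One-way scans use the published convention: probabilities and proportions
over 0–100 %, utilities 0–1, costs $0–500,000. Varying one management-mix
member rescales the others proportionally so the mix stays normalized
(equal split of the remainder when the others are at zero). Thresholds are
located on a 101-point pre-scan (to catch multiple crossings — NMB need not
be monotone in every parameter) followed by bisection to |NMB| < $0.001 or
100 iterations. The two-way frontier evaluates the NMB sign on a grid
(default 51×51) over the two new-finding probabilities. Tornado spreads are
|NMB(high) − NMB(low)| with alphabetical tie-breaking, so the ranking is
order-independent.

## Probabilistic sensitivity analysis

Parameters are sampled independently (apart from the joint Dirichlet mix) —
no correlation structure is imposed. Per-draw seeds are spawned from a
counter-based `SeedSequence`, so draw *i* is reproducible irrespective of
evaluation order. Two cost-effectiveness summaries are exposed: the CEAC
rule (NMB > 0) and the headline rule (cost-saving, or ICER below λ in the
NE quadrant). They differ only for cost-saving draws whose QALY loss is
worth more than the saving; both are reported so neither is silently
preferred. Dominance ties at exactly zero increments classify as a tie, to
favour neither strategy.

## Microsimulation oracle

The individual-patient simulator consumes the same per-cycle probabilities
and reward vectors as the cohort engine, isolating the propagation logic as
the tested difference (closed-form matrix examples cover the matrix-build
step separately). The strategy's upfront cost is a tree-level expectation
and is added to every patient as a constant, so it contributes no variance.
Agreement is asserted within 3 standard errors at 50,000 patients across
random parameter sets, and the cycle-wise state histogram converges to the
cohort occupancy (total-variation distance < 0.02 at 100,000 patients).

## Numerical conventions and problem sizes

- Mass conservation is enforced to 1e-9 per cycle; entry allocations to
  1e-12; Dirichlet base sums to 1e-9.
- Float serialization is round-trip exact in all three formats (`.17g`
  CSV writing, round-trip float parsing).
- Degenerate inputs: zero-probability branches are dropped from
  allocations; a zero-width bisection bracket returns the endpoint; the
  all-fixed PSA collapses to the base case by construction.
- Reported runs use 60 cycles, 101-point threshold pre-scans, 51×51
  two-way grids, 10,000 PSA draws, and 50,000-patient microsimulations;
  test batches are smaller (e.g. 2×2,500-draw PSA batches for the Monte
  Carlo error check, with the variance of a difference of proportions).

## Known limitations

- Absolute results under the synthetic reference set are illustrative;
  real analyses require transcribing the original parameter tables into
  the documented file format.
- Constant per-state hazards (no time-in-state dependence), no disease
  transformation, no transplantation, exactly two strategies.
- Utilities are state-based, not truth-based; false-positive upstaged
  patients can be given distinct disease-course parameters via
  `<name>__<truth>` overrides, but default to the advanced-management
  values.
- The QALY-monotonicity of progression probabilities holds when state
  utilities are nonincreasing along the disease pathway (true of the
  reference set); it is not a theorem for arbitrary utility orderings.
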