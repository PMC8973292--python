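# flcea

A cost-utility decision model of **PET/CT staging in early-stage follicular
lymphoma (FL)**, from the perspective of a single-payer health-care system.

Early-stage (Ann Arbor I–II) FL is potentially curable with definitive
radiotherapy (RT), while advanced-stage FL is indolent but incurable.
Staging with CT alone misses occult advanced disease and disease outside the
planned RT field; adding PET/CT can divert truly advanced patients to
noncurative management (rituximab monotherapy, watchful waiting, palliative
RT, or bendamustine–rituximab) and can enlarge the RT field to cover
out-of-field disease. `flcea` quantifies what that information is worth: it
simulates both staging strategies through a decision tree feeding a 6-month-
cycle state-transition (Markov) cohort model over a 30-year horizon, and
reports lifetime costs (2019 CAD), quality-adjusted life years (QALYs), and
the usual decision metrics. It is written for health-economics and
radiation-oncology researchers who want a transparent, fully scriptable
version of such a model.

## The model in brief

For strategies *s* ∈ {PET/CT, no-PET/CT} the engine computes discounted
expected cost *C_s* and effectiveness *E_s* (QALYs) and summarizes

- incremental cost and effect: ΔC = C_PET − C_noPET, ΔE = E_PET − E_noPET,
- the ICER ΔC/ΔE when the signs indicate a trade-off (a dominance label
  otherwise),
- the net monetary benefit at willingness-to-pay λ: **NMB = λ·ΔE − ΔC**,
  with λ = $100,000/QALY by default.

QALYs and costs are discounted at 1.5 %/year; the cohort starts at age 60
and background mortality comes from a life table (a Gompertz-style synthetic
table is generated when real national tables are not at hand). Sensitivity
machinery includes one-way NMB curves with automatic threshold detection
(bisection), tornado ranking, a two-way preferred-strategy frontier over the
two PET/CT new-finding probabilities, a 10,000-draw probabilistic
sensitivity analysis (PSA) with cost-effectiveness acceptability curve, and
an individual-patient microsimulation that cross-checks the cohort engine.

Because the original model's full parameter tables are not redistributed,
the package ships a *synthetic reference parameter set*
(`generate_reference_parameters()`): every literature-documented value is
tagged `[literature]` in its `source_note`, every stand-in `[synthetic]`.
Absolute results under the reference set are therefore illustrative; the
pipeline accepts transcribed parameter files (YAML/JSON/CSV) for real
analyses.

## Worked example

```python
from flcea import generate_reference_parameters, run_base_case, find_threshold

ps = generate_reference_parameters(0)
res = run_base_case(ps)
print(res.to_dict())
```

prints (reference set, full precision abbreviated):

```
no_petct : cost $101,056.19, 14.1171 QALYs
petct    : cost  $98,810.70, 14.1741 QALYs
delta_cost = -2245.48   delta_qaly = 0.0570
classification = strongly_dominant   icer = dominant   nmb = 7950.12
```

PET/CT staging is *strongly dominant* here: it saves about $2,245 per
patient over a lifetime **and** adds 0.057 QALYs, so no price per QALY needs
to be paid — the NMB of ≈ $7,950 at λ = $100,000/QALY is the monetized
value of adding the scan. A threshold search on the scan price,

```python
find_threshold(ps, "c_petct").thresholds   # -> (9492.1,)
```

shows the conclusion flips only if a PET/CT scan cost more than ≈ $9,492 —
several times its actual price.

The same pipeline is available from the shell:

```bash
flcea make-reference --seed 1 --out ref/
flcea basecase --params ref/params.yaml --lifetable ref/lifetable.csv --out results.json
flcea owsa --params ref/params.yaml --lifetable ref/lifetable.csv --param c_petct --out curve.csv
flcea psa  --params ref/params.yaml --lifetable ref/lifetable.csv --n 10000 --seed 1 --out-dir psa/
```

with `--set name=value` overrides for single-parameter scenarios.

## Layout

- `src/flcea/params.py` — parameter schema, distributions, sampling, synthetic reference set, life table
- `src/flcea/tree.py` — decision tree and entry-state allocation
- `src/flcea/cohort.py` — state-transition cohort engine
- `src/flcea/cea.py` — ICER, dominance, NMB
- `src/flcea/sensitivity.py` — one-way / two-way / tornado analyses
- `src/flcea/psa.py` — probabilistic sensitivity analysis and CEAC
- `src/flcea/microsim.py` — individual-patient simulation oracle
- `src/flcea/cli.py` — `flcea` command-line interface
- `docs/methods.md` — modelling assumptions, conventions, and limitations
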