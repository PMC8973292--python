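from dataclasses import replace

import numpy as np
import pytest
from hypothesis import settings as hyp_settings

from flcea import (
    DistributionSpec,
    LifeTable,
    ParameterSet,
    Settings,
    generate_reference_parameters,
    sample_parameter_set,
)

hyp_settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
hyp_settings.load_profile("suite")


@pytest.fixture(scope="session")
def ref_ps() -> ParameterSet:
    return generate_reference_parameters(0)


@pytest.fixture(scope="session")
def sampled_sets(ref_ps):
    """Ten parameter sets drawn from the reference distributions."""
    children = np.random.SeedSequence(2024).spawn(10)
    return [sample_parameter_set(ref_ps, c) for c in children]


def make_degenerate_ps(ref_ps, *, utility=1.0, discount=0.0, background_q=0.0,
                       costs=0.0, **extra):
    """A single-absorbing-living-state model for closed-form checks.

    No findings (everyone enters post-RT remission in-field), no disease
    events, no background mortality, uniform utilities, zero costs.
    """
    updates = {}
    for name, p in ref_ps.parameters.items():
        if p.role == "probability-per-cycle":
            updates[name] = 0.0
        elif p.role == "utility":
            updates[name] = utility
        elif p.role == "cost-CAD-2019":
            updates[name] = costs
    updates.update(p_newfinding_adv=0.0, p_newfinding_outfield=0.0)
    updates.update(extra)
    ps = ref_ps.with_values(updates)
    lt = ref_ps.life_table
    return ParameterSet(
        ps.parameters,
        replace(ref_ps.settings, discount_rate=discount),
        LifeTable(lt.ages, np.full(lt.ages.size, background_q)),
    )


def all_fixed(ps: ParameterSet) -> ParameterSet:
    """Replace every distribution by 'fixed' (degenerate PSA)."""
    params = {n: replace(p, dist=DistributionSpec("fixed")) for n, p in ps.parameters.items()}
    return ParameterSet(params, ps.settings, ps.life_table)
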