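import numpy as np
import pytest

from conftest import make_degenerate_ps
from flcea import (
    STATES,
    Stratum,
    allocate_no_petct,
    allocate_petct,
    build_transition_matrix,
    discount_factor,
    run_cohort,
)
from flcea.cohort import (
    DEAD_OTHER,
    LIVING,
    S,
    SUCCESSOR_IDX,
    cycle_background_mortality,
    event_probabilities,
)

IN_FIELD = Stratum("early_in_field", False)


class TestTransitionMatrix:
    def test_identity_when_no_events_and_no_mortality(self, ref_ps):
        ps = make_degenerate_ps(ref_ps)
        P = build_transition_matrix(ps, IN_FIELD, 65)
        assert np.allclose(P, np.eye(len(STATES)))

    def test_certain_background_mortality_sends_living_to_dead_other(self, ref_ps):
        ps = make_degenerate_ps(ref_ps, background_q=1.0)
        P = build_transition_matrix(ps, IN_FIELD, 70)
        for s, name in enumerate(STATES):
            if LIVING[s]:
                assert P[s, DEAD_OTHER] == pytest.approx(1.0)

    def test_independent_competing_risk_composition(self, ref_ps):
        # progression 0.1/cycle with per-cycle background 0.02:
        # P(stay) = 0.9 * 0.98 = 0.882
        annual = 1 - (1 - 0.02) ** 2  # annual prob whose 6-mo conversion is 0.02
        ps = make_degenerate_ps(ref_ps, background_q=annual,
                                p_prog_rmono=0.1)
        P = build_transition_matrix(ps, IN_FIELD, 60)
        i = S["Adv_Rmono"]
        assert P[i, i] == pytest.approx(0.882, abs=1e-12)
        assert P[i, SUCCESSOR_IDX[i]] == pytest.approx(0.98 * 0.1, abs=1e-12)
        assert P[i, DEAD_OTHER] == pytest.approx(0.02, abs=1e-12)

    def test_rows_sum_to_one_and_respect_successor_mask(self, sampled_sets):
        for ps in sampled_sets[:3]:
            for truth in ("early_in_field", "early_out_of_field", "advanced"):
                P = build_transition_matrix(ps, Stratum(truth, False), 72)
                assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
                for s in range(len(STATES)):
                    allowed = {s, DEAD_OTHER, int(SUCCESSOR_IDX[s])}
                    assert all(P[s, j] == 0.0 for j in range(len(STATES)) if j not in allowed)

    def test_dead_states_absorbing(self, ref_ps):
        P = build_transition_matrix(ref_ps, IN_FIELD, 80)
        for name in ("Dead_lymphoma", "Dead_other"):
            row = P[S[name]]
            assert row[S[name]] == 1.0 and row.sum() == 1.0

    def test_stratum_selects_relapse_profile(self, ref_ps):
        i = S["PostRT_Remission"]
        d_in = event_probabilities(ref_ps, Stratum("early_in_field", False))[i]
        d_out = event_probabilities(ref_ps, Stratum("early_out_of_field", False))[i]
        d_cov = event_probabilities(ref_ps, Stratum("early_out_of_field", True))[i]
        d_adv = event_probabilities(ref_ps, Stratum("advanced", False))[i]
        assert d_in == ref_ps["p_relapse_rt_infield"]
        assert d_out == ref_ps["p_relapse_rt_outfield"]
        assert d_cov == ref_ps["p_relapse_rt_infield"]
        assert d_adv == ref_ps["p_relapse_rt_advanced"]

    def test_per_truth_override_changes_one_stratum_only(self, ref_ps):
        from flcea.params import Parameter

        params = dict(ref_ps.parameters)
        params["p_prog_rmono__early_in_field"] = Parameter(
            "p_prog_rmono__early_in_field", "probability-per-cycle", 0.2)
        ps = type(ref_ps)(params, ref_ps.settings, ref_ps.life_table)
        ps.validate()
        i = S["Adv_Rmono"]
        assert event_probabilities(ps, Stratum("early_in_field", False))[i] == 0.2
        assert event_probabilities(ps, Stratum("advanced", False))[i] == ref_ps["p_prog_rmono"]


class TestDiscountFactor:
    def test_zero_rate_is_unity(self):
        assert discount_factor(17, 0.5, 0.0) == 1.0

    def test_closed_form_value(self):
        assert discount_factor(2, 0.5, 0.015) == pytest.approx(1 / 1.015, rel=1e-12)

    def test_strictly_decreasing_in_cycle(self):
        f = [discount_factor(k, 0.5, 0.015) for k in range(10)]
        assert all(b < a for a, b in zip(f, f[1:]))


class TestCohortEngine:
    def test_undiscounted_single_state_accrues_horizon_qalys(self, ref_ps):
        ps = make_degenerate_ps(ref_ps, discount=0.0)
        trace = run_cohort(allocate_no_petct(ps), ps)
        assert trace.total_qalys == pytest.approx(30.0, abs=1e-9)
        assert trace.total_cost == pytest.approx(0.0, abs=1e-12)

    def test_discounted_single_state_matches_geometric_series(self, ref_ps):
        ps = make_degenerate_ps(ref_ps, discount=0.015)
        trace = run_cohort(allocate_no_petct(ps), ps)
        expected = sum(0.5 * 1.015 ** (-0.5 * k) for k in range(60))
        assert trace.total_qalys == pytest.approx(expected, abs=1e-9)

    def test_zero_utilities_give_zero_qalys(self, ref_ps):
        ps = make_degenerate_ps(ref_ps, utility=0.0, costs=100.0,
                                p_prog_ww=0.3, background_q=0.1)
        trace = run_cohort(allocate_no_petct(ps), ps)
        assert trace.total_qalys == 0.0
        assert trace.total_cost > 0.0

    def test_mass_conservation_and_monotone_living_mass(self, ref_ps):
        for alloc in (allocate_no_petct(ref_ps), allocate_petct(ref_ps)):
            trace = run_cohort(alloc, ref_ps)
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
            living = trace.occupancy[:, LIVING.astype(bool)].sum(axis=1)
            assert np.all(np.diff(living) <= 1e-12)

    def test_discounting_never_increases_totals(self, ref_ps):
        alloc = allocate_petct(ref_ps)
        disc = run_cohort(alloc, ref_ps)
        from dataclasses import replace

        ps0 = type(ref_ps)(ref_ps.parameters, replace(ref_ps.settings, discount_rate=0.0),
                           ref_ps.life_table)
        undisc = run_cohort(allocate_petct(ps0), ps0)
        assert disc.total_qalys < undisc.total_qalys
        assert disc.total_cost < undisc.total_cost

    def test_matches_explicit_matrix_propagation(self, sampled_sets):
        # the vectorized engine must reproduce per-cycle matrix products
        ps = sampled_sets[0]
        alloc = allocate_petct(ps)
        trace = run_cohort(alloc, ps)
        from flcea.cohort import _profiles_of

        strata, occ = _profiles_of(alloc)
        st = ps.settings
        for k in range(st.n_cycles):
            age = st.start_age + k * st.cycle_years
            occ = np.array([
                occ[i] @ build_transition_matrix(ps, strata[i], age)
                for i in range(len(strata))
            ])
            assert np.allclose(occ.sum(axis=0), trace.occupancy[k + 1], atol=1e-12)

    def test_qalys_bounded_by_discounted_life_expectancy(self, sampled_sets):
        for ps in sampled_sets:
            trace = run_cohort(allocate_petct(ps), ps)
            util1 = ps.with_values({n: 1.0 for n, p in ps.parameters.items()
                                    if p.role == "utility"})
            ref_trace = run_cohort(allocate_petct(util1), util1)
            assert trace.total_qalys <= ref_trace.total_qalys + 1e-9

    def test_raising_progression_does_not_increase_qalys(self, ref_ps):
        base = run_cohort(allocate_petct(ref_ps), ref_ps).total_qalys
        for name, p in ref_ps.parameters.items():
            if p.role != "probability-per-cycle":
                continue
            bumped = ref_ps.with_values({name: min(1.0, p.base * 1.5)})
            assert run_cohort(allocate_petct(bumped), bumped).total_qalys <= base + 1e-9

    def test_background_hazard_nondecreasing_with_age(self, ref_ps):
        bg = cycle_background_mortality(ref_ps)
        assert np.all(np.diff(bg) >= 0)

    def test_half_cycle_correction_shrinks_qalys(self, ref_ps):
        from dataclasses import replace

        hcc = type(ref_ps)(ref_ps.parameters,
                           replace(ref_ps.settings, half_cycle_correction=True),
                           ref_ps.life_table)
        # rewards average the start and end occupancy of each cycle; with a
        # shrinking living cohort that can only lower the QALY total
        q_hcc = run_cohort(allocate_petct(hcc), hcc).total_qalys
        q_std = run_cohort(allocate_petct(ref_ps), ref_ps).total_qalys
        assert q_hcc < q_std

    def test_trace_export_columns(self, ref_ps, tmp_path):
        trace = run_cohort(allocate_no_petct(ref_ps), ref_ps)
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns[:2]) == ["cycle", "age"]
        assert set(STATES) <= set(df.columns)
        assert {"cycle_cost_disc", "cycle_qaly_disc"} <= set(df.columns)
        assert df["cycle_qaly_disc"].sum() == pytest.approx(trace.total_qalys)
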