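import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cvdms.estimation import TransitionProbs
from cvdms.markov import (
    conditional_tle,
    first_passage_onset,
    lifetime_risk,
    mean_onset_age,
    metrics_row,
    microsim_metrics,
    occupancy_forward,
    state_expectancies,
)
from cvdms.states import CVD, DEAD, FREE


def chain(p_fc=0.0, p_fd=0.0, p_cd=0.0):
    return TransitionProbs.constant(p_fc, p_fd, p_cd)


class TestOccupancyForward:
    def test_identity_chain_stays_free_forever(self):
        occ = occupancy_forward(chain())
        assert (occ.occupancy(FREE) == 1.0).all()

    def test_certain_death_from_cvd_absorbs_next_step(self):
        occ = occupancy_forward(chain(p_cd=1.0), start_state=CVD, start_age=480)
        assert occ.occupancy(DEAD)[0] == 0.0
        assert (occ.occupancy(DEAD)[1:] == 1.0).all()

    def test_geometric_free_occupancy(self):
        occ = occupancy_forward(chain(p_fc=0.02, p_fd=0.01))
        # constant stay probability 0.97: closed form after 10 steps
        assert occ.occupancy(FREE)[10] == pytest.approx(0.97**10, abs=1e-12)
        assert occ.occupancy(FREE)[10] == pytest.approx(0.73742, abs=5e-6)

    def test_dead_occupancy_is_monotone_and_rows_normalized(self, baseline_probs):
        occ = occupancy_forward(baseline_probs)
        assert (np.diff(occ.occupancy(DEAD)) >= -1e-15).all()
        assert np.max(np.abs(occ.probs.sum(axis=1) - 1.0)) < 1e-12

    def test_off_grid_or_terminal_start_age_rejected(self):
        with pytest.raises(ValueError):
            occupancy_forward(chain(), start_age=481)
        with pytest.raises(ValueError):
            occupancy_forward(chain(), start_age=1200)

    def test_mid_grid_start(self):
        occ = occupancy_forward(chain(p_fd=0.5), start_age=780)
        assert len(occ.ages) == 141
        assert occ.occupancy(FREE)[1] == pytest.approx(0.5)


class TestLifetimeRisk:
    def test_zero_incidence_gives_zero(self):
        assert lifetime_risk(chain(p_fd=0.01)) == 0.0

    def test_certain_first_interval_onset_gives_one(self):
        assert lifetime_risk(chain(p_fc=1.0)) == pytest.approx(1.0, abs=1e-15)

    def test_truncated_geometric_closed_form(self):
        # p_onset=0.02, p_death=0.01 per step over 240 intervals
        expected = 0.02 * (1 - 0.97**240) / 0.03
        assert lifetime_risk(chain(0.02, 0.01)) == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(0.6662, abs=5e-5)

    def test_accounting_identity_with_death_and_survival(self, baseline_probs):
        occ = occupancy_forward(baseline_probs)
        still_free = occ.occupancy(FREE)[:-1]
        die_free = float((still_free * baseline_probs.prob(FREE, DEAD)).sum())
        alive_free_end = occ.occupancy(FREE)[-1]
        total = lifetime_risk(baseline_probs) + die_free + alive_free_end
        assert total == pytest.approx(1.0, abs=1e-12)


class TestMeanOnsetAge:
    def test_single_interval_onset_lands_on_destination_grid_point(self):
        tp = chain()
        arr = tp.array.copy()
        arr[0, 0] = [0.0, 1.0, 0.0]  # onset certain in the first interval
        tp = TransitionProbs(arr, tp.ages, tp.period, tp.subgroup)
        assert mean_onset_age(tp) == pytest.approx(483 / 12.0, abs=1e-12)
        assert mean_onset_age(tp) == pytest.approx(40.25)

    def test_zero_incidence_returns_nan_with_warning(self):
        with pytest.warns(RuntimeWarning, match="undefined"):
            assert np.isnan(mean_onset_age(chain(p_fd=0.01)))

    def test_matches_brute_force_first_passage_summation(self):
        tp = chain(0.02, 0.01)
        # independent oracle: enumerate the 240 first-passage intervals
        num = den = 0.0
        surv = 1.0
        for t in range(240):
            mass = surv * 0.02
            num += mass * (480 + 3 * (t + 1)) / 12.0
            den += mass
            surv *= 0.97
        assert mean_onset_age(tp) == pytest.approx(num / den, abs=1e-10)
        # mean onset sits ~33 quarters after age 40 for this chain
        assert num / den == pytest.approx(48.29, abs=0.01)

    def test_first_passage_mass_equals_lifetime_risk(self, baseline_probs):
        fp = first_passage_onset(baseline_probs)
        assert fp.total_mass == pytest.approx(lifetime_risk(baseline_probs), abs=1e-14)
        assert 0.0 <= fp.total_mass <= 1.0


class TestStateExpectancies:
    def test_deathless_chain_exposes_truncation_at_sixty_years(self):
        e_free, e_cvd, tle, pct = state_expectancies(chain())
        assert tle == 60.0
        assert e_free == 60.0 and e_cvd == 0.0 and pct == 100.0

    def test_geometric_survival_closed_form(self):
        _, _, tle, _ = state_expectancies(chain(p_fd=0.01))
        expected = 0.25 * (1 - 0.99**240) / 0.01
        assert tle == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(22.76, abs=5e-3)

    def test_additivity_of_expectancies(self, baseline_probs):
        e_free, e_cvd, tle, _ = state_expectancies(baseline_probs)
        assert e_free + e_cvd - tle == pytest.approx(0.0, abs=1e-9)


class TestConditionalTle:
    def test_deathless_chain_gives_thirty_five_years(self):
        assert conditional_tle(chain()) == 35.0

    def test_immediate_absorption_leaves_quarter_year(self):
        assert conditional_tle(chain(p_cd=1.0)) == 0.25

    def test_geometric_closed_form(self):
        expected = 0.25 * (1 - 0.95**140) / 0.05
        assert conditional_tle(chain(p_cd=0.05)) == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(5.00, abs=5e-3)


class TestMonotonicity:
    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        p_fc=st.floats(0.001, 0.05),
        p_fd=st.floats(0.001, 0.05),
        p_cd=st.floats(0.001, 0.1),
        bump=st.floats(0.001, 0.05),
    )
    def test_raising_incidence_never_lowers_lifetime_risk(self, p_fc, p_fd, p_cd, bump):
        base = lifetime_risk(chain(p_fc, p_fd, p_cd))
        more = lifetime_risk(chain(p_fc + bump, p_fd, p_cd))
        assert more >= base - 1e-12

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        p_fc=st.floats(0.001, 0.05),
        p_fd=st.floats(0.001, 0.05),
        p_cd=st.floats(0.001, 0.1),
        bump=st.floats(0.001, 0.05),
    )
    def test_raising_mortality_never_raises_tle(self, p_fc, p_fd, p_cd, bump):
        _, _, base, _ = state_expectancies(chain(p_fc, p_fd, p_cd))
        _, _, worse, _ = state_expectancies(chain(p_fc, p_fd + bump, p_cd + bump))
        assert worse <= base + 1e-12


class TestMicrosimMetrics:
    def test_zero_incidence_scenario_has_zero_empirical_risk(self):
        with pytest.warns(RuntimeWarning, match="no simulated onsets"):
            row = microsim_metrics(chain(p_fd=0.02, p_cd=0.02), n=500, seed=3)
        assert row.lifetime_risk == 0.0

    def test_same_seed_reproduces_identical_row(self, baseline_probs):
        a = microsim_metrics(baseline_probs, n=2_000, seed=8)
        b = microsim_metrics(baseline_probs, n=2_000, seed=8)
        assert a.to_dict() == b.to_dict()

    def test_zero_trajectories_rejected(self, baseline_probs):
        with pytest.raises(ValueError):
            microsim_metrics(baseline_probs, n=0, seed=1)

    def test_matrix_and_microsim_agree_on_baseline(self, baseline_probs):
        exact = metrics_row(baseline_probs)
        sim = microsim_metrics(baseline_probs, n=30_000, seed=4)
        for name in ("lifetime_risk", "onset_age_mean", "e_free", "e_cvd", "tle",
                     "tle65_cvd"):
            delta = abs(getattr(sim, name) - getattr(exact, name))
            assert delta < 3 * sim.se[name], name
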