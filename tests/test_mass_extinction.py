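"""Mass-extinction perturbation: schedules, closed form, trajectories."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microdiv.core import BirthDeathModel, DiversificationParams, expected_richness
from microdiv.mass_extinction import (
    DEFAULT_EVENTS,
    ExtinctionEvent,
    ExtinctionSchedule,
    MassExtinctionModel,
    clade_vulnerability_scenario,
    default_schedule,
    epsilon_contour_me,
    load_schedule,
    richness_with_extinction,
    survival_factor,
    trajectory,
)
from microdiv.parameter_space import FeasibilityBounds, ParameterDomain, feasible_fraction

# lam (1 - eps) 4000 = ln(1e12): the 1e12-species baseline
LAM_1E12, EPS_1E12 = 0.0138155105579, 0.5


class TestSchedule:
    def test_default_schedule_composition(self):
        sched = default_schedule()
        assert len(sched.events) == 6
        hosts = [ev.host_associated for ev in sched.events]
        assert hosts == [False, True, True, True, True, True]
        assert sched.model_time(sched.events[0]) == 1550.0  # GOE at 4000 - 2450

    def test_events_must_be_ordered(self):
        with pytest.raises(ValueError, match="ordered"):
            ExtinctionSchedule(events=tuple(reversed(DEFAULT_EVENTS)))

    def test_total_annihilation_rejected(self):
        sched = default_schedule(p=1.0, q=1.0)
        with pytest.raises(ValueError, match="annihilation|every taxon"):
            survival_factor(sched)

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "schedule.yaml"
        path.write_text(
            "p: 0.9\nq: 0.1\nt_origin: 4000\nevents:\n"
            "  - {name: GOE, age_mya: 2450, host_associated: false}\n"
            "  - {name: K-T, age_mya: 66, host_associated: true, q: 0.5}\n"
        )
        sched = load_schedule(path)
        assert sched.p == 0.9
        assert sched.events[1].q_override == 0.5
        # (1 - 0.9) * (1 - 0.9 * 0.5)
        assert survival_factor(sched) == pytest.approx(0.1 * 0.55, rel=1e-12)


class TestSurvivalFactor:
    @pytest.mark.parametrize(
        "p, q, expected",
        [
            (0.9, 1.0, 1e-6),              # six events, all fully vulnerable
            (0.9, 0.1, 0.1 * 0.91 ** 5),   # GOE takes (1-p); Big Five (1-pq)
            (0.0, 0.7, 1.0),               # no mass extinction
        ],
    )
    def test_full_schedule(self, p, q, expected):
        assert survival_factor(default_schedule(p=p, q=q)) == pytest.approx(expected, rel=1e-12)

    def test_partial_horizon_counts_only_past_events(self):
        sched = default_schedule(p=0.9, q=1.0)
        # only the GOE (model time 1550) has happened by t = 2000
        assert survival_factor(sched, up_to_t=2000.0) == pytest.approx(0.1, rel=1e-12)
        assert survival_factor(sched, up_to_t=1000.0) == 1.0

    def test_multiplicative_over_schedule_partitions(self):
        sched = default_schedule(p=0.9, q=0.3)
        early = ExtinctionSchedule(sched.events[:3], p=0.9, q=0.3)
        late = ExtinctionSchedule(sched.events[3:], p=0.9, q=0.3)
        assert survival_factor(sched) == pytest.approx(
            survival_factor(early) * survival_factor(late), rel=1e-12
        )


class TestRichnessWithExtinction:
    def test_1e12_baseline_drops_to_1e6(self):
        params = DiversificationParams(LAM_1E12, EPS_1E12, 4000)
        assert expected_richness(params).log10_s == pytest.approx(12.0, abs=1e-9)
        perturbed = richness_with_extinction(params, default_schedule(p=0.9, q=1.0))
        assert perturbed.log10_s == pytest.approx(6.0, abs=1e-9)

    def test_1e12_baseline_with_low_q_stays_above_1e10(self):
        params = DiversificationParams(LAM_1E12, EPS_1E12, 4000)
        perturbed = richness_with_extinction(params, default_schedule(p=0.9, q=0.1))
        assert perturbed.s == pytest.approx(1e12 * 0.1 * 0.91 ** 5, rel=1e-9)
        assert perturbed.s > 1e10

    def test_figure_parameterization(self):
        params = DiversificationParams(0.015, 0.5, 4000)
        perturbed = richness_with_extinction(params, default_schedule(p=0.9, q=1.0))
        assert perturbed.s == pytest.approx(math.exp(30.0) * 1e-6, rel=1e-9)

    def test_monotone_in_p_and_q(self):
        params = DiversificationParams(0.015, 0.5, 4000)
        for grid, fixed in (("p", 0.7), ("q", 0.7)):
            values = []
            for x in (0.1, 0.3, 0.5, 0.9):
                kwargs = {"p": x, "q": fixed} if grid == "p" else {"p": fixed, "q": x}
                values.append(richness_with_extinction(params, default_schedule(**kwargs)).log10_s)
            assert values == sorted(values, reverse=True)


class TestTrajectory:
    def test_p_zero_is_pure_exponential(self):
        params = DiversificationParams(0.015, 0.5, 4000)
        traj = trajectory(params, default_schedule(p=0.0), step=100.0)
        expected = params.net_rate * traj.times / math.log(10)
        assert np.allclose(traj.log10_richness, expected)

    def test_drop_at_goe(self):
        params = DiversificationParams(0.015, 0.5, 4000)
        traj = trajectory(params, default_schedule(p=0.9, q=1.0), step=1.0)
        at = np.searchsorted(traj.times, 1550.0)
        # value just after the GOE: e^(0.0075*1550) * 0.1
        assert 10.0 ** traj.log10_richness[at] == pytest.approx(
            math.exp(0.0075 * 1550) * 0.1, rel=1e-9
        )
        # value just before: no reduction yet
        assert 10.0 ** traj.log10_richness[at - 1] == pytest.approx(
            math.exp(0.0075 * 1549), rel=1e-9
        )

    def test_terminal_matches_closed_form(self):
        params = DiversificationParams(0.02, 0.4, 4000)
        sched = default_schedule(p=0.5, q=0.5)
        traj = trajectory(params, sched, step=50.0)
        assert traj.log10_richness[-1] == pytest.approx(
            richness_with_extinction(params, sched).log10_s, rel=1e-12
        )

    def test_step_must_divide_horizon(self):
        params = DiversificationParams(0.02, 0.4, 4000)
        with pytest.raises(ValueError, match="divide"):
            trajectory(params, default_schedule(), step=300.0)


class TestContourME:
    def test_reduces_to_birth_death_at_p0(self):
        bd = BirthDeathModel(4000.0)
        sched = default_schedule(p=0.0)
        for lam in (0.005, 0.015, 0.03):
            me = epsilon_contour_me(lam, 1e12, sched)
            core = bd.epsilon_contour(lam, 1e12)
            assert me.epsilon == core.epsilon

    @pytest.mark.parametrize(
        "lam, s_target, p, q, expected",
        [
            (0.03, 1e6, 0.9, 1.0, 1 - math.log(1e12) / 120),  # survival 1e-6 shifts target
            (0.015, 1e12, 0.9, 0.1, 1 - math.log(1e12 / (0.1 * 0.91 ** 5)) / 60),
        ],
    )
    def test_closed_form(self, lam, s_target, p, q, expected):
        c = epsilon_contour_me(lam, s_target, default_schedule(p=p, q=q))
        assert c.epsilon == pytest.approx(expected, rel=1e-10)

    @given(
        lam=st.floats(0.004, 0.03),
        log_s=st.floats(0.0, 20.0),
        p=st.floats(0.0, 0.9),
        q=st.floats(0.0, 1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, lam, log_s, p, q):
        """ME contour and perturbed richness invert each other to 10 s.d."""
        sched = default_schedule(p=p, q=q)
        c = epsilon_contour_me(lam, 10.0 ** log_s, sched)
        if not c.in_range:
            return
        rich = richness_with_extinction(DiversificationParams(lam, c.epsilon, 4000), sched)
        assert rich.log10_s == pytest.approx(log_s, abs=1e-10 + 1e-10 * abs(log_s))


class TestParameterSpaceEquivalence:
    def test_me_feasibility_equals_bd_with_rescaled_bounds(self, domain):
        """Dividing the bounds by the survival factor maps ME onto BD."""
        sched = default_schedule(p=0.9, q=1.0)
        me = MassExtinctionModel(sched)
        bd = BirthDeathModel(4000.0)
        v = survival_factor(sched)
        me_frac = feasible_fraction(domain, FeasibilityBounds(1e6, 1e23), me)
        bd_frac = feasible_fraction(domain, FeasibilityBounds(1e6 / v, 1e23 / v), bd)
        assert me_frac == pytest.approx(bd_frac, rel=1e-12)


class TestCladeScenario:
    PARAMS = DiversificationParams(0.015, 0.5, 4000)

    def test_single_fully_vulnerable_clade_reduces_to_closed_form(self):
        sched = default_schedule(p=0.9, q=1.0)
        scenario = clade_vulnerability_scenario(
            self.PARAMS, sched, [1.0], [[True] * 6], step=100.0
        )
        assert scenario.total.log10_richness[-1] == pytest.approx(
            richness_with_extinction(self.PARAMS, sched).log10_s, rel=1e-12
        )

    def test_two_clades_one_sheltered(self):
        big_five = ExtinctionSchedule(DEFAULT_EVENTS[1:], p=0.9, q=1.0)
        scenario = clade_vulnerability_scenario(
            self.PARAMS, big_five, [0.5, 0.5], [[True] * 5, [False] * 5], step=100.0
        )
        expected = 0.5 * math.exp(30.0) * (1.0 + 0.1 ** 5)
        assert 10.0 ** scenario.total.log10_richness[-1] == pytest.approx(expected, rel=1e-9)

    def test_zero_share_clade_contributes_nothing(self):
        sched = default_schedule(p=0.9, q=1.0)
        scenario = clade_vulnerability_scenario(
            self.PARAMS, sched, [1.0, 0.0], [[True] * 6, [False] * 6], step=100.0
        )
        assert scenario.total.log10_richness[-1] == pytest.approx(
            richness_with_extinction(self.PARAMS, sched).log10_s, rel=1e-12
        )

    def test_shares_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            clade_vulnerability_scenario(
                self.PARAMS, default_schedule(), [0.5, 0.4], [[True] * 6] * 2
            )
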