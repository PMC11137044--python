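import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_valid_params
from empen.phenology import (
    N_CRECHE_TRIPS,
    PhenologyParams,
    agent_oracle,
    breeding_outcome,
    build_event_schedule,
    event_dates,
    occupancy,
    oracle_standard_error,
    season_grid,
    total_time_at_sea_colony,
    trip_durations,
)


class TestTripDurations:
    def test_creche_linear_ramp_at_sea(self, pg_params):
        p = pg_params.replace(s_max=20.0, s_min=6.0, c_max=4.0, c_min=1.0)
        creche = trip_durations(p)["creche"]["male"]
        assert creche[3][0] == pytest.approx(13.0)  # midpoint of the ramp
        assert [c[1] for c in creche] == pytest.approx([4, 3.5, 3, 2.5, 2, 1.5, 1])

    def test_degenerate_ramp(self, pg_params):
        p = pg_params.replace(s_max=10.0, s_min=10.0, s_fem=10.0)
        creche = trip_durations(p)["creche"]["female"]
        assert all(sea == pytest.approx(10.0) for sea, _ in creche)

    def test_female_first_guard_trip_is_s_fem(self, pg_params):
        guard = trip_durations(pg_params)["guard"]
        assert guard["female"][0][0] == pg_params.s_fem
        assert guard["female"][0][0] <= guard["male"][0][0]

    def test_invalid_ordering_raises(self, pg_params):
        with pytest.raises(ValueError):
            trip_durations(pg_params.replace(s_min=pg_params.s_max + 1))


class TestTotalTimes:
    def test_constant_trips(self, pg_params):
        p = pg_params.replace(s_max=10.0, s_min=10.0, s_fem=10.0)
        sea, _ = total_time_at_sea_colony(p)
        assert sea == pytest.approx(70.0)

    def test_colony_arithmetic_series(self, pg_params):
        p = pg_params.replace(c_max=4.0, c_min=1.0)
        _, col = total_time_at_sea_colony(p)
        assert col == pytest.approx(17.5)

    def test_sex_symmetric_creche(self, pg_params):
        trips = trip_durations(pg_params)["creche"]
        assert trips["female"] == trips["male"]


class TestEventSchedule:
    def test_headcount_conserved_without_losses(self, pg_params):
        p = pg_params.replace(nb=0.0, hr=1.0, f=1.0)
        sched = build_event_schedule(p)
        for cohort in ("female_breeder", "male_breeder"):
            mags = [e.magnitude for e in sched.for_cohort(cohort)]
            assert all(abs(m) == pytest.approx(p.bp) for m in mags)
            assert sum(mags) == pytest.approx(0.0, abs=1e-9)

    def test_no_hatching_means_no_chicks(self, pg_params):
        p = pg_params.replace(hr=0.0, f=0.0)
        sched = build_event_schedule(p)
        assert sched.for_cohort("chick") == []
        assert not any("female_return" == e.label for e in sched.events)

    def test_hatching_mean_is_t0_m_b(self, pg_params):
        sched = build_event_schedule(pg_params)
        ret = [e for e in sched.events if e.label == "female_return"][0]
        assert ret.mean_day == pytest.approx(pg_params.t0 + pg_params.m + pg_params.b)

    def test_signed_magnitudes_empty_colony_at_season_end(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = random_valid_params(rng)
            sched = build_event_schedule(p, validate_season=False)
            for cohort in ("female_breeder", "male_breeder", "non_breeder", "chick"):
                total = sum(e.magnitude for e in sched.for_cohort(cohort))
                assert total <= 1e-6 * p.bp

    def test_schedule_past_season_end_raises(self, pg_params):
        late = pg_params.replace(t0=150.0, b=100.0, m=42.0, s_max=21.0, s_min=21.0,
                                 s_fem=21.0, c_max=5.0, c_min=5.0, db=14.0, dt0=4.0)
        with pytest.raises(ValueError, match="season"):
            build_event_schedule(late)

    def test_guard_phase_keeps_one_parent_present(self, pg_params):
        """Mean-timeline alternation: a surviving pair always attends the egg/chick."""
        sched = build_event_schedule(pg_params)
        p = pg_params
        t_r = p.t0 + p.m + p.b
        t_e = event_dates(p)["emancipation"]
        fem = {e.label: e.mean_day for e in sched.for_cohort("female_breeder")}
        mal = {e.label: e.mean_day for e in sched.for_cohort("male_breeder")}
        # female absent between her departures/returns; male must be present
        assert mal["guard_return_1"] + p.c_max == pytest.approx(fem["guard_departure_1"])
        assert fem["guard_return_1"] + p.c_max == pytest.approx(mal["guard_departure_2"])
        assert mal["guard_return_2"] + p.c_max == pytest.approx(fem["guard_departure_2"])
        assert fem["guard_return_2"] + p.c_max == pytest.approx(t_e)
        assert t_r < mal["guard_return_1"] < t_e


class TestOccupancy:
    def test_far_left_tail_empty(self, pg_params):
        sched = build_event_schedule(pg_params)
        days = np.array([pg_params.t0 - 6 * pg_params.dt0])
        occ = occupancy(sched, days)
        assert occ.total[0] == pytest.approx(0.0, abs=1e-3 * pg_params.bp)

    def test_courtship_plateau_level(self, pg_params):
        p = pg_params.replace(nb=0.1, bp=3000.0)
        sched = build_event_schedule(p)
        mid = np.array([p.t0 + p.m / 2.0])
        occ = occupancy(sched, mid)
        # plateau = (2 + NB) * BP
        assert occ.adults[0] == pytest.approx(2.1 * 3000.0, rel=0.01)

    def test_bounds_hold_everywhere(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = random_valid_params(rng)
            occ = occupancy(build_event_schedule(p, validate_season=False))
            assert np.all(occ.adults >= 0)
            assert np.all(occ.chicks >= 0)
            assert np.all(occ.adults <= p.bp * (2 + p.nb) * (1 + 1e-9))
            assert np.all(occ.chicks <= p.hr * p.bp * (1 + 1e-9))

    def test_continuity_in_time(self, pg_params):
        sched = build_event_schedule(pg_params)
        days = np.linspace(60, 424, 3000)
        tot = occupancy(sched, days).total
        # daily change bounded by event mass in one step
        assert np.max(np.abs(np.diff(tot))) < 0.05 * pg_params.bp

    def test_sd_to_zero_limit_is_step_function(self, pg_params):
        p = pg_params.replace(dt0=4.0, db=4.0)
        tight = build_event_schedule(p)
        for e in tight.events:
            object.__setattr__(e, "sd_day", 1e-6)
        days = np.array([p.t0 - 1.0, p.t0 + 1.0])
        occ = occupancy(tight, days)
        assert occ.females[0] == pytest.approx(0.0, abs=1e-6)
        assert occ.females[1] == pytest.approx(p.bp)


class TestBreedingOutcome:
    @pytest.mark.parametrize(
        "bp, hr, f, expected",
        [
            (1000, 0.8, 0.6, (600, 200, 200)),
            (1000, 1.0, 1.0, (1000, 0, 0)),
            (1000, 0.5, 0.0, (0, 500, 500)),
        ],
    )
    def test_split(self, pg_params, bp, hr, f, expected):
        out = breeding_outcome(pg_params.replace(bp=bp, hr=hr, f=f))
        assert (out.fledged, out.dead_chicks, out.lost_eggs) == pytest.approx(expected)
        assert out.total == pytest.approx(bp)

    def test_f_above_hr_rejected(self, pg_params):
        with pytest.raises(ValueError):
            breeding_outcome(pg_params.replace(hr=0.5, f=0.6))

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=200, deadline=None)
    def test_conservation_property(self, seed):
        p = random_valid_params(np.random.default_rng(seed))
        out = breeding_outcome(p)
        assert out.total == pytest.approx(p.bp, abs=1e-9 * p.bp)
        assert out.fledged >= 0 and out.dead_chicks >= -1e-12 and out.lost_eggs >= -1e-12


class TestEventDates:
    def test_date_arithmetic(self, pg_params):
        p = pg_params.replace(t0=97.0, m=35.0, b=60.0)  # Apr 7 arrival
        d = event_dates(p)
        assert d["female_return"] == pytest.approx(192.0)  # ~July 11
        assert d["hatching"] == d["female_return"]

    def test_dates_match_schedule_means(self, pg_params):
        sched = build_event_schedule(pg_params)
        d = event_dates(pg_params)
        entry = [e for e in sched.events if e.label == "emancipation_entry"][0]
        fledge = [e for e in sched.events if e.label == "fledging"][0]
        assert d["emancipation"] == pytest.approx(entry.mean_day)
        assert d["fledging"] == pytest.approx(fledge.mean_day)


class TestAgentOracle:
    def test_fixed_seed_reproducible(self, pg_params):
        a = agent_oracle(pg_params, 2000, seed=9)
        b = agent_oracle(pg_params, 2000, seed=9)
        assert np.array_equal(a.total, b.total)

    def test_integer_headcounts(self, pg_params):
        occ = agent_oracle(pg_params, 1000, seed=3)
        scaled = occ.total * (1000 / pg_params.bp)
        assert np.allclose(scaled, np.round(scaled), atol=1e-6)

    def test_matches_analytic_within_mc_error(self):
        """Analytic occupancy equals the oracle mean within Monte-Carlo error."""
        rng = np.random.default_rng(7)
        days = season_grid()
        for rep in range(5):
            p = random_valid_params(rng)
            occ = occupancy(build_event_schedule(p, validate_season=False), days)
            sim = agent_oracle(p, 20000, seed=50 + rep, days=days)
            se = oracle_standard_error(p, 20000, days)
            for attr, key in [
                ("females", "female_breeder"),
                ("males", "male_breeder"),
                ("chicks", "chick"),
            ]:
                mad = np.mean(np.abs(getattr(occ, attr) - getattr(sim, attr)))
                assert mad <= 3.0 * max(np.mean(se[key]), 1e-9)

    def test_rejects_zero_pairs(self, pg_params):
        with pytest.raises(ValueError):
            agent_oracle(pg_params, 0, seed=1)


def test_params_validation_catches_each_constraint(pg_params):
    bad = [
        dict(b=120.0),
        dict(s_min=20.0, s_max=15.0),
        dict(f=0.9, hr=0.8),
        dict(db=3.0, dt0=6.0),
        dict(c_min=4.0, c_max=3.0),
    ]
    for kw in bad:
        assert PhenologyParams(**{**pg_params.to_dict(), **kw}).violations()
    assert pg_params.violations() == []
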