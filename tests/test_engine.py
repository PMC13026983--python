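"""Discrete-event engine: schedules, routing, sample-path correctness."""

import math

import numpy as np
import pytest

from sonoflow import (
    ArrivalSchedule,
    DoctorSchedule,
    ScenarioConfig,
    SimulationError,
    USType,
    USTypeCatalog,
    build_scenario,
    capacity_at,
    compute_kpis,
    draw_patient_type,
    next_arrival,
    parse_distribution,
    pick_dedicated_queue,
    pick_idle_doctor,
    run_replication,
)
from sonoflow.engine import DAY_MINUTES


def make_config(routing="pooled", arrival="Expo(10)", service="Expo(14)",
                blocks=((0.0, DAY_MINUTES, 4),), horizon=DAY_MINUTES):
    """Single-type, single-block test configuration."""
    return ScenarioConfig(
        id="custom",
        routing=routing,
        schedule=DoctorSchedule(tuple(blocks)),
        arrival=ArrivalSchedule(((0.0, horizon, parse_distribution(arrival)),)),
        catalog=USTypeCatalog((USType("X", 1.0, parse_distribution(service)),)),
        horizon=horizon,
    )


class TestSchedules:
    def test_baseline_capacity(self):
        sched = build_scenario("S1").schedule
        assert capacity_at(sched, 100) == 4
        assert capacity_at(sched, 301) == 3
        assert capacity_at(sched, 300) == 3  # half-open blocks: shift ends at 300
        assert capacity_at(sched, 540) == 3

    def test_allday3_capacity(self):
        sched = build_scenario("S5").schedule
        assert capacity_at(sched, 100) == 3

    def test_outside_horizon_raises(self):
        sched = build_scenario("S1").schedule
        with pytest.raises(ValueError):
            capacity_at(sched, 541)
        with pytest.raises(ValueError):
            capacity_at(sched, -1)

    def test_arrival_blocks_must_be_contiguous(self):
        spec = parse_distribution("Expo(10)")
        with pytest.raises(ValueError):
            ArrivalSchedule(((0, 60, spec), (120, 180, spec)))


class TestNextArrival:
    def test_past_cutoff_returns_none(self):
        sched = build_scenario("S1").arrival
        rng = np.random.default_rng(0)
        assert next_arrival(sched, 600.0, rng) is None
        assert next_arrival(sched, 615.0, rng) is None

    def test_degenerate_uniform_block(self):
        sched = ArrivalSchedule(((0.0, 540.0, parse_distribution("UNIF(10, 10)")),))
        assert next_arrival(sched, 30.0, np.random.default_rng(0)) == 40.0

    def test_zero_draw_advances_by_tick(self):
        sched = ArrivalSchedule(((0.0, 540.0, parse_distribution("CONST(0)")),))
        t = next_arrival(sched, 30.0, np.random.default_rng(0))
        assert t == pytest.approx(30.0 + 1e-6)

    def test_draw_landing_past_horizon_suppressed(self):
        sched = ArrivalSchedule(((0.0, 540.0, parse_distribution("CONST(600)")),))
        assert next_arrival(sched, 0.0, np.random.default_rng(0)) is None


class TestTypeDraw:
    def test_zero_variate_gives_first_catalog_entry(self):
        catalog = build_scenario("S1").catalog

        class ZeroRng:
            def random(self):
                return 0.0

        assert draw_patient_type(catalog, ZeroRng()) == "Abdominal Ultrasound"

    def test_renormalized_abdominal_probability(self):
        catalog = build_scenario("S1").catalog
        assert catalog.probabilities[0] == pytest.approx(0.361 / 0.999)

    def test_frequencies_within_binomial_error(self):
        catalog = build_scenario("S1").catalog
        rng = np.random.default_rng(5)
        n = 100_000
        draws = [draw_patient_type(catalog, rng) for _ in range(n)]
        counts = {name: 0 for name in (e.name for e in catalog.entries)}
        for d in draws:
            counts[d] += 1
        for entry, p in zip(catalog.entries, catalog.probabilities):
            se = math.sqrt(p * (1 - p) / n)
            assert abs(counts[entry.name] / n - p) <= 4 * se


class TestRoutingRules:
    def test_idle_doctor_is_lowest_index(self):
        assert pick_idle_doctor([2, 0, 3, 1]) == 0
        assert pick_idle_doctor([3]) == 3
        assert pick_idle_doctor([]) is None

    def test_pooled_rotation_cycles_through_idle_doctors(self):
        assert pick_idle_doctor([0, 1, 2, 3], after=1) == 2
        assert pick_idle_doctor([0, 1, 2, 3], after=3) == 0  # wraps around
        assert pick_idle_doctor([3], after=0) == 3
        assert pick_idle_doctor([], after=2) is None

    def test_shortest_dedicated_queue(self):
        # doctors 0-1 busy; queue lengths (2, 0, 1, 1) -> doctor 1's queue
        assert pick_dedicated_queue([2, 0, 1, 1], eligible=[0, 1, 2, 3]) == 1

    def test_dedicated_queue_tie_breaks_low_index(self):
        assert pick_dedicated_queue([1, 1, 1], eligible=[0, 1, 2]) == 0
        assert pick_dedicated_queue([3, 1, 1], eligible=[1, 2]) == 1

    def test_pooled_service_is_fifo(self):
        cfg = make_config(routing="pooled", arrival="Expo(5)", service="Expo(30)")
        log = run_replication(cfg, 21)
        by_queue = sorted(log.patients, key=lambda p: (p.queue_enter, p.id))
        starts = [p.service_start for p in by_queue]
        assert starts == sorted(starts)

    def test_dedicated_utilization_profile_non_increasing(self):
        """Lowest-index-first dedicated routing loads doctor 1 the most."""
        cfg = build_scenario("S1")
        utils = np.zeros(4)
        for seed in range(40):
            utils += compute_kpis(run_replication(cfg, seed), cfg.schedule).util
        utils /= 40
        assert all(utils[i] >= utils[i + 1] for i in range(3))

    def test_pooled_utilizations_roughly_equal(self):
        """Round-robin pooled routing shares load evenly among always-on doctors."""
        cfg = build_scenario("S6")
        utils = np.zeros(3)
        for seed in range(40):
            utils += compute_kpis(run_replication(cfg, seed), cfg.schedule).util
        utils /= 40
        assert utils.max() - utils.min() < 0.05


class TestRunReplication:
    def test_empty_system(self):
        cfg = make_config(arrival="CONST(1000000000)")
        log = run_replication(cfg, 0)
        assert log.patients == []
        with pytest.warns(UserWarning):
            k = compute_kpis(log, cfg.schedule)
        assert k.util == (0.0, 0.0, 0.0, 0.0)
        assert k.awt == k.wip == k.pst == 0.0

    def test_single_deterministic_patient(self):
        # one arrival at minute 300, CONST(10) service, four idle doctors
        cfg = make_config(arrival="CONST(300)", service="CONST(10)")
        log = run_replication(cfg, 0)
        assert len(log.patients) == 1
        p = log.patients[0]
        assert p.arrival == 300.0
        assert p.waiting == 0.0
        assert p.system_time == 10.0
        assert p.doctor == 0
        assert log.busy[0] == [(300.0, 310.0)]

    def test_conservation_and_record_ordering(self):
        for sid in ("S1", "S2", "S5"):
            cfg = build_scenario(sid)
            log = run_replication(cfg, 99)
            assert all(math.isfinite(p.service_end) for p in log.patients)
            for p in log.patients:
                assert p.arrival <= p.prep_end <= p.queue_enter
                assert p.queue_enter <= p.service_start <= p.service_end
                assert p.arrival < cfg.horizon

    def test_busy_intervals_disjoint_and_match_services(self):
        cfg = build_scenario("S2")
        log = run_replication(cfg, 17)
        served = {(p.doctor, p.service_start, p.service_end) for p in log.patients}
        for d, ivals in log.busy.items():
            ordered = sorted(ivals)
            for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
                assert e1 <= s2
            for s, e in ivals:
                assert (d, s, e) in served
        assert len(served) == sum(len(v) for v in log.busy.values())

    def test_determinism_bit_identical(self):
        cfg = build_scenario("S3")
        a = run_replication(cfg, 123)
        b = run_replication(cfg, 123)
        assert a.patients_dataframe().equals(b.patients_dataframe())
        assert a.busy == b.busy

    def test_fourth_doctor_takes_no_patient_after_shift_end(self):
        cfg = build_scenario("S1")
        for seed in range(20):
            log = run_replication(cfg, seed)
            starts_late = [s for s, e in log.busy.get(3, []) if s >= 300.0]
            assert starts_late == []
            # may finish one service past minute 300, never start one
            past = [e for s, e in log.busy.get(3, []) if e > 300.0]
            assert len(past) <= 1

    def test_lindley_recursion_single_doctor(self):
        """Single-server FIFO waits satisfy W(n+1)=max(0, W(n)+S(n)−A(n+1))."""
        cfg = make_config(routing="pooled", arrival="Expo(12)", service="Expo(10)",
                          blocks=((0.0, DAY_MINUTES, 1),))
        log = run_replication(cfg, 31)
        ps = log.patients
        assert len(ps) > 10
        w = 0.0
        for prev, cur in zip(ps, ps[1:]):
            w = max(0.0, w + prev.service_time - (cur.arrival - prev.arrival))
            assert cur.waiting == pytest.approx(w, abs=1e-9)

    def test_utilization_in_unit_interval(self):
        for sid in ("S1", "S2", "S4", "S5", "S6"):
            cfg = build_scenario(sid)
            k = compute_kpis(run_replication(cfg, 3), cfg.schedule)
            assert all(0.0 <= u <= 1.0 for u in k.util)
            assert 0.0 <= k.util_adc <= 1.0

    def test_registration_delay_shifts_queue_entry(self):
        from dataclasses import replace

        cfg = replace(make_config(arrival="CONST(100)", service="CONST(10)"),
                      registration=5.0)
        log = run_replication(cfg, 0)
        p = log.patients[0]
        assert p.arrival == 100.0
        assert p.queue_enter == 105.0
        assert p.waiting == 0.0
        assert p.system_time == 15.0  # registration counts toward system time

    def test_unstaffed_schedule_raises(self):
        cfg = make_config(blocks=((0.0, DAY_MINUTES, 0),))
        with pytest.raises((SimulationError, ValueError)):
            run_replication(cfg, 0)
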