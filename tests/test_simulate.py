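"""Schedule simulator: closed forms, oracle equivalence, monotonicity."""

import math
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from vge.errors import ValidationError
from vge.simulate import (
    ScheduleTimeline,
    SimRequest,
    ideal_makespan,
    mds_load_check,
    rounds_bounds,
    simulate,
    timeline_export,
    timeline_load,
)


# ---------------------------------------------------------------------------
# Independent oracle: unit-step time simulation, integer durations >= 1.
# FIFO queue, lowest idle worker id first; a request's units are released
# once its submit time passed and its predecessor (by index) fully finished.


def brute_force(requests, n_workers):
    """requests: list of dicts with n_units, duration, submit_time, depends_on."""
    total = sum(r["n_units"] for r in requests)
    queue = []
    running = {}  # wid -> (req_i, task_index, end)
    idle = set(range(1, n_workers + 1))
    remaining = [r["n_units"] for r in requests]
    released = [False] * len(requests)
    order = []
    records = []
    finished = 0
    t = 0
    while finished < total:
        for wid in sorted(running):
            ri, idx, end = running[wid]
            if end == t:
                del running[wid]
                idle.add(wid)
                remaining[ri] -= 1
                finished += 1
        for i, r in enumerate(requests):
            dep = r["depends_on"]
            if (
                not released[i]
                and t >= r["submit_time"]
                and (dep is None or remaining[dep] == 0)
            ):
                released[i] = True
                queue.extend((i, idx) for idx in range(1, r["n_units"] + 1))
        while queue and idle:
            ri, idx = queue.pop(0)
            wid = min(idle)
            idle.remove(wid)
            running[wid] = (ri, idx, t + requests[ri]["duration"])
            order.append((ri, idx, wid))
            records.append((ri, idx, wid, t, t + requests[ri]["duration"]))
        t += 1
        assert t < 10_000, "oracle runaway"
    makespan = max(r[4] for r in records) - min(r["submit_time"] for r in requests)
    return order, makespan


def to_sim_requests(requests):
    out = []
    for r in requests:
        out.append(
            SimRequest(
                n_units=r["n_units"],
                duration=float(r["duration"]),
                submit_time=float(r["submit_time"]),
                name=f"req{len(out)}",
                depends_on=out[r["depends_on"]] if r["depends_on"] is not None else None,
            )
        )
    return out


request_dicts = st.lists(
    st.fixed_dictionaries(
        {
            "n_units": st.integers(1, 12),
            "duration": st.integers(1, 5),
            "submit_time": st.integers(0, 6),
        }
    ),
    min_size=1,
    max_size=5,
).map(lambda rs: [{**r, "depends_on": None} for r in rs])


class TestClosedForms:
    def test_case2_ideal_makespan_is_6120_seconds(self):
        # 100,000 array jobs of 120 s sleep on 1,999 workers, zero overhead
        assert ideal_makespan(100000, 1999, 120) == 6120

    @pytest.mark.parametrize("n,d", [(5, 3.0), (1999, 120.0)])
    def test_one_round_when_jobs_equal_workers(self, n, d):
        assert ideal_makespan(n, n, d) == d

    def test_case1_scaled_agrees_with_event_simulation(self):
        tl = simulate([SimRequest(n_units=10000, duration=120.0)], 1999, 0.0)
        assert tl.makespan == ideal_makespan(10000, 1999, 120) == 720

    def test_no_jobs_zero_makespan(self):
        assert ideal_makespan(0, 5, 120) == 0.0

    def test_zero_workers_with_jobs_is_error(self):
        with pytest.raises(ValidationError):
            ideal_makespan(10, 0, 1.0)

    def test_case1_workers_execute_five_or_six_jobs(self):
        assert rounds_bounds(10000, 1999) == (5, 6)

    @pytest.mark.parametrize(
        "n,w,expected", [(6, 3, (2, 2)), (7, 3, (2, 3)), (3, 8, (0, 1))]
    )
    def test_rounds_bounds_floor_ceil(self, n, w, expected):
        assert rounds_bounds(n, w) == expected

    def test_bounds_match_enumerated_greedy_assignment(self):
        # enumerate greedy round-robin for (7, 3): counts 3,2,2
        order, _ = brute_force(
            [{"n_units": 7, "duration": 1, "submit_time": 0, "depends_on": None}], 3
        )
        counts = {w: sum(1 for *_, wid in order if wid == w) for w in (1, 2, 3)}
        assert (min(counts.values()), max(counts.values())) == rounds_bounds(7, 3)


class TestSimulate:
    def test_four_units_two_workers_two_rounds(self):
        tl = simulate([SimRequest(n_units=4, duration=1.0)], 2, 0.0)
        assert tl.makespan == 2.0
        assert dict(tl.per_worker_counts) == {1: 2, 2: 2}
        tl.validate()

    def test_dependency_blocks_until_predecessor_completes(self):
        split = SimRequest(n_units=2, duration=5.0, name="split")
        align = SimRequest(n_units=8, duration=3.0, name="align", depends_on=split)
        tl = simulate([split, align], 4, 0.0)
        split_end = max(r.t_end for r in tl.records if r.submission == "split")
        align_start = min(r.t_start for r in tl.records if r.submission == "align")
        assert align_start >= split_end
        tl.validate()

    def test_multi_pipeline_stage2_never_precedes_own_stage1(self):
        reqs = []
        for s in range(14):
            split = SimRequest(n_units=2, duration=2.0, name=f"split{s}")
            align = SimRequest(
                n_units=10, duration=3.0 + s % 3, name=f"align{s}", depends_on=split
            )
            reqs.extend([split, align])
        tl = simulate(reqs, 5000, 0.0)
        assert sum(1 for r in tl.records if r.submission.startswith("split")) == 28
        for s in range(14):
            split_end = max(
                r.t_end for r in tl.records if r.submission == f"split{s}"
            )
            align_start = min(
                r.t_start for r in tl.records if r.submission == f"align{s}"
            )
            assert align_start >= split_end

    def test_cyclic_dependency_rejected(self):
        a = SimRequest(n_units=1, duration=1.0, name="a")
        b = SimRequest(n_units=1, duration=1.0, name="b", depends_on=a)
        a.depends_on = b
        with pytest.raises(ValidationError):
            simulate([a, b], 2, 0.0)

    @given(
        n=st.integers(1, 400),
        w=st.integers(1, 32),
        d=st.floats(0.5, 100.0),
    )
    def test_uniform_zero_overhead_matches_ideal_closed_form(self, n, w, d):
        tl = simulate([SimRequest(n_units=n, duration=d)], w, 0.0)
        assert tl.makespan == pytest.approx(ideal_makespan(n, w, d))

    @given(request_dicts, st.integers(1, 8))
    def test_oracle_equivalence_independent_requests(self, requests, w):
        """Event simulation equals unit-step brute force: makespan and order."""
        order, makespan = brute_force(requests, w)
        tl = simulate(to_sim_requests(requests), w, 0.0)
        assert tl.makespan == pytest.approx(makespan)
        got = [(int(r.submission[3:]), r.task_index, r.worker_id) for r in tl.records]
        assert got == order

    @pytest.mark.parametrize("seed", range(8))
    def test_oracle_equivalence_with_dependency_chains(self, seed):
        rng = random.Random(seed)
        requests = []
        for i in range(rng.randint(2, 5)):
            dep = rng.choice([None] + list(range(len(requests)))) if requests else None
            requests.append(
                {
                    "n_units": rng.randint(1, 10),
                    "duration": rng.randint(1, 4),
                    "submit_time": rng.randint(0, 4),
                    "depends_on": dep,
                }
            )
        w = rng.randint(1, 8)
        order, makespan = brute_force(requests, w)
        tl = simulate(to_sim_requests(requests), w, 0.0)
        assert tl.makespan == pytest.approx(makespan)
        got = [(int(r.submission[3:]), r.task_index, r.worker_id) for r in tl.records]
        assert got == order

    @given(st.integers(5, 60), st.integers(1, 6), st.integers(2, 6))
    def test_makespan_monotone_nonincreasing_in_workers(self, n, w, extra):
        req = [SimRequest(n_units=n, duration=3.0)]
        assert (
            simulate(req, w + extra, 0.0).makespan <= simulate(req, w, 0.0).makespan
        )

    @given(st.integers(5, 60), st.integers(1, 6), st.floats(0.0, 2.0))
    def test_makespan_monotone_nondecreasing_in_overhead(self, n, w, ovh):
        req = [SimRequest(n_units=n, duration=3.0)]
        assert simulate(req, w, ovh).makespan >= simulate(req, w, 0.0).makespan

    def test_overhead_serializes_assignments(self):
        tl = simulate([SimRequest(n_units=4, duration=0.0)], 4, 1.0)
        assert sorted(r.t_start for r in tl.records) == [1.0, 2.0, 3.0, 4.0]


class TestTimelineExport:
    def test_rows_sorted_and_round_trip_preserves_makespan(self, tmp_path):
        reqs = [
            SimRequest(n_units=5, duration=2.0, name="a"),
            SimRequest(n_units=3, duration=1.0, name="b"),
        ]
        tl = simulate(reqs, 3, 0.0)
        path = timeline_export(tl, tmp_path / "tl.tsv")
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 9  # header + 8 units
        starts = [float(l.split("\t")[3]) for l in lines[1:]]
        assert starts == sorted(starts)
        back = timeline_load(path)
        assert back.makespan == pytest.approx(tl.makespan)

    def test_export_per_worker_counts_within_rounds_bounds(self, tmp_path):
        tl = simulate([SimRequest(n_units=100, duration=120.0)], 8, 0.0)
        path = timeline_export(tl, tmp_path / "case1.tsv")
        back = timeline_load(path)
        lo, hi = rounds_bounds(100, 8)
        assert set(back.per_worker_counts.values()) <= {lo, hi}

    def test_busy_count_reflects_filling(self):
        tl = simulate([SimRequest(n_units=6, duration=2.0)], 4, 0.0)
        assert tl.busy_count(0.5) == 4
        assert tl.busy_count(2.5) == 2
        assert tl.busy_count(4.5) == 0


class TestMdsAdvisor:
    def test_observed_launch_storm_exceeds_limit(self):
        rate, exceeds = mds_load_check(20000, 1.0, 1300)
        assert rate == 20000
        assert exceeds

    def test_zero_ops_fine(self):
        assert mds_load_check(0, 1.0, 1300) == (0.0, False)

    def test_boundary_rate_equal_to_limit_not_exceeded(self):
        rate, exceeds = mds_load_check(1300, 1.0, 1300)
        assert rate == 1300
        assert not exceeds

    def test_default_limit_is_sustainable_mds_rate(self):
        _, exceeds = mds_load_check(1301, 1.0)
        assert exceeds
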