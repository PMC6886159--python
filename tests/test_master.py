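"""Master scheduling: registration, two-pool refill, assignment, completion."""

import random

import pytest

from vge.core import JobState, TaskRequest, WorkerStatus
from vge.errors import SubmissionRejected, UnknownSubmission, ValidationError
from vge.farm import drive_engine
from vge.master import EXIT_CANCELLED, EXIT_WORKER_LOST, EngineConfig
from vge.transport import worker_endpoint


def submit(engine, max_task, basename="job", command="exit 0"):
    return engine.handle_submit(TaskRequest(command, max_task, basename))


class TestConfig:
    def test_interval_and_worker_count_validation(self):
        with pytest.raises(ValidationError):
            EngineConfig(worker_count=-1)
        with pytest.raises(ValidationError):
            EngineConfig(cycle_interval=0)

    def test_from_toml(self, tmp_path):
        p = tmp_path / "engine.toml"
        p.write_text(
            '[engine]\nworker_count = 7\nlog_dir = "x"\nfail_fast = true\n'
        )
        cfg = EngineConfig.from_toml(p)
        assert cfg.worker_count == 7
        assert cfg.fail_fast
        assert cfg.mds_request_limit == 1300.0


class TestSubmit:
    def test_units_registered_pending_in_main(self, engine_factory):
        engine, _ = engine_factory(worker_count=4)
        submit(engine, 4)
        assert len(engine.main) == 4
        assert all(u.state is JobState.PENDING for u in engine.main)

    def test_fourteen_pipelines_of_two_units_fill_main_with_28(self, engine_factory):
        engine, _ = engine_factory(worker_count=0)
        for s in range(14):
            submit(engine, 2, basename=f"fastq_splitter_data{s}")
        assert len(engine.main) == 28

    def test_submit_after_shutdown_rejected_without_pool_change(self, engine_factory):
        engine, _ = engine_factory(worker_count=1)
        engine.shutdown(ack_timeout=0.1)
        with pytest.raises(SubmissionRejected):
            submit(engine, 3)
        assert len(engine.main) == 0

    def test_basename_collision_resolved_with_submission_id(self, engine_factory):
        engine, _ = engine_factory()
        sid1 = submit(engine, 1, basename="same")
        sid2 = submit(engine, 1, basename="same")
        assert engine.query_status(sid1).basename == "same"
        assert engine.query_status(sid2).basename == f"same-{sid2}"


class TestRefill:
    def test_two_step_refill_policy(self, engine_factory):
        engine, _ = engine_factory(worker_count=8)
        for _ in range(25):
            submit(engine, 4)
        assert engine.refill() == (100, 8)
        assert (len(engine.main), len(engine.second), len(engine.first)) == (0, 92, 8)

    def test_no_movement_while_first_nonempty(self, engine_factory):
        engine, _ = engine_factory(worker_count=8)
        for _ in range(25):
            submit(engine, 4)
        engine.refill()
        submit(engine, 4)  # lands in MAIN
        assert engine.refill() == (0, 0)
        assert len(engine.main) == 4

    def test_main_untouched_while_second_nonempty(self, engine_factory):
        engine, _ = engine_factory(worker_count=8)
        for _ in range(25):
            submit(engine, 4)
        engine.refill()
        submit(engine, 4)
        # drain FIRST without scheduling, then refill: SECOND feeds FIRST, MAIN waits
        while len(engine.first):
            engine.first.popleft()
        assert engine.refill() == (0, 8)
        assert len(engine.main) == 4

    def test_all_pools_empty_is_noop(self, engine_factory):
        engine, _ = engine_factory()
        assert engine.refill() == (0, 0)


class TestScheduleStep:
    def test_assignments_bounded_by_idle_workers(self, engine_factory):
        engine, clock = engine_factory(worker_count=2)
        submit(engine, 3)
        issued = engine.schedule_step()
        assert len(issued) == 2
        busy = [w for w in engine.workers.values() if w.status is WorkerStatus.BUSY]
        assert len(busy) == 2

    def test_no_idle_workers_no_assignments(self, engine_factory):
        engine, _ = engine_factory(worker_count=1)
        submit(engine, 2)
        assert len(engine.schedule_step()) == 1
        assert engine.schedule_step() == []

    def test_assign_message_carries_script_and_identity(self, engine_factory):
        engine, _ = engine_factory(worker_count=1)
        sid = submit(engine, 1, basename="named")
        (payload,) = engine.schedule_step()
        assert payload["submission_id"] == sid
        assert payload["task_index"] == 1
        assert payload["basename"] == "named"
        assert payload["script_path"].endswith("named.sh")

    def test_lost_worker_marks_unit_failed_with_sentinel(self, engine_factory):
        engine, _ = engine_factory(worker_count=2)
        sid = submit(engine, 2)
        engine.transport.close(worker_endpoint(1))
        issued = engine.schedule_step()
        # worker 1 lost; its unit failed with the sentinel, worker 2 got the other
        assert len(issued) == 1
        assert engine.workers[1].status is WorkerStatus.STOPPED
        st = engine.query_status(sid)
        assert st.counts[JobState.FAILED] == 1
        failed = [u for u in engine.submissions[sid].units if u.finished]
        assert failed[0].exit_code == EXIT_WORKER_LOST
        # stopped worker excluded from further scheduling
        submit(engine, 4)
        assert all(p["task_index"] for p in engine.schedule_step())
        assert engine.workers[1].completed_count == 0


class TestComplete:
    def test_exit_zero_is_done_and_worker_freed(self, engine_factory):
        engine, _ = engine_factory(worker_count=1)
        sid = submit(engine, 1)
        (payload,) = engine.schedule_step()
        st = engine.handle_complete(1, (sid, 1), 0, t=engine.clock())
        assert st.counts[JobState.DONE] == 1
        assert engine.workers[1].status is WorkerStatus.IDLE
        assert engine.workers[1].completed_count == 1

    def test_nonzero_exit_is_failed_but_counts_toward_all_done(self, engine_factory):
        engine, _ = engine_factory(worker_count=1)
        sid = submit(engine, 1)
        engine.schedule_step()
        st = engine.handle_complete(1, (sid, 1), 7, t=engine.clock())
        assert st.counts[JobState.FAILED] == 1
        assert st.all_done
        assert st.exit_codes[1] == 7

    def test_duplicate_complete_rejected_idempotently(self, engine_factory):
        engine, _ = engine_factory(worker_count=1)
        sid = submit(engine, 1)
        engine.schedule_step()
        first = engine.handle_complete(1, (sid, 1), 0, t=engine.clock())
        again = engine.handle_complete(1, (sid, 1), 0, t=engine.clock())
        assert first.all_done
        assert again is None
        assert engine.workers[1].completed_count == 1

    def test_unknown_unit_and_wrong_worker_rejected(self, engine_factory):
        engine, _ = engine_factory(worker_count=2)
        sid = submit(engine, 1)
        engine.schedule_step()
        assert engine.handle_complete(1, (99, 1), 0) is None
        assert engine.handle_complete(2, (sid, 1), 0) is None
        assert engine.query_status(sid).counts[JobState.ASSIGNED] == 1

    def test_fail_fast_cancels_pending_units(self, engine_factory, tmp_path):
        engine, _ = engine_factory(worker_count=1, fail_fast=True)
        sid = submit(engine, 5)
        engine.schedule_step()
        st = engine.handle_complete(1, (sid, 1), 3, t=engine.clock())
        assert st.all_done
        codes = [engine.units[(sid, i)].exit_code for i in range(2, 6)]
        assert codes == [EXIT_CANCELLED] * 4
        # cancelled units were removed from the pools
        assert len(engine.main) == len(engine.second) == len(engine.first) == 0


class TestStatusAndShutdown:
    def test_fresh_submission_status(self, engine_factory):
        engine, _ = engine_factory()
        sid = submit(engine, 5)
        st = engine.query_status(sid)
        assert st.counts[JobState.PENDING] == 5
        assert not st.all_done

    def test_unknown_submission(self, engine_factory):
        engine, _ = engine_factory()
        with pytest.raises(UnknownSubmission):
            engine.query_status(42)

    def test_shutdown_reports_never_assigned_units(self, engine_factory):
        engine, _ = engine_factory(worker_count=0)
        submit(engine, 3)
        summary = engine.shutdown(ack_timeout=0.1)
        assert summary["never_assigned"] == 3
        assert summary["done"] == 0

    def test_summary_per_worker_counts_cross_check_timeline(self, engine_factory):
        engine, clock = engine_factory(worker_count=3)
        for n in (4, 5, 2):
            submit(engine, n)
        drive_engine(engine, clock=clock)
        summary = engine.shutdown(ack_timeout=0.1)
        per_worker = summary["per_worker_completed"]
        assert sum(per_worker.values()) == summary["done"] == 11
        tl_counts = engine.timeline().per_worker_counts
        assert dict(tl_counts) == {w: n for w, n in per_worker.items() if n}


class TestSchedulingInvariants:
    def test_exactly_once_assignment_under_randomized_workload(self, engine_factory):
        engine, clock = engine_factory(worker_count=5)
        rng = random.Random(7)
        total = 0
        for s in range(12):
            n = rng.randint(1, 9)
            total += n
            submit(engine, n, basename=f"r{s}")
        order = drive_engine(engine, clock=clock)
        assert len(order) == total
        assert len(set(order)) == total  # no duplicate assignment
        assert all(u.state is JobState.DONE for u in engine.units.values())

    def test_counts_sum_to_max_task_at_every_poll(self, engine_factory):
        """Fuzz run: status snapshots stay consistent mid-flight."""
        engine, clock = engine_factory(worker_count=3)
        sid = submit(engine, 17)
        for _ in range(40):
            engine.schedule_step()
            st = engine.query_status(sid)
            assert sum(st.counts.values()) == 17
            # complete whatever is in flight, one per cycle
            for w in list(engine.workers.values()):
                if w.status is WorkerStatus.BUSY:
                    engine.handle_complete(w.worker_id, w.current_unit, 0)
                    break
            clock.advance()
        assert sum(engine.query_status(sid).counts.values()) == 17

    def test_liveness_pending_unit_plus_idle_worker_yields_assignment(
        self, engine_factory
    ):
        engine, _ = engine_factory(worker_count=1)
        submit(engine, 1)
        assert len(engine.schedule_step()) >= 1

    def test_global_fifo_dispatch_order(self, engine_factory):
        engine, clock = engine_factory(worker_count=2)
        expected = []
        for s in range(5):
            sid = submit(engine, 3, basename=f"r{s}")
            expected.extend((sid, i) for i in range(1, 4))
        order = drive_engine(engine, clock=clock)
        assert order == expected
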