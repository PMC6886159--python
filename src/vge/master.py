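"""The master: registers submissions, maintains the three job pools,
assigns units to idle workers, records completions, answers status
queries, and shuts the farm down.

Scheduling policy
-----------------
Submissions are expanded and appended to the MAIN pool in arrival order.
The dispatch cycle (:meth:`Engine.schedule_step`) works exclusively off the
small FIRST pool; when FIRST drains, :meth:`Engine.refill` either bulk-copies
everything from MAIN into SECOND (only when SECOND is also empty) or
extracts the ``worker_count`` oldest units from SECOND into FIRST.  MAIN is
therefore touched once per bulk copy rather than once per assignment, which
is the point of the two local pools.  Within a step, idle workers are
served in worker-id order and each receives at most one unit, so uniform
workloads complete in lock-step rounds of ``worker_count`` assignments and
every worker ends with ``floor`` or ``ceil`` of ``n/W`` completions.

Failure policy
--------------
There is no automatic retry.  A FAILED unit counts as finished for
blocking/dependency purposes; the nonzero exit codes are surfaced to the
submitting call.  A worker whose transport fails is marked STOPPED and its
in-flight unit FAILED with exit code 255.  With ``fail_fast`` enabled, the
first failure of a submission cancels its still-pending units (exit code
125).
"""

from __future__ import annotations

import logging
import threading
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

from .core import (
    JobPool,
    JobState,
    JobUnit,
    PoolRole,
    SubmissionStatus,
    TaskRequest,
    WorkerRecord,
    WorkerStatus,
    dequeue_next,
    expand_request,
    extract_batch,
    status_of,
    transfer_all,
)
from .errors import SubmissionRejected, TransportError, UnknownSubmission, ValidationError
from .protocol import Message, MessageKind, decode, encode
from .simulate import ScheduleTimeline, TimelineRecord
from .transport import MASTER, InMemoryTransport, worker_endpoint
from .worker import materialize_script

__all__ = ["EngineConfig", "Engine", "EXIT_WORKER_LOST", "EXIT_CANCELLED"]

log = logging.getLogger("vge.master")

#: exit code recorded for a unit whose worker was lost mid-flight
EXIT_WORKER_LOST = 255
#: exit code recorded for units cancelled by fail_fast
EXIT_CANCELLED = 125
#: reserved pseudo worker id used when the engine itself terminates a unit
ENGINE_ACTOR = 0

try:  # Python 3.11+
    import tomllib
except ImportError:  # pragma: no cover
    tomllib = None


@dataclass
class EngineConfig:
    """Engine tunables.

    ``mds_request_limit`` feeds the metadata-load advisor (sustainable
    metadata-server request rate, ops/second).
    """

    worker_count: int = 1
    host: str = "127.0.0.1"
    port: int = 0
    poll_interval: float = 0.5
    cycle_interval: float = 0.01
    log_dir: str = "vge_logs"
    mds_request_limit: float = 1300.0
    fail_fast: bool = False

    def __post_init__(self) -> None:
        if self.worker_count < 0:
            raise ValidationError(f"worker_count must be >= 0, got {self.worker_count}")
        if self.poll_interval <= 0 or self.cycle_interval <= 0:
            raise ValidationError("intervals must be > 0")

    @classmethod
    def from_toml(cls, path) -> "EngineConfig":
        if tomllib is None:  # pragma: no cover
            raise RuntimeError("tomllib unavailable")
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls(**data.get("engine", data))


@dataclass
class _Submission:
    submission_id: int
    request: TaskRequest
    units: list[JobUnit]
    script_path: Optional[Path]

    def status(self) -> SubmissionStatus:
        return status_of(self.submission_id, self.request.basename, self.units)


class Engine:
    """Single master owning pools, worker records and the scheduling cycle.

    All state-mutating entry points take one internal lock, so the engine
    may be driven by one event loop or serviced concurrently (socket server
    threads, worker completions) without extra coordination.
    """

    def __init__(
        self,
        config: EngineConfig,
        transport=None,
        clock: Callable[[], float] = time.time,
    ):
        self.config = config
        self.clock = clock
        self.transport = transport if transport is not None else InMemoryTransport()
        self.transport.register(MASTER)
        self._lock = threading.RLock()
        self.main = JobPool(PoolRole.MAIN)
        self.second = JobPool(PoolRole.SECOND)
        self.first = JobPool(
            PoolRole.FIRST,
            capacity=config.worker_count if config.worker_count > 0 else None,
        )
        self.units: dict[tuple[int, int], JobUnit] = {}
        self.submissions: dict[int, _Submission] = {}
        self.workers: dict[int, WorkerRecord] = {
            wid: WorkerRecord(worker_id=wid) for wid in range(1, config.worker_count + 1)
        }
        for wid in self.workers:
            self.transport.register(worker_endpoint(wid))
        self.accepting = True
        self.stopped = False
        self._next_sid = 1
        self._basenames: set[str] = set()
        self._ack_pending: set[int] = set()

    # -- submission ---------------------------------------------------------

    def handle_submit(self, req: TaskRequest) -> int:
        """Expand a request and append its units to MAIN; return the id."""
        with self._lock:
            if not self.accepting:
                raise SubmissionRejected("engine is shutting down")
            sid = self._next_sid
            self._next_sid += 1
            req.submit_time = self.clock()
            basename = req.basename
            if basename in self._basenames:
                basename = f"{basename}-{sid}"
                req.basename = basename
            self._basenames.add(basename)
            script = materialize_script(req.command_text, basename, self.config.log_dir)
            units = expand_request(req, sid)
            for u in units:
                u.t_submit = req.submit_time
                self.units[u.key] = u
                self.main.append(u)
            self.submissions[sid] = _Submission(sid, req, units, script)
            log.info("submission %d (%s): %d units registered", sid, basename, len(units))
            return sid

    # -- pool management ----------------------------------------------------

    def refill(self) -> tuple[int, int]:
        """Refill the dispatch pool; returns (moved MAIN→SECOND, SECOND→FIRST).

        MAIN is drained into SECOND only when both local pools are empty,
        and FIRST receives at most ``worker_count`` units; MAIN is never
        touched while SECOND still holds units.
        """
        with self._lock:
            second_filled = 0
            first_filled = 0
            if len(self.first) == 0:
                if len(self.second) == 0:
                    second_filled = transfer_all(self.main, self.second)
                if len(self.second) > 0:
                    first_filled = extract_batch(
                        self.second, self.first, self.config.worker_count
                    )
            return second_filled, first_filled

    # -- scheduling ---------------------------------------------------------

    def schedule_step(self, now: Optional[float] = None) -> list[dict]:
        """Pair queued units with idle workers, FIFO; returns issued assignments.

        The idle set is snapshotted at entry (worker-id order) and each
        idle worker receives at most one unit per step.
        """
        with self._lock:
            if now is None:
                now = self.clock()
            if len(self.first) == 0:
                self.refill()
            issued: list[dict] = []
            idle = sorted(
                (w for w in self.workers.values() if w.status is WorkerStatus.IDLE),
                key=lambda w: w.worker_id,
            )
            for w in idle:
                unit = dequeue_next(self.first)
                if unit is None:
                    break
                sub = self.submissions[unit.submission_id]
                unit.assign(w.worker_id, now)
                w.status = WorkerStatus.BUSY
                w.current_unit = unit.key
                payload = {
                    "submission_id": unit.submission_id,
                    "task_index": unit.task_index,
                    "basename": sub.request.basename,
                    "command_text": sub.request.command_text,
                    "script_path": str(sub.script_path) if sub.script_path else None,
                }
                try:
                    self.transport.send(
                        encode(Message(MessageKind.ASSIGN, payload)),
                        dest=worker_endpoint(w.worker_id),
                        source=MASTER,
                    )
                except TransportError as exc:
                    log.warning("worker %d lost at assignment: %s", w.worker_id, exc)
                    self._lose_worker(w, unit, now)
                    continue
                issued.append(payload)
            return issued

    def _lose_worker(self, w: WorkerRecord, unit: JobUnit, now: float) -> None:
        w.status = WorkerStatus.STOPPED
        w.current_unit = None
        unit.start(now)
        unit.finish(EXIT_WORKER_LOST, now)
        if self.config.fail_fast:
            self._cancel_pending(unit.submission_id, now)

    def _cancel_pending(self, sid: int, now: float) -> None:
        """fail_fast: terminate the submission's still-pending units.

        Cancelled units traverse the normal lifecycle atomically with the
        reserved engine actor id as their worker, so the state machine and
        the conservation invariant are untouched.
        """
        for unit in self.submissions[sid].units:
            if unit.state is JobState.PENDING:
                for pool in (self.main, self.second, self.first):
                    try:
                        pool.remove(unit)
                        break
                    except ValueError:
                        continue
                unit.assign(ENGINE_ACTOR, now)
                unit.start(now)
                unit.finish(EXIT_CANCELLED, now)

    # -- completion ---------------------------------------------------------

    def handle_complete(
        self,
        worker_id: int,
        unit_key: tuple[int, int],
        exit_code: int,
        t: Optional[float] = None,
        t_start: Optional[float] = None,
    ) -> Optional[SubmissionStatus]:
        """Record a completion signal; returns the submission's new status.

        A completion for an unknown unit, the wrong worker, or a unit that
        already finished is a protocol error: it is logged and the state is
        left unchanged (``None`` is returned).
        """
        with self._lock:
            key = tuple(unit_key)
            unit = self.units.get(key)
            if unit is None:
                log.error("COMPLETE for unknown unit %s from worker %d", key, worker_id)
                return None
            if unit.finished or unit.worker_id != worker_id:
                log.error(
                    "COMPLETE rejected for unit %s (state=%s, bound worker=%s, sender=%d)",
                    key, unit.state.value, unit.worker_id, worker_id,
                )
                return None
            if t is None:
                t = self.clock()
            if unit.state is JobState.ASSIGNED:
                unit.start(t_start if t_start is not None else t)
            unit.finish(exit_code, t)
            w = self.workers.get(worker_id)
            if w is not None and w.status is not WorkerStatus.STOPPED:
                w.status = WorkerStatus.IDLE
                w.current_unit = None
                w.completed_count += 1
            if exit_code != 0 and self.config.fail_fast:
                self._cancel_pending(unit.submission_id, t)
            return self.submissions[unit.submission_id].status()

    # -- queries ------------------------------------------------------------

    def query_status(self, submission_id: int) -> SubmissionStatus:
        with self._lock:
            sub = self.submissions.get(submission_id)
            if sub is None:
                raise UnknownSubmission(f"unknown submission id {submission_id}")
            return sub.status()

    def all_done(self) -> bool:
        with self._lock:
            return all(u.finished for u in self.units.values())

    # -- message dispatch (client-facing and worker-facing) ------------------

    def handle_message(self, msg: Message) -> Message:
        """Serve one client request; used by every submission carrier."""
        cid = msg.correlation_id
        if msg.kind is MessageKind.SUBMIT:
            try:
                req = TaskRequest(
                    command_text=msg.payload["command_text"],
                    max_task=int(msg.payload["max_task"]),
                    basename=msg.payload["basename"],
                    pipeline_id=msg.payload.get("pipeline_id", ""),
                )
                sid = self.handle_submit(req)
            except (SubmissionRejected, ValidationError, KeyError) as exc:
                return Message(MessageKind.SUBMIT_ACK, {"error": str(exc)}, cid)
            return Message(MessageKind.SUBMIT_ACK, {"submission_id": sid}, cid)
        if msg.kind is MessageKind.STATUS_QUERY:
            try:
                st = self.query_status(int(msg.payload["submission_id"]))
            except (UnknownSubmission, KeyError, ValueError) as exc:
                return Message(MessageKind.STATUS_REPLY, {"error": str(exc)}, cid)
            return Message(
                MessageKind.STATUS_REPLY,
                {
                    "submission_id": st.submission_id,
                    "basename": st.basename,
                    "max_task": st.max_task,
                    "counts": {s.value: n for s, n in st.counts.items()},
                    "all_done": st.all_done,
                    "exit_codes": {str(i): c for i, c in st.exit_codes.items()},
                    "stopped": self.stopped,
                },
                cid,
            )
        if msg.kind is MessageKind.SHUTDOWN:
            with self._lock:
                self.accepting = False
            return Message(MessageKind.SHUTDOWN_ACK, {"initiated": True}, cid)
        return Message(
            MessageKind.STATUS_REPLY, {"error": f"unsupported kind {msg.kind.value}"}, cid
        )

    def pump(self, budget: Optional[int] = None) -> int:
        """Drain the master mailbox (worker COMPLETE / SHUTDOWN_ACK frames).

        Returns the number of frames processed.
        """
        n = 0
        while budget is None or n < budget:
            item = self.transport.recv(MASTER, timeout=0)
            if item is None:
                return n
            frame, _source = item
            msg = decode(frame)
            if msg.kind is MessageKind.COMPLETE:
                p = msg.payload
                self.handle_complete(
                    p["worker_id"],
                    (p["submission_id"], p["task_index"]),
                    p["exit_code"],
                    t=p.get("t_end"),
                    t_start=p.get("t_start"),
                )
            elif msg.kind is MessageKind.SHUTDOWN_ACK:
                self._ack_pending.discard(msg.payload.get("worker_id"))
            n += 1
        return n

    # -- lifecycle ----------------------------------------------------------

    def shutdown(self, ack_timeout: float = 5.0) -> dict:
        """Stop accepting work, dismiss workers, and summarize the run."""
        with self._lock:
            self.accepting = False
            live = [
                w.worker_id
                for w in self.workers.values()
                if w.status is not WorkerStatus.STOPPED
            ]
            self._ack_pending = set(live)
        for wid in live:
            try:
                self.transport.send(
                    encode(Message(MessageKind.SHUTDOWN, {})),
                    dest=worker_endpoint(wid),
                    source=MASTER,
                )
            except TransportError:
                self._ack_pending.discard(wid)
        deadline = time.monotonic() + ack_timeout
        while self._ack_pending and time.monotonic() < deadline:
            item = self.transport.recv(MASTER, timeout=0.05)
            if item is None:
                continue
            msg = decode(item[0])
            if msg.kind is MessageKind.SHUTDOWN_ACK:
                self._ack_pending.discard(msg.payload.get("worker_id"))
            elif msg.kind is MessageKind.COMPLETE:
                p = msg.payload
                self.handle_complete(
                    p["worker_id"],
                    (p["submission_id"], p["task_index"]),
                    p["exit_code"],
                    t=p.get("t_end"),
                    t_start=p.get("t_start"),
                )
        with self._lock:
            self.stopped = True
            return self.summary(unresponsive=sorted(self._ack_pending))

    def summary(self, unresponsive: Optional[list] = None) -> dict:
        """Run summary: terminal counts, per-worker counts, makespan."""
        with self._lock:
            done = sum(1 for u in self.units.values() if u.state is JobState.DONE)
            failed = sum(1 for u in self.units.values() if u.state is JobState.FAILED)
            never_assigned = sum(
                1 for u in self.units.values() if u.state is JobState.PENDING
            )
            in_flight = len(self.units) - done - failed - never_assigned
            ends = [u.t_end for u in self.units.values() if u.t_end is not None]
            starts = [u.t_submit for u in self.units.values() if u.t_submit is not None]
            return {
                "total_units": len(self.units),
                "done": done,
                "failed": failed,
                "never_assigned": never_assigned,
                "in_flight": in_flight,
                "per_worker_completed": {
                    w.worker_id: w.completed_count for w in self.workers.values()
                },
                "makespan": (max(ends) - min(starts)) if ends and starts else 0.0,
                "unresponsive_workers": unresponsive or [],
            }

    def timeline(self) -> ScheduleTimeline:
        """Timeline of all finished units (for export and plots)."""
        with self._lock:
            records = [
                TimelineRecord(
                    submission=self.submissions[u.submission_id].request.basename,
                    task_index=u.task_index,
                    worker_id=u.worker_id if u.worker_id is not None else -1,
                    t_start=u.t_start,
                    t_end=u.t_end,
                )
                for u in self.units.values()
                if u.finished and u.t_start is not None
            ]
            records.sort(key=lambda r: (r.t_start, r.submission, r.task_index))
            starts = [u.t_submit for u in self.units.values() if u.t_submit is not None]
            return ScheduleTimeline(records=records, t0=min(starts, default=0.0))


def write_summary_tsv(summary: dict, path) -> Path:
    """Persist a run summary as key/value TSV with one per-worker section."""
    path = Path(path)
    with open(path, "w") as fh:
        for key in (
            "total_units", "done", "failed", "never_assigned", "in_flight", "makespan",
        ):
            fh.write(f"{key}\t{summary[key]}\n")
        fh.write(
            "unresponsive_workers\t"
            + ",".join(str(w) for w in summary["unresponsive_workers"]) + "\n"
        )
        fh.write("worker_id\tcompleted\n")
        for wid, n in sorted(summary["per_worker_completed"].items()):
            fh.write(f"{wid}\t{n}\n")
    return path
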