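"""Domain model of the job farm: submissions, array-expanded job units,
the three FIFO job pools, and worker state.

A *submission* is one array job: a command script plus the number of array
elements (``max_task``) and a label (``basename``).  The engine expands it
into ``max_task`` :class:`JobUnit` objects, one per 1-based task index, and
moves them through three pools:

``MAIN``
    registration pool; every submission is appended here in arrival order.
``SECOND``
    bulk staging pool; the entire MAIN pool is copied here at once so the
    scheduler does not touch the (conceptually shared) MAIN pool on every
    assignment.
``FIRST``
    dispatch pool, at most one unit per worker; the scheduler assigns from
    here so the container it scans stays small.

Pools hold *references* to units — a unit's lifecycle state has one home —
and a unit resides in at most one pool at a time.  This module is pure data
and pool-transfer logic; it performs no I/O and knows nothing about
transports or clocks.
"""

from __future__ import annotations

import enum
from collections import deque
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

from .errors import ContractError, InvalidTransition, ValidationError

__all__ = [
    "JobState",
    "PoolRole",
    "WorkerStatus",
    "TaskRequest",
    "JobUnit",
    "JobPool",
    "WorkerRecord",
    "SubmissionStatus",
    "expand_request",
    "transfer_all",
    "extract_batch",
    "dequeue_next",
]


class JobState(str, enum.Enum):
    PENDING = "PENDING"
    ASSIGNED = "ASSIGNED"
    RUNNING = "RUNNING"
    DONE = "DONE"
    FAILED = "FAILED"


class PoolRole(str, enum.Enum):
    MAIN = "MAIN"
    SECOND = "SECOND"
    FIRST = "FIRST"


class WorkerStatus(str, enum.Enum):
    IDLE = "IDLE"
    BUSY = "BUSY"
    STOPPED = "STOPPED"


# legal forward edges of the unit lifecycle
_TRANSITIONS = {
    JobState.PENDING: {JobState.ASSIGNED},
    JobState.ASSIGNED: {JobState.RUNNING},
    JobState.RUNNING: {JobState.DONE, JobState.FAILED},
    JobState.DONE: set(),
    JobState.FAILED: set(),
}


@dataclass
class TaskRequest:
    """One array-job submission: the COMMAND / MAX_TASK / BASENAME triple.

    ``command_text`` is either the content of a shell script or the path to
    an existing executable script.  ``max_task`` is the number of array
    elements.  ``basename`` labels log files and status lookups.
    """

    command_text: str
    max_task: int
    basename: str
    pipeline_id: str = ""
    submit_time: Optional[float] = None

    def __post_init__(self) -> None:
        if not isinstance(self.max_task, int) or self.max_task < 1:
            raise ValidationError(f"max_task must be an integer >= 1, got {self.max_task!r}")
        if not self.basename:
            raise ValidationError("basename must be a non-empty string")
        if not self.command_text:
            raise ValidationError("command_text must be non-empty")


@dataclass
class JobUnit:
    """One array element with its lifecycle state and timestamps.

    State moves only along PENDING → ASSIGNED → RUNNING → {DONE, FAILED};
    any other transition raises :class:`InvalidTransition`.  ``exit_code``
    is present exactly in the terminal states, and DONE means exit code 0.
    """

    submission_id: int
    task_index: int
    state: JobState = JobState.PENDING
    worker_id: Optional[int] = None
    exit_code: Optional[int] = None
    t_submit: Optional[float] = None
    t_assign: Optional[float] = None
    t_start: Optional[float] = None
    t_end: Optional[float] = None

    @property
    def key(self) -> tuple[int, int]:
        return (self.submission_id, self.task_index)

    @property
    def finished(self) -> bool:
        return self.state in (JobState.DONE, JobState.FAILED)

    def _move(self, new: JobState) -> None:
        if new not in _TRANSITIONS[self.state]:
            raise InvalidTransition(
                f"unit {self.key}: illegal transition {self.state.value} -> {new.value}"
            )
        self.state = new

    def assign(self, worker_id: int, t: float) -> None:
        self._move(JobState.ASSIGNED)
        self.worker_id = worker_id
        self.t_assign = t

    def start(self, t: float) -> None:
        self._move(JobState.RUNNING)
        self.t_start = t

    def finish(self, exit_code: int, t: float) -> None:
        self._move(JobState.DONE if exit_code == 0 else JobState.FAILED)
        self.exit_code = exit_code
        self.t_end = t


class JobPool:
    """Ordered FIFO container of job-unit references for one pool role."""

    def __init__(self, role: PoolRole, capacity: Optional[int] = None):
        self.role = PoolRole(role)
        self.capacity = capacity
        self._units: deque[JobUnit] = deque()

    def append(self, unit: JobUnit) -> None:
        if self.capacity is not None and len(self._units) >= self.capacity:
            raise ContractError(
                f"{self.role.value} pool is at capacity {self.capacity}"
            )
        self._units.append(unit)

    def popleft(self) -> JobUnit:
        return self._units.popleft()

    def remove(self, unit: JobUnit) -> None:
        self._units.remove(unit)

    def __len__(self) -> int:
        return len(self._units)

    def __iter__(self) -> Iterator[JobUnit]:
        return iter(self._units)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"JobPool({self.role.value}, n={len(self)})"


@dataclass
class WorkerRecord:
    """Identity and occupancy of one worker endpoint."""

    worker_id: int
    status: WorkerStatus = WorkerStatus.IDLE
    current_unit: Optional[tuple[int, int]] = None
    completed_count: int = 0


@dataclass(frozen=True)
class SubmissionStatus:
    """Snapshot of one submission's per-state unit counts."""

    submission_id: int
    basename: str
    max_task: int
    counts: dict
    exit_codes: dict = field(default_factory=dict)

    @property
    def all_done(self) -> bool:
        return all(
            self.counts.get(s, 0) == 0
            for s in (JobState.PENDING, JobState.ASSIGNED, JobState.RUNNING)
        )

    @property
    def n_failed(self) -> int:
        return self.counts.get(JobState.FAILED, 0)


def expand_request(req: TaskRequest, submission_id: int) -> list[JobUnit]:
    """Expand a submission into ``max_task`` PENDING units, ascending index."""
    if req.max_task < 1:
        raise ValidationError(f"max_task must be >= 1, got {req.max_task}")
    return [
        JobUnit(
            submission_id=submission_id,
            task_index=i,
            t_submit=req.submit_time,
        )
        for i in range(1, req.max_task + 1)
    ]


def transfer_all(main: JobPool, second: JobPool) -> int:
    """Move every unit from MAIN to SECOND, preserving order; return count."""
    if main.role is not PoolRole.MAIN or second.role is not PoolRole.SECOND:
        raise ContractError(
            f"transfer_all needs MAIN->SECOND, got {main.role.value}->{second.role.value}"
        )
    moved = 0
    while len(main):
        second.append(main.popleft())
        moved += 1
    return moved


def extract_batch(second: JobPool, first: JobPool, worker_count: int) -> int:
    """Move the ``min(worker_count, |SECOND|)`` oldest units SECOND → FIRST.

    FIRST must be fully drained first: the dispatch pool is refilled only
    when empty, which is what keeps it at most one unit per worker.
    """
    if second.role is not PoolRole.SECOND or first.role is not PoolRole.FIRST:
        raise ContractError(
            f"extract_batch needs SECOND->FIRST, got {second.role.value}->{first.role.value}"
        )
    if len(first):
        raise ContractError("FIRST pool must be empty before a refill")
    if worker_count < 0:
        raise ContractError(f"worker_count must be >= 0, got {worker_count}")
    k = min(worker_count, len(second))
    for _ in range(k):
        first.append(second.popleft())
    return k


def dequeue_next(first: JobPool) -> Optional[JobUnit]:
    """Remove and return the oldest unit of FIRST, or None when empty."""
    if first.role is not PoolRole.FIRST:
        raise ContractError(f"dequeue_next needs FIRST, got {first.role.value}")
    if not len(first):
        return None
    return first.popleft()


def status_of(
    submission_id: int, basename: str, units: Sequence[JobUnit]
) -> SubmissionStatus:
    """Build a consistent status snapshot over a submission's units."""
    counts = {s: 0 for s in JobState}
    exit_codes: dict[int, Optional[int]] = {}
    for u in units:
        counts[u.state] += 1
        exit_codes[u.task_index] = u.exit_code
    return SubmissionStatus(
        submission_id=submission_id,
        basename=basename,
        max_task=len(units),
        counts=counts,
        exit_codes=exit_codes,
    )
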