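"""Worker endpoints: execute assigned array elements in a POSIX shell and
report completion.

Each unit runs with grid-engine-style context variables in its
environment:

==================  =====================================================
``VGE_TASK_ID``     1-based array index of the unit (the SGE convention)
``VGE_BASENAME``    submission label
``VGE_SUBMISSION_ID``  engine-assigned submission id
``VGE_WORKER_ID``   id of the executing worker
==================  =====================================================

Log discipline: every worker appends one tab-separated line per executed
unit to ``<log_dir>/worker_<id>.log``.  Those files are created *once, by a
single actor, before any worker starts* (:func:`precreate_logs`); workers
only append.  On distributed file systems whose metadata servers sustain on
the order of a thousand requests per second, thousands of workers each
creating a log file at launch is enough to stall the whole machine, so file
creation is kept out of the workers entirely.
"""

from __future__ import annotations

import os
import subprocess
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

from .errors import WorkerError
from .protocol import Message, MessageKind, decode, encode
from .transport import MASTER, worker_endpoint

__all__ = [
    "ExecutionRecord",
    "precreate_logs",
    "materialize_script",
    "run_unit",
    "Worker",
    "EXIT_SCRIPT_UNAVAILABLE",
]

#: reported when the command script cannot be materialized or read
EXIT_SCRIPT_UNAVAILABLE = 254

_SHELL = "/bin/sh"


@dataclass
class ExecutionRecord:
    """Everything one unit execution produced."""

    unit_key: tuple[int, int]
    script_path: Optional[Path]
    env: dict = field(default_factory=dict)
    exit_code: int = 0
    t_start: float = 0.0
    t_end: float = 0.0
    log_path: Optional[Path] = None
    stdout: str = ""
    stderr: str = ""


def precreate_logs(worker_count: int, log_dir) -> list[Path]:
    """Create the per-worker log files from one process, before launch.

    Idempotent: existing files (and anything already appended to them) are
    preserved.  Returns the paths in worker-id order.
    """
    log_dir = Path(log_dir)
    try:
        log_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for wid in range(1, worker_count + 1):
            p = log_dir / f"worker_{wid}.log"
            p.touch(exist_ok=True)
            paths.append(p)
    except OSError as exc:
        raise WorkerError(f"cannot prepare log directory {log_dir}: {exc}") from exc
    return paths


def worker_log_path(log_dir, worker_id: int) -> Path:
    return Path(log_dir) / f"worker_{worker_id}.log"


def materialize_script(command_text: str, basename: str, log_dir) -> Path:
    """Resolve a submission's command to an on-disk script, once.

    If ``command_text`` names an existing file it is used as-is; otherwise
    the text is written to ``<log_dir>/<basename>.sh``.  One script per
    submission (not per unit) keeps metadata operations proportional to
    submissions, not array sizes; units share the script and differ only in
    their environment.
    """
    candidate = Path(command_text.strip())
    try:
        if len(command_text.strip().splitlines()) == 1 and candidate.is_file():
            return candidate
    except OSError:
        pass
    log_dir = Path(log_dir)
    log_dir.mkdir(parents=True, exist_ok=True)
    path = log_dir / f"{basename}.sh"
    text = command_text if command_text.endswith("\n") else command_text + "\n"
    path.write_text(text)
    return path


def _shell_runner(script_path: Path, env: dict) -> tuple[int, str, str]:
    full_env = dict(os.environ)
    full_env.update(env)
    try:
        proc = subprocess.run(
            [_SHELL, str(script_path)],
            env=full_env,
            capture_output=True,
            text=True,
        )
    except FileNotFoundError as exc:  # no shell: the worker cannot operate
        raise WorkerError(f"shell {_SHELL} unavailable: {exc}") from exc
    return proc.returncode, proc.stdout, proc.stderr


def run_unit(
    assignment: dict,
    worker_id: int,
    *,
    log_path=None,
    clock: Callable[[], float] = time.time,
    runner: Optional[Callable[[Path, dict], tuple[int, str, str]]] = None,
) -> ExecutionRecord:
    """Execute one assigned unit and return its record.

    ``assignment`` is an ASSIGN payload: ``submission_id``, ``task_index``,
    ``basename``, and ``script_path`` (materialized by the master at
    submission time).  When ``log_path`` is given it must already exist —
    workers never create files — and one tab-separated line is appended:
    ``t_end  worker_id  submission_id  task_index  COMPLETE  exit_code``.
    """
    key = (assignment["submission_id"], assignment["task_index"])
    env = {
        "VGE_TASK_ID": str(assignment["task_index"]),
        "VGE_BASENAME": str(assignment.get("basename", "")),
        "VGE_SUBMISSION_ID": str(assignment["submission_id"]),
        "VGE_WORKER_ID": str(worker_id),
    }
    if log_path is not None:
        log_path = Path(log_path)
        if not log_path.exists():
            raise WorkerError(
                f"log file {log_path} does not exist; logs must be pre-created"
            )

    script = assignment.get("script_path")
    t_start = clock()
    if script is None or not Path(script).is_file():
        exit_code, out, err = EXIT_SCRIPT_UNAVAILABLE, "", "command script unavailable"
        script_path = None
    else:
        script_path = Path(script)
        exit_code, out, err = (runner or _shell_runner)(script_path, env)
    t_end = clock()

    if log_path is not None:
        with open(log_path, "a") as fh:
            fh.write(
                f"{t_end:.6f}\t{worker_id}\t{assignment['submission_id']}\t"
                f"{assignment['task_index']}\tCOMPLETE\t{exit_code}\n"
            )

    return ExecutionRecord(
        unit_key=key,
        script_path=script_path,
        env=env,
        exit_code=exit_code,
        t_start=t_start,
        t_end=t_end,
        log_path=log_path,
        stdout=out,
        stderr=err,
    )


class Worker:
    """Receive loop of one worker endpoint.

    Waits for ASSIGN frames from the master, executes each unit, sends a
    COMPLETE frame back, and acknowledges SHUTDOWN before exiting.
    """

    def __init__(
        self,
        worker_id: int,
        transport,
        *,
        log_path=None,
        clock: Callable[[], float] = time.time,
        runner: Optional[Callable[[Path, dict], tuple[int, str, str]]] = None,
        recv_timeout: float = 0.2,
    ):
        self.worker_id = worker_id
        self.endpoint = worker_endpoint(worker_id)
        self.transport = transport
        self.log_path = log_path
        self.clock = clock
        self.runner = runner
        self.recv_timeout = recv_timeout
        transport.register(self.endpoint)

    def run(self) -> None:
        """Serve until SHUTDOWN arrives or the endpoint closes."""
        while True:
            try:
                item = self.transport.recv(self.endpoint, timeout=self.recv_timeout)
            except Exception:
                return
            if item is None:
                continue
            frame, _source = item
            msg = decode(frame)
            if msg.kind is MessageKind.SHUTDOWN:
                self._send(Message(MessageKind.SHUTDOWN_ACK, {"worker_id": self.worker_id}))
                return
            if msg.kind is MessageKind.ASSIGN:
                self.serve_one(msg.payload)

    def serve_one(self, assignment: dict) -> ExecutionRecord:
        record = run_unit(
            assignment,
            self.worker_id,
            log_path=self.log_path,
            clock=self.clock,
            runner=self.runner,
        )
        self._send(
            Message(
                MessageKind.COMPLETE,
                {
                    "worker_id": self.worker_id,
                    "submission_id": assignment["submission_id"],
                    "task_index": assignment["task_index"],
                    "exit_code": record.exit_code,
                    "t_start": record.t_start,
                    "t_end": record.t_end,
                },
            )
        )
        return record

    def _send(self, msg: Message) -> None:
        try:
            self.transport.send(encode(msg), dest=MASTER, source=self.endpoint)
        except Exception:
            pass
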