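"""Farm orchestration: wire an engine to its workers on a chosen carrier.

Two ways to run the same engine:

* :class:`LocalFarm` — live mode: the master loop and each worker run in
  their own threads of one process over the in-memory transport, with an
  optional loopback-socket submission server for out-of-process clients.
  This is the desk-scale stand-in for the production layout where the
  master is rank 0 of an MPI job and workers are ranks 1..W.
* :func:`drive_engine` — deterministic mode: a single cooperative loop
  plays master and workers turn by turn on a virtual clock.  Schedules are
  exactly reproducible, which is what the scheduling tests and the
  simulator cross-checks need.
"""

from __future__ import annotations

import threading
from typing import Callable, Optional

from .errors import TransportClosed, VGEError
from .master import Engine, EngineConfig
from .protocol import Message, MessageKind, decode, encode
from .transport import MASTER, InMemoryTransport, MessageServer, worker_endpoint
from .worker import Worker, precreate_logs, worker_log_path

__all__ = ["LocalFarm", "InMemoryClient", "ManualClock", "drive_engine"]


class InMemoryClient:
    """Request channel that calls the engine's dispatcher directly."""

    def __init__(self, engine: Engine):
        self._engine = engine

    def request(self, msg: Message) -> Message:
        return self._engine.handle_message(msg)

    def close(self) -> None:
        pass


class ManualClock:
    """Deterministic clock for driven runs; one tick per scheduling cycle."""

    def __init__(self, start: float = 0.0, tick: float = 1.0):
        self.now = start
        self.tick = tick

    def __call__(self) -> float:
        return self.now

    def advance(self) -> float:
        self.now += self.tick
        return self.now


class LocalFarm:
    """Master + W worker threads in one process.

    Log files are pre-created by this constructor — a single actor, before
    any worker thread starts — and workers only ever append to them.
    """

    def __init__(
        self,
        config: EngineConfig,
        *,
        serve_socket: bool = False,
        runner: Optional[Callable] = None,
    ):
        self.config = config
        self.transport = InMemoryTransport()
        self.log_paths = precreate_logs(config.worker_count, config.log_dir)
        self.engine = Engine(config, self.transport)
        self._workers = [
            Worker(
                wid,
                self.transport,
                log_path=worker_log_path(config.log_dir, wid),
                runner=runner,
            )
            for wid in range(1, config.worker_count + 1)
        ]
        self._threads: list[threading.Thread] = []
        self._stop = threading.Event()
        self._server: Optional[MessageServer] = None
        self._serve_socket = serve_socket
        self.address: Optional[tuple[str, int]] = None
        self._started = False

    def start(self) -> "LocalFarm":
        if self._started:
            raise VGEError("farm already started")
        self._started = True
        for w in self._workers:
            t = threading.Thread(target=w.run, name=f"vge-worker-{w.worker_id}", daemon=True)
            t.start()
            self._threads.append(t)
        master = threading.Thread(target=self._master_loop, name="vge-master", daemon=True)
        master.start()
        self._threads.append(master)
        if self._serve_socket:
            self._server = MessageServer(
                self.engine.handle_message, self.config.host, self.config.port
            )
            self.address = self._server.address
        return self

    def _master_loop(self) -> None:
        while not self._stop.is_set():
            self.engine.pump()
            self.engine.schedule_step()
            self._stop.wait(self.config.cycle_interval)

    def client(self) -> InMemoryClient:
        return InMemoryClient(self.engine)

    def shutdown(self, ack_timeout: float = 5.0) -> dict:
        """Stop the master loop, dismiss workers, and return the summary."""
        self._stop.set()
        summary = self.engine.shutdown(ack_timeout=ack_timeout)
        for t in self._threads:
            t.join(timeout=2.0)
        if self._server is not None:
            self._server.stop()
        return summary

    def __enter__(self) -> "LocalFarm":
        return self.start()

    def __exit__(self, *exc) -> None:
        if not self.engine.stopped:
            self.shutdown()


def drive_engine(
    engine: Engine,
    *,
    executor: Optional[Callable[[dict], int]] = None,
    clock: Optional[ManualClock] = None,
    max_cycles: int = 10_000_000,
) -> list[tuple[int, int]]:
    """Run an engine to completion cooperatively and deterministically.

    Plays every role in turn: one scheduling step, then each worker's
    mailbox is drained and its assignments answered with COMPLETE frames
    (exit code from ``executor``, default 0), then completions are pumped
    back into the master.  The engine must have been constructed with the
    same :class:`ManualClock` passed here (or none, in which case wall time
    stamps are used but the schedule is still deterministic).

    Returns the unit keys in assignment order.
    """
    executor = executor or (lambda assignment: 0)
    transport = engine.transport
    order: list[tuple[int, int]] = []
    for _ in range(max_cycles):
        issued = engine.schedule_step()
        order.extend((p["submission_id"], p["task_index"]) for p in issued)
        now = engine.clock()
        for wid in engine.workers:
            while True:
                try:
                    item = transport.recv(worker_endpoint(wid), timeout=0)
                except TransportClosed:
                    break
                if item is None:
                    break
                msg = decode(item[0])
                if msg.kind is not MessageKind.ASSIGN:
                    continue
                p = msg.payload
                transport.send(
                    encode(
                        Message(
                            MessageKind.COMPLETE,
                            {
                                "worker_id": wid,
                                "submission_id": p["submission_id"],
                                "task_index": p["task_index"],
                                "exit_code": executor(p),
                                "t_start": now,
                                "t_end": now,
                            },
                        )
                    ),
                    dest=MASTER,
                    source=worker_endpoint(wid),
                )
        engine.pump()
        if clock is not None:
            clock.advance()
        if engine.all_done() and not (
            len(engine.main) or len(engine.second) or len(engine.first)
        ):
            return order
    raise VGEError("drive_engine exceeded max_cycles without draining the farm")
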