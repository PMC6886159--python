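"""Pluggable frame delivery between client, master and workers.

Three carriers, one codec:

* :class:`InMemoryTransport` — thread-safe mailboxes inside one process;
  the default for tests and the in-process demo farm.
* :class:`SocketClient` / :class:`MessageServer` — length-prefixed frames
  over a loopback TCP socket; carries client↔master submission traffic
  the way the original middleware's job controller does.  The server binds
  to 127.0.0.1 by default because the submitting pipeline and the master
  are expected to share the master node.
* :class:`MPITransport` — point-to-point messages with the master at rank
  0 and workers at ranks 1..W.  Requires ``mpi4py``; imported lazily.

Delivery contract (all carriers): frames from a given sender to a given
receiver arrive exactly once, in send order, and never partially.
"""

from __future__ import annotations

import socket
import struct
import threading
import time
from collections import deque
from typing import Callable, Optional

from .errors import EngineUnreachable, FramingError, TransportClosed, TransportError
from .protocol import Message, decode, encode

__all__ = [
    "MASTER",
    "worker_endpoint",
    "InMemoryTransport",
    "SocketClient",
    "MessageServer",
    "MPITransport",
]

MASTER = "master"


def worker_endpoint(worker_id: int) -> str:
    return f"worker-{worker_id}"


class InMemoryTransport:
    """Named mailboxes with blocking receive; FIFO per receiver."""

    def __init__(self) -> None:
        self._lock = threading.Lock()
        self._cond = threading.Condition(self._lock)
        self._boxes: dict[str, deque] = {}
        self._closed: set[str] = set()

    def register(self, name: str) -> str:
        with self._lock:
            self._boxes.setdefault(name, deque())
            self._closed.discard(name)
        return name

    def send(self, frame: bytes, dest: str, source: str = "") -> None:
        with self._cond:
            if dest not in self._boxes:
                raise TransportError(f"unknown endpoint {dest!r}")
            if dest in self._closed:
                raise TransportError(f"endpoint {dest!r} is closed")
            self._boxes[dest].append((bytes(frame), source))
            self._cond.notify_all()

    def recv(
        self,
        name: str,
        timeout: Optional[float] = None,
        source_filter: Optional[str] = None,
    ) -> Optional[tuple[bytes, str]]:
        """Next matching (frame, source) or ``None`` on timeout.

        A closed endpoint drains its queued frames first, then raises
        :class:`TransportClosed`.
        """
        deadline = None if timeout is None else time.monotonic() + timeout
        with self._cond:
            while True:
                if name not in self._boxes:
                    raise TransportError(f"unknown endpoint {name!r}")
                box = self._boxes[name]
                for i, (frame, source) in enumerate(box):
                    if source_filter is None or source == source_filter:
                        del box[i]
                        return frame, source
                if name in self._closed:
                    raise TransportClosed(f"endpoint {name!r} is closed")
                if deadline is not None:
                    remaining = deadline - time.monotonic()
                    if remaining <= 0:
                        return None
                    self._cond.wait(remaining)
                else:
                    self._cond.wait()

    def close(self, name: str) -> None:
        with self._cond:
            self._closed.add(name)
            self._cond.notify_all()


# ---------------------------------------------------------------------------
# Loopback socket carrier (client <-> master request/reply)


def _read_exact(sock: socket.socket, n: int) -> bytes:
    buf = b""
    while len(buf) < n:
        chunk = sock.recv(n - len(buf))
        if not chunk:
            raise FramingError(f"connection closed mid-frame ({len(buf)}/{n} bytes)")
        buf += chunk
    return buf


def read_frame(sock: socket.socket) -> bytes:
    header = _read_exact(sock, 4)
    (n,) = struct.unpack(">I", header)
    return header + _read_exact(sock, n)


class SocketClient:
    """Persistent request/reply connection to the submission server."""

    def __init__(self, host: str, port: int, connect_timeout: float = 5.0):
        self._lock = threading.Lock()
        try:
            self._sock = socket.create_connection((host, port), timeout=connect_timeout)
        except OSError as exc:
            raise EngineUnreachable(f"cannot reach engine at {host}:{port}: {exc}") from exc
        self._sock.settimeout(None)

    def request(self, msg: Message) -> Message:
        with self._lock:
            try:
                self._sock.sendall(encode(msg))
                return decode(read_frame(self._sock))
            except OSError as exc:
                raise EngineUnreachable(f"connection lost: {exc}") from exc

    def close(self) -> None:
        try:
            self._sock.close()
        except OSError:
            pass


class MessageServer:
    """Threaded loopback TCP server dispatching frames to a handler.

    The handler is called with each decoded :class:`Message` and must
    return the reply message; the server owns framing only.
    """

    def __init__(self, handler: Callable[[Message], Message], host: str = "127.0.0.1", port: int = 0):
        self._handler = handler
        self._srv = socket.socket(socket.AF_INET, socket.SOCK_STREAM)
        self._srv.setsockopt(socket.SOL_SOCKET, socket.SO_REUSEADDR, 1)
        self._srv.bind((host, port))
        self._srv.listen()
        self.address: tuple[str, int] = self._srv.getsockname()
        self._stop = threading.Event()
        self._threads: list[threading.Thread] = []
        self._accept_thread = threading.Thread(target=self._accept_loop, daemon=True)
        self._accept_thread.start()

    def _accept_loop(self) -> None:
        self._srv.settimeout(0.2)
        while not self._stop.is_set():
            try:
                conn, _ = self._srv.accept()
            except socket.timeout:
                continue
            except OSError:
                break
            t = threading.Thread(target=self._serve, args=(conn,), daemon=True)
            t.start()
            self._threads.append(t)

    def _serve(self, conn: socket.socket) -> None:
        with conn:
            conn.settimeout(0.2)
            while not self._stop.is_set():
                try:
                    frame = read_frame(conn)
                except socket.timeout:
                    continue
                except (FramingError, OSError):
                    return
                reply = self._handler(decode(frame))
                try:
                    conn.sendall(encode(reply))
                except OSError:
                    return

    def stop(self) -> None:
        self._stop.set()
        try:
            self._srv.close()
        except OSError:
            pass
        for t in self._threads:
            t.join(timeout=1.0)
        self._accept_thread.join(timeout=1.0)


# ---------------------------------------------------------------------------
# MPI carrier (optional)


class MPITransport:
    """Frame delivery over MPI point-to-point messages.

    The master occupies rank 0; worker ``i`` occupies rank ``i``.  Endpoint
    names map to ranks (``master`` → 0, ``worker-i`` → i).  Requires
    ``mpi4py``, which is imported lazily so the rest of the package works
    without an MPI stack.
    """

    def __init__(self) -> None:
        try:
            from mpi4py import MPI  # type: ignore[import-not-found]
        except ImportError as exc:  # pragma: no cover - depends on environment
            raise TransportError(
                "the MPI backend requires mpi4py; install the 'mpi' extra"
            ) from exc
        self._mpi = MPI
        self._comm = MPI.COMM_WORLD

    @staticmethod
    def _rank_of(name: str) -> int:
        if name == MASTER:
            return 0
        if name.startswith("worker-"):
            return int(name.split("-", 1)[1])
        raise TransportError(f"unknown endpoint {name!r}")

    def register(self, name: str) -> str:  # pragma: no cover - needs MPI run
        return name

    def send(self, frame: bytes, dest: str, source: str = "") -> None:  # pragma: no cover
        self._comm.send((bytes(frame), source), dest=self._rank_of(dest))

    def recv(self, name, timeout=None, source_filter=None):  # pragma: no cover
        status = self._mpi.Status()
        src = (
            self._rank_of(source_filter)
            if source_filter is not None
            else self._mpi.ANY_SOURCE
        )
        if timeout is not None:
            deadline = time.monotonic() + timeout
            while not self._comm.iprobe(source=src):
                if time.monotonic() > deadline:
                    return None
                time.sleep(0.001)
        frame, source = self._comm.recv(source=src, status=status)
        return frame, source

    def close(self, name: str) -> None:  # pragma: no cover
        pass
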