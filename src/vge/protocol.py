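"""Wire messages, framing codec, and the blocking client call ``vge_task``.

Frame layout (documented bit-exactly):

    +----------------------+----------------------------------------+
    | 4 bytes              | N bytes                                |
    | big-endian uint32 N  | UTF-8 JSON object, keys sorted         |
    +----------------------+----------------------------------------+

The JSON object always has exactly the fields ``kind`` (one of the
:class:`MessageKind` values), ``correlation_id`` (opaque string) and
``payload`` (kind-specific object).  Encoding is deterministic for a given
message: keys are sorted and separators are compact, so equal messages
produce identical byte frames.  Frames are self-delimiting, so any number
of them may be concatenated on one stream.

``vge_task`` is the submission call that replaces ``qsub``: it sends one
SUBMIT, then polls STATUS_QUERY until every array element has finished,
and only then returns the exit codes.  Because it blocks, writing two
calls one after the other in a pipeline script *is* the dependency
mechanism: the second task cannot be submitted before the first completes.
"""

from __future__ import annotations

import enum
import json
import struct
import time
import uuid
from dataclasses import dataclass, field
from typing import Iterable, Optional, Protocol

from .errors import (
    DecodeError,
    EngineInterrupted,
    FramingError,
    SubmissionRejected,
    UnknownSubmission,
    ValidationError,
)

__all__ = [
    "MessageKind",
    "Message",
    "encode",
    "decode",
    "decode_stream",
    "vge_task",
    "RequestChannel",
]

_HEADER = struct.Struct(">I")


class MessageKind(str, enum.Enum):
    SUBMIT = "SUBMIT"
    SUBMIT_ACK = "SUBMIT_ACK"
    STATUS_QUERY = "STATUS_QUERY"
    STATUS_REPLY = "STATUS_REPLY"
    ASSIGN = "ASSIGN"
    COMPLETE = "COMPLETE"
    SHUTDOWN = "SHUTDOWN"
    SHUTDOWN_ACK = "SHUTDOWN_ACK"


@dataclass
class Message:
    kind: MessageKind
    payload: dict = field(default_factory=dict)
    correlation_id: str = ""

    def __post_init__(self) -> None:
        self.kind = MessageKind(self.kind)
        if not self.correlation_id:
            self.correlation_id = uuid.uuid4().hex


def encode(msg: Message) -> bytes:
    """Serialize a message to one self-delimiting frame."""
    try:
        body = json.dumps(
            {
                "kind": msg.kind.value,
                "correlation_id": msg.correlation_id,
                "payload": msg.payload,
            },
            sort_keys=True,
            separators=(",", ":"),
        ).encode("utf-8")
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"payload is not JSON-encodable: {exc}") from exc
    return _HEADER.pack(len(body)) + body


def decode(frame: bytes) -> Message:
    """Inverse of :func:`encode` for exactly one frame."""
    msg, rest = _decode_one(frame)
    if rest:
        raise FramingError(f"{len(rest)} trailing bytes after frame")
    return msg


def _decode_one(buf: bytes) -> tuple[Message, bytes]:
    if len(buf) < _HEADER.size:
        raise FramingError(f"frame too short for length prefix ({len(buf)} bytes)")
    (n,) = _HEADER.unpack_from(buf)
    body = buf[_HEADER.size : _HEADER.size + n]
    if len(body) < n:
        raise FramingError(f"length prefix says {n} bytes, body has {len(body)}")
    try:
        obj = json.loads(body.decode("utf-8"))
    except (UnicodeDecodeError, json.JSONDecodeError) as exc:
        raise DecodeError(f"malformed frame body: {exc}") from exc
    if not isinstance(obj, dict) or set(obj) != {"kind", "correlation_id", "payload"}:
        raise DecodeError("frame body must be an object with kind/correlation_id/payload")
    try:
        kind = MessageKind(obj["kind"])
    except ValueError:
        raise DecodeError(f"unknown message kind {obj['kind']!r}") from None
    if not isinstance(obj["payload"], dict):
        raise DecodeError("payload must be an object")
    return (
        Message(kind=kind, payload=obj["payload"], correlation_id=obj["correlation_id"]),
        buf[_HEADER.size + n :],
    )


def decode_stream(buf: bytes) -> tuple[list[Message], bytes]:
    """Decode all complete frames at the head of ``buf``.

    Returns the decoded messages in stream order plus any unconsumed tail
    (a partial trailing frame is not an error here; it is simply returned).
    """
    out: list[Message] = []
    while True:
        if len(buf) < _HEADER.size:
            return out, buf
        (n,) = _HEADER.unpack_from(buf)
        if len(buf) < _HEADER.size + n:
            return out, buf
        msg, _ = _decode_one(buf[: _HEADER.size + n])
        buf = buf[_HEADER.size + n :]
        out.append(msg)


class RequestChannel(Protocol):
    """Anything that can carry a request/reply exchange with the master."""

    def request(self, msg: Message) -> Message: ...


def vge_task(
    command: str,
    max_task: int,
    basename: str,
    endpoint,
    *,
    pipeline_id: str = "",
    poll_interval: float = 0.05,
    timeout: Optional[float] = None,
) -> list[int]:
    """Submit one array job and block until every element has finished.

    Parameters
    ----------
    command
        Shell-script content, or the path of an existing executable script.
    max_task
        Number of array elements; each runs with ``VGE_TASK_ID`` set to its
        1-based index.
    basename
        Label for logs and status lookup.
    endpoint
        A :class:`RequestChannel`, or a ``(host, port)`` tuple naming the
        loopback submission socket.
    poll_interval
        Seconds between status polls while waiting for completion.
    timeout
        Optional overall deadline in seconds.

    Returns
    -------
    list[int]
        Exit codes indexed by task (element ``i`` is task_index ``i+1``);
        always of length ``max_task``.  Nonzero codes are returned, not
        raised: the caller decides whether a failed element is fatal.
    """
    if max_task < 1:
        raise ValidationError(f"max_task must be >= 1, got {max_task}")
    if not basename:
        raise ValidationError("basename must be non-empty")

    channel, owned = _as_channel(endpoint)
    try:
        ack = channel.request(
            Message(
                MessageKind.SUBMIT,
                {
                    "command_text": command,
                    "max_task": max_task,
                    "basename": basename,
                    "pipeline_id": pipeline_id,
                },
            )
        )
        if ack.kind is not MessageKind.SUBMIT_ACK:
            raise SubmissionRejected(f"unexpected reply kind {ack.kind.value}")
        if "error" in ack.payload:
            raise SubmissionRejected(ack.payload["error"])
        sid = ack.payload["submission_id"]

        deadline = None if timeout is None else time.monotonic() + timeout
        while True:
            reply = channel.request(
                Message(MessageKind.STATUS_QUERY, {"submission_id": sid})
            )
            if reply.kind is not MessageKind.STATUS_REPLY:
                raise SubmissionRejected(f"unexpected reply kind {reply.kind.value}")
            if "error" in reply.payload:
                raise UnknownSubmission(reply.payload["error"])
            if reply.payload["all_done"]:
                codes = reply.payload["exit_codes"]
                return [codes[str(i)] for i in range(1, max_task + 1)]
            if reply.payload.get("stopped"):
                raise EngineInterrupted(
                    f"engine shut down while submission {sid} was incomplete",
                    partial_status=reply.payload,
                )
            if deadline is not None and time.monotonic() > deadline:
                raise EngineInterrupted(
                    f"timed out waiting for submission {sid}",
                    partial_status=reply.payload,
                )
            time.sleep(poll_interval)
    finally:
        if owned:
            channel.close()


def _as_channel(endpoint) -> tuple:
    if isinstance(endpoint, tuple) and len(endpoint) == 2:
        from .transport import SocketClient

        return SocketClient(endpoint[0], endpoint[1]), True
    return endpoint, False
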