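"""Exception hierarchy for the engine, protocol and transports."""


class VGEError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(VGEError, ValueError):
    """Invalid user input (bad request fields, malformed data files)."""


class ContractError(VGEError):
    """An internal precondition was violated (e.g. pool role mismatch)."""


class InvalidTransition(ContractError):
    """A job unit was asked to move outside its legal state machine."""


class FramingError(VGEError):
    """A wire frame is truncated or its length prefix is inconsistent."""


class DecodeError(VGEError):
    """A frame body is not a valid message (bad JSON, unknown kind)."""


class TransportError(VGEError):
    """A frame could not be delivered."""


class TransportClosed(TransportError):
    """The endpoint was closed and its mailbox is drained."""


class EngineUnreachable(VGEError):
    """The submission endpoint could not be contacted."""


class SubmissionRejected(VGEError):
    """The engine refused a submission (e.g. it is shutting down)."""


class UnknownSubmission(VGEError, KeyError):
    """Status was requested for a submission id the engine never issued."""


class EngineInterrupted(VGEError):
    """The engine shut down while a blocking submission was waiting.

    Carries the last observed status snapshot, if any, as ``partial_status``.
    """

    def __init__(self, message: str, partial_status=None):
        super().__init__(message)
        self.partial_status = partial_status


class WorkerError(VGEError):
    """A worker could not operate (missing log file, no shell)."""


class FastqFormatError(ValidationError):
    """A FASTQ stream violates the strict 4-line record dialect."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number
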