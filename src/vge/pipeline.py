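"""Demonstration workload: synthetic paired-end FASTQ data, record-aligned
FASTQ splitting, and the two-stage split → align pipeline pattern.

The pipeline mirrors the canonical scatter step of short-read analysis: a
*splitter* stage divides each input FASTQ into record-aligned chunks (one
array element per input file), and an *align* stage processes every chunk
independently (one array element per chunk).  The aligner is an opaque
command template — by default a stub that records each chunk's record count
and checksum, so the whole pipeline runs offline; substituting e.g. a real
``bwa mem`` template is a configuration change, never a code change.

FASTQ dialect: strict 4-line records (identifier, sequence, separator,
quality), no line wrapping.  The splitter is byte-preserving: concatenating
the chunks in order reproduces the input file exactly.
"""

from __future__ import annotations

import random
import shlex
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

from .errors import FastqFormatError, ValidationError
from .protocol import vge_task

try:
    import tomllib
except ImportError:  # pragma: no cover
    tomllib = None

__all__ = [
    "FastqRecord",
    "ChunkPlan",
    "SampleConfig",
    "generate_fastq",
    "parse_fastq",
    "count_records",
    "chunk_plan",
    "split_fastq",
    "stub_align_script",
    "simple_pipeline",
]

_BASES = "ACGT"
#: read length of the emulated study data (paired-end short reads)
DEFAULT_READ_LEN = 152


@dataclass(frozen=True)
class FastqRecord:
    """One strict 4-line FASTQ record."""

    identifier: str  # includes the leading "@"
    sequence: str
    separator: str  # includes the leading "+"
    quality: str

    def __post_init__(self) -> None:
        if not self.identifier.startswith("@"):
            raise FastqFormatError(f"identifier must start with '@': {self.identifier!r}")
        if not self.separator.startswith("+"):
            raise FastqFormatError(f"separator must start with '+': {self.separator!r}")
        if len(self.sequence) != len(self.quality):
            raise FastqFormatError(
                f"sequence length {len(self.sequence)} != quality length {len(self.quality)}"
            )

    def serialize(self) -> str:
        return f"{self.identifier}\n{self.sequence}\n{self.separator}\n{self.quality}\n"


@dataclass(frozen=True)
class ChunkPlan:
    """Balanced record partition: earlier chunks never smaller than later."""

    total_records: int
    n_chunks: int
    counts: tuple

    def __post_init__(self) -> None:
        if sum(self.counts) != self.total_records:
            raise ValidationError("chunk counts must sum to total_records")
        if self.counts and max(self.counts) - min(self.counts) > 1:
            raise ValidationError("chunk counts must differ by at most 1")
        if list(self.counts) != sorted(self.counts, reverse=True):
            raise ValidationError("earlier chunks must not be smaller than later ones")


def chunk_plan(total_records: int, n_chunks: int) -> ChunkPlan:
    """Plan ``n_chunks`` record counts for ``total_records`` reads.

    Counts are ``ceil`` for the first ``total % n`` chunks and ``floor``
    for the rest.  Empty chunks are refused: ``total_records`` must be at
    least ``n_chunks``.
    """
    if n_chunks < 1:
        raise ValidationError(f"n_chunks must be >= 1, got {n_chunks}")
    if total_records < n_chunks:
        raise ValidationError(
            f"cannot split {total_records} records into {n_chunks} non-empty chunks"
        )
    base, extra = divmod(total_records, n_chunks)
    counts = tuple(base + 1 if i < extra else base for i in range(n_chunks))
    return ChunkPlan(total_records, n_chunks, counts)


def generate_fastq(
    n_reads: int,
    read_len: int = DEFAULT_READ_LEN,
    paired: bool = True,
    seed: int = 0,
    out_dir=".",
    basename: str = "sample",
) -> list[Path]:
    """Write synthetic FASTQ file(s); deterministic for a given seed.

    Paired output yields ``<basename>_R1.fastq`` and ``<basename>_R2.fastq``
    with identical record counts and mate-consistent identifiers
    (``@basename:NNNNNN/1`` and ``/2``).  Bases are i.i.d. uniform over
    ACGT and qualities uniform over Phred 2..40 (offset 33) — shaped like
    real short-read data for splitting/accounting purposes, with no error
    model or genome behind it.
    """
    if n_reads < 0:
        raise ValidationError(f"n_reads must be >= 0, got {n_reads}")
    if read_len < 1:
        raise ValidationError(f"read_len must be >= 1, got {read_len}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)
    mates = (1, 2) if paired else (1,)
    paths = [out_dir / f"{basename}_R{m}.fastq" for m in mates]
    handles = [open(p, "w") for p in paths]
    try:
        for i in range(1, n_reads + 1):
            for m, fh in zip(mates, handles):
                seq = "".join(rng.choice(_BASES) for _ in range(read_len))
                qual = "".join(chr(33 + rng.randint(2, 40)) for _ in range(read_len))
                fh.write(f"@{basename}:{i:06d}/{m}\n{seq}\n+\n{qual}\n")
    finally:
        for fh in handles:
            fh.close()
    return paths


def parse_fastq(path) -> Iterator[FastqRecord]:
    """Iterate strict 4-line records; malformed input raises with line number."""
    with open(path) as fh:
        lineno = 0
        while True:
            id_line = fh.readline()
            if not id_line:
                return
            lineno += 1
            lines = [id_line]
            for _ in range(3):
                line = fh.readline()
                if not line:
                    raise FastqFormatError("truncated record at end of file", lineno)
                lines.append(line)
            id_l, seq, sep, qual = (ln.rstrip("\n") for ln in lines)
            if not id_l.startswith("@"):
                raise FastqFormatError(f"expected '@' identifier, got {id_l!r}", lineno)
            if not sep.startswith("+"):
                raise FastqFormatError(
                    f"expected '+' separator, got {sep!r} (wrapped sequences are not supported)",
                    lineno + 2,
                )
            if len(seq) != len(qual):
                raise FastqFormatError(
                    f"sequence/quality length mismatch ({len(seq)} vs {len(qual)})", lineno + 3
                )
            yield FastqRecord(id_l, seq, sep, qual)
            lineno += 3


def count_records(path) -> int:
    return sum(1 for _ in parse_fastq(path))


def split_fastq(fastq_path, n_chunks: int, out_dir) -> list[Path]:
    """Split a FASTQ file into record-aligned, byte-preserving chunks.

    Chunk ``k`` (1-based, zero-padded) is named ``<stem>.chunk<k>.fastq``.
    Concatenating the chunks in order is byte-identical to the input.
    """
    fastq_path = Path(fastq_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # validate structure first (raises with a line number on malformed input)
    total = count_records(fastq_path)
    plan = chunk_plan(total, n_chunks)
    width = len(str(n_chunks))
    stem = fastq_path.name
    for suffix in (".fastq", ".fq"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    paths = []
    with open(fastq_path, "rb") as src:
        for k, n_records in enumerate(plan.counts, start=1):
            chunk_path = out_dir / f"{stem}.chunk{k:0{width}d}.fastq"
            with open(chunk_path, "wb") as dst:
                for _ in range(n_records * 4):
                    dst.write(src.readline())
            paths.append(chunk_path)
    return paths


@dataclass
class SampleConfig:
    """One sample's pipeline configuration."""

    inputs: list
    n_chunks: int
    workdir: Path
    name: str = "sample"
    aligner_template: Optional[str] = None  # placeholders: {input} {output} {task_id}
    fail_fast: bool = False

    def __post_init__(self) -> None:
        self.inputs = [Path(p) for p in self.inputs]
        self.workdir = Path(self.workdir)
        if not 1 <= len(self.inputs) <= 2:
            raise ValidationError("a sample has one (single-end) or two (paired) inputs")
        if self.n_chunks < 1:
            raise ValidationError("n_chunks must be >= 1")

    @classmethod
    def from_toml(cls, path) -> "SampleConfig":
        if tomllib is None:  # pragma: no cover
            raise RuntimeError("tomllib unavailable")
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls(**data.get("sample", data))


def _select_by_task_id(list_file: Path) -> str:
    # pick line $VGE_TASK_ID of a list file, POSIX sh
    return f'line=$(sed -n "${{VGE_TASK_ID}}p" {shlex.quote(str(list_file))})\n'


def splitter_script(cfg: SampleConfig, inputs_list: Path, chunks_dir: Path) -> str:
    """Stage-1 command: array element i splits input file i."""
    return (
        "set -e\n"
        + _select_by_task_id(inputs_list)
        + f'{shlex.quote(sys.executable)} -m vge split "$line" '
        f"--chunks {cfg.n_chunks} --out-dir {shlex.quote(str(chunks_dir))}\n"
    )


def stub_align_script(chunks_list: Path, out_dir: Path) -> str:
    """Default stage-2 command: per-chunk record count + checksum TSV.

    Stands in for an aligner so the pipeline is fully testable offline;
    output is ``<out_dir>/<chunk>.tsv`` with columns (chunk, n_records,
    checksum).
    """
    return (
        "set -e\n"
        + _select_by_task_id(chunks_list)
        + f'out={shlex.quote(str(out_dir))}/$(basename "$line").tsv\n'
        'n=$(( $(wc -l < "$line") / 4 ))\n'
        'sum=$(cksum < "$line" | cut -d" " -f1)\n'
        'printf "%s\\t%s\\t%s\\n" "$(basename "$line")" "$n" "$sum" > "$out"\n'
    )


def aligner_script(template: str, chunks_list: Path, out_dir: Path) -> str:
    """Wrap a user aligner template into a per-chunk array command."""
    body = template.format(
        input='"$line"', output='"$out"', task_id='"$VGE_TASK_ID"'
    )
    return (
        "set -e\n"
        + _select_by_task_id(chunks_list)
        + f'out={shlex.quote(str(out_dir))}/$(basename "$line").out\n'
        + body
        + "\n"
    )


def simple_pipeline(cfg: SampleConfig, endpoint, *, poll_interval: float = 0.02) -> dict:
    """Run the two-stage split → align pipeline for one sample.

    Stage 1 submits one splitter array job with ``max_task`` equal to the
    number of input files (two for a paired sample); because the submission
    call blocks, stage 2 — one array element per produced chunk — cannot be
    submitted before every split has finished.  Returns per-stage exit
    codes: ``{"splitter": [...], "align": [...]}`` (``align`` is ``None``
    if stage 1 failed under ``fail_fast``).
    """
    cfg.workdir.mkdir(parents=True, exist_ok=True)
    chunks_dir = cfg.workdir / "chunks"
    align_dir = cfg.workdir / "aligned"
    chunks_dir.mkdir(exist_ok=True)
    align_dir.mkdir(exist_ok=True)
    inputs_list = cfg.workdir / "inputs.list"
    inputs_list.write_text("".join(f"{p.resolve()}\n" for p in cfg.inputs))

    codes1 = vge_task(
        splitter_script(cfg, inputs_list, chunks_dir),
        max_task=len(cfg.inputs),
        basename=f"fastq_splitter_{cfg.name}",
        endpoint=endpoint,
        pipeline_id=cfg.name,
        poll_interval=poll_interval,
    )
    report: dict = {"splitter": codes1, "align": None}
    if any(codes1) and cfg.fail_fast:
        return report

    chunks = sorted(chunks_dir.glob("*.fastq"))
    if not chunks:
        raise ValidationError(f"splitter produced no chunks in {chunks_dir}")
    chunks_list = cfg.workdir / "chunks.list"
    chunks_list.write_text("".join(f"{p.resolve()}\n" for p in chunks))

    if cfg.aligner_template:
        script = aligner_script(cfg.aligner_template, chunks_list, align_dir)
    else:
        script = stub_align_script(chunks_list, align_dir)
    report["align"] = vge_task(
        script,
        max_task=len(chunks),
        basename=f"bwa_align_{cfg.name}",
        endpoint=endpoint,
        pipeline_id=cfg.name,
        poll_interval=poll_interval,
    )
    return report
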