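# Methods

## The execution model

`vge` emulates a grid-engine array-job service on a master–worker farm.
One master owns all job state; `W` workers execute shell commands and
report exit codes. The participants exchange length-prefixed JSON frames
(4-byte big-endian length + UTF-8 JSON object with fields `kind`,
`correlation_id`, `payload`; keys sorted, so encoding is deterministic)
over one of three interchangeable carriers: in-process mailboxes, a
loopback TCP socket for client↔master submission traffic, or MPI
point-to-point messages with the master at rank 0. The scheduling logic is
carrier-independent, which the tests exploit: the same workload must
produce the identical schedule on the in-memory and socket paths.

### Two local pools

Submissions are appended to the MAIN pool in arrival order. Because the
main pool is conceptually shared with the submission side, the master
minimises how often it touches it: when its dispatch pool (FIRST) and
staging pool (SECOND) are both empty, it moves *everything* from MAIN to
SECOND in one operation, and whenever FIRST alone is empty it extracts the
`W` oldest units from SECOND. Assignment scans only FIRST, whose size is
bounded by `W` regardless of how many jobs are queued. The refill trigger
("FIRST drained, and MAIN only when SECOND is also drained") is the
deterministic resolution of an otherwise unspecified "from time to time"
copy; it preserves global FIFO order exactly, so the order in which units
leave FIRST equals their registration order into MAIN.

### Dispatch and its determinism

`schedule_step` snapshots the idle workers at entry, sorts them by worker
id, and gives each at most one unit per cycle. In a single-event-loop
master this is equivalent to the natural "while an idle worker and a queued
unit exist, pair them" loop — no completion can arrive mid-step — and it
makes uniform workloads provably round-based: `n` equal-duration units on
`W` workers complete in `ceil(n/W)` rounds, every worker finishing
`floor(n/W)` or `ceil(n/W)` units. These closed forms
(`ideal_makespan`, `rounds_bounds`) are the desk-scale checks for farm
behaviour at any scale: 100,000 × 120 s on 1,999 workers gives
`ceil(100000/1999) · 120 = 6120` s, and 10,000 jobs on 1,999 workers give
five or six jobs per worker.

### Unit lifecycle and failure policy

Units move only along PENDING → ASSIGNED → RUNNING → {DONE, FAILED}; DONE
is exactly exit code 0. There is no automatic retry: a FAILED unit counts
as finished for blocking purposes and its code is surfaced to the caller,
which matches how grid-engine pipelines usually treat array-element
failures (inspect, then resubmit). Two sentinel codes are reserved: 255
for a unit whose worker was lost in flight (the worker is excluded from
further scheduling), 254 for a command script that could not be read. With
`fail_fast` enabled, the first failure of a submission cancels its
still-pending units with code 125; cancelled units are driven through the
normal lifecycle with the reserved actor id 0 as their worker, so the state
machine and the conservation invariant (every expanded unit is in exactly
one pool or terminal, no loss, no duplication) hold unconditionally.

### Blocking submission

`vge_task(command, max_task, basename, endpoint)` submits once and then
polls the master's status endpoint until all elements are terminal
(default poll interval 0.5 s in engine config; the library call takes an
explicit `poll_interval`). Polling rather than a push channel is a design
choice: it is the simplest contract that satisfies the blocking semantics,
it needs no server-initiated connections, and the interval is
configurable. The blocking call is what implements inter-stage
dependencies: a later `vge_task` in the same script cannot submit before an
earlier one returns, so stage order in the script is the dependency graph.
A failed element does not change this — both DONE and FAILED count as
finished, and the caller decides what a nonzero code means.

### File-system discipline

Per-worker log files are created by a single actor before any worker
starts (`precreate_logs`); workers only append one line per executed unit
(timestamp, worker, submission, task index, event, exit code — an invented
but machine-parseable schema). Command scripts are materialized once per
submission, not per unit. Both choices bound the farm's file-creation rate
by `W + #submissions` instead of `#units`, which matters on Lustre-family
file systems: metadata servers sustain on the order of 1300 requests/s
(the default of `mds_load_check`), while naive per-worker file creation at
launch has been observed above 20,000 requests/s on large machines.
`mds_load_check(n_ops, window, limit)` is a strict-inequality advisor:
`rate == limit` is treated as sustainable.

## The simulator

`simulate(requests, n_workers, per_assignment_overhead)` builds the greedy
FIFO schedule by discrete events. A request's units enter the ready queue
in ascending index when the request becomes eligible (submit time reached,
predecessor fully completed); simultaneous eligibility resolves in
request-list order, and all events sharing a timestamp are folded into one
scheduling round (completions first, then releases) before any assignment.
The fold is what makes zero-duration workloads distribute `floor/ceil`
per worker instead of racing one worker through the queue, and it is the
semantics the live engine's cycle-based dispatch realizes. Idle-worker
ties break by lowest worker id.

Master overhead is modelled as a serial occupation of the master for
`per_assignment_overhead` seconds per assignment; a unit starts when its
assignment completes. The measured per-assignment cost of any particular
machine is an *input* to this model, never an assertion of the package —
it is hardware-specific. With overhead 0 the simulated makespan equals
`ideal_makespan` for uniform workloads, which is both a property test and
the cross-check used by the acceptance script.

The simulator is validated against an independent unit-step brute-force
oracle (integer durations, explicit tick loop) on small instances
(n ≤ 50, W ≤ 8): makespan and full assignment order must match. Makespan
monotonicity (non-increasing in workers, non-decreasing in overhead) is
property-tested for independent requests; under dependency constraints
greedy list scheduling can in principle exhibit the classic scheduling
anomalies, so no such guarantee is claimed there.

## The demo pipeline and the synthetic data

`pipeline.simple_pipeline` is the canonical two-stage scatter workload:
stage 1 (`fastq_splitter`) has one array element per input FASTQ file —
two for a paired-end sample — each splitting its file into `n_chunks`
record-aligned chunks; stage 2 (`bwa_align`-shaped) has one element per
chunk. The aligner is an opaque command template with `{input}`,
`{output}`, `{task_id}` placeholders; the default stub writes each chunk's
record count and checksum so the pipeline runs entirely offline, and a real
aligner is a configuration substitution, never a code dependency.

The generator emulates the shape of the emulated study's data — paired-end
reads of 152 bp with mate-consistent identifiers — with i.i.d. uniform
bases and Phred 2–40 qualities, deterministic per seed. It deliberately
models *none* of the content of real sequencing data (no genome, error
profile, duplicate structure or quality correlation): the engine and
splitter treat reads as opaque 4-line records, so passing tests demonstrate
scheduling, splitting and accounting correctness, not anything about
alignment quality. Chunk counts per file are a free parameter (real runs
used file counts in the thousands; the demo defaults to 3 per file to keep
runs instant). The FASTQ dialect is strictly 4 lines per record; wrapped
sequences are rejected with a line number rather than guessed at, and the
splitter is byte-preserving (concatenating chunks reproduces the input
exactly).

## Problem sizes and numerical choices

Desk-scale parameters were chosen so every check runs comfortably on one
CPU: the closed-form/simulator cross-check uses the full 100,000-unit
workload (sub-second), the live-engine jobs-per-worker check runs 10,007
zero-duration units on 8 workers through the real message path
(~15 s), and the wall-clock bound runs 64 × 2 s sleeps on 8 threaded
workers against the 16 s ideal with 50% slack — an informational bound on
scheduling overhead, not a hardware calibration. Timestamps use the wall
clock in live mode and a manual tick clock in driven (deterministic) mode;
timeline exports sort by start time with (submission, index) tie-breaks.

## Known limitations

* The master is single-homed; there is no failover, queue checkpointing,
  priority, preemption, or per-job resource requests.
* Worker loss is detected only at assignment (send failure), not by
  heartbeat while a unit runs.
* The MPI carrier maps endpoints to ranks and is import-guarded; it is not
  exercised by the test suite and should be treated as a deployment
  skeleton.
* The simulator models master overhead as a single serial cost and ignores
  network topology, staging, and storage bandwidth.
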