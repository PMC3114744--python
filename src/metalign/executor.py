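"""Hierarchical dynamic job execution.

A job has an *action*, may create *children* (including from inside the
action, so hierarchies grow dynamically), and may carry a *follow-on*
job that runs only after the job's action and every one of its
descendants have completed successfully. This child/follow-on discipline
is what lets a partitioning step fan out sub-problems in parallel and
then reassemble them afterwards.

Scheduling is intra-process: a serial FIFO mode and a thread-pool
parallel mode. Results must be written by actions into their own slots;
both modes then yield bit-identical outputs.
"""

from __future__ import annotations

import threading
from collections import deque
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Callable, Optional

from .errors import SchedulingError


class Job:
    """An executable action with children and an optional follow-on."""

    _counter = 0
    _counter_lock = threading.Lock()

    def __init__(self, name: str, action: Optional[Callable[["Job"], None]] = None):
        with Job._counter_lock:
            Job._counter += 1
            self.job_id = Job._counter
        self.name = name
        self.action = action
        self.children: list[Job] = []
        self.follow_on: Optional[Job] = None
        self.parent: Optional[Job] = None
        self._attached = False

    def add_child(self, job: "Job") -> "Job":
        if job._attached:
            raise SchedulingError(
                f"job {job.name!r} is already attached to the job graph"
            )
        job._attached = True
        job.parent = self
        self.children.append(job)
        return job

    def set_follow_on(self, job: "Job") -> "Job":
        if self.follow_on is not None:
            raise SchedulingError(f"job {self.name!r} already has a follow-on")
        if job._attached:
            raise SchedulingError(
                f"job {job.name!r} is already attached to the job graph"
            )
        job._attached = True
        job.parent = self
        self.follow_on = job
        return job

    def ancestry(self) -> list[str]:
        chain, node = [], self
        while node is not None:
            chain.append(node.name)
            node = node.parent
        return list(reversed(chain))


@dataclass
class CompletionReport:
    """Outcome of a run: start order, and failure details if any."""

    order: list[str] = field(default_factory=list)
    failed: Optional[str] = None
    failure_ancestry: list[str] = field(default_factory=list)
    error: Optional[BaseException] = None
    cancelled: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.failed is None


class _Scheduler:
    """Tracks subtree completion: a job is *complete* once its action, all
    its children's subtrees, and its follow-on's subtree are done."""

    def __init__(self, report: CompletionReport):
        self.report = report
        self.lock = threading.Lock()
        self.pending_children: dict[int, int] = {}
        self.action_done: dict[int, bool] = {}
        self.failed = False
        self.ready: deque[Job] = deque()

    def submit(self, job: Job) -> None:
        self.pending_children[job.job_id] = 0
        self.action_done[job.job_id] = False
        self.ready.append(job)

    def run_action(self, job: Job) -> list[Job]:
        """Execute the action; returns newly runnable jobs. Thread-safe."""
        pre_children = list(job.children)
        with self.lock:
            self.report.order.append(job.name)
        if job.action is not None:
            job.action(job)
        new_children = job.children
        with self.lock:
            self.action_done[job.job_id] = True
            self.pending_children[job.job_id] = len(new_children)
            for child in new_children:
                self.pending_children[child.job_id] = 0
                self.action_done[child.job_id] = False
            if new_children:
                return list(new_children)
            return self._on_subtree_maybe_done(job)

    def _on_subtree_maybe_done(self, job: Job) -> list[Job]:
        """Called with the lock held, when job's action+children are done."""
        runnable: list[Job] = []
        if job.follow_on is not None and not self.action_done.get(
            job.follow_on.job_id, None
        ) and job.follow_on.job_id not in self.pending_children:
            # children complete; release the follow-on
            fo = job.follow_on
            self.pending_children[fo.job_id] = 0
            self.action_done[fo.job_id] = False
            runnable.append(fo)
            return runnable
        # subtree fully complete -> notify parent
        parent = job.parent
        if parent is not None:
            if parent.follow_on is job:
                # parent's follow-on finished: parent's subtree is complete
                runnable.extend(self._on_subtree_maybe_done(parent))
            else:
                self.pending_children[parent.job_id] -= 1
                if (
                    self.pending_children[parent.job_id] == 0
                    and self.action_done[parent.job_id]
                ):
                    runnable.extend(self._on_subtree_maybe_done(parent))
        return runnable

    def child_finished(self, job: Job) -> list[Job]:
        """A leaf-completion hook used after run_action for childless jobs."""
        return []


def run(root: Job, mode: str = "serial", workers: int = 1) -> CompletionReport:
    """Execute a job hierarchy; raises on failure after cancelling the rest.

    ``mode`` is ``serial`` (deterministic FIFO on one thread) or
    ``parallel`` (thread pool of ``workers``). Child/follow-on ordering is
    honoured in both modes.
    """
    if workers < 1:
        raise SchedulingError("workers must be >= 1")
    if mode not in ("serial", "parallel"):
        raise SchedulingError(f"unknown mode {mode!r}")
    if root._attached:
        raise SchedulingError("root job must not be attached to another graph")
    report = CompletionReport()
    sched = _Scheduler(report)
    sched.submit(root)

    if mode == "serial" or workers == 1:
        queue = sched.ready
        while queue:
            job = queue.popleft()
            try:
                runnable = sched.run_action(job)
            except Exception as exc:
                report.failed = job.name
                report.failure_ancestry = job.ancestry()
                report.error = exc
                report.cancelled = [j.name for j in queue]
                raise SchedulingError(
                    f"job {job.name!r} failed "
                    f"(ancestry: {' -> '.join(job.ancestry())}): {exc}"
                ) from exc
            queue.extend(runnable)
        return report

    done = threading.Event()
    in_flight = [0]
    flight_lock = threading.Lock()
    first_error: list = []

    with ThreadPoolExecutor(max_workers=workers) as pool:

        def dispatch(job: Job) -> None:
            with flight_lock:
                in_flight[0] += 1
            pool.submit(worker, job)

        def worker(job: Job) -> None:
            try:
                if not first_error:
                    runnable = sched.run_action(job)
                    for nxt in runnable:
                        dispatch(nxt)
                else:
                    with sched.lock:
                        report.cancelled.append(job.name)
            except Exception as exc:
                with sched.lock:
                    if not first_error:
                        first_error.append((job, exc))
                        report.failed = job.name
                        report.failure_ancestry = job.ancestry()
                        report.error = exc
            finally:
                with flight_lock:
                    in_flight[0] -= 1
                    if in_flight[0] == 0:
                        done.set()

        while sched.ready:
            dispatch(sched.ready.popleft())
        done.wait()

    if first_error:
        job, exc = first_error[0]
        raise SchedulingError(
            f"job {job.name!r} failed "
            f"(ancestry: {' -> '.join(job.ancestry())}): {exc}"
        ) from exc
    return report


@dataclass(frozen=True)
class ExecutorConfig:
    """How sub-problems are scheduled: 1 job = serial, >1 = thread pool."""

    jobs: int = 1

    @property
    def mode(self) -> str:
        return "serial" if self.jobs <= 1 else "parallel"

    def run(self, root: Job) -> CompletionReport:
        return run(root, mode=self.mode, workers=max(1, self.jobs))
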