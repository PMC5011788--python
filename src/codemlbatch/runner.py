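"""Execute codeml tasks with bounded concurrency, monitoring and control.

The scheduler dispatches tasks FIFO in manifest order, never letting more
than ``max_concurrent`` run at once (one task per core).  With
``max_concurrent="auto"`` the bound is the machine's idle-core estimate at
launch: ``floor(total cores − load average)``, clamped to at least 1.

An *executor* is either an argv prefix (run as a subprocess in the task
directory with the ctl filename appended — the contract real codeml
satisfies) or a Python callable ``f(task_dir) -> exit code`` (used by the
mock).  A failing task never blocks the rest of the batch; with ``resume``
only tasks that are not already done are re-executed.

Tasks are grouped under a batch id; running tasks can be terminated singly
(by process id) or as a whole group, mirroring the interactive process
manager of the original workflow.  A completion summary can be handed to a
pluggable notification channel (a log file by default); channel failures
are logged, never raised into the batch result.
"""

from __future__ import annotations

import json
import logging
import math
import os
import subprocess
import threading
import time
from dataclasses import dataclass, field

from .errors import ValidationError
from .templates import read_ctl

log = logging.getLogger(__name__)

TERMINAL = ("done", "failed")


def estimate_available_cores(total: int, load: float) -> int:
    """Idle-core estimate: floor(total − load), clamped to [1, total]."""
    if total < 1:
        raise ValidationError("total cores must be >= 1")
    if load < 0:
        raise ValidationError("load must be >= 0")
    return max(1, min(total, math.floor(total - load)))


def system_available_cores() -> int:
    total = os.cpu_count() or 1
    try:
        load = os.getloadavg()[0]
    except OSError:
        load = 0.0
    return estimate_available_cores(total, load)


@dataclass
class TaskRun:
    """The scheduler's account of one task."""

    task_dir: str
    proc_id: int
    status: str = "pending"
    exit_code: int | None = None
    started: float | None = None
    ended: float | None = None
    note: str = ""
    stalled: bool = False
    _popen: object = field(default=None, repr=False)
    _thread: object = field(default=None, repr=False)
    _result: dict = field(default_factory=dict, repr=False)
    _terminate: bool = field(default=False, repr=False)


@dataclass
class RunReport:
    group_id: str
    tasks: list = field(default_factory=list)
    peak_concurrency: int = 0

    @property
    def counts(self) -> dict:
        out = {"pending": 0, "running": 0, "done": 0, "failed": 0}
        for t in self.tasks:
            out[t.status] += 1
        return out

    def running(self):
        return [t for t in self.tasks if t.status == "running"]

    def summary(self) -> str:
        c = self.counts
        return (f"group {self.group_id}: {len(self.tasks)} tasks — "
                f"done {c['done']}, failed {c['failed']}, "
                f"pending {c['pending']}, running {c['running']}; "
                f"peak concurrency {self.peak_concurrency}")

    def persist(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            for t in self.tasks:
                fh.write(json.dumps({
                    "task_dir": t.task_dir, "proc_id": t.proc_id,
                    "group_id": self.group_id, "status": t.status,
                    "exit_code": t.exit_code, "started": t.started,
                    "ended": t.ended, "note": t.note, "stalled": t.stalled,
                }) + "\n")


def _task_outfile(task_dir: str) -> str | None:
    ctl = os.path.join(task_dir, "codeml.ctl")
    if not os.path.exists(ctl):
        return None
    try:
        params = read_ctl(ctl).params
    except Exception:
        return None
    return os.path.join(task_dir, params.get("outfile", "results.txt"))


def _task_done(task_dir: str) -> bool:
    out = _task_outfile(task_dir)
    return bool(out and os.path.exists(out) and os.path.getsize(out) > 0)


def _start(task: TaskRun, executor, root: str):
    task_dir = os.path.join(root, task.task_dir)
    task.started = time.time()
    task.status = "running"
    if callable(executor):
        def run():
            try:
                task._result["code"] = executor(task_dir)
            except Exception as e:   # executor bugs count as task failures
                task._result["code"] = 1
                task._result["error"] = str(e)
        th = threading.Thread(target=run, daemon=True)
        task._thread = th
        th.start()
    else:
        argv = list(executor) + ["codeml.ctl"]
        try:
            task._popen = subprocess.Popen(
                argv, cwd=task_dir,
                stdout=subprocess.DEVNULL, stderr=subprocess.DEVNULL,
            )
        except OSError as e:
            task.status = "failed"
            task.ended = time.time()
            task.note = f"executor not found or failed to start: {e}"


def _poll(task: TaskRun) -> bool:
    """True when the task just reached a terminal state."""
    if task.status != "running":
        return False
    code = None
    if task._popen is not None:
        code = task._popen.poll()
        if code is None:
            return False
    elif task._thread is not None:
        if task._thread.is_alive():
            return False
        code = task._result.get("code", 1)
    else:
        return False
    task.ended = time.time()
    task.exit_code = code
    if task._terminate or (task._popen is not None and code is not None and code < 0):
        task.status = "failed"
        task.note = task.note or "terminated"
    elif code == 0:
        task.status = "done"
    else:
        task.status = "failed"
        task.note = task._result.get("error", task.note)
    return True


def schedule(tasks, max_concurrent="auto", executor=None, root: str = ".",
             resume: bool = False, poll_interval: float = 0.01,
             controller=None, stall_timeout: float | None = None,
             report_path: str | None = None, group_id: str | None = None) -> RunReport:
    """Run a batch of tasks under a concurrency bound; returns the report.

    *tasks* is the manifest task list (dicts with ``task_dir``) or TaskSpec
    objects.  *controller*, if given, is invoked with the live report on
    every poll cycle (the hook the interactive monitor and the termination
    tests use).  With *stall_timeout*, a running task whose output file has
    not grown for that many seconds is flagged ``stalled`` (flagged only,
    never killed).
    """
    if executor is None:
        executor = ["codeml"]
    if max_concurrent == "auto":
        bound = system_available_cores()
    else:
        bound = int(max_concurrent)
        if bound < 1:
            raise ValidationError("max_concurrent must be >= 1")
    gid = group_id or f"batch-{os.getpid()}-{int(time.time() * 1000) % 1000000}"
    report = RunReport(group_id=gid)
    queue = []
    for i, t in enumerate(tasks, 1):
        task_dir = t["task_dir"] if isinstance(t, dict) else t.task_dir
        run = TaskRun(task_dir=task_dir, proc_id=i)
        report.tasks.append(run)
        if resume and _task_done(os.path.join(root, task_dir)):
            run.status = "done"
            run.exit_code = 0
            run.note = "already complete (resume)"
        else:
            queue.append(run)

    watch = {}   # proc_id -> (outfile, last size, last change time)
    while True:
        for task in report.running():
            _poll(task)
        while queue and len(report.running()) < bound:
            task = queue.pop(0)
            if task.status != "pending":    # terminated while queued
                continue
            _start(task, executor, root)
            report.peak_concurrency = max(report.peak_concurrency,
                                          len(report.running()))
            if stall_timeout:
                out = _task_outfile(os.path.join(root, task.task_dir))
                watch[task.proc_id] = [out, -1, time.time()]
        if stall_timeout:
            now = time.time()
            for task in report.running():
                w = watch.get(task.proc_id)
                if not w:
                    continue
                size = os.path.getsize(w[0]) if w[0] and os.path.exists(w[0]) else -1
                if size != w[1]:
                    w[1], w[2] = size, now
                elif now - w[2] > stall_timeout:
                    task.stalled = True
        if controller is not None:
            controller(report)
        if not queue and not report.running():
            break
        time.sleep(poll_interval)

    if report_path:
        report.persist(report_path)
    return report


def terminate_tasks(report: RunReport, group: str | None = None,
                    proc: int | None = None) -> list:
    """Terminate a whole group (``G:<id>``) or one task (``P:<id>``).

    Returns a list of message strings describing what happened.  Unknown
    ids and already-finished tasks produce warnings and no change.
    """
    messages = []
    if group is not None:
        if group != report.group_id:
            return [f"unknown group id {group!r}"]
        targets = list(report.tasks)
    elif proc is not None:
        targets = [t for t in report.tasks if t.proc_id == proc]
        if not targets:
            return [f"unknown process id {proc}"]
    else:
        raise ValidationError("give a group or a process id")
    for task in targets:
        if task.status in TERMINAL:
            messages.append(f"task {task.proc_id} already {task.status}; no-op")
            continue
        task._terminate = True
        task.note = "terminated"
        if task.status == "pending":
            task.status = "failed"
            messages.append(f"task {task.proc_id} removed from queue")
        elif task._popen is not None:
            task._popen.terminate()
            messages.append(f"task {task.proc_id} sent SIGTERM")
        else:
            messages.append(f"task {task.proc_id} flagged for termination")
    return messages


@dataclass
class DeliveryRecord:
    delivered: bool
    message: str


class LogChannel:
    """Built-in notification channel: appends the summary to a log file."""

    def __init__(self, path):
        self.path = str(path)

    def __call__(self, summary: str):
        with open(self.path, "a", encoding="utf-8") as fh:
            fh.write(summary + "\n")


def notify(report: RunReport, channel=None) -> DeliveryRecord:
    """Hand the batch summary to a notification channel (optional).

    No channel configured is silent success; a channel that raises is
    logged and reported undelivered — notification never corrupts the
    batch result.
    """
    summary = report.summary()
    if channel is None:
        return DeliveryRecord(False, "no channel configured")
    try:
        channel(summary)
    except Exception as e:
        log.error("notification channel failed: %s", e)
        return DeliveryRecord(False, f"channel failed: {e}")
    return DeliveryRecord(True, summary)
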