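"""Scheduler: core estimation, concurrency bound, failure isolation,
termination, resume and notification."""

import json
import os
import random
import sys
import threading
import time

import pytest

from codemlbatch import runner
from codemlbatch.errors import ValidationError
from codemlbatch.runner import (LogChannel, RunReport, estimate_available_cores,
                                notify, schedule, terminate_tasks)


class TestCoreEstimate:
    @pytest.mark.parametrize("total,load,expected", [
        (8, 0.0, 8),
        (32, 20.5, 11),
        (4, 6.0, 1),
        (1, 0.0, 1),
        (16, 15.9, 1),  # floor then clamp
        (8, -0.0, 8),
    ])
    def test_floor_and_clamp(self, total, load, expected):
        assert estimate_available_cores(total, load) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            estimate_available_cores(0, 1.0)
        with pytest.raises(ValidationError):
            estimate_available_cores(4, -1.0)


def _make_tasks(tmp_path, n, outfile="results.txt"):
    tasks = []
    for i in range(n):
        d = tmp_path / f"t{i}"
        d.mkdir()
        (d / "codeml.ctl").write_text(f"outfile = {outfile}\n")
        tasks.append({"task_dir": f"t{i}"})
    return tasks


class _Probe:
    """In-process executor instrumenting concurrent invocations."""

    def __init__(self, durations=None, fail=(), write_output=True):
        self.lock = threading.Lock()
        self.active = 0
        self.peak = 0
        self.calls = []
        self.durations = durations or {}
        self.fail = set(fail)
        self.write_output = write_output

    def __call__(self, task_dir):
        name = os.path.basename(task_dir)
        with self.lock:
            self.active += 1
            self.peak = max(self.peak, self.active)
            self.calls.append(name)
        time.sleep(self.durations.get(name, 0.01))
        with self.lock:
            self.active -= 1
        if name in self.fail:
            return 1
        if self.write_output:
            with open(os.path.join(task_dir, "results.txt"), "w") as fh:
                fh.write("ok\n")
        return 0


class TestSchedule:
    def test_bound_respected_and_all_done(self, tmp_path):
        tasks = _make_tasks(tmp_path, 5)
        probe = _Probe()
        report = schedule(tasks, max_concurrent=2, executor=probe,
                          root=str(tmp_path))
        assert report.counts["done"] == 5
        assert probe.peak <= 2
        assert report.peak_concurrency <= 2

    def test_bound_never_exceeded_over_randomized_trials(self, tmp_path, rng):
        """Randomized durations, many trials: concurrency stays within -n."""
        for trial in range(50):
            base = tmp_path / f"trial{trial}"
            base.mkdir()
            n = rng.randint(2, 6)
            bound = rng.randint(1, 4)
            tasks = _make_tasks(base, n)
            probe = _Probe(durations={f"t{i}": rng.uniform(0, 0.02)
                                      for i in range(n)})
            report = schedule(tasks, max_concurrent=bound, executor=probe,
                              root=str(base), poll_interval=0.002)
            assert probe.peak <= bound
            assert report.peak_concurrency <= bound
            assert report.counts["done"] == n

    def test_empty_batch(self, tmp_path):
        report = schedule([], max_concurrent=2, executor=_Probe(),
                          root=str(tmp_path))
        assert report.tasks == [] and report.counts["done"] == 0

    def test_failing_task_isolated(self, tmp_path):
        tasks = _make_tasks(tmp_path, 3)
        probe = _Probe(fail={"t1"})
        report = schedule(tasks, max_concurrent=2, executor=probe,
                          root=str(tmp_path))
        statuses = {t.task_dir: t.status for t in report.tasks}
        assert statuses == {"t0": "done", "t1": "failed", "t2": "done"}

    def test_fifo_dispatch_in_manifest_order(self, tmp_path):
        tasks = _make_tasks(tmp_path, 6)
        probe = _Probe()
        schedule(tasks, max_concurrent=1, executor=probe, root=str(tmp_path))
        assert probe.calls == [f"t{i}" for i in range(6)]

    def test_missing_subprocess_executor_fails_tasks(self, tmp_path):
        tasks = _make_tasks(tmp_path, 2)
        report = schedule(tasks, max_concurrent=1,
                          executor=["/nonexistent/codeml-binary"],
                          root=str(tmp_path))
        assert report.counts["failed"] == 2
        assert all("executor" in t.note for t in report.tasks)

    def test_status_counts_sum_to_task_count(self, tmp_path):
        tasks = _make_tasks(tmp_path, 4)
        report = schedule(tasks, max_concurrent=2, executor=_Probe(fail={"t0"}),
                          root=str(tmp_path))
        assert sum(report.counts.values()) == 4

    def test_resume_reruns_only_unfinished(self, tmp_path):
        tasks = _make_tasks(tmp_path, 4)
        probe = _Probe(fail={"t2"})
        schedule(tasks, max_concurrent=2, executor=probe, root=str(tmp_path))
        probe2 = _Probe()
        report = schedule(tasks, max_concurrent=2, executor=probe2,
                          root=str(tmp_path), resume=True)
        assert sorted(probe2.calls) == ["t2"]
        assert report.counts["done"] == 4
        notes = {t.task_dir: t.note for t in report.tasks}
        assert "already complete" in notes["t0"]

    def test_report_persisted(self, tmp_path):
        tasks = _make_tasks(tmp_path, 2)
        path = tmp_path / "report.jsonl"
        schedule(tasks, max_concurrent=2, executor=_Probe(),
                 root=str(tmp_path), report_path=str(path))
        lines = [json.loads(l) for l in path.read_text().splitlines()]
        assert [l["status"] for l in lines] == ["done", "done"]
        assert len({l["group_id"] for l in lines}) == 1


class TestTermination:
    def _sleeper_argv(self):
        return [sys.executable, "-c",
                "import time, sys; time.sleep(30)", "--"]

    def test_terminate_single_of_three(self, tmp_path):
        tasks = _make_tasks(tmp_path, 3)
        done = {}

        def controller(report):
            running = report.running()
            if running and not done.get("fired"):
                done["fired"] = True
                msgs = terminate_tasks(report, proc=running[0].proc_id)
                done["msgs"] = msgs
                done["victim"] = running[0].task_dir
                # release the others quickly
                for t in report.tasks:
                    if t is not running[0] and t._popen is not None:
                        t._popen.terminate()

        report = schedule(tasks, max_concurrent=3,
                          executor=self._sleeper_argv(), root=str(tmp_path),
                          controller=controller, poll_interval=0.02)
        victim = next(t for t in report.tasks if t.task_dir == done["victim"])
        assert victim.status == "failed" and victim.note == "terminated"
        assert done["msgs"]

    def test_terminate_group_kills_all(self, tmp_path):
        tasks = _make_tasks(tmp_path, 3)
        fired = {}

        def controller(report):
            if report.running() and not fired.get("x"):
                fired["x"] = True
                terminate_tasks(report, group=report.group_id)

        report = schedule(tasks, max_concurrent=2,
                          executor=self._sleeper_argv(), root=str(tmp_path),
                          controller=controller, poll_interval=0.02)
        assert report.counts["failed"] == 3
        assert all(t.note == "terminated" for t in report.tasks)

    def test_terminate_finished_is_noop(self, tmp_path):
        tasks = _make_tasks(tmp_path, 1)
        report = schedule(tasks, max_concurrent=1, executor=_Probe(),
                          root=str(tmp_path))
        msgs = terminate_tasks(report, proc=1)
        assert "no-op" in msgs[0]
        assert report.tasks[0].status == "done"

    def test_unknown_ids(self, tmp_path):
        report = RunReport(group_id="g1")
        assert "unknown group" in terminate_tasks(report, group="nope")[0]
        assert "unknown process" in terminate_tasks(report, proc=9)[0]


class TestNotify:
    def _report(self):
        r = RunReport(group_id="g")
        r.tasks = [runner.TaskRun("a", 1, status="done"),
                   runner.TaskRun("b", 2, status="failed")]
        return r

    def test_log_channel_summary_counts(self, tmp_path):
        r = self._report()
        path = tmp_path / "notify.log"
        rec = notify(r, LogChannel(path))
        assert rec.delivered
        line = path.read_text()
        assert "done 1" in line and "failed 1" in line and "2 tasks" in line

    def test_no_channel_is_silent_success(self):
        rec = notify(self._report(), None)
        assert not rec.delivered and "no channel" in rec.message

    def test_channel_failure_never_raises(self):
        def bad(_): raise OSError("smtp down")
        rec = notify(self._report(), bad)
        assert not rec.delivered and "smtp down" in rec.message
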