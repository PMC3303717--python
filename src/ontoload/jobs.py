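"""Fault-tolerant job dispatch for batch loading.

Each entry of each flat file becomes one job carrying its seek offsets and
GI number, with a state machine ready -> pending -> loaded (pending jobs
can be reset to ready after a failure).  The ledger is persisted as a JSON
snapshot written atomically at checkpoints; completions between
checkpoints live in memory only, so after a hard crash they are simply
re-dispatched — per-entry transactions plus GI-idempotent loading make
re-execution harmless (exactly-once effect on the database).
"""
from __future__ import annotations

import json
import os
import threading
from dataclasses import dataclass, field
from typing import Optional

from .errors import JobStateError, OntoloadError
from . import parser

READY, PENDING, LOADED = "ready", "pending", "loaded"


@dataclass
class Job:
    path: str
    header_seek_offset: int
    sequence_seek_offset: int
    gi: int
    state: str = READY


@dataclass
class JobLedger:
    path: Optional[str] = None  # persistence path; None keeps it in memory
    jobs: dict[int, Job] = field(default_factory=dict)  # keyed by gi
    checkpoint_interval: int = 10
    _lock: threading.Lock = field(default_factory=threading.Lock, repr=False)
    _since_checkpoint: int = 0

    # -- construction ------------------------------------------------------

    @classmethod
    def open(cls, path: str, checkpoint_interval: int = 10) -> "JobLedger":
        ledger = cls(path=path, checkpoint_interval=checkpoint_interval)
        if os.path.exists(path):
            with open(path, "r", encoding="utf-8") as fh:
                data = json.load(fh)
            for rec in data.get("jobs", []):
                job = Job(**rec)
                if job.state == PENDING:  # dispatched but never completed
                    job.state = PENDING
                ledger.jobs[job.gi] = job
        return ledger

    def counts(self) -> dict[str, int]:
        with self._lock:
            out = {READY: 0, PENDING: 0, LOADED: 0}
            for job in self.jobs.values():
                out[job.state] += 1
            return out

    # -- persistence -------------------------------------------------------

    def checkpoint(self) -> None:
        """Write a durable snapshot (atomic replace). No-op for in-memory ledgers."""
        if self.path is None:
            return
        with self._lock:
            payload = {
                "jobs": [
                    {
                        "path": j.path,
                        "header_seek_offset": j.header_seek_offset,
                        "sequence_seek_offset": j.sequence_seek_offset,
                        "gi": j.gi,
                        "state": j.state,
                    }
                    for j in sorted(self.jobs.values(), key=lambda j: j.gi)
                ]
            }
            tmp = self.path + ".tmp"
            with open(tmp, "w", encoding="utf-8") as fh:
                json.dump(payload, fh)
                fh.flush()
                os.fsync(fh.fileno())
            os.replace(tmp, self.path)
            self._since_checkpoint = 0

    # -- dispatch protocol -------------------------------------------------

    def next_job(self) -> Optional[Job]:
        """Atomically move one ready job to pending; None when exhausted."""
        with self._lock:
            for job in sorted(self.jobs.values(), key=lambda j: j.gi):
                if job.state == READY:
                    job.state = PENDING
                    return job
            return None

    def mark_completed(self, gi: int) -> None:
        """pending -> loaded. Completing twice is acknowledged silently;
        completing a never-dispatched job is a state error."""
        checkpoint_now = False
        with self._lock:
            job = self.jobs.get(gi)
            if job is None:
                raise JobStateError(f"unknown job gi {gi}")
            if job.state == LOADED:
                return
            if job.state != PENDING:
                raise JobStateError(f"job {gi} is {job.state}, cannot complete")
            job.state = LOADED
            self._since_checkpoint += 1
            checkpoint_now = (
                self.checkpoint_interval > 0
                and self._since_checkpoint >= self.checkpoint_interval
            )
        if checkpoint_now:
            self.checkpoint()

    def reset_pending(self) -> int:
        """Recovery: all pending jobs go back to ready (no active workers assumed)."""
        with self._lock:
            n = 0
            for job in self.jobs.values():
                if job.state == PENDING:
                    job.state = READY
                    n += 1
        if n:
            self.checkpoint()
        return n


def build_job_list(
    flat_file_paths: list[str],
    ledger_path: Optional[str] = None,
    checkpoint_interval: int = 10,
) -> JobLedger:
    """Index flat files into one ready job per entry.

    Rebuilding over an existing ledger preserves loaded states, so a new
    release can be layered on without re-loading what is already in.
    """
    existing: dict[int, str] = {}
    if ledger_path and os.path.exists(ledger_path):
        old = JobLedger.open(ledger_path)
        existing = {gi: j.state for gi, j in old.jobs.items()}
    ledger = JobLedger(path=ledger_path, checkpoint_interval=checkpoint_interval)
    seen: dict[int, str] = {}
    duplicates: list[int] = []
    for path in flat_file_paths:
        for header_off, seq_off, gi in parser.index_entries(path):
            if gi in seen:
                duplicates.append(gi)
                continue
            seen[gi] = path
            state = LOADED if existing.get(gi) == LOADED else READY
            ledger.jobs[gi] = Job(
                path=str(path),
                header_seek_offset=header_off,
                sequence_seek_offset=seq_off,
                gi=gi,
                state=state,
            )
    if duplicates:
        raise OntoloadError(f"duplicate GI numbers across input files: {sorted(duplicates)}")
    ledger.checkpoint()
    return ledger
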