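"""Docking orchestration: job enumeration, config generation, pluggable
backends, checkpointed execution, and a claim/ack work queue.

Every (receptor, ligand) pair is docked in independent replicates (three by
default), each with its own persisted random seed, to reduce the chance of
the stochastic search converging to a local minimum.  Completion is
recorded by zero-byte ``.done`` markers written only after the output file
is fully on disk, so an interrupted campaign resumes exactly where it
stopped and the final result set is independent of worker count and claim
order.
"""

from __future__ import annotations

import subprocess
import threading
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Protocol

from .errors import EmptyOutputError, VinascreenError
from .formats import Pose, parse_vina_output
from .receptor_prep import SearchBox
from .rng import stable_seed

if TYPE_CHECKING:  # pragma: no cover
    from .fixtures import MockLandscape

DEFAULT_EXHAUSTIVENESS = 9
DEFAULT_CPU = 9
DEFAULT_REPLICATES = 3
DEFAULT_NUM_MODES = 9


@dataclass
class DockingJob:
    receptor_id: str
    ligand_id: str
    replicate_index: int  # 1-based
    seed: int
    box: SearchBox | None = None
    exhaustiveness: int = DEFAULT_EXHAUSTIVENESS
    cpu: int = DEFAULT_CPU
    num_modes: int = DEFAULT_NUM_MODES
    receptor_path: str = ""
    ligand_path: str = ""
    out_path: str = ""
    config_path: str = ""

    @property
    def key(self) -> str:
        return f"{self.receptor_id}__{self.ligand_id}__rep{self.replicate_index}"


@dataclass
class DockingRunResult:
    job: DockingJob
    poses: list[Pose]
    status: str  # ok | failed | empty
    backend_name: str

    def __post_init__(self):
        if self.status == "ok" and not self.poses:
            raise VinascreenError("status ok requires at least one pose")


class CheckpointLedger:
    """Marker-per-job completion ledger backed by a directory of zero-byte
    files named after the job key.  The marker is written only after the
    result file exists, so marker presence implies a complete output."""

    def __init__(self, done_dir: str | Path):
        self.done_dir = Path(done_dir)
        self.done_dir.mkdir(parents=True, exist_ok=True)

    def _marker(self, job: DockingJob) -> Path:
        return self.done_dir / f"{job.key}.done"

    def is_done(self, job: DockingJob) -> bool:
        return self._marker(job).exists()

    def mark_done(self, job: DockingJob) -> None:
        self._marker(job).touch()

    def clear(self, job: DockingJob) -> None:
        self._marker(job).unlink(missing_ok=True)


def enumerate_jobs(
    receptor_ids: Iterable[str],
    ligand_ids: Iterable[str],
    replicates: int = DEFAULT_REPLICATES,
    master_seed: int = 0,
    box_of: dict[str, SearchBox] | None = None,
    **job_kwargs,
) -> list[DockingJob]:
    """The full cross product receptors x ligands x replicates.

    Per-job seeds are a pure function of (master seed, receptor, ligand,
    replicate); identical inputs always yield the identical job list and
    seed manifest.  Seeds within one (receptor, ligand) triple are kept
    distinct by salted re-hashing in the (vanishingly rare) collision case.
    """
    receptor_ids = list(receptor_ids)
    ligand_ids = list(ligand_ids)
    if not receptor_ids or not ligand_ids:
        raise VinascreenError("receptor and ligand id lists must be non-empty")
    if len(set(receptor_ids)) != len(receptor_ids):
        raise VinascreenError("duplicate receptor ids")
    if len(set(ligand_ids)) != len(ligand_ids):
        raise VinascreenError("duplicate ligand ids")
    if replicates < 1:
        raise VinascreenError("replicates must be >= 1")
    jobs = []
    for rid in receptor_ids:
        box = box_of.get(rid) if box_of else None
        for lid in ligand_ids:
            seeds: set[int] = set()
            for rep in range(1, replicates + 1):
                salt = 0
                seed = stable_seed(master_seed, rid, lid, rep)
                while seed in seeds:
                    salt += 1
                    seed = stable_seed(master_seed, rid, lid, rep, salt)
                seeds.add(seed)
                jobs.append(DockingJob(
                    receptor_id=rid, ligand_id=lid, replicate_index=rep,
                    seed=seed, box=box, **job_kwargs,
                ))
    return jobs


def write_seed_manifest(jobs: Iterable[DockingJob], path: str | Path) -> None:
    lines = ["receptor_id\tligand_id\treplicate\tseed"]
    lines += [f"{j.receptor_id}\t{j.ligand_id}\t{j.replicate_index}\t{j.seed}" for j in jobs]
    Path(path).write_text("\n".join(lines) + "\n")


def generate_docking_config(job: DockingJob) -> str:
    """Vina-dialect config text for one job."""
    if job.box is None:
        raise VinascreenError(f"job {job.key} has no search box")
    b = job.box
    lines = [
        f"receptor = {job.receptor_path}",
        f"ligand = {job.ligand_path}",
        f"center_x = {b.center_x:g}",
        f"center_y = {b.center_y:g}",
        f"center_z = {b.center_z:g}",
        f"size_x = {b.size_x:g}",
        f"size_y = {b.size_y:g}",
        f"size_z = {b.size_z:g}",
        f"exhaustiveness = {job.exhaustiveness}",
        f"num_modes = {job.num_modes}",
        f"cpu = {job.cpu}",
        f"seed = {job.seed}",
        f"out = {job.out_path}",
    ]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Backends
# ---------------------------------------------------------------------------

class DockingBackend(Protocol):
    """A backend produces the Vina-style output file for one job."""

    name: str

    def run(self, job: DockingJob) -> int:
        """Execute the job, writing ``job.out_path``; return exit status."""
        ...  # pragma: no cover


class ExternalVinaBackend:
    """Invokes an AutoDock Vina executable with a generated config file.

    The conformational search itself is entirely the engine's; this class
    only shells out and reports the exit status.
    """

    name = "vina"

    def __init__(self, executable: str = "vina"):
        self.executable = executable

    def run(self, job: DockingJob) -> int:
        if not job.config_path:
            raise VinascreenError(f"job {job.key} has no config path")
        Path(job.config_path).write_text(generate_docking_config(job))
        proc = subprocess.run(
            [self.executable, "--config", job.config_path],
            capture_output=True, text=True,
        )
        return proc.returncode


class MockBackend:
    """Deterministic stand-in for the docking engine.

    Pose energies come from a :class:`~vinascreen.fixtures.MockLandscape`
    as a pure function of (receptor, ligand, replicate seed), and a
    syntactically valid Vina output file is written so the downstream
    parsing path is exercised end to end.
    """

    name = "mock"

    def __init__(self, landscape: "MockLandscape"):
        self.landscape = landscape

    def run(self, job: DockingJob) -> int:
        energies = self.landscape.pose_energies(
            job.receptor_id, job.ligand_id, job.seed, n_modes=job.num_modes
        )
        lines = []
        for mode, energy in enumerate(energies, start=1):
            lines.append("MODEL %8d" % mode)
            lines.append(f"REMARK VINA RESULT:    {energy:8.3f}      0.000      0.000")
            lines.append("ENDMDL")
        Path(job.out_path).parent.mkdir(parents=True, exist_ok=True)
        Path(job.out_path).write_text("\n".join(lines) + "\n")
        return 0


def mock_dock(job: DockingJob, landscape: "MockLandscape") -> DockingRunResult:
    """One-shot mock execution (no ledger)."""
    backend = MockBackend(landscape)
    rc = backend.run(job)
    if rc != 0:  # pragma: no cover - mock never fails
        return DockingRunResult(job=job, poses=[], status="failed", backend_name=backend.name)
    poses = parse_vina_output(Path(job.out_path).read_text())
    return DockingRunResult(job=job, poses=poses, status="ok", backend_name=backend.name)


# ---------------------------------------------------------------------------
# Execution with checkpointing
# ---------------------------------------------------------------------------

def run_job(job: DockingJob, backend: DockingBackend, ledger: CheckpointLedger) -> DockingRunResult:
    """Execute one job unless already checkpointed; marker written last.

    A checkpointed job is not re-run: its existing output file is re-parsed,
    so results are idempotent under resubmission.
    """
    if not job.out_path:
        raise VinascreenError(f"job {job.key} has no output path")
    if ledger.is_done(job):
        poses = parse_vina_output(Path(job.out_path).read_text())
        return DockingRunResult(job=job, poses=poses, status="ok", backend_name=backend.name)
    rc = backend.run(job)
    if rc != 0:
        return DockingRunResult(job=job, poses=[], status="failed", backend_name=backend.name)
    try:
        poses = parse_vina_output(Path(job.out_path).read_text())
    except (EmptyOutputError, FileNotFoundError):
        return DockingRunResult(job=job, poses=[], status="empty", backend_name=backend.name)
    ledger.mark_done(job)
    return DockingRunResult(job=job, poses=poses, status="ok", backend_name=backend.name)


def pending_jobs(all_jobs: Iterable[DockingJob], ledger: CheckpointLedger) -> list[DockingJob]:
    """Jobs without completion markers, in original order."""
    return [j for j in all_jobs if not ledger.is_done(j)]


@dataclass
class InProcessQueue:
    """Claim/ack queue: jobs enqueued once; workers atomically claim the
    next unclaimed job.  The same interface shape fits an external
    key-value queue service for cluster deployments."""

    jobs: list[DockingJob]
    _next: int = 0
    _lock: threading.Lock = field(default_factory=threading.Lock)

    def claim(self) -> DockingJob | None:
        with self._lock:
            if self._next >= len(self.jobs):
                return None
            job = self.jobs[self._next]
            self._next += 1
            return job


def run_queue(
    jobs: list[DockingJob],
    backend: DockingBackend,
    ledger: CheckpointLedger,
    workers: int = 1,
    crash_after: int | None = None,
) -> dict[str, DockingRunResult]:
    """Drain the queue with ``workers`` concurrent workers.

    Returns results keyed by job key; the mapping is independent of worker
    count and claim order.  ``crash_after`` aborts each worker after that
    many claims (crash-injection hook for resume tests): claimed-but-
    unfinished jobs keep no marker and stay pending.
    """
    queue = InProcessQueue(jobs=list(jobs))
    results: dict[str, DockingRunResult] = {}
    results_lock = threading.Lock()

    def worker_loop():
        claimed = 0
        while True:
            job = queue.claim()
            if job is None:
                return
            claimed += 1
            if crash_after is not None and claimed > crash_after:
                return
            result = run_job(job, backend, ledger)
            with results_lock:
                results[job.key] = result

    if workers <= 1:
        worker_loop()
    else:
        threads = [threading.Thread(target=worker_loop) for _ in range(workers)]
        for t in threads:
            t.start()
        for t in threads:
            t.join()
    return results
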