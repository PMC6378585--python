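"""Interleaved frame-parallel localization with order-preserving merge.

Because every frame of an SMLM acquisition is localized independently, the
stack can be split across W workers.  A contiguous split would be badly
unbalanced — emitter activity decays roughly exponentially over the
acquisition, so early blocks carry far more localizations — hence frames
are dealt round-robin: worker w processes frames w, w+W, w+2W, ...  Each
frame subset then samples the whole acquisition and the per-worker work is
near-equal.

Workers run as isolated OS processes (a local process pool standing in for
an HPC array job; a manifest-export mode writes one job description per
worker for external schedulers).  Each worker writes its own partial CSV,
a config file naming its frame subset, and a log.  The merge step restores
original frame order by a stable sort on the frame column, so the merged
table is bit-identical to a single-worker run for deterministic engines.
"""

from __future__ import annotations

import time
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import calibrate as _calmod
from .detect import DetectionParams
from .errors import MergeError, PlanError, RunError
from .io_formats import (
    LocalizationTable,
    MovieHandle,
    RunLog,
    concat_tables,
    open_movie,
    read_table,
    write_table,
)
from .localize import ENGINES, localize_frames


@dataclass(frozen=True)
class WorkerPlan:
    """Round-robin assignment of frames 1..n_frames to workers 1..n_workers."""

    n_frames: int
    n_workers: int

    def frames_for(self, worker: int) -> list[int]:
        if not 1 <= worker <= self.n_workers:
            raise PlanError(f"worker {worker} outside 1..{self.n_workers}")
        return list(range(worker, self.n_frames + 1, self.n_workers))

    @property
    def assignments(self) -> list[list[int]]:
        return [self.frames_for(w) for w in range(1, self.n_workers + 1)]


def plan_interleave(n_frames: int, n_workers: int) -> WorkerPlan:
    """Build the interleaved plan; errors rather than idling spare workers."""
    if n_workers < 1:
        raise PlanError(f"need at least one worker, got {n_workers}")
    if n_workers > n_frames:
        raise PlanError(
            f"{n_workers} workers for {n_frames} frames: workers would idle")
    return WorkerPlan(n_frames=n_frames, n_workers=n_workers)


@dataclass(frozen=True)
class WorkerConfig:
    """Everything a worker needs besides the movie path and its index."""

    engine: str = "nwls"
    detection: Optional[DetectionParams] = None
    calibration: Optional[_calmod.AstigCalibration] = None
    sigma_prior_px: float = 1.3

    def __post_init__(self) -> None:
        if self.engine not in ENGINES:
            raise PlanError(f"unknown engine {self.engine!r}")


@dataclass
class RunReport:
    """Outcome of one parallel localization run."""

    worker_counts: list[int]
    worker_times_s: list[float]
    merged_table: LocalizationTable
    merged_table_path: Path
    log_path: Optional[Path]
    worker_dirs: list[Path] = field(default_factory=list)


def _worker_task(movie_path: str, worker: int, n_workers: int,
                 config: WorkerConfig, workdir: str) -> tuple[int, int, float]:
    """Executed inside the worker process: localize one frame subset."""
    t0 = time.perf_counter()
    wdir = Path(workdir) / f"worker_{worker}"
    wdir.mkdir(parents=True, exist_ok=True)
    handle = open_movie(movie_path)
    plan = plan_interleave(handle.n_frames, n_workers)
    frames = plan.frames_for(worker)
    (wdir / f"config_{worker}.txt").write_text(
        f"movie: {movie_path}\nworker: {worker} of {n_workers}\n"
        f"frames: {frames[0]}..{frames[-1]} stride {n_workers} "
        f"({len(frames)} frames)\n")
    log = RunLog(wdir / f"log_{worker}.txt")
    log.log(f"worker {worker}/{n_workers} starting on {Path(movie_path).name}")
    table = localize_frames(handle, start=worker, stride=n_workers,
                            engine=config.engine, detection=config.detection,
                            calibration=config.calibration, log=log,
                            sigma_prior_px=config.sigma_prior_px)
    write_table(table, wdir / f"part_{worker}.csv")
    log.log(f"worker {worker} wrote {len(table)} localizations")
    return worker, len(table), time.perf_counter() - t0


def run_parallel(handle: MovieHandle, plan: WorkerPlan, config: WorkerConfig,
                 workdir, log: Optional[RunLog] = None,
                 processes: bool = True,
                 max_processes: Optional[int] = None) -> RunReport:
    """Localize the movie with ``plan.n_workers`` isolated workers and merge.

    Per-worker CSVs, frame-subset configs and logs land in
    ``workdir/worker_<w>/``; the merged raw table is written to
    ``workdir/merged_raw.csv``.  A worker failure raises :class:`RunError`
    naming the worker and its frame subset; completed partial results are
    left in place for diagnosis.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    w_range = range(1, plan.n_workers + 1)
    results: dict[int, tuple[int, float]] = {}
    if log is not None:
        log.log(f"parallel localization: {plan.n_workers} workers on "
                f"{plan.n_frames} frames, engine={config.engine}")
    if processes and plan.n_workers > 1:
        with ProcessPoolExecutor(max_workers=max_processes
                                 or plan.n_workers) as pool:
            futures = {w: pool.submit(_worker_task, handle.path, w,
                                      plan.n_workers, config, str(workdir))
                       for w in w_range}
            for w, fut in futures.items():
                try:
                    worker, count, dt = fut.result()
                except Exception as exc:
                    frames = plan.frames_for(w)
                    raise RunError(
                        f"worker {w} failed on frames {frames[0]}..{frames[-1]}"
                        f" stride {plan.n_workers}: {exc}") from exc
                results[worker] = (count, dt)
    else:
        for w in w_range:
            try:
                worker, count, dt = _worker_task(handle.path, w,
                                                 plan.n_workers, config,
                                                 str(workdir))
            except Exception as exc:
                frames = plan.frames_for(w)
                raise RunError(
                    f"worker {w} failed on frames {frames[0]}..{frames[-1]}"
                    f" stride {plan.n_workers}: {exc}") from exc
            results[worker] = (count, dt)

    worker_dirs = [workdir / f"worker_{w}" for w in w_range]
    tables = [read_table(workdir / f"worker_{w}" / f"part_{w}.csv")
              for w in w_range]
    for w, t in zip(w_range, tables):
        t.provenance.append(f"worker {w}: {len(t)} localizations")
    merged = merge_tables(tables)
    merged_path = workdir / "merged_raw.csv"
    write_table(merged, merged_path)
    if log is not None:
        for w in w_range:
            log.extend_from(workdir / f"worker_{w}" / f"log_{w}.txt")
        log.log(f"merged {len(merged)} localizations into {merged_path.name}")
    return RunReport(worker_counts=[results[w][0] for w in w_range],
                     worker_times_s=[results[w][1] for w in w_range],
                     merged_table=merged, merged_table_path=merged_path,
                     log_path=log.path if log is not None else None,
                     worker_dirs=worker_dirs)


def merge_tables(worker_tables: Sequence[LocalizationTable]
                 ) -> LocalizationTable:
    """Restore original frame order across frame-disjoint worker tables.

    Stable sort of the concatenation by frame (each frame belongs to exactly
    one worker, so within-frame order is the worker's detection order); ids
    are reassigned 1..M; provenance concatenates in worker order.
    """
    seen: set[int] = set()
    for t in worker_tables:
        frames = set(int(f) for f in t.df["frame"].unique())
        overlap = seen & frames
        if overlap:
            raise MergeError(
                f"worker tables overlap on frames {sorted(overlap)[:5]}...")
        seen |= frames
    merged = concat_tables(list(worker_tables))
    df = merged.df.sort_values("frame", kind="stable").reset_index(drop=True)
    out = LocalizationTable(df, merged.dim, merged.provenance)
    out.provenance.append(
        f"merge: {len(worker_tables)} worker tables, {len(df)} records, "
        "sorted to original frame order")
    return out.reassign_ids()


def contiguous_block_counts(table: LocalizationTable, n_frames: int,
                            n_workers: int) -> list[int]:
    """Per-worker localization counts under a contiguous-block split.

    Diagnostic used to quantify why interleaving is needed: with decaying
    emitter activity, contiguous blocks are badly unbalanced.
    """
    edges = np.linspace(1, n_frames + 1, n_workers + 1)
    frames = table.df["frame"].to_numpy()
    return [int(np.sum((frames >= lo) & (frames < hi)))
            for lo, hi in zip(edges[:-1], edges[1:])]


# ---------------------------------------------------------------------------
# manifest export (external-scheduler mode)


def export_manifests(movie_path, plan: WorkerPlan, config: WorkerConfig,
                     out_dir) -> list[Path]:
    """Write one YAML job description per worker for an external scheduler.

    Each manifest is self-contained: movie path, worker index/stride, engine
    and detection/calibration parameters.  :func:`run_worker_from_manifest`
    executes one of them.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for w in range(1, plan.n_workers + 1):
        doc: dict = {
            "movie": str(movie_path),
            "worker": w,
            "n_workers": plan.n_workers,
            "engine": config.engine,
            "sigma_prior_px": config.sigma_prior_px,
            "workdir": str(out_dir),
        }
        if config.detection is not None:
            d = config.detection
            doc["detection"] = {"dog_sigma1_px": d.dog_sigma1_px,
                                "dog_sigma2_px": d.dog_sigma2_px,
                                "k_threshold": d.k_threshold,
                                "roi_radius_px": d.roi_radius_px}
        if config.calibration is not None:
            cal_path = out_dir / "calibration.yaml"
            if not cal_path.exists():
                _calmod.save_calibration(config.calibration, cal_path)
            doc["calibration"] = str(cal_path)
        p = out_dir / f"worker_{w}.yaml"
        p.write_text(yaml.safe_dump(doc, sort_keys=True))
        paths.append(p)
    return paths


def run_worker_from_manifest(manifest_path) -> Path:
    """Execute one exported worker job; returns the partial CSV path."""
    doc = yaml.safe_load(Path(manifest_path).read_text())
    det = DetectionParams(**doc["detection"]) if "detection" in doc else None
    cal = (_calmod.load_calibration(doc["calibration"])
           if "calibration" in doc else None)
    config = WorkerConfig(engine=doc["engine"], detection=det, calibration=cal,
                          sigma_prior_px=float(doc.get("sigma_prior_px", 1.3)))
    w = int(doc["worker"])
    _worker_task(doc["movie"], w, int(doc["n_workers"]), config,
                 doc["workdir"])
    return Path(doc["workdir"]) / f"worker_{w}" / f"part_{w}.csv"


def run_batch(movie_paths: Sequence, n_slots: int, run_config,
              **kwargs) -> list:
    """Batch mode: each movie is processed end-to-end within one slot.

    Thin wrapper over :func:`parastorm.pipeline.run_batch`; movies are
    dispatched round-robin to ``n_slots`` slots and each is localized with
    the slot's internal workers, postprocessed and rendered into its own
    job-numbered output directory.
    """
    from . import pipeline
    return pipeline.run_batch(movie_paths, n_slots, run_config, **kwargs)
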