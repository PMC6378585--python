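"""End-to-end processing of one or many movies.

One movie runs through the four workflow stages — load, frame-parallel
localization, single-pass postprocessing, rendering — with all outputs
collected in a job-numbered subdirectory next to the input movie:

    <input_dir>/<job_id>/
        run.log                          human-readable processing log
        workers/worker_<w>/...           per-worker partial CSVs, configs, logs
        loc_raw.csv                      merged raw localization table
        loc_post_<tokens>.csv            postprocessed table (tokens in name)
        drift.png                        drift summary graph (when drift ran)
        preview_2D.png / preview_3D.png  optional preview rendering

Batch mode dispatches whole movies round-robin to slots; each movie is
processed end-to-end within its slot with the slot's internal workers, so
the raw data never has to be shared between slots.
"""

from __future__ import annotations

import datetime as _dt
import secrets
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

from . import calibrate as _calmod
from .detect import DetectionParams
from .errors import ParastormError
from .io_formats import MovieHandle, RunLog, open_movie, write_table
from .parallel_engine import (
    RunReport,
    WorkerConfig,
    plan_interleave,
    run_parallel,
)
from .postprocess import PostprocessConfig, apply_filter_chain
from .render import RenderSettings, render_image, render_z_projection, save_render


@dataclass(frozen=True)
class RunConfig:
    """Launch options for one processing job (mirrors the CLI flags)."""

    calibration_path: Optional[str] = None
    engine: str = "nwls"
    n_nodes: int = 1
    jobs_per_node: int = 4
    post_tokens: str = "minphot,sigma,zunc,drift,merge"
    preview: bool = False
    detection: Optional[DetectionParams] = None
    render_settings: RenderSettings = field(default_factory=RenderSettings)
    postprocess_overrides: dict = field(default_factory=dict)
    processes: bool = True
    max_processes: Optional[int] = None
    seed: int = 0

    @property
    def n_workers(self) -> int:
        return self.n_nodes * self.jobs_per_node


@dataclass
class JobResult:
    """Everything a finished job produced."""

    movie_path: Path
    out_dir: Path
    report: RunReport
    raw_csv: Path
    post_csv: Path
    preview_paths: list[Path]
    log_path: Path
    dim: int


def make_job_dir(movie_path, when: Optional[_dt.datetime] = None) -> Path:
    """Create ``<input_dir>/<job_id>/`` with a unique timestamped job id."""
    when = when or _dt.datetime.now(_dt.timezone.utc)
    movie_path = Path(movie_path)
    job_id = when.strftime("%Y%m%dT%H%M%S") + "_" + secrets.token_hex(2)
    out = movie_path.parent / job_id
    out.mkdir(parents=True, exist_ok=False)
    return out


def process_movie(movie_path, config: RunConfig,
                  out_dir=None) -> JobResult:
    """Run the full pipeline on one movie.

    Localizes with ``n_nodes * jobs_per_node`` interleaved workers, merges,
    applies the configured postprocessing chain, optionally renders a
    preview (ASH for 2D; mean-z colour projection for 3D), and leaves all
    outputs plus the run log in the job directory.
    """
    movie_path = Path(movie_path)
    out_dir = Path(out_dir) if out_dir is not None else make_job_dir(movie_path)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = RunLog(out_dir / "run.log")
    log.log(f"job start: {movie_path.name} -> {out_dir.name}")

    calibration = None
    if config.calibration_path is not None:
        calibration = _calmod.load_calibration(config.calibration_path)
        log.log(f"3D processing: calibration {Path(config.calibration_path).name}"
                f" (engine_tag={calibration.engine_tag})")
    handle: MovieHandle = open_movie(movie_path)
    log.log(f"movie: {handle.n_frames} frames of "
            f"{handle.height}x{handle.width} px, pixel "
            f"{handle.camera.pixel_size_nm} nm")

    plan = plan_interleave(handle.n_frames,
                           min(config.n_workers, handle.n_frames))
    worker_cfg = WorkerConfig(engine=config.engine, detection=config.detection,
                              calibration=calibration)
    report = run_parallel(handle, plan, worker_cfg, out_dir / "workers",
                          log=log, processes=config.processes,
                          max_processes=config.max_processes)
    raw_csv = out_dir / "loc_raw.csv"
    write_table(report.merged_table, raw_csv)
    log.log(f"raw table: {len(report.merged_table)} localizations "
            f"-> {raw_csv.name}")

    post_cfg = PostprocessConfig.from_tokens(config.post_tokens,
                                             **config.postprocess_overrides)
    post = apply_filter_chain(report.merged_table, post_cfg,
                              pixel_size_nm=handle.camera.pixel_size_nm,
                              drift_plot_path=(out_dir / "drift.png"
                                               if "drift" in post_cfg.steps
                                               else None),
                              log=log)
    token_tag = "-".join(post_cfg.steps)
    post_csv = out_dir / f"loc_post_{token_tag}.csv"
    write_table(post, post_csv)
    log.log(f"postprocessed table: {len(post)} localizations -> {post_csv.name}")

    previews: list[Path] = []
    if config.preview and len(post):
        if post.dim == 3:
            rgb, _ = render_z_projection(post, config.render_settings)
            previews.extend(save_render(rgb, out_dir / "preview", tag="3D"))
        else:
            img, _ = render_image(post, config.render_settings, mode="ash")
            previews.extend(save_render(img, out_dir / "preview", tag="2D"))
        log.log(f"preview rendered: {', '.join(p.name for p in previews)}")
    log.log("job complete")
    return JobResult(movie_path=movie_path, out_dir=out_dir, report=report,
                     raw_csv=raw_csv, post_csv=post_csv,
                     preview_paths=previews, log_path=out_dir / "run.log",
                     dim=post.dim)


@dataclass
class BatchSummary:
    results: list[JobResult]
    failures: list[tuple[Path, str]]


def run_batch(movie_paths: Sequence, n_slots: int, config: RunConfig
              ) -> BatchSummary:
    """Batch mode: process whole movies in independent slots.

    Movies are dealt round-robin to ``n_slots`` slots; each slot processes
    its movies sequentially, end-to-end, using ``jobs_per_node`` internal
    workers (the raw data for a movie is only ever touched by one slot).
    One movie failing does not abort the others; failures are returned in
    the summary.
    """
    movie_paths = [Path(p) for p in movie_paths]
    if not movie_paths:
        raise ParastormError("batch mode needs at least one movie")
    n_slots = max(1, min(n_slots, len(movie_paths)))
    slot_cfg = replace(config, n_nodes=1)
    slots: list[list[Path]] = [movie_paths[i::n_slots] for i in range(n_slots)]
    results: list[JobResult] = []
    failures: list[tuple[Path, str]] = []
    for slot_movies in slots:
        for movie in slot_movies:
            try:
                results.append(process_movie(movie, slot_cfg))
            except Exception as exc:  # keep remaining movies running
                failures.append((movie, str(exc)))
    return BatchSummary(results=results, failures=failures)
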