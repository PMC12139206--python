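"""End-to-end processing of a tag cohort.

`process_fish` chains the per-fish stages — calibration, decimation,
static/dynamic split, VeDBA, tailbeat metrics (high-rate records only),
hourly summaries and plateau detection, depth smoothing and first-dive
detection, fast starts, and (for records of at least a month) the
diel-similarity analysis — and `run_pipeline` drives a whole directory,
writing per-fish reports and a cohort summary.  Any stage failure aborts
with the stage name and fish id.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import accel, diel, events, movement, tailbeat
from .config import PipelineConfig
from .io import SensorSeries, TagDeployment, read_deployment_table, read_tag_series

log = logging.getLogger("tunatag")

__all__ = ["process_fish", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, fish_id: str, stage: str, cause: Exception):
        super().__init__(f"fish {fish_id}, stage {stage}: {cause}")
        self.fish_id = fish_id
        self.stage = stage


def _stage(fish_id: str, name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(fish_id, name, exc) from exc
            return False
    return _Ctx()


def process_fish(series: SensorSeries, deployment: TagDeployment,
                 config: PipelineConfig | None = None,
                 depth_series: SensorSeries | None = None,
                 track: movement.Track | None = None) -> dict:
    """Run every applicable analysis stage for one fish.

    ``series`` holds the acceleration channels (ax/ay/az) and, for low-rate
    tags, depth/temp as well; high-rate tags supply depth separately.
    Returns a nested report dict of plain Python/numpy values.
    """
    cfg = config or PipelineConfig()
    fid = deployment.fish_id
    report: dict = {"fish_id": fid, "tag_type": deployment.tag_type,
                    "fs": series.fs, "config": cfg.to_dict()}

    with _stage(fid, "decimate"):
        if series.fs > 20.0:
            series = accel.decimate_to_20hz(series)

    with _stage(fid, "activity"):
        window = (cfg.static_window_s if series.fs >= cfg.tailbeat_min_fs
                  else cfg.static_window_lowres_s)
        act = accel.activity_series(series, static_window_s=window,
                                    vedba_smooth_s=cfg.vedba_smooth_s)

    with _stage(fid, "tailbeat"):
        if series.fs >= cfg.tailbeat_min_fs:
            tb = tailbeat.tailbeat_metrics(
                act.dynamic["ay"], series.fs,
                noise_floor=cfg.dsf_noise_floor_g,
                n_periods=cfg.cwt_n_periods)
            report["tailbeat"] = {
                "computable": True,
                "median_dsf_hz": float(np.nanmedian(tb.dsf)),
                "median_tba_g": float(np.nanmedian(tb.tba)),
                "median_tbp_s": float(np.nanmedian(tb.tbp)),
            }
            if np.isfinite(deployment.curved_fork_length):
                norm = tailbeat.normalise_by_length(
                    tb, deployment.curved_fork_length)
                report["tailbeat"]["median_dsf_per_cm"] = float(
                    np.nanmedian(norm.dsf))
        else:
            tb = None
            report["tailbeat"] = {
                "computable": False,
                "reason": f"not computable: fs {series.fs} Hz < "
                          f"{cfg.tailbeat_min_fs} Hz (tailbeat signal lost)",
            }

    with _stage(fid, "hourly"):
        horizon = min(cfg.plateau_horizon_h,
                      int(series.duration_s // 3600))
        hourly = accel.hourly_means(act.vedba, series.fs,
                                    horizon_h=max(horizon, 1))
        report["hourly_vedba"] = hourly.to_dict(orient="list")
        if horizon >= 24:
            report["burst_ratio"] = accel.burst_ratio(hourly)
            report["plateau_hour"] = accel.plateau_time(
                hourly, frac=cfg.plateau_frac)

    depth_src = depth_series if depth_series is not None else (
        series if "depth" in series.channels else None)
    if depth_src is not None:
        with _stage(fid, "depth"):
            d = events.temperature_correct_depth(
                depth_src["depth"], depth_src.channels.get(
                    "temp", np.full(len(depth_src), np.nan)),
                cfg.depth_temp_coeff_m_per_degc, cfg.depth_temp_ref_degc)
            dser = SensorSeries(depth_src.start_epoch, depth_src.fs,
                                {"depth": d})
            if dser.fs > cfg.lowres_fs:
                dser = accel.downsample_to(dser, cfg.lowres_fs)
            smoothed = events.smooth_depth(dser["depth"], dser.fs,
                                           cfg.depth_smooth_s)
            dive = events.detect_first_dive(
                smoothed, dser.fs, cfg.dive_depth_threshold_m,
                cfg.dive_min_duration_s)
            report["first_dive"] = (None if dive is None else {
                "duration_min": dive.duration_s / 60.0,
                "max_depth_m": dive.max_depth_m,
                "start_s": dive.start_s})

    with _stage(fid, "fast_starts"):
        v_detect = (act.vedba if series.fs >= cfg.tailbeat_min_fs
                    else act.vedba_smooth)
        thr = events.fast_start_threshold(v_detect, cfg.fast_start_quantile)
        fs_sum = events.detect_fast_starts(v_detect, series.fs, thr,
                                           inactive_frac=cfg.inactive_day_frac)
        flags, weekly = events.inactive_days(
            fs_sum.percent_per_day, cutoff_percent=100 * cfg.inactive_day_frac)
        report["fast_starts"] = {
            "threshold_g": fs_sum.threshold_g,
            "n_events": len(fs_sum.events),
            "percent_per_day": fs_sum.percent_per_day.tolist(),
            "inactive_days": flags.tolist(),
            "inactive_per_week": weekly.tolist(),
        }

    n_days = int(series.duration_s // 86400)
    if n_days >= cfg.block_days:
        with _stage(fid, "similarity"):
            prof_v = diel.hourly_profiles(act.vedba_smooth, series.fs,
                                          series.start_epoch, cfg.block_days)
            sim_v = diel.similarity_analysis(
                prof_v, n_perm=cfg.n_permutations, seed=cfg.rng_seed,
                q=cfg.flag_quantile, window_days=cfg.post_window_days,
                rank_mean_cutoff=cfg.rank_mean_cutoff,
                rank_mean_inclusive=cfg.rank_mean_inclusive,
                flag_inclusive=cfg.flag_inclusive,
                min_common_hours=cfg.min_common_hours)
            report["similarity_activity"] = sim_v.to_row()
            if depth_src is not None:
                prof_d = diel.hourly_profiles(
                    depth_src["depth"], depth_src.fs, depth_src.start_epoch,
                    cfg.block_days)
                sim_d = diel.similarity_analysis(
                    prof_d, n_perm=cfg.n_permutations, seed=cfg.rng_seed,
                    q=cfg.flag_quantile, window_days=cfg.post_window_days,
                    rank_mean_cutoff=cfg.rank_mean_cutoff,
                    rank_mean_inclusive=cfg.rank_mean_inclusive,
                    flag_inclusive=cfg.flag_inclusive,
                    min_common_hours=cfg.min_common_hours)
                report["similarity_depth"] = sim_d.to_row()

        with _stage(fid, "diel"):
            times = series.times()
            is_day = diel.day_night_partition(
                times, day_start_hour=cfg.day_start_hour,
                day_end_hour=cfg.day_end_hour)
            day_idx = (series.seconds_since_start() // 86400).astype(int)
            flags = []
            for d in range(min(n_days, cfg.block_days)):
                sel = day_idx == d
                prof = diel.hourly_profiles(
                    np.where(sel, act.vedba_smooth, np.nan), series.fs,
                    series.start_epoch, n_days)[d]
                hrs = np.arange(24)
                day_hours = (hrs >= cfg.day_start_hour) & (hrs < cfg.day_end_hour)
                cls, _, _ = diel.classify_diel(prof[day_hours],
                                               prof[~day_hours], cfg.alpha)
                flags.append(cls == "diurnal")
            report["diel_return_day"] = diel.diel_return_day(
                flags, cfg.diel_window_days, cfg.diel_min_days)
            report["diurnal_days"] = flags

    if track is not None:
        with _stage(fid, "movement"):
            tr = movement.steps_and_angles(track)
            summary = movement.track_summary(tr)
            report["movement"] = {
                "straightness": summary.straightness,
                "weekly_straightness": summary.weekly_straightness,
                "cumulative_km": summary.cumulative_km,
                "net_km": summary.net_km,
            }
            steps = tr.df["step_km"].to_numpy()[1:]
            if np.isfinite(steps).sum() >= cfg.hmm_min_days:
                model = movement.MovementHMM.from_track(tr,
                                                        cfg.hmm_n_states)
                fit = model.fit(n_restarts=cfg.hmm_n_restarts,
                                seed=cfg.rng_seed)
                report["movement"]["hmm"] = {
                    "step_mean_km": fit.step_mean.tolist(),
                    "step_sd_km": fit.step_sd.tolist(),
                    "angle_kappa": fit.angle_kappa.tolist(),
                    "transition": fit.transition.tolist(),
                    "loglik": fit.loglik,
                    "states": fit.decode().tolist(),
                }
    return report


def _fish_inputs(input_dir: Path, fish_id: str):
    combined = input_dir / f"{fish_id}_series.csv"
    if combined.exists():
        s = read_tag_series(combined)
        return s, None
    acc = input_dir / f"{fish_id}_accel.csv"
    dep = input_dir / f"{fish_id}_depth.csv"
    if not acc.exists():
        raise FileNotFoundError(f"no series CSV for fish {fish_id}")
    s = read_tag_series(acc)
    d = read_tag_series(dep) if dep.exists() else None
    return s, d


class _JSONEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return super().default(o)


def run_pipeline(config: PipelineConfig, input_dir: str | Path,
                 out_dir: str | Path) -> dict:
    """Process every fish in ``input_dir`` and write a report bundle.

    Expects a ``deployments.csv`` table plus per-fish series CSVs in the
    core dialects.  Writes ``<fish>_report.json`` per fish, a cohort
    ``summary.csv``, and ``run_log.json`` recording the config and seed.
    Output is bit-identical across runs with the same inputs and config.
    """
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    table = input_dir / "deployments.csv"
    if not table.exists():
        raise FileNotFoundError(f"no deployment table at {table}")
    deployments = read_deployment_table(table)
    if not deployments:
        raise ValueError("deployment table is empty")
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for dep in deployments:
        series, depth = _fish_inputs(input_dir, dep.fish_id)
        track_path = input_dir / f"{dep.fish_id}_track.csv"
        track = movement.read_track(track_path) if track_path.exists() else None
        report = process_fish(series, dep, config, depth_series=depth,
                              track=track)
        with open(out_dir / f"{dep.fish_id}_report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True, cls=_JSONEncoder)
        rows.append({
            "fish_id": dep.fish_id,
            "tag_type": dep.tag_type,
            "tailbeat_computable": report["tailbeat"]["computable"],
            "burst_ratio": report.get("burst_ratio", np.nan),
            "plateau_hour": report.get("plateau_hour", np.nan),
            "first_dive_min": (report.get("first_dive") or {}).get(
                "duration_min", np.nan),
            "altered_week_activity": report.get(
                "similarity_activity", {}).get("altered_first_week", None),
            "altered_week_depth": report.get(
                "similarity_depth", {}).get("altered_first_week", None),
            "diel_return_day": report.get("diel_return_day", None),
        })
        log.info("processed fish %s", dep.fish_id)
    summary = pd.DataFrame(rows)
    summary.to_csv(out_dir / "summary.csv", index=False)
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump({"config": config.to_dict(), "seed": config.rng_seed,
                   "n_fish": len(rows)}, fh, indent=1, sort_keys=True)
    return {"summary": summary, "out_dir": out_dir}
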