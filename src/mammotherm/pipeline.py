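"""End-to-end pipeline driver: simulate → extract → sync → cosinor → compare → npi.

Each stage reads/writes CSV under the configured output directory and logs
its input/output row counts; any stage failure aborts the run with the
stage name in the exception. A run manifest (config echo, seed, versions,
row counts) makes a run reproducible from its output directory alone.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .config import GROUPS, PipelineConfig
from .cosinor import acrophase_diff, fit_group_rhythms
from .io import (
    plateaus_to_daily_log,
    read_daily_log,
    read_traces,
    write_daily_log,
    write_traces,
)
from .plateau import PlateauExtractor
from .simulate import emit_minute_traces, simulate_cohort
from .stats import cohort_summary, luteal_stats, pooled_t_test, score_pathology
from .sync import group_daily_means, sync_backwards, synced_to_frame

logger = logging.getLogger("mammotherm")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise StageError(name, str(exc)) from exc

        return wrapper

    return deco


@_stage("simulate")
def _run_simulate(cfg: PipelineConfig, out: Path, manifest: dict) -> tuple[Path, Path, Path | None]:
    sim_cfg = cfg.sim.replace(seed=cfg.seed)
    cohort = simulate_cohort(sim_cfg)
    daily_path = out / "daily_log.csv"
    daily = write_daily_log(cohort, daily_path)
    pathology_path = out / "pathology.csv"
    cohort.pathology.to_csv(pathology_path, index=False)
    (out / "sim_config.json").write_text(json.dumps(sim_cfg.to_dict(), indent=2, sort_keys=True))
    manifest["rows"]["daily_log"] = len(daily)
    manifest["rows"]["pathology"] = len(cohort.pathology)
    traces_path = None
    if cfg.emit_traces:
        rng = np.random.default_rng(cfg.seed + 1)
        traces = []
        for s in cohort.subjects:
            traces.extend(emit_minute_traces(s, sim_cfg, rng))
        traces_path = out / "traces.csv"
        write_traces(traces, traces_path)
        manifest["rows"]["traces"] = len(traces)
    return daily_path, pathology_path, traces_path


@_stage("extract")
def _run_extract(cfg: PipelineConfig, traces_path: Path, daily_path: Path, out: Path, manifest: dict) -> Path:
    traces = read_traces(traces_path)
    extractor = PlateauExtractor(
        smooth_window=cfg.smooth_window,
        slope_tol=cfg.slope_tol,
        min_duration=cfg.min_duration,
        discard_initial=cfg.discard_initial,
    ).fit()
    plateaus = extractor.transform(traces)
    plateaus.to_csv(out / "plateaus.csv", index=False)
    daily = pd.read_csv(daily_path)
    merged = plateaus_to_daily_log(plateaus, daily)
    extracted_path = out / "daily_log_extracted.csv"
    merged.to_csv(extracted_path, index=False)
    manifest["rows"]["plateaus"] = len(plateaus)
    return extracted_path


@_stage("sync")
def _run_sync(cfg: PipelineConfig, daily_path: Path, out: Path, manifest: dict):
    series, quarantined = read_daily_log(daily_path)
    if len(quarantined):
        quarantined.to_csv(out / "quarantined.csv", index=False)
    synced = [sync_backwards(s) for s in series]
    synced_df = synced_to_frame(synced)
    synced_df.to_csv(out / "synced.csv", index=False)
    present_groups = [g for g in GROUPS if g in set(synced_df["group"])] or sorted(set(synced_df["group"]))
    means = {}
    for g in present_groups:
        means[g] = group_daily_means(synced_df, g)
    wide = pd.concat(
        [m.set_index("cycle_day")["mean"].rename(g) for g, m in means.items()], axis=1
    ).sort_index()
    wide.to_csv(out / "daily_means.csv")
    manifest["rows"]["synced"] = len(synced_df)
    manifest["rows"]["quarantined"] = len(quarantined)
    return synced, wide


@_stage("cosinor")
def _run_cosinor(cfg: PipelineConfig, synced, out: Path, manifest: dict) -> pd.DataFrame:
    rows = []
    pool = "daily-means" if cfg.cosinor_on_moving_average else "days"
    for variable in ("vascularity_C", "progesterone_pM"):
        try:
            group_fits, subject_fits = fit_group_rhythms(synced, variable, pool=pool)
        except ValueError as exc:
            logger.warning("cosinor: skipping %s (%s)", variable, exc)
            continue
        for g, fit in group_fits.items():
            rows.append(
                {
                    "level": "group",
                    "id": g,
                    "variable": variable,
                    "mesor": fit.mesor,
                    "amplitude": fit.amplitude,
                    "acrophase_days_after_onset": fit.acrophase_days_after_onset,
                    "n": fit.n,
                    "f_statistic": fit.f_statistic,
                    "p_zero_amplitude": fit.p_zero_amplitude,
                }
            )
        for _, r in subject_fits.iterrows():
            rows.append(
                {
                    "level": "subject",
                    "id": r["subject_id"],
                    "variable": variable,
                    "mesor": r["mesor"],
                    "amplitude": r["amplitude"],
                    "acrophase_days_after_onset": r["acrophase_days_after_onset"],
                    "n": r["n"],
                    "f_statistic": r["f_statistic"],
                    "p_zero_amplitude": r["p_zero_amplitude"],
                }
            )
    rhythms = pd.DataFrame(rows)
    rhythms.to_csv(out / "rhythms.csv", index=False)
    manifest["rows"]["rhythms"] = len(rhythms)
    # group acrophase differences (vascularity), vs the control group if present
    vasc = rhythms[(rhythms["level"] == "group") & (rhythms["variable"] == "vascularity_C")]
    if "control" in set(vasc["id"]):
        ref = float(vasc.loc[vasc["id"] == "control", "acrophase_days_after_onset"].iloc[0])
        diffs = [
            {
                "group": r["id"],
                "acrophase_days_after_onset": r["acrophase_days_after_onset"],
                "diff_vs_control_d": acrophase_diff(float(r["acrophase_days_after_onset"]), ref),
            }
            for _, r in vasc.iterrows()
        ]
        pd.DataFrame(diffs).to_csv(out / "acrophase_differences.csv", index=False)
    return rhythms


@_stage("compare")
def _run_compare(cfg: PipelineConfig, daily_means: pd.DataFrame, out: Path, manifest: dict) -> pd.DataFrame:
    lo, hi = cfg.luteal_window
    stats_rows = []
    samples = {}
    for g in daily_means.columns:
        ls = luteal_stats(daily_means[g], group=g, window=(lo, hi))
        samples[g] = ls.daily_means.to_numpy()
        stats_rows.append(
            {"group": g, "n_days": ls.n_days, "mean_C": ls.overall_mean, "sd_C": ls.overall_sd}
        )
    pd.DataFrame(stats_rows).to_csv(out / "luteal_stats.csv", index=False)
    pairs = [(a, b) for i, a in enumerate(daily_means.columns) for b in list(daily_means.columns)[i + 1 :]]
    cmp_rows = []
    for a, b in pairs:
        res = pooled_t_test(samples[a], samples[b], a, b, welch=cfg.welch)
        cmp_rows.append(
            {
                "group_a": a,
                "group_b": b,
                "mean_difference_C": res.mean_difference,
                "t": res.t_stat,
                "df": res.df,
                "p_two_tailed": res.p_two_tailed,
            }
        )
    comparisons = pd.DataFrame(cmp_rows)
    comparisons.to_csv(out / "luteal_comparisons.csv", index=False)
    manifest["rows"]["luteal_comparisons"] = len(comparisons)
    return comparisons


@_stage("npi")
def _run_npi(cfg: PipelineConfig, pathology_path: Path, out: Path, manifest: dict) -> pd.DataFrame:
    pathology = pd.read_csv(pathology_path)
    if "in_situ" in pathology.columns:
        pathology["in_situ"] = pathology["in_situ"].astype(bool)
    scored = score_pathology(pathology)
    scored.to_csv(out / "npi.csv", index=False)
    summary = cohort_summary(pathology)
    summary.to_csv(out / "cohort_summary.csv", index=False)
    manifest["rows"]["npi"] = len(scored)
    return scored


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the configured stages end-to-end; returns the report bundle.

    The bundle maps stage outputs to in-memory frames; all outputs are also
    written as CSV under ``config.out_dir`` together with ``manifest.json``.
    Reruns with the same config and seed are bit-identical.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": config.to_dict(),
        "seed": config.seed,
        "versions": {"mammotherm": __version__, "python": sys.version.split()[0]},
        "rows": {},
    }
    bundle: dict[str, Any] = {"out_dir": out}

    daily_path, pathology_path, traces_path = config.daily_log, config.pathology, config.traces
    if config.simulate:
        daily_path, pathology_path, traces_path = _run_simulate(config, out, manifest)
    if daily_path is None:
        raise StageError("sync", "no daily log: enable simulate or provide daily_log")
    if config.extract:
        if traces_path is None:
            raise StageError("extract", "no traces: enable emit_traces or provide traces")
        daily_path = _run_extract(config, traces_path, daily_path, out, manifest)
    if config.sync:
        synced, daily_means = _run_sync(config, daily_path, out, manifest)
        bundle["synced"] = synced
        bundle["daily_means"] = daily_means
        if config.cosinor:
            bundle["rhythms"] = _run_cosinor(config, synced, out, manifest)
        if config.compare:
            bundle["comparisons"] = _run_compare(config, daily_means, out, manifest)
    if config.npi and pathology_path is not None:
        bundle["npi"] = _run_npi(config, pathology_path, out, manifest)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    bundle["manifest"] = manifest
    logger.info("pipeline complete: %s", out)
    return bundle
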