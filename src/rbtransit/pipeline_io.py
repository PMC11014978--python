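"""File formats, run configuration, and the end-to-end pipeline.

Traces, stepped fits, and pause records travel as TSV; fits, reports, and
configuration as JSON.  All randomness flows from one master seed through
named substreams, and every output carries the config hash that produced
it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import (pause_analysis, step_detection, synthetic_data,
               trace_alignment)
from .model_fitting import SearchConfig, fit_global
from .pause_analysis import ExpFit, PauseRecord
from .samples import PauseSample
from .step_detection import SteppedTrace
from .synthetic_data import (CohortRow, Condition, RawTrace, TemplateGeometry,
                             TraceGenConfig, default_geometry)

__all__ = [
    "RunConfig",
    "read_trace",
    "write_trace",
    "read_stepped",
    "write_stepped",
    "read_records",
    "write_records",
    "read_geometry",
    "write_geometry",
    "write_json",
    "config_hash",
    "run_pipeline",
]

log = logging.getLogger("rbtransit")


# ---------------------------------------------------------------- traces

def read_trace(path) -> RawTrace:
    """Read a trace TSV (columns time_s, extension_nm; empty = gap)."""
    df = pd.read_csv(path, sep="\t")
    required = {"time_s", "extension_nm"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: trace TSV needs columns {sorted(required)}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size >= 2:
        dt = np.diff(t)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0]):
            raise ValueError(f"{path}: timestamps must be uniform and "
                             "strictly increasing")
    ext = df["extension_nm"].to_numpy(dtype=float)
    meta = {}
    sidecar = Path(path).with_suffix(".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return RawTrace(t=t, extension=ext, meta=meta)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_trace(trace: RawTrace, path, sidecar: bool = True) -> None:
    """Write a trace TSV plus a JSON sidecar with meta and ground truth.

    Large per-sample truth arrays are dropped from the sidecar; scalars,
    events, and knots survive the round trip.
    """
    df = pd.DataFrame({"time_s": trace.t, "extension_nm": trace.extension})
    df.to_csv(path, sep="\t", index=False, na_rep="")
    if sidecar:
        meta = dict(trace.meta)
        truth = meta.get("truth")
        if isinstance(truth, dict):
            truth = {k: v for k, v in truth.items()
                     if k not in ("latent_nm", "position_bp")}
            meta["truth"] = truth
        Path(path).with_suffix(".meta.json").write_text(
            json.dumps(_jsonable(meta), indent=1))


def write_stepped(stepped: SteppedTrace, path) -> None:
    n = stepped.levels.size
    seg_id = np.full(n, -1, dtype=int)
    for k, (s0, s1) in enumerate(stepped.segments):
        seg_id[s0:s1] = k
    t = stepped.t if stepped.t is not None else np.arange(n, dtype=float)
    pd.DataFrame({"time_s": t, "level_nm": stepped.levels,
                  "segment_id": seg_id}).to_csv(path, sep="\t", index=False,
                                                na_rep="")


def read_stepped(path) -> SteppedTrace:
    df = pd.read_csv(path, sep="\t")
    levels = df["level_nm"].to_numpy(dtype=float)
    t = df["time_s"].to_numpy(dtype=float)
    segments = step_detection.split_on_gaps(levels)
    breakpoints = []
    for s0, s1 in segments:
        d = np.flatnonzero(np.diff(levels[s0:s1]) != 0.0) + s0 + 1
        breakpoints.extend(d.tolist())
    dt = float(t[1] - t[0]) if t.size >= 2 else 1.0
    return SteppedTrace(levels=levels,
                        breakpoints=np.asarray(breakpoints, dtype=int),
                        lambda_used=float("nan"), segments=segments,
                        objective=float("nan"), t=t, dt_sample=dt)


# --------------------------------------------------------------- records

def write_records(records: list[PauseRecord], path) -> None:
    pd.DataFrame([{
        "trace_id": r.trace_id,
        "start_s": r.start,
        "duration_s": r.duration,
        "position_bp": r.position,
        "outcome": r.outcome,
    } for r in records]).to_csv(path, sep="\t", index=False)


def read_records(path) -> list[PauseRecord]:
    df = pd.read_csv(path, sep="\t")
    return [PauseRecord(start=float(row.start_s),
                        duration=float(row.duration_s),
                        position=float(row.position_bp),
                        outcome=str(row.outcome),
                        trace_id=str(row.trace_id))
            for row in df.itertuples()]


def write_geometry(geometry: TemplateGeometry, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(geometry), indent=1))


def read_geometry(path) -> TemplateGeometry:
    return TemplateGeometry(**json.loads(Path(path).read_text()))


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=1))


# ---------------------------------------------------------------- config

@dataclass(frozen=True)
class RunConfig:
    """Everything an end-to-end run needs; hashable for provenance."""

    rows: tuple[CohortRow, ...]
    master_seed: int = 0
    outdir: str = "rbtransit_out"
    geometry: TemplateGeometry | None = None
    lambda_mode: str = "auto"       # "auto" or a number as str
    bin_width_nm: float = 1.0
    window_bp: float = pause_analysis.DEFAULT_WINDOW_BP
    min_pause_s: float = pause_analysis.DEFAULT_MIN_PAUSE_S
    do_model_fit: bool = False
    search: SearchConfig = SearchConfig()
    make_figures: bool = False
    log_level: str = "INFO"
    schema_version: int = 1


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# -------------------------------------------------------------- pipeline

def process_trace(trace: RawTrace, geometry: TemplateGeometry,
                  lambda_mode: str = "auto", bin_width_nm: float = 1.0,
                  window_bp: float = pause_analysis.DEFAULT_WINDOW_BP,
                  min_pause_s: float = pause_analysis.DEFAULT_MIN_PAUSE_S,
                  nm_per_bp: float = synthetic_data.NM_PER_BP,
                  refine: bool = False,
                  boundary_bias_samples: float = 1.0,
                  trace_id: str = "") -> dict:
    """detect -> align -> extract for one trace; returns stage outputs.

    ``boundary_bias_samples`` undoes the step fit's one-sample boundary
    absorption on pause durations; ``refine=True`` switches to the
    sub-sample changepoint estimate instead (best on traces whose travel
    is close to a clean ramp).
    """
    lam = (step_detection.default_lambda(trace.extension)
           if lambda_mode == "auto" else float(lambda_mode))
    stepped = step_detection.fit_steps(trace.extension, lam, t=trace.t)
    hist = trace_alignment.dwell_histogram(stepped, bin_width=bin_width_nm)
    landmarks = trace_alignment.landmark_positions_nm(geometry, nm_per_bp)
    align = trace_alignment.optimize_scale(hist, landmarks)
    positions_bp = trace_alignment.apply_scale(stepped, align, nm_per_bp)
    raw_positions_bp = (align.a * trace.extension + align.b) / nm_per_bp

    truth = trace.meta.get("truth", {})
    end_state = truth.get("outcome", "stalled_censored")
    if end_state == "transited":
        # a trace that transited ends at the terminator, not the roadblock;
        # pauses touching the data end are still censored-by-window
        end_state = "stalled_censored"
    records = pause_analysis.extract_pauses(
        positions_bp, geometry, window_bp=window_bp,
        min_pause_s=min_pause_s, dt_sample=stepped.dt_sample,
        raw_positions_bp=raw_positions_bp, refine=refine,
        boundary_bias_samples=0.0 if refine else boundary_bias_samples,
        end_state=end_state,
        condition=trace.meta.get("condition"), trace_id=trace_id)
    return {"stepped": stepped, "hist": hist, "alignment": align,
            "positions_bp": positions_bp, "records": records,
            "lambda": lam}


def run_pipeline(config: RunConfig) -> dict:
    """synth -> detect -> align -> extract -> fit-exp [-> fit-model].

    Writes per-stage TSV/JSON outputs under ``config.outdir`` and returns
    the report dict.  Deterministic given the master seed.
    """
    logging.basicConfig(level=config.log_level)
    chash = config_hash(config)
    outdir = Path(config.outdir)
    (outdir / "traces").mkdir(parents=True, exist_ok=True)
    log.info("run %s: %d cohort rows", chash, len(config.rows))

    cohort = synthetic_data.generate_cohort(list(config.rows),
                                            config.master_seed,
                                            geometry=config.geometry)
    report: dict = {"config_hash": chash, "master_seed": config.master_seed,
                    "conditions": {}}
    all_records: dict[str, list[PauseRecord]] = {}
    obs_for_fit = []

    for label, traces in cohort.items():
        row = next(r for r in config.rows if r.label == label)
        geometry = config.geometry
        if geometry is None:
            direction = ("opposing"
                         if row.condition.force_direction != "assisting"
                         else "assisting")
            geometry = default_geometry(direction)
        records: list[PauseRecord] = []
        n_ok = 0
        for trace in traces:
            tid = trace.meta.get("trace_id", "")
            write_trace(trace, outdir / "traces" / f"{_safe(tid)}.tsv")
            out = process_trace(
                trace, geometry, config.lambda_mode, config.bin_width_nm,
                config.window_bp, config.min_pause_s,
                nm_per_bp=row.gen.nm_per_bp, trace_id=tid)
            if out["alignment"].ok:
                n_ok += 1
            records.extend(out["records"])
        all_records[label] = records
        write_records(records, outdir / f"records_{_safe(label)}.tsv")

        sample = pause_analysis.records_to_sample(
            records, condition=row.condition, n_traces=len(traces))
        sample.meta["obs_window"] = row.gen.obs_window
        cond_report = {
            "n_traces": len(traces),
            "n_aligned": n_ok,
            "n_records": len(records),
            "input_hash": _records_hash(records),
        }
        if (~sample.censored).sum() >= 2:
            single = pause_analysis.fit_exp_single(
                sample, seed=_stage_seed(config.master_seed, "boot", label))
            cond_report["fit_single"] = _fit_summary(single)
            if (~sample.censored).sum() >= 20:
                double = pause_analysis.fit_exp_double(
                    sample, seed=_stage_seed(config.master_seed, "em", label))
                choice = pause_analysis.select_model(single, double)
                cond_report["fit_double"] = _fit_summary(double)
                cond_report["model_choice"] = choice.model
                cond_report["delta_aic"] = choice.delta_aic
        if records:
            frac, ci = pause_analysis.passage_fraction(records)
            cond_report["passage_fraction"] = frac
            cond_report["passage_ci95"] = ci
        report["conditions"][label] = cond_report
        obs_for_fit.append((row.condition, sample))

        if config.make_figures:
            _figures(outdir, label, sample)

    if config.do_model_fit:
        fit = fit_global(obs_for_fit, config.search)
        report["model_fit"] = {
            "distance": fit.distance,
            "p_values": fit.p_values,
            "regimes": {k: {"label": v.label, "ratio": v.ratio}
                        for k, v in fit.regimes.items()},
            "params": _jsonable(fit.params_by_roadblock),
            "converged": fit.converged,
        }

    write_json(report, outdir / "report.json")
    return report


def _safe(label: str) -> str:
    return "".join(ch if ch.isalnum() or ch in "-_." else "_"
                   for ch in label)


def _stage_seed(master_seed: int, stage: str, label: str) -> int:
    digest = hashlib.sha256(f"{master_seed}/{stage}/{label}".encode()).digest()
    return int.from_bytes(digest[:4], "little")


def _records_hash(records: list[PauseRecord]) -> str:
    payload = json.dumps([(r.trace_id, r.start, r.duration, r.outcome)
                          for r in records])
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _fit_summary(fit: ExpFit) -> dict:
    return {"model": fit.model, "tau_s": list(fit.tau),
            "weight": fit.weight, "ci90": _jsonable(fit.ci90),
            "loglik": fit.loglik, "n_used": fit.n_used}


def _figures(outdir: Path, label: str, sample: PauseSample) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(sample) == 0:
        return
    t, s = pause_analysis.ccdf(sample)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.step(t, s, where="post")
    ax.set_xlabel("pause time (s)")
    ax.set_ylabel("CCDF")
    ax.set_title(label)
    ax.set_yscale("log")
    fig.tight_layout()
    fig.savefig(outdir / f"ccdf_{_safe(label)}.png", dpi=120)
    plt.close(fig)
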