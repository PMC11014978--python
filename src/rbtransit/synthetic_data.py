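"""Synthetic tether-extension traces and pause datasets with ground truth.

Generates the statistical structure the analysis pipeline assumes: monotone
transcription progress, one kinetic-model roadblock pause at the operator,
short ubiquitous pauses, Gaussian measurement noise, a per-bead scale
factor, optional NaN gaps, and observation-window censoring.  Every trace
carries its ground truth so downstream stages can be validated round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np

from . import kinetics_sim
from .kinetics_sim import KineticParams
from .samples import PauseSample

__all__ = [
    "NM_PER_BP",
    "B_DNA_NM_PER_BP",
    "TemplateGeometry",
    "Condition",
    "TraceGenConfig",
    "RawTrace",
    "CohortRow",
    "default_geometry",
    "default_obs_window",
    "generate_pause_sample",
    "generate_trace",
    "generate_cohort",
]

#: Default position conversion: makes the +/-20 nm pause-classification
#: window exactly 60 bp.
NM_PER_BP = 1.0 / 3.0

#: Crystallographic B-DNA rise, available as an alternative.
B_DNA_NM_PER_BP = 0.34

ROADBLOCKS = ("LacI-Os", "LacI-O1", "LacI-O2", "EcoRI-Q111")
FORCE_DIRECTIONS = ("opposing", "assisting", "zero")
FORCE_MAGNITUDES_PN = (0.0, 0.2, 0.7, 2.0, 5.0)
SALT_MM = (50, 150)


@dataclass(frozen=True)
class TemplateGeometry:
    """Transcribed-template landmark positions, in bp from the start site."""

    operator_pos: float = 709.0
    terminator_pos: float = 709.0 + 612.0
    anchor_offset: float = 1021.0
    direction: str = "opposing"
    promoter_pos: float = 0.0

    def __post_init__(self):
        if not 0 < self.operator_pos < self.terminator_pos:
            raise ValueError("need 0 < operator_pos < terminator_pos")
        if self.anchor_offset <= 0:
            raise ValueError("anchor_offset must be positive")
        if self.direction not in ("opposing", "assisting"):
            raise ValueError(f"unknown direction {self.direction!r}")


def default_geometry(direction: str = "opposing") -> TemplateGeometry:
    """Template geometry of the study's constructs for either force sense.

    The anchor-to-start distance is 1021 bp on the opposing-force template
    and 2014 bp on the assisting-force template.
    """
    return TemplateGeometry(
        anchor_offset=1021.0 if direction == "opposing" else 2014.0,
        direction=direction,
    )


@dataclass(frozen=True)
class Condition:
    """One experimental condition (roadblock, force, GreA, salt)."""

    roadblock: str
    force_direction: str
    force_pN: float = 0.2
    grea_uM: float = 0.0
    salt_mM: int = 50

    def __post_init__(self):
        if self.roadblock not in ROADBLOCKS:
            raise ValueError(f"unknown roadblock {self.roadblock!r}")
        if self.force_direction not in FORCE_DIRECTIONS:
            raise ValueError(f"unknown force direction {self.force_direction!r}")
        if (self.force_pN == 0.0) != (self.force_direction == "zero"):
            raise ValueError("force_pN must be 0 exactly for zero-force")
        if self.force_pN not in FORCE_MAGNITUDES_PN:
            raise ValueError(f"force must be one of {FORCE_MAGNITUDES_PN} pN")
        if self.grea_uM < 0:
            raise ValueError("grea_uM must be non-negative")
        if self.salt_mM not in SALT_MM:
            raise ValueError(f"salt must be one of {SALT_MM} mM")

    def label(self) -> str:
        return (f"{self.roadblock}/{self.force_direction}"
                f"{self.force_pN:g}pN/GreA{self.grea_uM:g}uM/{self.salt_mM}mM")


def default_obs_window(roadblock: str) -> float:
    """Observation window: 30 min for O1/O2, 1 h for the strong roadblocks."""
    return 1800.0 if roadblock in ("LacI-O1", "LacI-O2") else 3600.0


@dataclass(frozen=True)
class TraceGenConfig:
    """Knobs of the trace generator (artifact plumbing, not paper values)."""

    velocity: float = 10.0              # bp/s
    noise_sd: float = 4.0               # nm
    a_true: float = 1.0                 # per-bead scale factor
    ubiquitous_pause_rate: float = 1.0 / 200.0   # events per bp
    ubiquitous_pause_mean: float = 3.0  # s
    nm_per_bp: float = NM_PER_BP
    obs_window: float = 1800.0          # s
    seed: int = 0
    initial_dwell_s: float = 180.0      # promoter dwell before NTP addition
    gap_after_dwell_s: float = 0.0      # NaN run at NTP addition (0 = off)
    ec_dissociation_prob: float = 0.0   # EC lost at roadblock (high salt)
    dt_sample: float = 1.0              # s

    def __post_init__(self):
        if self.velocity <= 0:
            raise ValueError("velocity must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 < self.a_true <= 1.2:
            raise ValueError("a_true must be in (0, 1.2]")
        if self.nm_per_bp <= 0:
            raise ValueError("nm_per_bp must be positive")
        if self.obs_window <= 0 or self.dt_sample <= 0:
            raise ValueError("obs_window and dt_sample must be positive")
        if not 0 <= self.ec_dissociation_prob <= 1:
            raise ValueError("ec_dissociation_prob must be a probability")

    def replace(self, **kw) -> "TraceGenConfig":
        return replace(self, **kw)


@dataclass
class RawTrace:
    """A noisy extension record with full generation ground truth in meta."""

    t: np.ndarray
    extension: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        if self.t.shape != self.extension.shape:
            raise ValueError("t and extension must have equal length")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0]):
                raise ValueError("t must be strictly increasing and uniform")


def generate_pause_sample(params: KineticParams, n: int, obs_window: float,
                          seed: int) -> PauseSample:
    """Draw ``n`` roadblock pauses, censored at the observation window.

    Durations reaching ``obs_window`` are truncated there and flagged
    censored ("indefinitely stalled").
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if obs_window <= 0:
        raise ValueError("obs_window must be positive")
    if obs_window > params.t_max:
        raise ValueError("obs_window must not exceed params.t_max")
    sample, _ = kinetics_sim.simulate_ensemble(params, n, seed)
    durations = sample.durations.copy()
    censored = sample.censored.copy()
    over = durations >= obs_window
    durations[over] = obs_window
    censored |= over
    return PauseSample(durations=durations, censored=censored,
                       meta={"params": params, "seed": int(seed),
                             "obs_window": float(obs_window)})


def _derive_seed(*keys: int) -> int:
    """Deterministic child seed from a tuple of integer keys."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0])


def generate_trace(geometry: TemplateGeometry, condition: Condition,
                   gen: TraceGenConfig, params: KineticParams) -> RawTrace:
    """One synthetic trace: latent piecewise-linear progress plus noise.

    The latent position starts with a promoter dwell, advances at
    ``gen.velocity`` with Poisson-placed exponential ubiquitous pauses, one
    kinetic-model pause at the operator, and holds at the terminator once
    reached.  Extension is ``a_true * nm_per_bp * position`` plus i.i.d.
    Gaussian noise; everything is truncated at the observation window.
    """
    rng = np.random.default_rng(np.random.SeedSequence([gen.seed, 2026]))

    rb = generate_pause_sample(params, 1, min(gen.obs_window, params.t_max),
                               seed=_derive_seed(gen.seed, 1))
    rb_duration = float(rb.durations[0])
    rb_censored = bool(rb.censored[0])

    # ubiquitous pauses along the template (excluding the endpoints)
    n_ub = rng.poisson(gen.ubiquitous_pause_rate * geometry.terminator_pos)
    ub_pos = np.sort(rng.uniform(0.0, geometry.terminator_pos, size=n_ub))
    ub_dur = rng.exponential(gen.ubiquitous_pause_mean, size=n_ub)

    outcome = "transited" if not rb_censored else "stalled_censored"
    terminate_at = None
    if gen.ec_dissociation_prob > 0 and rng.uniform() < gen.ec_dissociation_prob:
        outcome = "terminated_at_roadblock"
        terminate_at = rng.uniform(0.0, rb_duration)

    # build (time, position) knots of the latent trajectory
    v = gen.velocity
    knots_t = [0.0, gen.initial_dwell_s]
    knots_p = [0.0, 0.0]
    events = []  # (pos_bp, t_start, duration, kind)

    def advance_to(pos):
        t_arr = knots_t[-1] + (pos - knots_p[-1]) / v
        knots_t.append(t_arr)
        knots_p.append(pos)
        return t_arr

    def dwell(dur):
        knots_t.append(knots_t[-1] + dur)
        knots_p.append(knots_p[-1])

    done = False
    for p, d in zip(ub_pos, ub_dur):
        if p >= geometry.operator_pos:
            break
        t_arr = advance_to(p)
        events.append((float(p), float(t_arr), float(d), "ubiquitous"))
        dwell(d)

    rb_start = advance_to(geometry.operator_pos)
    if outcome == "terminated_at_roadblock":
        events.append((float(geometry.operator_pos), float(rb_start),
                       float(terminate_at), "roadblock"))
        dwell(terminate_at)
        done = True
    else:
        events.append((float(geometry.operator_pos), float(rb_start),
                       float(rb_duration), "roadblock"))
        dwell(rb_duration)
        if rb_censored:
            done = True

    if not done:
        for p, d in zip(ub_pos, ub_dur):
            if p <= geometry.operator_pos:
                continue
            t_arr = advance_to(p)
            events.append((float(p), float(t_arr), float(d), "ubiquitous"))
            dwell(d)
        advance_to(geometry.terminator_pos)
        dwell(gen.obs_window)  # hold at terminator until the window closes

    t = np.arange(0.0, gen.obs_window, gen.dt_sample)
    position = np.interp(t, knots_t, knots_p)
    if outcome == "terminated_at_roadblock":
        # tether lost: no samples after the EC dissociates
        t_end = knots_t[-1]
        t = t[t <= t_end]
        position = position[: t.size]
    latent_nm = gen.a_true * gen.nm_per_bp * position
    extension = latent_nm + rng.normal(0.0, gen.noise_sd, size=t.size)

    if gen.gap_after_dwell_s > 0:
        g0 = gen.initial_dwell_s
        gap = (t >= g0) & (t < g0 + gen.gap_after_dwell_s)
        extension[gap] = np.nan

    meta = {
        "geometry": geometry,
        "condition": condition,
        "gen": gen,
        "params": params,
        "truth": {
            "knots_t": np.asarray(knots_t),
            "knots_p": np.asarray(knots_p),
            "latent_nm": latent_nm,
            "position_bp": position,
            "events": events,
            "roadblock_start_s": float(rb_start),
            "roadblock_duration_s": float(
                terminate_at if terminate_at is not None else rb_duration),
            "roadblock_censored": rb_censored,
            "outcome": outcome,
        },
    }
    return RawTrace(t=t, extension=extension, meta=meta)


@dataclass(frozen=True)
class CohortRow:
    label: str
    condition: Condition
    n_traces: int
    params: KineticParams
    gen: TraceGenConfig = TraceGenConfig()

    def __post_init__(self):
        if self.n_traces < 1:
            raise ValueError("n_traces must be at least 1")


def generate_cohort(rows: Sequence[CohortRow], master_seed: int,
                    geometry: TemplateGeometry | None = None,
                    ) -> dict[str, list[RawTrace]]:
    """Independent seeded traces per row; bit-reproducible per master seed.

    Per-trace seeds derive deterministically from
    ``(master_seed, row index, trace index)``.
    """
    labels = [r.label for r in rows]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate condition labels in cohort config")
    cohort: dict[str, list[RawTrace]] = {}
    for i, row in enumerate(rows):
        geo = geometry
        if geo is None:
            direction = ("opposing"
                         if row.condition.force_direction != "assisting"
                         else "assisting")
            geo = default_geometry(direction)
        traces = []
        for j in range(row.n_traces):
            gen = row.gen.replace(seed=_derive_seed(master_seed, i, j))
            tr = generate_trace(geo, row.condition, gen, row.params)
            tr.meta["label"] = row.label
            tr.meta["trace_id"] = f"{row.label}#{j:03d}"
            traces.append(tr)
        cohort[row.label] = traces
    return cohort
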