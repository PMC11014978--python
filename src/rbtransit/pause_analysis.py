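"""Roadblock-pause extraction and pause-time distribution statistics.

Pauses are constant-level dwell intervals of an aligned trace.  A pause is
roadblock-associated when it sits within +/-60 bp (+/-20 nm) of the
roadblock site; pauses shorter than 20 s are treated as ubiquitous and
dropped.  Indefinitely stalled complexes enter as right-censored records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from .samples import PauseSample
from .synthetic_data import Condition, TemplateGeometry

__all__ = [
    "PauseRecord",
    "ExpFit",
    "ModelChoice",
    "PauseSample",
    "extract_pauses",
    "records_to_sample",
    "ccdf",
    "fit_exp_single",
    "fit_exp_double",
    "fit_exp_ccdf_lsq",
    "select_model",
    "passage_fraction",
]

#: Classification window around the roadblock site, bp (+/-20 nm).
DEFAULT_WINDOW_BP = 60.0
#: Pauses shorter than this are ubiquitous, not roadblock-induced (s).
DEFAULT_MIN_PAUSE_S = 20.0
#: Adjacent fitted levels closer than this merge into one pause (bp); they
#: are sub-steps of one dwell (e.g. backtracking wobble), not progress.
#: Calibrated on synthetic traces: plateau sub-pieces wobble by < ~5 bp
#: while 1 s travel steps advance ~10 bp.
DEFAULT_MERGE_TOL_BP = 7.0
#: Long sub-pieces (dwell >= DEFAULT_MIN_SUB_DWELL_S on both sides) merge
#: up to this level difference near the roadblock: a split plateau has two
#: long halves, whereas travel pieces last only a sample or two.
DEFAULT_COARSE_TOL_BP = 15.0
DEFAULT_MIN_SUB_DWELL_S = 4.0


@dataclass(frozen=True)
class PauseRecord:
    """One roadblock-associated pause of one trace."""

    start: float
    duration: float
    position: float
    outcome: str  # transited | stalled_censored | terminated_at_roadblock
    condition: Condition | None = None
    trace_id: str = ""

    @property
    def censored(self) -> bool:
        return self.outcome == "stalled_censored"


@dataclass
class ExpFit:
    """Exponential (or two-exponential-mixture) fit of pause times."""

    model: str                      # "single" | "double"
    tau: tuple[float, ...]          # characteristic time(s), ascending
    weight: float | None            # mixture fraction of the fast component
    ci90: tuple[tuple[float, float], ...] | None
    loglik: float
    n_used: int
    meta: dict = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return 1 if self.model == "single" else 3

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik


def _pieces(values: np.ndarray, dt: float):
    """Runs of identical finite values: (start_idx, n_samples, level,
    includes_last_finite_sample)."""
    finite = np.isfinite(values)
    idx = np.flatnonzero(finite)
    if idx.size == 0:
        return []
    last_finite = idx[-1]
    pieces = []
    run_start = idx[0]
    run_level = values[idx[0]]
    run_n = 1
    prev = idx[0]
    for i in idx[1:]:
        if values[i] == run_level:
            run_n += 1
        else:
            pieces.append((run_start, run_n, float(run_level), prev == last_finite))
            run_start = i
            run_level = values[i]
            run_n = 1
        prev = i
    pieces.append((run_start, run_n, float(run_level), True))
    return pieces


def _merge_pieces(pieces, operator_pos, window_bp, merge_tol_bp,
                  coarse_tol_bp, min_sub, raw):
    """Chain-merge sub-steps of one dwell.

    Neighbours closer than ``merge_tol_bp`` always merge; near the
    roadblock, long-dwelling neighbours (a split plateau) merge up to
    ``coarse_tol_bp``.  When raw positions are available, merged levels
    are re-estimated from them -- the step fit shrinks adjacent levels
    toward each other, which would understate separations.
    """
    def level_of(s, n, fallback):
        if raw is None:
            return fallback
        seg = raw[s:s + n]
        seg = seg[np.isfinite(seg)]
        return float(seg.mean()) if seg.size else fallback

    merged: list[tuple[int, int, float, bool]] = []
    for s, n, lvl, last in pieces:
        lvl = level_of(s, n, lvl)
        if merged:
            ms, mn, mlvl, mlast = merged[-1]
            dl = abs(lvl - mlvl)
            near = (abs(mlvl - operator_pos) <= window_bp
                    and abs(lvl - operator_pos) <= window_bp)
            if dl <= merge_tol_bp or (near and dl <= coarse_tol_bp
                                      and mn >= min_sub and n >= min_sub):
                n2 = mn + n
                lvl2 = level_of(ms, n2, (mlvl * mn + lvl * n) / n2)
                merged[-1] = (ms, n2, lvl2, mlast or last)
                continue
        merged.append((s, n, lvl, last))
    return merged


def _local_velocity(raw, a, b, fallback):
    """Transcription rate (bp/sample) from a short stretch of raw data."""
    seg = raw[a:b]
    mask = np.isfinite(seg)
    if mask.sum() < 5:
        return fallback
    x = np.arange(seg.size, dtype=float)[mask]
    slope = float(np.polyfit(x, seg[mask], 1)[0])
    return slope if slope > 2.0 else fallback


def _refine_boundary(raw, level, velocity, k0, side, search=6, pad=12,
                     grid=0.2):
    """Sub-sample arrival/departure time of a plateau.

    Fits a ramp-to-plateau changepoint against the raw positions: before
    arrival (after departure) the position follows the local transcription
    ramp, at the plateau it sits at ``level``.  Returns the changepoint in
    sample units.
    """
    n = raw.size
    lo, hi = max(1, k0 - search), min(n - 2, k0 + search)
    if hi <= lo:
        return float(k0)
    i0, i1 = max(0, lo - pad), min(n, hi + pad)
    tt = np.arange(i0, i1, dtype=float)
    yy = raw[i0:i1]
    mask = np.isfinite(yy)
    tt, yy = tt[mask], yy[mask]
    best = (np.inf, float(k0))
    for c in np.arange(float(lo), float(hi) + 1e-9, grid):
        if side == "L":
            mu = np.where(tt < c, level - velocity * (c - tt), level)
        else:
            mu = np.where(tt > c, level + velocity * (tt - c), level)
        sse = float(np.sum((yy - mu) ** 2))
        if sse < best[0]:
            best = (sse, c)
    return best[1]


def extract_pauses(positions_bp: np.ndarray,
                   geometry: TemplateGeometry,
                   window_bp: float = DEFAULT_WINDOW_BP,
                   min_pause_s: float = DEFAULT_MIN_PAUSE_S,
                   dt_sample: float = 1.0,
                   merge_tol_bp: float = DEFAULT_MERGE_TOL_BP,
                   coarse_tol_bp: float = DEFAULT_COARSE_TOL_BP,
                   min_sub_dwell_s: float = DEFAULT_MIN_SUB_DWELL_S,
                   raw_positions_bp: np.ndarray | None = None,
                   refine: bool = False,
                   boundary_bias_samples: float = 0.0,
                   fallback_velocity_bp_s: float = 10.0,
                   end_state: str = "stalled_censored",
                   condition: Condition | None = None,
                   trace_id: str = "") -> list[PauseRecord]:
    """Roadblock-associated pauses of one aligned, stepped trace.

    ``positions_bp`` is the stepped trace in bp coordinates (NaN = gap).
    Constant-level runs are found, sub-steps of one dwell merged, and
    intervals of at least ``min_pause_s`` whose level lies within
    ``window_bp`` of the roadblock site are returned.  A pause containing
    the last finite sample takes ``end_state`` as its outcome (the trace
    ended there); all others transited.

    Two optional corrections sharpen durations against the raw aligned
    positions (``raw_positions_bp``): ``refine=True`` replaces the
    sample-count duration with a sub-sample ramp/plateau changepoint fit
    of the arrival and departure, and ``boundary_bias_samples`` subtracts
    a fixed count to undo the step fit's tendency to absorb boundary
    samples into long plateaus (about one sample at the default penalty).
    """
    positions_bp = np.asarray(positions_bp, dtype=float)
    raw = (None if raw_positions_bp is None
           else np.asarray(raw_positions_bp, dtype=float))
    pieces = _pieces(positions_bp, dt_sample)
    if not pieces:
        return []
    min_sub = max(int(round(min_sub_dwell_s / dt_sample)), 1)
    merged = _merge_pieces(pieces, geometry.operator_pos, window_bp,
                           merge_tol_bp, coarse_tol_bp, min_sub, raw)

    records = []
    for start, n, level, has_end in merged:
        if abs(level - geometry.operator_pos) > window_bp:
            continue
        start_s = start * dt_sample
        duration = (n - boundary_bias_samples) * dt_sample
        if refine and raw is not None and not has_end:
            stop = start + n
            v_in = _local_velocity(raw, max(0, start - 14), max(0, start - 1),
                                   fallback_velocity_bp_s * dt_sample)
            v_out = _local_velocity(raw, min(raw.size, stop + 1),
                                    min(raw.size, stop + 14),
                                    fallback_velocity_bp_s * dt_sample)
            arr = _refine_boundary(raw, level, v_in, start, "L")
            dep = _refine_boundary(raw, level, v_out, stop - 1, "R")
            if dep > arr:
                start_s = arr * dt_sample
                duration = (dep - arr) * dt_sample
        if duration < min_pause_s:
            continue
        outcome = end_state if has_end else "transited"
        records.append(PauseRecord(
            start=float(start_s), duration=float(duration),
            position=float(level), outcome=outcome,
            condition=condition, trace_id=trace_id))
    return records


def records_to_sample(records: Sequence[PauseRecord],
                      condition: Condition | None = None,
                      n_traces: int | None = None) -> PauseSample:
    """Pool pause records into a fit-ready sample (censored = stalled)."""
    return PauseSample(
        durations=np.array([r.duration for r in records], dtype=float),
        censored=np.array([r.censored for r in records], dtype=bool),
        condition=condition,
        n_traces=n_traces if n_traces is not None else len(records),
    )


def ccdf(sample: PauseSample, method: str = "km"
         ) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of pauses longer than t.

    ``km``: product-limit (Kaplan-Meier) estimate in which censored
    records stay in the at-risk set up to their censoring time.  ``naive``:
    empirical fraction of all recorded durations exceeding t.  Returns the
    right-continuous step function as ``(t, fraction)`` with t ascending.
    """
    if len(sample) == 0:
        raise ValueError("empty sample")
    d = sample.durations
    c = sample.censored
    order = np.argsort(d, kind="stable")
    d, c = d[order], c[order]
    times = np.unique(d[~c]) if method == "km" else np.unique(d)
    if times.size == 0:
        # everything censored: survival stays at 1 over the observed range
        return np.array([0.0, d.max()]), np.array([1.0, 1.0])
    if method == "km":
        from lifelines import KaplanMeierFitter

        kmf = KaplanMeierFitter()
        kmf.fit(d, event_observed=~c)
        surv = kmf.survival_function_at_times(times).to_numpy()
        return np.concatenate([[0.0], times]), np.concatenate([[1.0], surv])
    if method == "naive":
        frac = [(d > t).mean() for t in times]
        return np.concatenate([[0.0], times]), np.concatenate([[1.0], frac])
    raise ValueError(f"unknown method {method!r}")


def _censored_exp_loglik(tau: float, d: np.ndarray, c: np.ndarray) -> float:
    n_unc = int((~c).sum())
    return -n_unc * math.log(tau) - float(d.sum()) / tau


def fit_exp_single(sample: PauseSample, n_boot: int = 1000, seed: int = 0,
                   ci_level: float = 0.90) -> ExpFit:
    """Censored-exponential maximum likelihood fit.

    The MLE is total observed time over number of transits,
    ``tau = sum(durations) / n_uncensored`` (censored records contribute
    exposure only).  The CI comes from a seeded parametric bootstrap that
    reuses the sample's censoring design.
    """
    d, c = sample.durations, sample.censored
    n_unc = int((~c).sum())
    if n_unc == 0:
        raise ValueError("tau is unidentifiable with zero uncensored records")
    tau = float(d.sum()) / n_unc

    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        limits = np.where(c, d, np.inf)
        obs_window = sample.meta.get("obs_window")
        if obs_window is not None:
            limits = np.full(d.size, float(obs_window))
        draws = rng.exponential(tau, size=(n_boot, d.size))
        cens_b = draws >= limits
        obs_b = np.minimum(draws, limits)
        n_unc_b = (~cens_b).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            taus_b = obs_b.sum(axis=1) / n_unc_b
        taus_b = taus_b[n_unc_b > 0]
        alpha = (1.0 - ci_level) / 2.0
        ci = ((float(np.quantile(taus_b, alpha)),
               float(np.quantile(taus_b, 1.0 - alpha))),)

    return ExpFit(model="single", tau=(tau,), weight=None, ci90=ci,
                  loglik=_censored_exp_loglik(tau, d, c), n_used=int(d.size))


def _mixture_loglik(d, c, w, tau1, tau2):
    unc = ~c
    f = (w / tau1) * np.exp(-d / tau1) + ((1 - w) / tau2) * np.exp(-d / tau2)
    s = w * np.exp(-d / tau1) + (1 - w) * np.exp(-d / tau2)
    with np.errstate(divide="ignore"):
        ll = np.where(unc, np.log(np.maximum(f, 1e-300)),
                      np.log(np.maximum(s, 1e-300)))
    return float(ll.sum())


def fit_exp_double(sample: PauseSample, n_starts: int = 5, seed: int = 0,
                   max_iter: int = 1000, tol: float = 1e-9) -> ExpFit:
    """Two-component exponential mixture by EM, with right censoring.

    Censored records contribute survival mass; their expected residual
    life ``d + tau_j`` enters the M-step.  The best of ``n_starts`` seeded
    starts is kept; degenerate convergence (vanishing weight or merged
    components) falls back to the single-exponential fit.
    """
    d, c = sample.durations, sample.censored
    if int((~c).sum()) < 2:
        raise ValueError("need at least 2 uncensored records")
    rng = np.random.default_rng(seed)
    base = float(d.sum()) / max(int((~c).sum()), 1)

    best = None
    for _ in range(n_starts):
        tau1 = base * rng.uniform(0.1, 0.7)
        tau2 = base * rng.uniform(1.2, 4.0)
        w = rng.uniform(0.25, 0.75)
        ll_old = -np.inf
        for _ in range(max_iter):
            # E-step
            f1 = (w / tau1) * np.exp(-d / tau1)
            f2 = ((1 - w) / tau2) * np.exp(-d / tau2)
            s1 = w * np.exp(-d / tau1)
            s2 = (1 - w) * np.exp(-d / tau2)
            num1 = np.where(c, s1, f1)
            num2 = np.where(c, s2, f2)
            tot = np.maximum(num1 + num2, 1e-300)
            g1 = num1 / tot
            g2 = 1.0 - g1
            # M-step (censored records live d + tau_j in expectation)
            t1 = np.where(c, d + tau1, d)
            t2 = np.where(c, d + tau2, d)
            sum1 = g1.sum()
            sum2 = g2.sum()
            if sum1 < 1e-12 or sum2 < 1e-12:
                break
            w = sum1 / d.size
            tau1 = float((g1 * t1).sum() / sum1)
            tau2 = float((g2 * t2).sum() / sum2)
            ll = _mixture_loglik(d, c, w, tau1, tau2)
            if abs(ll - ll_old) < tol * (1.0 + abs(ll)):
                break
            ll_old = ll
        ll = _mixture_loglik(d, c, w, tau1, tau2)
        if best is None or ll > best[0]:
            best = (ll, w, tau1, tau2)

    ll, w, tau1, tau2 = best
    if tau1 > tau2:
        tau1, tau2, w = tau2, tau1, 1.0 - w
    degenerate = (w < 0.02 or w > 0.98
                  or (tau1 > 0 and tau2 / max(tau1, 1e-300) < 1.05))
    if degenerate:
        single = fit_exp_single(sample, n_boot=0)
        single.meta["degenerate_double"] = True
        return single
    return ExpFit(model="double", tau=(tau1, tau2), weight=float(w),
                  ci90=None, loglik=ll, n_used=int(d.size))


def fit_exp_ccdf_lsq(sample: PauseSample) -> ExpFit:
    """Alternative backend: least-squares fit of exp(-t/tau) to the CCDF.

    Kept as a cross-check of the MLE route (the two must agree closely on
    clean exponential data).
    """
    t, s = ccdf(sample, method="km")

    def cost(log_tau):
        return float(np.sum((s - np.exp(-t / math.exp(log_tau))) ** 2))

    guess = math.log(max(float(np.mean(sample.durations)), 1e-9))
    res = optimize.minimize_scalar(cost, bracket=(guess - 2, guess, guess + 2))
    tau = math.exp(res.x)
    return ExpFit(model="single", tau=(tau,), weight=None, ci90=None,
                  loglik=_censored_exp_loglik(tau, sample.durations,
                                              sample.censored),
                  n_used=len(sample), meta={"backend": "ccdf_lsq"})


@dataclass(frozen=True)
class ModelChoice:
    model: str
    delta_aic: float  # AIC(double) - AIC(single); negative favours double


def select_model(single: ExpFit, double: ExpFit) -> ModelChoice:
    """Pick the mixture only when it buys AIC outright; ties go single."""
    if double.model == "single":  # degenerate fallback
        return ModelChoice("single", 0.0)
    delta = double.aic - single.aic
    return ModelChoice("double" if delta < 0 else "single", float(delta))


def passage_fraction(records: Sequence[PauseRecord],
                     ) -> tuple[float, tuple[float, float]]:
    """Fraction of pauses that ended in transit, with a 95% Wilson interval.

    Stalled (censored) and terminated records count as non-passage.
    """
    if len(records) == 0:
        raise ValueError("no records")
    n = len(records)
    k = sum(1 for r in records if r.outcome == "transited")
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return k / n, (float(lo), float(hi))
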