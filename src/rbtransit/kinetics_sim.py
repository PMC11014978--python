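"""Six-state kinetic model of RNA polymerase transit through a roadblock.

A paused elongation complex (EC) can transit a DNA-bound roadblock two
ways: passively, waiting for the roadblock to dissociate (rate ``k3``), or
actively, cycling through backtracking (rate ``k1``) and recovery (rate
``k2``) and ramming the roadblock with dislodging probability ``P1`` per
encounter.  The discrete-time Monte Carlo walks states

    1 pre-encounter -> 5 ramming -> {6 transited | 2 at roadblock}
    2 -> 3 backtracked -> 5 -> ...      (active / reciprocating path)
    2 -> 6 once the roadblock is gone   (passive path)

with per-step hazards ``1 - exp(-k * dt)`` and a hard cap ``t_max`` after
which the EC is scored as indefinitely stalled (right-censored).

Two implementations are provided: a compiled batch kernel used everywhere,
and :func:`simulate_pause_reference`, a literal line-by-line transcription
of the published pseudocode kept as an independent oracle.  Fed the same
uniform stream they produce identical trajectories; fed independent
streams their duration distributions are statistically indistinguishable
(both are asserted in the test suite).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from ._kernels import _simulate_batch
from ._rng import UniformStream
from .samples import PauseSample

__all__ = [
    "KineticParams",
    "PauseOutcome",
    "GreaModel",
    "RegimeClass",
    "EnsembleSummary",
    "k_passive",
    "k_active",
    "grea_adjusted_k2",
    "passive_limit_mean",
    "classify_regime",
    "simulate_single",
    "simulate_ensemble",
    "simulate_pause_reference",
]


@dataclass(frozen=True)
class KineticParams:
    """Rates and probabilities of the transit model.

    k1: backtracking rate (1/s); k2: recovery rate (1/s); k3: roadblock
    dissociation rate (1/s); p1: dislodging probability per encounter;
    dt: simulation step (s); t_max: censoring cap (s).
    """

    k1: float
    k2: float
    k3: float
    p1: float
    dt: float = 1.0
    t_max: float = 5000.0

    def __post_init__(self):
        if min(self.k1, self.k2, self.k3) < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.p1 <= 1.0:
            raise ValueError("p1 must be a probability")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_max < 2 * self.dt:
            raise ValueError("t_max must allow at least two steps")

    def replace(self, **kw) -> "KineticParams":
        from dataclasses import replace as _replace

        return _replace(self, **kw)


@dataclass(frozen=True)
class PauseOutcome:
    """Result of one simulated transit attempt."""

    duration: float
    outcome: str  # "transited" | "stalled_censored"
    n_cycles: int
    dislodged: bool


@dataclass(frozen=True)
class GreaModel:
    """Michaelis-Menten dependence of the recovery rate on GreA.

    ``k2(c) = k2_basal + k2_cat * c / (km_uM + c)``: intrinsic recovery
    plus a saturable cleavage-stimulated increment.
    """

    k2_basal: float
    k2_cat: float
    km_uM: float

    def __post_init__(self):
        if min(self.k2_basal, self.k2_cat, self.km_uM) < 0:
            raise ValueError("GreA model constants must be non-negative")


@dataclass(frozen=True)
class RegimeClass:
    label: str  # "passive" | "hybrid" | "active"
    ratio: float


@dataclass(frozen=True)
class EnsembleSummary:
    mean_duration: float
    censored_fraction: float
    transit_fraction: float
    dislodged_fraction: float
    mean_n_cycles: float


def k_passive(params: KineticParams) -> float:
    """Transit rate of the passive pathway: spontaneous dissociation."""
    return params.k3


def k_active(params: KineticParams) -> float:
    """Transit-cycle rate of the active pathway, ``k1 / (1 + k1/k2)``.

    Equals ``1 / (1/k1 + 1/k2)`` for positive rates: the harmonic
    combination of one backtrack and one recovery.  Zero when ``k1 == 0``
    (no backtracking) or ``k2 == 0`` with ``k1 > 0`` (recovery never
    completes, so cycles never finish).
    """
    if params.k1 == 0.0:
        return 0.0
    if params.k2 == 0.0:
        return 0.0
    return params.k1 / (1.0 + params.k1 / params.k2)


def grea_adjusted_k2(model: GreaModel, grea_uM: float) -> float:
    """Recovery rate at a given GreA concentration (uM)."""
    if grea_uM < 0:
        raise ValueError("GreA concentration must be non-negative")
    return model.k2_basal + model.k2_cat * grea_uM / (model.km_uM + grea_uM)


def passive_limit_mean(k3: float, dt: float = 1.0) -> float:
    """Expected pause duration in the pure-passive limit (k1=0, P1=0).

    With per-step dissociation probability ``p = 1 - exp(-k3*dt)`` and an
    uncensored clock, enumerating the walk gives
    ``2*dt + dt*(1-p)**2 / p``: two steps minimum, plus the geometric
    wait beyond the two free dissociation checks.  Used as a test oracle.
    """
    if k3 <= 0:
        raise ValueError("k3 must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = -math.expm1(-k3 * dt)
    return 2.0 * dt + dt * (1.0 - p) ** 2 / p


def classify_regime(params: KineticParams, lo: float = 0.1,
                    hi: float = 10.0) -> RegimeClass:
    """Label the transit regime by the ratio ``k_active / k_passive``."""
    if not 0 < lo < hi:
        raise ValueError("thresholds must satisfy 0 < lo < hi")
    ka = k_active(params)
    kp = k_passive(params)
    if kp == 0.0:
        if ka == 0.0:
            raise ValueError("both pathway rates are zero: no transit possible")
        return RegimeClass("active", math.inf)
    ratio = ka / kp
    if ratio <= lo:
        label = "passive"
    elif ratio >= hi:
        label = "active"
    else:
        label = "hybrid"
    return RegimeClass(label, ratio)


def _hazards(params: KineticParams) -> tuple[float, float, float]:
    dt = params.dt
    return (-math.expm1(-params.k1 * dt),
            -math.expm1(-params.k2 * dt),
            -math.expm1(-params.k3 * dt))


def _max_steps(params: KineticParams) -> int:
    return int(round(params.t_max / params.dt))


def simulate_single(params: KineticParams, seed: int) -> PauseOutcome:
    """Simulate one transit attempt (trajectory 0 of the given seed)."""
    p_back, p_rec, p_off = _hazards(params)
    steps = np.empty(1, dtype=np.int64)
    cens = np.empty(1, dtype=np.bool_)
    cyc = np.empty(1, dtype=np.int64)
    dis = np.empty(1, dtype=np.bool_)
    _simulate_batch(p_back, p_rec, p_off, params.p1, _max_steps(params),
                    seed, 0, 1, steps, cens, cyc, dis)
    return PauseOutcome(
        duration=float(steps[0]) * params.dt,
        outcome="stalled_censored" if cens[0] else "transited",
        n_cycles=int(cyc[0]),
        dislodged=bool(dis[0]),
    )


def simulate_ensemble(params: KineticParams, n: int, seed: int,
                      ) -> tuple[PauseSample, EnsembleSummary]:
    """Simulate ``n`` independent transit attempts.

    Trajectory ``i`` uses the counter-derived stream ``(seed, i)``, so the
    ensemble is reproducible and each trajectory is independent of ``n``.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    p_back, p_rec, p_off = _hazards(params)
    steps = np.empty(n, dtype=np.int64)
    cens = np.empty(n, dtype=np.bool_)
    cyc = np.empty(n, dtype=np.int64)
    dis = np.empty(n, dtype=np.bool_)
    _simulate_batch(p_back, p_rec, p_off, params.p1, _max_steps(params),
                    seed, 0, n, steps, cens, cyc, dis)
    durations = steps.astype(float) * params.dt
    sample = PauseSample(
        durations=durations,
        censored=cens.copy(),
        meta={"params": params, "seed": int(seed),
              "n_cycles": cyc.copy(), "dislodged": dis.copy()},
    )
    summary = EnsembleSummary(
        mean_duration=float(durations.mean()),
        censored_fraction=float(cens.mean()),
        transit_fraction=float(1.0 - cens.mean()),
        dislodged_fraction=float(dis.mean()),
        mean_n_cycles=float(cyc.mean()),
    )
    return sample, summary


def simulate_pause_reference(params: KineticParams,
                             next_uniform: Callable[[], float] | None = None,
                             seed: int | None = None) -> PauseOutcome:
    """Literal transcription of the published pause-time pseudocode.

    Kept deliberately naive (explicit state names, one decision per line)
    as an independent oracle for the compiled kernel.  Draws uniforms from
    ``next_uniform`` if given, else from the SplitMix64 stream of
    ``(seed, 0)`` -- the same stream the kernel would consume, making the
    two paths comparable draw for draw.
    """
    if next_uniform is None:
        if seed is None:
            raise ValueError("provide next_uniform or seed")
        next_uniform = UniformStream(seed, 0)

    k1, k2, k3, p1 = params.k1, params.k2, params.k3, params.p1
    dt, t_max = params.dt, params.t_max

    rnap_state = 1
    roadblock_on = True
    t_c = 0.0
    n_cycles = 0
    dislodged = False

    while rnap_state != 6 and t_c < t_max:
        if roadblock_on:
            if next_uniform() < 1.0 - math.exp(-k3 * dt):
                roadblock_on = False
        if rnap_state == 1:
            rnap_state = 5
        elif rnap_state == 2:
            if roadblock_on:
                if next_uniform() < 1.0 - math.exp(-k1 * dt):
                    rnap_state = 3
            else:
                rnap_state = 6
        elif rnap_state == 3:
            if next_uniform() < 1.0 - math.exp(-k2 * dt):
                rnap_state = 5
                n_cycles += 1
        elif rnap_state == 5:
            if roadblock_on:
                if next_uniform() < p1:
                    rnap_state = 6
                    dislodged = True
                else:
                    rnap_state = 2
            else:
                rnap_state = 6
        t_c = t_c + dt

    return PauseOutcome(
        duration=t_c,
        outcome="transited" if rnap_state == 6 else "stalled_censored",
        n_cycles=n_cycles,
        dislodged=dislodged,
    )
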