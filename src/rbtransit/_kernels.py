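"""Compiled inner loops (numba), with pure-Python fallbacks.

Each kernel mirrors a normative pure-Python implementation elsewhere in the
package; the test suite asserts matching behaviour so the compiled path is
an optimization, never a reinterpretation.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


_U64 = np.uint64
_GOLD = _U64(0x9E3779B97F4A7C15)
_MIX1 = _U64(0xBF58476D1CE4E5B9)
_MIX2 = _U64(0x94D049BB133111EB)
_STREAM = _U64(0xD1B54A32D192ED03)
_INV53 = 1.0 / 9007199254740992.0


@njit(cache=False)
def _mix64(z):
    z = (z ^ (z >> _U64(30))) * _MIX1
    z = (z ^ (z >> _U64(27))) * _MIX2
    return z ^ (z >> _U64(31))


@njit(cache=False)
def _simulate_batch(p_back, p_rec, p_off, p1, max_steps, seed, start_index, n,
                    steps_out, censored_out, cycles_out, dislodged_out):
    """Run ``n`` transit trajectories of the six-state model.

    Probabilities are per-step hazards already converted from rates
    (``p = 1 - exp(-k * dt)``).  States follow the published scheme:
    1 pre-encounter, 2 at roadblock, 3 backtracked, 5 ramming, 6 transited.
    State 4 (roadblock gone, RNAP free to go) is implicit in the roadblock
    flag.  Trajectory ``start_index + j`` consumes SplitMix64 stream
    ``(seed, start_index + j)`` in the same draw order as the pure-Python
    reference in :mod:`rbtransit.kinetics_sim`.
    """
    for j in range(n):
        state64 = _mix64(_U64(seed) * _GOLD
                         + _U64(start_index + j + 1) * _STREAM)

        rnap = 1
        rb_on = True
        steps = 0
        cycles = 0
        dislodged = False
        while rnap != 6 and steps < max_steps:
            if rb_on:
                state64 += _GOLD
                u = float(_mix64(state64) >> _U64(11)) * _INV53
                if u < p_off:
                    rb_on = False
            if rnap == 1:
                rnap = 5
            elif rnap == 2:
                if rb_on:
                    state64 += _GOLD
                    u = float(_mix64(state64) >> _U64(11)) * _INV53
                    if u < p_back:
                        rnap = 3
                else:
                    rnap = 6
            elif rnap == 3:
                state64 += _GOLD
                u = float(_mix64(state64) >> _U64(11)) * _INV53
                if u < p_rec:
                    rnap = 5
                    cycles += 1
            else:  # rnap == 5
                if rb_on:
                    state64 += _GOLD
                    u = float(_mix64(state64) >> _U64(11)) * _INV53
                    if u < p1:
                        rnap = 6
                        dislodged = True
                    else:
                        rnap = 2
                else:
                    rnap = 6
            steps += 1
        steps_out[j] = steps
        censored_out[j] = rnap != 6
        cycles_out[j] = cycles
        dislodged_out[j] = dislodged


@njit(cache=False)
def _tv_denoise_dp(y, lam, x):
    """Exact 1-D total-variation denoising by message clipping.

    Minimizes ``0.5 * sum((x - y)**2) + lam * sum(|x[t+1] - x[t]|)`` by
    forward dynamic programming over the convex value functions
    ``f_t(v) = 0.5*(v - y[t])**2 + min_w [f_{t-1}(w) + lam*|v - w|]``.

    The derivative of each ``f_t`` is a nondecreasing piecewise-linear
    function kept as a double-ended array of linear pieces with a global
    (slope, intercept) offset, so the per-step clip at ``-lam`` / ``+lam``
    amortizes to O(1).  Backtracing the clip points recovers the exact
    minimizer.  O(n) time and memory.
    """
    n = y.shape[0]
    if n == 0:
        return
    if lam <= 0.0 or n == 1:
        for i in range(n):
            x[i] = y[i]
        return

    cap = 2 * n + 2
    z = np.empty(cap)       # left endpoint of each piece (z[head] = -inf)
    sl = np.empty(cap)      # piece slope, stored minus the global offset
    ic = np.empty(cap)      # piece intercept, stored minus the global offset
    lo = np.empty(n - 1)    # clip points for backtracing
    hi = np.empty(n - 1)

    head = n
    tail = n + 1
    z[head] = -np.inf
    sl[head] = 1.0
    ic[head] = -y[0]
    a_off = 0.0
    b_off = 0.0

    for t in range(1, n):
        # clip the current derivative at -lam (from the left) ...
        j = head
        while j + 1 < tail and (sl[j + 1] + a_off) * z[j + 1] \
                + ic[j + 1] + b_off < -lam:
            j += 1
        blo = (-lam - ic[j] - b_off) / (sl[j] + a_off)
        z[j] = blo
        head = j - 1
        z[head] = -np.inf
        sl[head] = -a_off
        ic[head] = -lam - b_off

        # ... and at +lam (from the right)
        j = tail - 1
        while j > head and (sl[j] + a_off) * z[j] + ic[j] + b_off > lam:
            j -= 1
        bhi = (lam - ic[j] - b_off) / (sl[j] + a_off)
        tail = j + 2
        z[tail - 1] = bhi
        sl[tail - 1] = -a_off
        ic[tail - 1] = lam - b_off

        lo[t - 1] = blo
        hi[t - 1] = bhi

        # absorb the new data term 0.5*(v - y[t])**2 into the offset
        a_off += 1.0
        b_off -= y[t]

    # minimize f_{n-1}: find the zero of its derivative
    j = head
    while j + 1 < tail and (sl[j + 1] + a_off) * z[j + 1] \
            + ic[j + 1] + b_off < 0.0:
        j += 1
    xt = (-ic[j] - b_off) / (sl[j] + a_off)

    x[n - 1] = xt
    for t in range(n - 2, -1, -1):
        if xt < lo[t]:
            xt = lo[t]
        elif xt > hi[t]:
            xt = hi[t]
        x[t] = xt
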