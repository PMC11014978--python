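"""Counter-based per-trajectory random streams.

The transit simulator draws its uniforms from SplitMix64 streams keyed by
(master seed, trajectory index).  This makes ensembles reproducible and
order-independent: trajectory ``i`` sees the same stream no matter how many
trajectories are simulated around it, and regardless of whether the fast
kernel or the pure-Python reference consumes the stream.

The pure-Python implementation here is the normative one; the compiled
kernel in :mod:`rbtransit._kernels` mirrors it bit for bit (checked by the
test suite).
"""

from __future__ import annotations

_MASK = (1 << 64) - 1
_GOLD = 0x9E3779B97F4A7C15
_MIX1 = 0xBF58476D1CE4E5B9
_MIX2 = 0x94D049BB133111EB
_STREAM = 0xD1B54A32D192ED03

#: 2**-53, converts the top 53 bits of a draw to a uniform in [0, 1).
_INV53 = 1.0 / 9007199254740992.0


def mix64(z: int) -> int:
    """Finalization mix of SplitMix64 (Stafford variant 13)."""
    z &= _MASK
    z = ((z ^ (z >> 30)) * _MIX1) & _MASK
    z = ((z ^ (z >> 27)) * _MIX2) & _MASK
    return z ^ (z >> 31)


def stream_state(seed: int, index: int) -> int:
    """Initial SplitMix64 state for trajectory ``index`` under ``seed``."""
    z = ((seed & _MASK) * _GOLD + ((index + 1) & _MASK) * _STREAM) & _MASK
    return mix64(z)


def next_uniform(state: int) -> tuple[int, float]:
    """Advance a stream one step; return ``(new_state, u)`` with u in [0, 1)."""
    state = (state + _GOLD) & _MASK
    z = mix64(state)
    return state, (z >> 11) * _INV53


class UniformStream:
    """Stateful view of one SplitMix64 stream (callable, returns uniforms)."""

    __slots__ = ("_state",)

    def __init__(self, seed: int, index: int = 0):
        self._state = stream_state(seed, index)

    def __call__(self) -> float:
        self._state, u = next_uniform(self._state)
        return u
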