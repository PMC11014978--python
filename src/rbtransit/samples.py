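"""Shared sample containers used across simulation and analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass
class PauseSample:
    """A collection of pause durations with right-censoring flags.

    ``durations`` are in seconds; ``censored[i]`` is True when trajectory
    ``i`` showed no transit within its observation window (an "indefinitely
    stalled" complex), in which case ``durations[i]`` is the censoring time.
    """

    durations: np.ndarray
    censored: np.ndarray
    condition: Any = None
    n_traces: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.durations = np.asarray(self.durations, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.durations.shape != self.censored.shape:
            raise ValueError("durations and censored must have equal length")
        if self.durations.size and np.any(self.durations <= 0):
            raise ValueError("durations must be positive")
        if self.n_traces is None:
            self.n_traces = int(self.durations.size)

    def __len__(self) -> int:
        return int(self.durations.size)

    @property
    def uncensored_durations(self) -> np.ndarray:
        return self.durations[~self.censored]

    @property
    def censored_fraction(self) -> float:
        if self.durations.size == 0:
            return float("nan")
        return float(np.mean(self.censored))

    def dropping_censored(self) -> "PauseSample":
        """The sub-sample of transits only (censored records removed)."""
        keep = ~self.censored
        return PauseSample(
            durations=self.durations[keep],
            censored=self.censored[keep],
            condition=self.condition,
            n_traces=int(keep.sum()),
            meta=dict(self.meta),
        )
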