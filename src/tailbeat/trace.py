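"""The bilateral trace: paired left/right activity sampled on a uniform grid.

This is the central currency of the pipeline.  A trace may come from the CPG
simulator, from ROI densitometry on rendered frames, or from a CSV file; all
downstream rhythm statistics consume it.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

#: Maximum tolerated jitter (s) of the time grid around 1/rate_hz spacing.
GRID_TOL_S = 1e-9


@dataclass
class BilateralTrace:
    """Paired left/right time series at a fixed sampling rate.

    Parameters
    ----------
    t : ndarray
        Strictly increasing, uniformly spaced sample times in seconds.
    left, right : ndarray
        Activity samples (arbitrary units), one per time point.
    rate_hz : float
        Sampling rate; the spacing of ``t`` must equal ``1/rate_hz``.
    condition : str
        Free-text condition label (e.g. a preset name).
    seed : int or None
        RNG seed that produced the trace, if synthetic.
    """

    t: np.ndarray
    left: np.ndarray
    right: np.ndarray
    rate_hz: float
    condition: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        n = len(self.t)
        if n < 2:
            raise ParameterError("t: need at least 2 samples")
        if len(self.left) != n or len(self.right) != n:
            raise ParameterError(
                f"left/right: lengths ({len(self.left)}, {len(self.right)}) "
                f"do not match t ({n})"
            )
        for name in ("t", "left", "right"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ParameterError(f"{name}: contains non-finite values")
        if not (np.isfinite(self.rate_hz) and self.rate_hz > 0):
            raise ParameterError("rate_hz: must be a positive finite number")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ParameterError("t: must be strictly increasing")
        if np.max(np.abs(dt - 1.0 / self.rate_hz)) > GRID_TOL_S:
            raise ParameterError(
                "t: spacing deviates from 1/rate_hz by more than "
                f"{GRID_TOL_S} s"
            )

    # -- convenience ------------------------------------------------------
    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return len(self.t) / self.rate_hz

    def swapped(self) -> "BilateralTrace":
        """Return a copy with the left/right channels exchanged."""
        return BilateralTrace(
            t=self.t.copy(),
            left=self.right.copy(),
            right=self.left.copy(),
            rate_hz=self.rate_hz,
            condition=self.condition,
            seed=self.seed,
        )


def make_time_grid(n: int, rate_hz: float) -> np.ndarray:
    """Uniform time grid of ``n`` samples starting at 0 with exact spacing."""
    return np.arange(n, dtype=float) / rate_hz
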