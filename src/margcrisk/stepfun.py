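"""Right-continuous step functions used as carriers for cumulative hazards,
cumulative incidence functions, and residual processes.

A :class:`StepFunction` is zero before its first jump and piecewise constant
between jumps.  Evaluation is right-continuous, ``f(t) = sum of jumps at
times <= t``; the left limit is ``f(t-) = sum of jumps at times < t``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["StepFunction"]


class StepFunction:
    """Nondecreasing-in-time carrier f(t) = sum_{u <= t} jump(u), f(0) = 0.

    Parameters
    ----------
    jump_times : array-like
        Strictly increasing positive jump locations.
    jump_sizes : array-like
        Jump heights (any sign; cumulative hazards use nonnegative jumps).
    """

    def __init__(self, jump_times, jump_sizes):
        t = np.asarray(jump_times, dtype=float)
        s = np.asarray(jump_sizes, dtype=float)
        if t.ndim != 1 or s.shape != t.shape:
            raise ValueError("jump_times and jump_sizes must be 1-d and equal length")
        if t.size and (np.any(np.diff(t) <= 0) or t[0] <= 0):
            raise ValueError("jump_times must be strictly increasing and positive")
        self.jump_times = t
        self.jump_sizes = s
        self._cum = np.cumsum(s)

    @property
    def values(self):
        """Function values at the jump times (right-continuous)."""
        return self._cum.copy()

    def __call__(self, t):
        """Value at ``t`` (right-continuous); vectorized."""
        idx = np.searchsorted(self.jump_times, np.asarray(t, dtype=float), side="right")
        out = np.where(idx > 0, self._cum[np.maximum(idx - 1, 0)], 0.0)
        return out if np.ndim(t) else float(out)

    def left_limit(self, t):
        """Value at ``t-`` (sum of jumps strictly before t); vectorized."""
        idx = np.searchsorted(self.jump_times, np.asarray(t, dtype=float), side="left")
        out = np.where(idx > 0, self._cum[np.maximum(idx - 1, 0)], 0.0)
        return out if np.ndim(t) else float(out)

    def scaled(self, factor: float) -> "StepFunction":
        """New step function with all jumps multiplied by ``factor``."""
        return StepFunction(self.jump_times, self.jump_sizes * factor)

    def to_frame(self):
        """Two-column (time, value) pandas DataFrame of the jump skeleton."""
        import pandas as pd

        return pd.DataFrame({"time": self.jump_times, "value": self._cum})

    def __repr__(self):  # pragma: no cover
        k = self.jump_times.size
        tail = f", last={self._cum[-1]:.4g} at t={self.jump_times[-1]:.4g}" if k else ""
        return f"StepFunction({k} jumps{tail})"
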