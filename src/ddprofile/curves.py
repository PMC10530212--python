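"""Profile-likelihood curve container and point/interval summaries."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ProfileCurve", "curve_summary"]


@dataclass
class ProfileCurve:
    """A log-profile-likelihood curve on a grid, normalized so max = 0.

    ``method`` tags the producer: 'algorithm1' (flat-prior componentwise DD),
    'algorithm2' (normal-prior DD for a general function), 'oracle'
    (constrained optimization of an analytic likelihood), or 'quadratic'
    (constrained optimization of the quadratic surrogate).
    """

    psi_grid: np.ndarray
    logpl: np.ndarray
    method: str = "oracle"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.psi_grid = np.asarray(self.psi_grid, dtype=float)
        self.logpl = np.asarray(self.logpl, dtype=float)
        if self.psi_grid.shape != self.logpl.shape or self.psi_grid.ndim != 1:
            raise ValueError("psi_grid and logpl must be matching 1-D arrays")
        if self.psi_grid.size > 1 and not np.all(np.diff(self.psi_grid) > 0):
            raise ValueError("psi_grid must be strictly increasing")
        if not np.all(np.isfinite(self.logpl)):
            raise ValueError("logpl contains non-finite values")
        self.logpl = self.logpl - np.max(self.logpl)  # exact max-normalization

    @property
    def psi_hat(self) -> float:
        return float(self.psi_grid[int(np.argmax(self.logpl))])

    def interp(self, psi: np.ndarray) -> np.ndarray:
        """Linear interpolation of the curve (no extrapolation)."""
        psi = np.asarray(psi, dtype=float)
        if np.any(psi < self.psi_grid[0]) or np.any(psi > self.psi_grid[-1]):
            raise ValueError("interpolation point outside the curve's grid")
        return np.interp(psi, self.psi_grid, self.logpl)


def curve_summary(curve: ProfileCurve, level_drop: float = 1.92
                  ) -> tuple[float, tuple[float, float], bool]:
    """Grid argmax and the connected likelihood-interval at a given drop.

    ``level_drop=1.92`` (half the 3.84 chi-square critical value) gives the
    asymptotic 95% profile-likelihood set.  Returns ``(psi_hat, (lo, hi),
    boundary_flag)``; the flag is set when the interval touches the grid
    boundary, i.e. the curve was not profiled far enough out.
    """
    if level_drop <= 0:
        raise ValueError("level_drop must be positive")
    if not np.isclose(np.max(curve.logpl), 0.0, atol=1e-9):
        raise ValueError("curve must be max-normalized")
    g, v = curve.psi_grid, curve.logpl
    i_hat = int(np.argmax(v))
    thr = -level_drop
    # walk out from the peak while above the threshold
    lo_i = i_hat
    while lo_i > 0 and v[lo_i - 1] >= thr:
        lo_i -= 1
    hi_i = i_hat
    while hi_i < len(g) - 1 and v[hi_i + 1] >= thr:
        hi_i += 1
    boundary = (lo_i == 0) or (hi_i == len(g) - 1)
    # linear interpolation to the crossing just outside the run
    if lo_i > 0:
        f = (thr - v[lo_i]) / (v[lo_i - 1] - v[lo_i])
        lo = g[lo_i] + f * (g[lo_i - 1] - g[lo_i])
    else:
        lo = g[0]
    if hi_i < len(g) - 1:
        f = (thr - v[hi_i]) / (v[hi_i + 1] - v[hi_i])
        hi = g[hi_i] + f * (g[hi_i + 1] - g[hi_i])
    else:
        hi = g[-1]
    return float(g[i_hat]), (float(lo), float(hi)), bool(boundary)
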