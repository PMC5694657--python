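"""Expert assessment of consciousness level (EACL).

The regression target: each anaesthesiologist's hand-scored
consciousness curve (0-100) is resampled onto a common 5 s grid by
linear interpolation, and the panel is averaged pointwise into the EACL
with a per-time spread band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, InvalidArgumentError

DEFAULT_GRID_STEP = 5.0  # s, matches the vital-sign / BIS recording cadence


@dataclass
class GriddedCurve:
    """One assessor's scores on the uniform grid; NaN where the raw
    curve does not cover the grid point."""

    times: np.ndarray
    scores: np.ndarray
    valid: np.ndarray


@dataclass
class EACLCurve:
    """Panel mean +/- SD on the 5 s grid; optionally the aligned
    per-assessor matrix (n_assessors x n_times)."""

    times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    per_assessor: np.ndarray | None = None

    def __post_init__(self):
        ok = np.isfinite(self.mean)
        if np.any(self.mean[ok] < 0) or np.any(self.mean[ok] > 100):
            raise InvalidArgumentError("mean scores must lie in [0, 100]")
        if np.any(self.sd[np.isfinite(self.sd)] < 0):
            raise InvalidArgumentError("sd must be nonnegative")

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.mean)


def make_grid(t_start: float, t_end: float, step: float = DEFAULT_GRID_STEP) -> np.ndarray:
    """Uniform grid of multiples of ``step`` covering [t_start, t_end]."""
    k0 = int(np.ceil(t_start / step - 1e-9))
    k1 = int(np.floor(t_end / step + 1e-9))
    return np.arange(k0, k1 + 1) * step


def resample_assessor(raw_times, raw_scores, step: float = DEFAULT_GRID_STEP,
                      grid: np.ndarray | None = None) -> GriddedCurve:
    """Linearly interpolate one assessor's curve onto the common grid.

    Grid points outside the raw time range are marked invalid rather
    than extrapolated.  Scores must already be on the 0-100 scale.
    """
    raw_times = np.asarray(raw_times, dtype=float)
    raw_scores = np.asarray(raw_scores, dtype=float)
    if raw_times.size < 2:
        raise InsufficientDataError("need >= 2 raw assessment points")
    if np.any(np.diff(raw_times) <= 0):
        raise InvalidArgumentError("raw times must be strictly increasing")
    if np.any(raw_scores < 0) or np.any(raw_scores > 100):
        raise InvalidArgumentError("scores must lie in [0, 100]")
    if grid is None:
        grid = make_grid(raw_times[0], raw_times[-1], step)
    valid = (grid >= raw_times[0] - 1e-9) & (grid <= raw_times[-1] + 1e-9)
    scores = np.full(grid.size, np.nan)
    scores[valid] = np.interp(grid[valid], raw_times, raw_scores)
    return GriddedCurve(times=np.asarray(grid, dtype=float), scores=scores, valid=valid)


def average_assessors(curves: list[GriddedCurve]) -> EACLCurve:
    """Pointwise mean and sample SD (n-1) across the assessor panel.

    All curves must share the grid; a grid point is valid only where
    every assessor is valid there.
    """
    if not curves:
        raise InvalidArgumentError("need >= 1 assessor curve")
    grid = curves[0].times
    for c in curves[1:]:
        if c.times.shape != grid.shape or np.any(np.abs(c.times - grid) > 1e-9):
            raise InvalidArgumentError("assessor curves must share the same grid")
    matrix = np.vstack([c.scores for c in curves])
    valid = np.all(np.vstack([c.valid for c in curves]), axis=0)
    mean = np.full(grid.size, np.nan)
    sd = np.full(grid.size, np.nan)
    mean[valid] = matrix[:, valid].mean(axis=0)
    if matrix.shape[0] > 1:
        sd[valid] = matrix[:, valid].std(axis=0, ddof=1)
    else:
        sd[valid] = 0.0
    return EACLCurve(times=grid.copy(), mean=mean, sd=sd, per_assessor=matrix)


def eacl_from_raw(assessor_curves, step: float = DEFAULT_GRID_STEP) -> EACLCurve:
    """Raw (times, scores) pairs -> gridded panel -> EACL, on the
    intersection grid all assessors cover."""
    starts = [np.asarray(t)[0] for t, _ in assessor_curves]
    ends = [np.asarray(t)[-1] for t, _ in assessor_curves]
    grid = make_grid(max(starts), min(ends), step)
    gridded = [resample_assessor(t, s, step=step, grid=grid) for t, s in assessor_curves]
    return average_assessors(gridded)
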