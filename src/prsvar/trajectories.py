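"""Trajectory-shape statistics for single-cell time courses.

Quantifies two aspects of a set of per-cell transmitted-signal
trajectories P(t):

* population dispersion over time — the progressive spread distribution
  (PSD) and its median, the MPS.  At each timepoint the per-cell values are
  divided by the population median and the spread is the width of the
  shortest interval containing half the cells (the "shortest half").  For a
  symmetric distribution this width converges to the interquartile range,
  but unlike the IQR it stays meaningful for the heavy, asymmetric tails of
  mutant populations.
* per-cell instability — the crookedness index ``I_C = 1 - |net change| /
  total variation``, 0 for any monotone trajectory and approaching 1 when a
  trajectory repeatedly reverses.  Cells with ``I_C`` above a threshold
  (0.3 by default) are classified as "crooked".

Both statistics are invariant to positive rescaling of P and to
relabeling of cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError, InsufficientDataError, ParameterError

__all__ = [
    "TrajectorySet",
    "shortest_half_width",
    "progressive_spread",
    "mps",
    "crookedness_index",
    "classify_crooked",
]


@dataclass(frozen=True)
class TrajectorySet:
    """Per-cell trajectories on a common, strictly increasing time grid."""

    times: np.ndarray  # (T,) minutes
    P: np.ndarray  # (n_cells, T)
    strain: str = "reference"
    cell_ids: np.ndarray | None = None

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        P = np.asarray(self.P, dtype=float)
        if times.ndim != 1 or np.any(np.diff(times) <= 0):
            raise ParameterError("times must be 1-D and strictly increasing")
        if P.ndim != 2 or P.shape[1] != times.size:
            raise ParameterError("P must be (n_cells, len(times))")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "P", P)
        if self.cell_ids is None:
            object.__setattr__(self, "cell_ids", np.arange(P.shape[0]))
        else:
            ids = np.asarray(self.cell_ids)
            if ids.shape != (P.shape[0],):
                raise ParameterError("cell_ids must have one entry per trajectory")
            object.__setattr__(self, "cell_ids", ids)

    @property
    def n_cells(self) -> int:
        return self.P.shape[0]

    @classmethod
    def from_long(
        cls,
        df: pd.DataFrame,
        *,
        cell_col: str = "cell_id",
        time_col: str = "time_min",
        value_col: str = "P",
        strain: str = "reference",
    ) -> "TrajectorySet":
        """Build from a long-format table (cell_id, time_min, P)."""
        wide = df.pivot(index=cell_col, columns=time_col, values=value_col)
        if wide.isna().any().any():
            raise DomainError("trajectories must share a common time grid")
        times = wide.columns.to_numpy(dtype=float)
        order = np.argsort(times)
        return cls(
            times=times[order],
            P=wide.to_numpy(dtype=float)[:, order],
            strain=strain,
            cell_ids=wide.index.to_numpy(),
        )

    def to_long(self) -> pd.DataFrame:
        n, t = self.P.shape
        return pd.DataFrame(
            {
                "cell_id": np.repeat(self.cell_ids, t),
                "time_min": np.tile(self.times, n),
                "P": self.P.ravel(),
            }
        )


def shortest_half_width(values: Sequence[float]) -> float:
    """Width of the shortest interval containing ceil(n/2) of the values."""
    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = x.size
    if n < 2:
        raise InsufficientDataError("need at least 2 values")
    if not np.all(np.isfinite(x)):
        raise DomainError("values must be finite")
    h = -(-n // 2)  # ceil(n/2) points per window
    return float(np.min(x[h - 1 :] - x[: n - h + 1]))


def default_onset_index(tset: TrajectorySet, frac: float = 0.05) -> int:
    """First timepoint where the median P exceeds ``frac`` of its final value.

    Avoids dividing by near-zero medians early in induction.  Falls back to
    0 when the final median is not positive.
    """
    med = np.median(tset.P, axis=0)
    if med[-1] <= 0:
        return 0
    above = np.flatnonzero(med > frac * med[-1])
    return int(above[0]) if above.size else 0


def progressive_spread(
    tset: TrajectorySet, onset_index: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Progressive spread distribution: shortest-half width of P_i(t)/median.

    Returns ``(times_used, spreads)``; timepoints with zero median are
    skipped with a warning.
    """
    if tset.n_cells < 4:
        raise InsufficientDataError("need at least 4 cells for spread statistics")
    if onset_index is None:
        onset_index = default_onset_index(tset)
    if not 0 <= onset_index < tset.times.size:
        raise ParameterError("onset_index outside the time grid")
    times_used, spreads = [], []
    skipped = 0
    for k in range(onset_index, tset.times.size):
        col = tset.P[:, k]
        med = np.median(col)
        if med == 0:
            skipped += 1
            continue
        times_used.append(tset.times[k])
        spreads.append(shortest_half_width(col / med))
    if skipped:
        warnings.warn(f"skipped {skipped} timepoint(s) with zero median P", stacklevel=2)
    if not spreads:
        raise InsufficientDataError("no timepoints with nonzero median P")
    return np.asarray(times_used), np.asarray(spreads)


@dataclass(frozen=True)
class MPSResult:
    mps: float
    ci_low: float
    ci_high: float
    n_boot: int


def mps(
    tset: TrajectorySet,
    n_boot: int = 10_000,
    seed: int | None = None,
    onset_index: int | None = None,
    alpha: float = 0.05,
) -> MPSResult:
    """Median progressive spread with a percentile bootstrap CI over cells."""
    if n_boot < 2:
        raise InsufficientDataError("n_boot must be >= 2")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable CIs", stacklevel=2)
    if onset_index is None:
        onset_index = default_onset_index(tset)
    _, spreads = progressive_spread(tset, onset_index)
    point = float(np.median(spreads))

    rng = np.random.default_rng(seed)
    n = tset.n_cells
    boots = np.empty(n_boot)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            sub = TrajectorySet(times=tset.times, P=tset.P[idx], strain=tset.strain)
            _, s = progressive_spread(sub, onset_index)
            boots[b] = np.median(s)
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return MPSResult(mps=point, ci_low=float(lo), ci_high=float(hi), n_boot=n_boot)


def crookedness_index(values: Sequence[float], smooth_window: int | None = None) -> float:
    """Crookedness I_C = 1 - |P(T) - P(0)| / sum(|increments|), in [0, 1].

    0 for monotone trajectories; 0 by convention when the trajectory is
    constant (zero total variation).  ``smooth_window`` applies a moving
    median before computing increments (off by default).
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 3:
        raise InsufficientDataError("need at least 3 timepoints")
    if not np.all(np.isfinite(x)):
        raise DomainError("values must be finite")
    if smooth_window is not None and smooth_window > 1:
        x = _moving_median(x, smooth_window)
    inc = np.diff(x)
    total = np.abs(inc).sum()
    if total == 0:
        return 0.0
    return float(1.0 - abs(x[-1] - x[0]) / total)


def _moving_median(x: np.ndarray, w: int) -> np.ndarray:
    half = w // 2
    padded = np.pad(x, half, mode="edge")
    return np.array([np.median(padded[i : i + w]) for i in range(x.size)])


def classify_crooked(
    tset: TrajectorySet,
    threshold: float = 0.3,
    smooth_window: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Flag crooked cells (I_C > threshold) and summarize the population.

    Returns ``(per_cell, summary)``.  ``per_cell`` has one row per cell
    with its I_C, crooked flag, final P, and whether the final P lies below
    the population mean of final P.  ``summary`` reports the crooked
    fraction and, among crooked cells, the fraction ending below the mean.
    """
    if not 0 <= threshold <= 1:
        raise ParameterError("threshold must be in [0, 1]")
    ic = np.array(
        [crookedness_index(row, smooth_window=smooth_window) for row in tset.P]
    )
    final = tset.P[:, -1]
    below = final < final.mean()
    crooked = ic > threshold
    per_cell = pd.DataFrame(
        {
            "cell_id": tset.cell_ids,
            "I_C": ic,
            "crooked": crooked,
            "final_P": final,
            "below_mean": below,
        }
    )
    n_crooked = int(crooked.sum())
    summary = {
        "strain": tset.strain,
        "n_cells": tset.n_cells,
        "n_crooked": n_crooked,
        "crooked_fraction": n_crooked / tset.n_cells if tset.n_cells else np.nan,
        "crooked_below_mean_fraction": (
            float(below[crooked].mean()) if n_crooked else np.nan
        ),
    }
    return per_cell, summary
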