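"""Variability decomposition for dual-reporter single-cell populations.

The unit of cell-to-cell variability is the normalized variance
``eta2(X) = var(X) / mean(X)**2`` (sample variance, n-1 denominator).
For a population measured with a pheromone-inducible reporter ``ind_r``
and a constitutive reporter ``con_y``:

* system output ``O`` and expression output ``G`` are channel *medians*;
  transmitted signal ``P = O / G``;
* pathway variability is estimated as the sample variance of the
  difference of the *mean*-normalized channels,
  ``var(ind_r/<ind_r> - con_y/<con_y>)``, which equals
  ``eta2(P) + eta2(gamma)``: shared expression-capacity fluctuations cancel
  in the difference, leaving pathway variability plus intrinsic expression
  noise;
* with a twin inducible reporter (two channels driven by identical
  promoters), intrinsic noise ``eta2(gamma)`` is the sample variance of the
  twin normalized difference.  Note this is the *full* difference variance,
  not half of it: under this convention the pathway-variability estimator
  above decomposes exactly as eta2(P) + eta2(gamma).  The halved
  (per-channel) convention used elsewhere in the intrinsic/extrinsic noise
  literature is available via ``convention="halved"``.

Medians for O and G versus means inside the variance estimators is
deliberate and follows the measurement definitions of the assay; the two
must not be conflated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError, InsufficientDataError, PairingError, SchemaError

__all__ = [
    "VariabilityDecomposition",
    "eta2",
    "normalize_channel",
    "pathway_variability",
    "intrinsic_noise",
    "decompose_population",
    "decompose_table",
    "bootstrap_decomposition",
]

GROUP_COLUMNS = ("strain", "dose_nM", "replicate")


@dataclass(frozen=True)
class VariabilityDecomposition:
    """Summary statistics for one strain x dose x replicate population."""

    O: float
    G: float
    P: float
    eta2_O: float
    eta2_G: float
    eta2_P_plus_gamma: float
    n_cells: int
    eta2_gamma: float | None = None
    eta2_P_corrected: float | None = None
    corrected_clipped: bool = False
    correlation_term: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _check_values(values, min_n: int = 2) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size < min_n:
        raise InsufficientDataError(f"need at least {min_n} values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise DomainError("values must be finite")
    return arr


def eta2(values: Sequence[float]) -> float:
    """Normalized variance: sample variance over squared sample mean."""
    arr = _check_values(values)
    mean = arr.mean()
    if mean <= 0:
        raise DomainError(f"mean must be > 0, got {mean}")
    return float(arr.var(ddof=1) / mean**2)


def normalize_channel(values: Sequence[float]) -> np.ndarray:
    """Divide values by their sample mean; output has mean exactly 1."""
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise InsufficientDataError("empty channel")
    if not np.all(np.isfinite(arr)):
        raise DomainError("values must be finite")
    mean = arr.mean()
    if mean <= 0:
        raise DomainError(f"channel mean must be > 0, got {mean}")
    return arr / mean


def _normalized_difference_variance(a, b) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise PairingError(f"channels must be paired per cell: {a.size} != {b.size}")
    if a.size < 2:
        raise InsufficientDataError("need at least 2 paired cells")
    diff = normalize_channel(a) - normalize_channel(b)
    return float(diff.var(ddof=1))


def pathway_variability(inducible, constitutive) -> float:
    """eta2(P) + eta2(gamma): variance of the normalized-channel difference."""
    return _normalized_difference_variance(inducible, constitutive)


def intrinsic_noise(inducible_1, inducible_2, convention: str = "difference") -> float:
    """eta2(gamma) from twin reporters driven by identical promoters.

    ``convention="difference"`` (default) returns the full variance of the
    normalized twin difference; ``"halved"`` returns half of it.
    """
    v = _normalized_difference_variance(inducible_1, inducible_2)
    if convention == "difference":
        return v
    if convention == "halved":
        return v / 2.0
    raise DomainError(f"unknown convention {convention!r}")


def _trim_mask(df: pd.DataFrame, channels, trim: tuple[float, float]) -> np.ndarray:
    lo, hi = trim
    keep = np.ones(len(df), dtype=bool)
    for col in channels:
        v = df[col].to_numpy()
        qlo, qhi = np.quantile(v, [lo, hi])
        keep &= (v >= qlo) & (v <= qhi)
    return keep


def decompose_population(
    population: pd.DataFrame,
    *,
    trim: tuple[float, float] | None = None,
    gamma_convention: str = "difference",
) -> VariabilityDecomposition:
    """Compute the full variability decomposition for one population.

    ``population`` needs columns ``ind_r`` and ``con_y``; a twin inducible
    channel ``ind_c``, when present, additionally yields the intrinsic
    noise eta2(gamma), the corrected pathway variability
    ``eta2_P_corrected = max(0, eta2_P_plus_gamma - eta2_gamma)`` and the
    residual correlation term of the small-noise identity
    ``eta2(O) = eta2(P) + eta2(gamma) + eta2(G) + 2*rho*eta(L)*eta(G)``.

    ``trim=(lo, hi)`` optionally keeps only cells inside those quantiles on
    every channel (off by default; real cytometry data usually need it,
    simulated data do not).
    """
    if "con_y" not in population.columns:
        raise SchemaError("missing required column 'con_y'")
    if "ind_r" not in population.columns:
        raise SchemaError("missing required column 'ind_r'")
    channels = ["ind_r", "con_y"] + (["ind_c"] if "ind_c" in population.columns else [])
    df = population
    if trim is not None:
        df = df[_trim_mask(df, channels, trim)]
    if len(df) < 2:
        raise InsufficientDataError("need at least 2 cells after filtering")

    ind_r = df["ind_r"].to_numpy(dtype=float)
    con_y = df["con_y"].to_numpy(dtype=float)
    o_med = float(np.median(ind_r))
    g_med = float(np.median(con_y))
    if g_med <= 0:
        raise DomainError("median constitutive signal must be > 0")

    e_o = eta2(ind_r)
    e_g = eta2(con_y)
    e_pg = pathway_variability(ind_r, con_y)
    corr_term = e_o - (e_pg + e_g)

    e_gamma = None
    e_p_corr = None
    clipped = False
    if "ind_c" in df.columns:
        e_gamma = intrinsic_noise(ind_r, df["ind_c"].to_numpy(dtype=float), gamma_convention)
        raw = e_pg - e_gamma
        clipped = raw < 0
        e_p_corr = max(0.0, raw)

    return VariabilityDecomposition(
        O=o_med,
        G=g_med,
        P=o_med / g_med,
        eta2_O=e_o,
        eta2_G=e_g,
        eta2_P_plus_gamma=e_pg,
        n_cells=len(df),
        eta2_gamma=e_gamma,
        eta2_P_corrected=e_p_corr,
        corrected_clipped=clipped,
        correlation_term=corr_term,
    )


def decompose_table(
    cells: pd.DataFrame,
    by: Sequence[str] = GROUP_COLUMNS,
    **kwargs,
) -> pd.DataFrame:
    """Decompose every strain x dose x replicate population in a cell table.

    Returns one tidy row per population with the fields of
    :class:`VariabilityDecomposition` plus the grouping columns.
    """
    missing = [c for c in by if c not in cells.columns]
    if missing:
        raise SchemaError(f"missing grouping column(s): {', '.join(missing)}")
    rows = []
    for keys, group in cells.groupby(list(by), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        rec = dict(zip(by, keys))
        rec.update(decompose_population(group, **kwargs).to_dict())
        rows.append(rec)
    if not rows:
        raise InsufficientDataError("no populations found")
    return pd.DataFrame(rows)


_BOOT_FIELDS = ("eta2_O", "eta2_G", "eta2_P_plus_gamma", "eta2_gamma", "eta2_P_corrected")


def bootstrap_decomposition(
    population: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Percentile bootstrap CIs for the variability estimators of one population.

    Resamples cells with replacement; returns a table with one row per
    statistic (estimate, ci_low, ci_high).  Vectorized over resamples.
    """
    if n_boot < 2:
        raise InsufficientDataError("n_boot must be >= 2")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable CIs", stacklevel=2)
    base = decompose_population(population)
    rng = np.random.default_rng(seed)
    n = len(population)
    idx = rng.integers(0, n, size=(n_boot, n))

    ind_r = population["ind_r"].to_numpy(dtype=float)[idx]
    con_y = population["con_y"].to_numpy(dtype=float)[idx]
    has_twin = "ind_c" in population.columns
    ind_c = population["ind_c"].to_numpy(dtype=float)[idx] if has_twin else None

    def row_eta2(m):
        return m.var(axis=1, ddof=1) / m.mean(axis=1) ** 2

    def row_diffvar(a, b):
        d = a / a.mean(axis=1, keepdims=True) - b / b.mean(axis=1, keepdims=True)
        return d.var(axis=1, ddof=1)

    stats = {
        "eta2_O": row_eta2(ind_r),
        "eta2_G": row_eta2(con_y),
        "eta2_P_plus_gamma": row_diffvar(ind_r, con_y),
    }
    if has_twin:
        stats["eta2_gamma"] = row_diffvar(ind_r, ind_c)
        stats["eta2_P_corrected"] = np.clip(
            stats["eta2_P_plus_gamma"] - stats["eta2_gamma"], 0.0, None
        )

    rows = []
    base_d = base.to_dict()
    for name in _BOOT_FIELDS:
        if name not in stats:
            continue
        lo, hi = np.quantile(stats[name], [alpha / 2, 1 - alpha / 2])
        rows.append(
            {"statistic": name, "estimate": base_d[name], "ci_low": lo, "ci_high": hi}
        )
    return pd.DataFrame(rows)
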