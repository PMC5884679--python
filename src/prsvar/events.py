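"""Statistics for scored single-cell event timings.

Given per-cell event timings (e.g. time to first signaling-site patch,
patch durations, gap/overlap between consecutive patches) and qualitative
category flags (no polarization, gap, overlap), this module provides:

* bootstrap point estimates and standard errors for the mean, SD and
  coefficient of variation of each timing variable;
* permutation tests of a mutant group against a reference group on any of
  those statistics (exhaustive enumeration when the number of group
  assignments is small enough, Monte-Carlo otherwise);
* Fisher's exact test for 2x2 category counts (two-sided by the
  minimum-likelihood convention of standard count-data usage).

Missing timings (cells that never polarized) are excluded per statistic,
with excluded counts reported.
"""

from __future__ import annotations

import math
import warnings
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DomainError, InsufficientDataError, ParameterError, SchemaError

__all__ = [
    "bootstrap_summary",
    "permutation_test",
    "fisher_exact",
    "summarize_event_table",
    "category_tests",
]

_STATISTICS = ("mean", "sd", "cv")
_EXHAUSTIVE_LIMIT = 100_000


def _clean(values, min_n: int) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    arr = arr[np.isfinite(arr)]
    if arr.size < min_n:
        raise InsufficientDataError(f"need at least {min_n} non-missing values")
    return arr


def _stat_fns(statistic: str):
    """Row-wise statistic over a 2-D array (resamples x values)."""
    if statistic == "mean":
        return lambda m: m.mean(axis=-1)
    if statistic == "sd":
        return lambda m: m.std(axis=-1, ddof=1)
    if statistic == "cv":

        def cv(m):
            mu = m.mean(axis=-1)
            with np.errstate(divide="ignore", invalid="ignore"):
                return np.where(mu != 0, m.std(axis=-1, ddof=1) / mu, np.nan)

        return cv
    raise ParameterError(f"unknown statistic {statistic!r}; use one of {_STATISTICS}")


def bootstrap_summary(
    values,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> dict:
    """Mean +- SEM, SD +- SE and CV +- SE, with bootstrap standard errors.

    Point estimates come from the full sample (SD with n-1; CV = SD/mean);
    each SE is the standard deviation of the statistic over ``n_boot``
    with-replacement resamples.  Deterministic given ``seed``.
    """
    arr = _clean(values, 3)
    if n_boot < 2:
        raise ParameterError("n_boot must be >= 2")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if mean <= 0:
        raise DomainError("mean must be > 0 to report a coefficient of variation")
    cv = sd / mean

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(n_boot, arr.size))
    resamples = arr[idx]
    boot_mean = resamples.mean(axis=1)
    boot_sd = resamples.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        boot_cv = np.where(boot_mean != 0, boot_sd / boot_mean, np.nan)
    return {
        "n": int(arr.size),
        "mean": mean,
        "sem": float(boot_mean.std(ddof=1)),
        "sd": sd,
        "sd_se": float(boot_sd.std(ddof=1)),
        "cv": float(cv),
        "cv_se": float(np.nanstd(boot_cv, ddof=1)),
        "n_boot": int(n_boot),
    }


def permutation_test(
    group_a,
    group_b,
    statistic: str = "mean",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> float:
    """Two-sided permutation p-value for |statistic(A) - statistic(B)|.

    All assignments are enumerated exhaustively when C(n_a + n_b, n_a) <=
    1e5 (p = #extreme / #total); otherwise ``n_perm`` random relabelings
    are drawn and p = (1 + #extreme) / (n_perm + 1).
    """
    fn = _stat_fns(statistic)
    a = _clean(group_a, 2)
    b = _clean(group_b, 2)
    pool = np.concatenate([a, b])
    n_a, n_tot = a.size, a.size + b.size
    t_obs = abs(float(fn(a[None, :])[0] - fn(b[None, :])[0]))

    if math.comb(n_tot, n_a) <= _EXHAUSTIVE_LIMIT:
        count = total = 0
        all_idx = frozenset(range(n_tot))
        for combo in combinations(range(n_tot), n_a):
            ia = np.fromiter(combo, dtype=int)
            ib = np.fromiter(all_idx - set(combo), dtype=int)
            t = abs(float(fn(pool[ia][None, :])[0] - fn(pool[ib][None, :])[0]))
            total += 1
            if t >= t_obs - 1e-12:
                count += 1
        return count / total

    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.broadcast_to(pool, (n_perm, n_tot)).copy(), axis=1)
    t_star = np.abs(fn(perms[:, :n_a]) - fn(perms[:, n_a:]))
    count = int(np.sum(t_star >= t_obs - 1e-12))
    return (1.0 + count) / (n_perm + 1.0)


def fisher_exact(table, alternative: str = "two-sided") -> float:
    """Fisher's exact test p-value for a 2x2 table of counts.

    Two-sided by the minimum-likelihood convention: the sum of
    hypergeometric probabilities of all tables with the observed margins
    whose probability does not exceed that of the observed table.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ParameterError("table must be 2x2")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise ParameterError("counts must be integers")
        arr = arr.astype(int)
    if np.any(arr < 0):
        raise ParameterError("counts must be nonnegative")
    if arr.sum(axis=0).min() <= 0 or arr.sum(axis=1).min() <= 0:
        raise DomainError("both margins must be positive")
    return float(sps.fisher_exact(arr, alternative=alternative).pvalue)


TIMING_COLUMNS = (
    "time_to_first_patch",
    "duration_first",
    "duration_second",
    "gap_or_overlap",
)
CATEGORY_COLUMNS = ("no_polarization", "gap", "overlap")


def summarize_event_table(
    events: pd.DataFrame,
    timing_columns: Sequence[str] = TIMING_COLUMNS,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-strain bootstrap summaries (mean/SD/CV +- SE) of timing variables.

    Absolute values are used for the CV of signed variables (gap/overlap
    can be negative); excluded (missing) counts are reported per variable.
    """
    if "strain" not in events.columns:
        raise SchemaError("missing required column 'strain'")
    root = np.random.SeedSequence(seed)
    rows = []
    for (strain, col), child in zip(
        [(s, c) for s in sorted(events["strain"].unique()) for c in timing_columns],
        root.spawn(events["strain"].nunique() * len(timing_columns)),
    ):
        if col not in events.columns:
            continue
        values = events.loc[events["strain"] == strain, col]
        n_missing = int(values.isna().sum())
        try:
            v = values.to_numpy(dtype=float)
            use = np.abs(v) if np.nanmin(v) < 0 else v
            summary = bootstrap_summary(
                use, n_boot=n_boot, seed=int(child.generate_state(1)[0] % 2**31)
            )
        except (InsufficientDataError, DomainError):
            continue
        rows.append({"strain": strain, "variable": col, "n_missing": n_missing, **summary})
    return pd.DataFrame(rows)


def compare_to_reference(
    events: pd.DataFrame,
    reference: str,
    timing_columns: Sequence[str] = TIMING_COLUMNS,
    statistics: Sequence[str] = _STATISTICS,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permutation p-values of every strain against the reference strain."""
    if reference not in set(events["strain"]):
        raise ParameterError(f"reference strain {reference!r} not in table")
    root = np.random.SeedSequence(seed)
    rows = []
    others = sorted(s for s in events["strain"].unique() if s != reference)
    children = iter(root.spawn(len(others) * len(timing_columns) * len(statistics)))
    for strain in others:
        for col in timing_columns:
            if col not in events.columns:
                continue
            a = events.loc[events["strain"] == strain, col]
            b = events.loc[events["strain"] == reference, col]
            for stat in statistics:
                child = next(children)
                try:
                    p = permutation_test(
                        a,
                        b,
                        statistic=stat,
                        n_perm=n_perm,
                        seed=int(child.generate_state(1)[0] % 2**31),
                    )
                except (InsufficientDataError, DomainError):
                    continue
                rows.append(
                    {"strain": strain, "variable": col, "statistic": stat, "p_value": p}
                )
    return pd.DataFrame(rows)


def category_tests(
    events: pd.DataFrame,
    reference: str,
    category_columns: Sequence[str] = CATEGORY_COLUMNS,
    correction: str | None = None,
) -> pd.DataFrame:
    """Fisher's exact test per category flag, each strain vs the reference.

    Each test is a 2x2 table (strain vs reference) x (flag vs not).
    ``correction`` in {None, "bonferroni", "bh"} optionally adjusts the
    p-values across the strain x category family (uncorrected by default).
    """
    if reference not in set(events["strain"]):
        raise ParameterError(f"reference strain {reference!r} not in table")
    rows = []
    ref = events[events["strain"] == reference]
    for strain in sorted(s for s in events["strain"].unique() if s != reference):
        sub = events[events["strain"] == strain]
        for col in category_columns:
            if col not in events.columns:
                continue
            a1 = int(sub[col].sum())
            a0 = int(len(sub) - a1)
            b1 = int(ref[col].sum())
            b0 = int(len(ref) - b1)
            table = [[a1, a0], [b1, b0]]
            try:
                p = fisher_exact(table)
            except DomainError:
                p = np.nan
            rows.append(
                {
                    "strain": strain,
                    "category": col,
                    "count": a1,
                    "n": a1 + a0,
                    "ref_count": b1,
                    "ref_n": b1 + b0,
                    "p_value": p,
                }
            )
    out = pd.DataFrame(rows)
    if correction and len(out):
        p = out["p_value"].to_numpy()
        ok = np.isfinite(p)
        adj = np.full_like(p, np.nan)
        if correction == "bonferroni":
            adj[ok] = np.minimum(p[ok] * ok.sum(), 1.0)
        elif correction == "bh":
            m = ok.sum()
            order = np.argsort(p[ok])
            ranked = p[ok][order] * m / (np.arange(m) + 1)
            ranked = np.minimum.accumulate(ranked[::-1])[::-1]
            vals = np.empty(m)
            vals[order] = np.minimum(ranked, 1.0)
            adj[ok] = vals
        else:
            raise ParameterError("correction must be None, 'bonferroni' or 'bh'")
        out["p_adjusted"] = adj
    return out
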