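"""Hit-calling for a multi-strain variability screen.

Strains are screened on three variables — median output O at the low dose,
pathway variability eta2(P) at the low dose, and eta2(P) at the high dose —
against thresholds placed in the tails of the distribution of reference-
strain replicates.  Five criteria codes are used:

    1: O(low) below the lower threshold       (weak output)
    2: O(low) above the upper threshold       (strong output)
    3: eta2(P)(low) below the lower threshold (low variability)
    4: eta2(P)(low) above the upper threshold (high variability)
    5: eta2(P)(high) above the upper threshold

All comparisons are strict inequalities; boundary equality is not
selected.  A strain may carry several codes; it is "selected" when it
carries at least one.  Confirmation across replicate re-assays uses a
k-of-m vote per criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, ParameterError, SchemaError

__all__ = ["SelectionThresholds", "HitCall", "derive_thresholds", "call_hits", "confirm_hits"]

ETA2P_COLUMN = "eta2_P_plus_gamma"  # the screen's eta2(P) estimate (twin-free)


@dataclass(frozen=True)
class SelectionThresholds:
    """Tail thresholds for the five selection criteria."""

    low_dose: float
    high_dose: float
    o_low_lower: float
    o_low_upper: float
    eta2p_low_lower: float
    eta2p_low_upper: float
    eta2p_high_upper: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class HitCall:
    strain: str
    criteria: frozenset
    selected: bool
    missing: frozenset = frozenset()

    def to_dict(self) -> dict:
        return {
            "strain": self.strain,
            "criteria": ",".join(str(c) for c in sorted(self.criteria)),
            "selected": self.selected,
            "missing": ",".join(str(c) for c in sorted(self.missing)),
        }


def derive_thresholds(
    reference_rows: pd.DataFrame,
    tail_prob: float = 0.025,
    *,
    low_dose: float = 0.6,
    high_dose: float = 20.0,
    eta2p_column: str = ETA2P_COLUMN,
) -> SelectionThresholds:
    """Empirical tail quantiles of the reference-replicate distributions.

    ``reference_rows`` is a decomposition table restricted to reference
    replicates (must cover both doses, >= 5 rows each).  Quantiles use
    linear interpolation of order statistics.
    """
    if not 0 < tail_prob < 0.5:
        raise ParameterError("tail_prob must be in (0, 0.5)")
    for col in ("dose_nM", "O", eta2p_column):
        if col not in reference_rows.columns:
            raise SchemaError(f"missing required column '{col}'")

    def dose_rows(dose):
        sub = reference_rows[np.isclose(reference_rows["dose_nM"], dose)]
        if len(sub) < 5:
            raise InsufficientDataError(
                f"need >= 5 reference replicates at {dose} nM, got {len(sub)}"
            )
        return sub

    low = dose_rows(low_dose)
    high = dose_rows(high_dose)

    def tails(values):
        lo, hi = np.quantile(np.asarray(values, dtype=float), [tail_prob, 1 - tail_prob])
        if lo == hi:
            warnings.warn(
                "degenerate reference distribution: lower == upper threshold",
                stacklevel=2,
            )
        return float(lo), float(hi)

    o_lo, o_hi = tails(low["O"])
    e_lo, e_hi = tails(low[eta2p_column])
    _, eh_hi = tails(high[eta2p_column])
    return SelectionThresholds(
        low_dose=low_dose,
        high_dose=high_dose,
        o_low_lower=o_lo,
        o_low_upper=o_hi,
        eta2p_low_lower=e_lo,
        eta2p_low_upper=e_hi,
        eta2p_high_upper=eh_hi,
    )


def _criteria_for(
    o_low, eta2p_low, eta2p_high, thresholds: SelectionThresholds
) -> tuple[set, set]:
    """Strictly compare the three measurements; return (criteria, missing codes)."""
    criteria, missing = set(), set()
    if o_low is None or not np.isfinite(o_low):
        missing |= {1, 2}
    else:
        if o_low < thresholds.o_low_lower:
            criteria.add(1)
        if o_low > thresholds.o_low_upper:
            criteria.add(2)
    if eta2p_low is None or not np.isfinite(eta2p_low):
        missing |= {3, 4}
    else:
        if eta2p_low < thresholds.eta2p_low_lower:
            criteria.add(3)
        if eta2p_low > thresholds.eta2p_low_upper:
            criteria.add(4)
    if eta2p_high is None or not np.isfinite(eta2p_high):
        missing.add(5)
    elif eta2p_high > thresholds.eta2p_high_upper:
        criteria.add(5)
    return criteria, missing


def call_hits(
    strain_rows: pd.DataFrame,
    thresholds: SelectionThresholds,
    *,
    eta2p_column: str = ETA2P_COLUMN,
) -> list[HitCall]:
    """Apply the five selection criteria to each strain.

    ``strain_rows`` is a decomposition table (one row per strain x dose; if
    several replicates are present per strain and dose they are averaged
    first).  Strains missing a measurement get a partial call with the
    unevaluable codes recorded in ``missing``.
    """
    for col in ("strain", "dose_nM", "O", eta2p_column):
        if col not in strain_rows.columns:
            raise SchemaError(f"missing required column '{col}'")
    agg = (
        strain_rows.groupby(["strain", "dose_nM"], sort=True)[["O", eta2p_column]]
        .mean()
        .reset_index()
    )
    calls = []
    for strain, sub in agg.groupby("strain", sort=True):
        low = sub[np.isclose(sub["dose_nM"], thresholds.low_dose)]
        high = sub[np.isclose(sub["dose_nM"], thresholds.high_dose)]
        o_low = float(low["O"].iloc[0]) if len(low) else None
        e_low = float(low[eta2p_column].iloc[0]) if len(low) else None
        e_high = float(high[eta2p_column].iloc[0]) if len(high) else None
        criteria, missing = _criteria_for(o_low, e_low, e_high, thresholds)
        calls.append(
            HitCall(
                strain=strain,
                criteria=frozenset(criteria),
                selected=bool(criteria),
                missing=frozenset(missing),
            )
        )
    return calls


def call_hits_per_replicate(
    decomposition_rows: pd.DataFrame,
    thresholds: SelectionThresholds,
    *,
    eta2p_column: str = ETA2P_COLUMN,
) -> pd.DataFrame:
    """One hit call per strain x replicate; rows of criteria-code booleans."""
    rows = []
    for rep, sub in decomposition_rows.groupby("replicate", sort=True):
        for call in call_hits(sub, thresholds, eta2p_column=eta2p_column):
            rec = {"strain": call.strain, "replicate": rep}
            for code in range(1, 6):
                rec[f"criterion_{code}"] = code in call.criteria
            rows.append(rec)
    return pd.DataFrame(rows)


def confirm_hits(replicate_calls: pd.DataFrame, k: int = 2) -> list[HitCall]:
    """Confirm a strain under a criterion when >= k replicates carry it.

    ``replicate_calls`` is the output of :func:`call_hits_per_replicate`.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    calls = []
    crit_cols = [f"criterion_{c}" for c in range(1, 6)]
    for strain, sub in replicate_calls.groupby("strain", sort=True):
        counts = sub[crit_cols].sum()
        criteria = frozenset(
            c for c in range(1, 6) if counts[f"criterion_{c}"] >= k
        )
        calls.append(HitCall(strain=strain, criteria=criteria, selected=bool(criteria)))
    return calls


def hit_table(calls: Iterable[HitCall]) -> pd.DataFrame:
    return pd.DataFrame([c.to_dict() for c in calls])
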