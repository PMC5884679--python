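"""Synthetic single-cell dual-reporter data with known ground truth.

Three generators, all built on the multiplicative model described in
:mod:`prsvar.params`:

* :func:`simulate_population` — snapshot populations (flow-cytometry-like
  per-cell fluorescence at one dose), optionally with a twin inducible
  reporter for intrinsic-noise estimation.
* :func:`simulate_trajectories` — per-cell time courses of the cumulative
  transmitted-signal ratio P(t), with optional injected "crooked" events
  (transient pathway-rate excursions that produce the non-monotone jumps
  seen in unstable signaling).
* :func:`simulate_screen` — a multi-strain screen at two doses with
  planted per-strain effects on mean output and on pathway variability,
  plus a ground-truth table for parameter-recovery tests.

Every generator is deterministic given (params, seed).
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .params import SimulationParams
from .trajectories import TrajectorySet

__all__ = ["simulate_population", "simulate_trajectories", "simulate_screen"]


def _capacity_multipliers(
    params: SimulationParams,
    internals,
    n: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Correlated lognormal pair (l, g), each mean 1, calibrated variances.

    The Gaussian-copula correlation is inverted exactly so that
    corr(l, g) = rho on the raw (relative) scale.
    """
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    r_z = params.copula_corr(internals)
    z2 = r_z * z1 + math.sqrt(1.0 - r_z * r_z) * z2
    s_l = math.sqrt(math.log1p(internals.v_L))
    s_g = math.sqrt(math.log1p(internals.v_G))
    ell = np.exp(s_l * z1 - 0.5 * s_l * s_l) if s_l > 0 else np.ones(n)
    g = np.exp(s_g * z2 - 0.5 * s_g * s_g) if s_g > 0 else np.ones(n)
    return ell, g


def _pathway_capacity(
    params: SimulationParams,
    internals,
    n: int,
    dose_nM: float,
    ell: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cell pathway capacity L_i, additive noise lambda_i, nonresponder mask.

    Nonresponders sit at the basal capacity with no stimulation noise.
    """
    lbar = params.mean_capacity(dose_nM)
    cap = lbar * ell
    sd = internals.lam_sd
    lam = rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)
    nonresp = (
        rng.random(n) < params.nonresponder_frac
        if params.nonresponder_frac > 0
        else np.zeros(n, dtype=bool)
    )
    cap = np.where(nonresp, params.L_basal, cap)
    lam = np.where(nonresp, 0.0, lam)
    return cap, lam, nonresp


def simulate_population(
    params: SimulationParams,
    n_cells: int,
    dose_nM: float,
    twin_inducible: bool = False,
    *,
    strain: str = "reference",
    replicate: str = "r1",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one snapshot population of per-cell fluorescence records.

    Returns a table with columns ``strain, dose_nM, replicate, cell_id,
    ind_r, con_y`` (and ``ind_c`` when ``twin_inducible``), the canonical
    per-cell format consumed by :mod:`prsvar.decomposition`.
    """
    if not isinstance(n_cells, (int, np.integer)) or n_cells < 1:
        raise ParameterError("n_cells must be a positive integer")
    if dose_nM < 0:
        raise ParameterError("dose_nM must be >= 0")
    params.check_truncation(dose_nM)
    if rng is None:
        rng = np.random.default_rng(params.seed)

    n = int(n_cells)
    internals = params.noise_internals(dose_nM)
    ell, g = _capacity_multipliers(params, internals, n, rng)
    cap, lam, nonresp = _pathway_capacity(params, internals, n, dose_nM, ell, rng)
    pathway = np.clip(cap + lam, 0.0, None)

    expr_cap = params.Gbar * g
    g_sd = internals.gamma_sd

    def channel() -> np.ndarray:
        gamma = rng.normal(0.0, g_sd, n) if g_sd > 0 else np.zeros(n)
        return np.clip(expr_cap + gamma, 0.0, None)

    ind_r = pathway * channel() * params.delta_T
    con_y = params.con_scale * channel() * params.delta_T
    data = {
        "strain": strain,
        "dose_nM": float(dose_nM),
        "replicate": replicate,
        "cell_id": np.arange(n),
        "ind_r": ind_r,
        "con_y": con_y,
    }
    if twin_inducible:
        data["ind_c"] = pathway * channel() * params.delta_T
    df = pd.DataFrame(data)
    if params.nonresponder_frac > 0:
        df["nonresponder"] = nonresp
    return df


def simulate_trajectories(
    params: SimulationParams,
    n_cells: int,
    times: Sequence[float],
    crooked_frac: float = 0.0,
    jump_magnitude: float = 3.0,
    *,
    dose_nM: float = 20.0,
    strain: str = "reference",
    rng: np.random.Generator | None = None,
) -> tuple[TrajectorySet, pd.DataFrame]:
    """Simulate per-cell trajectories of cumulative transmitted signal P(t).

    Each cell accumulates inducible signal at rate ``(L_i + lambda_ik) *
    G_i`` (fresh lambda draw per sampling interval) and constitutive signal
    at rate ``con_scale * G_i``; ``P(t)`` is the ratio of the two cumulative
    signals (0 at the first timepoint, before anything has accumulated).

    A fraction ``crooked_frac`` of cells receives one transient pathway-rate
    excursion: for a single, uniformly chosen interior sampling interval the
    inducible rate is multiplied by ``jump_magnitude`` or divided by it
    (equal probability).  Because the excursion is transient, the cumulative
    ratio overshoots and then relaxes back — the non-monotone "jump" that
    the crookedness index is designed to flag.  A sustained rate switch
    would only re-level the trajectory monotonically and would be invisible
    to any total-variation statistic.

    Returns ``(trajectory_set, truth)`` where ``truth`` has one row per
    cell: ``cell_id, crooked, jump_interval, jump_factor, nonresponder``.
    """
    if not 0.0 <= crooked_frac <= 1.0:
        raise ParameterError("crooked_frac must be in [0, 1]")
    if jump_magnitude <= 0:
        raise ParameterError("jump_magnitude must be > 0")
    if n_cells < 0 or not isinstance(n_cells, (int, np.integer)):
        raise ParameterError("n_cells must be a nonnegative integer")
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0):
        raise ParameterError("times must be strictly increasing with length >= 2")
    n_int = times.size - 1
    if crooked_frac > 0 and n_int < 3:
        raise ParameterError(
            "crooked events need >= 3 sampling intervals (one interior interval "
            "with room for the trajectory to relax afterwards)"
        )
    params.check_truncation(dose_nM)
    if rng is None:
        rng = np.random.default_rng(params.seed)

    n = int(n_cells)
    if n == 0:
        empty = TrajectorySet(times=times, P=np.empty((0, times.size)), strain=strain)
        truth = pd.DataFrame(
            columns=["cell_id", "crooked", "jump_interval", "jump_factor", "nonresponder"]
        )
        return empty, truth

    internals = params.noise_internals(dose_nM)
    ell, g = _capacity_multipliers(params, internals, n, rng)
    cap, _, nonresp = _pathway_capacity(params, internals, n, dose_nM, ell, rng)
    expr_cap = params.Gbar * g

    sd = internals.lam_sd
    lam = rng.normal(0.0, sd, (n, n_int)) if sd > 0 else np.zeros((n, n_int))
    lam[nonresp] = 0.0

    mult = np.ones((n, n_int))
    crooked = rng.random(n) < crooked_frac
    jump_interval = np.full(n, -1)
    jump_factor = np.ones(n)
    n_crooked = int(crooked.sum())
    if n_crooked:
        # interior intervals only: not the first, and leave at least one
        # interval afterwards so the reversal is observable
        idx = rng.integers(1, n_int - 1, n_crooked)
        up = rng.random(n_crooked) < 0.5
        fac = np.where(up, jump_magnitude, 1.0 / jump_magnitude)
        jump_interval[crooked] = idx
        jump_factor[crooked] = fac
        mult[np.flatnonzero(crooked), idx] = fac

    dts = np.diff(times)
    rate_ind = np.clip(cap[:, None] + lam, 0.0, None) * mult * expr_cap[:, None]
    cum_ind = np.concatenate(
        [np.zeros((n, 1)), np.cumsum(rate_ind * dts[None, :], axis=1)], axis=1
    )
    cum_con = params.con_scale * expr_cap[:, None] * (times - times[0])[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(cum_con > 0, cum_ind / np.where(cum_con > 0, cum_con, 1.0), 0.0)

    tset = TrajectorySet(times=times, P=P, strain=strain)
    truth = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "crooked": crooked,
            "jump_interval": jump_interval,
            "jump_factor": jump_factor,
            "nonresponder": nonresp,
        }
    )
    return tset, truth


def simulate_screen(
    params: SimulationParams,
    n_strains: int,
    n_replicates: int = 1,
    n_cells_per_rep: int = 400,
    *,
    mean_multipliers: Sequence[float] | None = None,
    var_multipliers: Sequence[float] | None = None,
    cluster_labels: Sequence | None = None,
    doses: Sequence[float] = (0.6, 20.0),
    strain_names: Sequence[str] | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a multi-strain screen at two (or more) doses.

    ``mean_multipliers`` scale each strain's mean pathway capacity (both
    basal and maximal, so the dose-response shape is preserved);
    ``var_multipliers`` scale its pathway-variability parameters (eta2_L
    and eta2_lambda together).  Both default to 1 (reference-like strains).

    Returns ``(cells, truth)``: a long-format per-cell table and a
    ground-truth table with one row per strain (``strain, mean_multiplier,
    var_multiplier, cluster`` plus the expected pathway variability at each
    dose).
    """
    if n_strains < 1 or n_replicates < 1 or n_cells_per_rep < 1:
        raise ParameterError("n_strains, n_replicates and n_cells_per_rep must be >= 1")
    mean_mult = _as_multipliers(mean_multipliers, n_strains, "mean_multipliers")
    var_mult = _as_multipliers(var_multipliers, n_strains, "var_multipliers")
    if cluster_labels is None:
        cluster_labels = ["none"] * n_strains
    elif len(cluster_labels) != n_strains:
        raise ParameterError("cluster_labels must have one entry per strain")
    if strain_names is None:
        width = max(4, len(str(n_strains)))
        strain_names = [f"strain_{i:0{width}d}" for i in range(n_strains)]
    elif len(strain_names) != n_strains:
        raise ParameterError("strain_names must have one entry per strain")
    doses = [float(d) for d in doses]

    root = np.random.SeedSequence(params.seed if seed is None else seed)
    children = root.spawn(n_strains)

    frames = []
    truth_rows = []
    for s in range(n_strains):
        sp = params.replace(
            Lbar_max=params.Lbar_max * mean_mult[s],
            L_basal=params.L_basal * mean_mult[s],
            eta2_L=params.eta2_L * var_mult[s],
            eta2_lambda=params.eta2_lambda * var_mult[s],
        )
        rng = np.random.default_rng(children[s])
        for rep in range(n_replicates):
            for dose in doses:
                frames.append(
                    simulate_population(
                        sp,
                        n_cells_per_rep,
                        dose,
                        strain=strain_names[s],
                        replicate=f"rep{rep + 1}",
                        rng=rng,
                    )
                )
        row = {
            "strain": strain_names[s],
            "mean_multiplier": mean_mult[s],
            "var_multiplier": var_mult[s],
            "cluster": cluster_labels[s],
        }
        for dose in doses:
            row[f"true_eta2_P_at_{dose:g}nM"] = sp.expected_eta2_P(dose)
            row[f"true_mean_capacity_at_{dose:g}nM"] = sp.mean_capacity(dose)
        truth_rows.append(row)

    cells = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return cells, truth


def _as_multipliers(values, n: int, name: str) -> np.ndarray:
    if values is None:
        return np.ones(n)
    arr = np.asarray(values, dtype=float)
    if arr.shape != (n,):
        raise ParameterError(f"{name} must have one entry per strain")
    if np.any(arr <= 0):
        raise ParameterError(f"{name} must be > 0")
    return arr
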