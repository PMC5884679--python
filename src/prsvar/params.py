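"""Ground-truth parameters for the stochastic dual-reporter model.

The generative model treats the fluorescence output of each cell ``i`` as a
product of a pathway term and an expression term accumulated over the
stimulation window::

    O_i = (L_i + lambda_i) * (G_i + gamma_i) * delta_T

``L_i`` is the cell's pathway capacity (its mean over the population
follows a Hill function of pheromone dose), ``lambda_i`` is fast
stochastic fluctuation in pathway operation, ``G_i`` is the cell's general
gene expression capacity, and ``gamma_i`` is fast intrinsic expression
noise, drawn independently for every fluorescence channel.  Cell-to-cell
variability of any quantity ``X`` is ``eta2(X) = var(X)/mean(X)**2``.

Distributional choices (the experimental system fixes none of them):

* ``L_i = Lbar(dose) * l_i`` and ``G_i = Gbar * g_i`` with ``(l_i, g_i)`` a
  correlated lognormal pair (capacities must stay positive); the
  correlation ``rho`` is imposed exactly on the relative scale through the
  Gaussian copula.
* ``lambda_i`` and the per-channel ``gamma_i`` are zero-mean Gaussian,
  clipped so capacities stay nonnegative; parameters whose clipped mass
  would exceed 1e-4 are rejected rather than silently biased.

Calibration.  The eta2 parameters are *population-level targets for the
estimators* of :mod:`prsvar.decomposition`, not raw variances of the
internal draws.  In a multiplicative model the estimators pick up exact
second-order terms: with per-cell pathway relative variance ``a``,
expression-capacity relative variance ``v_G`` and per-channel intrinsic
relative variance ``q``, at ``rho = 0``

    E[eta2(constitutive)]        = v_G + q
    E[twin difference variance]  = 2 q (1 + a)
    E[dual difference variance]  = a + 2 q + a (v_G + q)

Internal variances are therefore solved so that, at the simulated dose and
``rho = 0``, the constitutive-channel eta2 equals ``eta2_G``, the
twin-reporter intrinsic-noise estimator equals ``eta2_gamma``, and the
gamma-corrected pathway variability equals ``eta2_L + eta2_lambda``:
parameter recovery is exact in expectation, not merely to first order.
With ``rho != 0`` additional cross terms of order ``rho *
sqrt(eta2_L * eta2_G) * eta2`` remain (about 1-2% relative at the default
scales).

``lambda_mode`` fixes how the pathway fluctuation scales with dose:
``"relative"`` keeps its contribution to pathway variability equal to
``eta2_lambda`` at every dose; ``"absolute"`` (default) anchors its SD at
the saturating capacity, so pathway variability falls monotonically with
increasing dose — the behavior observed for the yeast pheromone response
system.  ``eta2_lambda`` is then the contribution at saturation, and
``expected_eta2_P(dose)`` reports the dose-specific ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from .exceptions import ParameterError

__all__ = ["SimulationParams", "NoiseInternals"]


@dataclass(frozen=True)
class NoiseInternals:
    """Internal noise variances realizing the eta2 targets at one dose."""

    v_L: float  # relative variance of the lognormal pathway capacity
    lam_sd: float  # SD of the additive pathway fluctuation (capacity units)
    v_G: float  # relative variance of the lognormal expression capacity
    gamma_sd: float  # per-channel SD of intrinsic noise (capacity units)
    a: float  # total pathway relative variance v_L + (lam_sd/Lbar)^2


@dataclass(frozen=True)
class SimulationParams:
    """Ground truth for the synthetic-data generator.

    Defaults mirror the scales of the screen this package models: at the
    low screening dose (0.6 nM) median output is ~5 A.U. and pathway
    variability ~0.045; at the saturating dose (20 nM) output is ~20 A.U.
    and pathway variability ~0.015.
    """

    Lbar_max: float = 8.0  # mean pathway capacity at saturating dose
    L_basal: float = 0.1  # mean capacity at dose 0
    EC50: float = 2.0  # nM, dose of half-maximal capacity
    hill_h: float = 1.0  # Hill coefficient
    Gbar: float = 0.014  # mean expression capacity, A.U./min
    delta_T: float = 180.0  # stimulation duration, min
    eta2_L: float = 0.013
    eta2_lambda: float = 0.002
    eta2_G: float = 0.04
    eta2_gamma: float = 0.005
    rho: float = -0.3  # correlation between per-cell L and G deviations
    nonresponder_frac: float = 0.0
    lambda_mode: str = "absolute"  # or "relative"
    con_scale: float = 1.0  # constitutive-channel gain
    seed: int = 0

    _MAX_TRUNCATION_MASS = 1e-4

    def __post_init__(self) -> None:
        for name in ("eta2_L", "eta2_lambda", "eta2_G", "eta2_gamma"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("EC50", "hill_h", "delta_T", "Gbar", "con_scale"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.Lbar_max < 0 or self.L_basal < 0:
            raise ParameterError("Lbar_max and L_basal must be >= 0")
        if self.L_basal > self.Lbar_max:
            raise ParameterError("L_basal must not exceed Lbar_max")
        if not 0.0 <= self.nonresponder_frac <= 1.0:
            raise ParameterError("nonresponder_frac must be in [0, 1]")
        if not -1.0 <= self.rho <= 1.0:
            raise ParameterError("rho must be in [-1, 1]")
        if self.lambda_mode not in ("absolute", "relative"):
            raise ParameterError("lambda_mode must be 'absolute' or 'relative'")
        if not isinstance(self.seed, (int, np.integer)):
            raise ParameterError("seed must be a Python integer")
        if self.eta2_gamma > 0 and self.eta2_G < self.eta2_gamma / 2.0:
            raise ParameterError(
                "eta2_gamma too large: the constitutive channel cannot carry "
                "per-channel intrinsic noise exceeding eta2_G"
            )
        # the requested rho must be feasible for lognormal capacities
        _copula_corr(self.eta2_L, self.eta2_G, self.rho)

    # -- model functionals ------------------------------------------------

    def mean_capacity(self, dose_nM: float) -> float:
        """Mean pathway capacity Lbar(d): Hill curve between basal and max."""
        if dose_nM < 0:
            raise ParameterError("dose_nM must be >= 0")
        if dose_nM == 0:
            return self.L_basal
        d_h = dose_nM**self.hill_h
        frac = d_h / (self.EC50**self.hill_h + d_h)
        return self.L_basal + (self.Lbar_max - self.L_basal) * frac

    def expected_eta2_lambda(self, dose_nM: float) -> float:
        """Target contribution of lambda to pathway variability at a dose."""
        lbar = self.mean_capacity(dose_nM)
        if lbar == 0.0:
            return 0.0
        if self.lambda_mode == "relative":
            return self.eta2_lambda
        return self.eta2_lambda * (self.Lbar_max / lbar) ** 2

    def expected_eta2_P(self, dose_nM: float) -> float:
        """Ground-truth pathway variability eta2(L) + eta2(lambda) at a dose."""
        return self.eta2_L + self.expected_eta2_lambda(dose_nM)

    def noise_internals(self, dose_nM: float) -> NoiseInternals:
        """Solve the internal noise variances for the eta2 targets at a dose.

        See the module docstring: at rho = 0 the estimators then recover
        eta2_P, eta2_G and eta2_gamma exactly in expectation.
        """
        target_p = self.expected_eta2_P(dose_nM)
        target_g = self.eta2_G
        target_gamma = self.eta2_gamma

        # a (1 + target_g) - a * target_gamma / (1 + a) = target_p
        a = target_p
        for _ in range(50):
            denom = 1.0 + target_g - target_gamma / (1.0 + a)
            a_new = target_p / denom
            if abs(a_new - a) < 1e-15:
                a = a_new
                break
            a = a_new
        q = target_gamma / (2.0 * (1.0 + a))
        v_g = target_g - q
        if v_g < 0:
            raise ParameterError(
                "eta2_gamma incompatible with eta2_G at this dose"
            )
        scale = a / target_p if target_p > 0 else 1.0
        v_l = self.eta2_L * scale
        lam_var = self.expected_eta2_lambda(dose_nM) * scale
        lbar = self.mean_capacity(dose_nM)
        lam_sd = math.sqrt(lam_var) * lbar if lbar > 0 else 0.0
        gamma_sd = math.sqrt(q) * self.Gbar
        return NoiseInternals(v_L=v_l, lam_sd=lam_sd, v_G=v_g, gamma_sd=gamma_sd, a=a)

    def copula_corr(self, internals: NoiseInternals) -> float:
        """Gaussian correlation giving exactly rho between capacity multipliers."""
        return _copula_corr(internals.v_L, internals.v_G, self.rho)

    def check_truncation(self, dose_nM: float) -> None:
        """Reject parameters whose additive-noise clipping would bias output.

        Capacities are clipped at zero after adding lambda/gamma; the
        clipped probability mass must stay below 1e-4 (computed by
        Gauss-Hermite quadrature over the lognormal capacity multiplier).
        """
        internals = self.noise_internals(dose_nM)
        checks = (
            ("eta2_lambda", self.mean_capacity(dose_nM), internals.v_L, internals.lam_sd),
            ("eta2_gamma", self.Gbar, internals.v_G, internals.gamma_sd),
        )
        for label, mean, mult_var, sd in checks:
            if sd == 0.0:
                continue
            if mean == 0.0:
                raise ParameterError(f"{label}: additive noise with zero mean capacity")
            mass = _clip_mass(mean, mult_var, sd)
            if mass >= self._MAX_TRUNCATION_MASS:
                raise ParameterError(
                    f"{label}: truncation mass {mass:.2e} >= 1e-4 at dose "
                    f"{dose_nM} nM; reduce the noise or raise the capacity"
                )

    def replace(self, **changes) -> "SimulationParams":
        from dataclasses import replace as _replace

        return _replace(self, **changes)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _copula_corr(v_l: float, v_g: float, rho: float) -> float:
    """Gaussian correlation for a mean-1 bivariate lognormal with raw corr rho.

    Inverts corr(l, g) = (exp(r_z*sL*sG) - 1)/sqrt((exp(sL^2)-1)(exp(sG^2)-1))
    exactly.
    """
    if v_l == 0 or v_g == 0 or rho == 0:
        return 0.0
    s_l = math.sqrt(math.log1p(v_l))
    s_g = math.sqrt(math.log1p(v_g))
    arg = 1.0 + rho * math.sqrt(v_l * v_g)
    if arg <= 0:
        raise ParameterError("rho too negative for lognormal capacities")
    r_z = math.log(arg) / (s_l * s_g)
    if not -1.0 <= r_z <= 1.0:
        raise ParameterError("rho not attainable for these eta2_L, eta2_G")
    return r_z


def _clip_mass(mean: float, mult_var: float, sd: float) -> float:
    """P(mean * lognormal + Normal(0, sd) < 0) by Gauss-Hermite quadrature."""
    from scipy.stats import norm

    if mult_var == 0.0:
        return float(norm.cdf(-mean / sd))
    s = math.sqrt(math.log1p(mult_var))
    nodes, weights = np.polynomial.hermite_e.hermegauss(40)
    mult = np.exp(s * nodes - 0.5 * s * s)
    probs = norm.cdf(-mean * mult / sd)
    return float(np.sum(weights * probs) / math.sqrt(2.0 * math.pi))
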