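"""Closed-form precision of the treatment-effect estimator under covariate
dichotomization.

For a two-arm 1:1 randomized trial analysed with the linear model

    y = alpha + gamma*z + beta*x + eps,   eps ~ N(0, sigma_eps),

with x a skew-normal baseline covariate, three analyses are compared:

* the *full* model (x entered raw),
* the *restricted* model (x omitted),
* the *partially restricted* model (x dichotomized at its tau-th percentile,
  the two levels coded as the conditional means below/above the threshold —
  or any affine recoding, e.g. a 0/1 indicator, which leaves the fit of a
  single regressor unchanged).

The sampling variances of gamma-hat under the three models have closed
forms, and the *dichotomization efficiency*

    D = [V(restricted) - V(partial)] / [V(restricted) - V(full)]

— the fraction of the full-adjustment precision gain retained after
dichotomizing — depends only on the shape parameter lambda and the
dichotomization percentile tau.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .skewnormal import (
    SNParams,
    TruncationBounds,
    sn_pdf,
    sn_quantile,
    sn_variance,
    truncated_mean,
)

__all__ = [
    "TrialDesign",
    "DichotomizationSpec",
    "EfficiencyResult",
    "var_gamma_full",
    "var_gamma_restricted",
    "var_xd",
    "var_gamma_partial",
    "variance_reductions",
    "dichotomization_efficiency",
    "dichotomization_efficiency_from_params",
    "efficiency_curve",
    "efficiency_result",
    "dichotomization_spec",
]

# tau*(1-tau) appears in denominators; refuse numerically hopeless percentiles.
TAU_MIN = 1e-6
TAU_MAX = 1.0 - 1e-6


@dataclass(frozen=True)
class TrialDesign:
    """Design of a two-arm 1:1 randomized trial with a linear outcome model.

    ``n_total`` participants are split n/2 per arm; ``gamma`` is the
    treatment effect, ``beta`` the covariate slope, ``sigma_eps`` the
    residual SD and ``intercept`` the model intercept (all in outcome units,
    beta per covariate unit).
    """

    n_total: int
    gamma: float
    beta: float
    sigma_eps: float
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.n_total < 4 or self.n_total % 2 != 0:
            raise ValueError(
                f"n_total must be even and >= 4 for 1:1 allocation, got {self.n_total}"
            )
        if not self.sigma_eps > 0:
            raise ValueError(f"sigma_eps must be > 0, got {self.sigma_eps}")


@dataclass(frozen=True)
class DichotomizationSpec:
    """A dichotomization threshold and the conditional means it induces."""

    tau: float
    u: float
    u_minus: float
    u_plus: float


@dataclass(frozen=True)
class EfficiencyResult:
    """The three model variances of gamma-hat, the two variance reductions
    relative to the restricted model, and their ratio D."""

    var_full: float
    var_restricted: float
    var_partial: float
    reduction_full: float
    reduction_partial: float
    D: float


def _check_tau(tau: float) -> None:
    if not (TAU_MIN <= tau <= TAU_MAX):
        raise ValueError(
            f"dichotomization percentile must lie in [{TAU_MIN}, {TAU_MAX}], got {tau}"
        )


def dichotomization_spec(cov: SNParams, tau: float) -> DichotomizationSpec:
    """Threshold value and below/above conditional means for percentile tau."""
    _check_tau(tau)
    u = float(sn_quantile(tau, cov))
    u_minus = truncated_mean(cov, TruncationBounds(-math.inf, u))
    u_plus = truncated_mean(cov, TruncationBounds(u, math.inf))
    return DichotomizationSpec(tau=tau, u=u, u_minus=u_minus, u_plus=u_plus)


def var_gamma_full(design: TrialDesign) -> float:
    """V(gamma-hat) with the raw covariate in the model: 4*sigma_eps^2 / n."""
    return 4.0 * design.sigma_eps**2 / design.n_total


def var_gamma_restricted(design: TrialDesign, cov: SNParams) -> float:
    """V(gamma-hat) with the covariate omitted: its variance moves into the
    residual, giving 4*(sigma_eps^2 + beta^2 * V[x]) / n."""
    return 4.0 * (design.sigma_eps**2 + design.beta**2 * sn_variance(cov)) / design.n_total


def var_xd(cov: SNParams, tau: float) -> float:
    """Variance of the dichotomized covariate x_d.

    With u the tau-quantile and the two levels set to the conditional means,
    x_d is a two-point random variable and

        V(x_d) = (omega^2 / (tau*(1-tau)))
                 * (f(F^-1(tau)) + delta*sqrt(2/pi) * (tau - Phi(F^-1(tau)*sqrt(1+lambda^2))))^2

    in standardized units (f, F the standard skew-normal pdf/cdf).
    Always 0 < V(x_d) <= V(x); the gap V(x) - V(x_d) is the within-group
    variance lost to dichotomization.
    """
    _check_tau(tau)
    std = SNParams(0.0, 1.0, cov.shape)
    z_u = float(sn_quantile(tau, std))
    lam = cov.shape
    s = math.sqrt(1.0 + lam * lam)
    skew_term = cov.delta * math.sqrt(2.0 / math.pi)
    core = float(sn_pdf(z_u, std)) + skew_term * (tau - float(ndtr(z_u * s)))
    return cov.scale**2 * core * core / (tau * (1.0 - tau))


def var_gamma_partial(design: TrialDesign, cov: SNParams, tau: float) -> float:
    """V(gamma-hat) with the dichotomized covariate: the residual variance of
    x around x_d moves into the error term, giving
    4*(sigma_eps^2 + beta^2*(V[x] - V[x_d])) / n."""
    resid_var = sn_variance(cov) - var_xd(cov, tau)
    return 4.0 * (design.sigma_eps**2 + design.beta**2 * resid_var) / design.n_total


def variance_reductions(
    design: TrialDesign, cov: SNParams, tau: float
) -> tuple[float, float]:
    """Precision gains over the restricted model.

    Returns ``(reduction_full, reduction_partial)``: the drop in V(gamma-hat)
    achieved by full adjustment (4*beta^2*V[x]/n) and by adjustment with the
    dichotomized covariate (4*beta^2*V[x_d]/n).
    """
    scale = 4.0 * design.beta**2 / design.n_total
    return scale * sn_variance(cov), scale * var_xd(cov, tau)


def dichotomization_efficiency(lambda_: float, tau: float) -> float:
    """Dichotomization efficiency D(lambda, tau) in (0, 1).

    The fraction of the variance reduction from full covariate adjustment
    that is retained when the covariate is dichotomized at its tau-th
    percentile; invariant to location and scale, so a function of the shape
    parameter and tau alone:

        D = V(x_d) / V(x)   for the standard distribution.
    """
    std = SNParams(0.0, 1.0, lambda_)
    return var_xd(std, tau) / sn_variance(std)


def dichotomization_efficiency_from_params(cov: SNParams, tau: float) -> float:
    """Convenience wrapper taking full parameters; location and scale cancel
    exactly, so only the shape is used."""
    return dichotomization_efficiency(cov.shape, tau)


def efficiency_curve(lambda_: float, tau_grid) -> list[tuple[float, float]]:
    """Evaluate D along an increasing grid of percentiles; returns (tau, D) pairs."""
    grid = np.asarray(tau_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("tau grid must be a non-empty 1-D sequence")
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("tau grid values must lie strictly inside (0, 1)")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("tau grid must be strictly increasing")
    return [(float(t), dichotomization_efficiency(lambda_, float(t))) for t in grid]


def efficiency_result(design: TrialDesign, cov: SNParams, tau: float) -> EfficiencyResult:
    """Assemble the three variances, the two reductions and D in one record."""
    v_f = var_gamma_full(design)
    v_r = var_gamma_restricted(design, cov)
    v_p = var_gamma_partial(design, cov, tau)
    red_full, red_partial = variance_reductions(design, cov, tau)
    return EfficiencyResult(
        var_full=v_f,
        var_restricted=v_r,
        var_partial=v_p,
        reduction_full=red_full,
        reduction_partial=red_partial,
        D=dichotomization_efficiency(cov.shape, tau),
    )
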