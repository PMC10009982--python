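"""Optimal dichotomization percentile and the acceptable cut-point range.

For each shape parameter, a grid search over percentiles tau finds the
cut-point maximizing the dichotomization efficiency D, plus the smallest
and largest percentiles keeping D strictly above a threshold (default 0.6,
i.e. retaining at least 60% of the full-adjustment precision gain).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .efficiency import dichotomization_efficiency

__all__ = [
    "CutpointReport",
    "optimal_cutpoint",
    "acceptable_range",
    "cutpoint_table",
    "cutpoint_frame",
    "DEFAULT_SHAPES",
]

DEFAULT_SHAPES = (0.0, 2.0, 5.0, 10.0, 20.0)
_TIE_TOL = 1e-12


@dataclass(frozen=True)
class CutpointReport:
    """Grid-search result for one shape parameter.

    ``optimal_tau`` maximizes D; ``tau_min``/``tau_max`` bound the percentile
    range keeping D strictly above ``threshold`` (both None when no grid
    point qualifies).
    """

    shape: float
    optimal_tau: float
    tau_min: float | None
    tau_max: float | None
    threshold: float
    resolution: float


def _tau_grid(resolution: float) -> np.ndarray:
    if not (0.0 < resolution <= 0.1):
        raise ValueError(f"resolution must lie in (0, 0.1], got {resolution}")
    n = int(round(1.0 / resolution)) - 1
    # build from integer multiples to dodge float accumulation
    grid = np.arange(1, n + 1) * resolution
    return grid[(grid > 0.0) & (grid < 1.0)]


def optimal_cutpoint(lambda_: float, resolution: float = 0.01, refine: bool = False) -> float:
    """Percentile maximizing D for the given shape, on a tau grid of the given step.

    Ties within numerical noise resolve to the grid point closest to the
    median.  The result is rounded to the grid's decimal precision.  With
    ``refine=True`` a golden-section polish around the grid argmax is
    returned instead (unrounded).
    """
    grid = _tau_grid(resolution)
    vals = np.array([dichotomization_efficiency(lambda_, t) for t in grid])
    best = vals.max()
    tied = grid[vals >= best - _TIE_TOL]
    opt = float(tied[np.argmin(np.abs(tied - 0.5))])
    if refine:
        lo = max(opt - resolution, 1e-6)
        hi = min(opt + resolution, 1.0 - 1e-6)
        res = optimize.minimize_scalar(
            lambda t: -dichotomization_efficiency(lambda_, t),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        return float(res.x)
    decimals = max(0, int(round(-np.log10(resolution))))
    return round(opt, decimals)


def acceptable_range(
    lambda_: float, threshold: float = 0.6, resolution: float = 0.01
) -> tuple[float | None, float | None]:
    """Smallest and largest grid percentiles with D strictly above ``threshold``.

    Returns ``(None, None)`` when no grid point qualifies (e.g. a threshold
    above the achievable maximum of D).
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    grid = _tau_grid(resolution)
    vals = np.array([dichotomization_efficiency(lambda_, t) for t in grid])
    ok = grid[vals > threshold]
    if ok.size == 0:
        return None, None
    decimals = max(0, int(round(-np.log10(resolution))))
    return round(float(ok.min()), decimals), round(float(ok.max()), decimals)


def cutpoint_table(
    shapes=DEFAULT_SHAPES, threshold: float = 0.6, resolution: float = 0.01
) -> list[CutpointReport]:
    """One :class:`CutpointReport` per shape parameter."""
    shapes = list(shapes)
    if not shapes:
        raise ValueError("shape list must be non-empty")
    reports = []
    for lam in shapes:
        opt = optimal_cutpoint(lam, resolution)
        lo, hi = acceptable_range(lam, threshold, resolution)
        reports.append(
            CutpointReport(
                shape=float(lam),
                optimal_tau=opt,
                tau_min=lo,
                tau_max=hi,
                threshold=threshold,
                resolution=resolution,
            )
        )
    return reports


def cutpoint_frame(reports: list[CutpointReport]) -> pd.DataFrame:
    """Tabular view with columns shape, optimal, minimum, maximum."""
    return pd.DataFrame(
        {
            "shape": [r.shape for r in reports],
            "optimal": [r.optimal_tau for r in reports],
            "minimum": [r.tau_min for r in reports],
            "maximum": [r.tau_max for r in reports],
        }
    )
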