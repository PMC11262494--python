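"""One-way weight sensitivity (tornado) and temporal benefit-risk.

The tornado analysis moves one nonfatal endpoint's weight at a time to
``mean ± 2 SD`` (clamped to [0, 1]) while holding every other weight at
its mean, and records the resulting MCDA score difference. Because the
value model is linear, the bar half-width before clamping is exactly
``2 · SD · |Δr|``, so wide bars flag the weights the conclusion is
sensitive to. The fatal endpoint is excluded — its weight is 1 by
definition.

The temporal analysis evaluates the weighted score on a Kaplan-Meier
grid: at each grid time ``t``

    ΔS(t) = Σ_i w_i · (F_active,i(t) − F_control,i(t)) · 10 000,

where ``F`` is cumulative incidence — utility death equivalents per
10 000 *patients* by time ``t`` (a per-population quantity, distinct from
the per-10 000-patient-year rate scale of the main score). Uncertainty
bands come from Monte Carlo over Gaussian (Greenwood-variance)
perturbations of each cumulative incidence, clipped to [0, 1], combined
with the weight distributions; normal-theory bands are available as a
cheaper alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .config import ConfigError, ValueTree, WeightSpec
from .mcda import mcda_score_difference, weight_from_utility
from .montecarlo import sample_weights
from .rates import KMCurve, RateDifference

__all__ = ["OneWayResult", "TemporalBR", "one_way_sensitivity",
           "temporal_mcda", "default_grid_days"]


@dataclass(frozen=True)
class OneWayResult:
    """Score difference with one endpoint's weight at mean ± 2 SD.

    ``delta_s_low`` / ``delta_s_high`` correspond to the weight at
    ``mean − 2 SD`` / ``mean + 2 SD`` (each clamped to [0, 1]); ``base``
    is the all-means score difference.
    """

    endpoint: str
    base: float
    delta_s_low: float
    delta_s_high: float
    weight_low: float
    weight_high: float

    @property
    def bar_width(self) -> float:
        return abs(self.delta_s_high - self.delta_s_low)


@dataclass(frozen=True)
class TemporalBR:
    """Weighted benefit-risk trajectory on a KM time grid."""

    grid_days: np.ndarray
    delta_s: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    method: str
    units: str = "utility death equivalents per 10 000 patients"


def default_grid_days(start: int = 90, step: int = 91,
                      end: int = 1100) -> np.ndarray:
    """Quarterly evaluation grid, ~day 90 to ~day 1100."""
    return np.arange(start, end + 1, step)


def one_way_sensitivity(
    rate_differences: Mapping[str, RateDifference],
    weights: Mapping[str, WeightSpec],
    tree: ValueTree,
    model: int = 1,
) -> list[OneWayResult]:
    """Tornado results for every nonfatal endpoint of the model."""
    base = mcda_score_difference(rate_differences, weights, tree, model)
    out = []
    for ep in tree.model_endpoints(model):
        if ep.fatal:
            continue  # fatal weight is fixed at 1; only nonfatal weights vary
        spec = weights[ep.name]
        m = weight_from_utility(spec)
        w_lo = float(np.clip(m - 2 * spec.utility_sd, 0.0, 1.0))
        w_hi = float(np.clip(m + 2 * spec.utility_sd, 0.0, 1.0))
        dr = rate_differences[ep.name].delta
        out.append(OneWayResult(
            endpoint=ep.name,
            base=base.score_difference,
            delta_s_low=base.score_difference + (w_lo - m) * dr,
            delta_s_high=base.score_difference + (w_hi - m) * dr,
            weight_low=w_lo,
            weight_high=w_hi,
        ))
    return out


def temporal_mcda(
    curves: Mapping[str, Mapping[str, KMCurve]],
    weights: Mapping[str, WeightSpec],
    grid_days: np.ndarray | None = None,
    n_draws: int = 10_000,
    seed: int = 0,
    method: str = "monte-carlo",
) -> TemporalBR:
    """Weighted cumulative-incidence score difference over time.

    ``curves`` maps each endpoint to ``{"active": KMCurve, "control":
    KMCurve}`` from the same scope. Grid times beyond both arms' last
    observed time are dropped with a warning. ``method`` is
    ``"monte-carlo"`` (Greenwood-Gaussian perturbations plus weight
    draws) or ``"normal"`` (delta-method bands at mean weights).
    """
    if method not in ("monte-carlo", "normal"):
        raise ConfigError(f"unknown temporal CI method {method!r}")
    grid = np.asarray(default_grid_days() if grid_days is None else grid_days,
                      dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ConfigError("grid_days must be strictly increasing")

    names = list(curves)
    last_obs = max(
        max(float(c["active"].durations.max()), float(c["control"].durations.max()))
        for c in curves.values()
    )
    if grid.size and grid[-1] > last_obs:
        warnings.warn(
            f"temporal grid truncated at last observed time {last_obs:.0f} days",
            stacklevel=2,
        )
        grid = grid[grid <= last_obs]

    k = len(names)
    w_mean = np.array([weight_from_utility(weights[n]) for n in names])
    f_a = np.stack([curves[n]["active"].cuminc_at(grid) for n in names])   # (k, T)
    f_c = np.stack([curves[n]["control"].cuminc_at(grid) for n in names])
    se_a = np.stack([curves[n]["active"].se_at(grid) for n in names])
    se_c = np.stack([curves[n]["control"].se_at(grid) for n in names])

    point = 1e4 * (w_mean @ (f_a - f_c))

    if method == "normal":
        var = (w_mean[:, None] ** 2 * (se_a ** 2 + se_c ** 2)).sum(axis=0)
        half = 1.959963984540054 * 1e4 * np.sqrt(var)
        lo, hi = point - half, point + half
    else:
        rng = np.random.default_rng(seed)
        w_draws = np.stack([sample_weights(weights[n], n_draws, rng)
                            for n in names])                     # (k, R)
        za = rng.standard_normal((k, n_draws, grid.size))
        zc = rng.standard_normal((k, n_draws, grid.size))
        fa = np.clip(f_a[:, None, :] + za * se_a[:, None, :], 0.0, 1.0)
        fc = np.clip(f_c[:, None, :] + zc * se_c[:, None, :], 0.0, 1.0)
        ds = 1e4 * np.einsum("kr,krt->rt", w_draws, fa - fc)
        lo, hi = np.percentile(ds, [2.5, 97.5], axis=0)

    return TemporalBR(grid_days=grid, delta_s=point, ci_lo=np.asarray(lo),
                      ci_hi=np.asarray(hi), method=method)
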