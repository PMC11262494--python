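"""Deterministic utility-weighted MCDA scoring layer.

The score is a linear additive value model over the value-tree endpoints,
with no range normalization: each endpoint contributes its incidence-rate
difference (active − control, per 10 000 patient-years) multiplied by its
weight ``w = 1 − utility``. Because the fatal endpoint carries weight
exactly 1, the score difference

    ΔS = Σ_i w_i · Δr_i

is expressed in *utility death equivalents per 10 000 patient-years*: the
utility-equivalent number of extra (positive) or fewer (negative) deaths
under the active treatment. Negative values mean benefits outweigh risks
in favour of the active arm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .config import ConfigError, EndpointSpec, ValueTree, WeightSpec
from .rates import RateDifference

__all__ = ["SCORE_UNITS", "MCDAResult", "weight_from_utility",
           "contribution", "mcda_score_difference"]

SCORE_UNITS = "utility death equivalents per 10 000 patient-years"


@dataclass(frozen=True)
class MCDAResult:
    """Deterministic MCDA score difference and its per-endpoint makeup.

    ``score_difference == sum(contributions.values())`` exactly, and
    equals ``score_active - score_control`` when per-arm rates were
    available (aggregate inputs built from printed differences only leave
    the per-arm scores as ``None``).
    """

    model: int
    contributions: dict[str, float]
    score_difference: float
    score_active: float | None
    score_control: float | None
    units: str = SCORE_UNITS


def weight_from_utility(spec: WeightSpec) -> float:
    """MCDA weight: ``1 - utility_mean`` (death -> 1, perfect health -> 0)."""
    return spec.weight_mean


def contribution(rd: RateDifference, w: float) -> float:
    """Endpoint contribution ``w * delta`` in utility death equivalents per 10 000 PY."""
    if not 0.0 <= w <= 1.0:
        raise ConfigError(f"weight must lie in [0, 1], got {w}")
    return w * rd.delta


def mcda_score_difference(
    rate_differences: Mapping[str, RateDifference],
    weights: Mapping[str, WeightSpec],
    tree: ValueTree | Sequence[EndpointSpec] | None = None,
    model: int = 1,
) -> MCDAResult:
    """Weighted between-arm score difference over one model's endpoints.

    Every model endpoint must have exactly one rate difference and one
    weight; a missing endpoint raises :class:`ConfigError`. When ``tree``
    is None the endpoint set is taken from the rate differences directly.
    """
    if tree is None:
        names = list(rate_differences)
    else:
        endpoints = tree.model_endpoints(model) if isinstance(tree, ValueTree) \
            else tuple(tree)
        names = [e.name for e in endpoints]

    missing = [n for n in names if n not in rate_differences]
    if missing:
        raise ConfigError(f"model {model}: missing rate differences for {missing}")
    missing_w = [n for n in names if n not in weights]
    if missing_w:
        raise ConfigError(f"model {model}: missing weights for {missing_w}")

    contribs: dict[str, float] = {}
    score_a = 0.0
    score_c = 0.0
    have_arm_rates = True
    for n in names:
        rd = rate_differences[n]
        w = weight_from_utility(weights[n])
        contribs[n] = contribution(rd, w)
        if rd.rate_active is None or rd.rate_control is None:
            have_arm_rates = False
        else:
            score_a += w * rd.rate_active
            score_c += w * rd.rate_control

    return MCDAResult(
        model=model,
        contributions=contribs,
        score_difference=sum(contribs.values()),
        score_active=score_a if have_arm_rates else None,
        score_control=score_c if have_arm_rates else None,
    )
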