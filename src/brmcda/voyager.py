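"""Published intention-to-treat summary inputs for the VOYAGER PAD analysis.

VOYAGER PAD randomized 6564 patients with symptomatic peripheral artery
disease after lower-extremity revascularization 1:1 to rivaroxaban 2.5 mg
twice daily plus aspirin (n=3286) or aspirin alone (n=3278), with a median
follow-up of about 31 months. The published model-1 ITT table reports, for
each value-tree endpoint, per-arm first-event incidence rates per 10 000
patient-years, the Wald rate difference with 95% CI, and the mean MCDA
weight (1 − health-state utility). Those printed numbers are the inputs to
the aggregate analysis path; they are data, not results computed here.
"""

from __future__ import annotations

import pandas as pd

from .config import DEFAULT_UTILITY_SD, WeightSpec
from .rates import RateDifference

__all__ = [
    "itt_model1_table",
    "itt_rate_differences",
    "itt_weight_specs",
    "PUBLISHED_SCORE_DIFFERENCE_ITT",
    "PUBLISHED_P_BENEFIT_ITT",
]

# Published ITT model-1 MCDA summary (Monte Carlo, 5e6 runs):
# score difference -13.7 (95% CI -85.3 to 52.6) utility death equivalents
# per 10 000 patient-years; probability benefits outweigh risks 64.4%.
PUBLISHED_SCORE_DIFFERENCE_ITT = -13.7
PUBLISHED_P_BENEFIT_ITT = 64.4

# endpoint, rate_active, rate_control, delta, ci_lo, ci_hi, weight
# Rates and differences per 10 000 patient-years. The printed difference
# is carried verbatim (it can differ from the rate subtraction in the last
# decimal through rounding of the rates, e.g. amputation -21.9 vs -22.0).
_ROWS = [
    ("fatal_composite",          264.2, 227.7,   36.5,  -12.1,  85.1, 1.00),
    ("nonfatal_amputation",      120.5, 142.5,  -21.9,  -57.9,  14.1, 0.59),
    ("nonfatal_ich_bleeding",     22.7,  20.2,    2.5,  -11.9,  17.0, 0.42),
    ("nonfatal_ali",             191.0, 291.3, -100.3, -149.6, -51.0, 0.36),
    ("nonfatal_stroke",           76.3,  90.4,  -14.1,  -42.6,  14.5, 0.35),
    ("nonfatal_mi",              141.0, 154.3,  -13.3,  -51.5,  24.8, 0.22),
    ("nonfatal_nonich_bleeding",  77.6,  51.9,   25.7,    0.5,  50.8, 0.22),
]


def itt_model1_table() -> pd.DataFrame:
    """The published model-1 ITT endpoint table as a DataFrame."""
    return pd.DataFrame(
        _ROWS,
        columns=["endpoint", "rate_active", "rate_control", "delta",
                 "ci_lo", "ci_hi", "weight"],
    )


def itt_rate_differences() -> dict[str, RateDifference]:
    """Printed ITT rate differences as :class:`RateDifference` objects.

    The SE is recovered from the printed 95% CI as width / 3.92.
    """
    return {
        name: RateDifference.from_point_and_ci(
            name, delta, lo, hi, rate_active=ra, rate_control=rc
        )
        for name, ra, rc, delta, lo, hi, _w in _ROWS
    }


def itt_weight_specs(utility_sd: float = DEFAULT_UTILITY_SD) -> dict[str, WeightSpec]:
    """Weight specs at the published mean weights.

    The published table reports mean weights only; ``utility_sd`` supplies
    the dispersion used for Monte Carlo weight uncertainty (0 for the
    fatal composite, whose utility is 0 by definition).
    """
    out = {}
    for name, *_rest, w in _ROWS:
        if w == 1.0:
            out[name] = WeightSpec(name, 0.0, 0.0, "fixed")
        else:
            out[name] = WeightSpec(name, round(1.0 - w, 10), utility_sd, "beta")
    return out
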