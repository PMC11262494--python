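"""Exposure-adjusted incidence rates, rate differences and Kaplan-Meier curves.

Benefits and risks are compared on the scale of first-event incidence
rates per 10 000 patient-years. For a treatment arm with ``d`` first
events over ``PY`` patient-years at risk the rate is ``10 000 * d / PY``;
the between-arm contrast is the rate difference with a Wald (normal
approximation) 95% CI using the Poisson variance ``d / PY**2`` per arm.
A rate difference can be read as the excess number of patients with the
event in a hypothetical population of 10 000 patient-years.

Kaplan-Meier machinery (product-limit cumulative incidence, Greenwood
standard errors, between-arm difference curves with a Pocock-style
at-risk restriction) supports the temporal benefit-risk analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DAYS_PER_YEAR",
    "ArmEndpointSummary",
    "RateDifference",
    "KMCurve",
    "summarize_endpoint",
    "rate_difference",
    "nnt",
    "km_curve",
    "km_difference_curve",
]

DAYS_PER_YEAR = 365.25
Z95 = 1.959963984540054  # two-sided 95% normal quantile
RATE_SCALE = 10_000.0


@dataclass(frozen=True)
class ArmEndpointSummary:
    """First-event count and exposure for one endpoint in one arm."""

    endpoint: str
    arm: str
    events: int
    patient_years: float

    def __post_init__(self) -> None:
        if self.patient_years <= 0:
            raise ValueError(
                f"{self.endpoint}/{self.arm}: patient_years must be > 0"
            )
        if self.events < 0:
            raise ValueError(f"{self.endpoint}/{self.arm}: events must be >= 0")

    @property
    def rate(self) -> float:
        """Incidence rate per 10 000 patient-years."""
        return RATE_SCALE * self.events / self.patient_years


@dataclass(frozen=True)
class RateDifference:
    """Active-minus-control incidence-rate difference per 10 000 PY.

    ``se`` and the 95% bounds are on the same scale. ``rate_active`` /
    ``rate_control`` are carried when the difference was built from
    per-arm summaries (they are None on the aggregate path when only a
    printed difference and CI are available).
    """

    endpoint: str
    delta: float
    se: float
    ci_lo: float
    ci_hi: float
    rate_active: float | None = None
    rate_control: float | None = None

    @classmethod
    def from_summaries(cls, active: ArmEndpointSummary,
                       control: ArmEndpointSummary) -> "RateDifference":
        return rate_difference(active, control)

    @classmethod
    def from_point_and_ci(cls, endpoint: str, delta: float,
                          ci_lo: float, ci_hi: float,
                          rate_active: float | None = None,
                          rate_control: float | None = None) -> "RateDifference":
        """Build from a printed point estimate and 95% CI (SE = width / 3.92)."""
        if not ci_lo <= delta <= ci_hi:
            raise ValueError(f"{endpoint}: delta must lie inside its CI")
        se = (ci_hi - ci_lo) / (2 * Z95)
        return cls(endpoint, delta, se, ci_lo, ci_hi, rate_active, rate_control)


def summarize_endpoint(first_events: pd.DataFrame, at_risk: pd.DataFrame,
                       endpoint: str) -> dict[str, ArmEndpointSummary]:
    """Per-arm first-event count and patient-years for one endpoint.

    Parameters
    ----------
    first_events
        Output of :func:`brmcda.scoping.first_events` — columns
        ``patient_id``, ``endpoint``, ``time_days``.
    at_risk
        Per-patient censoring table from :func:`brmcda.scoping.apply_scope`
        — columns ``patient_id``, ``arm``, ``censor_days``.
    endpoint
        Endpoint name to summarise.

    Each patient contributes ``min(first event time, censoring time)`` to
    the time at risk (converted at 365.25 days/year) and one event if the
    first event occurred at or before censoring.
    """
    ev = first_events.loc[first_events["endpoint"] == endpoint,
                          ["patient_id", "time_days"]]
    merged = at_risk.merge(ev, on="patient_id", how="left")
    has_event = merged["time_days"].notna() & (
        merged["time_days"] <= merged["censor_days"]
    )
    risk_days = np.where(has_event, merged["time_days"], merged["censor_days"])
    out = {}
    for arm, grp in merged.assign(_risk=risk_days, _event=has_event).groupby("arm"):
        out[arm] = ArmEndpointSummary(
            endpoint=endpoint,
            arm=str(arm),
            events=int(grp["_event"].sum()),
            patient_years=float(grp["_risk"].sum() / DAYS_PER_YEAR),
        )
    return out


def rate_difference(active: ArmEndpointSummary,
                    control: ArmEndpointSummary) -> RateDifference:
    """Wald rate difference (active − control) per 10 000 patient-years.

    The variance of each arm's rate is Poisson, ``d / PY**2``, so
    ``se = 10 000 * sqrt(d_a/PY_a^2 + d_c/PY_c^2)`` and the 95% CI is
    ``delta ± 1.96 se``.
    """
    if active.endpoint != control.endpoint:
        raise ValueError(
            f"endpoint mismatch: {active.endpoint!r} vs {control.endpoint!r}"
        )
    delta = active.rate - control.rate
    var = (active.events / active.patient_years**2
           + control.events / control.patient_years**2)
    se = RATE_SCALE * math.sqrt(var)
    return RateDifference(
        endpoint=active.endpoint,
        delta=delta,
        se=se,
        ci_lo=delta - Z95 * se,
        ci_hi=delta + Z95 * se,
        rate_active=active.rate,
        rate_control=control.rate,
    )


def nnt(rd: RateDifference) -> float:
    """Number needed to treat (or harm), in patient-years per event.

    ``10 000 / |delta|`` patient-years of exposure per one event prevented
    (negative delta) or caused (positive delta). A zero difference yields
    ``inf`` — flagged, not raised, since an exactly null contrast is a
    legitimate display case.
    """
    if rd.delta == 0:
        return math.inf
    return RATE_SCALE / abs(rd.delta)


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier cumulative incidence with Greenwood standard errors.

    ``times`` are the distinct observed event times (days), ``cuminc`` the
    product-limit cumulative incidence just after each, ``se`` its
    Greenwood standard error and ``at_risk`` the number at risk just
    before each event time. ``durations`` keeps the raw follow-up times so
    at-risk fractions can be evaluated exactly at arbitrary times.
    """

    times: np.ndarray
    cuminc: np.ndarray
    se: np.ndarray
    at_risk: np.ndarray
    n_total: int
    durations: np.ndarray = field(repr=False, default=None)

    def cuminc_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """Step-function cumulative incidence at time(s) ``t`` (0 before the first event)."""
        idx = np.searchsorted(self.times, np.asarray(t), side="right")
        vals = np.concatenate([[0.0], self.cuminc])
        return vals[idx]

    def se_at(self, t: np.ndarray | float) -> np.ndarray | float:
        idx = np.searchsorted(self.times, np.asarray(t), side="right")
        vals = np.concatenate([[0.0], self.se])
        return vals[idx]

    def at_risk_fraction(self, t: float) -> float:
        """Fraction of the cohort still at risk at time ``t``."""
        if self.durations is None:
            raise ValueError("curve has no stored durations")
        return float(np.count_nonzero(self.durations >= t)) / self.n_total


def km_curve(durations: np.ndarray, event_observed: np.ndarray) -> KMCurve:
    """Product-limit estimator of cumulative incidence under right censoring.

    Ties at the same event day follow the standard simultaneous-death
    convention (all deaths at a time use the common at-risk count).
    """
    durations = np.asarray(durations, dtype=float)
    event_observed = np.asarray(event_observed, dtype=bool)
    if durations.size == 0:
        raise ValueError("empty cohort")
    if np.any(durations < 0):
        raise ValueError("negative durations")
    n = durations.size

    order = np.argsort(durations, kind="stable")
    t_sorted = durations[order]
    e_sorted = event_observed[order]

    event_times = np.unique(t_sorted[e_sorted])
    surv = 1.0
    gw = 0.0  # running Greenwood sum d / (n (n - d))
    cuminc, se, at_risk = [], [], []
    for t in event_times:
        n_at = n - np.searchsorted(t_sorted, t, side="left")
        d = int(np.count_nonzero(e_sorted & (t_sorted == t)))
        surv *= 1.0 - d / n_at
        if n_at > d:
            gw += d / (n_at * (n_at - d))
        else:
            gw = math.inf  # survival hit zero; variance degenerate
        cuminc.append(1.0 - surv)
        se.append(surv * math.sqrt(gw) if math.isfinite(gw) else 0.0)
        at_risk.append(n_at)
    return KMCurve(
        times=event_times,
        cuminc=np.asarray(cuminc),
        se=np.asarray(se),
        at_risk=np.asarray(at_risk, dtype=int),
        n_total=n,
        durations=durations,
    )


def km_difference_curve(active: KMCurve, control: KMCurve,
                        at_risk_floor: float = 0.10) -> pd.DataFrame:
    """Between-arm cumulative-incidence difference over the merged time grid.

    The curve is truncated at the last time at which *both* arms retain at
    least ``at_risk_floor`` of their patients at risk (Pocock's 10%
    restriction by default; 0 disables truncation). Returns a DataFrame
    with columns ``time_days``, ``diff``, ``se`` (SEs combined as
    independent arms).
    """
    if not 0.0 <= at_risk_floor < 1.0:
        raise ValueError("at_risk_floor must lie in [0, 1)")
    grid = np.union1d(active.times, control.times)
    if grid.size == 0:
        return pd.DataFrame({"time_days": [], "diff": [], "se": []})
    if at_risk_floor > 0:
        keep = [t for t in grid
                if active.at_risk_fraction(t) >= at_risk_floor
                and control.at_risk_fraction(t) >= at_risk_floor]
        grid = np.asarray(keep)
    diff = active.cuminc_at(grid) - control.cuminc_at(grid)
    se = np.sqrt(active.se_at(grid) ** 2 + control.se_at(grid) ** 2)
    return pd.DataFrame({"time_days": grid, "diff": diff, "se": se})
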