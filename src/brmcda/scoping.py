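"""Analysis scopes (ITT vs on-treatment) and first-event extraction.

Two population / data-scope definitions are supported:

* **ITT**: every randomized patient, with events counted from
  randomization until the administrative cutoff regardless of treatment
  discontinuation.
* **On-treatment**: patients who received at least one dose, with events
  counted until the last study-drug dose plus a fixed window
  (conventionally 2 days); later events and follow-up are excluded. An
  event exactly at ``last_dose + window`` is included (closed interval).

Death ends observation: a patient's follow-up is truncated for *all*
endpoints at their earliest in-scope fatal event. Nonfatal events do not
censor other endpoints — endpoints are analysed marginally, so one
patient can contribute a first event to several endpoints.

To avoid double-counting deaths, a fatal occurrence is attributed only to
the model's fatal endpoint (the cardiovascular-death/fatal-bleeding
composite in model 1, all-cause death in model 2), never to a nonfatal
endpoint.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ConfigError, EndpointSpec, ScopeConfig, ValueTree

__all__ = ["DataError", "apply_scope", "first_events"]


class DataError(ValueError):
    """Raised when event/patient tables are mutually inconsistent."""


def apply_scope(patients: pd.DataFrame, events: pd.DataFrame,
                scope: ScopeConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply a data scope, returning ``(scoped_events, at_risk)``.

    ``at_risk`` has one row per in-scope patient with columns
    ``patient_id``, ``arm``, ``censor_days``. Events strictly after the
    censoring time are dropped (boundary inclusive). Under the
    on-treatment scope, patients without any dose (``last_dose_days``
    missing) are excluded entirely.
    """
    if not isinstance(scope, ScopeConfig):
        raise ConfigError("scope must be a ScopeConfig")
    known = set(patients["patient_id"])
    orphans = set(events["patient_id"]) - known
    if orphans:
        raise DataError(f"events reference unknown patients: {sorted(orphans)[:5]}")

    pats = patients.copy()
    if scope.name == "itt":
        pats["censor_days"] = pats["followup_end_days"].astype(float)
    else:  # on_treatment
        pats = pats[pats["last_dose_days"].notna()].copy()
        pats["censor_days"] = np.minimum(
            pats["followup_end_days"].astype(float),
            pats["last_dose_days"].astype(float) + scope.window_after_last_dose_days,
        )

    at_risk = pats[["patient_id", "arm", "censor_days"]].reset_index(drop=True)
    ev = events.merge(at_risk[["patient_id", "censor_days"]], on="patient_id")
    ev = ev[ev["time_days"] <= ev["censor_days"]].copy()

    # Death truncates all endpoints: censor at the earliest in-scope fatal
    # event; same-day nonfatal events survive (boundary inclusive).
    fatal_first = (ev[ev["fatal"].astype(bool)]
                   .groupby("patient_id")["time_days"].min()
                   .rename("fatal_days"))
    at_risk = at_risk.merge(fatal_first, on="patient_id", how="left")
    at_risk["censor_days"] = np.fmin(at_risk["censor_days"], at_risk["fatal_days"])
    at_risk = at_risk.drop(columns="fatal_days")
    ev = (ev.drop(columns="censor_days")
            .merge(at_risk[["patient_id", "censor_days"]], on="patient_id"))
    ev = ev[ev["time_days"] <= ev["censor_days"]].drop(columns="censor_days")

    return ev.reset_index(drop=True), at_risk


def first_events(events: pd.DataFrame,
                 tree: ValueTree | None = None,
                 model: int = 1) -> pd.DataFrame:
    """Earliest qualifying event per (patient, endpoint) for one model.

    Fatal occurrences are routed to the model's fatal endpoint: in model 1
    only fatal events of endpoints flagged ``in_fatal_composite`` qualify
    (e.g. a fatal bleeding event becomes a fatal-composite event; a
    non-cardiovascular death is dropped), in model 2 every fatal event
    counts toward all-cause death. Nonfatal events keep their endpoint and
    are kept only if that endpoint belongs to the model.

    Raises :class:`DataError` for an event naming an endpoint absent from
    the value tree.
    """
    tree = tree if tree is not None else _tree_default()
    model_set = {e.name for e in tree.model_endpoints(model)}
    sink = tree.fatal_endpoint(model).name
    spec_by_name = {e.name: e for e in tree}

    unknown = set(events["endpoint"]) - set(tree.names)
    if unknown:
        raise DataError(f"events name endpoints absent from the value tree: {sorted(unknown)}")

    ev = events.copy()
    spec_fatal = ev["endpoint"].map(lambda n: spec_by_name[n].fatal)
    is_fatal = ev["fatal"].astype(bool) | spec_fatal  # fatal endpoints are fatal by definition
    eligible_sink = ev["endpoint"].map(
        lambda n: True if model == 2 else spec_by_name[n].in_fatal_composite
    )

    routed = ev.loc[is_fatal & eligible_sink].assign(endpoint=sink, fatal=True)
    nonfatal = ev.loc[~is_fatal & ev["endpoint"].isin(model_set)].assign(fatal=False)
    combined = pd.concat([routed, nonfatal], ignore_index=True)
    if combined.empty:
        return pd.DataFrame(columns=["patient_id", "endpoint", "time_days", "fatal"])

    firsts = (combined.sort_values(["patient_id", "endpoint", "time_days"],
                                   kind="stable")
                      .groupby(["patient_id", "endpoint"], as_index=False)
                      .first())
    return firsts[["patient_id", "endpoint", "time_days", "fatal"]]


def _tree_default() -> ValueTree:
    from .config import default_value_tree
    return default_value_tree()
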