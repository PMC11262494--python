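"""End-to-end analysis assembly and machine-readable reporting.

``run_pipeline`` executes the full chain on patient-level data — scoping,
per-endpoint rates and Wald differences, deterministic MCDA, Monte Carlo
uncertainty, one-way weight sensitivity and the temporal KM analysis —
and returns an :class:`AnalysisBundle` that serializes losslessly to
JSON. ``run_pipeline_aggregate`` runs the same chain from printed
per-endpoint summaries (rates / CIs), where patient-level stages (KM,
temporal) are unavailable by construction.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .config import ConfigError, ScopeConfig, ValueTree, WeightSpec
from .mcda import MCDAResult, mcda_score_difference
from .montecarlo import MCConfig, MCSummary, run_monte_carlo
from .rates import (KMCurve, RateDifference, km_curve, nnt, rate_difference,
                    summarize_endpoint)
from .scoping import apply_scope, first_events
from .sensitivity import OneWayResult, TemporalBR, one_way_sensitivity, temporal_mcda

__all__ = ["AnalysisBundle", "forest_table", "run_pipeline",
           "run_pipeline_aggregate"]

logger = logging.getLogger("brmcda")


@dataclass(frozen=True)
class AnalysisBundle:
    """Complete result set for one (scope, model) analysis."""

    scope: str
    model: int
    rate_table: pd.DataFrame
    mcda: MCDAResult
    mc: MCSummary
    sensitivity: list[OneWayResult]
    temporal: TemporalBR | None
    provenance: dict

    def to_dict(self) -> dict:
        d = {
            "scope": self.scope,
            "model": self.model,
            "rate_table": self.rate_table.to_dict(orient="records"),
            "mcda": {
                "model": self.mcda.model,
                "contributions": self.mcda.contributions,
                "score_difference": self.mcda.score_difference,
                "score_active": self.mcda.score_active,
                "score_control": self.mcda.score_control,
                "units": self.mcda.units,
            },
            "mc": {
                "mean_delta_s": self.mc.mean_delta_s,
                "ci_lo": self.mc.ci_lo,
                "ci_hi": self.mc.ci_hi,
                "p_benefit": self.mc.p_benefit,
                "mean_contributions": self.mc.mean_contributions,
                "n_runs": self.mc.n_runs,
                "units": self.mc.units,
            },
            "sensitivity": [dataclasses.asdict(r) for r in self.sensitivity],
            "temporal": None,
            "provenance": self.provenance,
        }
        if self.temporal is not None:
            d["temporal"] = {
                "grid_days": self.temporal.grid_days.tolist(),
                "delta_s": self.temporal.delta_s.tolist(),
                "ci_lo": self.temporal.ci_lo.tolist(),
                "ci_hi": self.temporal.ci_hi.tolist(),
                "method": self.temporal.method,
                "units": self.temporal.units,
            }
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def forest_table(rate_differences: Mapping[str, RateDifference],
                 tree: ValueTree, model: int | None = 1) -> pd.DataFrame:
    """Ordered display table of excess events per 10 000 PY with 95% CIs.

    Fatal/irreversible endpoints come first (value-tree grouping), then
    the remaining endpoints in value-tree order; the row order is
    deterministic. ``nnt`` is patient-years of exposure per event
    prevented or caused (infinite for a null difference; a benefit-role
    endpoint with a positive difference is an NNH-style excess, flagged by
    the sign of ``delta``).
    """
    endpoints = tree.model_endpoints(model) if model is not None else tuple(tree)
    ordered = [e for e in endpoints if e.fatal] + [e for e in endpoints if not e.fatal]
    rows = []
    for e in ordered:
        if e.name not in rate_differences:
            continue
        rd = rate_differences[e.name]
        rows.append({
            "endpoint": e.name,
            "role": e.role,
            "fatal": e.fatal,
            "delta": rd.delta,
            "ci_lo": rd.ci_lo,
            "ci_hi": rd.ci_hi,
            "se": rd.se,
            "nnt": nnt(rd),
        })
    if not rows:
        raise ConfigError("no rate differences to tabulate")
    return pd.DataFrame(rows)


def _provenance(seed: int, n_runs: int, scope: str, model: int,
                extra: dict | None = None) -> dict:
    payload = {"scope": scope, "model": model, "seed": seed, "n_runs": n_runs}
    if extra:
        payload.update(extra)
    config_hash = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]
    prov = dict(payload)
    prov["config_hash"] = config_hash
    prov["timestamp"] = datetime.now(timezone.utc).isoformat()
    return prov


def run_pipeline(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    tree: ValueTree,
    weights: Mapping[str, WeightSpec],
    scope: ScopeConfig,
    model: int,
    mc_config: MCConfig,
    grid_days: np.ndarray | None = None,
    include_temporal: bool = True,
) -> AnalysisBundle:
    """Full patient-level analysis for one scope and model."""
    scoped_events, at_risk = apply_scope(patients, events, scope)
    firsts = first_events(scoped_events, tree, model)

    endpoints = tree.model_endpoints(model)
    rds: dict[str, RateDifference] = {}
    summaries = {}
    for e in endpoints:
        per_arm = summarize_endpoint(firsts, at_risk, e.name)
        if set(per_arm) != {"active", "control"}:
            raise ConfigError(f"endpoint {e.name!r}: need both arms, got {sorted(per_arm)}")
        summaries[e.name] = (per_arm["active"], per_arm["control"])
        rds[e.name] = rate_difference(per_arm["active"], per_arm["control"])

    mcda = mcda_score_difference(rds, weights, tree, model)
    mc_inputs = summaries if mc_config.rate_model == "gamma-by-counts" else rds
    mc = run_monte_carlo(mc_inputs, weights, mc_config)
    sens = one_way_sensitivity(rds, weights, tree, model)

    temporal = None
    if include_temporal:
        curves: dict[str, dict[str, KMCurve]] = {}
        merged = at_risk.merge(
            firsts.pivot(index="patient_id", columns="endpoint", values="time_days"),
            on="patient_id", how="left",
        )
        for e in endpoints:
            curves[e.name] = {}
            for arm, grp in merged.groupby("arm"):
                t_event = grp[e.name] if e.name in grp else pd.Series(np.nan, index=grp.index)
                observed = t_event.notna()
                durations = np.where(observed, t_event, grp["censor_days"])
                curves[e.name][str(arm)] = km_curve(durations, observed.to_numpy())
        temporal = temporal_mcda(curves, weights, grid_days, seed=mc_config.seed)

    total_py = float(at_risk["censor_days"].sum() / 365.25)
    prov = _provenance(mc_config.seed, mc_config.n_runs, scope.name, model,
                       {"input": "patient-level", "total_patient_years": total_py,
                        "n_patients": int(len(at_risk))})
    logger.info("pipeline %s/model%d: %d patients, %.1f PY, seed=%d, runs=%d, hash=%s",
                scope.name, model, len(at_risk), total_py,
                mc_config.seed, mc_config.n_runs, prov["config_hash"])

    return AnalysisBundle(
        scope=scope.name, model=model,
        rate_table=forest_table(rds, tree, model),
        mcda=mcda, mc=mc, sensitivity=sens, temporal=temporal, provenance=prov,
    )


def run_pipeline_aggregate(
    rate_differences: Mapping[str, RateDifference],
    weights: Mapping[str, WeightSpec],
    tree: ValueTree,
    model: int,
    mc_config: MCConfig,
    scope_name: str = "itt",
    include_temporal: bool = False,
) -> AnalysisBundle:
    """Aggregate-input analysis from printed rates / rate differences.

    The temporal KM analysis needs patient-level data and raises
    :class:`ConfigError` if requested on this path.
    """
    if include_temporal:
        raise ConfigError(
            "temporal analysis requires patient-level data; "
            "aggregate summaries carry no Kaplan-Meier information"
        )
    if mc_config.rate_model != "normal-by-ci":
        raise ConfigError("aggregate inputs support only rate_model='normal-by-ci'")
    mcda = mcda_score_difference(rate_differences, weights, tree, model)
    model_names = [e.name for e in tree.model_endpoints(model)]
    mc = run_monte_carlo({n: rate_differences[n] for n in model_names},
                         weights, mc_config)
    sens = one_way_sensitivity(rate_differences, weights, tree, model)
    prov = _provenance(mc_config.seed, mc_config.n_runs, scope_name, model,
                       {"input": "aggregate"})
    logger.info("aggregate pipeline %s/model%d: seed=%d, runs=%d, hash=%s",
                scope_name, model, mc_config.seed, mc_config.n_runs,
                prov["config_hash"])
    return AnalysisBundle(
        scope=scope_name, model=model,
        rate_table=forest_table(rate_differences, tree, model),
        mcda=mcda, mc=mc, sensitivity=sens, temporal=None, provenance=prov,
    )
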