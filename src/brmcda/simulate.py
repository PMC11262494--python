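"""Synthetic two-arm trial generator.

Emulates the statistical structure the downstream benefit-risk analysis
assumes: two randomized arms, per-endpoint constant (exponential) hazards,
staggered uniform enrollment with a common administrative cutoff,
exponential permanent study-drug discontinuation, and death ending
observation for every endpoint. Event times are drawn independently
across endpoints within a patient (time-to-first-event per endpoint, no
recurrent events, no covariates).

Defaults are calibrated to the published trial conditions: 3286 vs 3278
patients, per-endpoint hazards equal to the printed ITT rates per 10 000
patient-years, ~14%/year permanent discontinuation and a median follow-up
of about 31 months (1-year uniform enrollment, calendar cutoff 31/12 + 0.5
years after study start).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import ConfigError, ValueTree, default_value_tree
from .rates import DAYS_PER_YEAR

__all__ = ["SimConfig", "simulate_trial", "default_voyager_config",
           "PATIENT_COLUMNS", "EVENT_COLUMNS"]

#: Documented CSV headers for the two output tables.
PATIENT_COLUMNS = ("patient_id", "arm", "followup_end_days", "last_dose_days")
EVENT_COLUMNS = ("patient_id", "endpoint", "time_days", "fatal")

ARMS = ("active", "control")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic trial.

    Parameters
    ----------
    n_per_arm
        Patient counts ``(active, control)``.
    endpoint_hazards
        ``{endpoint: (hazard_active, hazard_control)}`` in events per
        patient-year (a rate of 191 per 10 000 PY is 0.0191/PY).
    fatal_fraction
        Per-endpoint probability that a drawn occurrence is fatal.
        Endpoints absent from the mapping default to 0. Fatal occurrences
        end the patient's follow-up for every endpoint.
    discontinuation_rate
        Exponential rate (per patient-year) of permanent study-drug
        discontinuation; 0 disables discontinuation.
    max_followup_years
        Calendar time from study start to the administrative data cutoff.
    entry_stagger_years
        Length of the uniform enrollment window; a patient entering at
        calendar time ``e`` is censored administratively after
        ``max_followup_years - e`` years.
    seed
        Base RNG seed; per-patient substreams are spawned from it, so
        enlarging the trial does not perturb earlier patients.
    """

    n_per_arm: tuple[int, int]
    endpoint_hazards: dict[str, tuple[float, float]]
    fatal_fraction: dict[str, float] = field(default_factory=dict)
    discontinuation_rate: float = 0.0
    max_followup_years: float = 3.0
    entry_stagger_years: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        n_a, n_c = self.n_per_arm
        if n_a <= 0 or n_c <= 0:
            raise ConfigError("n_per_arm entries must be > 0")
        if not self.endpoint_hazards:
            raise ConfigError("endpoint_hazards must not be empty")
        for ep, hz in self.endpoint_hazards.items():
            if len(hz) != 2 or any(h < 0 for h in hz):
                raise ConfigError(f"endpoint {ep!r}: hazards must be two values >= 0")
        for ep, f in self.fatal_fraction.items():
            if ep not in self.endpoint_hazards:
                raise ConfigError(f"fatal_fraction names unknown endpoint {ep!r}")
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"endpoint {ep!r}: fatal_fraction must lie in [0, 1]")
        if self.discontinuation_rate < 0:
            raise ConfigError("discontinuation_rate must be >= 0")
        if self.max_followup_years <= 0:
            raise ConfigError("max_followup_years must be > 0")
        if not 0.0 <= self.entry_stagger_years < self.max_followup_years:
            raise ConfigError("entry_stagger_years must lie in [0, max_followup_years)")

    def validate_against(self, tree: ValueTree) -> None:
        """Check every simulated endpoint exists in the value tree."""
        unknown = set(self.endpoint_hazards) - set(tree.names)
        if unknown:
            raise ConfigError(f"hazards name endpoints absent from the value tree: {sorted(unknown)}")

    # -- serialization ----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["n_per_arm"] = list(self.n_per_arm)
        doc["endpoint_hazards"] = {k: list(v) for k, v in self.endpoint_hazards.items()}
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        doc = yaml.safe_load(Path(path).read_text())
        try:
            return cls(
                n_per_arm=tuple(doc["n_per_arm"]),
                endpoint_hazards={k: tuple(v) for k, v in doc["endpoint_hazards"].items()},
                fatal_fraction=dict(doc.get("fatal_fraction", {})),
                discontinuation_rate=float(doc.get("discontinuation_rate", 0.0)),
                max_followup_years=float(doc["max_followup_years"]),
                entry_stagger_years=float(doc.get("entry_stagger_years", 0.0)),
                seed=int(doc.get("seed", 0)),
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"malformed simulation config {path}: {exc}") from exc


def default_voyager_config(seed: int = 20240402) -> SimConfig:
    """Trial-calibrated default configuration.

    Hazards equal the published ITT rates converted to events per
    patient-year. Table rates for nonfatal endpoints are already net of
    the fatal-attribution rule, so their fatal fractions are 0 and the two
    death streams are drawn directly (fatal fraction 1). The
    non-cardiovascular death hazard is a free parameter (not printed);
    60 per 10 000 PY in both arms makes all-cause mortality plausibly
    exceed cardiovascular mortality in this population.
    """
    from .voyager import itt_model1_table

    tbl = itt_model1_table()
    hazards = {
        row.endpoint: (row.rate_active / 1e4, row.rate_control / 1e4)
        for row in tbl.itertuples()
    }
    hazards["noncardiovascular_death"] = (60.0 / 1e4, 60.0 / 1e4)
    return SimConfig(
        n_per_arm=(3286, 3278),
        endpoint_hazards=hazards,
        fatal_fraction={"fatal_composite": 1.0, "noncardiovascular_death": 1.0},
        discontinuation_rate=0.14,
        max_followup_years=31.0 / 12.0 + 0.5,
        entry_stagger_years=1.0,
        seed=seed,
    )


def simulate_trial(config: SimConfig,
                   tree: ValueTree | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one synthetic trial.

    Returns ``(patients, events)`` DataFrames with columns
    :data:`PATIENT_COLUMNS` and :data:`EVENT_COLUMNS`. For each patient
    and endpoint at most one event time is drawn from the exponential with
    that arm's hazard and kept only if it falls within follow-up; the
    earliest fatal occurrence truncates follow-up for all endpoints.
    Bit-reproducible for a fixed seed.
    """
    if tree is not None:
        config.validate_against(tree)
    endpoints = sorted(config.endpoint_hazards)  # fixed draw order
    hz = config.endpoint_hazards
    frac = {ep: config.fatal_fraction.get(ep, 0.0) for ep in endpoints}

    n_a, n_c = config.n_per_arm
    total = n_a + n_c
    children = np.random.SeedSequence(config.seed).spawn(total)

    pat_rows = []
    ev_pid, ev_ep, ev_t, ev_fatal = [], [], [], []
    for i in range(total):
        arm_idx = 0 if i < n_a else 1
        rng = np.random.default_rng(children[i])

        entry = rng.uniform(0.0, config.entry_stagger_years) \
            if config.entry_stagger_years > 0 else 0.0
        admin_days = (config.max_followup_years - entry) * DAYS_PER_YEAR

        # Fixed-size draw block per patient: one exponential + one uniform
        # per endpoint, then discontinuation.
        u_exp = rng.exponential(1.0, size=len(endpoints))
        u_fatal = rng.random(size=len(endpoints))
        disc_draw = rng.exponential(1.0)

        times, fatals = [], []
        for j, ep in enumerate(endpoints):
            h = hz[ep][arm_idx]
            t = (u_exp[j] / h) * DAYS_PER_YEAR if h > 0 else math.inf
            times.append(t)
            fatals.append(u_fatal[j] < frac[ep])

        death = min((t for t, f in zip(times, fatals) if f), default=math.inf)
        fu_end = min(admin_days, death)

        if config.discontinuation_rate > 0:
            disc_days = (disc_draw / config.discontinuation_rate) * DAYS_PER_YEAR
        else:
            disc_days = math.inf
        last_dose = min(disc_days, fu_end)

        for ep, t, f in zip(endpoints, times, fatals):
            if t <= fu_end:
                ev_pid.append(i)
                ev_ep.append(ep)
                ev_t.append(t)
                ev_fatal.append(f)
        pat_rows.append((i, ARMS[arm_idx], fu_end, last_dose))

    patients = pd.DataFrame(pat_rows, columns=list(PATIENT_COLUMNS))
    events = pd.DataFrame(
        {"patient_id": np.asarray(ev_pid, dtype=int),
         "endpoint": ev_ep,
         "time_days": np.asarray(ev_t, dtype=float),
         "fatal": np.asarray(ev_fatal, dtype=bool)}
    )
    return patients, events
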