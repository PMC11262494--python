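"""Value-tree and weight configuration for benefit-risk analyses.

A benefit-risk *value tree* organises a trial's efficacy (benefit) and
safety (risk) endpoints. Endpoints are grouped by whether they are fatal /
irreversible; to avoid double-counting deaths, every endpoint other than
the fatal ones is defined as nonfatal, and fatal occurrences are attributed
to a single fatal endpoint per model:

* model 1 scores a composite of cardiovascular death and fatal major
  bleeding as its fatal endpoint;
* model 2 scores all-cause death instead, capturing every death event.

Weights come from health state utility values (HSUVs): a utility ``u`` in
[0, 1] (1 = perfect health, 0 = death) yields the MCDA weight ``w = 1 - u``,
so a death counts 1.0 and milder outcomes count proportionally less.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import yaml

__all__ = [
    "ConfigError",
    "EndpointSpec",
    "WeightSpec",
    "ScopeConfig",
    "ValueTree",
    "default_value_tree",
    "default_weight_specs",
    "load_value_tree",
    "save_value_tree",
    "DEFAULT_UTILITY_SD",
]

#: Default SD of the health-state utility for nonfatal endpoints when a
#: study-specific value is not supplied. HSUV dispersions reported in
#: cost-effectiveness registries typically fall in 0.05-0.15.
DEFAULT_UTILITY_SD = 0.10

ROLES = ("benefit", "risk")
WEIGHT_FAMILIES = ("beta", "truncated-normal", "fixed")


class ConfigError(ValueError):
    """Raised for an inconsistent value tree, weight or scope configuration."""


@dataclass(frozen=True)
class EndpointSpec:
    """One node of the benefit-risk value tree.

    Parameters
    ----------
    name
        Endpoint label used throughout event tables and results.
    role
        ``"benefit"`` (efficacy side) or ``"risk"`` (safety side).
    fatal
        True for a model's fatal endpoint (death sink). Each model has
        exactly one.
    in_model1, in_model2
        Membership in the two MCDA endpoint sets.
    in_fatal_composite
        Whether a *fatal* occurrence of this endpoint belongs to the
        model-1 composite of cardiovascular death and fatal bleeding.
        Non-cardiovascular deaths set this False: they count in model 2
        (all-cause death) but not in model 1.
    """

    name: str
    role: str
    fatal: bool = False
    in_model1: bool = True
    in_model2: bool = True
    in_fatal_composite: bool = True

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ConfigError(
                f"endpoint {self.name!r}: role must be one of {ROLES}, got {self.role!r}"
            )


@dataclass(frozen=True)
class WeightSpec:
    """Health-state-utility weight specification for one endpoint.

    The MCDA weight is ``1 - utility_mean``; ``utility_sd`` feeds the
    Monte Carlo weight distribution (``family``: beta moment-matched,
    normal truncated to [0, 1], or fixed at the mean).
    """

    endpoint: str
    utility_mean: float
    utility_sd: float = 0.0
    family: str = "beta"

    def __post_init__(self) -> None:
        if not 0.0 <= self.utility_mean <= 1.0:
            raise ConfigError(
                f"weight for {self.endpoint!r}: utility_mean must lie in [0, 1]"
            )
        if self.utility_sd < 0:
            raise ConfigError(f"weight for {self.endpoint!r}: utility_sd must be >= 0")
        if self.family not in WEIGHT_FAMILIES:
            raise ConfigError(
                f"weight for {self.endpoint!r}: family must be one of {WEIGHT_FAMILIES}"
            )

    @property
    def weight_mean(self) -> float:
        """Mean MCDA weight, ``1 - utility_mean``."""
        return 1.0 - self.utility_mean


@dataclass(frozen=True)
class ScopeConfig:
    """Analysis population / data-scope definition.

    ``itt``: all randomized patients, events until the administrative
    cutoff. ``on_treatment``: dosed patients only, events until the last
    study-drug dose plus ``window_after_last_dose_days`` (conventionally 2).
    """

    name: str
    window_after_last_dose_days: int = 2

    def __post_init__(self) -> None:
        if self.name not in ("itt", "on_treatment"):
            raise ConfigError(f"unknown scope {self.name!r}; use 'itt' or 'on_treatment'")
        if self.window_after_last_dose_days < 0:
            raise ConfigError("window_after_last_dose_days must be >= 0")


@dataclass(frozen=True)
class ValueTree:
    """An ordered collection of :class:`EndpointSpec` with model views."""

    endpoints: tuple[EndpointSpec, ...]

    def __post_init__(self) -> None:
        names = [e.name for e in self.endpoints]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate endpoint names in value tree")
        for model in (1, 2):
            fatal = [e for e in self.model_endpoints(model) if e.fatal]
            if len(fatal) != 1:
                raise ConfigError(
                    f"model {model} must contain exactly one fatal endpoint, "
                    f"found {[e.name for e in fatal]}"
                )

    def __iter__(self):
        return iter(self.endpoints)

    def get(self, name: str) -> EndpointSpec:
        for e in self.endpoints:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.endpoints)

    def model_endpoints(self, model: int) -> tuple[EndpointSpec, ...]:
        if model not in (1, 2):
            raise ConfigError(f"model must be 1 or 2, got {model}")
        attr = "in_model1" if model == 1 else "in_model2"
        return tuple(e for e in self.endpoints if getattr(e, attr))

    def fatal_endpoint(self, model: int) -> EndpointSpec:
        """The single fatal endpoint of the requested model."""
        return next(e for e in self.model_endpoints(model) if e.fatal)


def default_value_tree() -> ValueTree:
    """Value tree for a trial of an antithrombotic after limb revascularization.

    Benefits are the ischemic endpoints (acute limb ischemia, major
    amputation of vascular cause, myocardial infarction, ischemic stroke,
    cardiovascular death); risks are major bleeding endpoints. The
    ``noncardiovascular_death`` stream carries deaths outside the model-1
    composite so that model 2's all-cause death endpoint is complete.
    """
    return ValueTree(
        endpoints=(
            EndpointSpec("fatal_composite", "benefit", fatal=True,
                         in_model1=True, in_model2=False),
            EndpointSpec("nonfatal_amputation", "benefit"),
            EndpointSpec("nonfatal_ich_bleeding", "risk"),
            EndpointSpec("nonfatal_ali", "benefit"),
            EndpointSpec("nonfatal_stroke", "benefit"),
            EndpointSpec("nonfatal_mi", "benefit"),
            EndpointSpec("nonfatal_nonich_bleeding", "risk"),
            EndpointSpec("all_cause_death", "benefit", fatal=True,
                         in_model1=False, in_model2=True,
                         in_fatal_composite=False),
            EndpointSpec("noncardiovascular_death", "benefit", fatal=True,
                         in_model1=False, in_model2=False,
                         in_fatal_composite=False),
        )
    )


def default_weight_specs(utility_sd: float = DEFAULT_UTILITY_SD) -> dict[str, WeightSpec]:
    """Mean HSUV-based weights for the default value tree.

    Fatal endpoints have utility 0 (weight exactly 1, no uncertainty);
    nonfatal endpoints get ``utility_sd`` as their default dispersion.
    """
    means = {
        "fatal_composite": 0.0,
        "nonfatal_amputation": 0.41,
        "nonfatal_ich_bleeding": 0.58,
        "nonfatal_ali": 0.64,
        "nonfatal_stroke": 0.65,
        "nonfatal_mi": 0.78,
        "nonfatal_nonich_bleeding": 0.78,
        "all_cause_death": 0.0,
        "noncardiovascular_death": 0.0,
    }
    out: dict[str, WeightSpec] = {}
    for name, u in means.items():
        if u == 0.0:
            out[name] = WeightSpec(name, 0.0, 0.0, "fixed")
        else:
            out[name] = WeightSpec(name, u, utility_sd, "beta")
    return out


def save_value_tree(path: str | Path, tree: ValueTree,
                    weights: dict[str, WeightSpec] | None = None) -> None:
    doc: dict = {"endpoints": [asdict(e) for e in tree.endpoints]}
    if weights is not None:
        doc["weights"] = [asdict(w) for w in weights.values()]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_value_tree(path: str | Path) -> tuple[ValueTree, dict[str, WeightSpec]]:
    """Load a value tree (and optional weights) from YAML or JSON text."""
    doc = yaml.safe_load(Path(path).read_text())
    try:
        tree = ValueTree(tuple(EndpointSpec(**e) for e in doc["endpoints"]))
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"malformed value-tree file {path}: {exc}") from exc
    weights = {}
    for w in doc.get("weights", []):
        spec = WeightSpec(**w)
        if spec.endpoint not in tree.names:
            raise ConfigError(f"weight for unknown endpoint {spec.endpoint!r}")
        weights[spec.endpoint] = spec
    return tree, weights
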