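"""Experiment configuration, validation and provenance.

A single YAML file describes an experiment: which of the packaged
experiment designs to run (``fifty_year``, ``california``,
``null_control``, ``ode_analysis``), the population-generation parameters,
the per-scenario sentence targets and initial prevalences, replicate
counts and seeds.  Every omitted field is materialised from the packaged
defaults, and the fully-resolved configuration — including the fitted
sentence-distribution parameters and the package version — is echoed into
a provenance record so any run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version

import yaml

from .population import PopulationConfig
from .sentencing import BLACK_TARGETS, WHITE_TARGETS

EXPERIMENTS = ("fifty_year", "california", "null_control", "ode_analysis")


class ConfigError(ValueError):
    pass


@dataclass
class ScenarioSpec:
    name: str
    sentence_mean: float
    sentence_median: int
    init_prevalence: float


@dataclass
class ExperimentSpec:
    experiment: str = "fifty_year"
    population: PopulationConfig = field(default_factory=PopulationConfig)
    scenarios: list = field(default_factory=list)
    n_replicates: int = 250
    horizon: int = 600
    base_seed: int = 0
    min_incarcerable_age: int = 15
    adult_child_age: int = 18
    calibration_sentence: int = 14
    life_table_csv: str | None = None
    survey_csv: str | None = None
    # null_control only
    target_prevalence: float = 0.03
    tolerance: float = 0.003
    tuning_replicates: int = 25
    # ode_analysis only: published mean-rate calibration unless logs supplied
    ode_p: float = 0.0612
    out_dir: str = "results"

    def validate(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ConfigError(
                f"experiment must be one of {EXPERIMENTS}, got {self.experiment!r}")
        self.population.validate()
        if self.n_replicates < 1 or self.horizon < 1:
            raise ConfigError("n_replicates and horizon must be >= 1")
        for sc in self.scenarios:
            if not 0 <= sc.init_prevalence <= 1:
                raise ConfigError(
                    f"scenario {sc.name!r}: init_prevalence outside [0, 1]")


def _default_scenarios(experiment: str) -> list:
    if experiment == "california":
        return [ScenarioSpec("black", *BLACK_TARGETS, init_prevalence=0.01),
                ScenarioSpec("white", *WHITE_TARGETS, init_prevalence=0.0015)]
    return [ScenarioSpec("black", *BLACK_TARGETS, init_prevalence=0.01),
            ScenarioSpec("white", *WHITE_TARGETS, init_prevalence=0.01)]


_TOP_KEYS = {f.name for f in dataclasses.fields(ExperimentSpec)}
_POP_KEYS = {f.name for f in dataclasses.fields(PopulationConfig)}
_SCEN_KEYS = {f.name for f in dataclasses.fields(ScenarioSpec)}


def load_config(path) -> ExperimentSpec:
    """Load and validate a YAML experiment file, materialising defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return spec_from_dict(raw)


def spec_from_dict(raw: dict) -> ExperimentSpec:
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    kwargs = dict(raw)
    pop_raw = kwargs.pop("population", {}) or {}
    unknown = set(pop_raw) - _POP_KEYS
    if unknown:
        raise ConfigError(f"unknown population keys: {sorted(unknown)}")
    # YAML gives string keys for pmfs; coerce to ints
    for pmf_key in ("friend_count_pmf", "children_count_pmf"):
        if pmf_key in pop_raw:
            pop_raw[pmf_key] = {int(k): float(v)
                                for k, v in pop_raw[pmf_key].items()}
    scen_raw = kwargs.pop("scenarios", None)
    spec = ExperimentSpec(population=PopulationConfig(**pop_raw), **kwargs)
    if scen_raw is None:
        spec.scenarios = _default_scenarios(spec.experiment)
    else:
        scenarios = []
        for s in scen_raw:
            unknown = set(s) - _SCEN_KEYS
            if unknown:
                raise ConfigError(f"unknown scenario keys: {sorted(unknown)}")
            scenarios.append(ScenarioSpec(**s))
        spec.scenarios = scenarios
    if spec.experiment == "california" and spec.horizon == 600 and "horizon" not in raw:
        spec.horizon = 300
    spec.validate()
    return spec


def spec_to_dict(spec: ExperimentSpec) -> dict:
    d = dataclasses.asdict(spec)
    return d


def save_config(spec: ExperimentSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)


def provenance_record(spec: ExperimentSpec, extra: dict | None = None) -> dict:
    """Everything needed to re-run: full spec, fitted laws, package version."""
    try:
        pkg_version = version("incarsis")
    except PackageNotFoundError:  # running from a source tree
        pkg_version = "unknown"
    rec = {"package": "incarsis", "version": pkg_version,
           "spec": spec_to_dict(spec)}
    if extra:
        rec.update(extra)
    return rec


def write_provenance(rec: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(rec, fh, indent=2, default=str)
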