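"""Run configuration with published defaults and flat-file loading.

The defaults mirror the reference hyper-parameter table: population size 8,
100 iterations, search domain [0, 1], GA crossover 0.8 / mutation 0.01,
fitness weight alpha 0.99 (beta = 1 - alpha), 10-fold cross-validation.
Keys belonging to the out-of-scope deep classifier (momentum, batch size,
learning rate, dropout, class weights, loss function) are accepted and
echoed in run manifests but never used.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

#: Config keys accepted for documentation only; they configure the deep
#: classifier that this toolkit replaces with a pluggable evaluator.
UNUSED_KEYS = frozenset(
    {"momentum", "batch_size", "learning_rate", "weight_decay", "dropout",
     "loss_function", "class_weights"}
)

#: Sentinel for "sharing disabled" (accepted as the string "off" in files).
SHARING_OFF = "off"


class ConfigError(ValueError):
    """A configuration key is malformed or out of range."""


@dataclass
class OptimizerConfig:
    """Resolved settings for one optimization run.

    ``sharing_radius`` semantics: ``None`` means auto
    (``0.02 * sqrt(dimensionality)``), ``"off"`` or ``0`` disables
    fitness sharing, a positive float is used as-is. The auto rule keeps
    niching local: with a radius a few times larger, leader ranking stays
    niche-penalized after the pack converges and final solutions degrade
    measurably on the planted-feature benchmark.
    """

    population_size: int = 8
    iterations: int = 100
    dimensionality: int = 1
    domain_low: float = 0.0
    domain_high: float = 1.0
    orientation: str = "maximize"
    seed: int = 0
    sharing_radius: float | str | None = None
    ga_crossover_prob: float = 0.8
    ga_mutation_prob: float = 0.01
    ga_generations: int = 20
    bits_per_dimension: int = 8
    fitness_alpha: float = 0.99
    k_folds: int = 10
    cv_repeats: int = 10
    k_neighbors: int = 1
    unused: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.population_size < 3:
            raise ConfigError(
                f"population_size must be >= 3 (three leaders), got {self.population_size}")
        if self.iterations < 1:
            raise ConfigError(f"iterations must be >= 1, got {self.iterations}")
        if self.dimensionality < 1:
            raise ConfigError(f"dimensionality must be >= 1, got {self.dimensionality}")
        if not self.domain_low < self.domain_high:
            raise ConfigError(
                f"domain_low must be < domain_high, got [{self.domain_low}, {self.domain_high}]")
        if self.orientation not in ("maximize", "minimize"):
            raise ConfigError(f"orientation must be 'maximize' or 'minimize', got {self.orientation!r}")
        for key in ("ga_crossover_prob", "ga_mutation_prob", "fitness_alpha"):
            value = getattr(self, key)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{key} must lie in [0, 1], got {value}")
        if self.ga_generations < 0:
            raise ConfigError(f"ga_generations must be >= 0, got {self.ga_generations}")
        if self.bits_per_dimension < 1:
            raise ConfigError(f"bits_per_dimension must be >= 1, got {self.bits_per_dimension}")
        if isinstance(self.sharing_radius, str) and self.sharing_radius != SHARING_OFF:
            raise ConfigError(
                f"sharing_radius must be a number, 'off', or null, got {self.sharing_radius!r}")
        if isinstance(self.sharing_radius, (int, float)) and self.sharing_radius < 0:
            raise ConfigError(f"sharing_radius must be >= 0, got {self.sharing_radius}")

    @property
    def sharing_enabled(self) -> bool:
        if self.sharing_radius == SHARING_OFF:
            return False
        if isinstance(self.sharing_radius, (int, float)) and self.sharing_radius == 0:
            return False
        return True

    def resolved_sharing_radius(self) -> float | None:
        """Concrete radius for the configured dimensionality, or None if off."""
        if not self.sharing_enabled:
            return None
        if self.sharing_radius is None:
            return 0.02 * math.sqrt(self.dimensionality)
        return float(self.sharing_radius)

    def with_(self, **overrides) -> "OptimizerConfig":
        return replace(self, **overrides)

    def as_dict(self) -> dict:
        out = {f.name: getattr(self, f.name) for f in fields(self) if f.name != "unused"}
        out["unused"] = dict(self.unused)
        return out


# aliases accepted in config files for the published table's terse key names
_KEY_ALIASES = {
    "k": "k_folds",
    "i": "iterations",
    "p.s": "population_size",
    "ps": "population_size",
    "d": "domain",
    "alpha": "fitness_alpha",
    "crossover": "ga_crossover_prob",
    "crossover_prob": "ga_crossover_prob",
    "mutation": "ga_mutation_prob",
    "mutation_prob": "ga_mutation_prob",
    "m": "momentum",
    "bs": "batch_size",
    "lr": "learning_rate",
    "wd": "weight_decay",
    "lf": "loss_function",
    "cw": "class_weights",
}

_FIELD_NAMES = {f.name for f in fields(OptimizerConfig)} - {"unused"}


def load_config(path: str | Path | None = None, **overrides) -> OptimizerConfig:
    """Resolve a configuration from defaults, an optional file, and overrides.

    The file is a flat key-value YAML document. Missing file -> pure
    defaults. Keys present in the file override defaults; keyword
    ``overrides`` (typically CLI flags) override both. Unknown keys warn
    but do not fail; documented-but-unused deep-net keys are collected
    under ``unused``.
    """
    settings: dict = {}
    unused: dict = {}
    if path is not None:
        path = Path(path)
        try:
            raw = yaml.safe_load(path.read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"malformed config file {path}: {exc}") from exc
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must be a flat key-value mapping")
        for key, value in raw.items():
            name = _KEY_ALIASES.get(str(key).lower(), str(key).lower())
            if name in UNUSED_KEYS:
                unused[name] = value
            elif name == "domain":
                low, high = _parse_domain(value)
                settings["domain_low"], settings["domain_high"] = low, high
            elif name in _FIELD_NAMES:
                settings[name] = value
            else:
                warnings.warn(f"unknown config key {key!r} ignored", stacklevel=2)
    for key, value in overrides.items():
        if value is None:
            continue
        if key not in _FIELD_NAMES:
            raise ConfigError(f"unknown config override {key!r}")
        settings[key] = value
    try:
        return OptimizerConfig(unused=unused, **settings)
    except TypeError as exc:  # bad key slipped through
        raise ConfigError(str(exc)) from exc


def _parse_domain(value) -> tuple[float, float]:
    if isinstance(value, str):
        value = value.strip().lstrip("[").rstrip("]").split(",")
    try:
        low, high = (float(v) for v in value)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"domain must be a [low, high] pair, got {value!r}") from exc
    return low, high
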