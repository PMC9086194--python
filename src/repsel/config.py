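"""Run configuration: defaults, YAML/JSON loading and validation."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .base_selectors import SelectorConfig
from .ensemble import DEFAULT_BASE_METHODS, EnsembleConfig

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unparseable run configuration."""


@dataclass
class RunConfig:
    """Flat run configuration shared by the CLI subcommands.

    Defaults mirror the ensemble's standard operating point: rho = 0.75,
    K = 50 permutation rounds, tau = 0.5 selection-frequency threshold, and
    the four-member base-learner roster.
    """

    rho: float = 0.75
    K: int = 50
    tau: float = 0.5
    base_methods: tuple[str, ...] = DEFAULT_BASE_METHODS
    no_base_learners: bool = False
    seed: int = 0
    n_jobs: int = 1
    top_fraction: float = 0.05
    cv_folds: int = 5
    rf_trees: int = 500
    boruta_max_iter: int = 100
    log_level: str = "INFO"
    out_dir: str = "."

    def __post_init__(self) -> None:
        if not 0 < self.rho < 1:
            raise ConfigError(f"rho must lie in (0, 1), got {self.rho}")
        if self.K < 1:
            raise ConfigError(f"K must be >= 1, got {self.K}")
        if not 0 < self.tau <= 1:
            raise ConfigError(f"tau must lie in (0, 1], got {self.tau}")
        if self.cv_folds < 2:
            raise ConfigError(f"cv_folds must be >= 2, got {self.cv_folds}")
        if isinstance(self.base_methods, list):
            self.base_methods = tuple(self.base_methods)

    def selector_config(self, seed: int | None = None) -> SelectorConfig:
        return SelectorConfig(
            top_fraction=self.top_fraction,
            cv_folds=self.cv_folds,
            rf_trees=self.rf_trees,
            boruta_max_iter=self.boruta_max_iter,
            seed=self.seed if seed is None else seed,
        )

    def ensemble_config(self) -> EnsembleConfig:
        return EnsembleConfig(
            rho=self.rho, K=self.K, tau=self.tau,
            base_methods=tuple(self.base_methods),
            no_base_learners=self.no_base_learners,
            selector=self.selector_config(),
            n_jobs=self.n_jobs,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["base_methods"] = list(self.base_methods)
        return d


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML/JSON config file, apply overrides, validate.

    An empty or absent file yields pure defaults.  Unknown keys are an error
    (named in the message).  ``overrides`` (e.g. parsed CLI flags) win over
    file values; ``None`` override values are ignored.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        try:
            if str(path).endswith(".json"):
                data = json.loads(text) or {}
            else:
                data = yaml.safe_load(text) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"malformed config file {path}: {exc}") from exc
        except json.JSONDecodeError as exc:
            raise ConfigError(f"malformed config file {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
    return RunConfig(**data)
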