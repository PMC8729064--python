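"""Run configuration: the ten walk parameters plus numerical knobs.

Configs are flat key-value YAML files.  Missing keys take the published
operating point (all six inter-layer probabilities 0.2; layer weights
0.4/0.1/0.1 for lncRNA/miRNA/gene; restart probability 0.7; L1 tolerance
1e-6); unknown keys are rejected so typos cannot silently fall back to
defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

from .errors import ParameterError
from .network import TransitionParams

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    params: TransitionParams = field(default_factory=TransitionParams)
    lam: float = 0.7
    delta_disease: float = 0.5
    delta_go: float = 0.5
    gip_r_prime: float = 1.0
    gip_norm_convention: str = "squared"
    tol: float = 1e-6
    max_iter: int = 1000
    cv_folds: int = 10
    seed: int = 42
    static_similarity: bool = False

    def __post_init__(self):
        if not 0.0 < self.lam <= 1.0:
            raise ParameterError(f"restart probability must lie in (0, 1], got {self.lam}")
        for name in ("delta_disease", "delta_go"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ParameterError(f"{name} must lie in (0, 1), got {v}")
        if self.tol <= 0:
            raise ParameterError(f"tolerance must be > 0, got {self.tol}")
        if self.gip_r_prime <= 0:
            raise ParameterError(f"gip_r_prime must be > 0, got {self.gip_r_prime}")
        if self.gip_norm_convention not in ("squared", "literal"):
            raise ParameterError(
                f"gip_norm_convention must be 'squared' or 'literal', got {self.gip_norm_convention!r}"
            )
        if self.max_iter < 1:
            raise ParameterError("max_iter must be >= 1")
        if self.cv_folds < 2:
            raise ParameterError("cv_folds must be >= 2")

    def with_lambda(self, lam: float) -> "RunConfig":
        return replace(self, lam=lam)


_PARAM_KEYS = {f.name for f in fields(TransitionParams)}
_CONFIG_KEYS = {f.name for f in fields(RunConfig)} - {"params"}
_ALIASES = {"lambda": "lam", "k": "cv_folds", "delta": "delta_disease"}


def load_config(path: str | Path | None) -> RunConfig:
    """Read a flat YAML key-value file into a validated RunConfig.

    ``None`` (or an empty file) yields the default operating point.
    """
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ParameterError(f"config file {path} must be a flat key-value mapping")
    params_kwargs: dict[str, float] = {}
    config_kwargs: dict[str, object] = {}
    for key, value in raw.items():
        key = _ALIASES.get(str(key), str(key))
        if key in _PARAM_KEYS:
            params_kwargs[key] = float(value)
        elif key in _CONFIG_KEYS:
            config_kwargs[key] = value
        else:
            raise ParameterError(f"unknown config key {key!r}")
    return RunConfig(params=TransitionParams(**params_kwargs), **config_kwargs)
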