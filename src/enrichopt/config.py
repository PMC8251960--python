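"""Configuration files (YAML/JSON) for trial designs.

Flat key-value schema::

    n: 700
    sigma: 1.0
    alpha: 0.05
    lambda: 0.3
    mode: enrichment        # or umbrella
    prior:
      mu1: 0.1
      mu2: 0.0
      psi1: 0.3162
      psi2: 0.3162
      rho: 0.5
    stage1:
      s1: 0.5
      r1: 0.4
      w1: 0.4               # ignored in umbrella mode

Validation errors name the offending key path.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Tuple

import yaml

from .design import Mode, PriorSpec, StageOneParams, TrialConfig

__all__ = ["ConfigError", "load_config", "parse_config"]


class ConfigError(ValueError):
    """A configuration file failed validation; the message names the key."""


_TOP_KEYS = {"n", "sigma", "alpha", "lambda", "mode", "prior", "stage1"}
_PRIOR_KEYS = {"mu1", "mu2", "psi1", "psi2", "rho"}
_STAGE1_KEYS = {"s1", "r1", "w1"}


def _require(mapping: dict, key: str, where: str):
    if key not in mapping:
        raise ConfigError(f"missing required key '{where}{key}'")
    return mapping[key]


def parse_config(mapping: dict) -> Tuple[TrialConfig, PriorSpec, StageOneParams]:
    """Validate a config mapping and build the domain objects."""
    if not isinstance(mapping, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(mapping) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")

    mode = str(mapping.get("mode", "enrichment")).lower()
    if mode not in (Mode.ENRICHMENT.value, Mode.UMBRELLA.value):
        raise ConfigError(f"'mode' must be 'enrichment' or 'umbrella', got {mode!r}")

    try:
        cfg = TrialConfig(
            n=float(_require(mapping, "n", "")),
            sigma=float(mapping.get("sigma", 1.0)),
            alpha=float(mapping.get("alpha", 0.05)),
            lambda_pop=float(_require(mapping, "lambda", "")),
            mode=mode,
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc

    p = _require(mapping, "prior", "")
    if not isinstance(p, dict):
        raise ConfigError("'prior' must be a mapping")
    unknown = set(p) - _PRIOR_KEYS
    if unknown:
        raise ConfigError(f"unknown prior key(s): {sorted(unknown)}")
    try:
        prior = PriorSpec(
            mu1=float(_require(p, "mu1", "prior.")),
            mu2=float(_require(p, "mu2", "prior.")),
            psi1=float(_require(p, "psi1", "prior.")),
            psi2=float(_require(p, "psi2", "prior.")),
            rho=float(p.get("rho", 0.0)),
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(f"prior: {exc}") from exc

    s = _require(mapping, "stage1", "")
    if not isinstance(s, dict):
        raise ConfigError("'stage1' must be a mapping")
    unknown = set(s) - _STAGE1_KEYS
    if unknown:
        raise ConfigError(f"unknown stage1 key(s): {sorted(unknown)}")
    r1 = float(_require(s, "r1", "stage1."))
    if mode == Mode.UMBRELLA.value:
        w1 = 1.0 if r1 == 1 else (0.0 if r1 == 0 else 0.5)
    else:
        w1 = float(_require(s, "w1", "stage1."))
    try:
        a1 = StageOneParams(s1=float(_require(s, "s1", "stage1.")), r1_1=r1, w1_1=w1)
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(f"stage1: {exc}") from exc

    return cfg, prior, a1


def load_config(path) -> Tuple[TrialConfig, PriorSpec, StageOneParams]:
    """Load and validate a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        mapping = json.loads(text)
    else:
        mapping = yaml.safe_load(text)
    return parse_config(mapping)
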