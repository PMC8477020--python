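"""Run configuration: packaged defaults, strict YAML overrides, hashing.

Every tunable of the pipeline lives in :data:`DEFAULTS` (shipped as
``defaults.yaml``). A user config file may override any subset; unknown keys
are rejected so typos fail loudly instead of silently falling back.
"""

from __future__ import annotations

import copy
import hashlib
import json
from importlib import resources
from typing import Any, Mapping

import yaml

from .errors import ConfigError


def _load_defaults() -> dict:
    with resources.files("ptgtwin").joinpath("defaults.yaml").open("r") as fh:
        return yaml.safe_load(fh)


DEFAULTS: dict = _load_defaults()


def _merge_strict(base: dict, override: Mapping, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else str(key)
        if key not in base:
            raise ConfigError(f"unknown configuration key: {here!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, Mapping):
                raise ConfigError(f"{here!r} must be a mapping")
            out[key] = _merge_strict(base[key], value, here)
        else:
            out[key] = value
    return out


def _validate(cfg: dict) -> None:
    pop = cfg["population"]
    for key in ("sigma_max", "k_act", "k_deact", "k_cl", "v_d",
                "lambda_max", "mu", "alpha_p"):
        if not pop[key] > 0:
            raise ConfigError(f"population.{key} must be > 0")
    if not pop["h"] >= 1:
        raise ConfigError("population.h must be >= 1")
    if not 0 <= pop["eps_d"] < 1:
        raise ConfigError("population.eps_d must lie in [0, 1)")
    sol = cfg["solver"]
    if not (sol["rtol"] > 0 and sol["atol"] > 0):
        raise ConfigError("solver tolerances must be > 0")
    est = cfg["estimation"]
    if not est["window_days"] > 0:
        raise ConfigError("estimation.window_days must be > 0")
    if not 1 <= int(est["n_starts"]) <= 64:
        raise ConfigError("estimation.n_starts must lie in [1, 64]")
    for name, (lo, hi) in est["bounds"].items():
        if not lo < hi:
            raise ConfigError(f"estimation.bounds.{name} must satisfy lo < hi")
    if not cfg["prediction"]["horizon_days"] > 0:
        raise ConfigError("prediction.horizon_days must be > 0")


class RunConfig:
    """Immutable view over a validated configuration tree.

    Access groups as attributes (``cfg.population``) or the raw mapping via
    :meth:`as_dict`.
    """

    def __init__(self, tree: dict):
        _validate(tree)
        self._tree = copy.deepcopy(tree)
        if self._tree["balance_calibration"]["enforce"]:
            # balanced growth at the set-point: mu = lambda_max * phi = lambda_max/2
            self._tree["population"]["mu"] = self._tree["population"]["lambda_max"] / 2.0

    def __getattr__(self, name: str) -> Any:
        try:
            return copy.deepcopy(self._tree[name])
        except KeyError:
            raise AttributeError(name) from None

    def as_dict(self) -> dict:
        return copy.deepcopy(self._tree)

    def hash(self) -> str:
        """Stable SHA-256 over the canonical JSON form (for run logs)."""
        blob = json.dumps(self._tree, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(blob.encode()).hexdigest()

    def __repr__(self) -> str:  # pragma: no cover
        return f"RunConfig(hash={self.hash()[:12]})"


def load_config(path: str | None = None,
                overrides: Mapping | None = None) -> RunConfig:
    """Load defaults, optionally merged with a YAML file and a dict.

    Precedence: packaged defaults < ``path`` < ``overrides``.
    """
    tree = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, Mapping):
            raise ConfigError("config file must contain a mapping at top level")
        tree = _merge_strict(tree, user)
    if overrides:
        tree = _merge_strict(tree, overrides)
    return RunConfig(tree)
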