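"""Plain key-value configuration files (YAML or JSON) for simulator runs.

Recognised sections::

    tissue:                 # dimensional thermal properties (TissueProperties fields)
    mechanical:             # lambda_l, mu_l, gamma_c, T_0
    dimensionless-override: # any DimensionlessParams field, taking precedence
    loading:                # LoadingSpec fields (kind, theta0, nu, t0, omega, ...)
    numerics:               # InversionOptions fields plus t, n_x

Dimensional sections are converted through :func:`compute_dimensionless`;
overrides let users bypass dimensional inputs entirely, since the solved
system depends only on the dimensionless set.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .core_params import DimensionlessParams, TissueProperties, compute_dimensionless
from .errors import InvalidParameterError
from .inversion import InversionOptions
from .loading import LoadingSpec

__all__ = ["RunConfig", "load_config", "parse_config"]

_TISSUE_FIELDS = {f.name for f in dataclasses.fields(TissueProperties)}
_DIMLESS_FIELDS = {f.name for f in dataclasses.fields(DimensionlessParams)}
_LOADING_FIELDS = {f.name for f in dataclasses.fields(LoadingSpec)}
_NUMERIC_FIELDS = {f.name for f in dataclasses.fields(InversionOptions)}


@dataclasses.dataclass(frozen=True)
class RunConfig:
    params: DimensionlessParams
    loading: LoadingSpec
    inversion: InversionOptions
    t: float = 0.05
    n_x: int = 121


def _numeric(section: dict, keep_str: tuple[str, ...] = ()) -> dict:
    """Coerce numeric-looking strings (YAML 1.1 reads ``7.0e5`` as a string)."""
    out = {}
    for key, value in section.items():
        if isinstance(value, str) and key not in keep_str:
            try:
                value = float(value)
            except ValueError:
                pass
        out[key] = value
    return out


def _check_keys(section: dict, allowed: set, name: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise InvalidParameterError(
            f"unknown keys {sorted(unknown)} in [{name}]; allowed: {sorted(allowed)}")


def parse_config(cfg: dict) -> RunConfig:
    """Build a :class:`RunConfig` from a parsed mapping."""
    tissue = _numeric(dict(cfg.get("tissue", {})))
    tissue.update(_numeric(dict(cfg.get("mechanical", {}))))
    override = _numeric(dict(cfg.get("dimensionless-override", {})))
    _check_keys(tissue, _TISSUE_FIELDS, "tissue/mechanical")
    _check_keys(override, _DIMLESS_FIELDS, "dimensionless-override")

    shape_keys = {k: override.pop(k) for k in ("tau_q", "tau_T", "L")
                  if k in override}
    if tissue:
        props = TissueProperties(**tissue)
        params = compute_dimensionless(props, **shape_keys)
    else:
        params = DimensionlessParams(**shape_keys)
    if override:
        params = dataclasses.replace(params, **override)

    loading_sec = _numeric(dict(cfg.get("loading", {"kind": "thermal_shock"})),
                           keep_str=("kind", "harmonic_dialect"))
    _check_keys(loading_sec, _LOADING_FIELDS, "loading")
    load = LoadingSpec(**loading_sec)

    numerics = dict(cfg.get("numerics", {}))
    t = float(numerics.pop("t", 0.05))
    n_x = int(numerics.pop("n_x", 121))
    _check_keys(numerics, _NUMERIC_FIELDS, "numerics")
    opts = InversionOptions(**numerics)
    return RunConfig(params=params, loading=load, inversion=opts, t=t, n_x=n_x)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML (or JSON) configuration file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise InvalidParameterError(f"config root must be a mapping, got {type(cfg)}")
    return parse_config(cfg)
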