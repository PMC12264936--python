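"""Run configuration: YAML/JSON schema, validation, and defaults.

The schema is explicit and closed — unknown keys are rejected with the
offending field named, so a typo in a config file fails loudly instead of
silently falling back to a default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .ranking import FilterSpec, LOOSE_FILTER, STRICT_FILTER
from .vl_model import DEFAULT_BOUNDS, ParamBounds

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid run configuration; the message names the field."""


def _check_keys(section: dict, allowed, where: str):
    unknown = set(section) - set(allowed)
    if unknown:
        raise ConfigError(
            f"unknown key(s) in {where}: {', '.join(sorted(unknown))}"
        )


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int = 0
    outdir: Path = Path("vligand_run")
    mode: str = "full"                      # "full" or "filter_only"
    sense: str = "minimize"
    surrogate_mode: str = "taylor"          # taylor | weighted | direct
    surrogate_clip: bool = True
    surrogate_subsample: Optional[int] = None
    backend: dict = field(default_factory=dict)
    bounds: ParamBounds = DEFAULT_BOUNDS
    filters: tuple = (STRICT_FILTER, LOOSE_FILTER)
    database_source: str = "builtin"        # builtin | synthetic | <path>
    database_n_ligands: int = 21
    database_delta_scale: float = 1.0
    p_star: Optional[np.ndarray] = None
    projection_options: dict = field(default_factory=dict)
    vlao_options: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in ("full", "filter_only"):
            raise ConfigError(f"mode must be 'full' or 'filter_only', got {self.mode!r}")
        if self.sense not in ("minimize", "maximize"):
            raise ConfigError(f"sense must be 'minimize' or 'maximize', got {self.sense!r}")
        if self.surrogate_mode not in ("taylor", "weighted", "direct"):
            raise ConfigError(
                f"surrogate mode must be taylor|weighted|direct, got {self.surrogate_mode!r}"
            )
        if self.mode == "filter_only" and self.p_star is None:
            raise ConfigError("filter_only mode requires p_star")


_TOP_KEYS = {
    "seed", "outdir", "mode", "sense", "surrogate", "backend", "bounds",
    "filters", "database", "p_star", "projection", "vlao",
}
_BACKEND_KEYS = {
    "n", "m", "center", "quad_scale", "bump_amplitude", "warp", "offset", "seed",
}
_SURROGATE_KEYS = {"mode", "clip", "subsample"}
_DB_KEYS = {"source", "n_ligands", "delta_scale"}
_FILTER_KEYS = {"name", "l_min_max", "dp_norm_max"}
_PROJ_KEYS = {"tol", "max_iter", "restarts", "restart_scale", "seed"}
_VLAO_KEYS = {"tol", "max_iter", "p_init", "hessian_step"}


def _parse_bounds(raw) -> ParamBounds:
    _check_keys(raw, {"lower", "upper"}, "bounds")
    for key in ("lower", "upper"):
        if key not in raw:
            raise ConfigError(f"bounds.{key} is required")
    return ParamBounds(np.asarray(raw["lower"], float), np.asarray(raw["upper"], float))


def parse_config(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")

    backend = dict(raw.get("backend", {}))
    _check_keys(backend, _BACKEND_KEYS, "backend")

    surr = dict(raw.get("surrogate", {}))
    _check_keys(surr, _SURROGATE_KEYS, "surrogate")

    db = dict(raw.get("database", {"source": "builtin"}))
    _check_keys(db, _DB_KEYS, "database")

    proj = dict(raw.get("projection", {}))
    _check_keys(proj, _PROJ_KEYS, "projection")

    vlao = dict(raw.get("vlao", {}))
    _check_keys(vlao, _VLAO_KEYS, "vlao")

    filters = []
    for i, f in enumerate(raw.get("filters", [])):
        _check_keys(f, _FILTER_KEYS, f"filters[{i}]")
        try:
            filters.append(
                FilterSpec(
                    float(f["l_min_max"]), float(f["dp_norm_max"]),
                    name=str(f.get("name", f"filter{i}")),
                )
            )
        except KeyError as exc:
            raise ConfigError(f"filters[{i}]: missing {exc.args[0]}") from exc
    if not filters:
        filters = [STRICT_FILTER, LOOSE_FILTER]

    if "bounds" not in raw:
        raise ConfigError("bounds is required (lower/upper parameter ranges)")

    p_star = raw.get("p_star")
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        outdir=Path(raw.get("outdir", "vligand_run")),
        mode=str(raw.get("mode", "full")),
        sense=str(raw.get("sense", "minimize")),
        surrogate_mode=str(surr.get("mode", "taylor")),
        surrogate_clip=bool(surr.get("clip", True)),
        surrogate_subsample=surr.get("subsample"),
        backend=backend,
        bounds=_parse_bounds(raw["bounds"]),
        filters=tuple(filters),
        database_source=str(db.get("source", "builtin")),
        database_n_ligands=int(db.get("n_ligands", 21)),
        database_delta_scale=float(db.get("delta_scale", 1.0)),
        p_star=None if p_star is None else np.asarray(p_star, float),
        projection_options=proj,
        vlao_options=vlao,
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON) configuration file."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return parse_config(raw)
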