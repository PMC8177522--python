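"""Strict driver configuration.

The configuration dialect mirrors the dictionary a driver is constructed
from in the Python bindings of comparable FEM forward toolboxes: a
``type`` ("fitted"), a ``solver_type`` ("cg" or "dg"), an
``element_type``, and a ``volume_conductor`` section with
``grid.filename`` / ``tensors.filename`` paths.  Unknown keys are
rejected so typos fail loudly instead of silently running defaults.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

_SCHEMA: dict[str, Any] = {
    "type": str,
    "solver_type": str,
    "element_type": str,
    "volume_conductor": {
        "grid.filename": str,
        "tensors.filename": str,
    },
    "source_model": {
        "type": str,
        "post_process": bool,
        "reference_length": float,
        "moment_order": int,
        "regularization": float,
        "quad_order": int,
    },
    "solver": {
        "tolerance": float,
        "penalty": float,
        "preconditioner": str,
    },
    "electrodes": {"filename": str},
    "coils": {"filename": str},
    "dipoles": {"filename": str},
    "source_space": {"filename": str},
    "measurement": {"filename": str},
    "output": {"directory": str, "format": str},
}


class ConfigError(ValueError):
    pass


def _check_section(cfg: dict, schema: dict, path: str = "") -> None:
    for key, val in cfg.items():
        full = f"{path}{key}"
        if key not in schema:
            raise ConfigError(f"unknown configuration key {full!r}")
        expected = schema[key]
        if isinstance(expected, dict):
            if not isinstance(val, dict):
                raise ConfigError(f"{full!r} must be a section (dict)")
            _check_section(val, expected, full + ".")
        else:
            if expected is float and isinstance(val, int):
                continue
            if not isinstance(val, expected):
                raise ConfigError(
                    f"{full!r} must be {expected.__name__}, got "
                    f"{type(val).__name__}"
                )


@dataclass
class DriverConfig:
    """Validated driver configuration with defaults applied."""

    raw: dict
    type: str = "fitted"
    solver_type: str = "cg"
    element_type: str = "tetrahedron"
    grid_filename: str | None = None
    tensors_filename: str | None = None
    source_model: dict = field(default_factory=dict)
    tolerance: float = 1e-8
    penalty: float | None = None
    preconditioner: str = "auto"


def parse_config(cfg: dict) -> DriverConfig:
    """Validate a configuration dictionary (strict keys) and apply defaults."""
    if not isinstance(cfg, dict):
        raise ConfigError("configuration must be a dictionary")
    _check_section(cfg, _SCHEMA)
    typ = cfg.get("type", "fitted")
    if typ == "unfitted":
        raise ConfigError(
            "type 'unfitted' (level-set based discretizations) is "
            "unsupported in this implementation"
        )
    if typ != "fitted":
        raise ConfigError(f"unknown driver type {typ!r}")
    solver_type = cfg.get("solver_type", "cg")
    if solver_type not in ("cg", "dg"):
        raise ConfigError(f"unknown solver_type {solver_type!r}")
    element_type = cfg.get("element_type", "tetrahedron")
    if element_type not in ("tetrahedron", "hexahedron"):
        raise ConfigError(f"unknown element_type {element_type!r}")
    solver = cfg.get("solver", {})
    penalty = solver.get("penalty")
    if solver_type == "dg" and penalty is None:
        raise ConfigError(
            "solver_type 'dg' requires the solver.penalty parameter"
        )
    vc = cfg.get("volume_conductor", {})
    sm = dict(cfg.get("source_model", {}))
    sm.setdefault("type", "partial_integration")
    return DriverConfig(
        raw=cfg,
        type=typ,
        solver_type=solver_type,
        element_type=element_type,
        grid_filename=vc.get("grid.filename"),
        tensors_filename=vc.get("tensors.filename"),
        source_model=sm,
        tolerance=float(solver.get("tolerance", 1e-8)),
        penalty=float(penalty) if penalty is not None else None,
        preconditioner=solver.get("preconditioner", "auto"),
    )


def load_config(path) -> DriverConfig:
    with open(path) as fh:
        return parse_config(json.load(fh))
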