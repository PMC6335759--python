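"""Run configuration: schema-validated JSON for the end-to-end pipeline.

Unknown keys are rejected and errors carry a JSON-pointer path to the
offending entry, so a typo in a stage parameter fails fast rather than
silently falling back to a default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Configuration violates the schema; message carries a JSON pointer."""


_NUM = (int, float)

#: allowed keys and value types per section; None value type = nested section
_SCHEMA: dict[str, Any] = {
    "out_dir": str,
    "seed": int,
    "inputs": {
        "cube": str,
        "spectra": str,
        "cells": str,
        "roi": str,
    },
    "unmix": {
        "refine_spectra": bool,
        "tol": _NUM,
        "max_iter": int,
    },
    "segment": {
        "min_size": int,
        "split_size": int,
        "fragment_size": int,
        "max_iter": int,
        "h": _NUM,
        "pixel_spacing_um": _NUM,
    },
    "phenotype": {
        "thresholds": dict,
        "scale_direction": str,
        "overlap_min_offset_px": _NUM,
        "membrane_ring_px": int,
    },
    "montecarlo": {
        "enabled": bool,
        "n_iter": int,
        "pairs": (str, list),
    },
}

_REQUIRED = ("out_dir", "inputs")


def _validate(node: dict, schema: dict, pointer: str) -> None:
    for key, value in node.items():
        ptr = f"{pointer}/{key}"
        if key not in schema:
            raise ConfigError(f"unknown key at {ptr}")
        expected = schema[key]
        if isinstance(expected, dict):
            if not isinstance(value, dict):
                raise ConfigError(f"expected object at {ptr}")
            _validate(value, expected, ptr)
        elif expected is dict:
            if not isinstance(value, dict):
                raise ConfigError(f"expected object at {ptr}")
            for st, tv in value.items():
                if not isinstance(tv, _NUM):
                    raise ConfigError(f"expected number at {ptr}/{st}")
        elif not isinstance(value, expected) or (
            expected is int and isinstance(value, bool)
        ):
            raise ConfigError(f"wrong type at {ptr}")


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.raw, dict):
            raise ConfigError("config root must be an object")
        _validate(self.raw, _SCHEMA, "")
        for req in _REQUIRED:
            if req not in self.raw:
                raise ConfigError(f"missing required key /{req}")
        inputs = self.raw["inputs"]
        if "roi" not in inputs:
            raise ConfigError("missing required key /inputs/roi")
        if "cube" not in inputs and "cells" not in inputs:
            raise ConfigError("need /inputs/cube or /inputs/cells")

    @property
    def out_dir(self) -> Path:
        return Path(self.raw["out_dir"])

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    def section(self, name: str) -> dict:
        return dict(self.raw.get(name, {}))

    def input_path(self, name: str) -> Path | None:
        p = self.raw["inputs"].get(name)
        return Path(p) if p is not None else None


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig(json.load(fh))
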