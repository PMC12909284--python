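"""YAML configuration loading, resolved-config dumps, and logging setup.

Every CLI run resolves its configuration (file values merged over package
defaults merged over command-line overrides) into a plain dict and writes it
next to the outputs as ``resolved_config.json`` so a run can be repeated
exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from pathlib import Path
from typing import Any, Mapping

import yaml

LOG_FORMAT = "%(asctime)s %(levelname)s %(name)s: %(message)s"

logger = logging.getLogger("gsoelm")


def setup_logging(level: str = "INFO") -> None:
    """Configure the package logger to write plain-text logs to stderr."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter(LOG_FORMAT))
    root = logging.getLogger("gsoelm")
    root.handlers[:] = [handler]
    root.setLevel(getattr(logging, level.upper(), logging.INFO))


def load_yaml_config(path: str | Path | None) -> dict[str, Any]:
    """Read a YAML config file; ``None`` or a missing section yields ``{}``."""
    if path is None:
        return {}
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping at top level")
    return data


def merge_config(base: Mapping[str, Any], override: Mapping[str, Any]) -> dict[str, Any]:
    """Recursively merge ``override`` on top of ``base`` (dicts only)."""
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), Mapping):
            out[key] = merge_config(out[key], value)
        else:
            out[key] = value
    return out


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "tolist"):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    return obj


def dump_resolved_config(config: Mapping[str, Any], out_dir: str | Path) -> Path:
    """Write the fully resolved configuration as JSON for reproducibility."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "resolved_config.json"
    path.write_text(json.dumps(_jsonable(config), indent=2, sort_keys=True) + "\n")
    return path
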