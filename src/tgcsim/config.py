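"""JSON configuration loading/saving and the run manifest."""

from __future__ import annotations

import json
import os
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path

from pydantic import ValidationError

from .patient import PatientParams
from .protocol import TrialConfig

__all__ = [
    "ConfigError",
    "load_config",
    "save_config",
    "load_cohort",
    "save_cohort",
    "RunManifest",
    "write_manifest",
]


class ConfigError(ValueError):
    """Schema violation in a configuration file; lists offending keys."""

    def __init__(self, message: str, keys: list[str]):
        super().__init__(message)
        self.keys = keys


def _validation_keys(exc: ValidationError) -> list[str]:
    keys = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        keys.append(loc)
    return sorted(set(keys))


def load_config(path: str | Path) -> TrialConfig:
    """Load and validate a trial configuration.

    Missing fields take their defaults (an empty JSON object yields the
    full default protocol); unknown keys are rejected.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = json.load(fh)
    try:
        return TrialConfig.model_validate(raw)
    except ValidationError as exc:
        keys = _validation_keys(exc)
        raise ConfigError(
            f"invalid configuration in {path}: offending keys {keys}", keys
        ) from exc


def save_config(config: TrialConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(config.model_dump_json(indent=2))
        fh.write("\n")


def load_cohort(path: str | Path) -> list[PatientParams]:
    """Load a cohort (list of patient-parameter objects) from JSON."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = json.load(fh)
    if not isinstance(raw, list):
        raise ConfigError("cohort file must contain a JSON list", ["<root>"])
    try:
        return [PatientParams.model_validate(item) for item in raw]
    except ValidationError as exc:
        keys = _validation_keys(exc)
        raise ConfigError(f"invalid cohort in {path}: offending keys {keys}", keys) from exc


def save_cohort(cohort: list[PatientParams], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([p.model_dump() for p in cohort], fh, indent=2)
        fh.write("\n")


@dataclass
class RunManifest:
    """Reproducibility record written at the end of a CLI run."""

    seed: int
    software_version: str
    config: dict
    outputs: list[str] = field(default_factory=list)
    wall_time_s: float = 0.0
    created_unix: float = field(default_factory=time.time)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "software_version": self.software_version,
            "config": self.config,
            "outputs": self.outputs,
            "wall_time_s": self.wall_time_s,
            "created_unix": self.created_unix,
        }


def write_manifest(manifest: RunManifest, path: str | Path) -> None:
    """Write the manifest atomically (temp file + rename)."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            json.dump(manifest.to_dict(), fh, indent=2)
            fh.write("\n")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
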