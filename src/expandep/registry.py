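"""Bundled electrode-model registry and user-supplied model files."""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Union

import yaml

from .errors import ConfigurationError
from .geometry import ElectrodeSpec

__all__ = ["ModelPreset", "available_models", "get_model", "load_model_file"]


@dataclass(frozen=True)
class ModelPreset:
    """An electrode spec plus the planning defaults tied to that variant."""

    name: str
    spec: ElectrodeSpec
    voltage_granularity_V: int
    default_pulse_count: int
    default_target_field_V_per_cm: float
    default_regime: str
    description: str = ""


def _preset_from_entry(name: str, entry: dict) -> ModelPreset:
    try:
        spec = ElectrodeSpec(name=name, **entry["spec"])
        return ModelPreset(
            name=name,
            spec=spec,
            voltage_granularity_V=int(entry["voltage_granularity_V"]),
            default_pulse_count=int(entry["default_pulse_count"]),
            default_target_field_V_per_cm=float(entry["default_target_field_V_per_cm"]),
            default_regime=str(entry["default_regime"]),
            description=str(entry.get("description", "")).strip(),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"malformed model entry {name!r}: {exc}") from exc


def _bundled() -> dict[str, ModelPreset]:
    text = resources.files("expandep.data").joinpath("models.yaml").read_text()
    raw = yaml.safe_load(text)
    return {name: _preset_from_entry(name, entry) for name, entry in raw.items()}


def available_models() -> tuple[str, ...]:
    """Names of the bundled electrode variants."""
    return tuple(_bundled())


def load_model_file(path: Union[str, Path]) -> ModelPreset:
    """Load a single-model YAML file using the bundled schema.

    The file may either be a bare entry (spec + planning defaults) or a
    one-entry mapping of name -> entry.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"model file {path} does not contain a mapping")
    if "spec" in raw:
        return _preset_from_entry(path.stem, raw)
    if len(raw) == 1:
        name, entry = next(iter(raw.items()))
        return _preset_from_entry(name, entry)
    raise ConfigurationError(
        f"model file {path} must contain one model entry, found {len(raw)}"
    )


def get_model(name_or_path: Union[str, Path]) -> ModelPreset:
    """Resolve a bundled model name or a path to a model YAML file."""
    name = str(name_or_path)
    bundled = _bundled()
    if name in bundled:
        return bundled[name]
    if Path(name).exists():
        return load_model_file(name)
    raise ConfigurationError(
        f"unknown electrode model {name!r}; bundled models: {', '.join(bundled)}"
    )
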