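"""Run configuration: TOML config files with command-line overrides.

A config file is flat TOML whose keys are the model parameter names
(``rfd0``, ``kappa``, ``alpha``, ``d0``, ``d_max``).  Values given on the
command line override the file; omissions fall back to the weightlifter
defaults.  Unknown keys warn rather than error so a config can carry a
coach's own annotations.
"""

from __future__ import annotations

import tomllib
import warnings
from dataclasses import dataclass
from pathlib import Path

from .model import InterferenceParams

__all__ = ["RunConfig", "ConfigError", "load_params", "COMMANDS", "FORMATS"]

PARAM_KEYS = ("rfd0", "kappa", "alpha", "d0", "d_max")
COMMANDS = ("predict", "table", "sweep-alpha", "sweep-kappa", "curves", "compare")
FORMATS = ("csv", "json")


class ConfigError(ValueError):
    """A config file could not be parsed or validated."""


def load_params(
    config_path: str | Path | None = None, **overrides: float | None
) -> InterferenceParams:
    """Build model parameters from an optional TOML file plus overrides.

    ``overrides`` entries that are None are treated as "not given".
    Precedence: explicit override > config file > default.
    """
    values: dict[str, float] = {}
    if config_path is not None:
        try:
            with open(config_path, "rb") as fh:
                raw = tomllib.load(fh)
        except tomllib.TOMLDecodeError as err:  # message carries line/column
            raise ConfigError(f"malformed config {config_path}: {err}") from err
        for key, val in raw.items():
            if key in PARAM_KEYS:
                values[key] = float(val)
            else:
                warnings.warn(f"ignoring unknown config key {key!r}", stacklevel=2)
    for key, val in overrides.items():
        if key not in PARAM_KEYS:
            raise ConfigError(f"unknown parameter {key!r}")
        if val is not None:
            values[key] = float(val)
    return InterferenceParams(**values)


@dataclass(frozen=True)
class RunConfig:
    """A fully resolved CLI invocation."""

    params: InterferenceParams
    command: str
    durations: tuple[float, ...] = ()
    output_path: str | None = None  # None -> standard output
    output_format: str = "csv"
    verbosity: int = 0

    def __post_init__(self) -> None:
        if self.command not in COMMANDS:
            raise ConfigError(f"unknown command {self.command!r}; expected one of {COMMANDS}")
        if self.output_format not in FORMATS:
            raise ConfigError(
                f"unknown output format {self.output_format!r}; expected one of {FORMATS}"
            )
        if not self.durations:
            raise ConfigError(f"command {self.command!r} requires at least one duration")
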