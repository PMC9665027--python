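"""Engine parameter set.

All tunables of the immune core and pathology layer live in one flat
key -> value block.  The shipped defaults are read from the versioned
parameter file ``data/engine_defaults.yaml``; patient-specific overrides
(from the calibration table) and user overrides are applied on top.
"""

from __future__ import annotations

from importlib import resources
from typing import Any, Mapping

import yaml

__all__ = ["EngineParams", "load_default_params", "ParameterError"]


class ParameterError(KeyError):
    """Unknown parameter name in an override block."""


def _load_defaults() -> dict[str, Any]:
    ref = resources.files("rrmsim.data").joinpath("engine_defaults.yaml")
    with ref.open("r") as fh:
        raw = yaml.safe_load(fh)
    raw.pop("version", None)
    return raw


_DEFAULTS: dict[str, Any] | None = None


def load_default_params() -> dict[str, Any]:
    """The shipped default parameter block (cached copy)."""
    global _DEFAULTS
    if _DEFAULTS is None:
        _DEFAULTS = _load_defaults()
    return dict(_DEFAULTS)


class EngineParams:
    """Flat parameter namespace with attribute access.

    Construct via :meth:`with_overrides`; unknown keys raise
    :class:`ParameterError` so calibration-table typos fail loudly.
    """

    def __init__(self, values: Mapping[str, Any]):
        self.__dict__.update(values)

    @classmethod
    def with_overrides(cls, *override_blocks: Mapping[str, Any] | None) -> "EngineParams":
        values = load_default_params()
        for block in override_blocks:
            if not block:
                continue
            for key, val in block.items():
                if key not in values:
                    raise ParameterError(f"unknown engine parameter: {key!r}")
                values[key] = val
        return cls(values)

    def as_dict(self) -> dict[str, Any]:
        return dict(self.__dict__)

    # derived conveniences -------------------------------------------------

    @property
    def n_sites(self) -> int:
        return self.grid_side * self.grid_side

    def days(self, n_days: float) -> int:
        """Convert days to whole timesteps."""
        return int(round(n_days * self.steps_per_day))

    def __repr__(self) -> str:  # pragma: no cover
        return f"EngineParams({len(self.__dict__)} values)"
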