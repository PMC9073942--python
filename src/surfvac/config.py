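"""Structured-text (YAML) run configuration with strict validation.

Unknown keys are rejected with their dotted location; a fully resolved copy
(defaults filled in) is written next to any outputs so every reported number
is regenerable from the manifest.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .bias import PROTOCOL_PRESETS, BiasProtocol
from .errors import ConfigurationError
from .grids import GridSpec
from .mechanism import Region, StatePartition, default_partition
from .model_systems import LangevinParams, PotentialModel, make_potential

_SCHEMA = {
    "potential": {"name", "params"},
    "langevin": {"timestep", "temperature", "diffusion", "n_steps", "stride", "seed"},
    "protocol": {"preset", "widths", "height0", "bias_factor", "pace"},
    "grid": {"mins", "maxs", "bins", "periodic"},
    "mfi": {"bandwidth", "mask_threshold"},
    "work": {"commitment", "mode"},
    "classify": {"min_dwell", "commitment"},
    "partition": None,  # free-form: region name -> {cv: [lo, hi]}
}

_DEFAULTS = {
    "potential": {"name": "double_well_1d", "params": {}},
    "langevin": {
        "timestep": 0.005,
        "temperature": 1.0,
        "diffusion": 1.0,
        "n_steps": 200_000,
        "stride": 25,
        "seed": 0,
    },
    "protocol": {"preset": "toy1d"},
    "grid": {"mins": [-1.6], "maxs": [1.6], "bins": [161], "periodic": [False]},
    "mfi": {"bandwidth": 0.03, "mask_threshold": 1e-6},
    "work": {"commitment": 10, "mode": "detachment"},
    "classify": {"min_dwell": 5, "commitment": 10},
}


def _check_keys(data: dict, allowed, where: str):
    unknown = set(data) - set(allowed)
    if unknown:
        key = sorted(unknown)[0]
        raise ConfigurationError(
            f"unknown configuration key '{where}{key}'; valid keys here: "
            f"{sorted(allowed)}"
        )


@dataclass
class RunConfig:
    """Validated, fully-resolved run configuration."""

    raw: dict

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise ConfigurationError("configuration root must be a mapping")
        _check_keys(data, _SCHEMA, "")
        resolved = {}
        for section, defaults in _DEFAULTS.items():
            got = data.get(section, {})
            if not isinstance(got, dict):
                raise ConfigurationError(f"section '{section}' must be a mapping")
            _check_keys(got, _SCHEMA[section], f"{section}.")
            merged = dict(defaults)
            merged.update(got)
            resolved[section] = merged
        if "partition" in data:
            part = data["partition"]
            if not isinstance(part, dict):
                raise ConfigurationError("section 'partition' must be a mapping")
            resolved["partition"] = part
        cfg = cls(resolved)
        # eager construction surfaces bad values at load time
        cfg.potential()
        cfg.langevin()
        cfg.protocol()
        cfg.grid()
        cfg.partition()
        return cfg

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.raw, fh, sort_keys=True)

    # -- builders -----------------------------------------------------------
    def potential(self) -> PotentialModel:
        p = self.raw["potential"]
        return make_potential(p["name"], **(p["params"] or {}))

    def langevin(self, seed=None) -> LangevinParams:
        p = dict(self.raw["langevin"])
        if seed is not None:
            p["seed"] = seed
        return LangevinParams(
            timestep=p["timestep"],
            n_steps=int(p["n_steps"]),
            stride=int(p["stride"]),
            temperature=p["temperature"],
            diffusion=p["diffusion"],
            seed=int(p["seed"]),
        )

    def protocol(self) -> BiasProtocol:
        p = dict(self.raw["protocol"])
        preset = p.pop("preset", None)
        if preset is not None:
            if preset not in PROTOCOL_PRESETS:
                raise ConfigurationError(
                    f"unknown protocol preset {preset!r}; valid: "
                    f"{sorted(PROTOCOL_PRESETS)}"
                )
            base = dict(PROTOCOL_PRESETS[preset])
            base.update(p)
            p = base
        missing = {"widths", "height0", "bias_factor", "pace"} - set(p)
        if missing:
            raise ConfigurationError(f"protocol is missing keys {sorted(missing)}")
        return BiasProtocol(**p)

    def grid(self) -> GridSpec:
        g = self.raw["grid"]
        return GridSpec(
            tuple(g["mins"]), tuple(g["maxs"]), tuple(g["bins"]), tuple(g["periodic"])
        )

    def partition(self) -> StatePartition:
        if "partition" not in self.raw:
            return default_partition(self.raw["potential"]["name"])
        pot = self.potential()
        regions = {}
        for name, boxes in self.raw["partition"].items():
            if not isinstance(boxes, dict):
                raise ConfigurationError(
                    f"partition.{name} must map CV names to [lo, hi] pairs"
                )
            _check_keys(boxes, pot.cv_names, f"partition.{name}.")
            intervals = []
            for d, cv in enumerate(pot.cv_names):
                if cv in boxes:
                    lo, hi = boxes[cv]
                else:
                    lo, hi = pot.lo[d], pot.hi[d]
                intervals.append((float(lo), float(hi)))
            regions[name] = Region(tuple(intervals))
        return StatePartition(regions, periodic=pot.periodic)
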