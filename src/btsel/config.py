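"""Pipeline configuration: one master seed, lossless YAML round trip.

Stage seeds are derived from the master seed through a counter-based
``numpy.random.SeedSequence`` scheme so that each stage (landscape,
individuals, fates, observations, tracks, model, selection) can be rerun
independently yet reproducibly.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .hmodel import ModelSpec
from .landscape import (
    LandscapeSpec,
    georgia_landscape_spec,
    south_carolina_landscape_spec,
)
from .simulate import (
    GEORGIA,
    SOUTH_CAROLINA,
    SeasonCalendar,
    SimulationParams,
    TraitParams,
    default_calendars,
)

STAGE_INDEX = {
    "landscape": 0,
    "individuals": 1,
    "fates": 2,
    "observations": 3,
    "tracks": 4,
    "model": 5,
    "selection": 6,
}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2^31)."""
    ss = np.random.SeedSequence([int(master_seed), STAGE_INDEX[stage]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), STAGE_INDEX[stage]])
    )


@dataclass
class SelectionOptions:
    flip_risk: bool = True
    refit_subsets: bool = False
    max_failed_frac: float = 0.05


@dataclass
class PipelineConfig:
    seed: int = 0
    landscape: dict[str, LandscapeSpec] = field(
        default_factory=lambda: {
            GEORGIA: georgia_landscape_spec(),
            SOUTH_CAROLINA: south_carolina_landscape_spec(),
        }
    )
    simulation: SimulationParams = field(default_factory=SimulationParams)
    calendars: dict[str, SeasonCalendar] = field(default_factory=default_calendars)
    model: ModelSpec = field(default_factory=ModelSpec)
    selection: SelectionOptions = field(default_factory=SelectionOptions)
    write_tracks: bool = True
    schedule: dict[str, str] = field(
        default_factory=lambda: {GEORGIA: "hourly", SOUTH_CAROLINA: "30min"}
    )

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: convert(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [convert(v) for v in obj]
            if isinstance(obj, dt.date):
                return obj.isoformat()
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        return convert(
            {
                "seed": self.seed,
                "landscape": self.landscape,
                "simulation": self.simulation,
                "calendars": self.calendars,
                "model": self.model,
                "selection": self.selection,
                "write_tracks": self.write_tracks,
                "schedule": self.schedule,
            }
        )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def build(dc_type, data, **casts):
            fields = {f.name for f in dataclasses.fields(dc_type)}
            unknown = set(data) - fields
            if unknown:
                raise KeyError(
                    f"unknown {dc_type.__name__} key(s): {sorted(unknown)}"
                )
            kwargs = {}
            for k, v in data.items():
                kwargs[k] = casts[k](v) if k in casts else v
            return dc_type(**kwargs)

        cfg = cls()
        out = {}
        out["seed"] = int(d.get("seed", 0))
        if "landscape" in d:
            out["landscape"] = {
                pop: build(LandscapeSpec, spec,
                           shape=tuple, origin=tuple)
                for pop, spec in d["landscape"].items()
            }
        if "simulation" in d:
            sim = dict(d["simulation"])
            if "traits" in sim:
                sim["traits"] = {
                    t: build(TraitParams, tp) for t, tp in sim["traits"].items()
                }
            if sim.get("bt_correlation") is not None:
                sim["bt_correlation"] = np.asarray(sim["bt_correlation"], dtype=float)
            out["simulation"] = build(SimulationParams, sim)
        if "calendars" in d:
            out["calendars"] = {
                pop: build(
                    SeasonCalendar, c,
                    hunt_open=dt.date.fromisoformat,
                    hunt_close=dt.date.fromisoformat,
                )
                for pop, c in d["calendars"].items()
            }
        if "model" in d:
            model = dict(d["model"])
            if model.get("fix_variances") is not None:
                model["fix_variances"] = tuple(model["fix_variances"])
            out["model"] = build(ModelSpec, model)
        if "selection" in d:
            out["selection"] = build(SelectionOptions, d["selection"])
        out["write_tracks"] = bool(d.get("write_tracks", cfg.write_tracks))
        out["schedule"] = dict(d.get("schedule", cfg.schedule))
        return cls(**out)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()
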