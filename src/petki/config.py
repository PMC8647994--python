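"""Run configuration: acquisition schedules, population tail model,
sampling/SUV times and VOI parameters, with JSON override support."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .frames import (
    FramingSchedule,
    long_protocol_schedule,
    short_early_schedule,
    short_late_schedule,
)
from .kinetics import MonoexpParams

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Defaults follow the clinical protocol this package implements:
    45-min venous sample, SUV at 55 min, population tail
    (a, b, c) = (9.684, 16.410, 0.068 1/min), hottest-5-voxels VOI over
    three consecutive slices."""

    population_tail: MonoexpParams = MonoexpParams(a=9.684, b=16.410, c=0.068)
    blood_sample_time_min: float = 45.0
    suv_time_min: float = 55.0
    voi_n_per_slice: int = 5
    voi_n_slices: int = 3
    voi_mode: str = "per_slice"
    noise_scale: float = 0.0
    seed: int = 0
    schedule_long: FramingSchedule = field(default_factory=long_protocol_schedule)
    schedule_short_early: FramingSchedule = field(default_factory=short_early_schedule)
    schedule_short_late: FramingSchedule = field(default_factory=short_late_schedule)

    @staticmethod
    def from_json(path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        kwargs = {}
        if "population_tail" in data:
            kwargs["population_tail"] = MonoexpParams(**data.pop("population_tail"))
        for key in ("schedule_long", "schedule_short_early", "schedule_short_late"):
            if key in data:
                kwargs[key] = FramingSchedule(tuple(map(tuple, data.pop(key))))
        valid = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        kwargs.update(data)
        return RunConfig(**kwargs)

    def manifest(self) -> dict:
        """JSON-serialisable record of the configuration for run logs."""
        import petki

        return {
            "petki_version": petki.__version__,
            "population_tail": dataclasses.asdict(self.population_tail),
            "blood_sample_time_min": self.blood_sample_time_min,
            "suv_time_min": self.suv_time_min,
            "voi": {
                "n_per_slice": self.voi_n_per_slice,
                "n_slices": self.voi_n_slices,
                "mode": self.voi_mode,
            },
            "noise_scale": self.noise_scale,
            "seed": self.seed,
        }
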