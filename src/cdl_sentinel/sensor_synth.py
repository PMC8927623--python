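"""Synthetic sensor streams for the monitoring case study.

Each sensor has a documented normal range; baseline readings are drawn
from a truncated normal centered on the sensor's typical value with a
spread of 10% of the range width, so an unscheduled stream never leaves
its normal range (and therefore never raises an alert).  Anomalies are
injected exactly at scheduled ticks, either as absolute values or as
offsets from the baseline mean.

Default specs encode the case study's published thresholds: heart rate
60-100 bpm (typically 82), body temperature 97-99 °F, ECG interval
0.6-1.2 s, EMG amplitude 50 µV - 30 mV, EEG >= 8 Hz normal with <= 7 Hz
abnormal in awake adults, and household CO 0.5-5 ppm typical (5-15 ppm
with a properly fixed gas stove, >= 30 ppm alert-worthy).  Blood pressure,
CO2 and room temperature have no published thresholds in the source case
study; their defaults follow common clinical/indoor norms and are marked
``non_paper`` in the spec metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from scipy.stats import truncnorm

__all__ = [
    "AnomalySchedule",
    "ScheduledAnomaly",
    "SensorReading",
    "SensorSpec",
    "default_specs",
    "generate_stream",
    "inject_contradiction",
    "specs_by_kind",
]


@dataclass(frozen=True)
class SensorReading:
    sensor: str
    value: float
    unit: str
    tick: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"{self.sensor}: non-finite reading value")
        if self.tick < 0:
            raise ValueError(f"{self.sensor}: tick must be >= 0")


@dataclass
class SensorSpec:
    """A sensor kind with units, normal range and baseline distribution."""

    kind: str
    unit: str
    normal_range: tuple[float, float]
    baseline_mean: float
    baseline_sd: Optional[float] = None  # default: 10% of range width
    context_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.normal_range
        if lo > hi:
            raise ValueError(f"{self.kind}: normal range lo > hi")
        if not lo <= self.baseline_mean <= hi:
            raise ValueError(f"{self.kind}: baseline mean outside normal range")
        if self.baseline_sd is None:
            self.baseline_sd = 0.1 * (hi - lo)


@dataclass(frozen=True)
class ScheduledAnomaly:
    tick: int
    sensor: str
    value: Optional[float] = None
    offset: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.value is None) == (self.offset is None):
            raise ValueError(
                f"scheduled anomaly for {self.sensor!r} at tick {self.tick}: "
                "exactly one of value/offset required"
            )
        target = self.value if self.value is not None else self.offset
        if not math.isfinite(target):
            raise ValueError("scheduled anomaly value must be finite")


@dataclass(frozen=True)
class AnomalySchedule:
    entries: tuple[ScheduledAnomaly, ...] = ()

    def __post_init__(self) -> None:
        if not isinstance(self.entries, tuple):
            object.__setattr__(self, "entries", tuple(self.entries))

    def for_sensor(self, kind: str) -> dict[int, ScheduledAnomaly]:
        return {e.tick: e for e in self.entries if e.sensor == kind}

    def max_tick(self) -> int:
        return max((e.tick for e in self.entries), default=-1)


def default_specs() -> list[SensorSpec]:
    """The ten-sensor roster of the monitored smart home / smart hospital."""
    return [
        SensorSpec(
            "systolic_bp", "mmHg", (90.0, 120.0), 110.0,
            context_id="smart_hospital",
            metadata={"non_paper": True, "note": "clinical norm 120/80 mmHg"},
        ),
        SensorSpec(
            "diastolic_bp", "mmHg", (60.0, 80.0), 75.0,
            context_id="smart_hospital",
            metadata={"non_paper": True, "note": "clinical norm 120/80 mmHg"},
        ),
        SensorSpec(
            "body_temperature", "F", (97.0, 99.0), 98.2,
            context_id="smart_hospital",
        ),
        SensorSpec(
            "heart_rate", "bpm", (60.0, 100.0), 82.0,
            context_id="smart_hospital",
        ),
        SensorSpec(
            "eeg_frequency", "Hz", (8.0, 30.0), 10.0,
            context_id="smart_hospital",
            metadata={
                "abnormal_max_hz": 7.0,
                "note": "<= 7 Hz abnormal in awake adults; upper bound is a "
                "non_paper beta-band cap",
            },
        ),
        SensorSpec(
            "ecg_interval", "s", (0.6, 1.2), 0.9,
            context_id="smart_hospital",
        ),
        SensorSpec(
            "emg_amplitude", "mV", (0.05, 30.0), 5.0,
            context_id="smart_hospital",
            metadata={
                "amplitude_range": "50 uV - 30 mV",
                "frequency_criterion_hz": 7.0,
                "note": "source text also states a 7 Hz frequency criterion "
                "for EMG (apparently describing EEG); kept as labeled "
                "metadata, not silently corrected",
            },
        ),
        SensorSpec(
            "co", "ppm", (0.5, 15.0), 3.0,
            context_id="smart_home",
            metadata={
                "typical_range_ppm": (0.5, 5.0),
                "properly_fixed_stove_ppm": (5.0, 15.0),
                "alert_threshold_ppm": 30.0,
            },
        ),
        SensorSpec(
            "co2", "ppm", (350.0, 1000.0), 600.0,
            context_id="smart_home",
            metadata={"non_paper": True, "note": "indoor air-quality norm"},
        ),
        SensorSpec(
            "room_temperature", "C", (18.0, 27.0), 22.0,
            context_id="smart_home",
            metadata={"non_paper": True, "note": "comfortable indoor range"},
        ),
    ]


def specs_by_kind(
    specs: Optional[Iterable[SensorSpec]] = None,
) -> dict[str, SensorSpec]:
    return {s.kind: s for s in (specs if specs is not None else default_specs())}


def generate_stream(
    spec: SensorSpec,
    ticks: int,
    seed: Union[int, Sequence[int]],
    schedule: Optional[AnomalySchedule] = None,
) -> list[SensorReading]:
    """One reading per tick; scheduled ticks take the scheduled value
    verbatim, all others draw from the truncated baseline distribution.
    Identical (spec, ticks, seed, schedule) gives an identical stream.
    """
    if ticks <= 0:
        raise ValueError("ticks must be > 0")
    schedule = schedule or AnomalySchedule()
    scheduled = schedule.for_sensor(spec.kind)
    out_of_range = [t for t in scheduled if not 0 <= t < ticks]
    if out_of_range:
        raise ValueError(
            f"{spec.kind}: schedule ticks {sorted(out_of_range)} outside "
            f"run length {ticks}"
        )
    lo, hi = spec.normal_range
    rng = np.random.default_rng(seed)
    if spec.baseline_sd and hi > lo:
        a = (lo - spec.baseline_mean) / spec.baseline_sd
        b = (hi - spec.baseline_mean) / spec.baseline_sd
        baseline = truncnorm.rvs(
            a, b, loc=spec.baseline_mean, scale=spec.baseline_sd,
            size=ticks, random_state=rng,
        )
        baseline = np.clip(baseline, lo, hi)
    else:
        baseline = np.full(ticks, spec.baseline_mean)
    readings = []
    for tick in range(ticks):
        if tick in scheduled:
            entry = scheduled[tick]
            value = (
                entry.value
                if entry.value is not None
                else spec.baseline_mean + entry.offset
            )
        else:
            value = float(baseline[tick])
        readings.append(SensorReading(spec.kind, float(value), spec.unit, tick))
    return readings


def inject_contradiction(
    streams: Mapping[str, Sequence[SensorReading]],
    specs: Mapping[str, SensorSpec],
    tick: int,
    pair: tuple[tuple[str, float], tuple[str, float]],
) -> dict[str, list[SensorReading]]:
    """Force two sensors in *different* contexts to given values at one
    tick, so downstream context theories derive complementary literals and
    the MCS must invoke contextual defeasible resolution.

    Returns a modified copy of ``streams``.
    """
    (kind_a, value_a), (kind_b, value_b) = pair
    for kind in (kind_a, kind_b):
        if kind not in streams:
            raise ValueError(f"no stream for sensor {kind!r}")
        if kind not in specs:
            raise ValueError(f"no spec for sensor {kind!r}")
        if not 0 <= tick < len(streams[kind]):
            raise ValueError(f"tick {tick} outside stream for {kind!r}")
    if specs[kind_a].context_id == specs[kind_b].context_id:
        raise ValueError(
            f"sensors {kind_a!r} and {kind_b!r} share context "
            f"{specs[kind_a].context_id!r}; a cross-context contradiction "
            "needs two contexts"
        )
    result = {k: list(v) for k, v in streams.items()}
    for kind, value in ((kind_a, value_a), (kind_b, value_b)):
        old = result[kind][tick]
        result[kind][tick] = SensorReading(kind, float(value), old.unit, tick)
    return result
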