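"""Driving-behavior features from per-second vehicle sensor traces.

The study cars logged high-frequency CAN signals (speed, steering wheel,
pedals); the analysis variables summarize each trip: the share of seconds
spent turning the wheel, the share spent braking, the hourly rate of sudden
events (super-threshold acceleration or steering excursions, found with
SciPy's peak detection), the flow (actual over permissible speed), trip
length and average speed. A scenario generator with injected episodes gives
every extractor a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "SignalTrace",
    "simulate_signals",
    "steering_ratio",
    "braking_ratio",
    "count_sudden_events",
    "flow",
    "trip_length",
    "mean_speed",
    "extract_features",
]

# default thresholds; the study names a "prespecified threshold" without
# printing it, so these are reproducible stand-ins, all configurable
ACCEL_THRESHOLD = 2.5  # m/s^2
STEER_RATE_THRESHOLD = 90.0  # deg/s, sudden steering
TURNING_RATE_THRESHOLD = 2.0  # deg/s, "is turning the wheel" for steering ratio
MIN_SEPARATION = 2.0  # s, peaks closer than this merge into one event

KMH_TO_MS = 1.0 / 3.6


@dataclass(frozen=True)
class SignalTrace:
    """Per-second trip telemetry at the canonical 1 Hz sampling.

    ``speed`` and ``speed_limit`` in km/h, ``steering_angle`` in degrees,
    ``brake_engaged`` boolean. ``ground_truth`` carries the generator's
    injected quantities when the trace is synthetic.
    """

    speed: np.ndarray
    steering_angle: np.ndarray
    brake_engaged: np.ndarray
    speed_limit: np.ndarray
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arrays = {
            "speed": np.asarray(self.speed, dtype=float),
            "steering_angle": np.asarray(self.steering_angle, dtype=float),
            "brake_engaged": np.asarray(self.brake_engaged, dtype=bool),
            "speed_limit": np.asarray(self.speed_limit, dtype=float),
        }
        lengths = {k: len(v) for k, v in arrays.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"series lengths differ: {lengths}")
        if lengths["speed"] < 1:
            raise ValueError("trace must span at least 1 second")
        for k, v in arrays.items():
            object.__setattr__(self, k, v)

    @property
    def duration(self) -> int:
        """Trip duration in seconds (1 Hz sampling)."""
        return len(self.speed)

    @property
    def accel(self) -> np.ndarray:
        """Longitudinal acceleration in m/s^2 at the n-1 second transitions."""
        return np.diff(self.speed * KMH_TO_MS)

    @property
    def steering_rate(self) -> np.ndarray:
        """Steering-wheel angular rate in deg/s at the n-1 transitions."""
        return np.diff(self.steering_angle)

    # -- serialization (long-format CSV: second, channel, value) -----------

    def to_frame(self) -> pd.DataFrame:
        secs = np.arange(self.duration)
        frames = []
        for channel in ("speed", "steering_angle", "brake_engaged", "speed_limit"):
            frames.append(
                pd.DataFrame(
                    {
                        "second": secs,
                        "channel": channel,
                        "value": np.asarray(getattr(self, channel), dtype=float),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, hz: float = 1.0) -> "SignalTrace":
        """Read a long-format trace; higher-rate input is averaged per second."""
        channels = {}
        for channel, grp in df.groupby("channel"):
            vals = grp.sort_values("second")["value"].to_numpy(float)
            if hz > 1:
                step = int(round(hz))
                n = len(vals) // step * step
                vals = vals[:n].reshape(-1, step).mean(axis=1)
            channels[channel] = vals
        return cls(
            speed=channels["speed"],
            steering_angle=channels["steering_angle"],
            brake_engaged=channels["brake_engaged"] > 0.5,
            speed_limit=channels["speed_limit"],
        )

    @classmethod
    def from_csv(cls, path, hz: float = 1.0) -> "SignalTrace":
        return cls.from_frame(pd.read_csv(path), hz=hz)


def simulate_signals(trip_params: dict, seed: int = 0) -> SignalTrace:
    """Synthesize a trip trace with injected, counted episodes.

    ``trip_params`` keys (all optional except duration):

    - ``duration``: seconds (required, >= 1)
    - ``cruise_speed`` (km/h, default 50), ``speed_limit`` (default 50)
    - ``speed_noise``: SD of smooth km/h jitter (default 0, kept far below
      the sudden-event threshold)
    - ``braking_seconds``: seconds with the brake engaged (default 0)
    - ``turning_seconds``: seconds with the wheel turning at a moderate,
      sub-threshold rate (default 0)
    - ``n_sudden_events``: injected super-threshold steering spikes
      (default 0), spaced far apart so each is one ground-truth event
    - ``standstill_seconds``: seconds at speed 0 appended at the trip end

    The returned trace's ``ground_truth`` maps each extractor to the value
    it should recover by construction.
    """
    duration = int(trip_params.get("duration", 0))
    if duration < 1:
        raise ValueError("duration must be at least 1 second")
    rng = np.random.default_rng(seed)
    cruise = float(trip_params.get("cruise_speed", 50.0))
    limit = float(trip_params.get("speed_limit", 50.0))
    noise = float(trip_params.get("speed_noise", 0.0))
    braking_seconds = int(trip_params.get("braking_seconds", 0))
    turning_seconds = int(trip_params.get("turning_seconds", 0))
    n_events = int(trip_params.get("n_sudden_events", 0))
    standstill = int(trip_params.get("standstill_seconds", 0))
    if braking_seconds > duration or standstill > duration:
        raise ValueError("episode lengths cannot exceed the trip duration")
    if turning_seconds >= duration:
        raise ValueError("turning_seconds must leave at least one quiet second")

    speed = np.full(duration, cruise)
    if noise > 0:
        # smooth jitter: cumulative small steps; per-second speed changes are
        # N(0, noise) km/h, i.e. ~noise/3.6 m/s^2, far below the sudden-event
        # threshold for any sensible noise level
        steps = rng.normal(0.0, noise, size=duration).cumsum()
        steps -= np.linspace(steps[0], steps[-1], duration)
        speed = np.clip(speed + steps, 0.0, None)
    if standstill:
        # decelerate gradually (1.5 m/s^2 = 5.4 km/h per second) so the stop
        # never registers as a sudden acceleration event
        ramp_rate = 5.4
        t0 = duration - standstill
        for t in range(t0, duration):
            speed[t] = max(speed[t - 1] - ramp_rate, 0.0) if t > 0 else 0.0
    speed_limit = np.full(duration, limit)

    brake = np.zeros(duration, dtype=bool)
    brake[:braking_seconds] = True

    # moderate turning: alternate the wheel at half the turning threshold's
    # tenfold (well below the sudden-steer threshold, above the turning one)
    angle = np.zeros(duration)
    rate = 2.0 * TURNING_RATE_THRESHOLD
    sign = 1.0
    for t in range(1, turning_seconds + 1):
        if t < duration:
            angle[t] = angle[t - 1] + sign * rate
            sign = -sign
    for t in range(turning_seconds + 1, duration):
        angle[t] = angle[t - 1]

    # sudden steering spikes: a single-second jerk of 2x the sudden-steer
    # threshold, returning the next second; the return flank is closer than
    # the merge window, so each spike is exactly one ground-truth event
    gap = max(int(3 * MIN_SEPARATION) + 2, 8)
    start = turning_seconds + 4
    if n_events and start + n_events * gap >= duration:
        raise ValueError("trace too short for the requested number of events")
    spike = 2.0 * STEER_RATE_THRESHOLD
    for k in range(n_events):
        t = start + k * gap
        angle[t:] += spike
        angle[t + 1 :] -= spike

    # each injected spike has an up and a down flank, so it contributes two
    # turning seconds on top of the moderate-turning episode
    transitions = max(duration - 1, 1)
    gt = {
        "braking_ratio": braking_seconds / duration,
        "steering_ratio": (turning_seconds + 2 * n_events) / transitions,
        "n_sudden_events": n_events,
        "sudden_events_per_hour": n_events / (duration / 3600.0),
        "trip_length": float(duration),
        "mean_speed": float(speed.mean()),
    }
    if noise == 0 and standstill == 0:
        gt["flow"] = min(cruise / limit, 1.0)
    return SignalTrace(
        speed=speed,
        steering_angle=angle,
        brake_engaged=brake,
        speed_limit=speed_limit,
        ground_truth=gt,
    )


# ---------------------------------------------------------------------------
# extractors


def steering_ratio(
    trace: SignalTrace, angle_rate_threshold: float = TURNING_RATE_THRESHOLD
) -> float:
    """Share of the trip in which the driver is turning the wheel.

    A second counts as turning when the wheel angle changes by more than
    ``angle_rate_threshold`` degrees over it; the share is taken over the
    n - 1 second-to-second transitions of the trace.
    """
    rate = trace.steering_rate
    if rate.size == 0:
        return 0.0
    return float((np.abs(rate) > angle_rate_threshold).mean())


def braking_ratio(trace: SignalTrace) -> float:
    """Share of trip seconds with the brake pedal engaged."""
    return float(trace.brake_engaged.mean())


def _threshold_peaks(series: np.ndarray, threshold: float) -> np.ndarray:
    # pad so spikes at the trace boundary register as local maxima
    padded = np.concatenate([[0.0], np.abs(series), [0.0]])
    peaks, _ = find_peaks(padded, height=threshold)
    return peaks - 1


def count_sudden_events(
    trace: SignalTrace,
    accel_threshold: float = ACCEL_THRESHOLD,
    steer_threshold: float = STEER_RATE_THRESHOLD,
    min_separation: float = MIN_SEPARATION,
) -> float:
    """Hourly rate of sudden acceleration/steering excursions.

    Local maxima of |acceleration| and |steering rate| above their
    thresholds are detected per channel (SciPy peak detection); peak times
    across both channels closer than ``min_separation`` seconds are merged
    into a single event. The count is normalized by trip hours.
    """
    if accel_threshold <= 0 or steer_threshold <= 0:
        raise ValueError("thresholds must be positive")
    times = np.concatenate(
        [
            _threshold_peaks(trace.accel, accel_threshold),
            _threshold_peaks(trace.steering_rate, steer_threshold),
        ]
    )
    times.sort()
    events = 0
    last = -np.inf
    for t in times:
        if t - last >= min_separation:
            events += 1
        last = t
    hours = trace.duration / 3600.0
    return events / hours


def flow(trace: SignalTrace) -> float:
    """Mean per-second ratio of actual to permissible speed, capped at 1.

    Speeding does not raise flow above 1 (the denominator is the potential
    maximum); a zero limit with nonzero speed is an error, a standstill
    second with zero limit contributes 0.
    """
    speed, limit = trace.speed, trace.speed_limit
    bad = (limit <= 0) & (speed > 0)
    if bad.any():
        raise ValueError(f"zero speed limit with nonzero speed at {bad.sum()} second(s)")
    ratio = np.zeros_like(speed)
    ok = limit > 0
    ratio[ok] = np.minimum(speed[ok] / limit[ok], 1.0)
    return float(ratio.mean())


def trip_length(trace: SignalTrace) -> float:
    """Trip duration in seconds."""
    return float(trace.duration)


def mean_speed(trace: SignalTrace) -> float:
    """Average speed over the trip in km/h."""
    return float(trace.speed.mean())


def extract_features(trace: SignalTrace, **kwargs) -> dict[str, float]:
    """All trip features as one row, keyed by the study's variable names."""
    return {
        "steering": steering_ratio(
            trace, kwargs.get("angle_rate_threshold", TURNING_RATE_THRESHOLD)
        ),
        "braking": braking_ratio(trace),
        "sudden_events": count_sudden_events(
            trace,
            kwargs.get("accel_threshold", ACCEL_THRESHOLD),
            kwargs.get("steer_threshold", STEER_RATE_THRESHOLD),
            kwargs.get("min_separation", MIN_SEPARATION),
        ),
        "length": trip_length(trace),
        "speed": mean_speed(trace),
        "flow": flow(trace),
    }
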