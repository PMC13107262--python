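"""Acoustic tag firmware specifications.

Accelerometer/depth transmitters of the V13AP/V13TP class fire at random
intervals (uniform between a minimum and maximum delay), alternate 1:1
between their two sensors, and transmit a single smoothed acceleration
value: the mean of tri-axial samples taken at ``sample_hz`` over a
``window_len``-second listening window.  The transmitted value is clipped
to the tag's dynamic range, so the ceiling ``accel_max`` acts as a
right-censoring threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TagSpec",
    "STANDARD_TAG",
    "HIGH_RATE_TAG",
    "TAG_SPECS",
    "censor_value",
]


@dataclass(frozen=True)
class TagSpec:
    """Transmission protocol and sensor range of one tag model.

    Parameters
    ----------
    name
        Identifier used in fish metadata tables (``tag_spec_name`` column).
    delay_min, delay_max
        Bounds (seconds) of the uniform random inter-transmission delay.
    accel_max
        Ceiling of the transmitted acceleration (m/s^2); values at or above
        it are reported as exactly this value (right censoring).
    accel_min
        Floor of the transmitted acceleration, 0 m/s^2 on these tags.
    window_len
        Length (s) of the on-tag accelerometer sampling window.
    sample_hz
        On-tag sampling frequency (Hz) within the window.
    alternate_sensors
        Whether successive transmissions alternate depth/accel (1:1).
    high_rate
        Marks tag models transmitting ~5x more often than the standard
        protocol; their detections are thinned downstream.
    """

    name: str
    delay_min: float
    delay_max: float
    accel_max: float
    accel_min: float = 0.0
    window_len: float = 25.0
    sample_hz: float = 12.5
    alternate_sensors: bool = True
    high_rate: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.delay_min <= self.delay_max):
            raise ValueError("need 0 < delay_min <= delay_max")
        if self.accel_max <= 0:
            raise ValueError("accel_max must be positive")
        if self.window_len * self.sample_hz <= 1:
            raise ValueError("sampling window must contain more than one sample")

    @property
    def mean_delay(self) -> float:
        """Expected inter-transmission interval (s)."""
        return 0.5 * (self.delay_min + self.delay_max)

    @property
    def n_samples(self) -> int:
        """Number of accelerometer samples in one smoothing window."""
        return int(round(self.window_len * self.sample_hz))

    @property
    def accel_resolution(self) -> float:
        """Quantisation step of the transmitted 8-bit acceleration value."""
        return self.accel_max / 255.0


#: Standard protocol used 2019-2023: 200-300 s delays, 3.43 m/s^2 ceiling.
STANDARD_TAG = TagSpec("standard", delay_min=200.0, delay_max=300.0, accel_max=3.43)

#: 2024 protocol: 40-60 s delays (~5x rate), 4.9 m/s^2 ceiling.
HIGH_RATE_TAG = TagSpec(
    "high-rate-2024", delay_min=40.0, delay_max=60.0, accel_max=4.9, high_rate=True
)

TAG_SPECS: dict[str, TagSpec] = {t.name: t for t in (STANDARD_TAG, HIGH_RATE_TAG)}


def censor_value(a, tag: TagSpec):
    """Apply the tag's dynamic range to a smoothed acceleration value.

    Values at or above ``tag.accel_max`` are reported as exactly the
    ceiling; values below ``tag.accel_min`` as the floor.  Accepts scalars
    or arrays; NaN input raises.
    """
    arr = np.asarray(a, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("cannot censor NaN acceleration values")
    out = np.clip(arr, tag.accel_min, tag.accel_max)
    if np.ndim(a) == 0:
        return float(out)
    return out
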