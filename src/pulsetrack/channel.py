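"""Time-stamped single-channel sensor streams.

A :class:`SignalChannel` holds one stream of samples (PPG or one
accelerometer axis) with timestamps in seconds since session start and a
nominal sampling rate. Channels are the lingua franca of the pipeline:
preprocessing consumes and produces them, windowing slices them, and the
CSV interchange format (`time_s,value`) maps onto them one-to-one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = ["SignalChannel", "read_channel_csv", "write_channel_csv"]


@dataclass
class SignalChannel:
    """One time-stamped sample stream.

    Parameters
    ----------
    times
        Sample timestamps in seconds, strictly increasing.
    values
        Sensor readings (dimensionless a.u.), same length as ``times``.
    nominal_rate
        Nominal sampling rate in Hz (> 0). For non-uniform raw streams this
        is the advertised device rate; after resampling it is exact.
    label
        Channel name, conventionally ``ppg`` or ``acc_x``/``acc_y``/``acc_z``.
    """

    times: np.ndarray
    values: np.ndarray
    nominal_rate: float
    label: str = "ppg"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ConfigurationError("times and values must be 1-D and equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ConfigurationError(f"timestamps of {self.label!r} must be strictly increasing")
        if not self.nominal_rate > 0:
            raise ConfigurationError("nominal_rate must be positive")

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        """Span covered by the channel, in seconds."""
        if self.times.size == 0:
            return 0.0
        return float(self.times[-1] - self.times[0])

    @classmethod
    def from_uniform(
        cls,
        values: np.ndarray,
        rate: float,
        t0: float = 0.0,
        label: str = "ppg",
    ) -> "SignalChannel":
        """Build a channel on a uniform grid starting at ``t0``."""
        values = np.asarray(values, dtype=float)
        times = t0 + np.arange(values.size) / rate
        return cls(times=times, values=values, nominal_rate=rate, label=label)

    def replace_values(self, values: np.ndarray) -> "SignalChannel":
        """Same grid and metadata, new sample values."""
        return SignalChannel(
            times=self.times.copy(),
            values=np.asarray(values, dtype=float),
            nominal_rate=self.nominal_rate,
            label=self.label,
        )


def read_channel_csv(path, rate: float, label: str = "ppg") -> SignalChannel:
    """Read a `time_s,value` CSV into a channel with the given nominal rate."""
    df = pd.read_csv(path)
    if not {"time_s", "value"}.issubset(df.columns):
        raise ConfigurationError(f"{path}: expected columns 'time_s,value'")
    return SignalChannel(
        times=df["time_s"].to_numpy(dtype=float),
        values=df["value"].to_numpy(dtype=float),
        nominal_rate=rate,
        label=label,
    )


def write_channel_csv(channel: SignalChannel, path) -> None:
    """Write a channel as a `time_s,value` CSV."""
    pd.DataFrame({"time_s": channel.times, "value": channel.values}).to_csv(path, index=False)
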