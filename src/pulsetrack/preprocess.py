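"""Raw-signal conditioning: outlier repair, bandpass, resampling, smoothing.

The PPG stream from a wearable carries negative dropouts and large positive
spikes from contact loss, slow baseline wander from respiration and
perfusion changes, and broadband sensor noise. This module implements the
cleaning chain applied before any spectral analysis:

1.  Outlier rule — a sample ``p[n]`` is an outlier when ``p[n] < 0`` or
    ``p[n] > mu+ + 3*sigma+``, where ``mu+`` and ``sigma+`` are the mean and
    (population) standard deviation of the strictly positive samples of the
    whole channel. Flagged samples are repaired by linear interpolation
    between the nearest valid neighbours (edge runs take the nearest valid
    value).
2.  Bandpass — 5th-order Butterworth with −3 dB edges at 0.5 and 5 Hz,
    applied forward-backward (zero phase), so the effective magnitude
    response is 10th order.
3.  Resampling — the stream is first mapped onto a uniformly spaced axis
    spanning its original timestamps, then cubic-interpolated onto a new
    uniform grid at the target rate, so PPG and accelerometer channels end
    up on a common grid.
4.  Smoothing — a 7-point median filter followed by a 3-point centred
    moving average, with edge-value replication so constants pass through
    unchanged.

Accelerometer channels are signed, so the positivity-based outlier rule does
not apply to them; they receive resampling only.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, signal
from scipy.interpolate import interp1d

from .channel import SignalChannel
from .errors import ConfigurationError, DegenerateChannelError

__all__ = [
    "detect_outliers",
    "repair_outliers",
    "bandpass",
    "resample_uniform",
    "smooth",
    "preprocess_ppg",
    "preprocess_acc",
]


def detect_outliers(channel: SignalChannel, ddof: int = 0) -> np.ndarray:
    """Flag negative samples and samples above ``mu+ + 3*sigma+``.

    The statistics are computed once over the strictly positive samples of
    the whole channel (not per window). ``ddof=0`` selects the population
    standard deviation; pass ``ddof=1`` for the sample convention.

    Returns a boolean mask, True where the sample is an outlier.

    Raises
    ------
    DegenerateChannelError
        If the channel is empty or contains no positive sample.
    """
    v = channel.values
    if v.size == 0:
        raise DegenerateChannelError("empty channel")
    pos = v[v > 0]
    if pos.size == 0:
        raise DegenerateChannelError("no positive samples; outlier statistics undefined")
    mu = float(np.mean(pos))
    sd = float(np.std(pos, ddof=ddof))
    return (v < 0) | (v > mu + 3.0 * sd)


def repair_outliers(channel: SignalChannel, mask: np.ndarray) -> SignalChannel:
    """Replace flagged samples by linear interpolation between valid neighbours.

    Flagged runs at either end of the channel take the value of the nearest
    valid sample (constant extension). Unflagged samples are untouched.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != channel.values.shape:
        raise ConfigurationError("mask length must match the channel")
    if mask.all():
        raise DegenerateChannelError("all samples flagged; nothing to interpolate from")
    if not mask.any():
        return channel.replace_values(channel.values)
    valid = ~mask
    # np.interp clamps outside the valid support, giving edge extension free.
    repaired = channel.values.copy()
    repaired[mask] = np.interp(
        channel.times[mask], channel.times[valid], channel.values[valid]
    )
    return channel.replace_values(repaired)


def bandpass(
    channel: SignalChannel,
    low_hz: float = 0.5,
    high_hz: float = 5.0,
    order: int = 5,
) -> SignalChannel:
    """Zero-phase Butterworth bandpass (default 0.5–5 Hz, order 5).

    Applied forward-backward with reflective padding of three times the
    effective filter order, so pulse peaks keep their timing and the first
    samples of the record stay usable.
    """
    rate = channel.nominal_rate
    if rate <= 2 * high_hz:
        raise ConfigurationError(
            f"sampling rate {rate} Hz too low for a {high_hz} Hz passband edge"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=rate, output="sos")
    padlen = min(channel.values.size - 1, 3 * 2 * order)
    filtered = signal.sosfiltfilt(sos, channel.values, padtype="odd", padlen=padlen)
    return channel.replace_values(filtered)


def resample_uniform(channel: SignalChannel, target_rate: float) -> SignalChannel:
    """Cubic resampling onto a uniform grid at ``target_rate``.

    Two steps: the original samples are first reassigned to a uniformly
    spaced axis spanning ``[times[0], times[-1]]`` with the original sample
    count (absorbing device timestamp jitter), then cubic-interpolated onto
    the new uniform grid over the same span.
    """
    if not target_rate > 0:
        raise ConfigurationError("target_rate must be positive")
    n = channel.values.size
    if n < 4:
        raise DegenerateChannelError("cubic resampling needs at least 4 samples")
    t0, t1 = channel.times[0], channel.times[-1]
    uniform_axis = np.linspace(t0, t1, n)
    new_times = t0 + np.arange(int(np.floor((t1 - t0) * target_rate)) + 1) / target_rate
    interp = interp1d(uniform_axis, channel.values, kind="cubic", assume_sorted=True)
    return SignalChannel(
        times=new_times,
        values=interp(new_times),
        nominal_rate=target_rate,
        label=channel.label,
    )


def smooth(
    channel: SignalChannel, median_kernel: int = 7, mavg_window: int = 3
) -> SignalChannel:
    """Median filter (kernel 7) followed by a centred moving average (width 3).

    Edges are handled by replicating the edge value, which keeps constant
    signals exactly constant.
    """
    if channel.values.size < median_kernel:
        raise DegenerateChannelError(
            f"need at least {median_kernel} samples for the median filter"
        )
    med = ndimage.median_filter(channel.values, size=median_kernel, mode="nearest")
    avg = ndimage.uniform_filter1d(med, size=mavg_window, mode="nearest")
    return channel.replace_values(avg)


def preprocess_ppg(
    channel: SignalChannel,
    target_rate: float,
    low_hz: float = 0.5,
    high_hz: float = 5.0,
    order: int = 5,
) -> SignalChannel:
    """Outlier repair → bandpass → resample, the session-level PPG chain.

    Median/moving-average smoothing is applied later, per analysis window.
    """
    mask = detect_outliers(channel)
    repaired = repair_outliers(channel, mask)
    filtered = bandpass(repaired, low_hz=low_hz, high_hz=high_hz, order=order)
    return resample_uniform(filtered, target_rate)


def preprocess_acc(channel: SignalChannel, target_rate: float) -> SignalChannel:
    """Accelerometer chain: resampling onto the common grid only."""
    return resample_uniform(channel, target_rate)
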