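"""Synthetic PPG + accelerometer sessions with known ground truth.

The generator emulates the spectral structure the pipeline consumes during
ambulatory recording: a cardiac tone at the instantaneous HR frequency with
a weaker second harmonic, a cadence-locked motion-artifact tone shared
between the PPG and all three accelerometer axes, slow baseline wander,
additive Gaussian noise, and occasional negative dropout spikes that
trigger the outlier rule. Instantaneous HR and cadence follow piecewise
linear trajectories, and phases are accumulated by trapezoidal integration
of the instantaneous frequency so time-varying rates stay phase-continuous.

Default parameters reproduce the hardest illustrative condition the
pipeline is designed for: a 5-minute session at the smart-ring rates
(PPG 182 Hz, accelerometer 52 Hz) with HR 112.8 bpm (1.88 Hz), step cadence
2.8 Hz, and a motion artifact three times the cardiac amplitude, so the
strongest PPG spectral peak is the artifact, not the heart.

The generator makes no attempt at morphological realism (no dicrotic
notch, no pulse-shape variability): the pipeline is spectral, and spectral
structure is what is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .channel import SignalChannel
from .errors import ConfigurationError
from .tracking import HrEstimate, HrTrace

__all__ = ["SimulationConfig", "SyntheticSession", "simulate", "truth_on_windows"]

Trajectory = tuple[tuple[float, float], ...]


@dataclass
class SimulationConfig:
    """Knobs of the session generator.

    Trajectories are piecewise-linear ``((t_s, value), ...)`` breakpoints;
    a single breakpoint means a constant. HR is in bpm (30–300), cadence in
    steps/s (0.5–5 Hz, i.e. inside the analysis band). Amplitudes are in
    arbitrary sensor units; ``dc_offset`` shifts the PPG positive, as raw
    photodiode counts are, so the positivity-based outlier rule applies.
    ``outlier_rate`` is the fraction of PPG samples replaced by negative
    dropout spikes.
    """

    duration_s: float = 300.0
    ppg_rate: float = 182.0
    acc_rate: float = 52.0
    hr_trajectory: Trajectory = ((0.0, 112.8),)
    cadence_trajectory: Trajectory = ((0.0, 2.8),)
    cardiac_amp: float = 1.0
    cardiac_harmonic_amp: float = 0.3
    ma_amp: float = 3.0
    acc_amp: float = 1.0
    wander_amp: float = 0.5
    wander_freq: float = 0.25
    noise_sd: float = 0.2
    outlier_rate: float = 0.01
    dc_offset: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.ppg_rate <= 0 or self.acc_rate <= 0:
            raise ConfigurationError("duration and rates must be positive")
        hr_vals = [v for _, v in self.hr_trajectory]
        cad_vals = [v for _, v in self.cadence_trajectory]
        if not all(30.0 <= v <= 300.0 for v in hr_vals):
            raise ConfigurationError("HR trajectory must stay within 30-300 bpm")
        if not all(0.5 <= v <= 5.0 for v in cad_vals):
            raise ConfigurationError("cadence trajectory must stay within 0.5-5 Hz")
        for amp in (self.cardiac_amp, self.cardiac_harmonic_amp, self.ma_amp,
                    self.acc_amp, self.wander_amp, self.noise_sd):
            if amp < 0:
                raise ConfigurationError("amplitudes must be non-negative")
        if not 0.0 <= self.outlier_rate <= 0.1:
            raise ConfigurationError("outlier_rate must be in [0, 0.1]")
        if not self.wander_freq < 0.5:
            raise ConfigurationError("baseline wander must be below 0.5 Hz")


@dataclass
class SyntheticSession:
    """Generated channels plus the ground-truth HR trace on the 2 s grid."""

    ppg: SignalChannel
    acc_x: SignalChannel
    acc_y: SignalChannel
    acc_z: SignalChannel
    truth: HrTrace

    @property
    def acc_channels(self) -> tuple[SignalChannel, SignalChannel, SignalChannel]:
        return (self.acc_x, self.acc_y, self.acc_z)


def _traj_eval(traj: Trajectory, t: np.ndarray) -> np.ndarray:
    knots_t = np.array([p[0] for p in traj])
    knots_v = np.array([p[1] for p in traj])
    return np.interp(t, knots_t, knots_v)


def _phase(freq_hz: np.ndarray, t: np.ndarray) -> np.ndarray:
    """2*pi * integral of the instantaneous frequency (trapezoidal)."""
    return 2.0 * np.pi * cumulative_trapezoid(freq_hz, t, initial=0.0)


def simulate(config: SimulationConfig) -> SyntheticSession:
    """Generate one session; bitwise reproducible for a fixed seed."""
    rng = np.random.default_rng(config.seed)

    t_ppg = np.arange(int(round(config.duration_s * config.ppg_rate))) / config.ppg_rate
    t_acc = np.arange(int(round(config.duration_s * config.acc_rate))) / config.acc_rate

    hr_hz = _traj_eval(config.hr_trajectory, t_ppg) / 60.0
    ph_hr = _phase(hr_hz, t_ppg)
    ph_cad_ppg = _phase(_traj_eval(config.cadence_trajectory, t_ppg), t_ppg)
    ppg = (
        config.dc_offset
        + config.cardiac_amp * np.sin(ph_hr)
        + config.cardiac_harmonic_amp * np.sin(2.0 * ph_hr)
        + config.ma_amp * np.sin(ph_cad_ppg)
        + config.wander_amp * np.sin(2.0 * np.pi * config.wander_freq * t_ppg)
        + rng.normal(0.0, config.noise_sd, t_ppg.size)
    )
    if config.outlier_rate > 0:
        n_out = int(round(config.outlier_rate * t_ppg.size))
        if n_out:
            where = rng.choice(t_ppg.size, size=n_out, replace=False)
            ppg[where] = -config.dc_offset * rng.uniform(0.5, 1.5, n_out)

    ph_cad_acc = _phase(_traj_eval(config.cadence_trajectory, t_acc), t_acc)
    axes = []
    for name, offset in (("acc_x", 0.0), ("acc_y", 2 * np.pi / 3), ("acc_z", 4 * np.pi / 3)):
        vals = (
            config.acc_amp * np.sin(ph_cad_acc + offset)
            + 0.5 * config.acc_amp * np.sin(2.0 * ph_cad_acc + offset)
            + rng.normal(0.0, config.noise_sd, t_acc.size)
        )
        axes.append(SignalChannel(times=t_acc, values=vals,
                                  nominal_rate=config.acc_rate, label=name))

    grid = 2.0 * np.arange(int(config.duration_s // 2) + 1)
    truth = HrTrace(t=grid, hr=_traj_eval(config.hr_trajectory, grid))

    return SyntheticSession(
        ppg=SignalChannel(times=t_ppg, values=ppg,
                          nominal_rate=config.ppg_rate, label="ppg"),
        acc_x=axes[0], acc_y=axes[1], acc_z=axes[2],
        truth=truth,
    )


def truth_on_windows(
    session: SyntheticSession,
    config: SimulationConfig,
    window_s: float = 8.0,
    shift_s: float = 2.0,
) -> list[HrEstimate]:
    """Reference HR as the trajectory mean over each sliding window.

    Mirrors the ECG ground-truth convention (mean HR over 8 s windows at a
    2 s shift), anchored at window start.
    """
    n_win = int(np.floor((config.duration_s - window_s) / shift_s)) + 1
    if n_win < 1:
        raise ConfigurationError("session shorter than one window")
    out = []
    for i in range(n_win):
        t0 = i * shift_s
        tt = np.linspace(t0, t0 + window_s, 201)
        mean_hr = float(np.trapezoid(_traj_eval(config.hr_trajectory, tt), tt) / window_s)
        out.append(HrEstimate(t=t0, hr=mean_hr))
    return out
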