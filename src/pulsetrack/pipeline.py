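"""End-to-end session orchestration: channels in, smoothed HR trace out.

``run_pipeline`` wires the stages together exactly once, with every
parameter drawn from a single :class:`~pulsetrack.config.PipelineConfig`
applied unchanged across sessions:

    PPG: outlier repair → bandpass → cubic resample ┐
    accelerometer axes: cubic resample ─────────────┤
                                                    ├→ per-window smoothing,
                                                    │  Welch PSDs, candidate
                                                    │  frequencies, masking,
                                                    │  HR readout
                                                    └→ SAB-HRT tracking
"""

from __future__ import annotations

import logging

import numpy as np

from .channel import SignalChannel
from .config import PipelineConfig
from .errors import DegenerateChannelError, InsufficientDataError
from .preprocess import preprocess_acc, preprocess_ppg, smooth
from .spectral import (
    candidate_motion_frequencies,
    estimate_window_hr,
    mask_ppg_spectrum,
    welch_psd,
)
from .tracking import HrEstimate, HrTrace, track
from .windows import sliding_windows

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "estimate_windows"]


def _window_psd(win: SignalChannel, cfg: PipelineConfig, label: str):
    return welch_psd(
        win.values,
        rate=win.nominal_rate,
        seg_len=cfg.welch_seg_len,
        overlap=cfg.welch_overlap,
        grid_hz=cfg.welch_grid_hz,
        band=(cfg.band_low_hz, cfg.band_high_hz),
        label=label,
    )


def estimate_windows(
    ppg: SignalChannel,
    acc_x: SignalChannel,
    acc_y: SignalChannel,
    acc_z: SignalChannel,
    config: PipelineConfig | None = None,
) -> list[HrEstimate]:
    """Preprocess and run the spectral stage, one HR estimate per window.

    Channels may arrive at different rates; all are resampled onto the
    common grid first. Windows that fail preprocessing or retain no valid
    spectral peak yield missing estimates.
    """
    cfg = config or PipelineConfig()
    ppg_u = preprocess_ppg(
        ppg,
        target_rate=cfg.target_rate_hz,
        low_hz=cfg.bandpass_low_hz,
        high_hz=cfg.bandpass_high_hz,
        order=cfg.bandpass_order,
    )
    accs_u = [preprocess_acc(a, target_rate=cfg.target_rate_hz) for a in (acc_x, acc_y, acc_z)]

    spec = cfg.window_spec
    ppg_wins = sliding_windows(ppg_u, spec)
    acc_wins = [sliding_windows(a, spec) for a in accs_u]
    n_win = min(len(ppg_wins), *(len(w) for w in acc_wins))

    estimates: list[HrEstimate] = []
    for i in range(n_win):
        t0 = float(ppg_wins[i].times[0])
        try:
            ppg_smoothed = smooth(
                ppg_wins[i], median_kernel=cfg.median_kernel, mavg_window=cfg.mavg_window
            )
            ppg_psd = _window_psd(ppg_smoothed, cfg, "ppg")
            acc_psds = [_window_psd(w[i], cfg, w[i].label) for w in acc_wins]
        except (DegenerateChannelError, InsufficientDataError) as exc:
            logger.debug("window %d (t=%.1f s): no estimate (%s)", i, t0, exc)
            estimates.append(HrEstimate(t=t0, hr=None))
            continue
        candidates = candidate_motion_frequencies(*acc_psds)
        masked = mask_ppg_spectrum(
            ppg_psd,
            candidates,
            halfwidth_hz=cfg.mask_halfwidth_hz,
            plateau_frac=cfg.mask_plateau_frac,
            highcut_frac=cfg.mask_highcut_frac,
        )
        hr = estimate_window_hr(masked)
        logger.debug(
            "window %d (t=%.1f s): F=%s -> hr=%s", i, t0,
            np.round(candidates.freqs, 3).tolist(), hr,
        )
        estimates.append(HrEstimate(t=t0, hr=hr))
    return estimates


def run_pipeline(
    ppg: SignalChannel,
    acc_x: SignalChannel,
    acc_y: SignalChannel,
    acc_z: SignalChannel,
    config: PipelineConfig | None = None,
) -> HrTrace:
    """Full pipeline: preprocessing, spectral HR, SAB-HRT tracking.

    Deterministic: identical inputs and configuration give a byte-identical
    trace. Raises :class:`InsufficientDataError` when the session is too
    short to fill a tracking block or every window came back missing.
    """
    cfg = config or PipelineConfig()
    estimates = estimate_windows(ppg, acc_x, acc_y, acc_z, cfg)
    if not any(e.present for e in estimates):
        raise InsufficientDataError("spectral stage produced no HR estimate")
    return track(
        estimates,
        block_len=cfg.track_block_len,
        threshold=cfg.track_threshold_bpm,
        extension_len=cfg.track_extension_len,
        max_extensions=cfg.track_max_extensions,
        smooth_window_s=cfg.track_smooth_window_s,
        grid_step_s=cfg.window_shift_s,
    )
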