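"""Per-window spectral HR extraction with accelerometer-guided masking.

Motion artifacts in wrist/finger PPG are periodic at the step cadence and
its harmonics, and those same frequencies dominate the accelerometer
spectra. Each analysis window is therefore handled in four steps:

1.  Welch PSD of the PPG window and of each accelerometer axis, on a dense
    common frequency grid restricted to the 0.5–5 Hz analysis band.
2.  Candidate motion frequencies ``F``: the union of the two highest PSD
    peaks per accelerometer axis (at most six, duplicates merged).
3.  Masking of the PPG spectrum: bins within ±0.1 Hz of any candidate are
    invalid; around each PPG peak so removed, contiguous bins whose power
    is within 5 % of that peak's power are invalidated too (plateau
    extension); and when ``F`` is non-empty everything above 5 % beyond
    ``max(F)`` is invalid.
4.  HR readout: the highest-power valid local maximum gives
    ``HR = 60 * f_peak`` (bpm). If masking leaves no valid peak, the window
    yields a missing estimate, to be filled by the tracking stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import ConfigurationError, InsufficientDataError

__all__ = [
    "PsdSpectrum",
    "SpectralPeak",
    "CandidateSet",
    "MaskedSpectrum",
    "welch_psd",
    "top_peaks",
    "candidate_motion_frequencies",
    "mask_ppg_spectrum",
    "estimate_window_hr",
]


@dataclass
class PsdSpectrum:
    """Power spectral density on a uniform frequency grid (analysis band only)."""

    freqs: np.ndarray  # Hz, uniform spacing
    power: np.ndarray  # units^2/Hz, >= 0
    label: str = ""

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape or self.freqs.ndim != 1:
            raise ConfigurationError("freqs and power must be 1-D and equal length")

    @property
    def grid_step(self) -> float:
        return float(self.freqs[1] - self.freqs[0]) if self.freqs.size > 1 else 0.0


@dataclass(frozen=True)
class SpectralPeak:
    """A local PSD maximum pinned to a grid bin."""

    freq: float
    power: float
    bin_index: int


@dataclass
class CandidateSet:
    """Deduplicated motion-artifact candidate frequencies (|F| <= 6)."""

    freqs: np.ndarray = field(default_factory=lambda: np.empty(0))
    bins: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.bins = np.asarray(self.bins, dtype=int)

    def __len__(self) -> int:
        return self.freqs.size

    @property
    def max_freq(self) -> float:
        return float(self.freqs.max()) if len(self) else np.nan


@dataclass
class MaskedSpectrum:
    """A PPG spectrum plus a per-bin validity flag after artifact masking."""

    base: PsdSpectrum
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.base.freqs.shape:
            raise ConfigurationError("valid mask must match the spectrum grid")


def _next_pow2(n: int) -> int:
    return 1 << (int(n) - 1).bit_length()


def welch_psd(
    window_samples: np.ndarray,
    rate: float,
    seg_len: int = 256,
    overlap: float = 0.5,
    grid_hz: float = 0.01,
    band: tuple[float, float] = (0.5, 5.0),
    label: str = "",
) -> PsdSpectrum:
    """Welch PSD of one analysis window, restricted to the analysis band.

    Hann segments of ``min(seg_len, N)`` samples at 50 % overlap; the FFT is
    zero-padded so the frequency grid spacing is at most ``grid_hz`` (the
    ±0.1 Hz masking rule then spans at least ten bins and the 5 %-relative
    plateau comparison is meaningful).
    """
    x = np.asarray(window_samples, dtype=float)
    if x.size < 2 * rate:
        raise InsufficientDataError("window shorter than 2 s; no spectrum")
    nperseg = min(seg_len, x.size)
    nfft = _next_pow2(int(np.ceil(rate / grid_hz)))
    freqs, power = signal.welch(
        x,
        fs=rate,
        window="hann",
        nperseg=nperseg,
        noverlap=int(nperseg * overlap),
        nfft=max(nfft, nperseg),
        detrend="constant",
    )
    keep = (freqs >= band[0]) & (freqs <= band[1])
    return PsdSpectrum(freqs=freqs[keep], power=power[keep], label=label)


def top_peaks(spectrum: PsdSpectrum, k: int) -> list[SpectralPeak]:
    """The ``k`` highest local maxima, by power, descending.

    A peak is a bin strictly greater than both neighbours; band-edge bins
    cannot be peaks. Ties in power are broken toward the lower frequency.
    Fewer than ``k`` peaks are returned when fewer exist.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    p = spectrum.power
    if p.size < 3:
        return []
    idx = np.where((p[1:-1] > p[:-2]) & (p[1:-1] > p[2:]))[0] + 1
    order = sorted(idx, key=lambda i: (-p[i], spectrum.freqs[i]))
    return [
        SpectralPeak(freq=float(spectrum.freqs[i]), power=float(p[i]), bin_index=int(i))
        for i in order[:k]
    ]


def candidate_motion_frequencies(
    acc_x: PsdSpectrum, acc_y: PsdSpectrum, acc_z: PsdSpectrum
) -> CandidateSet:
    """Union of the top-2 PSD peak frequencies per accelerometer axis.

    Duplicates (peaks landing on the same grid bin across axes) are merged,
    so the set holds at most six frequencies. Flat axes contribute nothing;
    an empty set is legal and disables masking downstream.
    """
    spectra = (acc_x, acc_y, acc_z)
    grid = spectra[0].freqs
    for s in spectra[1:]:
        if s.freqs.shape != grid.shape or not np.allclose(s.freqs, grid):
            raise ConfigurationError("accelerometer spectra must share one frequency grid")
    bins: dict[int, float] = {}
    for s in spectra:
        for peak in top_peaks(s, k=2):
            bins.setdefault(peak.bin_index, peak.freq)
    order = sorted(bins)
    return CandidateSet(freqs=np.array([bins[b] for b in order]), bins=np.array(order))


def mask_ppg_spectrum(
    ppg: PsdSpectrum,
    candidates: CandidateSet,
    halfwidth_hz: float = 0.1,
    plateau_frac: float = 0.05,
    highcut_frac: float = 0.05,
) -> MaskedSpectrum:
    """Invalidate PPG spectral bins attributable to motion.

    Rules, applied in order:

    1. every bin within ``halfwidth_hz`` of any candidate frequency is
       invalid;
    2. for each PPG local maximum removed by rule 1, contiguous neighbouring
       bins whose power is within ``plateau_frac`` of that peak's power
       (relative, either side) are also invalidated, walking outward until
       the first failing bin;
    3. when the candidate set is non-empty, every bin with frequency above
       ``(1 + highcut_frac) * max(F)`` is invalid;
    4. an empty candidate set leaves the spectrum untouched.
    """
    n = ppg.freqs.size
    valid = np.ones(n, dtype=bool)
    if len(candidates) == 0:
        return MaskedSpectrum(base=ppg, valid=valid)

    eps = 1e-12
    rule1 = np.zeros(n, dtype=bool)
    for f in candidates.freqs:
        rule1 |= np.abs(ppg.freqs - f) <= halfwidth_hz + eps
    valid &= ~rule1

    for peak in top_peaks(ppg, k=n):  # all local maxima
        if not rule1[peak.bin_index]:
            continue
        pw = peak.power
        for step in (-1, 1):
            j = peak.bin_index + step
            while 0 <= j < n and abs(ppg.power[j] - pw) <= plateau_frac * pw + eps:
                valid[j] = False
                j += step

    valid &= ~(ppg.freqs > (1.0 + highcut_frac) * candidates.max_freq + eps)
    return MaskedSpectrum(base=ppg, valid=valid)


def estimate_window_hr(masked: MaskedSpectrum) -> float | None:
    """HR (bpm) from the highest-power valid local maximum, or None.

    ``HR = 60 * f_peak``, rounded to the nearest 0.1 bpm. Ties between
    equal-power valid peaks go to the lower frequency. When masking leaves
    no valid local maximum the window has no estimate; the tracking stage
    interpolates across such gaps.
    """
    peaks = [p for p in top_peaks(masked.base, k=masked.base.freqs.size)
             if masked.valid[p.bin_index]]
    if not peaks:
        return None
    best = min(peaks, key=lambda p: (-p.power, p.freq))
    return round(60.0 * best.freq, 1)
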