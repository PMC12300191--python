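"""One-size-fits-all pipeline configuration.

All defaults are the parameter set applied unchanged across recordings —
the method's premise is that no subject- or dataset-specific tuning is
needed. The YAML layout mirrors the stage structure::

    bandpass: {low_hz: 0.5, high_hz: 5.0, order: 5}
    smooth:   {median_kernel: 7, mavg_window: 3}
    resample: {target_rate_hz: 32.0}
    welch:    {seg_len: 256, overlap: 0.5, grid_hz: 0.01}
    band:     {low_hz: 0.5, high_hz: 5.0}
    mask:     {halfwidth_hz: 0.1, plateau_frac: 0.05, highcut_frac: 0.05}
    window:   {length_s: 8.0, shift_s: 2.0}
    track:    {block_len: 20, threshold_bpm: 10.0, extension_len: 10,
               max_extensions: 3, smooth_window_s: 30.0}
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import yaml

from .errors import ConfigurationError
from .windows import WindowSpec

__all__ = ["PipelineConfig"]

# flat attribute name <-> (yaml section, yaml key)
_YAML_MAP = {
    "bandpass_low_hz": ("bandpass", "low_hz"),
    "bandpass_high_hz": ("bandpass", "high_hz"),
    "bandpass_order": ("bandpass", "order"),
    "median_kernel": ("smooth", "median_kernel"),
    "mavg_window": ("smooth", "mavg_window"),
    "target_rate_hz": ("resample", "target_rate_hz"),
    "welch_seg_len": ("welch", "seg_len"),
    "welch_overlap": ("welch", "overlap"),
    "welch_grid_hz": ("welch", "grid_hz"),
    "band_low_hz": ("band", "low_hz"),
    "band_high_hz": ("band", "high_hz"),
    "mask_halfwidth_hz": ("mask", "halfwidth_hz"),
    "mask_plateau_frac": ("mask", "plateau_frac"),
    "mask_highcut_frac": ("mask", "highcut_frac"),
    "window_length_s": ("window", "length_s"),
    "window_shift_s": ("window", "shift_s"),
    "track_block_len": ("track", "block_len"),
    "track_threshold_bpm": ("track", "threshold_bpm"),
    "track_extension_len": ("track", "extension_len"),
    "track_max_extensions": ("track", "max_extensions"),
    "track_smooth_window_s": ("track", "smooth_window_s"),
}


@dataclass(frozen=True)
class PipelineConfig:
    bandpass_low_hz: float = 0.5
    bandpass_high_hz: float = 5.0
    bandpass_order: int = 5
    median_kernel: int = 7
    mavg_window: int = 3
    target_rate_hz: float = 32.0
    welch_seg_len: int = 256
    welch_overlap: float = 0.5
    welch_grid_hz: float = 0.01
    band_low_hz: float = 0.5
    band_high_hz: float = 5.0
    mask_halfwidth_hz: float = 0.1
    mask_plateau_frac: float = 0.05
    mask_highcut_frac: float = 0.05
    window_length_s: float = 8.0
    window_shift_s: float = 2.0
    track_block_len: int = 20
    track_threshold_bpm: float = 10.0
    track_extension_len: int = 10
    track_max_extensions: int = 3
    track_smooth_window_s: float = 30.0

    @property
    def window_spec(self) -> WindowSpec:
        return WindowSpec(length_s=self.window_length_s, shift_s=self.window_shift_s)

    def with_updates(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        kwargs = {}
        for section, content in (data or {}).items():
            if not isinstance(content, dict):
                raise ConfigurationError(f"config section {section!r} must be a mapping")
            for key, value in content.items():
                flat = f"{section}_{key}" if (f"{section}_{key}") in known else None
                if flat is None:
                    for attr, (sec, k) in _YAML_MAP.items():
                        if sec == section and k == key:
                            flat = attr
                            break
                if flat is None or flat not in known:
                    raise ConfigurationError(f"unknown config key {section}.{key}")
                kwargs[flat] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        out: dict[str, dict] = {}
        for attr, (sec, key) in _YAML_MAP.items():
            out.setdefault(sec, {})[key] = getattr(self, attr)
        return out
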