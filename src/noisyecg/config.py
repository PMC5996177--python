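"""Run configuration: every tunable of the chain, with study defaults.

Keys mirror the module namespaces (``quality.kurtosis_threshold``,
``detect.ma_window_s``, ...) and can be loaded from a flat TOML file;
explicit keyword overrides win over file values.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # signal quality
    quality_kurtosis_threshold: float = 3.6
    quality_sd_multiplier: float = 1.5
    quality_window_s: float = 2.0
    quality_min_segment_s: float = 2.0
    quality_bridge_s: float = 0.5
    # detection
    detect_bandpass_hz: tuple = (5.0, 15.0)
    detect_bandpass_order: int = 1
    detect_lowpass_hz: float = 8.0
    detect_lowpass_order: int = 3
    detect_ma_window_s: float = 5.0
    detect_upper_mult: float = 1.25
    detect_lower_mult: float = 0.3
    detect_refractory_ms: float = 200.0
    detect_gap_mult: float = 1.5
    detect_median_window_s: float = 20.0
    detect_refine_radius_ms: float = 150.0
    # ensemble
    ensemble_pre_ms: float = 300.0
    ensemble_post_ms: float = 500.0
    ensemble_min_beats: int = 60
    ensemble_hr_tol: float = 0.10
    ensemble_rms_lo: float = 0.75
    ensemble_rms_hi: float = 2.00
    # intervals
    hr_tol: float = 0.60
    hr_min_beats: int = 15
    hrv_min_beats: int = 60
    hrv_reject_outliers: bool = True
    # evaluation
    bxb_window_ms: float = 150.0
    bxb_strict_window_ms: float = 100.0
    seed: int = 0

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load flat dotted keys (e.g. ``"quality.kurtosis_threshold"``)."""
        raw = tomllib.loads(Path(path).read_text())
        flat: dict = {}
        for key, value in raw.items():
            if isinstance(value, dict):  # [quality] table form
                for sub, v in value.items():
                    flat[f"{key}_{sub}"] = v
            else:
                flat[key.replace(".", "_")] = value
        known = {f.name for f in fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        flat.update(overrides)
        cfg = cls(**flat)
        if isinstance(cfg.detect_bandpass_hz, list):
            cfg.detect_bandpass_hz = tuple(cfg.detect_bandpass_hz)
        return cfg

    def to_toml(self, path: str | Path) -> None:
        lines = []
        for f in fields(self):
            if f.name.startswith("_"):
                continue
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = list(v)
            if isinstance(v, bool):
                s = "true" if v else "false"
            elif isinstance(v, str):
                s = f'"{v}"'
            else:
                s = repr(v)
            lines.append(f"{f.name} = {s}")
        Path(path).write_text("\n".join(lines) + "\n")
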