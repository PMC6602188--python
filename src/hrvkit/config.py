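"""Analysis configuration.

Every tunable of the pipeline lives here, addressed by dotted keys
(``ectopic.window_beats``, ``spectrum.order``, ...) both in config files
and in :meth:`AnalysisConfig.with_updates`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Tuple


@dataclass(frozen=True)
class AnalysisConfig:
    """Pipeline defaults for a 5-minute resting RR recording.

    The defaults mirror a standard short-term HRV protocol: 300 s
    analysis segment, 2 Hz uniform resampling, wavelet-packet detrending
    with a 0.0391 Hz cutoff, order-16 Burg spectra, 30 s / 15 s
    time-frequency windows, sample entropy with m=2 and r=0.2, and a
    DFA short/long-range breakpoint at 13 beats.
    """

    # segment selection
    segment_duration_s: float = 300.0
    segment_offset_s: float = 0.0

    # ectopic beat detection / correction
    ectopic_window_beats: int = 11
    ectopic_rel_threshold: float = 0.2

    # outlier screening
    outlier_k_sd: float = 3.0

    # uniform resampling
    resample_rate_hz: float = 2.0

    # wavelet-packet detrending
    detrend_cutoff_hz: float = 0.0391
    detrend_wavelet: str = "db4"

    # Burg spectrum
    spectrum_order: int = 16
    spectrum_n_freq: int = 4096

    # frequency band edges, Hz
    bands_ulf: Tuple[float, float] = (0.0, 0.0033)
    bands_vlf: Tuple[float, float] = (0.0033, 0.04)
    bands_lf: Tuple[float, float] = (0.04, 0.15)
    bands_hf: Tuple[float, float] = (0.15, 0.4)

    # time-frequency windows
    tf_window_s: float = 30.0
    tf_overlap_s: float = 15.0
    tf_rlfhf_aggregation: str = "mean"  # or "median"

    # time-domain histogram
    histogram_bin_width_ms: float = 1000.0 / 128.0

    # sample entropy
    sampen_m: int = 2
    sampen_r_fraction: float = 0.2

    # detrended fluctuation analysis
    dfa_breakpoint: int = 13
    dfa_box_min: int = 4
    dfa_box_max: int = 64

    _KEYMAP = None  # populated lazily

    @classmethod
    def _keymap(cls) -> dict:
        # "ectopic.window_beats" -> "ectopic_window_beats"
        mapping = {}
        for f in dataclasses.fields(cls):
            if f.name.startswith("_"):
                continue
            mapping[f.name.replace("_", ".", 1)] = f.name
            mapping[f.name] = f.name
        return mapping

    def with_updates(self, **kwargs: Any) -> "AnalysisConfig":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **kwargs)

    def update_from_keys(self, items: dict) -> "AnalysisConfig":
        """Apply dotted-key updates such as ``{"spectrum.order": 20}``."""
        mapping = self._keymap()
        updates = {}
        for key, value in items.items():
            name = mapping.get(key)
            if name is None:
                raise KeyError(f"unknown config key: {key!r}")
            current = getattr(self, name)
            if isinstance(current, tuple):
                if isinstance(value, str):
                    value = tuple(float(v) for v in value.replace(",", " ").split())
                updates[name] = tuple(value)
            elif isinstance(current, bool):
                updates[name] = value in (True, "true", "True", "1", 1)
            elif isinstance(current, int):
                updates[name] = int(value)
            elif isinstance(current, float):
                updates[name] = float(value)
            else:
                updates[name] = value
        return dataclasses.replace(self, **updates)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Read a ``key = value`` config file ('#' starts a comment)."""
        items = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            items[key] = value
        return cls().update_from_keys(items)

    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            if not f.name.startswith("_"):
                out[f.name.replace("_", ".", 1)] = getattr(self, f.name)
        return out


DEFAULT_CONFIG = AnalysisConfig()
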