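"""Run configuration: every tunable of every pipeline stage, with validated defaults.

The defaults here are the single source of truth; the CLI and the library
functions pull their keyword defaults from :class:`RunConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "StabilizationConfig",
    "FilterConfig",
    "AdaptiveThresholdConfig",
    "FlowConfig",
    "ShapeConfig",
    "TumorConfig",
    "MRFConfig",
    "MorphometricsConfig",
    "RunConfig",
    "load_config",
    "ConfigError",
]


class ConfigError(ValueError):
    """Raised when a configuration value is outside its documented range."""


def _check(cond: bool, key: str, allowed: str) -> None:
    if not cond:
        raise ConfigError(f"config key '{key}' out of range: allowed {allowed}")


@dataclass
class StabilizationConfig:
    method: str = "standard"        # {standard, blur_robust}
    subpixel: bool = True           # quadratic peak refinement
    hann_window: bool = True        # pre-FFT Hann taper
    channel: str = "phase"          # channel used for shift estimation

    def validate(self) -> None:
        _check(self.method in ("standard", "blur_robust"),
               "stabilization.method", "{standard, blur_robust}")
        _check(self.channel in ("phase", "fluor_green", "fluor_red"),
               "stabilization.channel", "{phase, fluor_green, fluor_red}")


@dataclass
class FilterConfig:
    median_window: int = 5          # pixels, odd
    nlm_patch_size: int = 7         # pixels, odd
    nlm_search_window: int = 31     # pixels, odd
    nlm_h: float = 15.0             # weight-decay control parameter
    meanshift_spatial_radius: float = 10.0   # px
    meanshift_range_radius: float = 10.0     # intensity units
    entropy_radius: int = 3         # disc radius for the local entropy filter
    # (texture boundaries blur by about the disc radius; 3 px keeps
    # co-localization overlays well localized)

    def validate(self) -> None:
        _check(self.median_window >= 3 and self.median_window % 2 == 1,
               "filter.median_window", "odd integer >= 3")
        _check(self.nlm_patch_size % 2 == 1, "filter.nlm_patch_size", "odd integer")
        _check(self.nlm_search_window % 2 == 1,
               "filter.nlm_search_window", "odd integer")
        _check(self.nlm_patch_size <= self.nlm_search_window,
               "filter.nlm_patch_size", "<= nlm_search_window")
        _check(self.nlm_h > 0, "filter.nlm_h", "> 0")
        _check(self.meanshift_spatial_radius > 0,
               "filter.meanshift_spatial_radius", "> 0")
        _check(self.meanshift_range_radius > 0,
               "filter.meanshift_range_radius", "> 0")
        _check(self.entropy_radius >= 1, "filter.entropy_radius", ">= 1")


@dataclass
class AdaptiveThresholdConfig:
    block_halfwidth: int = 25       # k: window is (2k+1) x (2k+1)
    sigma: float | None = None      # Gaussian width; None -> (2k+1)/6
    kappa: float = 2.0              # constant subtracted from weighted mean
    min_area: int = 50              # px; smaller components removed

    @property
    def block_size(self) -> int:
        return 2 * self.block_halfwidth + 1

    @property
    def sigma_value(self) -> float:
        return self.sigma if self.sigma is not None else self.block_size / 6.0

    def validate(self) -> None:
        _check(self.block_halfwidth >= 1, "threshold.block_halfwidth", ">= 1")
        if self.sigma is not None:
            _check(self.sigma > 0, "threshold.sigma", "> 0")
        _check(self.min_area >= 0, "threshold.min_area", ">= 0")
        # kappa may be any real


@dataclass
class FlowConfig:
    levels: int = 3
    window: int = 15
    iterations: int = 3
    poly_n: int = 5
    poly_sigma: float = 1.1

    def validate(self) -> None:
        _check(self.levels >= 1, "flow.levels", ">= 1")
        _check(self.window >= 3, "flow.window", ">= 3")
        _check(self.iterations >= 1, "flow.iterations", ">= 1")
        _check(self.poly_n >= 3 and self.poly_n % 2 == 1,
               "flow.poly_n", "odd integer >= 3")
        _check(self.poly_sigma > 0, "flow.poly_sigma", "> 0")


@dataclass
class ShapeConfig:
    depth_threshold: float = 5.0    # px; defects deeper than this count as branches

    def validate(self) -> None:
        _check(self.depth_threshold >= 0, "shape.depth_threshold", ">= 0")


@dataclass
class TumorConfig:
    block_halfwidth: int = 25
    sigma: float | None = None
    kappa: float = 2.0
    min_area: int = 50
    smooth_radius: int = 3          # disc radius for closing-then-opening

    def validate(self) -> None:
        _check(self.block_halfwidth >= 1, "tumor.block_halfwidth", ">= 1")
        if self.sigma is not None:
            _check(self.sigma > 0, "tumor.sigma", "> 0")
        _check(self.min_area >= 0, "tumor.min_area", ">= 0")
        _check(self.smooth_radius >= 1, "tumor.smooth_radius", ">= 1")


@dataclass
class MRFConfig:
    lambda0: float = 0.5            # constant pairwise penalty
    lambda1: float = 2.0            # contrast-sensitive pairwise amplitude
    beta: float = 0.05              # contrast decay (8-bit intensity scale)
    em_restarts: int = 5
    max_sweeps: int = 10
    mixture_on_entropy: bool = True  # fit the mixture on entropy-filtered values

    def validate(self) -> None:
        _check(self.lambda0 >= 0, "mrf.lambda0", ">= 0")
        _check(self.lambda1 >= 0, "mrf.lambda1", ">= 0")
        _check(self.beta >= 0, "mrf.beta", ">= 0")
        _check(self.em_restarts >= 1, "mrf.em_restarts", ">= 1")
        _check(self.max_sweeps >= 1, "mrf.max_sweeps", ">= 1")


@dataclass
class MorphometricsConfig:
    mean_cell_area: float = 250.0   # px^2; CellNumber = Area / mean_cell_area
    appendage_open_radius: int = 4  # disc radius of the opening that strips appendages
    smoothing_window: int = 5       # frames; centered moving average for curves

    def validate(self) -> None:
        _check(self.mean_cell_area > 0, "morpho.mean_cell_area", "> 0")
        _check(self.appendage_open_radius >= 1, "morpho.appendage_open_radius", ">= 1")
        _check(self.smoothing_window >= 1 and self.smoothing_window % 2 == 1,
               "morpho.smoothing_window", "odd integer >= 1")


@dataclass
class RunConfig:
    stabilization: StabilizationConfig = field(default_factory=StabilizationConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    threshold: AdaptiveThresholdConfig = field(default_factory=AdaptiveThresholdConfig)
    flow: FlowConfig = field(default_factory=FlowConfig)
    shape: ShapeConfig = field(default_factory=ShapeConfig)
    tumor: TumorConfig = field(default_factory=TumorConfig)
    mrf: MRFConfig = field(default_factory=MRFConfig)
    morpho: MorphometricsConfig = field(default_factory=MorphometricsConfig)

    def validate(self) -> None:
        for f in fields(self):
            getattr(self, f.name).validate()


def _apply(section: Any, values: dict[str, Any], prefix: str) -> None:
    valid = {f.name for f in fields(section)}
    for key, val in values.items():
        if key not in valid:
            raise ConfigError(f"unknown config key '{prefix}.{key}'")
        setattr(section, key, val)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run configuration; unset keys keep their documented defaults.

    Raises :class:`ConfigError` naming the key and its allowed range for any
    out-of-range value.
    """
    cfg = RunConfig()
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping of sections")
        sections = {f.name: getattr(cfg, f.name) for f in fields(cfg)}
        for name, values in data.items():
            if name not in sections:
                raise ConfigError(f"unknown config section '{name}'")
            if values is None:
                continue
            if not isinstance(values, dict):
                raise ConfigError(f"config section '{name}' must be a mapping")
            _apply(sections[name], values, name)
    cfg.validate()
    return cfg


def config_to_dict(cfg: RunConfig) -> dict[str, Any]:
    """Serialize a RunConfig to nested plain dicts (for provenance logging)."""
    out: dict[str, Any] = {}
    for f in fields(cfg):
        sec = getattr(cfg, f.name)
        assert is_dataclass(sec)
        out[f.name] = {g.name: getattr(sec, g.name) for g in fields(sec)}
    return out
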