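"""Run configuration: a YAML-serializable bundle of all pipeline settings.

Threshold bands accept three spellings per dimension::

    rt: [-0.5, 0.5]                  # symmetric/asymmetric absolute band
    mz: [-0.01, 0.01, -5e-6, 5e-6]   # [lower_icpt, upper_icpt, lower_slope, upper_slope]
    fi: {lower_intercept: -1, upper_intercept: 1, lower_slope: 0, upper_slope: 0}

CLI flags override file values.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Any

import yaml

from .candidates import Band, ThresholdSpec
from .errors import ConfigError
from .filtering import PoorMatchConfig
from .scoring import WeightVector


def band_from_config(value: Any) -> Band:
    if isinstance(value, Band):
        return value
    if isinstance(value, dict):
        return Band(**value)
    if isinstance(value, (list, tuple)):
        if len(value) == 2:
            return Band(float(value[0]), float(value[1]))
        if len(value) == 4:
            return Band(float(value[0]), float(value[1]),
                        float(value[2]), float(value[3]))
    raise ConfigError(f"cannot interpret threshold band {value!r}")


def thresholds_from_config(cfg: dict) -> ThresholdSpec:
    if "rt" not in cfg or "mz" not in cfg:
        raise ConfigError("thresholds must define at least 'rt' and 'mz' bands")
    fi = band_from_config(cfg["fi"]) if cfg.get("fi") is not None else None
    return ThresholdSpec(rt=band_from_config(cfg["rt"]),
                         mz=band_from_config(cfg["mz"]),
                         fi=fi,
                         fi_enabled=bool(cfg.get("fi_enabled", fi is not None)))


@dataclass
class RunConfig:
    """Everything a `featmatch match` run needs."""

    ref: str = ""
    target: str = ""
    ref_samples: str | None = None
    target_samples: str | None = None
    thresholds: dict = field(default_factory=dict)
    neighbor_method: str = "cross"
    k: int | None = None
    k_fraction: float | None = None
    F: float = 3.0
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    centered: bool = True
    fi_enabled: bool = True
    poor_enabled: bool = True
    poor_method: str = "scores"
    F_tighten: float = 3.0
    output_dir: str = "featmatch_out"
    seed: int = 0
    verbosity: str = "INFO"
    column_map: dict | None = None

    def threshold_spec(self) -> ThresholdSpec:
        spec = thresholds_from_config(dict(self.thresholds))
        if not self.fi_enabled and spec.fi_enabled:
            spec = ThresholdSpec(rt=spec.rt, mz=spec.mz, fi=spec.fi, fi_enabled=False)
        return spec

    def weight_vector(self) -> WeightVector:
        w = WeightVector(*self.weights)
        if not self.fi_enabled and w.fi > 0:
            raise ConfigError("fi_enabled is false but W_FI > 0; set weights "
                              "consistently (e.g. W_FI = 0)")
        return w

    def poor_config(self) -> PoorMatchConfig | None:
        if not self.poor_enabled:
            return None
        return PoorMatchConfig(method=self.poor_method, F_tighten=self.F_tighten)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.weights, list):
            cfg.weights = tuple(cfg.weights)
        return cfg

    def to_yaml(self, path: str) -> None:
        data = asdict(self)
        data["weights"] = list(self.weights)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
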