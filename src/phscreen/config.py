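"""Run configuration: thresholds, windows, synthetic-screen parameters.

A single YAML file configures every stage; all defaults are the screen's
standard operating values.  The configuration hashes deterministically so
that output tables can be stamped with the exact settings that produced
them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .calibration import CalibrationCurve
from .errors import ConfigError
from .synthetic_data import PlantedStrain, SyntheticConfig

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs besides the input tables."""

    seed: int = 0
    # hit-calling thresholds
    z_primary: float = 2.0         # |Z| needed in one primary screen
    z_secondary: float = 1.0       # |Z| needed in the other, same sign
    alpha_confirm: float = 0.01    # rescreen t-test
    alpha_jackknife: float = 0.1   # trimmed re-test floor
    alpha_class: float = 0.01      # category II/III calls (corrected)
    require_same_sign: bool = True
    jackknife: str = "slow_grower"   # "slow_grower" | "all" | "none"
    # windows (hours unless noted)
    slope_window: int = 6          # points per growth-rate window
    measure_window: tuple[float, float] = (3.5, 4.5)
    class_window: tuple[float, float] = (4.0, 9.0)
    fit_exclusion: float = 1.5     # drop points earlier than this from the fit
    correction: str = "wildtype_floor"   # or "bonferroni"
    enrich_min_K: int = 2
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def __post_init__(self) -> None:
        for name in ("z_primary", "z_secondary", "alpha_confirm",
                     "alpha_jackknife", "alpha_class"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be positive")
        lo, hi = self.class_window
        if not lo < hi or hi > self.synthetic.duration_h:
            raise ConfigError(
                "class_window must be increasing and inside the observation span"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["measure_window"] = list(self.measure_window)
        d["class_window"] = list(self.class_window)
        return d


def _build_synthetic(raw: dict) -> SyntheticConfig:
    raw = dict(raw)
    planted = [PlantedStrain(**p) for p in raw.pop("planted", [])]
    calib = raw.pop("calibration", None)
    kwargs = {}
    if calib is not None:
        calib = dict(calib)
        if "valid_range" in calib:
            calib["valid_range"] = tuple(calib["valid_range"])
        kwargs["calibration"] = CalibrationCurve(**calib)
    known = {f.name for f in dataclasses.fields(SyntheticConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown synthetic config key(s): {sorted(unknown)}")
    return SyntheticConfig(**raw, planted=planted, **kwargs)


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config file; missing keys fall back to the defaults."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must be a YAML mapping")
        raw = loaded
    if overrides:
        raw = {**raw, **{k: v for k, v in overrides.items() if v is not None}}
    synth = raw.pop("synthetic", {})
    if "planted" in raw:  # allow planted at top level for convenience
        synth = {**synth, "planted": raw.pop("planted")}
    known = {f.name for f in dataclasses.fields(RunConfig)} - {"synthetic"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    for key in ("measure_window", "class_window"):
        if key in raw:
            raw[key] = tuple(raw[key])
    try:
        return RunConfig(**raw, synthetic=_build_synthetic(synth))
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the full configuration (calibration included)."""
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
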