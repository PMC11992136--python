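"""Run configuration: one YAML-serializable object covering every stage.

Defaults are the study conditions: 66/43/256 DEL/DUP/CTRL subjects,
4-minute 128-channel recordings at 500 Hz, 2-s epochs, the printed
spectral-parameterization settings, CSD with m=4 / lambda=1e-5 / 50
Legendre terms, and the 15th/85th-percentile IQR outlier rule.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict

import yaml

from .bands import DEFAULT_BANDS
from .csd import CsdParams
from .normative import OutlierRule
from .spectral import SpecParamSettings
from .synthetic import ArtifactSpec, EffectConfig


@dataclass
class RunConfig:
    out_dir: str = "runs/default"
    seed: int = 0
    # cohort
    n_ctrl: int = 256
    n_del: int = 66
    n_dup: int = 43
    effects: EffectConfig = field(default_factory=EffectConfig)
    # recordings
    n_channels: int = 128
    n_excluded: int = 28
    duration_s: float = 240.0
    rate: float = 500.0
    epoch_length_s: float = 2.0
    # preprocessing
    reject_k: float = 5.0
    interp_k: float = 8.0
    ica_corr_threshold: float = 0.7
    ica_max_remove: int = 2
    # transforms and features
    csd: CsdParams = field(default_factory=CsdParams)
    use_csd_for_connectivity: bool = True
    specparam: SpecParamSettings = field(default_factory=SpecParamSettings)
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    # normative model
    outlier: OutlierRule = field(default_factory=OutlierRule)
    min_train: int = 50
    gpr_restarts: int = 3

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bands"] = {k: list(v) for k, v in self.bands.items()}
        d["effects"]["shifts"] = {
            p: {g: list(v) for g, v in by_group.items()}
            for p, by_group in self.effects.shifts.items()
        }
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "effects" in d and isinstance(d["effects"], dict):
            eff = dict(d["effects"])
            if "artifacts" in eff and isinstance(eff["artifacts"], dict):
                eff["artifacts"] = ArtifactSpec(**eff["artifacts"])
            if "shifts" in eff:
                eff["shifts"] = {
                    p: {g: tuple(v) for g, v in by_group.items()}
                    for p, by_group in eff["shifts"].items()
                }
            if "coupling_band" in eff:
                eff["coupling_band"] = tuple(eff["coupling_band"])
            d["effects"] = EffectConfig(**eff)
        for key, typ in (("csd", CsdParams), ("outlier", OutlierRule),
                         ("specparam", SpecParamSettings)):
            if key in d and isinstance(d[key], dict):
                if key == "specparam" and "peak_width_limits" in d[key]:
                    d[key]["peak_width_limits"] = tuple(d[key]["peak_width_limits"])
                d[key] = typ(**d[key])
        if "bands" in d:
            d["bands"] = {k: tuple(v) for k, v in d["bands"].items()}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))
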