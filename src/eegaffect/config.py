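"""Pipeline configuration: one serializable object for every stage knob."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .simulate import CohortConfig, SourceSpec, default_sources


@dataclass
class CleaningParams:
    channel_z_thresh: float = 5.0
    epoch_ptp_thresh: float = 200.0   # µV
    epoch_z_thresh: float = 4.0


@dataclass
class IcaParams:
    algorithm: str = "extended-infomax"
    max_iter: int = 500
    tol: float = 1e-5
    sample_step: int = 1


@dataclass
class DipoleParams:
    grid_step_mm: float = 10.0
    refine_tol_mm: float = 0.5
    rv_max: float = 0.15
    brain_margin: float = 0.9
    psd_slope_band: tuple[float, float] = (20.0, 45.0)
    frontal_fraction_max: float = 0.6
    n_frontal: int = 4


@dataclass
class ClusterParams:
    k: int = 7
    outlier_sd: float = 3.0
    n_restarts: int = 20
    n_topo_pcs: int = 10
    n_erp_pcs: int = 5
    erp_window_s: tuple[float, float] = (0.0, 0.5)


@dataclass
class RegressionParams:
    min_epochs_per_participant: int = 8
    alpha: float = 0.025


@dataclass
class PipelineConfig:
    """Fully serializable run description.

    ``seed`` feeds a SeedSequence from which every stage draws its own
    named stream; no stage touches the global RNG.
    """

    seed: int = 0
    simulate: bool = True
    input_dir: str | None = None
    out_dir: str | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    cleaning: CleaningParams = field(default_factory=CleaningParams)
    ica: IcaParams = field(default_factory=IcaParams)
    dipole: DipoleParams = field(default_factory=DipoleParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    regression: RegressionParams = field(default_factory=RegressionParams)

    def validate(self) -> None:
        if not self.simulate and not self.input_dir:
            raise ValueError("need either simulate=true or an input cohort path")
        if self.ica.algorithm not in ("extended-infomax", "fixed-point-negentropy"):
            raise ValueError(f"unknown ICA algorithm {self.ica.algorithm!r}")
        if not 0 < self.regression.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return _encode(dataclasses.asdict(self))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        sources = [SourceSpec(**_decode_source(s)) for s in cohort.pop("sources", [])]
        if not sources:
            sources = default_sources()
        cfg = cls(
            cohort=CohortConfig(sources=sources, **cohort),
            cleaning=CleaningParams(**d.pop("cleaning", {})),
            ica=IcaParams(**d.pop("ica", {})),
            dipole=DipoleParams(**_tupled(d.pop("dipole", {}), "psd_slope_band")),
            cluster=ClusterParams(**_tupled(d.pop("cluster", {}), "erp_window_s")),
            regression=RegressionParams(**d.pop("regression", {})),
            **d,
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data)


def _tupled(d: dict, key: str) -> dict:
    if key in d and d[key] is not None:
        d[key] = tuple(d[key])
    return d


def _decode_source(s: dict) -> dict:
    s = dict(s)
    slopes = s.get("band_slopes", {})
    if slopes and isinstance(next(iter(slopes)), str):
        s["band_slopes"] = {tuple(k.split("/")): v for k, v in slopes.items()}
    if s.get("freq_range_hz") is not None:
        s["freq_range_hz"] = tuple(s["freq_range_hz"])
    return s


def _encode(obj):
    """Make nested dataclass dicts YAML/JSON-safe (arrays, tuple keys)."""
    if isinstance(obj, dict):
        out = {}
        for k, v in obj.items():
            if isinstance(k, tuple):
                k = "/".join(map(str, k))
            out[k] = _encode(v)
        return out
    if isinstance(obj, (list, tuple)):
        return [_encode(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
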