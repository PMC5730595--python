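"""Run configuration: one plain-text (YAML) schema for full pipeline runs.

A run is reproducible from its config alone: every stochastic stage derives
its seed from the master seed and the stage name (counter-based splitting),
so results do not depend on stage execution order.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ParameterError
from .inheritance import InheritanceConfig
from .model import ExtrinsicSpec, TwoStageParams
from .spatial import SpatialConfig
from .synthetic import TissueGenConfig

__all__ = ["RunConfig", "stage_seed"]

#: Reference parameter set of the photoconvertible-reporter analysis:
#: transcription 2.25 mRNA/h, mRNA half-life ~37 min, translation 45/mRNA/h
#: (cell-to-cell variance 100 h^-2), protein decay 0.09/h.
DEFAULT_PARAMS = dict(transcription_rate=2.25, mrna_decay=1.125,
                      translation_rate=45.0, protein_decay=0.09)
DEFAULT_EXTRINSIC = dict(mean=45.0, variance=100.0)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic, order-independent per-stage seed below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    master_seed: int = 0
    input_table: str | None = None  # measurement CSV; stages synthesize data if unset
    ks_alpha: float = 0.05
    decay_t1_h: float = 3.0
    decay_t2_h: float = 6.0
    autocorr_n_traj: int = 100_000
    params: TwoStageParams = field(
        default_factory=lambda: TwoStageParams(**DEFAULT_PARAMS))
    extrinsic: ExtrinsicSpec = field(
        default_factory=lambda: ExtrinsicSpec(**DEFAULT_EXTRINSIC))
    spatial: SpatialConfig = field(default_factory=SpatialConfig)
    tissue: TissueGenConfig = field(default_factory=TissueGenConfig)
    inheritance_mode: str = "state_only"
    inheritance_n_pairs: int = 10_000
    inheritance_mean_age_h: float | None = None  # None -> calibrated default
    kik_n_cells: int = 400
    kik_noise_sigma: float = 0.1

    def inheritance_config(self, mode: str | None = None) -> InheritanceConfig:
        return InheritanceConfig(
            params=self.params, spec=self.extrinsic,
            mode=mode or self.inheritance_mode,
            mean_division_age_h=self.inheritance_mean_age_h,
            n_pairs=self.inheritance_n_pairs,
            seed=stage_seed(self.master_seed, f"inherit:{mode or self.inheritance_mode}"),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)

        def listify(x):
            if isinstance(x, dict):
                return {k: listify(v) for k, v in x.items()}
            if isinstance(x, tuple):
                return [listify(v) for v in x]
            return x

        return listify(d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)

        def build(klass, sub):
            if sub is None:
                return klass()
            fields = {f.name for f in dataclasses.fields(klass)}
            unknown = set(sub) - fields
            if unknown:
                raise ParameterError(f"unknown {klass.__name__} key(s): {sorted(unknown)}")
            sub = {k: tuple(v) if isinstance(v, list) else v for k, v in sub.items()}
            return klass(**sub)

        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            v = d.pop(f.name)
            if f.name == "params":
                v = build(TwoStageParams, v)
            elif f.name == "extrinsic":
                v = build(ExtrinsicSpec, v)
            elif f.name == "spatial":
                v = build(SpatialConfig, v)
            elif f.name == "tissue":
                v = build(TissueGenConfig, v)
            kwargs[f.name] = v
        if d:
            raise ParameterError(f"unknown config key(s): {sorted(d)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ParameterError("config must be a YAML mapping")
        return cls.from_dict(data)
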