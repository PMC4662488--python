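"""Structured pipeline configuration (YAML) with validated defaults.

All published-workflow thresholds live here as defaults and are never
hardcoded in stage logic: FDR < 0.15 for known miRNAs, FDR < 0.10 for novel
miRNAs (both at P < 0.05), and P < 0.01 / FDR < 0.05 for the overtargeting
screen.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .core import InputError


@dataclass
class Thresholds:
    fdr_known: float = 0.15
    fdr_novel: float = 0.10
    p_da: float = 0.05
    overtarget_p: float = 0.01
    overtarget_fdr: float = 0.05


@dataclass
class AnnotationParams:
    min_overlap_frac: float = 0.5
    end_window: int = 5
    trna_size_range: tuple = (30, 33)
    start_tolerance: int = 1


@dataclass
class DAParams:
    trim_m: float = 0.30
    trim_a: float = 0.05
    prior_count: float = 2.0
    prior_df: float = 10.0
    top_k: int = 500


@dataclass
class SimulateParams:
    n_features: int = 2000
    n_per_group: int = 7
    frac_da: float = 0.1
    log2fc_magnitude: float = 2.0
    dispersion: float = 0.2
    libsize_range: tuple = (1_000_000, 5_000_000)
    n_reads: int = 50_000
    n_mirnas: int = 100
    n_genes: int = 400
    density: float = 0.2
    n_planted: int = 20
    boost: float = 4.0


@dataclass
class PipelineConfig:
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)
    annotation: AnnotationParams = field(default_factory=AnnotationParams)
    da: DAParams = field(default_factory=DAParams)
    simulate: SimulateParams = field(default_factory=SimulateParams)
    # optional external inputs; when unset the simulate stage provides them
    census_path: str | None = None
    pred_a_path: str | None = None
    pred_b_path: str | None = None
    validated_path: str | None = None

    def validate(self) -> "PipelineConfig":
        t = self.thresholds
        for name in ("fdr_known", "fdr_novel", "p_da", "overtarget_p", "overtarget_fdr"):
            v = getattr(t, name)
            if not 0 < v <= 1:
                raise InputError(f"threshold {name} must lie in (0, 1]")
        lo, hi = self.annotation.trna_size_range
        if lo > hi:
            raise InputError("trna_size_range must be ordered")
        if not 0 < self.annotation.min_overlap_frac <= 1:
            raise InputError("min_overlap_frac must lie in (0, 1]")
        import os

        for attr in ("census_path", "pred_a_path", "pred_b_path", "validated_path"):
            p = getattr(self, attr)
            if p is not None and not os.path.exists(p):
                raise InputError(f"{attr} does not exist: {p}")
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["annotation"]["trna_size_range"] = list(self.annotation.trna_size_range)
        d["simulate"]["libsize_range"] = list(self.simulate.libsize_range)
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        kwargs = {}
        for name, sub in (
            ("thresholds", Thresholds),
            ("annotation", AnnotationParams),
            ("da", DAParams),
            ("simulate", SimulateParams),
        ):
            payload = dict(d.pop(name, {}) or {})
            for key in ("trna_size_range", "libsize_range"):
                if key in payload:
                    payload[key] = tuple(payload[key])
            known = {f.name for f in dataclasses.fields(sub)}
            stray = set(payload) - known
            if stray:
                raise InputError(f"unknown {name} keys: {sorted(stray)}")
            kwargs[name] = sub(**payload)
        known = {f.name for f in dataclasses.fields(cls)}
        stray = set(d) - known
        if stray:
            raise InputError(f"unknown config keys: {sorted(stray)}")
        return cls(**{**d, **kwargs}).validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
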