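"""Run configuration: one flat YAML with per-stage sections.

Every pipeline run resolves its configuration (defaults overlaid by a YAML
file overlaid by CLI flags), validates it, and writes the resolved values
back out next to the outputs as the provenance record.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "LibrarySection", "PoolingSection", "SimulationSection", "AnalysisSection"]


@dataclass
class LibrarySection:
    k: int = 12
    w: int = 12
    q: float = 0.21
    allow_self: bool = False
    predictor: str = "surrogate_pwm"  # or 'table:<path>' or 'constant'

    def validate(self) -> None:
        if not (1 <= self.k <= 86):
            raise ValueError(f"library.k out of range: {self.k}")
        if not (2 <= self.w <= 2 * self.k):
            raise ValueError(f"library.w out of range: {self.w}")
        if not (0 < self.q <= 1):
            raise ValueError(f"library.q out of range: {self.q}")


@dataclass
class PoolingSection:
    pool_size: int = 33
    group_size: int = 4
    seed: int | None = 0

    def validate(self) -> None:
        if self.pool_size < 1:
            raise ValueError(f"pooling.pool_size out of range: {self.pool_size}")
        if self.group_size < 1:
            raise ValueError(f"pooling.group_size out of range: {self.group_size}")


@dataclass
class SimulationSection:
    background_mean: float = 2000.0
    signal_max: float = 50000.0
    lognormal_sigma: float = 0.15
    hill_slope: float = 1.0
    dropout_prob: float = 0.0
    dose: float = 2e-3
    colony_count: int | None = None  # None = exhaustive
    seed: int = 0

    def validate(self) -> None:
        if self.background_mean <= 0:
            raise ValueError("simulation.background_mean must be > 0")
        if self.signal_max < 0 or self.lognormal_sigma < 0:
            raise ValueError("simulation.signal_max/lognormal_sigma must be >= 0")
        if not (0 <= self.dropout_prob < 1):
            raise ValueError("simulation.dropout_prob must be in [0, 1)")
        if self.dose <= 0:
            raise ValueError("simulation.dose must be > 0")
        if self.colony_count is not None and self.colony_count < 1:
            raise ValueError("simulation.colony_count must be >= 1 (or null)")


@dataclass
class AnalysisSection:
    k_sd: float = 2.0
    sd_floor: float = 1.0
    use_dunnett: bool = True
    alpha: float = 0.05
    cdi_threshold: float = 3.0
    min_tpm: float = 26.0

    def validate(self) -> None:
        if self.k_sd <= 0 or self.sd_floor <= 0:
            raise ValueError("analysis.k_sd and analysis.sd_floor must be > 0")
        if not (0 < self.alpha < 1):
            raise ValueError(f"analysis.alpha out of range: {self.alpha}")
        if self.cdi_threshold <= 0:
            raise ValueError("analysis.cdi_threshold must be > 0")
        if self.min_tpm < 0:
            raise ValueError("analysis.min_tpm must be >= 0")


_SECTIONS = {
    "library": LibrarySection,
    "pooling": PoolingSection,
    "simulation": SimulationSection,
    "analysis": AnalysisSection,
}


@dataclass
class RunConfig:
    library: LibrarySection = field(default_factory=LibrarySection)
    pooling: PoolingSection = field(default_factory=PoolingSection)
    simulation: SimulationSection = field(default_factory=SimulationSection)
    analysis: AnalysisSection = field(default_factory=AnalysisSection)

    def validate(self) -> "RunConfig":
        for name in _SECTIONS:
            getattr(self, name).validate()
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(_SECTIONS)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        kwargs = {}
        for name, section_cls in _SECTIONS.items():
            payload = raw.get(name, {}) or {}
            valid_keys = {f.name for f in fields(section_cls)}
            bad = set(payload) - valid_keys
            if bad:
                raise ValueError(f"unknown keys in config section {name!r}: {sorted(bad)}")
            kwargs[name] = section_cls(**payload)
        return cls(**kwargs).validate()

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
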