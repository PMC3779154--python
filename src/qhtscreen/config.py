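"""Screen configuration: thresholds, series, generator block, sample manifest.

All decision thresholds of the pipeline live here with their screening
defaults: the 60% efficacy gate for the active category, the 80% boundary
between full- and partial-efficacy curve classes, the 25-point significance
threshold, the 30 uM consensus IC50 gate, the 5-fold potency-shift and
40-point efficacy-difference selectivity gates, the r2 floor for usable fits
and the 5% plateau tolerance for curve completeness.  Configs round-trip
losslessly through YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import InvalidArgumentError
from .plates import ConcentrationSeries, make_series
from .simulate import (
    DEFAULT_CLL_SAMPLES,
    DEFAULT_FRACTIONS,
    DEFAULT_NORMAL_SAMPLES,
    NoiseModel,
)


@dataclass(frozen=True)
class SeriesConfig:
    top_uM: float = 57.0
    factor: float = 5.0
    n_points: int = 8

    def make(self) -> ConcentrationSeries:
        return make_series(self.top_uM, self.factor, self.n_points)


@dataclass(frozen=True)
class Thresholds:
    efficacy_active: float = 60.0
    efficacy_high: float = 80.0
    act_threshold: float = 25.0
    ic50_gate_uM: float = 30.0
    fold_shift_gate: float = 5.0
    efficacy_diff_gate: float = 40.0
    r2_min: float = 0.3
    plateau_tol: float = 0.05

    def __post_init__(self) -> None:
        if any(v <= 0 for v in asdict(self).values()):
            raise InvalidArgumentError("all thresholds must be positive")


@dataclass(frozen=True)
class GeneratorConfig:
    n_compounds: int = 2816
    fractions: dict = field(default_factory=lambda: dict(DEFAULT_FRACTIONS))
    sigma_log10: float = 0.3
    noise: NoiseModel = field(default_factory=NoiseModel)


@dataclass(frozen=True)
class ScreenConfig:
    series: SeriesConfig = field(default_factory=SeriesConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    cll_samples: tuple[str, ...] = DEFAULT_CLL_SAMPLES
    normal_samples: tuple[str, ...] = DEFAULT_NORMAL_SAMPLES
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cll_samples"] = list(self.cll_samples)
        d["normal_samples"] = list(self.normal_samples)
        ramp = d["generator"]["noise"]["spatial_ramp"]
        if ramp is not None:
            d["generator"]["noise"]["spatial_ramp"] = list(ramp)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenConfig":
        gen = dict(d.get("generator", {}))
        noise = dict(gen.get("noise", {}))
        if noise.get("spatial_ramp") is not None:
            noise["spatial_ramp"] = tuple(noise["spatial_ramp"])
        gen["noise"] = NoiseModel(**noise)
        return cls(
            series=SeriesConfig(**d.get("series", {})),
            thresholds=Thresholds(**d.get("thresholds", {})),
            generator=GeneratorConfig(**gen),
            cll_samples=tuple(d.get("cll_samples", DEFAULT_CLL_SAMPLES)),
            normal_samples=tuple(d.get("normal_samples", DEFAULT_NORMAL_SAMPLES)),
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        """Stable short hash of the config for artifact provenance headers."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


#: unit-test scale screen: 64 compounds, 2 CLL + 2 normal samples
def mini_config(seed: int = 0, n_compounds: int = 64, full_samples: bool = True) -> ScreenConfig:
    """Desk-scale configuration used by the test fixtures.

    ``full_samples=True`` keeps the 6 CLL + 5 normal manifest; otherwise a
    2 + 2 manifest for the fastest checks.
    """
    cll = DEFAULT_CLL_SAMPLES if full_samples else DEFAULT_CLL_SAMPLES[:2]
    normal = DEFAULT_NORMAL_SAMPLES if full_samples else DEFAULT_NORMAL_SAMPLES[:2]
    return ScreenConfig(
        generator=GeneratorConfig(n_compounds=n_compounds),
        cll_samples=cll,
        normal_samples=normal,
        seed=seed,
    )
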