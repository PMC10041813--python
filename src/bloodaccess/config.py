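"""Run configuration: one nested YAML file drives the whole pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .accessibility import DecayParams
from .cost import TravelScenario
from .synthetic import CountyScenario

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs, round-trippable through YAML.

    ``scenario`` parameterises the synthetic county; ``travel`` the
    class-to-speed table; the analysis knobs (catchment threshold, decay
    friction, travel-time bands, SPAI class thresholds, SCI variant and
    market-share basis) default to the study's published settings.
    """

    scenario: CountyScenario = field(default_factory=CountyScenario)
    travel: TravelScenario = field(default_factory=TravelScenario.default)
    t_max: float = 60.0
    beta: float | None = None
    bands: list[float] = field(default_factory=lambda: [30.0, 60.0])
    class_mode: str = "fixed"
    class_thresholds: tuple[float, float] = (0.5, 1.5)
    sci_variant: str = "collapsed"
    share_basis: str = "transfused"
    outdir: str = "run"

    def __post_init__(self):
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")
        lo, hi = self.class_thresholds
        if not lo < hi:
            raise ValueError("class thresholds must be ordered")

    @property
    def decay(self) -> DecayParams:
        return DecayParams(t_max=self.t_max, beta=self.beta)

    # -- YAML round trip ----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "scenario": asdict(self.scenario),
            "travel": self.travel.to_mapping(),
            "t_max": self.t_max,
            "beta": self.beta,
            "bands": list(self.bands),
            "class_mode": self.class_mode,
            "class_thresholds": list(self.class_thresholds),
            "sci_variant": self.sci_variant,
            "share_basis": self.share_basis,
            "outdir": self.outdir,
        }
        d["scenario"]["grid_shape"] = list(self.scenario.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sc = dict(d.pop("scenario", {}))
        if "grid_shape" in sc:
            sc["grid_shape"] = tuple(sc["grid_shape"])
        travel = d.pop("travel", None)
        kwargs = {}
        if "class_thresholds" in d:
            d["class_thresholds"] = tuple(d["class_thresholds"])
        kwargs.update(d)
        return cls(
            scenario=CountyScenario(**sc),
            travel=TravelScenario.from_mapping(travel) if travel else TravelScenario.default(),
            **kwargs,
        )

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
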