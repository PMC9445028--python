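"""Declarative run configuration (YAML) for the pipeline CLI.

A single file holds the locus definition, caller thresholds, the
statistics block (onset model, selection parameters, statistics list)
and the simulation block.  Unknown keys are rejected so typos cannot
silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .caller import CallerConfig
from .locus import RepeatLocus
from .onset import LangbehnModel, SelectionModel
from .simulate import CohortSimConfig, ReadSimConfig


def _build(cls, data: dict, name: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown keys in {name!r} block: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class StatsConfig:
    onset_model: LangbehnModel = field(default_factory=LangbehnModel)
    selection: SelectionModel | str | None = "fit"   # model, "fit", or None
    statistics: tuple[str, ...] = ("sum", "diff", "max", "min", "n3rep")
    alpha: float = 0.05
    bonferroni_k: int = 4


@dataclass(frozen=True)
class RunConfig:
    locus: RepeatLocus = field(default_factory=RepeatLocus)
    caller: CallerConfig = field(default_factory=CallerConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    reads: ReadSimConfig = field(default_factory=ReadSimConfig)
    cohort: CohortSimConfig = field(default_factory=CohortSimConfig)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        kwargs = {}
        blocks = {
            "locus": RepeatLocus,
            "caller": CallerConfig,
            "reads": ReadSimConfig,
            "cohort": CohortSimConfig,
        }
        for key, sub in blocks.items():
            if key in data:
                kwargs[key] = _build(sub, data[key] or {}, key)
        if "stats" in data:
            block = dict(data["stats"] or {})
            if isinstance(block.get("onset_model"), dict):
                block["onset_model"] = _build(
                    LangbehnModel, block["onset_model"], "onset_model"
                )
            sel = block.get("selection")
            if isinstance(sel, dict):
                block["selection"] = _build(SelectionModel, sel, "selection")
            if isinstance(block.get("statistics"), list):
                block["statistics"] = tuple(block["statistics"])
            kwargs["stats"] = _build(StatsConfig, block, "stats")
        for key in ("seed", "log_level"):
            if key in data:
                kwargs[key] = data[key]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)
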