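"""Run configuration: a strict, YAML round-trippable bundle of settings."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .agent import BPParams
from .errors import ConfigError
from .walks import WalkConfig


@dataclass
class RunConfig:
    """Everything needed to run the pipeline end to end.

    ``walk`` configures the session stimulus, ``params`` the generative
    participant model; the remaining fields configure the training stimulus
    and the analysis.  Unknown keys in a config file are rejected.
    """

    walk: WalkConfig = field(default_factory=WalkConfig)
    params: BPParams = field(default_factory=BPParams)
    # training stimulus
    blob_step_deg: float = 10.0
    blob_step_period: float = 5.0
    training_duration: float = 130.0
    # analysis options
    n_bins: int = 9
    percept_step_sd: float = 1.0
    deadapt: bool = False
    target_intercept: float = 0.0
    q_bounds: tuple[float, float] = (0.0, 1e-2)
    discard: float = 10.0
    seed: int = 0
    out_prefix: str = "run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["q_bounds"] = list(self.q_bounds)
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        kwargs: dict = {}
        for sub_name, sub_cls in (("walk", WalkConfig), ("params", BPParams)):
            if sub_name in data:
                sub = data.pop(sub_name)
                _check_keys(sub, {f.name for f in dataclasses.fields(sub_cls)}, sub_name)
                kwargs[sub_name] = sub_cls(**sub)
        own = {f.name for f in dataclasses.fields(cls)} - {"walk", "params"}
        _check_keys(data, own, "run config")
        if "q_bounds" in data:
            data["q_bounds"] = tuple(data["q_bounds"])
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            data = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: invalid YAML ({exc})") from exc
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)


def _check_keys(data: dict, allowed: set[str], where: str) -> None:
    if not isinstance(data, dict):
        raise ConfigError(f"{where}: expected a mapping")
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}")
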