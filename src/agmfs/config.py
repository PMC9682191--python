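"""Run configuration: a validated YAML front-end over the library defaults."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

from .errors import ValidationError
from .optim import ALPHA_BETA_GRID, Hyperparams
from .synthetic import SyntheticSpec

__all__ = ["RunConfig", "load_config"]

_HP_KEYS = {f.name for f in fields(Hyperparams)}
_SIM_KEYS = {f.name for f in fields(SyntheticSpec)}


@dataclass
class RunConfig:
    """Everything a command run needs: data paths, hyperparameters, CV plan."""

    data_dir: str | None = None
    modality_files: list[str] = field(default_factory=list)
    labels_file: str | None = None
    out_dir: str = "."
    hyperparams: Hyperparams = field(default_factory=Hyperparams)
    simulate: SyntheticSpec = field(default_factory=SyntheticSpec)
    n_folds: int = 10
    n_select: list[int | None] = field(default_factory=lambda: [5, 10, 20, 40, None])
    alpha_grid: list[float] = field(default_factory=lambda: list(ALPHA_BETA_GRID))
    beta_grid: list[float] = field(default_factory=lambda: list(ALPHA_BETA_GRID))
    scale: bool = True
    seed: int = 0

    def validate(self) -> None:
        self.hyperparams.validate()
        if self.n_folds < 2:
            raise ValidationError("n_folds must be at least 2")
        if self.data_dir is not None and not Path(self.data_dir).exists():
            raise ValidationError(f"data_dir does not exist: {self.data_dir}")
        for p in self.modality_files:
            if not Path(p).exists():
                raise ValidationError(f"modality file does not exist: {p}")
        if self.labels_file is not None and not Path(self.labels_file).exists():
            raise ValidationError(f"labels file does not exist: {self.labels_file}")

    def to_dict(self) -> dict:
        out = asdict(self)
        return out


_TOP_KEYS = {f.name for f in fields(RunConfig)}


def load_config(path: str | Path | None, overrides: dict | None = None) -> RunConfig:
    """Load + validate a YAML config; unknown keys are rejected by name.

    ``overrides`` (e.g. CLI flags) are applied after the file, using the
    same key set.  A missing/empty file yields the documented defaults.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValidationError(f"config root must be a mapping: {path}")
        raw = loaded
    if overrides:
        raw = {**raw, **{k: v for k, v in overrides.items() if v is not None}}

    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValidationError(f"unknown config key(s): {sorted(unknown)}")

    hp_raw = raw.pop("hyperparams", {}) or {}
    if not isinstance(hp_raw, dict):
        raise ValidationError("hyperparams must be a mapping")
    bad = set(hp_raw) - _HP_KEYS
    if bad:
        raise ValidationError(f"unknown hyperparams key(s): {sorted(bad)}")
    sim_raw = raw.pop("simulate", {}) or {}
    if not isinstance(sim_raw, dict):
        raise ValidationError("simulate must be a mapping")
    bad = set(sim_raw) - _SIM_KEYS
    if bad:
        raise ValidationError(f"unknown simulate key(s): {sorted(bad)}")

    try:
        cfg = RunConfig(
            hyperparams=Hyperparams(**hp_raw),
            simulate=SyntheticSpec(**sim_raw),
            **raw,
        )
    except TypeError as e:
        raise ValidationError(f"bad config value: {e}") from e
    # run seed propagates to nested sections unless they set their own
    if "seed" not in hp_raw:
        cfg.hyperparams.seed = cfg.seed
    if "seed" not in sim_raw:
        cfg.simulate.seed = cfg.seed
    cfg.validate()
    return cfg
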