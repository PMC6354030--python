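"""Run configuration with flag > config-file > default precedence."""
from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigError
from .seqio import DEFAULT_GROUP_CAP


@dataclass
class RunConfig:
    """Parameters of one end-to-end run.

    Defaults: k=21, logarithmic weighting, cosine metric, 6-letter partition
    prefixes, 4 GiB staging-group cap, no abundance filter.
    """

    k: int = 21
    weighting: str = "logarithmic"
    metric: str = "cosine"
    prefix_len: int = 6
    group_cap: int = DEFAULT_GROUP_CAP
    min_freq: int = 1
    n_partitions: int | None = None  # default: one per worker
    n_workers: int = 1
    seed: int = 0
    output_dir: str = "kmersweep_out"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigError(f"k must be >= 1, got {self.k}")
        if self.min_freq < 1:
            raise ConfigError(f"min_freq must be >= 1, got {self.min_freq}")
        if self.n_workers < 1:
            raise ConfigError(f"n_workers must be >= 1, got {self.n_workers}")
        if self.n_partitions is not None and self.n_partitions < 1:
            raise ConfigError(f"n_partitions must be >= 1, got {self.n_partitions}")

    @property
    def effective_partitions(self) -> int:
        return self.n_partitions if self.n_partitions is not None else self.n_workers

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(
        cls, path: str | os.PathLike | None, **overrides
    ) -> "RunConfig":
        """Build a config from an optional YAML/JSON file plus flag overrides.

        ``overrides`` entries that are None are ignored (flag not given).
        """
        base: dict = {}
        if path is not None:
            text = Path(path).read_text(encoding="utf-8")
            loaded = yaml.safe_load(text) if text.strip() else {}
            if loaded is None:
                loaded = {}
            if not isinstance(loaded, dict):
                raise ConfigError(f"{path}: config must be a mapping")
            base.update(loaded)
        base.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(base) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**base)
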