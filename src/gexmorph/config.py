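"""Pipeline configuration: one YAML document, one root seed.

A config either points at input files (``mode: files``) or describes a
synthetic scenario (``mode: synthetic``, the default). All stage randomness
derives from the single root ``seed`` through named substreams, so a config
plus a seed pins the entire run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ._validate import ValidationError, require

_FILE_KEYS = ("scan_table", "responses", "probes", "samples", "expr",
              "whitelist", "atlas_regions", "atlas_labels", "atlas_label_map",
              "gmt")


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "results"
    mode: str = "synthetic"
    # synthetic-mode overrides, forwarded to the generator specs
    synthetic: dict = field(default_factory=dict)
    # files-mode input paths, keyed by _FILE_KEYS
    files: dict = field(default_factory=dict)
    # analysis parameters
    case_group: str = "persistent"
    control_group: str = "control"
    summary_mode: str = "absolute"
    fraction: float = 0.025
    percentiles: tuple[float, float] = (2.5, 97.5)
    min_category: int = 3
    max_dist_mm: float = 3.0
    min_samples: int = 1
    variants: list = field(default_factory=list)
    # optional cluster-extent simulation settings
    cluster_sim: dict | None = None
    make_plots: bool = False

    def validate(self) -> "PipelineConfig":
        require(self.mode in ("synthetic", "files"),
                f"mode must be 'synthetic' or 'files', got {self.mode!r}")
        require(self.summary_mode in ("absolute", "signed"),
                f"summary_mode must be 'absolute' or 'signed'")
        require(0.0 < self.fraction <= 1.0,
                f"fraction must lie in (0, 1], got {self.fraction}")
        lo, hi = self.percentiles
        require(0.0 < lo < hi < 100.0,
                f"percentiles must satisfy 0 < lo < hi < 100, got {self.percentiles}")
        require(self.min_category >= 1, "min_category must be >= 1")
        if self.mode == "files":
            unknown = set(self.files) - set(_FILE_KEYS)
            require(not unknown, f"unknown file keys: {sorted(unknown)}")
            for key in ("scan_table", "responses", "probes", "samples",
                        "expr", "whitelist", "atlas_regions", "gmt"):
                require(key in self.files, f"files mode requires files.{key}")
            for key, path in self.files.items():
                require(Path(path).exists(), f"files.{key}: {path} does not exist")
        for variant in self.variants:
            require(isinstance(variant, dict) and "kind" in variant,
                    f"variant entries need a 'kind' key: {variant!r}")
        return self

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["percentiles"] = list(self.percentiles)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "percentiles" in d:
            d["percentiles"] = tuple(d["percentiles"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
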