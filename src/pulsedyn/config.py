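"""Pipeline configuration: a single human-editable YAML file with defaults.

Unknown keys are rejected and out-of-range values reported with their
allowed range, so a typo fails fast instead of silently running defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError
from .quant_io import ExperimentDesign
from .replicate_union import BinScheme, default_bin_scheme
from .synthetic_data import PERSISTENCE_TIMES_H, RESUSCITATION_TIMES_H


@dataclass
class PipelineConfig:
    # paths
    input_table: str | None = None
    fasta: str | None = None
    annotations: str | None = None
    out_dir: str = "pulsedyn_out"
    # experiment design
    condition: str = "persistence"
    replicates: list[str] = field(default_factory=lambda: ["rep1", "rep2", "rep3"])
    time_points_h: list[float] = field(default_factory=list)
    bin_scheme: list[dict] | None = None  # [{label: ..., times: [...]}, ...]
    # stage parameters
    min_ratio_count: int = 2
    min_points: int = 5
    min_r2: float = 0.70
    k_clusters: int = 8
    span: float = 0.5
    fdr: float = 0.1
    min_category_size: int = 3
    min_pep_len: int = 7
    max_pep_len: int = 30
    max_missed: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in ("persistence", "resuscitation"):
            raise ConfigError(
                f"condition must be 'persistence' or 'resuscitation', got {self.condition!r}"
            )
        if not self.time_points_h:
            self.time_points_h = list(
                PERSISTENCE_TIMES_H
                if self.condition == "persistence"
                else RESUSCITATION_TIMES_H
            )
        _check_range("min_ratio_count", self.min_ratio_count, 0, None, int)
        _check_range("min_points", self.min_points, 1, None, int)
        _check_range("min_r2", self.min_r2, 0.0, 1.0)
        _check_range("k_clusters", self.k_clusters, 1, None, int)
        if not (0.0 < self.span <= 1.0):
            raise ConfigError(f"span must lie in (0, 1], got {self.span}")
        if not (0.0 < self.fdr <= 1.0):
            raise ConfigError(f"fdr must lie in (0, 1], got {self.fdr}")
        _check_range("min_category_size", self.min_category_size, 1, None, int)
        _check_range("min_pep_len", self.min_pep_len, 1, None, int)
        _check_range("max_pep_len", self.max_pep_len, self.min_pep_len, None, int)
        _check_range("max_missed", self.max_missed, 0, None, int)

    def design(self) -> ExperimentDesign:
        return ExperimentDesign(
            condition=self.condition,
            replicates=list(self.replicates),
            time_points_h=list(self.time_points_h),
        )

    def resolved_bin_scheme(self) -> BinScheme:
        design = self.design()
        if self.bin_scheme is None:
            return default_bin_scheme(self.condition, design.pulse_times_h)
        bins = []
        for entry in self.bin_scheme:
            unknown = set(entry) - {"label", "times"}
            if unknown:
                raise ConfigError(
                    f"unknown bin_scheme key(s): {', '.join(sorted(unknown))}"
                )
            bins.append((str(entry["label"]), [float(t) for t in entry["times"]]))
        scheme = BinScheme(bins=bins, condition=self.condition)
        scheme.validate_against(design)
        return scheme

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _check_range(name, value, lo, hi, typ=float) -> None:
    if typ is int and not isinstance(value, int):
        raise ConfigError(f"{name} must be an integer, got {value!r}")
    if lo is not None and value < lo:
        raise ConfigError(f"{name} must be >= {lo}, got {value}")
    if hi is not None and value > hi:
        raise ConfigError(f"{name} must be <= {hi}, got {value}")


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML config file into a typed PipelineConfig."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
    config = PipelineConfig(**raw)
    for key in ("input_table", "fasta", "annotations"):
        value = getattr(config, key)
        if value is not None and not Path(value).exists():
            raise ConfigError(f"{key} path does not exist: {value}")
    return config
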