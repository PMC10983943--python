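"""Run configuration: a single YAML file with CLI overrides."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml


class ConfigError(ValueError):
    """Invalid run configuration; message names the offending field."""


@dataclass
class MutationTableSpec:
    path: str
    group_label: str
    sample_id: Optional[str] = None
    intended_edit_position: Optional[int] = None
    spacer_id: Optional[str] = None


@dataclass
class RunConfig:
    genome: str
    output_dir: str
    mutation_tables: list[MutationTableSpec] = field(default_factory=list)
    annotation: Optional[str] = None
    spacers: dict[str, str] = field(default_factory=dict)
    parental_mutations: list[list] = field(default_factory=list)
    intended_edits: list[list] = field(default_factory=list)
    max_mismatch_plus_gap: int = 6
    max_gaps: int = 2
    pam_pattern: str = "NGG"
    min_read_fraction: float = 0.10
    pool_designs: list[dict] = field(default_factory=list)
    mu_nt: float = 2.0e-10
    generations: float = 80
    null_model: str = "poisson"
    alpha: float = 0.05
    proximity_within: int = 2000
    seed: int = 0

    def validate(self) -> None:
        if not self.genome:
            raise ConfigError("field 'genome' is required")
        if not Path(self.genome).exists():
            raise ConfigError(f"field 'genome': file not found: {self.genome}")
        if self.annotation and not Path(self.annotation).exists():
            raise ConfigError(
                f"field 'annotation': file not found: {self.annotation}"
            )
        for t in self.mutation_tables:
            if not Path(t.path).exists():
                raise ConfigError(
                    f"field 'mutation_tables': file not found: {t.path}"
                )
        if self.max_mismatch_plus_gap < 0 or self.max_gaps < 0:
            raise ConfigError("field 'max_gaps'/'max_mismatch_plus_gap': "
                              "scan bounds must be non-negative")
        if not 0 < self.alpha < 1:
            raise ConfigError("field 'alpha': must be in (0, 1)")
        if not 0 <= self.min_read_fraction < 1:
            raise ConfigError("field 'min_read_fraction': must be in [0, 1)")
        if self.null_model not in ("poisson", "linear"):
            raise ConfigError("field 'null_model': must be poisson or linear")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        tables = [
            MutationTableSpec(**t) if isinstance(t, dict) else t
            for t in raw.pop("mutation_tables", [])
        ]
        try:
            cfg = cls(mutation_tables=tables, **raw)
        except TypeError as exc:
            raise ConfigError(f"bad configuration key: {exc}") from exc
        cfg.validate()
        return cfg
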