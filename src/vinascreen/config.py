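"""Structured run configuration.

All tunables have materialized defaults; the effective values are echoed
into the run's provenance record so a finished run directory is
self-describing.  Unknown keys in a config file are rejected rather than
ignored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import VinascreenError


@dataclass
class PathsConfig:
    receptors_dir: str = "receptors"
    ligands_dir: str = "ligands"
    work_dir: str = "work"
    interaction_table: str = ""
    landscape: str = ""          # mock-backend landscape JSON


@dataclass
class DockingConfig:
    exhaustiveness: int = 9
    replicates: int = 3
    cpu: int = 9                 # cores per job; mirrors the exhaustiveness level
    num_modes: int = 9
    box_margin: float = 10.0     # Å added around the receptor extent
    backend: str = "mock"        # "mock" | "vina"
    vina_executable: str = "vina"
    master_seed: int = 0
    workers: int = 1


@dataclass
class ReceptorPrepConfig:
    plddt_threshold: float = 70.0
    alphafold: bool = True       # temperature factors are pLDDT


@dataclass
class ScoringConfig:
    z_threshold: float = -1.541
    minmax_fraction: float = 0.05
    sd_ddof: int = 0             # 0 = population sd
    minmax_per_row: bool = False


@dataclass
class ValidationConfig:
    target_column: str = "ACCESSION"
    drug_column: str = "DRUG_NAME"
    drug_id_map: str = ""        # optional TSV: raw drug value -> ligand id
    gene_names: str = ""         # optional TSV: receptor id -> gene name
    drug_names: str = ""         # optional TSV: ligand id -> drug name


@dataclass
class RunConfig:
    paths: PathsConfig = field(default_factory=PathsConfig)
    docking: DockingConfig = field(default_factory=DockingConfig)
    receptor_prep: ReceptorPrepConfig = field(default_factory=ReceptorPrepConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    validation: ValidationConfig = field(default_factory=ValidationConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        config = cls()
        for section_name, section_value in data.items():
            if not hasattr(config, section_name):
                raise VinascreenError(f"unknown config section {section_name!r}")
            section = getattr(config, section_name)
            if not isinstance(section_value, dict):
                raise VinascreenError(f"config section {section_name!r} must be a mapping")
            valid = {f.name for f in dataclasses.fields(section)}
            for key, value in section_value.items():
                if key not in valid:
                    raise VinascreenError(
                        f"unknown config key {section_name}.{key!r}; valid: {sorted(valid)}"
                    )
                setattr(section, key, value)
        return config

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def write_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
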