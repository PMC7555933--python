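"""Pipeline configuration: typed parameter blocks with YAML round-trip.

Configuration is a tree of dataclasses mirroring the pipeline stages.
Unknown keys are rejected on load and numeric parameters are validated
against their documented ranges, so a typo fails before any compute.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .core import MIN_MIRNA_LEN, MAX_MIRNA_LEN
from .normde import P_TIERS
from .qpcr import FOLD_DOWN, FOLD_UP
from .simulate import DEFAULT_ADAPTER, READ_LENGTH


@dataclass
class SimulateConfig:
    """Synthetic-study block; used when no external reads are supplied."""

    n_mirnas: int = 10
    length_range: tuple[int, int] = (MIN_MIRNA_LEN, MAX_MIRNA_LEN)
    n_replicates: int = 2
    sexes: tuple[str, ...] = ("M", "F")
    ages: tuple[int, ...] = (3, 6, 15, 25, 30)
    depth: int = 100_000
    n_de: int = 3
    log2fc: float = 2.0
    n_edited_sites: int = 3
    fraction_range: tuple[float, float] = (0.05, 0.40)
    baseline_mean_range: tuple[float, float] = (100.0, 10_000.0)
    dispersion: float = 25.0
    error_rate: float = 0.001
    read_length: int = READ_LENGTH

    def validate(self) -> None:
        if self.n_mirnas < 1 or self.depth < 1 or self.n_replicates < 1:
            raise ValueError("n_mirnas, depth and n_replicates must be >= 1")
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")


@dataclass
class CleanConfig:
    adapter: str = DEFAULT_ADAPTER
    min_len: int = MIN_MIRNA_LEN
    max_len: int = MAX_MIRNA_LEN
    max_fraction_n: float = 0.0
    min_mean_quality: float = 20.0

    def validate(self) -> None:
        if not self.adapter:
            raise ValueError("adapter must be non-empty")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if not 0.0 <= self.max_fraction_n <= 1.0:
            raise ValueError("max_fraction_n must be in [0, 1]")


@dataclass
class MapConfig:
    max_mm: int = 2
    max_3prime_slack: int = 2

    def validate(self) -> None:
        if self.max_mm < 0 or self.max_3prime_slack < 0:
            raise ValueError("max_mm and max_3prime_slack must be >= 0")


@dataclass
class EditConfig:
    error_rate: float = 0.001
    min_fraction_factor: float = 3.0
    min_edited_reads: int = 5
    min_avg_reads: float = 3000.0  # strict > on mean normalized count

    def validate(self) -> None:
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")
        if self.min_edited_reads < 1:
            raise ValueError("min_edited_reads must be >= 1")


@dataclass
class DEConfig:
    pseudocount: float = 1.0
    log_scale: bool = True
    equal_var: bool = False
    tiers: tuple[float, float, float] = P_TIERS

    def validate(self) -> None:
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if list(self.tiers) != sorted(self.tiers):
            raise ValueError("tiers must be increasing")


@dataclass
class QpcrConfig:
    control_age_months: int = 3
    fold_up: float = FOLD_UP
    fold_down: float = FOLD_DOWN
    rtc_max: float = 5.0
    gpc_min: float = 35.0

    def validate(self) -> None:
        if self.fold_down >= self.fold_up:
            raise ValueError("fold_down must be below fold_up")


@dataclass
class SangerConfig:
    reference_id: str | None = None  # miRNA id to validate (e.g. miR-143)
    min_identity: float = 0.8
    min_recurrence: int = 1

    def validate(self) -> None:
        if not 0.0 < self.min_identity <= 1.0:
            raise ValueError("min_identity must be in (0, 1]")


@dataclass
class PipelineConfig:
    """Full pipeline configuration.

    Inputs come either from files (``reference_fasta``, ``design_tsv``,
    ``reads_dir`` with ``<sample_id>.fastq``) or from the ``simulate``
    block; qPCR and Sanger inputs are optional side channels.
    """

    output_dir: str = "miredit_out"
    seed: int = 0
    reference_fasta: str | None = None
    design_tsv: str | None = None
    reads_dir: str | None = None
    ct_table_tsv: str | None = None
    clones_fasta: str | None = None
    clones_meta_tsv: str | None = None
    write_reads: bool = False
    plots: bool = False
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    clean: CleanConfig = field(default_factory=CleanConfig)
    mapping: MapConfig = field(default_factory=MapConfig)
    edit: EditConfig = field(default_factory=EditConfig)
    de: DEConfig = field(default_factory=DEConfig)
    qpcr: QpcrConfig = field(default_factory=QpcrConfig)
    sanger: SangerConfig = field(default_factory=SangerConfig)

    @property
    def simulate_mode(self) -> bool:
        return self.reads_dir is None

    def validate(self) -> None:
        for block in (
            self.simulate, self.clean, self.mapping, self.edit,
            self.de, self.qpcr, self.sanger,
        ):
            block.validate()
        if self.reads_dir is not None:
            if self.reference_fasta is None or self.design_tsv is None:
                raise ValueError(
                    "reads_dir requires reference_fasta and design_tsv"
                )
            for path in (self.reads_dir, self.reference_fasta, self.design_tsv):
                if not Path(path).exists():
                    raise ValueError(f"input path does not exist: {path}")
        if (self.clones_fasta is None) != (self.clones_meta_tsv is None):
            raise ValueError(
                "clones_fasta and clones_meta_tsv must be given together"
            )


_TUPLE_FIELDS = {
    "length_range", "fraction_range", "baseline_mean_range", "tiers",
    "sexes", "ages",
}


def _from_dict(cls, data: dict[str, Any], path: str = ""):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        where = path or cls.__name__
        raise ValueError(f"unknown configuration keys in {where}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = known[name].type
        if dataclasses.is_dataclass(_BLOCKS.get(name)) and isinstance(value, dict):
            kwargs[name] = _from_dict(_BLOCKS[name], value, f"{path}.{name}" if path else name)
        elif name in _TUPLE_FIELDS and isinstance(value, (list, tuple)):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


_BLOCKS = {
    "simulate": SimulateConfig,
    "clean": CleanConfig,
    "mapping": MapConfig,
    "edit": EditConfig,
    "de": DEConfig,
    "qpcr": QpcrConfig,
    "sanger": SangerConfig,
}


def config_from_dict(data: dict[str, Any]) -> PipelineConfig:
    cfg = _from_dict(PipelineConfig, data)
    cfg.validate()
    return cfg


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping: {path}")
    return config_from_dict(data)


def config_to_dict(cfg: PipelineConfig) -> dict[str, Any]:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: convert(getattr(obj, f.name)) for f in fields(obj)}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    return convert(cfg)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
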