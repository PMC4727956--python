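"""Pipeline configuration: stage-scoped parameter namespaces with the
method's published thresholds as defaults, plus YAML (de)serialisation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


class ConfigError(ValueError):
    """Invalid configuration value; message names the offending field."""


@dataclass
class BaitDesignParams:
    # candidate-exon filters
    min_len: int = 150                  # exons must be *longer* than this
    gc_lo: float = 0.30
    gc_hi: float = 0.70
    n_required_families: int = 7        # non-reference families with coverage
    min_overlap_fraction: float = 0.90  # covered fraction counting as "overlapping"
    unique_identity: float = 0.90       # reciprocal cross-gene hit thresholds
    unique_coverage: float = 0.80
    repeat_k: int = 15
    max_shared_kmer_fraction: float = 0.25
    low_complexity_max_fraction: float = 0.50
    low_complexity_min_entropy: float = 2.0
    # lenient transcriptome-to-reference mapping
    min_identity: float = 0.70
    # probe tiling
    probe_length: int = 60
    tiling_step: int = 1
    probe_replicates: int = 2

    def validate(self) -> None:
        if not 0 <= self.gc_lo < self.gc_hi <= 1:
            raise ConfigError(f"baitdesign.gc_lo/gc_hi: need 0 <= lo < hi <= 1, "
                              f"got {self.gc_lo}/{self.gc_hi}")
        if self.min_len < 1:
            raise ConfigError("baitdesign.min_len must be >= 1")
        if not 0 < self.min_identity <= 1:
            raise ConfigError("baitdesign.min_identity must be in (0, 1]")
        if self.tiling_step < 1:
            raise ConfigError("baitdesign.tiling_step must be >= 1")
        if self.repeat_k < 8:
            raise ConfigError("baitdesign.repeat_k must be >= 8")


@dataclass
class ReadProcParams:
    lenient_identity: float = 0.70   # first-pass mapping for reference adjustment
    strict_identity: float = 0.93    # final mapping feeding the pileup
    min_depth_call: int = 20         # below this, variant sites become N
    min_depth_keep: int = 5          # below this, positions are discarded
    min_alt_fraction: float = 0.25
    hom_fraction: float = 0.80       # alt fraction at/above which a call is hom
    max_rounds: int = 3              # reference-adjustment iterations
    adjust_min_depth: int = 2        # majority-difference support during adjustment
    min_read_len: int = 40           # post-trim length floor
    seed_k: int = 11                 # seed size for read-to-target assignment
    extend_flanks: bool = False      # greedy k-mer flank extension during adjustment

    def validate(self) -> None:
        if self.strict_identity <= self.lenient_identity:
            raise ConfigError("readproc.strict_identity must exceed lenient_identity")
        if self.min_depth_keep > self.min_depth_call:
            raise ConfigError("readproc.min_depth_keep must not exceed min_depth_call")
        if self.max_rounds < 1:
            raise ConfigError("readproc.max_rounds must be >= 1")


@dataclass
class AlignFilterParams:
    coverage_hard_cutoff: float = 200.0
    mad_multiplier: float = 4.0
    contaminant_k: int = 21
    contaminant_min_shared: float = 0.30
    skew_threshold: float = 0.15          # terminal branch / total tree length
    max_gap_row_fraction: float = 0.50    # a row this gappy counts as gappy
    max_gappy_row_share: float = 0.25     # flag gene when > this share of rows
    min_row_content: float = 0.30         # unambiguous fraction for a row to
                                          # enter the gene tree (else missing)
    keep_rdna_mito: bool = False          # optionally retain rDNA/mito-class hits

    def validate(self) -> None:
        if self.coverage_hard_cutoff <= 0:
            raise ConfigError("alignfilter.coverage_hard_cutoff must be > 0")
        if not 0 < self.skew_threshold < 1:
            raise ConfigError("alignfilter.skew_threshold must be in (0, 1)")


@dataclass
class PhyloParams:
    n_addition_replicates: int = 100
    bootstrap_replicates: int = 1000
    missing_char: str = "?"

    def validate(self) -> None:
        if self.n_addition_replicates < 1:
            raise ConfigError("phylo.n_addition_replicates must be >= 1")
        if self.bootstrap_replicates < 1:
            raise ConfigError("phylo.bootstrap_replicates must be >= 1")


@dataclass
class PipelineConfig:
    seed: int = 0
    baitdesign: BaitDesignParams = field(default_factory=BaitDesignParams)
    readproc: ReadProcParams = field(default_factory=ReadProcParams)
    alignfilter: AlignFilterParams = field(default_factory=AlignFilterParams)
    phylo: PhyloParams = field(default_factory=PhyloParams)

    def validate(self) -> "PipelineConfig":
        for section in (self.baitdesign, self.readproc, self.alignfilter, self.phylo):
            section.validate()
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTIONS = {"baitdesign": BaitDesignParams, "readproc": ReadProcParams,
             "alignfilter": AlignFilterParams, "phylo": PhyloParams}


def config_from_dict(data: dict) -> PipelineConfig:
    cfg = PipelineConfig(seed=int(data.get("seed", 0)))
    for name, cls in _SECTIONS.items():
        section = data.get(name) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(section) - known
        if unknown:
            raise ConfigError(f"{name}: unknown parameter(s) {sorted(unknown)}")
        setattr(cfg, name, cls(**section))
    return cfg.validate()


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return config_from_dict(data)


def save_config(path, cfg: PipelineConfig) -> None:
    with open(path, "w", newline="\n") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
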