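"""Configuration objects for the synthetic study and the pipeline.

``SimConfig`` holds the generative assumptions of the synthetic cohort:
two highly inbred strains bred from a pool of five sequenced founder
strains plus one latent "unknown" founder haplotype (standing in for the
unsequenced founders combined with the reference-like strain), with
recombination-map-modulated ancestry switch points, negative-binomial
read depths and binomial allele support.

``Thresholds`` collects the classification / analysis constants used
throughout the pipeline. Defaults: per-strain depth >= 5 with >= 90%
allele support, cross-check at 3 reads / 50%, repeat margin +-5 bp,
DE significance at adjusted p <= 0.1, 500 kb windows with 100 kb step,
SV target FDR 0.05.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = ["SimConfig", "Thresholds", "ConfigError"]


class ConfigError(ValueError):
    """Invalid configuration."""


def _default_recomb_map():
    # flat 0.5 cM/Mb over a 100 Mb chromosome -> 50 cM total
    return [(0, 0.5), (100_000_000, 0.5)]


@dataclass
class SimConfig:
    """Generative parameters of the synthetic two-strain study."""

    # founder pool and sites
    n_founders: int = 5                 # sequenced founders; one latent unknown is added
    n_sites: int = 5000
    chrom: str = "chr1"
    chrom_length: int = 100_000_000
    recomb_map: list = field(default_factory=_default_recomb_map)

    # mosaic ancestry
    switch_scale: float = 20.0          # expected ancestry switches per Morgan
    homozygosity: float = 0.9987        # fraction of fixed (homozygous) genotypes
    seq_error: float = 0.005            # per-read / per-genotype error probability

    # read support
    mean_depth: float = 30.0
    depth_dispersion: float = 3.0       # negative-binomial size parameter
    min_depth: int = 0                  # lower clip on simulated depths

    # founder panel structure
    founder_alt_freq: float = 0.35      # marginal alt-allele frequency per founder
    ibd_run_fraction: float = 0.10      # fraction of sites inside founder-pair IBD runs
    ibd_run_length: int = 100           # sites per IBD run
    unknown_fraction: float = 0.15      # sites where only the unknown founder is alt
    indel_fraction: float = 0.15        # fraction of sites that are small indels
    catalog_fraction: float = 0.85      # fraction of sites flagged as known-catalog

    # annotation / landscape tracks
    repeat_fraction: float = 0.05
    n_repeats: int = 40
    n_genes: int = 20
    n_qtl: int = 4
    qtl_fraction: float = 0.10          # genome fraction covered by QTL intervals
    qtl_density_boost: float = 1.0      # relative variant density inside QTLs

    # structural variants
    n_sv: int = 200
    sv_unique_fraction: float = 0.5
    sv_mean_support: float = 20.0
    sv_noise_support: float = 0.3       # Poisson mean of cross-strain noise support
    sv_duplicate_rate: float = 0.1      # redundant overlapping-call rate
    sv_translocation_fraction: float = 0.05
    sv_breakpoint_jitter: int = 50

    strain_names: tuple = ("strainA", "strainB")
    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.n_founders < 1:
            raise ConfigError("need at least one sequenced founder")
        if self.n_sites < 1:
            raise ConfigError("need at least one site")
        if not self.recomb_map:
            raise ConfigError("recombination map is empty")
        pos = [p for p, _ in self.recomb_map]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ConfigError("recombination map positions must be strictly increasing")
        for name in ("seq_error", "homozygosity", "founder_alt_freq",
                     "ibd_run_fraction", "unknown_fraction", "indel_fraction",
                     "catalog_fraction", "repeat_fraction", "qtl_fraction",
                     "sv_unique_fraction", "sv_duplicate_rate",
                     "sv_translocation_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.mean_depth <= 0:
            raise ConfigError("mean_depth must be positive")
        if self.switch_scale < 0:
            raise ConfigError("switch_scale must be non-negative")
        if len(self.strain_names) != 2:
            raise ConfigError("exactly two strains are modelled")
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["recomb_map"] = [list(t) for t in self.recomb_map]
        d["strain_names"] = list(self.strain_names)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown SimConfig fields: {sorted(unknown)}")
        d = dict(d)
        if "recomb_map" in d:
            d["recomb_map"] = [tuple(t) for t in d["recomb_map"]]
        if "strain_names" in d:
            d["strain_names"] = tuple(d["strain_names"])
        return cls(**d).validate()


@dataclass
class Thresholds:
    """Classification and analysis constants."""

    min_depth: int = 5
    min_support: float = 0.90
    cross_min_depth: int = 3
    cross_min_support: float = 0.50
    repeat_margin: int = 5
    alpha: float = 0.1
    borderline_factor: float = 2.0
    window_size: int = 500_000
    window_step: int = 100_000
    target_fdr: float = 0.05
    reciprocal_overlap: float = 0.5
    breakpoint_tol: int = 600

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Thresholds":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown Thresholds fields: {sorted(unknown)}")
        return cls(**d)


def load_config(path) -> tuple[SimConfig, Thresholds]:
    """Read a YAML pipeline config with optional ``sim`` / ``thresholds`` sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = SimConfig.from_dict(raw.get("sim", {}))
    thr = Thresholds.from_dict(raw.get("thresholds", {}))
    return sim, thr


def dump_config(path, sim: SimConfig, thr: Thresholds) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"sim": sim.to_dict(), "thresholds": thr.to_dict()}, fh,
                       sort_keys=False)
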