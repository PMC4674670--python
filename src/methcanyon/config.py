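"""Simulation configuration for matched WT/DKO bisulfite and RNA data.

The defaults describe a scaled-down haematopoietic stem/progenitor (LSK)
methylome with the features the downstream analysis assumes: a bimodal
genome-wide methylation distribution, unmethylated CpG islands and long
(>=3.5 kb) methylation canyons at promoters, intermediate-methylation
active enhancers, and a knockout condition (DKO, loss of the TET
demethylation machinery) that adds a slight global methylation gain plus
hypermethylation at canyon edges and enhancer flanks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class SimConfig:
    """Parameters of the synthetic methylome/transcriptome generator.

    All methylation parameters are fractions in [0, 1]; methylation after
    additive shifts is clamped to [0, 1].  Identical config + seed yields
    byte-identical output files.
    """

    # genome layout
    n_chroms: int = 2
    chrom_length: int = 1_500_000          # bp per chromosome
    cpg_background_rate: float = 0.008     # expected CpGs per bp outside CGIs
    cgi_cpg_rate: float = 0.04             # CpG density inside CGIs/canyons

    # annotation counts
    n_genes: int = 300
    n_cgis: int = 160
    n_enhancers: int = 140
    n_canyons: int = 50

    # methylation signal
    coverage_mean: float = 30.0            # Poisson mean reads per CpG
    baseline_beta_high: float = 0.85       # methylated compartment
    baseline_beta_low: float = 0.02        # CGIs / canyons
    enhancer_center_beta: float = 0.15     # central third of enhancers
    enhancer_flank_beta: float = 0.55      # outer thirds of enhancers
    beta_concentration: float = 60.0       # Beta-noise concentration around means

    # DKO (knockout) effects, all additive on true methylation
    dko_global_gain: float = 0.03
    edge_gain_fraction: float = 0.41       # fraction of canyons planted shrinking
    edge_gain_delta: float = 0.20          # shift on shrinking-canyon edge windows
    enhancer_gain_delta: float = 0.15      # shift on enhancer flanks

    # expression
    de_fraction: float = 0.10
    de_up_to_down_ratio: float = 2.0
    de_log2fc: float = 1.5
    nb_dispersion: float = 0.01          # BCV ~0.1: genetically identical mice
    n_replicates: int = 3

    seed: int = 0

    # geometry of planted features (bp)
    gene_length_min: int = 2_000
    gene_length_max: int = 8_000
    cgi_length: int = 1_000
    enhancer_length: int = 1_500
    canyon_length_min: int = 3_500
    canyon_length_max: int = 8_000

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        fractions = {
            "cpg_background_rate": self.cpg_background_rate,
            "cgi_cpg_rate": self.cgi_cpg_rate,
            "baseline_beta_high": self.baseline_beta_high,
            "baseline_beta_low": self.baseline_beta_low,
            "enhancer_center_beta": self.enhancer_center_beta,
            "enhancer_flank_beta": self.enhancer_flank_beta,
            "edge_gain_fraction": self.edge_gain_fraction,
            "de_fraction": self.de_fraction,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.coverage_mean < 0:
            raise ValueError("coverage_mean must be non-negative")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if self.canyon_length_min < 3_500:
            raise ValueError("canyon_length_min below the 3.5 kb canyon definition")
        for name in ("n_chroms", "chrom_length", "n_genes", "n_cgis",
                     "n_enhancers", "n_canyons"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
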