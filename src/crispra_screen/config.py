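"""Simulation configuration for synthetic CRISPRa screens.

The defaults describe a desk-scale version of a pooled CRISPRa screen in
mouse embryonic stem cells: 230 candidate target genes with two sgRNAs
each plus 15 non-targeting controls (475 guides), ~100 cells per guide,
a rare ZGA-like transcriptional state active in ~2% of baseline cells and
~8.6% of cells carrying a true-hit sgRNA, and amplicon/repeat read
generation with realistic error processes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

# Fixed 23-nt vector arms flanking the protospacer in amplicon reads.
# Arbitrary package constants standing in for the sgRNA-expression vector
# sequence; only their length (23 nt each) matters to the matching rules.
UPSTREAM_CONTEXT = "TGGAAAGGACGAAACACCGGTTT"
DOWNSTREAM_CONTEXT = "GTTTTAGAGCTAGGCCAACATGA"

DEFAULT_REPEAT_FAMILIES = (
    "LINE-1",
    "ERV1",
    "ERVK",
    "MERVL",
    "Major satellites",
    "SINE Alu B1",
    "SINE B2",
    "SINE B4",
)

# Mean repeat-family molecules per cell at baseline, roughly proportional
# to the relative read totals observed for these families in screen-scale
# repeat mapping (LINE-1 and ERVK dominate; MERVL is low outside the
# ZGA-like state).
DEFAULT_REPEAT_MEANS = {
    "LINE-1": 30.0,
    "ERV1": 2.2,
    "ERVK": 26.0,
    "MERVL": 2.5,
    "Major satellites": 0.7,
    "SINE Alu B1": 0.9,
    "SINE B2": 9.0,
    "SINE B4": 1.0,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic screen generator.

    Probabilities are in [0, 1]; counts are positive. ``total_guides``
    is ``n_target_genes * sgrnas_per_target + n_nontargeting``.
    """

    # library design
    n_target_genes: int = 230
    sgrnas_per_target: int = 2
    n_nontargeting: int = 15
    protospacer_length: int = 20
    min_guide_distance: int = 4

    # cell population
    cells_per_sgrna: int = 100
    n_genes: int = 2000
    n_signature_genes: int = 150
    n_mito_genes: int = 13

    # ZGA-like state
    baseline_state_prob: float = 0.02
    hit_state_prob: float = 0.0856
    n_true_hits: int = 10
    hits_share_gene: bool = True
    state_intensity_sigma: float = 0.3
    signature_fold: float = 8.0
    mervl_state_fold: float = 20.0

    # CRISPRa effect
    activation_log2fc: float = 2.0

    # count model
    nb_dispersion: float = 0.1
    median_libsize: float = 9000.0
    libsize_lognormal_sigma: float = 0.15
    gene_mean_lognormal_sigma: float = 0.5
    mito_beta_a: float = 16.0
    mito_beta_b: float = 784.0

    # planted low-quality cells (removed by QC)
    lowquality_cell_rate: float = 0.02
    lowquality_libsize: float = 1500.0
    lowquality_mito_beta_a: float = 30.0
    lowquality_mito_beta_b: float = 170.0

    # amplicon readout
    amplicon_reads_per_cell: float = 20.0
    contamination_rate: float = 0.05
    base_error_rate: float = 0.005
    doublet_rate: float = 0.04

    # repeat readout
    repeat_families: tuple = DEFAULT_REPEAT_FAMILIES
    repeat_means: dict = field(default_factory=lambda: dict(DEFAULT_REPEAT_MEANS))
    repeat_read_length: int = 50
    repeat_instances_per_family: int = 3
    repeat_instance_length: int = 300
    repeat_reads_per_molecule: float = 1.5

    seed: int = 0

    @property
    def total_guides(self) -> int:
        return self.n_target_genes * self.sgrnas_per_target + self.n_nontargeting

    def validate(self) -> None:
        probs = {
            "baseline_state_prob": self.baseline_state_prob,
            "hit_state_prob": self.hit_state_prob,
            "contamination_rate": self.contamination_rate,
            "base_error_rate": self.base_error_rate,
            "doublet_rate": self.doublet_rate,
            "lowquality_cell_rate": self.lowquality_cell_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        counts = {
            "n_target_genes": self.n_target_genes,
            "sgrnas_per_target": self.sgrnas_per_target,
            "cells_per_sgrna": self.cells_per_sgrna,
            "n_genes": self.n_genes,
            "n_signature_genes": self.n_signature_genes,
            "protospacer_length": self.protospacer_length,
        }
        for name, c in counts.items():
            if c <= 0:
                raise ValueError(f"{name} must be positive, got {c}")
        if self.n_nontargeting < 0 or self.n_mito_genes < 0:
            raise ValueError("n_nontargeting and n_mito_genes must be >= 0")
        if self.n_true_hits < 0 or self.n_true_hits > self.n_target_genes * self.sgrnas_per_target:
            raise ValueError("n_true_hits must be between 0 and the number of targeting guides")
        if self.n_signature_genes + self.n_mito_genes > self.n_genes:
            raise ValueError("signature and mitochondrial genes exceed n_genes")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.median_libsize <= 0:
            raise ValueError("median_libsize must be positive")
        missing = set(self.repeat_families) - set(self.repeat_means)
        if missing:
            raise ValueError(f"repeat_means missing for families: {sorted(missing)}")

    @classmethod
    def noiseless(cls, **overrides) -> "SimulationConfig":
        """A fully deterministic-effect preset: no read errors, no
        contamination, no doublets, no low-quality cells, and the ZGA-like
        state switched on in every hit-sgRNA cell and in no other cell.
        Used for exact end-to-end recovery checks."""
        params = dict(
            base_error_rate=0.0,
            contamination_rate=0.0,
            doublet_rate=0.0,
            lowquality_cell_rate=0.0,
            baseline_state_prob=0.0,
            hit_state_prob=1.0,
        )
        params.update(overrides)
        return cls(**params)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["repeat_families"] = list(self.repeat_families)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "repeat_families" in data:
            data["repeat_families"] = tuple(data["repeat_families"])
        cfg = cls(**data)
        cfg.validate()
        return cfg
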