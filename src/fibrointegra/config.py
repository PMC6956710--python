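"""Pipeline configuration: every threshold the analyses use, in one record.

All cutoffs that the published-style analyses depend on (variable-probe
fraction, |Δβ| and p cutoffs, consensus-clustering iterations, CPM filter,
XCI decision thresholds, compartment bin size) live here so that each output
can record the exact settings and seed that produced it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """A configuration value is outside its documented range."""


@dataclass
class GeneratorConfig:
    """Synthetic-cohort generator settings (study-profile defaults).

    Group sizes default to the study design: 10 normal myometria and
    24 fibroids split into 16 MED12-mutant, 4 HMGA2-high and 4 HMGA1-high.
    """

    # cohort design
    n_normal: int = 10
    n_med12: int = 16
    n_hmga2: int = 4
    n_hmga1: int = 4

    # array content
    n_cpg: int = 20_000
    n_cph: int = 200
    n_snp: int = 59

    # beta-value noise: Beta(mu*kappa, (1-mu)*kappa)
    kappa: float = 50.0
    missing_rate: float = 0.002

    # planted high-variance (subtype-informative) probes
    n_informative_pan: int = 30        # shifted in all fibroid subtypes
    n_informative_subtype: int = 40    # per subtype, shifted in that subtype only
    pan_delta: float = 0.4
    subtype_delta: float = 0.5

    # planted distal DMC probes feeding the TFBS enrichment
    n_tfbs_dmc: int = 200
    tfbs_dmc_delta: float = 0.25
    n_tfbs_background: int = 3000
    tf_labels: tuple[str, ...] = (
        "EZH2", "SUZ12", "ESR1", "CTCF", "FOXA1",
        "GATA3", "MYC", "REST", "SPI1", "STAT3",
    )
    enriched_tf: str = "EZH2"
    enriched_tf_rate: float = 0.8      # fraction of planted DMC probes in the enriched TF's sites
    background_tf_rate: float = 0.05   # per-TF membership rate among background distal probes

    # expression
    n_genes: int = 2000
    nb_dispersion: float = 0.1
    marker_base_cpm: float = 5.0
    # planted marker effects (gene, subtype) -> log2 fold change vs normal
    marker_log2fc: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("HMGA2", "HMGA2hi"): 11.6,
            ("HMGA2", "MED12mt"): 3.2,
            ("HOXA13", "HMGA2hi"): 4.4,
            ("HOXA13", "MED12mt"): 3.0,
            ("HMGA1", "HMGA1hi"): 3.0,
        }
    )
    # promoter-hypermethylation-coupled silenced genes (all fibroid subtypes)
    n_coupled_genes: int = 20
    coupled_log2fc: float = -2.0
    coupled_delta_beta: float = 0.35
    # shared transcriptional program (up/down in every fibroid subtype)
    n_program_genes: int = 100
    program_log2fc: float = 2.0
    # genes expressed below the CPM filter
    n_low_expressed: int = 200

    # purity (smooth-muscle / mesenchymal fraction)
    purity_fibroid: tuple[float, float] = (0.7, 0.9)
    purity_normal: tuple[float, float] = (0.85, 0.95)
    marker_kappa: float = 200.0

    # X-inactivation clonality
    n_x_loci: int = 30
    n_low_depth_loci: int = 2
    dna_depth: float = 40.0
    rna_depth: float = 50.0
    mono_fraction: float = 0.98
    seq_error: float = 0.01

    # compartment chromosome: alternating A/B blocks of 100-kb bins
    compartment_chrom: str = "chr20"
    n_blocks: int = 8
    bins_per_block: int = 5
    probes_per_a_bin: int = 8
    probes_per_b_bin: int = 4
    compartment_factor_sd: float = 0.08

    def validate(self) -> None:
        if min(self.n_normal, self.n_med12, self.n_hmga2, self.n_hmga1) < 2:
            raise ConfigError("every sample group needs >= 2 samples")
        n_special = (
            self.n_informative_pan
            + 3 * self.n_informative_subtype
            + self.n_tfbs_dmc
            + self.n_tfbs_background
            + self.n_blocks * self.bins_per_block
            * max(self.probes_per_a_bin, self.probes_per_b_bin)
            + 3 * self.n_coupled_genes
            + 8
        )
        if n_special > self.n_cpg:
            raise ConfigError(
                f"planted probes ({n_special}) exceed the CpG probe budget ({self.n_cpg})"
            )
        if self.n_coupled_genes + self.n_program_genes + self.n_low_expressed + 3 > self.n_genes:
            raise ConfigError("planted genes exceed the gene budget")
        if not 0 < self.kappa:
            raise ConfigError("kappa must be positive")


@dataclass
class PipelineConfig:
    """Analysis thresholds and the RNG seed, recorded in every output."""

    seed: int = 0
    beta_clip_eps: float = 1e-3

    # subtype discovery
    variable_fraction: float = 0.01
    variable_count: int | None = None   # absolute count overrides fraction when set
    linkage_method: str = "ward"
    consensus_iterations: int = 1000
    consensus_subsample: float = 0.8

    # subtype classification (fold change vs matched normal)
    hmga2_fold_min: float = 5.0
    hmga1_fold_min: float = 2.0

    # differential methylation
    dmc_min_delta: float = 0.2
    dmc_alpha: float = 0.05
    subtype_meth_min: float = 0.3
    subtype_normal_max: float = 0.2
    promoter_window: int = 2000
    tfbs_fdr: float = 1e-6

    # expression
    cpm_min: float = 1.0
    cpm_min_samples: int = 3
    deg_fdr: float = 0.05
    starburst_delta: float = 0.25
    starburst_p: float = 0.05
    promoter_summary: str = "max_abs"   # or "mean"

    # sample QC
    genotype_aa_max: float = 0.25
    genotype_bb_min: float = 0.75
    min_identity: float = 0.9
    min_shared_calls: int = 10

    # XCI clonality
    xci_min_depth: int = 10
    xci_het_band: tuple[float, float] = (0.2, 0.8)
    xci_mono_fraction: float = 0.9
    xci_min_informative: int = 5
    xci_shared_min: float = 0.9
    xci_independent_max: float = 0.1

    # compartments
    compartment_binsize: int = 100_000
    compartment_min_probes: int = 3
    compartment_flip: bool = True

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def validate(self) -> None:
        if not 0 < self.variable_fraction <= 1:
            raise ConfigError("variable_fraction must be in (0, 1]")
        if not 0 < self.consensus_subsample <= 1:
            raise ConfigError("consensus_subsample must be in (0, 1]")
        if self.consensus_iterations < 1:
            raise ConfigError("consensus_iterations must be >= 1")
        if not 0 < self.beta_clip_eps < 0.5:
            raise ConfigError("beta_clip_eps must be in (0, 0.5)")
        for name in ("dmc_alpha", "deg_fdr", "starburst_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must be in (0, 1)")
        if not 0 <= self.dmc_min_delta <= 1:
            raise ConfigError("dmc_min_delta must be in [0, 1]")
        lo, hi = self.xci_het_band
        if not 0 <= lo < hi <= 1:
            raise ConfigError("xci_het_band must be an increasing sub-interval of [0, 1]")
        if self.compartment_binsize <= 0:
            raise ConfigError("compartment_binsize must be positive")
        if self.promoter_summary not in ("max_abs", "mean"):
            raise ConfigError("promoter_summary must be 'max_abs' or 'mean'")
        self.generator.validate()

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["generator"]["marker_log2fc"] = {
            f"{gene}|{group}": fc
            for (gene, group), fc in self.generator.marker_log2fc.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        gen = dict(d.pop("generator", {}))
        if "marker_log2fc" in gen:
            gen["marker_log2fc"] = {
                tuple(k.split("|")): float(v) for k, v in gen["marker_log2fc"].items()
            }
        if "tf_labels" in gen:
            gen["tf_labels"] = tuple(gen["tf_labels"])
        for key in ("purity_fibroid", "purity_normal"):
            if key in gen:
                gen[key] = tuple(gen[key])
        if "xci_het_band" in d:
            d["xci_het_band"] = tuple(d["xci_het_band"])
        cfg = cls(**{**d, "generator": GeneratorConfig(**gen)})
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
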