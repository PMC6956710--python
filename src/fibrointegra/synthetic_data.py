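"""Synthetic multi-omics cohort generator with planted ground truth.

Emulates the statistical structure the downstream analyses assume for a
uterine-fibroid methylation/expression cohort:

* group-structured beta values — 10 normal myometria plus three fibroid
  subtypes (16 MED12-mutant, 4 HMGA2-high, 4 HMGA1-high) with planted
  mean shifts at informative probes, bimodal background betas, CpH probes
  and genotype-driven SNP probes;
* negative-binomial RNA-seq counts with planted marker-gene fold changes
  (HMGA2, HMGA1, HOXA13), promoter-methylation-coupled silenced genes and
  a shared pan-fibroid transcriptional program;
* purity-driven marker-promoter methylation (mesenchymal and smooth-muscle
  marker promoters tracking a planted cell fraction per sample);
* chrX heterozygous-SNP allelic counts under planted X-inactivation
  patterns: one patient with two same-clone fibroids (shared inactive X)
  and one with two independent fibroids (opposite inactive X);
* one chromosome with alternating correlated beta blocks at 100-kb scale
  for A/B-compartment reconstruction.

Beta noise is Beta(mu*kappa, (1-mu)*kappa) with kappa = 50 by default, so
planted group means are exact in expectation and recoverable as group
averages. Everything is drawn from a single numpy Generator: the same seed
reproduces the cohort bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ConfigError, GeneratorConfig, PipelineConfig
from .core_io import (
    AllelicCountTable,
    BetaMatrix,
    CountMatrix,
    Dataset,
    ProbeAnnotation,
    SampleSheet,
)

GROUPS = ("normal", "MED12mt", "HMGA2hi", "HMGA1hi")
FIBROID_GROUPS = ("MED12mt", "HMGA2hi", "HMGA1hi")


@dataclass
class TruthBundle:
    """Planted parameters of a simulated cohort, for recovery tests."""

    group_label: dict[str, str]
    # probe -> {group: planted mean shift vs normal}
    planted_informative_probes: dict[str, dict[str, float]]
    # contrast name -> probes with planted |group-mean difference| >= 0.2
    planted_dmc_sets: dict[str, list[str]]
    # gene -> {group: planted log2 fold change vs normal}
    planted_log2fc: dict[str, dict[str, float]]
    planted_coupled_genes: list[str]
    planted_tf_enrichment: dict[str, float]
    # patient -> "shared" | "independent"
    xci_assignment: dict[str, str]
    # chrom -> list of A/B labels per 100-kb bin
    compartment_block_labels: dict[str, list[str]]
    planted_purity: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthBundle":
        with open(path) as fh:
            return cls(**json.load(fh))


def study_profile(seed: int = 0) -> PipelineConfig:
    """The study-profile preset: group sizes 10/16/4/4, 20,000 CpG + 200 CpH
    + 59 SNP probes, published marker fold changes, two two-fibroid patients
    (one shared-XCI, one independent-XCI) and purity in [0.7, 0.9]."""
    cfg = PipelineConfig(seed=seed)
    cfg.validate()
    return cfg


#: Compatibility alias for the profile preset.
paper_profile = study_profile


# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = m + dispersion * m^2."""
    size = 1.0 / dispersion
    p = size / (size + np.maximum(mean, 1e-9))
    return rng.negative_binomial(size, p)


def _sample_design(gen: GeneratorConfig) -> pd.DataFrame:
    """Sample sheet rows plus the hidden group label per sample.

    Two MED12mt patients (P01, P02) carry two fibroids each; P01's pair is
    planted as one clone (shared inactive X), P02's as independent clones.
    Normals come from patients P01..P10 so SNP-probe pairing is exercised.
    """
    rows = []
    for i in range(gen.n_normal):
        pid = f"P{i + 1:02d}"
        rows.append((f"{pid}_N", pid, "normal_myometrium", False, None, "normal"))
    med12_slots: list[tuple[str, str]] = [
        ("P01", "P01_F1"), ("P01", "P01_F2"),
        ("P02", "P02_F1"), ("P02", "P02_F2"),
    ]
    next_patient = 3
    while len(med12_slots) < gen.n_med12:
        pid = f"P{next_patient:02d}"
        med12_slots.append((pid, f"{pid}_F1"))
        next_patient += 1
    for pid, sid in med12_slots:
        desc = "exon1_del24" if pid == "P01" else "exon2_c.130G>A"
        rows.append((sid, pid, "fibroid", True, desc, "MED12mt"))
    for group, n in (("HMGA2hi", gen.n_hmga2), ("HMGA1hi", gen.n_hmga1)):
        for _ in range(n):
            pid = f"P{next_patient:02d}"
            next_patient += 1
            rows.append((f"{pid}_F1", pid, "fibroid", False, None, group))
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "patient_id", "tissue", "med12_mutation",
                 "med12_descriptor", "group"],
    ).set_index("sample_id")
    df["race"] = None
    return df


def simulate_cohort(
    config: PipelineConfig, seed: int | None = None
) -> tuple[Dataset, TruthBundle]:
    """Generate one cohort plus its truth bundle. Deterministic under seed."""
    config.validate()
    gen = config.generator
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    design = _sample_design(gen)
    n_samples = len(design)
    sample_ids = list(design.index)
    group = design["group"]
    group_label = {s: g for s, g in group.items()}
    normals = list(design.index[group == "normal"])
    is_group = {g: (group == g).to_numpy() for g in GROUPS}

    # ---- probe bookkeeping -------------------------------------------
    probe_rows: list[dict] = []   # annotation rows
    mu_rows: list[np.ndarray] = []  # per-probe per-sample mean beta
    kappa_rows: list[float] = []

    def add_probe(pid, chrom, pos, pclass, gene, tssd, tfbs, mu_per_sample, kappa):
        probe_rows.append(
            dict(probe_id=pid, chrom=chrom, pos=pos, probe_class=pclass,
                 gene=gene, tss_distance=tssd, tfbs_sets=tfbs)
        )
        mu_rows.append(np.asarray(mu_per_sample, dtype=float))
        kappa_rows.append(kappa)

    def group_mu(mu_normal: float, deltas: dict[str, float]) -> np.ndarray:
        mu = np.full(n_samples, mu_normal)
        for g, d in deltas.items():
            mu[is_group[g]] = np.clip(mu_normal + d, 0.02, 0.98)
        return mu

    truth_informative: dict[str, dict[str, float]] = {}
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"cg{counter:07d}"

    autosomes = [f"chr{i}" for i in range(1, 20)]

    def rand_locus():
        return rng.choice(autosomes), int(rng.integers(10_000, 200_000_000))

    # planted informative probes: pan-fibroid + one block per subtype
    informative_plan: list[tuple[str | None, float, int]] = [
        (None, gen.pan_delta, gen.n_informative_pan),
        ("MED12mt", gen.subtype_delta, gen.n_informative_subtype),
        ("HMGA2hi", gen.subtype_delta, gen.n_informative_subtype),
        ("HMGA1hi", gen.subtype_delta, gen.n_informative_subtype),
    ]
    for target, delta, count in informative_plan:
        for _ in range(count):
            hyper = rng.random() < 0.5
            mu_n = rng.uniform(0.1, 0.3) if hyper else rng.uniform(0.7, 0.9)
            d = delta if hyper else -delta
            targets = list(FIBROID_GROUPS) if target is None else [target]
            deltas = {g: d for g in targets}
            pid = next_id()
            chrom, pos = rand_locus()
            add_probe(pid, chrom, pos, "CpG", None, np.nan, frozenset(),
                      group_mu(mu_n, deltas), gen.kappa)
            truth_informative[pid] = {
                g: float(np.clip(mu_n + d, 0.02, 0.98) - mu_n) for g in targets
            }

    # planted distal DMC probes for TFBS enrichment (hyper in all fibroids)
    tf_labels = list(gen.tf_labels)
    tfbs_dmc_probes = []
    for _ in range(gen.n_tfbs_dmc):
        pid = next_id()
        mu_n = rng.uniform(0.1, 0.3)
        tfbs = {t for t in tf_labels if rng.random() < gen.background_tf_rate}
        if rng.random() < gen.enriched_tf_rate:
            tfbs.add(gen.enriched_tf)
        if not tfbs:  # keep the probe inside the distal TFBS universe
            tfbs.add(tf_labels[int(rng.integers(len(tf_labels)))])
        chrom, pos = rand_locus()
        add_probe(pid, chrom, pos, "CpG", None, np.nan, frozenset(tfbs),
                  group_mu(mu_n, {g: gen.tfbs_dmc_delta for g in FIBROID_GROUPS}),
                  gen.kappa)
        tfbs_dmc_probes.append(pid)

    # background distal TFBS universe (no planted shift)
    for _ in range(gen.n_tfbs_background):
        pid = next_id()
        tfbs = {t for t in tf_labels if rng.random() < gen.background_tf_rate}
        if not tfbs:
            tfbs.add(tf_labels[int(rng.integers(len(tf_labels)))])
        mu_n = rng.uniform(0.05, 0.15) if rng.random() < 0.5 else rng.uniform(0.85, 0.95)
        chrom, pos = rand_locus()
        add_probe(pid, chrom, pos, "CpG", None, np.nan, frozenset(tfbs),
                  group_mu(mu_n, {}), gen.kappa)

    # purity-driven marker promoters: MIR200C/141 methylated in mesenchymal
    # cells; ACTA2 (smooth-muscle actin) promoter unmethylated in myofibroblasts
    purity = np.where(
        (group == "normal").to_numpy(),
        rng.uniform(*gen.purity_normal, n_samples),
        rng.uniform(*gen.purity_fibroid, n_samples),
    )
    planted_purity = {s: float(p) for s, p in zip(sample_ids, purity)}
    for marker, mu_vec in (("MIR200C141", purity), ("ACTA2", 1.0 - purity)):
        for j in range(4):
            pid = next_id()
            chrom, pos = rand_locus()
            add_probe(pid, chrom, pos, "CpG", marker, float(rng.integers(-400, 400)),
                      frozenset(), mu_vec, gen.marker_kappa)

    # promoter probes of coupled (hypermethylated & silenced) genes
    coupled_genes = [f"CPL{i + 1:03d}" for i in range(gen.n_coupled_genes)]
    coupled_promoter_probes: dict[str, list[str]] = {}
    for gene_name in coupled_genes:
        mu_n = rng.uniform(0.03, 0.1)
        probes = []
        for _ in range(3):
            pid = next_id()
            chrom, pos = rand_locus()
            add_probe(pid, chrom, pos, "CpG", gene_name, float(rng.integers(-450, 450)),
                      frozenset(),
                      group_mu(mu_n, {g: gen.coupled_delta_beta for g in FIBROID_GROUPS}),
                      gen.kappa)
            probes.append(pid)
        coupled_promoter_probes[gene_name] = probes

    # compartment chromosome: alternating A/B blocks of correlated bins.
    # A blocks are probe-dense (the orientation cue); bins within one
    # compartment co-vary across samples through a shared per-sample factor.
    binsize = config.compartment_binsize
    comp_labels: list[str] = []
    w_sample = rng.normal(0.0, gen.compartment_factor_sd, n_samples)
    for block in range(gen.n_blocks):
        label = "A" if block % 2 == 0 else "B"
        n_per_bin = gen.probes_per_a_bin if label == "A" else gen.probes_per_b_bin
        sign = 1.0 if label == "A" else -1.0
        for b in range(gen.bins_per_block):
            bin_idx = block * gen.bins_per_block + b
            comp_labels.append(label)
            mu_bin = rng.uniform(0.4, 0.6)
            mu_vec = np.clip(mu_bin + sign * w_sample, 0.05, 0.95)
            for _ in range(n_per_bin):
                pid = next_id()
                pos = int(bin_idx * binsize + rng.integers(0, binsize))
                add_probe(pid, gen.compartment_chrom, pos, "CpG", None, np.nan,
                          frozenset(), mu_vec, 300.0)

    # background CpG probes (bimodal marginal, no group structure)
    n_background = gen.n_cpg - len(probe_rows)
    if n_background < 0:
        raise ConfigError("planted probes exceed n_cpg")
    bg_low = rng.random(n_background) < 0.5
    bg_mu = np.where(bg_low, rng.uniform(0.03, 0.15, n_background),
                     rng.uniform(0.85, 0.97, n_background))
    background_ids = []
    for i in range(n_background):
        pid = next_id()
        chrom, pos = rand_locus()
        add_probe(pid, chrom, pos, "CpG", None, np.nan, frozenset(),
                  group_mu(bg_mu[i], {}), gen.kappa)
        background_ids.append(pid)

    # CpH probes: low methylation, slightly elevated in MED12mt/HMGA2hi
    for i in range(gen.n_cph):
        pid = f"ch{i + 1:07d}"
        mu_n = rng.uniform(0.01, 0.05)
        chrom, pos = rand_locus()
        add_probe(pid, chrom, pos, "CpH", None, np.nan, frozenset(),
                  group_mu(mu_n, {"MED12mt": 0.02, "HMGA2hi": 0.03}), gen.kappa)

    # SNP probes: Hardy-Weinberg genotypes per patient, tri-modal beta
    patients = sorted(design["patient_id"].unique())
    patient_idx = {p: i for i, p in enumerate(patients)}
    snp_freq = rng.uniform(0.2, 0.8, gen.n_snp)
    geno = np.empty((gen.n_snp, len(patients)), dtype=np.int8)
    for j in range(len(patients)):
        u = rng.random(gen.n_snp)
        aa = (1 - snp_freq) ** 2
        ab = 2 * snp_freq * (1 - snp_freq)
        geno[:, j] = np.where(u < aa, 0, np.where(u < aa + ab, 1, 2))
    geno_mu = np.array([0.03, 0.5, 0.97])
    sample_patient_col = np.array(
        [patient_idx[p] for p in design["patient_id"]], dtype=int
    )
    for i in range(gen.n_snp):
        pid = f"rs{i + 1:07d}"
        mu_vec = geno_mu[geno[i, sample_patient_col]]
        chrom, pos = rand_locus()
        add_probe(pid, chrom, pos, "SNP", None, np.nan, frozenset(), mu_vec, 150.0)

    # ---- draw the beta matrix ----------------------------------------
    mu_matrix = np.clip(np.vstack(mu_rows), 1e-3, 1 - 1e-3)
    kappas = np.asarray(kappa_rows)[:, None]
    values = rng.beta(mu_matrix * kappas, (1.0 - mu_matrix) * kappas)
    probe_ids = [r["probe_id"] for r in probe_rows]
    beta_df = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                           columns=sample_ids)
    # masked (non-detected) cells, restricted to background probes
    if gen.missing_rate > 0 and background_ids:
        bg_pos = beta_df.index.get_indexer(background_ids)
        mask_draw = rng.random((len(bg_pos), n_samples)) < gen.missing_rate
        arr = beta_df.to_numpy()
        rows_idx, cols_idx = np.nonzero(mask_draw)
        arr[bg_pos[rows_idx], cols_idx] = np.nan
        beta_df = pd.DataFrame(arr, index=beta_df.index, columns=beta_df.columns)

    annot_df = pd.DataFrame(probe_rows).set_index("probe_id")
    annotation = ProbeAnnotation(annot_df)
    beta = BetaMatrix(beta_df)

    # ---- expression ---------------------------------------------------
    marker_genes = ["HMGA2", "HMGA1", "HOXA13"]
    program_genes = [f"PRG{i + 1:03d}" for i in range(gen.n_program_genes)]
    low_genes = [f"LOW{i + 1:03d}" for i in range(gen.n_low_expressed)]
    n_filler = gen.n_genes - len(marker_genes) - len(coupled_genes) \
        - len(program_genes) - len(low_genes)
    filler_genes = [f"GEN{i + 1:04d}" for i in range(n_filler)]
    gene_ids = marker_genes + coupled_genes + program_genes + low_genes + filler_genes

    base_cpm = pd.Series(index=gene_ids, dtype=float)
    base_cpm[marker_genes] = gen.marker_base_cpm
    # coupled genes emulate well-expressed tumor suppressors later silenced
    # by promoter methylation, so their baseline sits well above the CPM filter
    base_cpm[coupled_genes] = 2.0 ** rng.uniform(5.0, 8.0, len(coupled_genes))
    base_cpm[program_genes] = 2.0 ** rng.uniform(4.0, 7.0, len(program_genes))
    base_cpm[low_genes] = rng.uniform(0.01, 0.2, len(low_genes))
    base_cpm[filler_genes] = 2.0 ** rng.uniform(0.5, 7.0, len(filler_genes))

    log2fc = pd.DataFrame(0.0, index=gene_ids, columns=list(GROUPS))
    truth_log2fc: dict[str, dict[str, float]] = {}
    for (gene_name, grp), fc in gen.marker_log2fc.items():
        log2fc.loc[gene_name, grp] = fc
        truth_log2fc.setdefault(gene_name, {})[grp] = fc
    for gene_name in coupled_genes:
        for grp in FIBROID_GROUPS:
            log2fc.loc[gene_name, grp] = gen.coupled_log2fc
        truth_log2fc[gene_name] = {g: gen.coupled_log2fc for g in FIBROID_GROUPS}
    half = len(program_genes) // 2
    for i, gene_name in enumerate(program_genes):
        fc = gen.program_log2fc if i < half else -gen.program_log2fc
        for grp in FIBROID_GROUPS:
            log2fc.loc[gene_name, grp] = fc
        truth_log2fc[gene_name] = {g: fc for g in FIBROID_GROUPS}

    # library sizes: fixed >=2-fold spread, shuffled across samples
    lib = 1e6 * 2.0 ** np.linspace(-0.6, 0.6, n_samples)
    rng.shuffle(lib)
    group_col = np.array([GROUPS.index(g) for g in group])
    fc_matrix = log2fc.to_numpy()[:, group_col]          # genes x samples
    mean_cpm = base_cpm.to_numpy()[:, None] * 2.0 ** fc_matrix
    mean_counts = mean_cpm * lib[None, :] / 1e6
    counts_arr = _nb_draw(rng, mean_counts, gen.nb_dispersion)
    counts = CountMatrix(
        pd.DataFrame(counts_arr.astype(np.int64),
                     index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    )

    # ---- chrX allelic counts ------------------------------------------
    xci_assignment = {"P01": "shared", "P02": "independent"}
    allelic_rows = []
    for pid, mode in xci_assignment.items():
        tumors = [s for s in sample_ids if s.startswith(pid + "_F")]
        normal = f"{pid}_N"
        members = tumors + ([normal] if normal in sample_ids else [])
        # inactive-X haplotype per tumor: the expressed haplotype is the
        # other one; "shared" pairs express the same haplotype everywhere.
        expressed_hap = {tumors[0]: 0, tumors[1]: 0 if mode == "shared" else 1}
        for li in range(gen.n_x_loci + gen.n_low_depth_loci):
            locus = f"{pid}_X{li + 1:03d}"
            pos = int(rng.integers(1_000_000, 150_000_000))
            low_depth = li >= gen.n_x_loci
            # phase: which allele sits on haplotype 0
            hap0_is_ref = bool(rng.random() < 0.5)
            for s in members:
                dna_depth = max(1, rng.poisson(3.0 if low_depth else gen.dna_depth))
                dna_alt = rng.binomial(dna_depth, 0.5)
                rna_depth = max(1, rng.poisson(gen.rna_depth))
                if s in expressed_hap:
                    expressed_is_ref = (expressed_hap[s] == 0) == hap0_is_ref
                    p_alt = (1.0 - gen.mono_fraction + gen.seq_error
                             if expressed_is_ref else gen.mono_fraction - gen.seq_error)
                else:  # polyclonal normal tissue: biallelic
                    p_alt = 0.5
                rna_alt = rng.binomial(rna_depth, p_alt)
                allelic_rows.append(
                    dict(locus_id=locus, chrom="chrX", pos=pos, sample_id=s,
                         dna_ref=int(dna_depth - dna_alt), dna_alt=int(dna_alt),
                         rna_ref=int(rna_depth - rna_alt), rna_alt=int(rna_alt))
                )
    allelic = AllelicCountTable(pd.DataFrame(allelic_rows))

    # ---- truth bundle --------------------------------------------------
    planted_dmc: dict[str, list[str]] = {}
    pan_informative = [
        p for p, d in truth_informative.items() if len(d) == len(FIBROID_GROUPS)
    ]
    coupled_probes_flat = [p for ps in coupled_promoter_probes.values() for p in ps]
    planted_dmc["fibroid_vs_normal"] = sorted(
        pan_informative + tfbs_dmc_probes + coupled_probes_flat
    )
    for grp in FIBROID_GROUPS:
        grp_probes = [
            p for p, d in truth_informative.items()
            if grp in d and abs(d[grp]) >= 0.2
        ]
        planted_dmc[f"{grp}_vs_normal"] = sorted(
            set(grp_probes) | set(tfbs_dmc_probes) | set(coupled_probes_flat)
        )

    truth = TruthBundle(
        group_label=group_label,
        planted_informative_probes=truth_informative,
        planted_dmc_sets=planted_dmc,
        planted_log2fc=truth_log2fc,
        planted_coupled_genes=list(coupled_genes),
        planted_tf_enrichment={
            gen.enriched_tf: gen.enriched_tf_rate / gen.background_tf_rate
        },
        xci_assignment=xci_assignment,
        compartment_block_labels={gen.compartment_chrom: comp_labels},
        planted_purity=planted_purity,
    )

    sheet = SampleSheet(
        design[["patient_id", "tissue", "med12_mutation", "med12_descriptor", "race"]]
    )
    ds = Dataset(beta=beta, annotation=annotation, counts=counts,
                 samples=sheet, allelic=allelic, config=config)
    return ds, truth


def groups_from_truth(truth: TruthBundle) -> dict[str, list[str]]:
    """Sample ids per planted group label."""
    out: dict[str, list[str]] = {}
    for s, g in truth.group_label.items():
        out.setdefault(g, []).append(s)
    return out
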