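# fibrointegra

Integrated DNA-methylation / exome / transcriptome analysis of uterine
fibroids, rebuilt as a tested, reusable Python pipeline. Uterine fibroids
(leiomyomas) fall into molecular subtypes — *MED12*-mutant, *HMGA2*-high and
*HMGA1*-high — that differ in DNA methylation, transcriptome and likely
cell of origin. This package implements the computational procedures such a
study runs between the preprocessed data matrices and the biological
conclusions, and pairs them with a synthetic-cohort generator that plants
known effects so every stage can be validated by parameter recovery.

It is aimed at epigenomics analysts who have an Infinium EPIC beta-value
matrix, an RNA-seq count matrix and (optionally) paired DNA/RNA allelic
counts, and want the following analyses with explicit, configurable rules:

- **Subtype discovery** — top-1% most-variable CpG selection by standard
  deviation, Ward hierarchical clustering on beta values, and consensus
  clustering (1,000 random 80% subsamples) with sample/cluster stability
  scores: stability(s, C) = mean consensus between sample *s* and the
  members of cluster *C*.
- **Rule-based subtype classification** — *MED12* mutation ⇒ MED12mt; else
  HMGA2 fold change > 5 vs matched normal ⇒ HMGA2hi; else HMGA1 > 2 ⇒
  HMGA1hi.
- **Differential methylation** — per-probe Welch *t* on M-values
  (M = log2(β/(1−β))), DMC rule |Δβ| ≥ 0.2 and p < 0.05; fibroid-specific
  probes (β ≥ 0.3 in ≥ 1 fibroid, ≤ 0.2 in all normals); hypergeometric
  TFBS enrichment of DMCs among distal probes at BH-adjusted 1e-6.
- **Expression and integration** — CPM ≥ 1 in ≥ 3 samples filter, Welch *t*
  on log2(CPM + 0.5), BH FDR < 0.05; starburst categories (promoter
  |Δβ| > 0.25, p < 0.05, joined with expression change); directional DEG
  overlap between contrasts by 1-df Pearson chi-square; Pearson/Kendall
  gene–gene correlation.
- **Clonality from X inactivation** — tumors from one founding cell express
  the same X at every heterozygous chrX locus; the caller scores expressed-
  allele concordance across DNA-heterozygous, RNA-monoallelic loci.
- **A/B compartments from methylation** — first eigenvector of the bin–bin
  correlation matrix of 100-kb mean betas, oriented by probe density (open
  A compartments are probe dense).
- **Sample QC** — marker-promoter cell-composition estimates (MIR200C/141,
  smooth-muscle actin) and SNP-probe genotype matching of samples to
  patients.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on a
generated cohort with the study's design: 10 normal myometria and 24
fibroids (16 MED12mt / 4 HMGA2hi / 4 HMGA1hi), 20,000 CpG + 200 CpH + 59
SNP probes, planted marker effects (HMGA2 log2FC 11.6 and HOXA13 log2FC 4.4
in HMGA2hi), two two-fibroid patients with planted shared/independent
X-inactivation, and an alternating-block compartment chromosome.

```sh
python analysis/01_simulate_cohort.py          # writes results/cohort/
python analysis/03_subtype_discovery.py
python analysis/05_expression_integration.py
python analysis/06_clonality.py
```

Output (seed 20260925):

```
consensus clusters at k=4: {1: 16, 2: 10, 3: 4, 4: 4}
cluster stability: {1: 1.0, 2: 1.0, 3: 1.0, 4: 1.0}
ARI vs planted groups: 1.000
rule-based subtype calls match planted labels: 100%
...
  HMGA2hi HMGA2 log2FC: estimated 11.45 (planted 11.6)
starburst: 20 hypermethylated+downregulated genes (20/20 planted silenced genes)
DEG overlap (up): 34 shared (expected 1.0), chi2 = 1186.5, p = 5.22e-260
...
P01 (P01_F1 vs P01_F2): 29/29 loci concordant, methylation r = 0.94 -> shared_origin (planted: shared)
P02 (P02_F1 vs P02_F2): 0/30 loci concordant, methylation r = 0.93 -> independent_origins (planted: independent)
24-nt in-frame CDS deletion removes 8 amino acids
```

Reading this: the consensus clusters reproduce the 10/16/4/4 design exactly
(adjusted Rand index 1.0 against the planted labels) with maximal stability;
the DE stage recovers the planted HMGA2 effect within noise; all 20 planted
promoter-silenced genes land in the starburst hyper_down quadrant; the DEG
overlap between MED12mt and HMGA2hi far exceeds the independence
expectation; and the two planted tumor pairs get the correct clonality
verdicts from expressed-allele concordance (29/29 concordant = one clone,
0/30 = independent origins).

`analysis/02_sample_qc.py`, `04_differential_methylation.py` and
`07_compartments.py` cover composition/identity QC, DMC + TFBS enrichment
(the planted EZH2-like factor is the only call at q ≤ 1e-6) and compartment
recovery (100% of unmasked 100-kb bins match the planted A/B blocks).

## Layout

```
src/fibrointegra/    library: core_io, synthetic_data, sample_qc, subtyping,
                     diffmeth, integration, clonality, compartments
analysis/            numbered narrative drivers writing under results/
tests/               pytest suite (unit, property and end-to-end recovery)
docs/methods.md      models, assumptions, parameter choices, limitations
```
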