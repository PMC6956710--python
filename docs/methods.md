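# Methods

This note documents the statistical procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Data model

Beta values are methylation fractions in [0, 1] per probe per sample.
Values of exactly 0 or 1 are clipped to [ε, 1−ε] with ε = 1e-3 on load so
that M-values, M = log2(β/(1−β)), stay finite; clipping never moves a value
by more than ε. Missing (non-detected) cells are masked (NaN) and never
imputed, except that hierarchical clustering fills masked cells with the
probe mean for distance computation only. Coordinates are 0-based half-open
internally and BED-style on disk.

## Subtype discovery

Variable-probe selection ranks CpG probes by across-sample standard
deviation (masked cells excluded, ddof = 1) and keeps the top
ceil(fraction × P), default fraction 0.01; ties break lexicographically by
probe id so the selection is deterministic. An absolute probe count can
override the fraction — the two conventions (top 1% vs a fixed 10,000)
both appear in practice and the package supports either without picking a
winner.

Clustering is Ward linkage on Euclidean distance over beta values, samples
as observations. Linkage and metric are configurable; Ward/Euclidean is the
default because it produces the compact clusters that subtype heatmaps
assume.

Consensus clustering draws ⌊0.8 n⌋ samples without replacement per
iteration (1,000 iterations by default), clusters each subsample at the
requested k, and tallies, per sample pair, how often the pair co-clusters
among the iterations where it was co-sampled. Final assignments cluster the
distance 1 − consensus at the same k. The subsample fraction 0.8 is the
referenced consensus-clustering convention; k is user-supplied (the study
presents k = 4) — no automatic model selection is attempted.

Stability: score(s, C) = mean consensus(s, m) over members m of C. When s
is itself a member it is excluded from the average — the published verbal
definition is ambiguous on this point, and self-exclusion avoids inflating
every member's score by the diagonal 1.0. A singleton cluster's member is
assigned score 1.0 and flagged with a warning. Cluster stability is the
mean of its members' scores.

Classification precedence is fixed: MED12 mutation ⇒ MED12mt regardless of
expression; else HMGA2 fold change > 5 before HMGA1 > 2, so a sample
exceeding both thresholds takes the stronger call.

## Differential methylation

DMCs are called per probe with a Welch two-sample t-test on M-values
(variance-stabilized scale), while Δβ and its threshold stay on the beta
scale where the biology is read: is_dmc ⇔ |Δβ| ≥ 0.2 and unadjusted
p < 0.05. BH-adjusted q-values are reported alongside for transparency.
This is a deliberate, defined simplification standing in for region-based
limma-style callers: it keeps the published thresholds while remaining
fully specifiable and testable at desk scale. Probes with fewer than two
unmasked values in either group are untestable and excluded from all
downstream universes.

"Unmethylated in normal" for fibroid-specific probes is quantified as
β ≤ 0.2 in every normal (no published number exists; exposed in config),
with the published inclusion rule β ≥ 0.3 in at least one subtype sample.

Promoters are |TSS distance| ≤ 2 kb with a gene assigned. The TFBS
enrichment universe is distal probes (outside promoters) carrying at least
one TFBS annotation. Per TF, both hypergeometric tails are computed
(P(X ≥ k) for enrichment, P(X ≤ k) for depletion); BH correction is applied
separately within the enrichment family and within the depletion family
across TFs — the published analysis says only "FDR correction" without
naming the family, so both families are computed and the per-direction
correction is the default. Calls use the published adjusted cutoff 1e-6.

## Expression and integration

CPM = count / library size × 1e6. A gene enters a contrast when CPM ≥ 1 in
at least 3 samples of that contrast. Tests are Welch t on log2(CPM + 0.5);
the pseudo-count 0.5 keeps zeros finite at the cost of a small downward
bias in extreme fold-change estimates (a planted log2FC of 11.6 on a
~5-CPM baseline is recovered around 11.3). BH is applied across filtered
genes; DEGs are q < 0.05.

Starburst: each gene's promoter methylation change is summarized by the
promoter probe with the largest |Δβ| (config: mean summary available — the
publication does not state its summary). Categories: hyper_down (Δβ > 0.25,
methylation p < 0.05, expression log2FC < 0 at q < 0.05), hypo_up
(symmetric), other. The categories partition genes.

Directional overlap: the universe is genes passing the CPM filter in both
contrasts (the publication does not state its universe; this definition is
the package's). Per direction, the 2×2 membership table is tested with a
1-df Pearson chi-square without continuity correction — expected counts in
intended use are large.

Correlations are standard product-moment r and Kendall tau-b with their
scipy p-values.

## Clonality from X inactivation

Loci are informative when, in both tumors, DNA depth ≥ 10 and DNA alt
fraction is in [0.2, 0.8] (heterozygous), and RNA is monoallelic
(major-allele fraction ≥ 0.9 at depth ≥ 10). Concordance is the fraction of
informative loci where both tumors express the same allele; verdicts:
shared_origin at ≥ 0.9, independent_origins at ≤ 0.1, indeterminate
otherwise or with < 5 informative loci. The published analysis describes
the logic but no cutoffs; all five thresholds are package policy, exposed
in config. Methylation-profile correlation between the tumors is reported
as corroborating evidence only and never overrides the allelic verdict.
Skewed XCI in bulk normal tissue is out of model; verdicts apply to tumor
pairs only.

`deletion_effect` translates the original and deleted CDS with the standard
code up to the first stop: a deletion is in-frame iff its length is
divisible by 3, and residues_removed is the difference in protein lengths
(so a 24-nt codon-boundary deletion removes 8 residues, a 45-nt one 15; a
deletion that creates a premature stop reports the truncated length).
Mutation burden is variants / Mb to 2 decimals, flagged above 0.5/Mb.

## Compartments

Mean CpG beta per 100-kb half-open bin (bins with < 3 probes masked), bin–
bin Pearson correlation across samples, first eigenvector (largest
eigenvalue). The eigenvector sign is arbitrary, so it is oriented by
per-bin probe density — A compartments are gene- and probe-dense — and the
default output convention puts open compartments positive: label A where
the final loading is positive. `flip=False` negates the loadings (and
therefore swaps labels), mirroring the plotting convention where the raw
eigenvector is shown multiplied by −1. All CpG probes are used (no
island/open-sea restriction). The eigenvector is computed for whatever
sample group is supplied; computing per subtype versus jointly is the
caller's choice.

## Synthetic cohort generator

The generator emulates the cohort structure the analyses assume, with a
truth bundle recording every planted effect:

- **Design**: 10 normal myometria (patients P01–P10) and 24 fibroids
  (16 MED12mt including two two-fibroid patients, 4 HMGA2hi, 4 HMGA1hi);
  20,000 CpG, 200 CpH and 59 SNP probes; 2,000 genes.
- **Beta noise**: β ~ Beta(μκ, (1−μ)κ) with κ = 50 — array-like dispersion
  with closed-form means, so planted shifts are recoverable as group-mean
  differences. The publication does not state a within-group dispersion; κ
  is an artifact choice exposed in config. Background probes have bimodal
  means (mass near 0 and 1) as on real arrays.
- **Informative probes**: 30 pan-fibroid (|Δβ| = 0.4 in all subtypes) and
  40 per subtype (|Δβ| = 0.5 in one subtype), hyper or hypo at random.
- **TFBS structure**: 200 distal probes hypermethylated by 0.25 in all
  fibroids, 80% of them inside the planted factor's binding sites
  (background membership 5% for each of 10 factors over a 3,200-probe
  distal universe) — odds sufficient for an unambiguous enrichment call.
- **Expression**: negative binomial with dispersion 0.1 and library sizes
  spanning ≥ 2-fold (so CPM normalization is exercised). Planted log2 fold
  changes: HMGA2 11.6 (HMGA2hi) and 3.2 (MED12mt); HOXA13 4.4 (HMGA2hi)
  and 3 (MED12mt); HMGA1 3.0 in HMGA1hi (no published number — the subtype
  is defined by a > 2-fold rule, and 3.0 places it clearly above that
  threshold). 20 promoter-silenced genes (log2FC −2 with promoter Δβ +0.35
  in all fibroids) drawn at 32–256 CPM baseline, emulating well-expressed
  silenced tumor suppressors; a 100-gene shared program (±2 in all
  fibroids) driving the DEG overlap; 200 genes below the CPM filter.
- **Purity**: each sample gets a smooth-muscle/mesenchymal fraction
  (fibroids U(0.7, 0.9), normals U(0.85, 0.95)) written into the
  MIR200C/141 (methylated-in-mesenchyme) and smooth-muscle-actin
  (unmethylated-in-target) marker promoter betas.
- **Genotypes**: 59 SNP probes with Hardy–Weinberg genotypes per patient
  (allele frequencies U(0.2, 0.8)), tri-modal betas at 0.03/0.5/0.97.
- **XCI**: patient P01's two fibroids express the same haplotype at every
  chrX locus (shared clone), P02's express opposite haplotypes
  (independent); RNA monoallelic fraction 0.98 with 1% sequencing error,
  DNA depth ~Poisson(40), RNA ~Poisson(50), plus two low-depth loci per
  patient to exercise the depth filter. Normal tissue is biallelic.
- **Compartments**: one chromosome with 8 alternating blocks of five
  100-kb bins; bins within a compartment co-vary through a shared
  per-sample factor (SD 0.08), and A blocks are probe-dense (8 vs 4 probes
  per bin), which is the orientation cue the caller uses.

The same seed reproduces a cohort bit-identically (single numpy Generator).

What the generator does **not** emulate — and what passing recovery tests
therefore do not show about real data: probe-level spatial correlation and
CpG-island structure, batch and chip effects, purity-driven attenuation of
Δβ (purity affects only the marker promoters), copy-number aberrations,
methylation–clonality coupling (the two planted tumor pairs have similar
methylation profiles regardless of XCI verdict, so the advisory
methylation correlation is uninformative on synthetic data), skewed XCI,
and realistic gene-length or GC biases in counts.

## Problem sizes and tolerances in the tests

Recovery tests run at the study-profile design (34 samples, ~20k probes),
the package's natural desk scale. The planted-Δβ oracle is checked in
aggregate (mean absolute error ≤ 0.05 plus correlation > 0.98 between
planted and recovered effects): at n = 4 per group the per-probe sampling
SE of a group-mean difference under κ = 50 noise is ~0.035, so a per-probe
bound at 0.05 would reject by chance. Consensus-clustering recovery uses
250 subsampling iterations across 20 seeds for the median-ARI property and
the full 1,000 iterations across 5 seeds in the end-to-end check. The
null-calibration test for the DMC stage uses 10v10 groups over 2,000
probes, where the Welch approximation is accurate; at 4v4 its small-sample
deviation would be attributable to the test, not the implementation.
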