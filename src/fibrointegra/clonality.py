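"""Tumor-pair clonality from X-chromosome inactivation, plus small variant
utilities (in-frame deletion effect, mutation burden).

One X chromosome is randomly silenced early in development, so all
descendants of a single founding cell express the same X. Two tumors from
one patient that express the same allele at (nearly) every heterozygous
chrX locus are consistent with one clonal origin; tumors expressing
opposite alleles must have arisen from different cells. The caller keeps
loci that are heterozygous in DNA in both tumors (depth ≥ 10, alt fraction
0.2–0.8), requires monoallelic RNA expression (major-allele fraction
≥ 0.9) in both, and scores the fraction of loci where the expressed allele
agrees. Methylation-profile correlation is reported as corroborating
evidence only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .config import ConfigError
from .core_io import AllelicCountTable, BetaMatrix, SampleSheet


def informative_x_loci(
    allelic: AllelicCountTable,
    tumor1: str,
    tumor2: str,
    min_depth: int = 10,
    het_band: tuple[float, float] = (0.2, 0.8),
) -> list[str]:
    """Loci heterozygous in DNA in both tumors (depth and alt-fraction rules)."""
    lo, hi = het_band
    keep: list[str] = []
    t1 = allelic.for_sample(tumor1)
    t2 = allelic.for_sample(tumor2)
    for locus in t1.index.intersection(t2.index):
        ok = True
        for t in (t1, t2):
            depth = t.loc[locus, "dna_ref"] + t.loc[locus, "dna_alt"]
            if depth < min_depth:
                ok = False
                break
            frac = t.loc[locus, "dna_alt"] / depth
            if not lo <= frac <= hi:
                ok = False
                break
        if ok:
            keep.append(str(locus))
    return keep


def expressed_allele(
    rna_ref: int, rna_alt: int, min_depth: int = 10, mono_frac: float = 0.9
) -> str:
    """Which allele the RNA expresses: REF, ALT, biallelic or uncallable."""
    depth = rna_ref + rna_alt
    if depth < min_depth:
        return "uncallable"
    major = max(rna_ref, rna_alt) / depth
    if major >= mono_frac:
        return "REF" if rna_ref >= rna_alt else "ALT"
    return "biallelic"


@dataclass
class ClonalityCall:
    patient_id: str
    tumor_pair: tuple[str, str]
    n_informative: int
    n_concordant: int
    concordance: float
    meth_correlation: float | None
    verdict: str  # shared_origin | independent_origins | indeterminate


def clonality_call(
    allelic: AllelicCountTable,
    tumor1: str,
    tumor2: str,
    samples: SampleSheet | None = None,
    beta: BetaMatrix | None = None,
    variable_probes: list[str] | None = None,
    min_depth: int = 10,
    het_band: tuple[float, float] = (0.2, 0.8),
    mono_frac: float = 0.9,
    min_informative: int = 5,
    shared_min: float = 0.9,
    independent_max: float = 0.1,
) -> ClonalityCall:
    """XCI concordance verdict for a tumor pair from one patient.

    Informative loci are DNA-heterozygous in both tumors with monoallelic
    RNA in both; concordance is the fraction expressing the same allele.
    Verdict: shared_origin when concordance ≥ shared_min, independent_origins
    when ≤ independent_max, else indeterminate (also when fewer than
    min_informative loci). Methylation correlation over the variable-probe
    set is advisory and never overrides the allelic verdict.
    """
    patient = ""
    if samples is not None:
        p1, p2 = samples.patient_of(tumor1), samples.patient_of(tumor2)
        if p1 != p2:
            raise ValueError(
                f"tumors are from different patients ({p1!r} vs {p2!r})"
            )
        patient = p1

    het = informative_x_loci(allelic, tumor1, tumor2, min_depth, het_band)
    t1 = allelic.for_sample(tumor1)
    t2 = allelic.for_sample(tumor2)
    n_informative = 0
    n_concordant = 0
    for locus in het:
        a1 = expressed_allele(int(t1.loc[locus, "rna_ref"]), int(t1.loc[locus, "rna_alt"]),
                              min_depth, mono_frac)
        a2 = expressed_allele(int(t2.loc[locus, "rna_ref"]), int(t2.loc[locus, "rna_alt"]),
                              min_depth, mono_frac)
        if a1 in ("REF", "ALT") and a2 in ("REF", "ALT"):
            n_informative += 1
            if a1 == a2:
                n_concordant += 1

    concordance = n_concordant / n_informative if n_informative else float("nan")
    if n_informative < min_informative:
        verdict = "indeterminate"
    elif concordance >= shared_min:
        verdict = "shared_origin"
    elif concordance <= independent_max:
        verdict = "independent_origins"
    else:
        verdict = "indeterminate"

    meth_r = None
    if beta is not None:
        probes = variable_probes if variable_probes is not None else list(beta.probe_ids)
        v = beta.values.loc[probes, [tumor1, tumor2]].dropna()
        if len(v) >= 3:
            meth_r = float(stats.pearsonr(v[tumor1], v[tumor2]).statistic)

    return ClonalityCall(
        patient_id=patient,
        tumor_pair=(tumor1, tumor2),
        n_informative=n_informative,
        n_concordant=n_concordant,
        concordance=concordance,
        meth_correlation=meth_r,
        verdict=verdict,
    )


@dataclass
class DeletionEffect:
    in_frame: bool
    residues_removed: int | None
    premature_stop: bool
    mutant_protein_length: int | None


def deletion_effect(cds: str, deletion: tuple[int, int]) -> DeletionEffect:
    """Effect of a CDS deletion (half-open interval, 0-based).

    In-frame iff the deleted length is divisible by 3; residues_removed is
    the difference in translated-protein length (standard code, stopping at
    the first stop codon). A deletion that introduces a premature stop is
    reported with the truncated length.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    start, end = deletion
    if not 0 <= start <= end <= len(cds):
        raise ValueError("deletion interval outside the CDS")
    length = end - start
    if length % 3 != 0:
        return DeletionEffect(False, None, False, None)
    mutant = cds[:start] + cds[end:]
    orig_protein = str(Seq(cds).translate(to_stop=True))
    mut_protein = str(Seq(mutant).translate(to_stop=True))
    removed = len(orig_protein) - len(mut_protein)
    premature = len(mut_protein) < len(mutant) // 3 - (
        1 if mutant.endswith(("TAA", "TAG", "TGA")) else 0
    )
    return DeletionEffect(True, removed, premature, len(mut_protein))


def mutation_burden(n_somatic: int, target_size_mb: float, outlier_above: float = 0.5
                    ) -> tuple[float, bool]:
    """Somatic variants per megabase (2 decimals) with an outlier flag.

    Fibroid burdens are typically below 0.5/Mb; values above are flagged.
    """
    if target_size_mb <= 0:
        raise ConfigError("target size must be positive (megabases)")
    if n_somatic < 0:
        raise ValueError("variant count must be non-negative")
    burden = round(n_somatic / target_size_mb, 2)
    return burden, burden > outlier_above
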