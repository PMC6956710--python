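"""Sample quality control: cell-composition markers and SNP-probe identity.

Cell composition uses promoter methylation of lineage markers as a
two-component linear mixture: the MIR200C/141 promoter is methylated in
mesenchymal cells and unmethylated in epithelial cells, so its mean
promoter beta reads out the mesenchymal fraction directly; the smooth-muscle
actin promoter is unmethylated in myofibroblast-lineage cells, so one minus
its mean beta reads out the smooth-muscle fraction.

Sample identity uses the array's SNP probes: beta at a SNP probe is
tri-modal (homozygous ~0 / heterozygous ~0.5 / homozygous ~1), giving a
genotype call per probe; the fraction of matching calls between two samples
separates same-patient pairs (identity ~1) from unrelated pairs (~0.4-0.5
under Hardy-Weinberg at 59 loci).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import BetaMatrix, CrossReferenceError

POLARITIES = ("methylated_in_target", "unmethylated_in_target")
GENOTYPES = ("AA", "AB", "BB")


@dataclass
class MarkerSet:
    """Promoter probes (within ±500 bp of the marker TSS) for one lineage marker."""

    name: str
    probe_ids: list[str]
    polarity: str  # methylated_in_target | unmethylated_in_target

    def __post_init__(self) -> None:
        if not self.probe_ids:
            raise ValueError(f"marker set {self.name!r} has no probes")
        if self.polarity not in POLARITIES:
            raise ValueError(f"unknown polarity {self.polarity!r}")


def marker_sets_from_annotation(annotation, markers: dict[str, str]) -> list[MarkerSet]:
    """Build marker sets from probes assigned to marker genes within ±500 bp.

    ``markers`` maps gene symbol -> polarity.
    """
    t = annotation.table
    out = []
    for gene, polarity in markers.items():
        probes = t.index[
            (t["gene"] == gene) & (t["tss_distance"].abs() <= 500)
        ].tolist()
        out.append(MarkerSet(gene, probes, polarity))
    return out


def read_marker_sets(path) -> list[MarkerSet]:
    """Marker TSV: columns name, probe_id, polarity (one row per probe)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for (name, polarity), sub in df.groupby(["name", "polarity"], sort=True):
        out.append(MarkerSet(str(name), list(sub["probe_id"].astype(str)), str(polarity)))
    return out


def estimate_composition(beta: BetaMatrix, markers: Sequence[MarkerSet]) -> pd.DataFrame:
    """Per-sample target-lineage fraction per marker set (linear two-component).

    methylated_in_target: fraction = mean beta over the marker probes;
    unmethylated_in_target: fraction = 1 - mean beta. Clipped to [0, 1].
    """
    cols = {}
    for m in markers:
        missing = [p for p in m.probe_ids if p not in beta.probe_ids]
        if missing:
            raise CrossReferenceError(
                f"marker {m.name!r}: probe(s) not in beta matrix: {missing[:5]}"
            )
        mean_b = beta.values.loc[m.probe_ids].mean(axis=0, skipna=True)
        frac = mean_b if m.polarity == "methylated_in_target" else 1.0 - mean_b
        cols[m.name] = frac.clip(0.0, 1.0)
    return pd.DataFrame(cols)


def call_snp_genotypes(
    beta: BetaMatrix, aa_max: float = 0.25, bb_min: float = 0.75
) -> pd.DataFrame:
    """Tri-modal genotype calls from SNP-probe betas.

    beta < aa_max -> AA; aa_max <= beta <= bb_min -> AB; beta > bb_min -> BB;
    masked -> missing (pd.NA). Returns snp_probes x samples of calls.
    """
    if len(beta.probe_ids) < 1:
        raise ValueError("need at least one SNP probe")
    b = beta.values
    calls = pd.DataFrame(
        np.select([b.isna(), b < aa_max, b > bb_min], [None, "AA", "BB"], default="AB"),
        index=b.index, columns=b.columns, dtype=object,
    )
    return calls


@dataclass
class MatchResult:
    """Pairwise SNP-call identity and single-linkage patient groupings."""

    identity: pd.DataFrame          # samples x samples, NaN = unevaluable pair
    shared_calls: pd.DataFrame      # non-missing shared loci per pair
    groups: dict[str, int]          # sample -> recovered group index
    unevaluable: list[str]          # samples with no usable calls
    mismatches: pd.DataFrame | None = None  # vs declared patient ids, if compared


def match_samples(
    genotypes: pd.DataFrame,
    min_identity: float = 0.9,
    min_shared: int = 10,
    declared_patients: pd.Series | None = None,
) -> MatchResult:
    """Group samples by SNP-call identity (single linkage at >= min_identity).

    identity(i, j) = matching calls / shared non-missing loci; pairs with
    fewer than ``min_shared`` shared calls are unevaluable (NaN).
    """
    samples = list(genotypes.columns)
    n = len(samples)
    if n < 2:
        raise ValueError("need at least two samples to match")
    arr = genotypes.to_numpy(dtype=object)
    valid = pd.notna(arr)
    unevaluable = [samples[j] for j in range(n) if not valid[:, j].any()]

    ident = np.full((n, n), np.nan)
    shared = np.zeros((n, n), dtype=int)
    for i in range(n):
        ident[i, i] = 1.0
        shared[i, i] = int(valid[:, i].sum())
        for j in range(i + 1, n):
            both = valid[:, i] & valid[:, j]
            shared[i, j] = shared[j, i] = int(both.sum())
            if shared[i, j] >= min_shared:
                frac = float(np.mean(arr[both, i] == arr[both, j]))
                ident[i, j] = ident[j, i] = frac

    # single-linkage union-find over pairs at identity >= threshold
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if np.isfinite(ident[i, j]) and ident[i, j] >= min_identity:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    roots: dict[int, int] = {}
    groups = {}
    for idx, s in enumerate(samples):
        r = find(idx)
        groups[s] = roots.setdefault(r, len(roots))

    mismatches = None
    if declared_patients is not None:
        rows = []
        for i in range(n):
            for j in range(i + 1, n):
                same_declared = declared_patients[samples[i]] == declared_patients[samples[j]]
                same_called = groups[samples[i]] == groups[samples[j]]
                if same_declared != same_called:
                    rows.append(
                        dict(sample_a=samples[i], sample_b=samples[j],
                             identity=ident[i, j], declared_same=same_declared,
                             called_same=same_called)
                    )
        mismatches = pd.DataFrame(
            rows, columns=["sample_a", "sample_b", "identity",
                           "declared_same", "called_same"]
        )

    return MatchResult(
        identity=pd.DataFrame(ident, index=samples, columns=samples),
        shared_calls=pd.DataFrame(shared, index=samples, columns=samples),
        groups=groups,
        unevaluable=unevaluable,
        mismatches=mismatches,
    )
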