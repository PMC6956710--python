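"""Methylation-derived A/B chromatin compartments at 100-kb resolution.

Megabase-scale open (A) and closed (B) chromatin domains co-vary in DNA
methylation: binning CpG betas along a chromosome, correlating bins across
samples and taking the first eigenvector of the bin-bin correlation matrix
recovers the compartment structure, the methylation analogue of Hi-C
compartment calling. The eigenvector sign is arbitrary, so it is oriented
against per-bin probe density (A compartments are gene- and probe-dense);
the default ``flip`` output multiplies by -1 to put open compartments in
the positive orientation, and bins with positive final loading are labeled
A, negative B. Bins with fewer than ``min_probes`` probes are masked.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import BetaMatrix, ProbeAnnotation


def bin_methylation(
    beta: BetaMatrix,
    annotation: ProbeAnnotation,
    chrom: str,
    binsize: int = 100_000,
    min_probes: int = 3,
    probe_class: str = "CpG",
) -> tuple[pd.DataFrame, pd.Series]:
    """Mean beta per half-open 100-kb bin per sample on one chromosome.

    Returns (bins x samples matrix with NaN rows for masked bins,
    probes-per-bin counts). Bin b covers [b*binsize, (b+1)*binsize).
    """
    t = annotation.table
    on_chrom = t.index[(t["chrom"] == chrom) & (t["probe_class"] == probe_class)]
    on_chrom = on_chrom.intersection(beta.probe_ids)
    if len(on_chrom) == 0:
        raise ValueError(f"no {probe_class} probes on {chrom}")
    pos = t.loc[on_chrom, "pos"].astype(int)
    bin_idx = pos // binsize
    n_bins = int(bin_idx.max()) + 1

    values = beta.values.loc[on_chrom]
    sums = np.zeros((n_bins, values.shape[1]))
    counts = np.zeros((n_bins, values.shape[1]))
    arr = values.to_numpy(dtype=float)
    ok = ~np.isnan(arr)
    np.add.at(sums, bin_idx.to_numpy(), np.where(ok, arr, 0.0))
    np.add.at(counts, bin_idx.to_numpy(), ok.astype(float))

    n_probes = pd.Series(
        np.bincount(bin_idx.to_numpy(), minlength=n_bins),
        index=range(n_bins), name="n_probes",
    )
    with np.errstate(invalid="ignore"):
        means = sums / counts
    means[n_probes.to_numpy() < min_probes, :] = np.nan
    binned = pd.DataFrame(means, index=range(n_bins), columns=values.columns)
    binned.index.name = "bin"
    return binned, n_probes


def compartment_eigenvector(
    binned: pd.DataFrame,
    n_probes: pd.Series,
    chrom: str,
    binsize: int = 100_000,
    flip: bool = True,
) -> pd.DataFrame:
    """A/B compartment track from the bin-bin correlation eigenvector.

    Computes the Pearson correlation matrix between unmasked bins (across
    samples), takes the eigenvector of the largest eigenvalue, orients it
    by per-bin probe density, applies the open-compartment-positive
    convention when ``flip`` (the default; ``flip=False`` negates loadings
    and therefore swaps labels), and labels A where the final loading is
    positive, B where negative. Masked bins propagate as 'masked'.
    """
    unmasked = binned.index[binned.notna().all(axis=1)]
    if len(unmasked) < 10:
        raise ValueError("need >= 10 unmasked bins")
    if binned.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    mat = binned.loc[unmasked].to_numpy(dtype=float)
    if np.any(np.std(mat, axis=1) == 0):
        raise ValueError("degenerate (constant) bin in the binned matrix")
    corr = np.corrcoef(mat)
    if not np.all(np.isfinite(corr)):
        raise ValueError("correlation matrix is degenerate")
    eigvals, eigvecs = np.linalg.eigh(corr)
    ev = eigvecs[:, -1]

    density = n_probes.loc[unmasked].to_numpy(dtype=float)
    dens_corr = np.corrcoef(ev, density)[0, 1]
    if np.isfinite(dens_corr) and dens_corr != 0:
        ev = ev * np.sign(dens_corr)  # probe-dense (A) bins positive
    if not flip:
        ev = -ev

    loading = pd.Series(np.nan, index=binned.index)
    loading.loc[unmasked] = ev
    label = pd.Series("masked", index=binned.index, dtype=object)
    label.loc[unmasked] = np.where(ev > 0, "A", "B")

    track = pd.DataFrame(
        {
            "chrom": chrom,
            "start": [int(b) * binsize for b in binned.index],
            "end": [(int(b) + 1) * binsize for b in binned.index],
            "loading": loading.to_numpy(),
            "compartment": label.to_numpy(),
            "n_probes": n_probes.reindex(binned.index).fillna(0).astype(int).to_numpy(),
        },
        index=binned.index,
    )
    return track


def call_compartments(
    beta: BetaMatrix,
    annotation: ProbeAnnotation,
    chrom: str,
    binsize: int = 100_000,
    min_probes: int = 3,
    flip: bool = True,
) -> pd.DataFrame:
    """bin_methylation + compartment_eigenvector in one step."""
    binned, n_probes = bin_methylation(beta, annotation, chrom, binsize, min_probes)
    return compartment_eigenvector(binned, n_probes, chrom, binsize, flip)
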