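"""Expression analysis and methylation-expression integration.

Differential expression is a defined, library-size-normalized procedure:
counts are converted to CPM, genes are kept when CPM ≥ 1 in at least 3
samples of the contrast, and a Welch t-test on log2(CPM + 0.5) with BH
correction calls genes at FDR < 0.05. This is a stand-in with the published
filter and FDR rules, not an edgeR/limma reimplementation.

The starburst integration joins each gene's strongest promoter methylation
change (probe with the largest |Δβ|) with its expression change and labels
hypermethylated-downregulated (hyper_down) and hypomethylated-upregulated
(hypo_up) genes at |Δβ| > 0.25, methylation p < 0.05 and expression
q < 0.05.

The directional overlap test asks whether two contrasts share more up- (or
down-) regulated genes than chance over the genes tested in both, by a 1-df
Pearson chi-square on the 2x2 membership table (no continuity correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CountMatrix
from .diffmeth import _bh, welch_ttest


def cpm(counts: CountMatrix, samples: Sequence[str] | None = None) -> pd.DataFrame:
    """Counts per million over the given samples (library-size normalized)."""
    sub = counts.counts if samples is None else counts.counts[list(samples)]
    lib = sub.sum(axis=0)
    if (lib == 0).any():
        bad = list(lib.index[lib == 0])
        raise ValueError(f"zero library size for sample(s): {bad}")
    return sub / lib * 1e6


def call_degs(
    counts: CountMatrix,
    case_samples: Sequence[str],
    control_samples: Sequence[str],
    cpm_min: float = 1.0,
    min_samples: int = 3,
    fdr: float = 0.05,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Differential expression, case vs control, on log2(CPM + pseudocount).

    Returns per-gene log2fc (mean difference of log2 CPM), p (Welch t),
    q (BH across genes passing the CPM filter), passed_filter and is_deg.
    """
    case_samples, control_samples = list(case_samples), list(control_samples)
    if len(case_samples) < 2 or len(control_samples) < 2:
        raise ValueError("need >= 2 samples per group")
    all_samples = case_samples + control_samples
    cpm_all = cpm(counts, all_samples)
    passed = (cpm_all >= cpm_min).sum(axis=1) >= min_samples

    log_cpm = np.log2(cpm_all + pseudocount)
    case = log_cpm[case_samples].to_numpy()
    ctrl = log_cpm[control_samples].to_numpy()
    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)
    p = welch_ttest(case, ctrl)
    p = np.where(np.isfinite(p), p, 1.0)

    q = np.full_like(p, np.nan)
    kept = passed.to_numpy()
    if kept.any():
        q[kept] = _bh(p[kept])
    is_deg = kept & (q < fdr)
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "passed_filter": kept,
            "is_deg": is_deg,
        },
        index=counts.gene_ids.copy(),
    )
    table.index.name = "gene_id"
    return table


def starburst(
    dmc: pd.DataFrame,
    probe_genes: pd.Series,
    degs: pd.DataFrame,
    delta_cut: float = 0.25,
    p_cut: float = 0.05,
    expr_fdr: float = 0.05,
    summary: str = "max_abs",
) -> pd.DataFrame:
    """Promoter-methylation / expression integration per gene.

    ``dmc``: call_dmcs output restricted to promoter probes; ``probe_genes``:
    probe_id -> gene for those probes. Each gene's promoter Δβ is summarized
    by its largest-|Δβ| probe (or the mean, per ``summary``). Categories:
    hyper_down (Δβ > delta_cut, p < p_cut, log2fc < 0, q < expr_fdr),
    hypo_up (symmetric), else other. Genes with no promoter probe are
    excluded and counted in the returned attrs.
    """
    if summary not in ("max_abs", "mean"):
        raise ValueError("summary must be 'max_abs' or 'mean'")
    dmc = dmc.loc[dmc.index.intersection(probe_genes.index)]
    genes_with_probes = probe_genes.loc[dmc.index]

    rows = []
    for gene, probes in genes_with_probes.groupby(genes_with_probes).groups.items():
        sub = dmc.loc[list(probes)].dropna(subset=["p"])
        if sub.empty:
            continue
        if summary == "max_abs":
            best = sub.loc[sub["delta_beta"].abs().sort_values(kind="stable").index[-1]]
            pdb, pp = float(best["delta_beta"]), float(best["p"])
        else:
            pdb = float(sub["delta_beta"].mean())
            pp = float(sub["p"].min())
        rows.append(dict(gene_id=gene, promoter_delta_beta=pdb, promoter_p=pp))
    meth = pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(
        columns=["promoter_delta_beta", "promoter_p"]
    )

    joined = meth.join(degs[["log2fc", "q"]], how="inner").rename(
        columns={"log2fc": "expr_log2fc", "q": "expr_q"}
    )
    n_excluded = len(set(degs.index) - set(joined.index))

    meth_sig = joined["promoter_p"] < p_cut
    expr_sig = joined["expr_q"] < expr_fdr
    hyper_down = (joined["promoter_delta_beta"] > delta_cut) & meth_sig \
        & (joined["expr_log2fc"] < 0) & expr_sig
    hypo_up = (joined["promoter_delta_beta"] < -delta_cut) & meth_sig \
        & (joined["expr_log2fc"] > 0) & expr_sig
    joined["category"] = np.select([hyper_down, hypo_up], ["hyper_down", "hypo_up"],
                                   default="other")
    joined.attrs["n_genes_without_promoter_probe"] = n_excluded
    return joined


@dataclass
class OverlapResult:
    """Directional DEG overlap between two contrasts."""

    direction: str
    universe_size: int
    n_a: int
    n_b: int
    overlap: int
    expected: float
    chi2: float
    p: float
    genes: list[str]


def _chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) for a 2x2 table."""
    total = table.sum()
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    expected = np.outer(row, col) / total
    if np.any(expected == 0):
        return 0.0, 1.0
    chi2 = float(((table - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def overlap_test(degs_a: pd.DataFrame, degs_b: pd.DataFrame) -> dict[str, OverlapResult]:
    """Up- and down-regulated DEG overlap over the shared tested universe.

    The universe is genes passing the CPM filter in both contrasts. For each
    direction, the 2x2 table {in A, not} x {in B, not} is tested with a 1-df
    Pearson chi-square.
    """
    universe = degs_a.index[degs_a["passed_filter"]].intersection(
        degs_b.index[degs_b["passed_filter"]]
    )
    if len(universe) == 0:
        raise ValueError("no genes pass the filter in both contrasts")
    a = degs_a.loc[universe]
    b = degs_b.loc[universe]
    out = {}
    for direction, sign in (("up", 1), ("down", -1)):
        in_a = a["is_deg"] & (np.sign(a["log2fc"]) == sign)
        in_b = b["is_deg"] & (np.sign(b["log2fc"]) == sign)
        k = int((in_a & in_b).sum())
        table = np.array(
            [
                [k, int((in_a & ~in_b).sum())],
                [int((~in_a & in_b).sum()), int((~in_a & ~in_b).sum())],
            ],
            dtype=float,
        )
        chi2, p = _chi2_2x2(table)
        out[direction] = OverlapResult(
            direction=direction,
            universe_size=len(universe),
            n_a=int(in_a.sum()),
            n_b=int(in_b.sum()),
            overlap=k,
            expected=float(in_a.sum() * in_b.sum() / len(universe)),
            chi2=chi2,
            p=p,
            genes=sorted(universe[(in_a & in_b).to_numpy()]),
        )
    return out


def correlate_genes(
    x: Sequence[float] | pd.Series,
    y: Sequence[float] | pd.Series,
    method: str = "pearson",
) -> tuple[float, float]:
    """Pearson r or Kendall tau-b between two paired expression vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    if method == "pearson":
        r = stats.pearsonr(x, y)
    elif method == "kendall":
        r = stats.kendalltau(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r.statistic), float(r.pvalue)


def correlate_expression(
    log_cpm: pd.DataFrame, gene_x: str, gene_y: str, method: str = "pearson"
) -> tuple[float, float]:
    """Correlation between two genes' expression profiles across samples."""
    return correlate_genes(log_cpm.loc[gene_x], log_cpm.loc[gene_y], method=method)
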