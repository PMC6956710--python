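"""Differential methylation and distal TFBS enrichment.

Differentially methylated cytosines (DMCs) are called per probe with a
Welch two-sample t-test on M-values (logit-transformed betas, variance
stabilized), while the effect threshold stays on the beta scale: a probe is
a DMC when |Δβ| (case minus control group mean) ≥ 0.2 and the unadjusted
p < 0.05. BH-adjusted q-values are reported alongside for transparency.
This is a defined simplification of region-based callers, not a
reimplementation of them.

Subtype-specific probes follow the rule: unmethylated in every normal
(β ≤ 0.2) but methylated (β ≥ 0.3) in at least one subtype sample.

TFBS enrichment tests, for each transcription factor, whether DMCs are
over- or under-represented among distal probes (outside ±2 kb of a TSS)
that carry TFBS annotation, by the hypergeometric tail; BH correction is
applied separately within the enrichment family and the depletion family,
with the published significance cutoff of 1e-6 on the adjusted value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import BetaMatrix, ProbeAnnotation


def _bh(p: np.ndarray) -> np.ndarray:
    return stats.false_discovery_control(p, method="bh")


def welch_ttest(case: np.ndarray, ctrl: np.ndarray) -> np.ndarray:
    """Row-wise Welch two-sample t-test p-values, NaN-aware.

    Equivalent to scipy's ttest_ind(equal_var=False, nan_policy='omit') but
    vectorized over rows with missing cells. Rows where the statistic is
    undefined (zero pooled variance or <2 values per group) return NaN.
    """
    import warnings as _warnings

    n1 = np.sum(~np.isnan(case), axis=1)
    n2 = np.sum(~np.isnan(ctrl), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(case, axis=1)
        m2 = np.nanmean(ctrl, axis=1)
        v1 = np.nanvar(case, axis=1, ddof=1)
        v2 = np.nanvar(ctrl, axis=1, ddof=1)
        se2 = v1 / n1 + v2 / n2
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where((n1 >= 2) & (n2 >= 2), p, np.nan)
    return p


def call_dmcs(
    beta: BetaMatrix,
    case_samples: Sequence[str],
    control_samples: Sequence[str],
    min_delta: float = 0.2,
    alpha: float = 0.05,
    eps: float = 1e-3,
) -> pd.DataFrame:
    """Per-probe differential methylation (case vs control).

    Returns a table with delta_beta (beta scale), p (Welch t on M-values),
    q (BH over testable probes), direction, is_dmc and testable flags.
    Probes with fewer than two unmasked values in either group are
    untestable and excluded from any downstream universe.
    """
    case = beta.values[list(case_samples)].to_numpy(dtype=float)
    ctrl = beta.values[list(control_samples)].to_numpy(dtype=float)
    n_case = np.sum(~np.isnan(case), axis=1)
    n_ctrl = np.sum(~np.isnan(ctrl), axis=1)
    testable = (n_case >= 2) & (n_ctrl >= 2)

    delta = np.nanmean(case, axis=1) - np.nanmean(ctrl, axis=1)

    def mvals(b):
        b = np.clip(b, eps, 1.0 - eps)
        return np.log2(b / (1.0 - b))

    p = welch_ttest(mvals(case), mvals(ctrl))
    p = np.where(testable, p, np.nan)
    # constant groups give nan p; treat as non-significant but testable
    p = np.where(testable & ~np.isfinite(p), 1.0, p)

    q = np.full_like(p, np.nan)
    if testable.any():
        q[testable] = _bh(p[testable])

    is_dmc = testable & (np.abs(delta) >= min_delta) & (p < alpha)
    table = pd.DataFrame(
        {
            "delta_beta": delta,
            "p": p,
            "q": q,
            "direction": np.where(delta > 0, "hyper", "hypo"),
            "is_dmc": is_dmc,
            "testable": testable,
        },
        index=beta.probe_ids.copy(),
    )
    table.index.name = "probe_id"
    return table


def subtype_specific_probes(
    beta: BetaMatrix,
    normal_samples: Sequence[str],
    subtype_samples: Sequence[str],
    meth_min: float = 0.3,
    normal_max: float = 0.2,
) -> list[str]:
    """Probes unmethylated in every normal but methylated (β ≥ meth_min) in
    at least one subtype sample."""
    if not len(normal_samples) or not len(subtype_samples):
        raise ValueError("both sample groups must be non-empty")
    normal = beta.values[list(normal_samples)]
    subtype = beta.values[list(subtype_samples)]
    normal_ok = (normal <= normal_max).all(axis=1) & normal.notna().all(axis=1)
    subtype_ok = (subtype >= meth_min).any(axis=1)
    return list(beta.probe_ids[(normal_ok & subtype_ok).to_numpy()])


def map_probes_to_promoters(
    annotation: ProbeAnnotation, window: int = 2000
) -> pd.DataFrame:
    """Label each probe promoter(gene) or distal; flag the TFBS universe.

    A probe is a promoter probe when |tss_distance| ≤ window and a gene is
    assigned; distal probes carrying TFBS annotation form the enrichment
    universe ("within TFBSs but not within gene promoters").
    """
    t = annotation.table
    has_gene = t["gene"].notna() & (t["gene"] != "")
    in_window = t["tss_distance"].abs() <= window
    is_promoter = (has_gene & in_window).fillna(False)
    has_tfbs = t["tfbs_sets"].map(lambda s: len(s) > 0)
    out = pd.DataFrame(
        {
            "location": np.where(is_promoter, "promoter", "distal"),
            "gene": np.where(is_promoter, t["gene"], None),
            "in_tfbs_universe": (~is_promoter) & has_tfbs,
        },
        index=t.index.copy(),
    )
    out.index.name = "probe_id"
    return out


def hypergeom_tails(N: int, K: int, n: int, k: int) -> tuple[float, float]:
    """Exact hypergeometric tails: P(X >= k) and P(X <= k) for overlap k
    between a TF set of size K and a draw of size n from a universe of N."""
    p_enrich = float(stats.hypergeom.sf(k - 1, N, K, n))
    p_deplete = float(stats.hypergeom.cdf(k, N, K, n))
    return min(p_enrich, 1.0), min(p_deplete, 1.0)


def tfbs_enrichment(
    dmc_probes: Sequence[str],
    annotation: ProbeAnnotation,
    window: int = 2000,
    fdr_cut: float = 1e-6,
) -> pd.DataFrame:
    """Hypergeometric TFBS enrichment/depletion of DMCs among distal probes.

    The universe is all distal probes with TFBS annotation; DMCs are
    intersected with it. Per TF: overlap k between the TF's probes (K) and
    the distal DMCs (n) out of N universe probes. BH within enrichment and
    within depletion tests separately; call at adjusted value ≤ fdr_cut.
    """
    mapping = map_probes_to_promoters(annotation, window=window)
    universe = set(mapping.index[mapping["in_tfbs_universe"]])
    if not universe:
        raise ValueError("distal TFBS universe is empty")
    dmc_in = set(dmc_probes) & universe

    tf_probes: dict[str, set[str]] = {}
    for pid, sets in annotation.table.loc[list(universe), "tfbs_sets"].items():
        for tf in sets:
            tf_probes.setdefault(tf, set()).add(pid)

    N, n = len(universe), len(dmc_in)
    rows = []
    for tf in sorted(tf_probes):
        K = len(tf_probes[tf])
        if K == 0:
            continue
        k = len(tf_probes[tf] & dmc_in)
        p_enr, p_dep = hypergeom_tails(N, K, n, k)
        rows.append(dict(tf_label=tf, universe_size=N, tf_set_size=K,
                         dmc_count=n, overlap=k, p_enrich=p_enr, p_deplete=p_dep))
    table = pd.DataFrame(rows).set_index("tf_label")
    table["q_enrich"] = _bh(table["p_enrich"].to_numpy())
    table["q_deplete"] = _bh(table["p_deplete"].to_numpy())
    table["call"] = np.select(
        [table["q_enrich"] <= fdr_cut, table["q_deplete"] <= fdr_cut],
        ["enriched", "depleted"],
        default="neither",
    )
    return table
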