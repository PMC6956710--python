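"""Differential methylation calls and TFBS hypergeometric enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibrointegra import BetaMatrix, ProbeAnnotation
from fibrointegra.diffmeth import (
    call_dmcs,
    hypergeom_tails,
    map_probes_to_promoters,
    subtype_specific_probes,
    tfbs_enrichment,
)
from fibrointegra.synthetic_data import groups_from_truth


def _beta_from(case_vals, ctrl_vals, n_probes=1):
    case_vals, ctrl_vals = np.atleast_2d(case_vals), np.atleast_2d(ctrl_vals)
    cols = [f"c{i}" for i in range(case_vals.shape[1])] + [
        f"n{i}" for i in range(ctrl_vals.shape[1])
    ]
    vals = np.hstack([case_vals, ctrl_vals])
    df = pd.DataFrame(vals, index=[f"p{i}" for i in range(vals.shape[0])], columns=cols)
    case = [c for c in cols if c.startswith("c")]
    ctrl = [c for c in cols if c.startswith("n")]
    return BetaMatrix(df), case, ctrl


class TestCallDmcs:
    def test_forced_separation_is_hyper_dmc(self):
        rng = np.random.default_rng(0)
        beta, case, ctrl = _beta_from(
            rng.normal(0.70, 0.01, (1, 4)), rng.normal(0.10, 0.01, (1, 4))
        )
        out = call_dmcs(beta, case, ctrl)
        row = out.iloc[0]
        assert row["is_dmc"] and row["direction"] == "hyper"
        assert row["delta_beta"] == pytest.approx(0.6, abs=0.05)

    def test_below_delta_threshold_is_not_dmc(self):
        rng = np.random.default_rng(1)
        beta, case, ctrl = _beta_from(
            rng.normal(0.55, 0.005, (1, 4)), rng.normal(0.40, 0.005, (1, 4))
        )
        out = call_dmcs(beta, case, ctrl)
        assert abs(out.iloc[0]["delta_beta"]) < 0.2
        assert not out.iloc[0]["is_dmc"]

    def test_null_type_one_error_within_binomial_bounds(self):
        """Under the null (both groups same Beta distribution), the fraction
        of probes at p < 0.05 stays inside 99% binomial bounds around 0.05."""
        rng = np.random.default_rng(123)
        n_probes, n = 2000, 10
        vals = rng.beta(0.4 * 50, 0.6 * 50, (n_probes, 2 * n))
        beta, case, ctrl = _beta_from(vals[:, :n], vals[:, n:])
        out = call_dmcs(beta, case, ctrl)
        frac = float((out["p"] < 0.05).mean())
        half_width = 2.576 * math.sqrt(0.05 * 0.95 / n_probes)
        assert 0.05 - half_width <= frac <= 0.05 + half_width

    def test_group_swap_negates_delta_preserves_p(self):
        rng = np.random.default_rng(2)
        vals = rng.beta(2, 3, (50, 8))
        beta, case, ctrl = _beta_from(vals[:, :4], vals[:, 4:])
        fwd = call_dmcs(beta, case, ctrl)
        rev = call_dmcs(beta, ctrl, case)
        assert np.allclose(fwd["delta_beta"], -rev["delta_beta"])
        assert np.allclose(fwd["p"], rev["p"])

    def test_masked_groups_untestable(self):
        beta, case, ctrl = _beta_from(
            np.array([[0.7, np.nan, np.nan, np.nan]]), np.array([[0.1, 0.1, 0.1, 0.1]])
        )
        out = call_dmcs(beta, case, ctrl)
        assert not out.iloc[0]["testable"]
        assert not out.iloc[0]["is_dmc"]
        assert np.isnan(out.iloc[0]["p"])

    def test_recovers_planted_dmcs(self, cohort, cohort_groups):
        ds, truth = cohort
        fibroids = [s for g in ("MED12mt", "HMGA2hi", "HMGA1hi") for s in cohort_groups[g]]
        out = call_dmcs(ds.beta, fibroids, cohort_groups["normal"])
        planted = set(truth.planted_dmc_sets["fibroid_vs_normal"])
        called = set(out.index[out["is_dmc"]])
        recovered = len(planted & called) / len(planted)
        assert recovered >= 0.9


class TestSubtypeSpecificProbes:
    def test_inclusion_rules(self):
        vals = pd.DataFrame(
            {
                "n1": [0.05, 0.05, 0.25],
                "n2": [0.05, 0.05, 0.05],
                "f1": [0.35, 0.29, 0.80],
                "f2": [0.05, 0.10, 0.80],
            },
            index=["included", "below_meth_min", "normal_methylated"],
        )
        got = subtype_specific_probes(
            BetaMatrix(vals), ["n1", "n2"], ["f1", "f2"]
        )
        assert got == ["included"]

    def test_boundary_is_inclusive_for_meth_min(self):
        vals = pd.DataFrame({"n1": [0.1], "n2": [0.1], "f1": [0.3]}, index=["p"])
        assert subtype_specific_probes(BetaMatrix(vals), ["n1", "n2"], ["f1"]) == ["p"]


class TestPromoterMapping:
    def _annot(self, rows):
        df = pd.DataFrame(
            rows, columns=["probe_id", "chrom", "pos", "probe_class", "gene",
                           "tss_distance", "tfbs_sets"]
        ).set_index("probe_id")
        return ProbeAnnotation(df)

    def test_window_rule_and_universe(self):
        annot = self._annot(
            [
                ("p1", "chr1", 100, "CpG", "GENE1", 1500.0, frozenset()),
                ("p2", "chr1", 200, "CpG", "GENE1", -2500.0, frozenset()),
                ("p3", "chr1", 300, "CpG", None, np.nan, frozenset({"EZH2"})),
                ("p4", "chr1", 400, "CpG", "GENE2", 500.0, frozenset({"EZH2"})),
            ]
        )
        out = map_probes_to_promoters(annot)
        assert out.loc["p1", "location"] == "promoter"
        assert out.loc["p2", "location"] == "distal"
        assert out.loc["p3", "location"] == "distal" and out.loc["p3", "in_tfbs_universe"]
        # a promoter probe never enters the TFBS universe even with TFBS hits
        assert not out.loc["p4", "in_tfbs_universe"]


class TestHypergeometric:
    def test_zero_overlap_closed_form(self):
        p_enr, p_dep = hypergeom_tails(100, 20, 10, 0)
        assert p_enr == pytest.approx(1.0)
        assert p_dep == pytest.approx(math.comb(80, 10) / math.comb(100, 10))

    def test_upper_tail_closed_form(self):
        p_enr, _ = hypergeom_tails(100, 20, 10, 8)
        expected = sum(
            math.comb(20, i) * math.comb(80, 10 - i) for i in range(8, 11)
        ) / math.comb(100, 10)
        assert p_enr == pytest.approx(expected, rel=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.data())
    def test_tails_match_enumeration(self, data):
        """Property: both tails equal brute-force enumeration for all N <= 30."""
        N = data.draw(st.integers(2, 30))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(1, N))
        k = data.draw(st.integers(0, min(K, n)))
        denom = math.comb(N, n)
        pmf = [math.comb(K, i) * math.comb(N - K, n - i) / denom
               for i in range(0, min(K, n) + 1)]
        p_enr, p_dep = hypergeom_tails(N, K, n, k)
        assert p_enr == pytest.approx(sum(pmf[k:]), abs=1e-12)
        assert p_dep == pytest.approx(sum(pmf[: k + 1]), abs=1e-12)
        assert p_enr + p_dep >= 1.0 - 1e-12  # tails share the k term


class TestEnrichment:
    def test_planted_tf_called_enriched_only(self, cohort, cohort_groups):
        ds, truth = cohort
        fibroids = [s for g in ("MED12mt", "HMGA2hi", "HMGA1hi") for s in cohort_groups[g]]
        dmc = call_dmcs(ds.beta, fibroids, cohort_groups["normal"])
        table = tfbs_enrichment(list(dmc.index[dmc["is_dmc"]]), ds.annotation)
        planted = set(truth.planted_tf_enrichment)
        for tf, row in table.iterrows():
            if tf in planted:
                assert row["call"] == "enriched"
                assert row["q_enrich"] <= 1e-6
            else:
                assert row["call"] == "neither"

    def test_tail_sum_invariant_on_cohort_table(self, cohort, cohort_groups):
        ds, _ = cohort
        fibroids = [s for g in ("MED12mt", "HMGA2hi", "HMGA1hi") for s in cohort_groups[g]]
        dmc = call_dmcs(ds.beta, fibroids, cohort_groups["normal"])
        table = tfbs_enrichment(list(dmc.index[dmc["is_dmc"]]), ds.annotation)
        assert ((table["p_enrich"] + table["p_deplete"]) >= 1.0 - 1e-12).all()
        assert (table["overlap"] <= table[["tf_set_size", "dmc_count"]].min(axis=1)).all()
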