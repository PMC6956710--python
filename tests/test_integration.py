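"""Differential expression, starburst integration, overlap test, correlation."""

import numpy as np
import pandas as pd
import pytest

from fibrointegra import CountMatrix, study_profile, simulate_cohort
from fibrointegra.diffmeth import call_dmcs, map_probes_to_promoters
from fibrointegra.integration import (
    _chi2_2x2,
    call_degs,
    correlate_genes,
    cpm,
    overlap_test,
    starburst,
)
from fibrointegra.synthetic_data import groups_from_truth


def _counts(arr, samples=None):
    arr = np.asarray(arr)
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return CountMatrix(
        pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                     columns=samples).astype(np.int64)
    )


class TestCallDegs:
    def test_cpm_filter_drops_sparse_gene(self):
        # g0 nonzero in only 2 of 8 samples -> fails "CPM >= 1 in >= 3"
        arr = np.full((50, 8), 100)
        arr = np.vstack([np.array([500, 500, 0, 0, 0, 0, 0, 0]), arr])
        counts = _counts(arr)
        out = call_degs(counts, counts.sample_ids[:4], counts.sample_ids[4:])
        assert not out.loc["g0", "passed_filter"]
        assert not out.loc["g0", "is_deg"]
        assert out.loc["g1", "passed_filter"]

    def test_group_swap_negates_log2fc_preserves_p(self):
        rng = np.random.default_rng(0)
        counts = _counts(rng.poisson(50, (100, 10)))
        a, b = list(counts.sample_ids[:5]), list(counts.sample_ids[5:])
        fwd = call_degs(counts, a, b)
        rev = call_degs(counts, b, a)
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert np.allclose(fwd["p"], rev["p"])

    def test_zero_library_raises(self):
        counts = _counts(np.zeros((5, 4), dtype=int))
        with pytest.raises(ValueError, match="library"):
            call_degs(counts, counts.sample_ids[:2], counts.sample_ids[2:])

    def test_null_gene_fdr_controlled(self):
        """Planted-null genes across 10 generator seeds: the realized false
        discovery fraction among them stays near or below the nominal 5%."""
        rates = []
        for seed in range(10):
            ds, truth = simulate_cohort(study_profile(seed=100 + seed), seed=100 + seed)
            groups = groups_from_truth(truth)
            out = call_degs(ds.counts, groups["MED12mt"], groups["normal"])
            null_genes = [
                g for g in out.index[out["passed_filter"]]
                if g not in truth.planted_log2fc
            ]
            rates.append(float(out.loc[null_genes, "is_deg"].mean()))
        assert np.mean(rates) <= 0.05 + 0.02

    def test_marker_effect_recovered(self, cohort, cohort_groups):
        ds, truth = cohort
        out = call_degs(ds.counts, cohort_groups["HMGA2hi"], cohort_groups["normal"])
        planted = truth.planted_log2fc["HMGA2"]["HMGA2hi"]
        assert out.loc["HMGA2", "log2fc"] == pytest.approx(planted, abs=1.0)


class TestStarburst:
    def _tables(self, delta, meth_p, log2fc, expr_q):
        dmc = pd.DataFrame(
            {"delta_beta": [delta], "p": [meth_p], "q": [meth_p], "direction": ["hyper"],
             "is_dmc": [True], "testable": [True]},
            index=pd.Index(["p1"], name="probe_id"),
        )
        genes = pd.Series({"p1": "G"})
        degs = pd.DataFrame(
            {"log2fc": [log2fc], "p": [expr_q], "q": [expr_q],
             "passed_filter": [True], "is_deg": [expr_q < 0.05]},
            index=pd.Index(["G"], name="gene_id"),
        )
        return starburst(dmc, genes, degs)

    def test_hyper_down_call(self):
        out = self._tables(0.3, 0.01, -2.0, 0.001)
        assert out.loc["G", "category"] == "hyper_down"

    def test_below_delta_cut_is_other(self):
        out = self._tables(0.20, 0.01, -2.0, 0.001)
        assert out.loc["G", "category"] == "other"

    def test_categories_partition_genes(self, cohort, cohort_groups):
        ds, _ = cohort
        fibroids = [s for g in ("MED12mt", "HMGA2hi", "HMGA1hi")
                    for s in cohort_groups[g]]
        normals = cohort_groups["normal"]
        dmc = call_dmcs(ds.beta, fibroids, normals)
        mapping = map_probes_to_promoters(ds.annotation)
        prom = mapping[mapping["location"] == "promoter"]
        degs = call_degs(ds.counts, fibroids, normals)
        out = starburst(dmc.loc[dmc.index.intersection(prom.index)], prom["gene"], degs)
        assert out["category"].isin(["hyper_down", "hypo_up", "other"]).all()
        assert not out.index.has_duplicates

    def test_planted_coupled_genes_recovered(self, cohort, cohort_groups):
        ds, truth = cohort
        fibroids = [s for g in ("MED12mt", "HMGA2hi", "HMGA1hi")
                    for s in cohort_groups[g]]
        normals = cohort_groups["normal"]
        dmc = call_dmcs(ds.beta, fibroids, normals)
        mapping = map_probes_to_promoters(ds.annotation)
        prom = mapping[mapping["location"] == "promoter"]
        degs = call_degs(ds.counts, fibroids, normals)
        out = starburst(dmc.loc[dmc.index.intersection(prom.index)], prom["gene"], degs)
        coupled = set(truth.planted_coupled_genes)
        recovered = coupled & set(out.index[out["category"] == "hyper_down"])
        assert len(recovered) / len(coupled) >= 0.9


class TestOverlap:
    @staticmethod
    def _degs(universe, up, down=()):
        idx = pd.Index([f"g{i}" for i in range(universe)], name="gene_id")
        fc = np.zeros(universe)
        is_deg = np.zeros(universe, bool)
        for i in up:
            fc[i], is_deg[i] = 1.0, True
        for i in down:
            fc[i], is_deg[i] = -1.0, True
        return pd.DataFrame(
            {"log2fc": fc, "p": 0.5, "q": 0.5, "passed_filter": True, "is_deg": is_deg},
            index=idx,
        )

    def test_independence_expectation_gives_zero_chi2(self):
        a = self._degs(100, up=range(20))
        b = self._degs(100, up=list(range(10)) + list(range(20, 60)))
        res = overlap_test(a, b)["up"]
        assert res.overlap == 10 and res.expected == pytest.approx(10.0)
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)

    def test_closed_form_chi2(self):
        a = self._degs(1000, up=range(100))
        b = self._degs(1000, up=list(range(50)) + list(range(100, 150)))
        res = overlap_test(a, b)["up"]
        expected_chi2 = 1000 * (50 * 850 - 50 * 50) ** 2 / (100 * 900 * 100 * 900)
        assert res.chi2 == pytest.approx(expected_chi2, rel=1e-12)

    def test_chi2_matches_closed_form_on_random_tables(self):
        """Property: the 2x2 statistic equals n(ad-bc)^2 / (row/col products)."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            t = rng.integers(1, 200, (2, 2)).astype(float)
            chi2, p = _chi2_2x2(t)
            n = t.sum()
            a, b, c, d = t.ravel()
            closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            assert chi2 == pytest.approx(closed, rel=1e-12)
            assert 0.0 <= p <= 1.0

    def test_planted_shared_program_significant_both_directions(self, cohort, cohort_groups):
        ds, _ = cohort
        normals = cohort_groups["normal"]
        degs_m = call_degs(ds.counts, cohort_groups["MED12mt"], normals)
        degs_h = call_degs(ds.counts, cohort_groups["HMGA2hi"], normals)
        res = overlap_test(degs_m, degs_h)
        assert res["up"].p < 0.001
        assert res["down"].p < 0.001
        assert res["up"].overlap > res["up"].expected

    def test_empty_universe_raises(self):
        a = self._degs(10, up=[0])
        b = self._degs(10, up=[1])
        b["passed_filter"] = False
        with pytest.raises(ValueError):
            overlap_test(a, b)


class TestCorrelation:
    def test_exact_linear_relation(self):
        x = np.arange(10, dtype=float)
        r, p = correlate_genes(x, 2 * x + 1, method="pearson")
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_rank_reversal_full_discordance(self):
        x = np.arange(10, dtype=float)
        tau, _ = correlate_genes(x, x[::-1], method="kendall")
        assert tau == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="zero-variance"):
            correlate_genes([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_monte_carlo_bivariate_normal(self):
        """Mean Pearson estimate over 200 reps of n=30 draws at rho=0.6 is
        within 0.1 of the truth."""
        rng = np.random.default_rng(11)
        rho, estimates = 0.6, []
        for _ in range(200):
            z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=30)
            r, _ = correlate_genes(z[:, 0], z[:, 1])
            estimates.append(r)
        assert np.mean(estimates) == pytest.approx(rho, abs=0.1)
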