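"""Variable-probe selection, clustering, consensus stability, classification."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from fibrointegra import BetaMatrix, ConfigError
from fibrointegra.subtyping import (
    k_scan,
    ClassificationError,
    adjusted_rand_index,
    classify_subtype,
    consensus_cluster,
    hier_cluster,
    select_variable_probes,
    stability_scores,
)


def _two_group_matrix(n_probes=50, n_per_group=5, gap=0.6, jitter=0.01, seed=0):
    rng = np.random.default_rng(seed)
    low = rng.normal(0.2, jitter, (n_probes, n_per_group))
    high = rng.normal(0.2 + gap, jitter, (n_probes, n_per_group))
    cols = [f"a{i}" for i in range(n_per_group)] + [f"b{i}" for i in range(n_per_group)]
    vals = np.clip(np.hstack([low, high]), 0, 1)
    return pd.DataFrame(vals, index=[f"p{i:03d}" for i in range(n_probes)], columns=cols)


class TestVariableProbes:
    def test_ceiling_arithmetic(self, cohort):
        ds, _ = cohort
        top = select_variable_probes(ds.beta, ds.annotation, fraction=0.01)
        assert len(top) == 200  # ceil(0.01 * 20,000)

    def test_constant_matrix_ties_lexicographic(self):
        vals = pd.DataFrame(0.5, index=[f"p{i:03d}" for i in range(300)],
                            columns=["s1", "s2", "s3"])
        with pytest.warns(UserWarning, match="zero"):
            top = select_variable_probes(BetaMatrix(vals), fraction=0.01)
        assert top == sorted(vals.index)[:3]

    def test_selection_matches_independent_sd_ranking(self, cohort):
        """Cross-check against a direct SD computation (pandas-free path)."""
        ds, _ = cohort
        top = select_variable_probes(ds.beta, ds.annotation, fraction=0.01)
        cpg = ds.annotation.of_class("CpG")
        arr = ds.beta.values.loc[cpg].to_numpy()
        sd = np.array([np.std(row[np.isfinite(row)], ddof=1) for row in arr])
        order = sorted(zip(-sd, cpg))[:200]
        assert top == [pid for _, pid in order]

    def test_planted_informative_probes_dominate_top(self, cohort):
        ds, truth = cohort
        top = set(select_variable_probes(ds.beta, ds.annotation, fraction=0.01))
        planted = set(truth.planted_informative_probes)
        assert len(planted & top) >= 140

    def test_bad_fraction_raises(self, cohort):
        ds, _ = cohort
        with pytest.raises(ConfigError):
            select_variable_probes(ds.beta, ds.annotation, fraction=1.5)

    def test_absolute_count_overrides_fraction(self, cohort):
        ds, _ = cohort
        top = select_variable_probes(ds.beta, ds.annotation, fraction=0.01, count=500)
        assert len(top) == 500


class TestHierCluster:
    def test_recovers_separated_groups(self):
        """Oracle: with between-group distance far above within-group spread,
        the k=2 cut must equal the partition found by thresholding pairwise
        distances directly."""
        data = _two_group_matrix()
        res = hier_cluster(data, k=2)
        labels = res.assignments
        # brute-force partition from pairwise distances
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(data.to_numpy().T))
        thresh = (d[d > 0].min() + d.max()) / 2
        group_a = {data.columns[0]} | {
            data.columns[j] for j in range(len(data.columns)) if d[0, j] < thresh
        }
        cut_a = {s for s in labels.index if labels[s] == labels[data.columns[0]]}
        assert cut_a == group_a

    def test_duplicate_sample_merges_at_zero_height(self):
        data = _two_group_matrix()
        data["dup"] = data["a0"]
        res = hier_cluster(data)
        assert res.linkage_matrix[0, 2] == pytest.approx(0.0)
        assert np.all(np.diff(res.linkage_matrix[:, 2]) >= -1e-9)

    def test_k_exceeding_samples_raises(self):
        data = _two_group_matrix(n_per_group=2)
        with pytest.raises(ConfigError):
            hier_cluster(data, k=10)

    def test_fibroid_subtree_has_three_clades(self, cohort, cohort_groups):
        """Study-profile cohort: the fibroids split into three clades of >= 2."""
        ds, truth = cohort
        top = select_variable_probes(ds.beta, ds.annotation, fraction=0.01)
        res = hier_cluster(ds.beta.values.loc[top], k=4)
        fibroids = [s for s, g in truth.group_label.items() if g != "normal"]
        fib_clusters = res.assignments[fibroids]
        sizes = fib_clusters.value_counts()
        assert len(sizes) == 3
        assert (sizes >= 2).all()

    def test_newick_export_parses(self, cohort):
        from io import StringIO

        from Bio import Phylo

        data = _two_group_matrix()
        tree = Phylo.read(StringIO(hier_cluster(data).to_newick()), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(data.columns)


class TestConsensus:
    def test_separated_groups_sharp_consensus(self):
        data = _two_group_matrix(n_per_group=4)
        res = consensus_cluster(data, k=2, iterations=200, seed=1)
        cons = res.consensus
        a = [c for c in data.columns if c.startswith("a")]
        b = [c for c in data.columns if c.startswith("b")]
        within = [cons.loc[x, y] for g in (a, b) for x in g for y in g if x != y]
        between = [cons.loc[x, y] for x in a for y in b]
        assert min(within) >= 0.95
        assert max(between) <= 0.05

    def test_same_seed_identical(self):
        data = _two_group_matrix()
        r1 = consensus_cluster(data, k=2, iterations=50, seed=3)
        r2 = consensus_cluster(data, k=2, iterations=50, seed=3)
        pd.testing.assert_frame_equal(r1.consensus, r2.consensus)
        assert (r1.assignments == r2.assignments).all()

    def test_consensus_entries_are_fractions(self, cohort):
        ds, _ = cohort
        top = select_variable_probes(ds.beta, ds.annotation)
        res = consensus_cluster(ds.beta.values.loc[top], k=4, iterations=100, seed=0)
        arr = res.consensus.to_numpy()
        assert np.allclose(arr, arr.T, equal_nan=True)
        finite = arr[np.isfinite(arr)]
        assert finite.min() >= 0.0 and finite.max() <= 1.0
        assert np.allclose(np.diag(arr), 1.0)

    def test_subtype_recovery_median_ari(self):
        """Over generator seeds at the study profile, consensus clustering at
        k=4 recovers the planted groups (median ARI >= 0.9); the internal ARI
        agrees with scikit-learn's."""
        from fibrointegra import study_profile, simulate_cohort

        aris = []
        for seed in range(20):
            ds, truth = simulate_cohort(study_profile(seed=seed), seed=seed)
            top = select_variable_probes(ds.beta, ds.annotation, fraction=0.01)
            res = consensus_cluster(
                ds.beta.values.loc[top], k=4, iterations=250, seed=seed
            )
            labels = pd.Series(truth.group_label)
            ari = adjusted_rand_index(res.assignments, labels)
            assert ari == pytest.approx(
                adjusted_rand_score(labels[res.assignments.index], res.assignments)
            )
            aris.append(ari)
        assert np.median(aris) >= 0.9


class TestStability:
    def test_all_ones_single_cluster(self):
        cons = pd.DataFrame(1.0, index=["s1", "s2", "s3"], columns=["s1", "s2", "s3"])
        assign = pd.Series(1, index=cons.index)
        scores, cluster_stab = stability_scores(cons, assign)
        assert np.allclose(scores.to_numpy(), 1.0)
        assert cluster_stab[1] == pytest.approx(1.0)

    def test_hand_computed_example(self):
        cons = pd.DataFrame(
            [[1.0, 0.8, 0.2], [0.8, 1.0, 0.4], [0.2, 0.4, 1.0]],
            index=["s1", "s2", "s3"], columns=["s1", "s2", "s3"],
        )
        assign = pd.Series({"s1": 1, "s2": 1, "s3": 2})
        with pytest.warns(UserWarning, match="singleton"):
            scores, cluster_stab = stability_scores(cons, assign)
        assert scores.loc["s1", 1] == pytest.approx(0.8)  # consensus(s1, s2)
        assert scores.loc["s3", 1] == pytest.approx(0.3)  # (0.2 + 0.4) / 2
        assert cluster_stab[1] == pytest.approx(0.8)
        assert scores.loc["s3", 2] == pytest.approx(1.0)  # singleton, flagged

    def test_matches_brute_force_on_random_matrices(self):
        """Property: scores equal naive averaging for random 6-sample matrices."""
        rng = np.random.default_rng(7)
        samples = [f"s{i}" for i in range(6)]
        for _ in range(25):
            m = rng.random((6, 6))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 1.0)
            cons = pd.DataFrame(m, index=samples, columns=samples)
            assign = pd.Series(rng.integers(1, 4, 6), index=samples)
            if assign.value_counts().min() < 2:
                continue
            scores, cluster_stab = stability_scores(cons, assign)
            for c in sorted(assign.unique()):
                members = [s for s in samples if assign[s] == c]
                for s in samples:
                    others = [x for x in members if x != s]
                    expected = np.mean([m[samples.index(s), samples.index(o)] for o in others])
                    assert scores.loc[s, c] == pytest.approx(expected)
                expected_cs = np.mean([scores.loc[s, c] for s in members])
                assert cluster_stab[c] == pytest.approx(expected_cs)


class TestClassification:
    def test_mutation_wins_outright(self):
        assert classify_subtype(True) == "MED12mt"
        assert classify_subtype(True, {"HMGA1": 99.0, "HMGA2": 99.0}) == "MED12mt"

    def test_precedence_hmga2_over_hmga1(self):
        assert classify_subtype(False, {"HMGA2": 6.0, "HMGA1": 3.0}) == "HMGA2hi"

    def test_hmga1_above_twofold(self):
        assert classify_subtype(False, {"HMGA2": 1.2, "HMGA1": 2.5}) == "HMGA1hi"

    def test_below_both_thresholds_unclassified(self):
        assert classify_subtype(False, {"HMGA1": 1.5, "HMGA2": 1.2}) == "unclassified"

    def test_missing_fold_changes_raise(self):
        with pytest.raises(ClassificationError):
            classify_subtype(False)

    def test_cohort_classification_recovers_planted_subtypes(self, cohort, cohort_groups):
        """Fold changes vs the normal-group mean CPM reproduce planted labels."""
        from fibrointegra.integration import cpm

        ds, truth = cohort
        normals = cohort_groups["normal"]
        all_cpm = cpm(ds.counts)
        normal_mean = all_cpm[normals].mean(axis=1)
        for sample, group in truth.group_label.items():
            if group == "normal":
                continue
            fc = {
                g: float((all_cpm.loc[g, sample] + 0.01) / (normal_mean[g] + 0.01))
                for g in ("HMGA1", "HMGA2")
            }
            med12 = bool(ds.samples.table.loc[sample, "med12_mutation"])
            assert classify_subtype(med12, fc) == group


def test_k_scan_reports_stability_without_choosing():
    data = _two_group_matrix(n_per_group=5)
    scan = k_scan(data, ks=(2, 3), iterations=60, seed=2)
    assert list(scan.index) == [2, 3]
    # the true two-group structure is maximally stable at k=2
    assert scan.loc[2, "mean_cluster_stability"] == pytest.approx(1.0, abs=0.02)
    assert scan.loc[2, "mean_cluster_stability"] >= scan.loc[3, "mean_cluster_stability"]
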