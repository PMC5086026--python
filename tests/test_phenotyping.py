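"""Decision rules, k-means contract, cluster ranking, phenotype assignment."""

import itertools

import numpy as np
import pandas as pd
import pytest

from panelweight import PhenotypeClassifier, PipelineConfig, classify_by_rules
from panelweight.features import KMEANS_FEATURES
from panelweight.phenotyping import (
    KMeansResult,
    assign_phenotypes,
    kmeans_cluster,
    pcp_outlier_stats,
    rank_clusters,
    split_lowest_cluster,
    wss_curve,
)

from .conftest import random_vectors, zero_vectors


def brute_force_wss(X: np.ndarray, k: int) -> float:
    """Exhaustive minimum within-cluster sum of squares over all k-partitions."""
    n = len(X)
    best = np.inf
    for assign in itertools.product(range(k), repeat=n):
        if len(set(assign)) < k:
            continue
        a = np.array(assign)
        wss = sum(
            float(((X[a == c] - X[a == c].mean(axis=0)) ** 2).sum())
            for c in range(k)
        )
        best = min(best, wss)
    return best


class TestRules:
    MEAN, SD = 2.3, 3.0

    def _classify(self, vec):
        return classify_by_rules(vec, self.MEAN, self.SD).iloc[0]

    def test_no_show_only_is_inactive(self):
        vec = zero_vectors(["p"])
        vec["no_show"] = 1
        assert self._classify(vec) == "inactive"

    def test_minimally_active_criteria(self):
        vec = zero_vectors(["p"])
        vec.loc["p", ["raw_pcp", "specialty_capped", "telephone",
                      "msgs_to_patient"]] = [1, 3, 2, 5]
        assert self._classify(vec) == "minimally_active"

    def test_high_outlier_above_six_sd(self):
        vec = zero_vectors(["p"])
        vec["raw_pcp"] = self.MEAN + 7 * self.SD
        assert self._classify(vec) == "high_outlier"

    def test_two_pcp_visits_proceed_to_clustering(self):
        vec = zero_vectors(["p"])
        vec["raw_pcp"] = 2
        assert self._classify(vec) == "none"

    def test_ed_visit_breaks_minimally_active(self):
        vec = zero_vectors(["p"])
        vec.loc["p", ["raw_pcp", "ed"]] = [1, 1]
        assert self._classify(vec) == "none"

    def test_sent_messages_block_inactive(self):
        # a patient who only sends messages has activity, hence not inactive
        vec = zero_vectors(["p"])
        vec["msgs_from_patient"] = 3
        assert self._classify(vec) == "minimally_active"

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            classify_by_rules(zero_vectors(["p"]), 2.0, -1.0)

    def test_outlier_precedes_minimal_screen(self):
        # meets the minimally-active count screen only if outliers are
        # removed first; high outlier must win
        vec = zero_vectors(["p"])
        vec["raw_pcp"] = 100
        out = classify_by_rules(vec, 1.0, 1.0)
        assert out.iloc[0] == "high_outlier"

    def test_stats_exclude_all_zero_patients(self):
        vec = zero_vectors(["a", "b", "c"])
        vec.loc["a", "raw_pcp"] = 2
        vec.loc["b", "raw_pcp"] = 4
        mean, sd = pcp_outlier_stats(vec)
        assert mean == pytest.approx(3.0)
        assert sd == pytest.approx(np.std([2, 4], ddof=1))


class TestKMeans:
    def _frame(self, X):
        return pd.DataFrame(X, columns=["f1", "f2"][: X.shape[1]])

    def test_separable_clouds_recovered(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (20, 2)), rng.normal(50, 0.1, (20, 2))])
        res = kmeans_cluster(self._frame(X), k=2, seed=0, features=["f1", "f2"])
        labels = res.assignments.to_numpy()
        assert len(set(labels[:20])) == 1
        assert len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_identical_points_zero_wss(self):
        X = np.ones((10, 2))
        res = kmeans_cluster(self._frame(X), k=2, seed=0, features=["f1", "f2"])
        assert res.wss == pytest.approx(0.0, abs=1e-12)

    def test_n_below_k_rejected(self):
        with pytest.raises(ValueError):
            kmeans_cluster(self._frame(np.ones((2, 2))), k=3, features=["f1", "f2"])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_partition_optimum(self, seed):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(0, 1, (3, 2)), rng.normal(4, 1, (3, 2))])
        res = kmeans_cluster(self._frame(X), k=2, seed=seed, features=["f1", "f2"])
        assert res.wss == pytest.approx(brute_force_wss(X, 2), rel=1e-9)

    def test_best_of_restarts_dominates(self):
        vec = random_vectors(60, seed=3)
        res = kmeans_cluster(vec, k=4, seed=5)
        assert res.wss == pytest.approx(min(res.per_restart_wss))
        assert all(res.wss <= w + 1e-9 for w in res.per_restart_wss)

    def test_wss_equals_sum_of_squared_distances(self):
        vec = random_vectors(50, seed=8)
        res = kmeans_cluster(vec, k=3, seed=8)
        X = vec[KMEANS_FEATURES].to_numpy()
        own = res.centers[res.assignments.to_numpy()]
        assert res.wss == pytest.approx(float(((X - own) ** 2).sum()), rel=1e-6)

    def test_deterministic_for_fixed_seed(self):
        vec = random_vectors(80, seed=1)
        r1 = kmeans_cluster(vec, k=4, seed=42)
        r2 = kmeans_cluster(vec, k=4, seed=42)
        assert r1.wss == r2.wss
        assert r1.assignments.equals(r2.assignments)


class TestRanking:
    def _result(self, assignments, k):
        ids = [f"p{i}" for i in range(len(assignments))]
        return KMeansResult(
            assignments=pd.Series(assignments, index=ids),
            centers=np.zeros((k, 1)), wss=0.0, seed=0, restarts=1, max_iter=1,
        )

    def test_sorted_by_median(self):
        # cluster medians (5, 1, 3) -> order (1, 2, 0)
        res = self._result([0, 0, 1, 1, 2, 2], 3)
        pcp = pd.Series([5, 5, 1, 1, 3, 3], index=res.assignments.index)
        assert rank_clusters(res, pcp) == [1, 2, 0]

    def test_single_cluster_identity(self):
        res = self._result([0, 0], 1)
        pcp = pd.Series([1, 2], index=res.assignments.index)
        assert rank_clusters(res, pcp) == [0]

    def test_tied_medians_broken_by_mean(self):
        res = self._result([0, 0, 0, 1, 1, 1], 2)
        pcp = pd.Series([1, 2, 6, 1, 2, 3], index=res.assignments.index)
        # both medians 2; means 3.0 vs 2.0 -> cluster 1 first
        assert rank_clusters(res, pcp) == [1, 0]


class TestSplitAndAssign:
    def test_two_points_become_singletons(self, config):
        vec = random_vectors(2, seed=0)
        res = split_lowest_cluster(vec, config.kmeans, seed=0)
        assert res.wss == pytest.approx(0.0, abs=1e-9)
        assert set(res.assignments) == {0, 1}

    def test_too_few_points_rejected(self, config):
        with pytest.raises(ValueError):
            split_lowest_cluster(random_vectors(1, seed=0), config.kmeans, seed=0)

    def test_assignment_partitions_population(self, config):
        vec = random_vectors(200, seed=6, scale=4.0)
        clf = PhenotypeClassifier(config=config, seed=0).fit(vec)
        phen = clf.training_assignments_
        assert len(phen) == len(vec)
        assert phen["phenotype"].isin(
            ["inactive", "A", "B", "C", "D", "E", "F", "G"]
        ).all()
        # rule provenance consistent with label
        assert (phen.loc[phen["phenotype"] == "A", "source"]
                == "rule_minimally_active").all()
        assert (phen.loc[phen["phenotype"] == "G", "source"]
                == "rule_high_outlier").all()

    def test_phenotype_medians_non_decreasing(self, small_pop, config):
        from panelweight.features import (
            build_visit_vectors, compute_specialty_caps, specialty_patient_counts,
        )

        caps = compute_specialty_caps(
            specialty_patient_counts(small_pop.encounters, config.year1)
        )
        vec = build_visit_vectors(
            small_pop.encounters, small_pop.patients["patient_id"],
            config.year1, caps,
        )
        active = vec[(vec > 0).any(axis=1)]
        clf = PhenotypeClassifier(config=config, seed=1).fit(active)
        phen = clf.training_assignments_["phenotype"]
        medians = [
            active.loc[phen[phen == p].index, "raw_pcp"].median()
            for p in "BCDEF"
            if (phen == p).any()
        ]
        assert medians == sorted(medians)

    def test_predict_agrees_with_training_assignments(self, config):
        vec = random_vectors(300, seed=9, scale=4.0)
        clf = PhenotypeClassifier(config=config, seed=0).fit(vec)
        predicted = clf.predict(vec)
        train = clf.training_assignments_
        # rules agree exactly; clustered patients agree up to boundary points
        rule_mask = train["source"].str.startswith("rule")
        assert predicted.loc[rule_mask, "phenotype"].equals(
            train.loc[rule_mask, "phenotype"]
        )
        agree = (predicted["phenotype"] == train["phenotype"]).mean()
        assert agree > 0.9


class TestWssCurve:
    def test_k1_closed_form_and_kn_zero(self):
        vec = random_vectors(12, seed=2)
        X = vec[KMEANS_FEATURES].to_numpy()
        curve = wss_curve(vec, [1, len(vec)], seed=0)
        total_ss = float(((X - X.mean(axis=0)) ** 2).sum())
        assert curve[1] == pytest.approx(total_ss, rel=1e-9)
        assert curve[len(vec)] == pytest.approx(0.0, abs=1e-9)

    def test_non_increasing_within_tolerance(self):
        vec = random_vectors(120, seed=4)
        curve = wss_curve(vec, range(1, 7), restarts=5, max_iter=20, seed=0)
        values = [curve[k] for k in sorted(curve)]
        for a, b in zip(values, values[1:]):
            assert b <= a * 1.05  # restart noise tolerance
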