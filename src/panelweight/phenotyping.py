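"""Utilization phenotyping: decision rules plus two rounds of k-means.

Patients are first screened by deterministic rules — high outliers (raw PCP
visits more than 6 SD above the population mean), minimally active (at most
one PCP visit, no ED visits or hospitalizations, few specialty, telephone and
message contacts), and inactive (no activity at all, missed appointments
excluded).  Everyone else is clustered: k-means with 4 centers on the raw
visit-rate features (all encounter categories except secure messaging,
deliberately unstandardised — the per-specialty capping is the only scale
control), then the lowest-ranked cluster is split in two by a second k-means.
The result is seven utilization phenotypes A-G plus the inactive group:
A = minimally active, G = high outlier, and B-F are the five clustered
groups in ascending order of median raw PCP visits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .config import KMeansSettings, PipelineConfig, RuleThresholds
from .features import KMEANS_FEATURES, VECTOR_COLUMNS

PHENOTYPES = ["inactive", "A", "B", "C", "D", "E", "F", "G"]

#: Vector columns that must all be zero for the inactive rule
#: (every activity category except missed appointments).
_ACTIVITY_COLUMNS = [c for c in VECTOR_COLUMNS if c not in ("no_show",)]


@dataclass
class KMeansResult:
    assignments: pd.Series          # patient_id -> cluster index
    centers: np.ndarray             # k x n_features
    wss: float                      # total within-cluster sum of squares
    seed: int
    restarts: int
    max_iter: int
    per_restart_wss: list = field(default_factory=list)


def pcp_outlier_stats(vectors: pd.DataFrame) -> tuple[float, float]:
    """Mean and sample SD of raw PCP visits among patients with any activity.

    The high-outlier rule is anchored on the population of patients with at
    least one encounter of any kind (no-shows included).
    """
    active = vectors[(vectors[VECTOR_COLUMNS] > 0).any(axis=1)]
    pcp = active["raw_pcp"].to_numpy(dtype=float)
    if pcp.size == 0:
        raise ValueError("no active patients to compute PCP statistics")
    sd = float(pcp.std(ddof=1)) if pcp.size > 1 else 0.0
    return float(pcp.mean()), sd


def classify_by_rules(
    vectors: pd.DataFrame,
    pcp_mean: float,
    pcp_sd: float,
    thresholds: RuleThresholds | None = None,
) -> pd.Series:
    """Rule screen: 'high_outlier', 'minimally_active', 'inactive' or 'none'.

    High outliers are removed first; the minimally-active screen is then
    applied, and within it patients with zero activity everywhere (missed
    appointments excluded) are inactive.  'none' proceeds to clustering.
    """
    if pcp_sd < 0:
        raise ValueError("pcp_sd must be non-negative")
    t = thresholds or RuleThresholds()

    out = pd.Series("none", index=vectors.index, name="rule")

    high = vectors["raw_pcp"] > pcp_mean + t.outlier_sd * pcp_sd
    hosp = vectors["emergent_hosp"] + vectors["elective_hosp"]
    minimal = (
        (vectors["raw_pcp"] <= t.max_pcp)
        & (vectors["ed"] <= t.max_ed)
        & (hosp <= t.max_hospitalizations)
        & (vectors["specialty_capped"] <= t.max_specialty)
        & (vectors["telephone"] <= t.max_telephone)
        & (vectors["msgs_to_patient"] <= t.max_msgs_to_patient)
    )
    inactive = (vectors[_ACTIVITY_COLUMNS] == 0).all(axis=1)

    out[minimal & ~high] = "minimally_active"
    out[inactive & ~high] = "inactive"
    out[high] = "high_outlier"
    return out


def _restart_seeds(seed: int, restarts: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(restarts) % (2**31)


def kmeans_cluster(
    vectors: pd.DataFrame,
    k: int,
    restarts: int = 5,
    max_iter: int = 10,
    seed: int = 0,
    features: list[str] | None = None,
) -> KMeansResult:
    """Best-of-``restarts`` k-means on the raw (unstandardised) features.

    Each restart is an independent random initialisation run for at most
    ``max_iter`` Lloyd iterations; the restart with the lowest within-cluster
    sum of squares wins.  Deterministic for a fixed seed.
    """
    features = features or KMEANS_FEATURES
    X = vectors[features].to_numpy(dtype=float)
    n = X.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} points, got {n}")

    best = None
    per_restart = []
    for rs in _restart_seeds(seed, restarts):
        km = KMeans(
            n_clusters=k, init="random", n_init=1, max_iter=max_iter,
            algorithm="lloyd", random_state=int(rs),
        ).fit(X)
        per_restart.append(float(km.inertia_))
        if best is None or km.inertia_ < best.inertia_:
            best = km

    return KMeansResult(
        assignments=pd.Series(best.labels_, index=vectors.index, name="cluster"),
        centers=best.cluster_centers_,
        wss=float(best.inertia_),
        seed=seed,
        restarts=restarts,
        max_iter=max_iter,
        per_restart_wss=per_restart,
    )


def rank_clusters(result: KMeansResult, raw_pcp: pd.Series) -> list[int]:
    """Cluster indices in ascending order of within-cluster median raw PCP
    visits; ties broken by mean raw PCP, then by cluster index."""
    stats = []
    for c in range(result.centers.shape[0]):
        members = raw_pcp[result.assignments[result.assignments == c].index]
        stats.append((float(members.median()), float(members.mean()), c))
    return [c for _, _, c in sorted(stats)]


def split_lowest_cluster(
    vectors: pd.DataFrame,
    settings: KMeansSettings,
    seed: int,
    features: list[str] | None = None,
) -> KMeansResult:
    """Second-round k-means (k=2, same settings) on the lowest-ranked
    round-1 cluster's members."""
    if len(vectors) < settings.split_k:
        raise ValueError("lowest cluster has too few patients to split")
    return kmeans_cluster(
        vectors, k=settings.split_k, restarts=settings.restarts,
        max_iter=settings.max_iter, seed=seed, features=features,
    )


def wss_curve(
    vectors: pd.DataFrame,
    k_range,
    restarts: int = 5,
    max_iter: int = 10,
    seed: int = 0,
) -> dict[int, float]:
    """Diagnostic within-group sum of squares as a function of k (the
    elbow curve used to justify k=4)."""
    return {
        int(k): kmeans_cluster(
            vectors, k=int(k), restarts=restarts, max_iter=max_iter,
            seed=seed + int(k),
        ).wss
        for k in k_range
    }


def assign_phenotypes(
    rule_labels: pd.Series,
    round1: KMeansResult,
    round1_order: list[int],
    round2: KMeansResult,
    raw_pcp: pd.Series,
) -> pd.DataFrame:
    """Combine rules and both clustering rounds into phenotypes.

    The five clustered groups (two halves of the split lowest cluster plus
    the three remaining round-1 clusters) are labelled B-F in ascending
    order of median raw PCP visits; minimally active patients are A and
    high outliers G.  Returns a DataFrame with 'phenotype' and 'source'.
    """
    out = pd.DataFrame(
        {"phenotype": pd.Series("", index=rule_labels.index, dtype=object),
         "source": pd.Series("", index=rule_labels.index, dtype=object)}
    )
    out.loc[rule_labels == "inactive", :] = ["inactive", "rule_inactive"]
    out.loc[rule_labels == "minimally_active", :] = ["A", "rule_minimally_active"]
    out.loc[rule_labels == "high_outlier", :] = ["G", "rule_high_outlier"]

    lowest = round1_order[0]
    groups: list[tuple[pd.Index, str]] = []
    for sub in range(round2.centers.shape[0]):
        ids = round2.assignments[round2.assignments == sub].index
        groups.append((ids, "kmeans_round2"))
    for c in round1_order[1:]:
        ids = round1.assignments[round1.assignments == c].index
        groups.append((ids, "kmeans_round1"))

    def _key(item):
        ids, _ = item
        members = raw_pcp[ids]
        return (float(members.median()), float(members.mean()))

    letters = ["B", "C", "D", "E", "F"]
    for letter, (ids, source) in zip(letters, sorted(groups, key=_key)):
        out.loc[ids, "phenotype"] = letter
        out.loc[ids, "source"] = source

    assert (out["phenotype"] != "").all(), "phenotype assignment must partition"
    return out


@dataclass
class PhenotypeClassifier:
    """Rule thresholds and frozen cluster centers learned on a training set,
    reusable to phenotype any later visit-vector table."""

    config: PipelineConfig
    seed: int
    pcp_mean: float = 0.0
    pcp_sd: float = 0.0
    round1_centers: np.ndarray | None = None
    round2_centers: np.ndarray | None = None
    round1_letters: dict = field(default_factory=dict)   # round-1 cluster -> letter
    round2_letters: dict = field(default_factory=dict)   # round-2 cluster -> letter
    lowest_cluster: int = -1
    features: list = field(default_factory=lambda: list(KMEANS_FEATURES))
    training_assignments_: pd.DataFrame | None = None
    wss_: float = float("nan")

    def fit(self, vectors: pd.DataFrame) -> "PhenotypeClassifier":
        cfg = self.config
        self.pcp_mean, self.pcp_sd = pcp_outlier_stats(vectors)
        rules = classify_by_rules(vectors, self.pcp_mean, self.pcp_sd, cfg.rules)

        clusterable = vectors[rules == "none"]
        round1 = kmeans_cluster(
            clusterable, k=cfg.kmeans.k, restarts=cfg.kmeans.restarts,
            max_iter=cfg.kmeans.max_iter, seed=self.seed, features=self.features,
        )
        raw_pcp = vectors["raw_pcp"]
        order = rank_clusters(round1, raw_pcp)
        self.lowest_cluster = order[0]
        lowest_ids = round1.assignments[round1.assignments == order[0]].index
        round2 = split_lowest_cluster(
            clusterable.loc[lowest_ids], cfg.kmeans, seed=self.seed + 1,
            features=self.features,
        )

        assigned = assign_phenotypes(rules, round1, order, round2, raw_pcp)
        self.round1_centers = round1.centers
        self.round2_centers = round2.centers
        self.round1_letters = {
            c: assigned.loc[
                round1.assignments[round1.assignments == c].index, "phenotype"
            ].iloc[0]
            for c in order[1:]
        }
        self.round2_letters = {
            s: assigned.loc[
                round2.assignments[round2.assignments == s].index, "phenotype"
            ].iloc[0]
            for s in range(round2.centers.shape[0])
        }
        self.training_assignments_ = assigned
        self.wss_ = round1.wss
        return self

    def predict(self, vectors: pd.DataFrame) -> pd.DataFrame:
        """Phenotype new patients: frozen rules first, then nearest frozen
        center (round 2 centers within the split cluster)."""
        if self.round1_centers is None:
            raise RuntimeError("classifier is not fitted")
        rules = classify_by_rules(vectors, self.pcp_mean, self.pcp_sd,
                                  self.config.rules)
        out = pd.DataFrame(
            {"phenotype": pd.Series("", index=vectors.index, dtype=object),
             "source": pd.Series("", index=vectors.index, dtype=object)}
        )
        out.loc[rules == "inactive", :] = ["inactive", "rule_inactive"]
        out.loc[rules == "minimally_active", :] = ["A", "rule_minimally_active"]
        out.loc[rules == "high_outlier", :] = ["G", "rule_high_outlier"]

        rest = vectors[rules == "none"]
        if not rest.empty:
            X = rest[self.features].to_numpy(dtype=float)
            near1 = cdist(X, self.round1_centers).argmin(axis=1)
            in_split = near1 == self.lowest_cluster
            letters = np.empty(len(rest), dtype=object)
            for c, letter in self.round1_letters.items():
                letters[near1 == c] = letter
            if in_split.any():
                near2 = cdist(X[in_split], self.round2_centers).argmin(axis=1)
                split_letters = np.array(
                    [self.round2_letters[s] for s in range(self.round2_centers.shape[0])]
                )
                letters[in_split] = split_letters[near2]
            out.loc[rest.index, "phenotype"] = letters
            out.loc[rest.index, "source"] = np.where(
                in_split, "kmeans_round2", "kmeans_round1"
            )
        return out
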