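"""Cluster weights and weighted panel sizes.

Weights are anchored on the median effective PCP visit count in each work
cluster: the medium and high weights are the ratios of their medians to the
low cluster's median, the inactive cluster gets a fixed nominal weight
(0.05 by default — empaneled but currently dormant), and a scaling factor w
rescales the low/medium/high weights so that the total weighted population
equals the total unweighted population.  A provider's weighted panel size is
then the weight-weighted count of their empaneled patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .work_clusters import FINAL_ORDER

ACTIVE_CLUSTERS = ["low", "medium", "high"]


@dataclass
class ClusterWeights:
    weight: dict                     # cluster -> weight
    w: float                         # conservation scaling factor
    medians: dict                    # cluster -> median effective PCP visits
    ratios: dict = field(default_factory=dict)
    inactive_weight_raw: float = 0.05

    def as_series(self) -> pd.Series:
        return pd.Series({c: self.weight[c] for c in FINAL_ORDER})


def cluster_medians(
    final: pd.Series, effective_pcp: pd.Series
) -> dict[str, float]:
    """Median effective PCP visits per active work cluster."""
    out = {}
    for cluster in ACTIVE_CLUSTERS:
        members = effective_pcp[final[final == cluster].index]
        if members.empty:
            raise ValueError(f"cluster {cluster!r} is empty; cannot take a median")
        out[cluster] = float(members.median())
    return out


def relative_ratios(medians: dict[str, float]) -> dict[str, float]:
    """Cluster medians relative to the low cluster (low := 1)."""
    low = medians["low"]
    if low <= 0:
        raise ValueError("low-cluster median must be positive")
    return {c: medians[c] / low for c in ACTIVE_CLUSTERS}


def solve_scaling_factor(
    cluster_sizes: dict[str, int],
    ratios: dict[str, float],
    inactive_weight_raw: float = 0.05,
    medians: dict | None = None,
) -> ClusterWeights:
    """Solve w so total weighted size equals total unweighted size.

    The inactive cluster keeps its fixed raw weight; w scales the
    low/medium/high ratio weights to absorb the remainder:
    w = (N_total - N_inactive * w_inactive) / sum_c N_c * ratio_c.
    """
    n_total = sum(cluster_sizes.get(c, 0) for c in FINAL_ORDER)
    n_inactive = cluster_sizes.get("inactive", 0)
    denom = sum(cluster_sizes.get(c, 0) * ratios[c] for c in ACTIVE_CLUSTERS)
    if denom <= 0:
        raise ValueError("active clusters are empty; scaling factor undefined")
    w = (n_total - n_inactive * inactive_weight_raw) / denom
    weight = {c: w * ratios[c] for c in ACTIVE_CLUSTERS}
    weight["inactive"] = inactive_weight_raw
    return ClusterWeights(
        weight=weight, w=w, medians=dict(medians or {}), ratios=dict(ratios),
        inactive_weight_raw=inactive_weight_raw,
    )


def compute_cluster_weights(
    final: pd.Series,
    effective_pcp: pd.Series,
    inactive_weight_raw: float = 0.05,
) -> ClusterWeights:
    """Medians -> ratios -> conservation solve, in one call."""
    medians = cluster_medians(final, effective_pcp)
    ratios = relative_ratios(medians)
    sizes = final.value_counts().to_dict()
    return solve_scaling_factor(sizes, ratios, inactive_weight_raw, medians)


def weighted_panel_size(
    assignments: pd.DataFrame,
    weights: ClusterWeights,
    unit: str = "provider",
) -> pd.DataFrame:
    """Per-unit (provider or clinic) weighted panel summary.

    ``assignments`` needs a ``final`` work-cluster column and the ``unit``
    column.  Weighted sizes are carried as reals; rounding is for display.
    """
    counts = (
        assignments.groupby([unit, "final"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=FINAL_ORDER, fill_value=0)
    )
    wvec = weights.as_series()
    out = counts.copy()
    out["unweighted_size"] = counts.sum(axis=1)
    out["weighted_size"] = counts.mul(wvec, axis=1).sum(axis=1)
    out["relative_change_pct"] = np.where(
        out["unweighted_size"] > 0,
        (out["weighted_size"] - out["unweighted_size"])
        / out["unweighted_size"] * 100.0,
        0.0,
    )
    return out


def panel_change_report(
    summaries: pd.DataFrame, min_panel: int = 150
) -> dict:
    """Distribution of relative panel-size change among units with
    unweighted panels larger than ``min_panel`` patients."""
    eligible = summaries[summaries["unweighted_size"] > min_panel]
    change = eligible["relative_change_pct"]
    return {
        "n_units": int(len(eligible)),
        "n_excluded": int(len(summaries) - len(eligible)),
        "mean_change_pct": float(change.mean()) if len(eligible) else float("nan"),
        "min_change_pct": float(change.min()) if len(eligible) else float("nan"),
        "max_change_pct": float(change.max()) if len(eligible) else float("nan"),
        "share_within_20pct": (
            float((change.abs() <= 20).mean()) if len(eligible) else float("nan")
        ),
        "total_weighted_minus_unweighted": float(
            summaries["weighted_size"].sum() - summaries["unweighted_size"].sum()
        ),
    }
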