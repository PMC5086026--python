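"""Collapse phenotypes into primary care work clusters with message escalation.

The seven utilization phenotypes are folded into three intermediate groups
X < Y < Z (ranked by median PCP visits), a secure-messaging escalation rule
promotes unusually message-heavy patients one group, and the groups are
relabelled low / medium / high.  Minimally active patients (phenotype A) are
exempt from escalation and join the low cluster at the end; inactive
patients bypass the whole step.
"""

from __future__ import annotations

import pandas as pd

from .config import EscalationThresholds, PipelineConfig

INTERMEDIATE_ORDER = ["X", "Y", "Z"]
FINAL_ORDER = ["inactive", "low", "medium", "high"]
_GROUP_TO_FINAL = {"X": "low", "Y": "medium", "Z": "high"}


def collapse_phenotypes(
    phenotypes: pd.Series, collapse_map: dict[str, str] | None = None
) -> pd.Series:
    """Map each phenotype A-G onto an intermediate group X/Y/Z.

    Inactive patients bypass the collapse and get 'n/a'.
    """
    cmap = collapse_map or PipelineConfig().collapse_map
    out = pd.Series("n/a", index=phenotypes.index, name="intermediate", dtype=object)
    active = phenotypes != "inactive"
    unmapped = set(phenotypes[active].unique()) - set(cmap)
    if unmapped:
        raise KeyError(f"phenotypes missing from collapse map: {sorted(unmapped)}")
    out[active] = phenotypes[active].map(cmap)
    return out


def message_escalation(
    groups: pd.Series,
    msgs_from_patient: pd.Series,
    msgs_to_patient: pd.Series,
    thresholds: EscalationThresholds | None = None,
    exempt: pd.Series | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Promote message-heavy patients one group (applied once, no cascade).

    A patient escalates if they SENT more messages than 1.5 SD above the
    mean of their originally assigned group, or RECEIVED more than 24
    messages from the care team.  The top group cannot escalate; group
    statistics are computed on the full originally assigned groups.
    Returns (escalated groups, boolean escalated flags).
    """
    t = thresholds or EscalationThresholds()
    exempt = exempt if exempt is not None else pd.Series(False, index=groups.index)

    new_groups = groups.copy()
    escalated = pd.Series(False, index=groups.index, name="escalated")
    in_group = groups.isin(INTERMEDIATE_ORDER)

    stats = msgs_from_patient[in_group].groupby(groups[in_group]).agg(["mean", "std"])
    for i, g in enumerate(INTERMEDIATE_ORDER[:-1]):
        members = groups == g
        if not members.any() or g not in stats.index:
            continue
        mean_g = stats.loc[g, "mean"]
        sd_g = stats.loc[g, "std"]
        sd_g = 0.0 if pd.isna(sd_g) else sd_g
        hot = members & ~exempt & (
            (msgs_from_patient > mean_g + t.msg_sd * sd_g)
            | (msgs_to_patient > t.max_msgs_to_patient)
        )
        new_groups[hot] = INTERMEDIATE_ORDER[i + 1]
        escalated[hot] = True
    return new_groups, escalated


def finalize(
    phenotypes: pd.Series,
    intermediate: pd.Series,
    escalated: pd.Series,
    escalated_groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Relabel X/Y/Z as low/medium/high; phenotype A is forced to low and
    inactive stays inactive.

    ``intermediate`` is the originally assigned group (kept for provenance);
    ``escalated_groups``, if given, is the post-escalation group that the
    final label is read from.
    """
    groups = escalated_groups if escalated_groups is not None else intermediate
    final = groups.map(_GROUP_TO_FINAL)
    final[phenotypes == "A"] = "low"
    final[phenotypes == "inactive"] = "inactive"
    out = pd.DataFrame(
        {
            "phenotype": phenotypes,
            "intermediate": intermediate,
            "final": final.astype(object),
            "escalated": escalated & (phenotypes != "A"),
        }
    )
    assert out["final"].isin(FINAL_ORDER).all()
    return out


def assign_work_clusters(
    phenotypes: pd.Series,
    vectors: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Full phenotype -> work-cluster step on one assignment population."""
    config = config or PipelineConfig()
    intermediate = collapse_phenotypes(phenotypes, config.collapse_map)
    exempt = phenotypes == "A"
    escalated_groups, escalated = message_escalation(
        intermediate,
        vectors["msgs_from_patient"],
        vectors["msgs_to_patient"],
        config.escalation,
        exempt=exempt,
    )
    return finalize(phenotypes, intermediate, escalated, escalated_groups)
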