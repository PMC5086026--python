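"""Per-patient annual visit vectors from raw encounter records.

Each empaneled patient's activity within a 12-month window is summarised as a
vector of annual encounter counts: an "effective" primary care visit count
(each office visit up-weighted by the active-medication count at that visit),
raw counts for the other encounter types, a per-specialty capped specialty
total, and secure-message counts split by direction.  Patients active for
less than the full window are NOT annualised — their counts are used as-is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import MedWeightBands, Window

#: Closed set of encounter categories in the raw feed.
CATEGORIES = [
    "pcp_visit",
    "no_show",
    "urgent_care",
    "telephone",
    "ed_visit",
    "emergent_hosp",
    "elective_hosp",
    "specialty_visit",
    "infusion",
    "transfusion",
    "radiology_procedure",
    "message_to_patient",
    "message_from_patient",
]

#: Visit-vector columns, in canonical order.
VECTOR_COLUMNS = [
    "raw_pcp",
    "effective_pcp",
    "no_show",
    "urgent_care",
    "telephone",
    "ed",
    "emergent_hosp",
    "elective_hosp",
    "specialty_capped",
    "infusion",
    "transfusion",
    "radiology",
    "msgs_to_patient",
    "msgs_from_patient",
]

#: Simple-count categories and the vector column each feeds.
_COUNT_MAP = {
    "no_show": "no_show",
    "urgent_care": "urgent_care",
    "telephone": "telephone",
    "ed_visit": "ed",
    "emergent_hosp": "emergent_hosp",
    "elective_hosp": "elective_hosp",
    "infusion": "infusion",
    "transfusion": "transfusion",
    "radiology_procedure": "radiology",
    "message_to_patient": "msgs_to_patient",
    "message_from_patient": "msgs_from_patient",
}

#: Feature columns entering k-means: every encounter category except the
#: secure-messaging counts, all in visits/year, unstandardised.
KMEANS_FEATURES = [
    "effective_pcp",
    "no_show",
    "urgent_care",
    "telephone",
    "ed",
    "emergent_hosp",
    "elective_hosp",
    "specialty_capped",
    "infusion",
    "transfusion",
    "radiology",
]

#: In-person encounter columns summed for the naive (septile) phenotype.
IN_PERSON_COLUMNS = [
    "raw_pcp",
    "urgent_care",
    "ed",
    "emergent_hosp",
    "elective_hosp",
    "specialty_capped",
    "infusion",
    "transfusion",
    "radiology",
]


@dataclass
class SpecialtyCaps:
    """Per-specialty annual visit ceilings (mean + 2 SD among that
    specialty's users)."""

    cap: dict

    def __getitem__(self, specialty: str) -> float:
        return self.cap[specialty]

    def __contains__(self, specialty: str) -> bool:
        return specialty in self.cap


def medication_visit_weight(
    med_count: int, bands: MedWeightBands | None = None
) -> float:
    """Weight of one primary care visit given the active-medication count.

    Visits with few medications count once; polypharmacy visits count more
    (1.5x for 6-10 medications, 1.75x above 10 by default) to reflect the
    extra reconciliation effort.
    """
    if med_count < 0:
        raise ValueError(f"med_count must be non-negative, got {med_count}")
    bands = bands or MedWeightBands()
    if med_count <= bands.low_max:
        return bands.low
    if med_count <= bands.mid_max:
        return bands.mid
    return bands.high


def medication_visit_weights(
    med_counts: np.ndarray, bands: MedWeightBands | None = None
) -> np.ndarray:
    """Vectorised :func:`medication_visit_weight`."""
    bands = bands or MedWeightBands()
    counts = np.asarray(med_counts)
    if (counts < 0).any():
        raise ValueError("med_count must be non-negative")
    out = np.full(counts.shape, bands.high, dtype=float)
    out[counts <= bands.mid_max] = bands.mid
    out[counts <= bands.low_max] = bands.low
    return out


def effective_pcp_visits(
    visits: Iterable[tuple], bands: MedWeightBands | None = None
) -> float:
    """Sum of medication-weighted primary care visits.

    ``visits`` is an iterable of ``(date, med_count)`` pairs for one patient
    within one window.
    """
    return float(
        sum(medication_visit_weight(med, bands) for _, med in visits)
    )


def compute_specialty_caps(
    population_specialty_counts: Mapping[str, Sequence[float]],
) -> SpecialtyCaps:
    """Annual visit cap per specialty: mean + 2 sample SD among patients
    with at least one visit to that specialty.

    A specialty seen by a single patient has no variance information; its
    cap is that patient's count.
    """
    caps = {}
    for specialty, counts in population_specialty_counts.items():
        arr = np.asarray(list(counts), dtype=float)
        arr = arr[arr > 0]
        if arr.size == 0:
            raise ValueError(f"specialty {specialty!r} has no patients with visits")
        if arr.size == 1:
            caps[specialty] = float(arr[0])
        else:
            caps[specialty] = float(arr.mean() + 2.0 * arr.std(ddof=1))
    return SpecialtyCaps(cap=caps)


def capped_specialty_total(
    counts: Mapping[str, float], caps: SpecialtyCaps
) -> float:
    """Total specialty visits with each specialty truncated at its cap."""
    total = 0.0
    for specialty, n in counts.items():
        if specialty not in caps:
            raise KeyError(f"no cap for observed specialty {specialty!r}")
        total += min(float(n), caps[specialty])
    return total


def specialty_patient_counts(
    encounters: pd.DataFrame, window: Window
) -> dict[str, np.ndarray]:
    """Per-specialty arrays of annual visit counts among the patients who
    saw that specialty inside ``window`` (cap-estimation input)."""
    spec = _in_window(encounters, window)
    spec = spec[spec["category"] == "specialty_visit"]
    if spec.empty:
        return {}
    counts = spec.groupby(["specialty", "patient_id"], observed=True).size()
    return {
        specialty: grp.to_numpy(dtype=float)
        for specialty, grp in counts.groupby(level=0, observed=True)
    }


def _in_window(encounters: pd.DataFrame, window: Window) -> pd.DataFrame:
    dates = pd.to_datetime(encounters["date"]).dt.date
    mask = (dates >= window.start) & (dates < window.end)
    return encounters.loc[mask]


def build_visit_vectors(
    encounters: pd.DataFrame,
    patient_ids: Sequence,
    window: Window,
    caps: SpecialtyCaps,
    bands: MedWeightBands | None = None,
) -> pd.DataFrame:
    """Visit vectors for every patient in ``patient_ids`` over ``window``.

    Records outside the window are ignored; patients with no in-window
    records get all-zero vectors.  Returns a DataFrame indexed by patient id
    with :data:`VECTOR_COLUMNS`.
    """
    bands = bands or MedWeightBands()
    enc = _in_window(encounters, window)
    index = pd.Index(patient_ids, name="patient_id")
    out = pd.DataFrame(0.0, index=index, columns=VECTOR_COLUMNS)

    # Simple per-category tallies.
    tally = (
        enc.groupby(["patient_id", "category"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    for category, column in _COUNT_MAP.items():
        if category in tally.columns:
            out[column] = tally[category].reindex(index, fill_value=0).astype(float)

    # Raw and medication-weighted PCP visits.
    pcp = enc[enc["category"] == "pcp_visit"]
    if not pcp.empty:
        meds = pcp["med_count"].fillna(0).to_numpy()
        weights = medication_visit_weights(meds, bands)
        per_patient = pd.DataFrame(
            {"patient_id": pcp["patient_id"].to_numpy(), "w": weights}
        ).groupby("patient_id")["w"]
        out["raw_pcp"] = per_patient.size().reindex(index, fill_value=0).astype(float)
        out["effective_pcp"] = per_patient.sum().reindex(index, fill_value=0.0)

    # Capped specialty totals: min(count, cap) summed over specialties.
    spec = enc[enc["category"] == "specialty_visit"]
    if not spec.empty:
        observed = set(spec["specialty"].dropna().unique())
        missing = observed - set(caps.cap)
        if missing:
            raise KeyError(f"no cap for observed specialties: {sorted(missing)}")
        by_spec = spec.groupby(["patient_id", "specialty"], observed=True).size()
        cap_values = by_spec.index.get_level_values("specialty").map(caps.cap)
        capped = np.minimum(by_spec.to_numpy(dtype=float), cap_values.to_numpy(dtype=float))
        totals = (
            pd.Series(capped, index=by_spec.index.get_level_values("patient_id"))
            .groupby(level=0)
            .sum()
        )
        out["specialty_capped"] = totals.reindex(index, fill_value=0.0)

    return out


def build_visit_vector(
    records: pd.DataFrame,
    window: Window,
    caps: SpecialtyCaps,
    bands: MedWeightBands | None = None,
) -> pd.Series:
    """Visit vector for a single patient's records."""
    ids = records["patient_id"].unique()
    if len(ids) > 1:
        raise ValueError("records must belong to one patient")
    pid = ids[0] if len(ids) else "patient"
    return build_visit_vectors(records, [pid], window, caps, bands).iloc[0]
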