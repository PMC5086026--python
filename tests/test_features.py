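"""Feature engineering: medication weights, specialty caps, visit vectors."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from panelweight import (
    SpecialtyCaps,
    Window,
    build_visit_vector,
    build_visit_vectors,
    capped_specialty_total,
    compute_specialty_caps,
    effective_pcp_visits,
    medication_visit_weight,
)
from panelweight.features import VECTOR_COLUMNS, medication_visit_weights

WINDOW = Window("2013-02-01", "2014-02-01")


def _records(rows):
    df = pd.DataFrame(
        rows, columns=["patient_id", "category", "date", "specialty", "med_count"]
    )
    df["msg_direction"] = ""
    return df


class TestMedicationWeight:
    @pytest.mark.parametrize(
        "med_count,expected",
        [(0, 1.0), (3, 1.0), (5, 1.0), (6, 1.5), (8, 1.5), (10, 1.5),
         (11, 1.75), (12, 1.75), (40, 1.75)],
    )
    def test_step_function(self, med_count, expected):
        assert medication_visit_weight(med_count) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            medication_visit_weight(-1)

    @given(st.integers(min_value=0, max_value=50), st.integers(min_value=0, max_value=50))
    def test_non_decreasing(self, a, b):
        lo, hi = sorted((a, b))
        assert medication_visit_weight(lo) <= medication_visit_weight(hi)

    def test_vectorised_matches_scalar(self):
        counts = np.arange(0, 30)
        vec = medication_visit_weights(counts)
        assert [medication_visit_weight(c) for c in counts] == vec.tolist()


class TestEffectivePcpVisits:
    def test_empty(self):
        assert effective_pcp_visits([]) == 0.0

    @pytest.mark.parametrize(
        "meds,expected", [([3, 12], 2.75), ([5, 5, 5], 3.0), ([6], 1.5)]
    )
    def test_weighted_sum(self, meds, expected):
        visits = [("2013-03-01", m) for m in meds]
        assert effective_pcp_visits(visits) == pytest.approx(expected)


class TestSpecialtyCaps:
    def test_zero_variance(self):
        caps = compute_specialty_caps({"derm": [1, 1, 1]})
        assert caps["derm"] == pytest.approx(1.0)

    def test_mean_plus_two_sd(self):
        caps = compute_specialty_caps({"derm": [1, 2, 3]})
        assert caps["derm"] == pytest.approx(4.0)  # mean 2 + 2 * sd 1

    def test_single_patient_gets_own_count(self):
        caps = compute_specialty_caps({"derm": [7]})
        assert caps["derm"] == pytest.approx(7.0)

    def test_zero_visit_patients_excluded(self):
        # denominator is patients *seen* by the specialty
        caps = compute_specialty_caps({"derm": [0, 0, 1, 2, 3]})
        assert caps["derm"] == pytest.approx(4.0)

    def test_no_users_rejected(self):
        with pytest.raises(ValueError):
            compute_specialty_caps({"derm": [0, 0]})


class TestCappedSpecialtyTotal:
    def test_worked_example(self):
        caps = SpecialtyCaps({"dermatology": 15.8, "cardiology": 6.7})
        total = capped_specialty_total({"dermatology": 20, "cardiology": 2}, caps)
        assert total == pytest.approx(17.8)

    def test_below_caps_is_plain_sum(self):
        caps = SpecialtyCaps({"a": 10, "b": 10})
        assert capped_specialty_total({"a": 3, "b": 4}, caps) == pytest.approx(7.0)

    def test_min_at_cap(self):
        assert capped_specialty_total(
            {"s": 10}, SpecialtyCaps({"s": 4})
        ) == pytest.approx(4.0)

    def test_missing_cap_rejected(self):
        with pytest.raises(KeyError):
            capped_specialty_total({"s": 1}, SpecialtyCaps({}))

    @given(
        st.dictionaries(
            st.sampled_from(["a", "b", "c", "d"]),
            st.integers(min_value=0, max_value=30),
            min_size=1,
        ),
        st.lists(st.floats(min_value=0.5, max_value=20), min_size=4, max_size=4),
    )
    def test_oracle_equivalence_and_contraction(self, counts, cap_values):
        caps = SpecialtyCaps(dict(zip("abcd", cap_values)))
        total = capped_specialty_total(counts, caps)
        # independent oracle: explicit per-specialty min then sum
        oracle = 0.0
        for s, n in counts.items():
            oracle += n if n <= caps[s] else caps[s]
        assert total == pytest.approx(oracle)
        raw = sum(counts.values())
        assert total <= raw + 1e-12
        if all(counts[s] <= caps[s] for s in counts):
            assert total == pytest.approx(raw)


class TestVisitVectors:
    CAPS = SpecialtyCaps({"cardiology": 6.7, "dermatology": 15.8})

    def test_no_records_zero_vector(self):
        vec = build_visit_vectors(_records([]), ["p1"], WINDOW, self.CAPS)
        assert (vec.loc["p1"] == 0).all()

    def test_direct_tally(self):
        rows = [
            ("p1", "pcp_visit", "2013-03-01", "", 3),
            ("p1", "pcp_visit", "2013-04-01", "", 12),
            ("p1", "ed_visit", "2013-05-01", "", None),
            ("p1", "telephone", "2013-05-02", "", None),
            ("p1", "telephone", "2013-05-03", "", None),
            ("p1", "telephone", "2013-05-04", "", None),
        ]
        vec = build_visit_vector(_records(rows), WINDOW, self.CAPS)
        assert vec["effective_pcp"] == pytest.approx(2.75)
        assert vec["raw_pcp"] == 2
        assert vec["ed"] == 1
        assert vec["telephone"] == 3

    def test_short_exposure_not_annualised(self):
        # a patient active only 3 months keeps raw counts (2 visits, not 8)
        rows = [
            ("p1", "pcp_visit", "2013-02-10", "", 1),
            ("p1", "pcp_visit", "2013-03-10", "", 1),
        ]
        vec = build_visit_vector(_records(rows), WINDOW, self.CAPS)
        assert vec["raw_pcp"] == 2

    def test_records_outside_window_ignored(self):
        rows = [
            ("p1", "pcp_visit", "2012-12-01", "", 1),
            ("p1", "pcp_visit", "2014-02-01", "", 1),  # end is exclusive
            ("p1", "pcp_visit", "2013-02-01", "", 1),  # start is inclusive
        ]
        vec = build_visit_vector(_records(rows), WINDOW, self.CAPS)
        assert vec["raw_pcp"] == 1

    def test_specialty_capping_in_vector(self):
        rows = [("p1", "specialty_visit", "2013-03-01", "cardiology", None)] * 10
        vec = build_visit_vector(_records(rows), WINDOW, self.CAPS)
        assert vec["specialty_capped"] == pytest.approx(6.7)

    def test_order_invariance(self):
        rows = [
            ("p1", "pcp_visit", "2013-03-01", "", 3),
            ("p1", "specialty_visit", "2013-04-01", "dermatology", None),
            ("p1", "no_show", "2013-05-01", "", None),
            ("p1", "message_from_patient", "2013-06-01", "", None),
        ]
        fwd = build_visit_vector(_records(rows), WINDOW, self.CAPS)
        rev = build_visit_vector(_records(rows[::-1]), WINDOW, self.CAPS)
        pd.testing.assert_series_equal(fwd, rev)

    def test_effective_at_least_raw_and_non_negative(self, small_pop, config):
        from panelweight.features import (
            compute_specialty_caps,
            specialty_patient_counts,
        )

        caps = compute_specialty_caps(
            specialty_patient_counts(small_pop.encounters, config.year1)
        )
        vec = build_visit_vectors(
            small_pop.encounters, small_pop.patients["patient_id"],
            config.year1, caps,
        )
        assert (vec[VECTOR_COLUMNS] >= 0).all().all()
        assert (vec["effective_pcp"] >= vec["raw_pcp"]).all()
        # capping is a contraction on the raw specialty count
        raw_spec = (
            small_pop.encounters.query("category == 'specialty_visit'")
            .groupby("patient_id").size()
            .reindex(vec.index, fill_value=0)
        )
        assert (vec["specialty_capped"] <= raw_spec + 1e-9).all()
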