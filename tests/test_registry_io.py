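"""Cohort screening: filters, exclusion bookkeeping, cross-registration dedup."""

import dataclasses

import pytest
from hypothesis import given
from hypothesis import strategies as st

from trialaudit.partialdates import PartialDate
from trialaudit.registry_io import (
    CTGOV,
    DRKS,
    REASON_COMPLETION,
    REASON_STATUS,
    REASON_TYPE,
    CohortCriteria,
    EuctrTrackerRow,
    TrialRecord,
    apply_cohort_filters,
    deduplicate_cross_registrations,
    normalize_trn,
    read_euctr_tracker_history,
    select_sponsor_for_umc,
)


def make_trial(trn="NCT00000001", registry=CTGOV, completion_year=2015, status="Completed",
               study_type="interventional", secondary_ids=(), **kwargs):
    return TrialRecord(
        trn=trn,
        registry=registry,
        lead_umcs=["UMC X"],
        completion_date=PartialDate(completion_year, 6),
        status=status,
        study_type=study_type,
        secondary_ids=list(secondary_ids),
        **kwargs,
    )


class TestCohortFilters:
    def test_fixed_order_and_counts(self):
        trials = (
            [make_trial(trn=f"NCT0000000{i}") for i in range(1, 8)]
            + [make_trial(trn="NCT00000008", completion_year=2008),
               make_trial(trn="NCT00000009", completion_year=2008)]
            + [make_trial(trn="NCT00000010", study_type="observational")]
        )
        included, tally = apply_cohort_filters(trials, CohortCriteria())
        assert len(included) == 7
        assert tally.excluded_by_reason == {
            REASON_COMPLETION: 2, REASON_STATUS: 0, REASON_TYPE: 0 + 1,
        }

    def test_first_reason_wins(self):
        # outside the window AND observational: counted under completion only
        trial = make_trial(completion_year=2008, study_type="observational")
        _, tally = apply_cohort_filters([trial], CohortCriteria())
        assert tally.excluded_by_reason[REASON_COMPLETION] == 1
        assert tally.excluded_by_reason[REASON_TYPE] == 0

    def test_missing_completion_excluded_under_completion_reason(self):
        trial = make_trial()
        trial.completion_date = None
        included, tally = apply_cohort_filters([trial], CohortCriteria())
        assert included == []
        assert tally.excluded_by_reason[REASON_COMPLETION] == 1

    def test_status_filter_uses_complete_statuses(self):
        trial = make_trial(status="Recruiting")
        _, tally = apply_cohort_filters([trial], CohortCriteria())
        assert tally.excluded_by_reason[REASON_STATUS] == 1
        crit = CohortCriteria(complete_statuses=frozenset({"Recruiting"}))
        included, _ = apply_cohort_filters([trial], crit)
        assert len(included) == 1

    def test_empty_input_gives_zero_tally(self):
        included, tally = apply_cohort_filters([], CohortCriteria())
        assert included == [] and tally.input_count == 0
        tally.check()

    def test_idempotence(self):
        trials = [make_trial(trn=f"NCT{i:08d}", completion_year=2005 + i % 15) for i in range(30)]
        included, _ = apply_cohort_filters(trials, CohortCriteria())
        again, tally2 = apply_cohort_filters(included, CohortCriteria())
        assert again == included
        assert sum(tally2.excluded_by_reason.values()) == 0

    @given(
        st.lists(
            st.tuples(
                st.integers(2005, 2020),  # completion year
                st.sampled_from(["Completed", "Recruiting", "Terminated"]),
                st.sampled_from(["interventional", "observational"]),
            ),
            max_size=40,
        )
    )
    def test_tally_conservation(self, rows):
        trials = [
            make_trial(trn=f"NCT{i:08d}", completion_year=y, status=s, study_type=t)
            for i, (y, s, t) in enumerate(rows)
        ]
        _, tally = apply_cohort_filters(trials, CohortCriteria())
        tally.check()  # input = included + duplicates + sum(exclusions)


class TestDedup:
    def test_pair_detected_from_ctgov_side(self):
        ct = make_trial(secondary_ids=["DRKS00004871"])
        dk = make_trial(trn="DRKS00004871", registry=DRKS)
        retained, removed, pairs = deduplicate_cross_registrations([ct, dk])
        assert removed == 1 and len(retained) == 1
        assert retained[0].registry == CTGOV
        assert pairs == [("NCT00000001", "DRKS00004871")]
        assert retained[0].cross_registered_trns == ["DRKS00004871"]

    def test_symmetry_reference_on_either_side(self):
        ct = make_trial()
        dk = make_trial(trn="DRKS00004871", registry=DRKS, secondary_ids=["NCT00000001"])
        retained, removed, _ = deduplicate_cross_registrations([ct, dk])
        ct2 = make_trial(secondary_ids=["DRKS00004871"])
        dk2 = make_trial(trn="DRKS00004871", registry=DRKS)
        retained2, removed2, _ = deduplicate_cross_registrations([ct2, dk2])
        assert removed == removed2 == 1
        assert [t.trn for t in retained] == [t.trn for t in retained2]

    def test_trn_normalization_in_matching(self):
        ct = make_trial(secondary_ids=["drks 0000-4871"])
        dk = make_trial(trn="DRKS00004871", registry=DRKS)
        _, removed, _ = deduplicate_cross_registrations([ct, dk])
        assert removed == 1
        assert normalize_trn("drks 0000-4871") == "DRKS00004871"

    def test_unrelated_trials_untouched(self):
        a, b = make_trial(), make_trial(trn="NCT00000002")
        retained, removed, pairs = deduplicate_cross_registrations([a, b])
        assert len(retained) == 2 and removed == 0 and pairs == []

    def test_references_merged_onto_retained_member(self):
        from trialaudit.registry_io import RegistryReference

        ct = make_trial(secondary_ids=["DRKS00004871"],
                        references=[RegistryReference(title="A")])
        dk = make_trial(trn="DRKS00004871", registry=DRKS,
                        references=[RegistryReference(title="B", pmid="123")])
        retained, _, _ = deduplicate_cross_registrations([ct, dk])
        titles = {r.title for r in retained[0].references}
        assert titles == {"A", "B"}

    def test_three_way_chain_collapses_to_one(self):
        a = make_trial(secondary_ids=["DRKS00004871"])
        b = make_trial(trn="DRKS00004871", registry=DRKS, secondary_ids=["DRKS00004872"])
        c = make_trial(trn="DRKS00004872", registry=DRKS)
        retained, removed, _ = deduplicate_cross_registrations([a, b, c])
        assert len(retained) == 1 and removed == 2
        assert retained[0].registry == CTGOV


class TestTracker:
    def test_percent_recomputed_and_sorted(self):
        rows = [
            {"sponsor": "A", "date": "2022-10-01", "total_due": 813, "total_reported": 647},
            {"sponsor": "A", "date": "2020-12-01", "total_due": 541, "total_reported": 223},
        ]
        out = read_euctr_tracker_history(rows)
        assert [r.snapshot_date.year for r in out] == [2020, 2022]
        assert out[0].percent_reported == pytest.approx(41.2, abs=0.05)
        assert out[1].percent_reported == pytest.approx(79.6, abs=0.05)

    def test_reported_exceeding_due_is_an_error(self):
        with pytest.raises(ValueError, match="B"):
            read_euctr_tracker_history(
                [{"sponsor": "B", "date": "2020-12-01", "total_due": 10, "total_reported": 12}]
            )


class TestSponsorSelection:
    def test_most_trials_wins(self):
        assert select_sponsor_for_umc([("X", 14), ("Y", 3)]) == "X"
        assert select_sponsor_for_umc([("X", 5)]) == "X"

    def test_tie_breaks_lexicographically(self):
        assert select_sponsor_for_umc([("B", 4), ("A", 4)]) == "A"

    def test_empty_candidates_error(self):
        with pytest.raises(ValueError):
            select_sponsor_for_umc([])


def test_trn_shape_validated_per_registry():
    with pytest.raises(ValueError):
        make_trial(trn="NCT123")  # 7-digit body rejected
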