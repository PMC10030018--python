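"""Per-trial transparency outcomes and their denominator rules."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from trialaudit.metrics import (
    DEFAULT_CONTEXT,
    FollowupContext,
    HostType,
    OAEvidence,
    OARecord,
    OAStatus,
    assess_trial,
    classify_oa_status,
    has_summary_results,
    is_eligible_for_followup,
    is_prospectively_registered,
    oa_metric_sample,
    reported_within,
    route_report_date,
)
from trialaudit.partialdates import PartialDate
from trialaudit.registry_io import RegistryReference, TrialRecord
from trialaudit.trn_linkage import Publication, assess_links


def make_trial(completion=PartialDate(2015, 6), registry="ctgov", **kwargs):
    trn = kwargs.pop("trn", "NCT00000001" if registry == "ctgov" else "DRKS00000001")
    return TrialRecord(
        trn=trn, registry=registry, lead_umcs=["UMC X"],
        completion_date=completion, status="Completed", **kwargs,
    )


class TestProspective:
    @pytest.mark.parametrize(
        "reg, start, expected",
        [
            (PartialDate(2015, 3), PartialDate(2015, 3), True),   # same month
            (PartialDate(2015, 2), PartialDate(2015, 3), True),   # previous month
            (PartialDate(2015, 4), PartialDate(2015, 3), False),  # after start
            (PartialDate(2015, 3, 31), PartialDate(2015, 3, 1), True),  # days ignored
            (None, PartialDate(2015, 3), None),
            (PartialDate(2015, 3), None, None),                   # no start date
            (PartialDate(2015), PartialDate(2015, 3), None),      # year-only registration
        ],
    )
    def test_month_level_rule(self, reg, start, expected):
        trial = make_trial(registration_date=reg, start_date=start)
        assert is_prospectively_registered(trial) is expected


class TestSummaryResults:
    def test_ctgov_uses_structured_field(self):
        assert has_summary_results(make_trial(has_structured_summary_results=True)) is True
        assert has_summary_results(make_trial()) is False

    @pytest.mark.parametrize(
        "title, expected",
        [
            ("Ergebnisbericht (PDF)", True),
            ("ABSCHLUSSBERICHT final", True),
            ("Studienprotokoll", False),
        ],
    )
    def test_drks_keyword_rule(self, title, expected):
        trial = make_trial(
            registry="drks", references=[RegistryReference(title=title)]
        )
        assert has_summary_results(trial) is expected

    def test_drks_custom_keywords(self):
        trial = make_trial(registry="drks", references=[RegistryReference(title="Final report")])
        assert has_summary_results(trial) is False
        assert has_summary_results(trial, keywords=("final report",)) is True


class TestRouteReportDate:
    def test_either_takes_the_earlier_date(self):
        trial = make_trial(
            has_structured_summary_results=True,
            summary_results_date=PartialDate(2018, 1, 5),
        )
        pub = Publication(pub_id="p", publication_date=PartialDate(2017, 6, 1))
        assert route_report_date(trial, pub, "either") == PartialDate(2017, 6, 1)

    def test_no_publication_is_absent(self):
        assert route_report_date(make_trial(), None, "publication") is None

    def test_dissertation_does_not_count_as_publication(self):
        pub = Publication(pub_id="p", publication_date=PartialDate(2016, 1, 1), is_dissertation=True)
        assert route_report_date(make_trial(), pub, "publication") is None
        assert route_report_date(make_trial(), pub, "either") is None

    def test_unknown_route_rejected(self):
        with pytest.raises(ValueError):
            route_report_date(make_trial(), None, "carrier-pigeon")


class TestFollowupEligibility:
    def test_five_year_window_just_missed(self):
        # completion 2017-12 + 5y = 2022-12 is past the 2022-11-01 download
        trial = make_trial(completion=PartialDate(2017, 12))
        assert is_eligible_for_followup(trial, "summary", 5, DEFAULT_CONTEXT) is False

    def test_five_year_window_closed(self):
        trial = make_trial(completion=PartialDate(2015, 6))
        assert is_eligible_for_followup(trial, "summary", 5, DEFAULT_CONTEXT) is True

    def test_either_route_needs_both_windows(self):
        ctx = FollowupContext(
            registry_download_date=PartialDate(2022, 11, 1),
            publication_search_date=PartialDate(2019, 1, 1),  # early search
        )
        trial = make_trial(completion=PartialDate(2015, 6))
        assert is_eligible_for_followup(trial, "summary", 5, ctx) is True
        assert is_eligible_for_followup(trial, "publication", 5, ctx) is False
        assert is_eligible_for_followup(trial, "either", 5, ctx) is False


class TestReportedWithin:
    def test_within_two_years(self):
        trial = make_trial(completion=PartialDate(2015, 6))
        pub = Publication(pub_id="p", publication_date=PartialDate(2017, 5, 1))
        assert reported_within(trial, "publication", 2, pub, DEFAULT_CONTEXT) is True

    def test_just_past_two_years(self):
        trial = make_trial(completion=PartialDate(2015, 6))
        pub = Publication(pub_id="p", publication_date=PartialDate(2017, 7, 1))
        assert reported_within(trial, "publication", 2, pub, DEFAULT_CONTEXT) is False

    def test_ineligible_trial_is_absent(self):
        trial = make_trial(completion=PartialDate(2017, 12))
        assert reported_within(trial, "summary", 5, None, DEFAULT_CONTEXT) is None

    @given(
        completion_year=st.integers(2009, 2017),
        completion_month=st.integers(1, 12),
        delay=st.integers(0, 90),
        has_pub=st.booleans(),
    )
    def test_five_year_rate_dominates_two_year(self, completion_year, completion_month, delay, has_pub):
        """Reporting within 2 years implies reporting within 5 (when defined)."""
        trial = make_trial(completion=PartialDate(completion_year, completion_month))
        pub = None
        if has_pub:
            y, m = divmod((completion_year * 12 + completion_month - 1) + delay, 12)
            pub = Publication(pub_id="p", publication_date=PartialDate(y, m + 1, 15))
        two = reported_within(trial, "publication", 2, pub, DEFAULT_CONTEXT)
        five = reported_within(trial, "publication", 5, pub, DEFAULT_CONTEXT)
        if two is True and five is not None:
            assert five is True
        if five is False and two is not None:
            assert two is False

    def test_either_dominates_single_routes(self):
        trial = make_trial(
            completion=PartialDate(2015, 6),
            has_structured_summary_results=True,
            summary_results_date=PartialDate(2016, 1, 10),
        )
        assert reported_within(trial, "summary", 2, None, DEFAULT_CONTEXT) is True
        assert reported_within(trial, "either", 2, None, DEFAULT_CONTEXT) is True


class TestOAClassification:
    GOLD = OAEvidence(HostType.PUBLISHER, journal_is_oa=True)
    HYBRID = OAEvidence(HostType.PUBLISHER, license_open=True)
    GREEN = OAEvidence(HostType.REPOSITORY)
    BRONZE = OAEvidence(HostType.PUBLISHER)

    def test_hierarchy_examples(self):
        assert classify_oa_status([self.GREEN, self.HYBRID]) is OAStatus.HYBRID
        assert classify_oa_status([self.BRONZE, self.GOLD]) is OAStatus.GOLD
        assert classify_oa_status([self.GREEN]) is OAStatus.GREEN
        assert classify_oa_status([self.BRONZE]) is OAStatus.BRONZE
        assert classify_oa_status([]) is OAStatus.CLOSED

    def test_permutation_invariance_exhaustive(self):
        evidence = [self.GOLD, self.HYBRID, self.GREEN, self.BRONZE]
        for r in range(len(evidence) + 1):
            for combo in itertools.combinations(evidence, r):
                results = {classify_oa_status(p) for p in itertools.permutations(combo)}
                assert len(results) == 1

    def test_status_total_order(self):
        assert OAStatus.GOLD > OAStatus.HYBRID > OAStatus.GREEN > OAStatus.BRONZE > OAStatus.CLOSED
        assert OAStatus.GOLD.is_open and not OAStatus.CLOSED.is_open

    def test_oa_sample_requires_doi_and_dated_record(self):
        pub = Publication(pub_id="p", doi="10.1/x")
        rec = OARecord(pub_id="p", unpaywall_date=PartialDate(2022, 11, 1), evidence=[self.GREEN])
        assert oa_metric_sample(pub, rec) is OAStatus.GREEN
        assert oa_metric_sample(Publication(pub_id="p"), rec) is None  # no DOI
        undated = OARecord(pub_id="p", evidence=[self.GREEN])
        assert oa_metric_sample(pub, undated) is None
        empty = OARecord(pub_id="p", unpaywall_date=PartialDate(2022, 11, 1))
        assert oa_metric_sample(pub, empty) is OAStatus.CLOSED


class TestAssessTrial:
    def make_exemplar(self):
        trial = make_trial(
            completion=PartialDate(2015, 6, 10),
            start_date=PartialDate(2013, 4, 1),
            registration_date=PartialDate(2013, 3, 2),
            has_structured_summary_results=True,
            summary_results_date=PartialDate(2016, 2, 1),
            references=[RegistryReference(title="Results", doi="10.5555/x")],
        )
        pub = Publication(
            pub_id="p",
            doi="10.5555/x",
            pmid="123",
            publication_date=PartialDate(2016, 5, 2),
            abstract="Trial NCT00000001 results.",
            full_text="Methods cite NCT00000001.",
        )
        oa = OARecord(
            pub_id="p",
            unpaywall_date=PartialDate(2022, 11, 1),
            evidence=[OAEvidence(HostType.PUBLISHER, journal_is_oa=True)],
        )
        return trial, pub, oa

    def test_fully_reported_exemplar(self):
        trial, pub, oa = self.make_exemplar()
        a = assess_trial(trial, assess_links(trial, pub), pub, oa)
        assert a.prospective is True
        assert a.summary_results is True
        assert a.trn_in_abstract is True and a.trn_in_full_text is True and a.trn_in_both is True
        assert a.publication_link_in_registry is True
        assert all(a.timely[(route, years)] is True for route in ("summary", "publication", "either") for years in (2, 5))
        assert a.oa is OAStatus.GOLD

    def test_trial_without_publication(self):
        trial, _, _ = self.make_exemplar()
        a = assess_trial(trial, assess_links(trial, None), None, None)
        assert a.trn_in_abstract is None and a.publication_link_in_registry is None
        assert a.oa is None
        assert a.timely[("publication", 2)] is False  # eligible but unreported

    def test_mismatched_keys_rejected(self):
        trial, pub, oa = self.make_exemplar()
        other = make_trial(trn="NCT09999999", completion=PartialDate(2015, 6))
        with pytest.raises(ValueError):
            assess_trial(trial, assess_links(other, pub), pub, oa)

    def test_denominators_fail_one_condition_at_a_time(self):
        trial, pub, oa = self.make_exemplar()
        # no PMID: abstract metric leaves the denominator, full text stays
        pub_no_pmid = Publication(**{**pub.__dict__, "pmid": None})
        a = assess_trial(trial, assess_links(trial, pub_no_pmid), pub_no_pmid, oa)
        assert a.trn_in_abstract is None and a.trn_in_full_text is True
        # dissertation: all publication-based metrics leave their denominators
        diss = Publication(**{**pub.__dict__, "is_dissertation": True})
        a = assess_trial(trial, assess_links(trial, diss), diss, oa)
        assert a.trn_in_abstract is None and a.publication_link_in_registry is None
        assert a.oa is None
        # start date removed: prospective leaves the denominator
        trial.start_date = None
        a = assess_trial(trial, assess_links(trial, pub), pub, oa)
        assert a.prospective is None
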