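"""Registration timing, publication lag, deposition, termination, vaccine subset."""

from datetime import date, timedelta

import pytest

from trialpubs.classify import (
    DepositionCategory,
    RegistrationTiming,
    TerminationCategory,
    deposition_category,
    days_to_publication,
    published_before_completion,
    registration_timing,
    termination_category,
    vaccine_subset,
)
from trialpubs.linking import LinkTable
from trialpubs.model import LinkRecord, OverallStatus
from .conftest import make_article, make_trial


class TestRegistrationTiming:
    def test_prior(self):
        t = make_trial(registration_date=date(2020, 1, 10), start_date=date(2020, 2, 1))
        assert registration_timing(t) == RegistrationTiming.PRIOR

    def test_after(self):
        t = make_trial(
            registration_date=date(2021, 6, 1),
            start_date=date(2020, 2, 1),
            primary_completion_date=date(2021, 2, 1),
        )
        assert registration_timing(t) == RegistrationTiming.AFTER

    def test_boundary_grid(self):
        # exhaustive grid around both boundaries: ties resolve to the
        # earlier class (start date -> prior, completion date -> during)
        start, pcd = date(2020, 2, 1), date(2021, 2, 1)
        for offset in range(-2, 3):
            t = make_trial(
                registration_date=start + timedelta(days=offset),
                start_date=start,
                primary_completion_date=pcd,
            )
            expected = RegistrationTiming.PRIOR if offset <= 0 else RegistrationTiming.DURING
            assert registration_timing(t) == expected
        for offset in range(-2, 3):
            t = make_trial(
                registration_date=pcd + timedelta(days=offset),
                start_date=start,
                primary_completion_date=pcd,
            )
            expected = RegistrationTiming.DURING if offset <= 0 else RegistrationTiming.AFTER
            assert registration_timing(t) == expected

    def test_missing_completion_date_rules(self):
        ongoing = make_trial(
            registration_date=date(2020, 3, 1),
            start_date=date(2020, 2, 1),
            primary_completion_date=None,
            overall_status=OverallStatus.RECRUITING,
        )
        assert registration_timing(ongoing) == RegistrationTiming.DURING
        ended = make_trial(
            registration_date=date(2020, 3, 1),
            start_date=date(2020, 2, 1),
            primary_completion_date=None,
            overall_status=OverallStatus.COMPLETED,
        )
        assert registration_timing(ended) == RegistrationTiming.INDETERMINATE

    def test_missing_start_indeterminate(self):
        t = make_trial(start_date=None)
        assert registration_timing(t) == RegistrationTiming.INDETERMINATE

    def test_partition_on_complete_dates(self, synth_corpus):
        corpus, truth = synth_corpus
        classes = {
            nct: registration_timing(t)
            for nct, t in ((t.nct_id, t) for t in corpus.trials)
            if t.registration_date and t.start_date and t.primary_completion_date
        }
        assert all(
            c in (RegistrationTiming.PRIOR, RegistrationTiming.DURING, RegistrationTiming.AFTER)
            for c in classes.values()
        )
        for nct, expected in truth.timing_by_trial.items():
            assert classes[nct] == expected


class TestDaysToPublication:
    def test_214_day_example(self):
        t = make_trial(start_date=date(2020, 3, 1))
        a = make_article(publication_date=date(2020, 10, 1))
        assert days_to_publication(t, a) == 214

    def test_negative_when_published_before_start(self):
        t = make_trial(start_date=date(2020, 3, 1))
        a = make_article(publication_date=date(2020, 2, 1))
        assert days_to_publication(t, a) == -29

    def test_missing_date_returns_none(self):
        assert days_to_publication(make_trial(start_date=None), make_article()) is None

    def test_mean_lag_recovery(self, synth_corpus):
        # generator plants lags with mean 214 days; the computed mean must
        # land within 3 standard errors
        import statistics

        corpus, truth = synth_corpus
        trials = corpus.trial_lookup()
        articles = corpus.article_lookup()
        lags = [
            days_to_publication(trials[nct], articles[pmid])
            for (nct, pmid) in truth.lag_days
        ]
        assert lags == [truth.lag_days[k] for k in truth.lag_days]
        mean = statistics.fmean(lags)
        se = statistics.stdev(lags) / len(lags) ** 0.5
        assert abs(mean - 214) <= 3 * se + 1  # +1 for the >=7-day truncation


class TestPublishedBeforeCompletion:
    def test_ongoing_trial_with_result_article(self):
        t = make_trial(
            overall_status=OverallStatus.RECRUITING,
            primary_completion_date=date(2022, 10, 27),
        )
        a = make_article(publication_date=date(2020, 12, 30))
        assert published_before_completion(t, a) is True

    def test_completed_trial_article_after_completion(self):
        t = make_trial(
            overall_status=OverallStatus.COMPLETED,
            primary_completion_date=date(2020, 12, 1),
        )
        a = make_article(publication_date=date(2021, 6, 1))
        assert published_before_completion(t, a) is False

    def test_tallies_match_recount(self, synth_corpus):
        corpus, _ = synth_corpus
        from trialpubs.pipeline import run

        result = run(corpus)
        trials = {t.nct_id: t for t in result.trials_in_scope}
        articles = corpus.article_lookup()
        got = sum(
            published_before_completion(trials[l.nct_id], articles[l.pmid])
            for l in result.link_table.links
        )
        brute = 0  # independent restatement of the rule
        for l in result.link_table.links:
            t, a = trials[l.nct_id], articles[l.pmid]
            if t.overall_status.value not in ("completed", "terminated"):
                brute += 1
            elif (
                t.primary_completion_date is not None
                and a.publication_date is not None
                and a.publication_date < t.primary_completion_date
            ):
                brute += 1
        assert got == brute
        assert got > 0  # the corpus plants ongoing trials with articles


class TestDeposition:
    def table(self, *pairs):
        return LinkTable(
            links=[LinkRecord(n, p, frozenset({"abstract"})) for n, p in pairs]
        )

    def test_quadrants(self):
        dep = make_trial("NCT04000001", has_deposited_results=True)
        nodep = make_trial("NCT04000002", has_deposited_results=False)
        linked = self.table(("NCT04000001", "1"), ("NCT04000002", "2"))
        empty = self.table()
        assert deposition_category(dep, empty) == DepositionCategory.DEPOSIT_ONLY
        assert deposition_category(dep, linked) == DepositionCategory.BOTH
        assert deposition_category(nodep, linked) == DepositionCategory.ARTICLE_ONLY
        assert deposition_category(nodep, empty) == DepositionCategory.NEITHER

    def test_category_recount_on_fixture(self):
        # 5 deposit_only / 3 both / 2 article_only / 4 neither by construction
        trials, links = [], []
        idx = 0
        for n, deposited, linked in [(5, True, False), (3, True, True), (2, False, True), (4, False, False)]:
            for _ in range(n):
                idx += 1
                nct = f"NCT0400{idx:04d}"
                trials.append(make_trial(nct, has_deposited_results=deposited))
                if linked:
                    links.append((nct, str(idx)))
        table = self.table(*links)
        counts = {}
        for t in trials:
            c = deposition_category(t, table)
            counts[c] = counts.get(c, 0) + 1
        assert counts == {
            DepositionCategory.DEPOSIT_ONLY: 5,
            DepositionCategory.BOTH: 3,
            DepositionCategory.ARTICLE_ONLY: 2,
            DepositionCategory.NEITHER: 4,
        }


class TestTermination:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("Unable to recruit participants due to declining cases", TerminationCategory.RECRUITMENT),
            ("Stopped for intervention safety concerns", TerminationCategory.SAFETY),
            ("Interim analysis showed futility", TerminationCategory.FUTILITY),
            ("Results from other trials made it unnecessary", TerminationCategory.EXTERNAL_RESULTS),
            ("Sponsor business decision", TerminationCategory.OTHER),
            ("", TerminationCategory.UNSPECIFIED),
            (None, TerminationCategory.UNSPECIFIED),
        ],
    )
    def test_stem_rules(self, text, expected):
        assert termination_category(text) == expected

    def test_rule_order_on_multi_stem_strings(self):
        # strings matching two stems resolve to the first rule in order
        assert termination_category("safety concerns halted enrollment") == TerminationCategory.RECRUITMENT
        assert termination_category("futility and adverse events") == TerminationCategory.SAFETY
        assert termination_category("futility; external results available") == TerminationCategory.FUTILITY

    def test_total_over_arbitrary_text(self):
        for text in ["\x00\x01", "ümläut", "1234", " " * 10]:
            assert termination_category(text) in TerminationCategory


class TestVaccineSubset:
    def test_title_match(self):
        t = make_trial(brief_title="Safety of BNT162b2 Vaccine Candidates")
        assert vaccine_subset([t]) == [t]

    def test_intervention_mention_does_not_qualify(self):
        t = make_trial(
            brief_title="A Prevention Study",
            official_title="A Prevention Study in Adults",
            intervention_names=["mRNA vaccine"],
        )
        assert vaccine_subset([t]) == []

    def test_matches_brute_force_scan(self, synth_corpus):
        corpus, truth = synth_corpus
        from trialpubs.pipeline import run

        result = run(corpus)
        brute = [
            t
            for t in result.trials_in_scope
            if "vaccine" in t.brief_title.lower()
            or "vaccine" in (t.official_title or "").lower()
        ]
        assert vaccine_subset(result.trials_in_scope) == brute
        assert {t.nct_id for t in result.vaccine_trials} == truth.vaccine_ncts
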