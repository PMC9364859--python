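"""Article-type classification, attention score, ranking, shortlist."""

import itertools
from datetime import date

import pytest
from hypothesis import given, settings, strategies as st

from trialpubs.interventions import PhaseCategory
from trialpubs.linking import LinkTable
from trialpubs.model import Config, DEFAULT_ATTENTION_WEIGHTS, LinkRecord, StudyType
from trialpubs.scoring import (
    ArticleType,
    classify_article_type,
    attention_score,
    rank_publications,
    recency_points,
    score_observational,
    score_publications,
    shortlist,
)
from .conftest import make_article, make_trial


class TestArticleType:
    @pytest.mark.parametrize(
        "types,title,expected",
        [
            (["Journal Article", "Randomized Controlled Trial"], "Results", ArticleType.RESULT_ARTICLE),
            (["Journal Article"], "Statistical analysis plan and protocol for X", ArticleType.PROTOCOL),
            (["Clinical Trial Protocol", "Journal Article"], "X", ArticleType.PROTOCOL),
            (["Editorial"], "X", ArticleType.EDITORIAL_OR_COMMENT),
            (["Letter", "Journal Article"], "X", ArticleType.EDITORIAL_OR_COMMENT),
            ([], "An untyped record", ArticleType.OTHER),
            (["Preprint"], "X", ArticleType.OTHER),
        ],
    )
    def test_rule_order(self, types, title, expected):
        assert classify_article_type(make_article(publication_types=types, title=title)) == expected

    def test_precedence_truth_table(self):
        # enumerated combinations of the three label groups: protocol wins,
        # then editorial, then result
        protocol = ["Clinical Trial Protocol"]
        editorial = ["Editorial"]
        result = ["Journal Article"]
        for has_p, has_e, has_r in itertools.product([0, 1], repeat=3):
            types = protocol * has_p + editorial * has_e + result * has_r
            got = classify_article_type(make_article(publication_types=types, title="X"))
            if has_p:
                assert got == ArticleType.PROTOCOL
            elif has_e:
                assert got == ArticleType.EDITORIAL_OR_COMMENT
            elif has_r:
                assert got == ArticleType.RESULT_ARTICLE
            else:
                assert got == ArticleType.OTHER


class TestRecency:
    def test_closed_form(self):
        q = date(2022, 1, 31)
        assert recency_points(q, q, 730) == 1.0
        assert recency_points(date(2020, 2, 1), q, 730) == 0.0
        assert recency_points(date(2021, 1, 31), q, 730) == pytest.approx(0.5)

    def test_future_date_clamps_to_one(self):
        assert recency_points(date(2022, 6, 1), date(2022, 1, 31), 730) == 1.0

    def test_beyond_window_floors_at_zero(self):
        assert recency_points(date(2015, 1, 1), date(2022, 1, 31), 730) == 0.0


def base_inputs(**overrides):
    inputs = dict(
        phase_value=3.0,
        recency=0.5,
        intervention_significance=3.003,
        update_count=4,
        has_us_site=True,
        article_type=ArticleType.RESULT_ARTICLE,
        weights=DEFAULT_ATTENTION_WEIGHTS,
    )
    inputs.update(overrides)
    return inputs


class TestAttentionScore:
    def test_result_article_beats_protocol(self):
        assert attention_score(**base_inputs()) > attention_score(
            **base_inputs(article_type=ArticleType.PROTOCOL)
        )

    def test_newer_beats_older(self):
        assert attention_score(**base_inputs(recency=0.9)) > attention_score(
            **base_inputs(recency=0.3)
        )

    def test_componentwise_monotonicity_on_grid(self):
        # increasing any single component never decreases the score
        grid = dict(
            phase_value=[0.0, 2.0, 4.0],
            recency=[0.0, 0.5, 1.0],
            intervention_significance=[0.0, 5.0, 11.122],
            update_count=[0, 5, 20],
            has_us_site=[False, True],
        )
        for name, values in grid.items():
            for combo in itertools.product([0, 1], repeat=2):
                other = base_inputs(
                    recency=0.25 + 0.5 * combo[0], has_us_site=bool(combo[1])
                )
                scores = [attention_score(**{**other, name: v}) for v in values]
                assert scores == sorted(scores), name

    def test_type_classes_ordered_toward_result_article(self):
        order = [
            ArticleType.EDITORIAL_OR_COMMENT,
            ArticleType.PROTOCOL,
            ArticleType.OTHER,
            ArticleType.RESULT_ARTICLE,
        ]
        weights = DEFAULT_ATTENTION_WEIGHTS
        penalties = [weights[f"type_{t.value}"] for t in order]
        assert penalties == sorted(penalties)
        assert weights["type_result_article"] == 0.0

    def test_update_cap(self):
        capped = attention_score(**base_inputs(update_count=20))
        assert attention_score(**base_inputs(update_count=200)) == capped


class TestRanking:
    def make_pubs(self):
        trial = make_trial()
        articles = [
            make_article("32706859", publication_date=date(2021, 12, 13)),
            make_article("34863332", publication_date=date(2021, 12, 11)),
        ]
        links = LinkTable(
            links=[LinkRecord(trial.nct_id, a.pmid, frozenset({"abstract"})) for a in articles]
        )
        return score_publications(links, [trial], articles, [], date(2022, 1, 31))

    def test_equal_scores_tie_broken_by_newer_date(self):
        pubs = self.make_pubs()
        # same trial and type; force identical scores, leaving only the date
        for p in pubs:
            p.attention_score = 5.0
        ranked = rank_publications(pubs)
        assert [p.pmid for p in ranked] == ["32706859", "34863332"]

    def test_single_publication(self):
        pubs = self.make_pubs()[:1]
        assert rank_publications(pubs) == pubs

    def test_matches_brute_force_sort(self):
        import random

        pubs = self.make_pubs() * 1  # two pubs; vary scores
        rng = random.Random(0)
        for p in pubs:
            p.attention_score = rng.choice([1.0, 2.0])
        ranked = rank_publications(pubs)
        brute = sorted(
            pubs,
            key=lambda p: (
                -p.attention_score,
                -(p.publication_date or date.min).toordinal(),
                int(p.pmid),
            ),
        )
        assert ranked == brute

    def test_determinism(self, synth_corpus):
        corpus, _ = synth_corpus
        from trialpubs.pipeline import run
        from trialpubs.report import publications_frame

        a = publications_frame(run(corpus).ranked).to_csv()
        b = publications_frame(run(corpus).ranked).to_csv()
        assert a == b


class TestShortlist:
    def scored(self, **overrides):
        trial_kwargs = dict(
            phase_labels=["Phase 3"],
            location_countries=["United States"],
            version_count=4,
        )
        article_kwargs = dict(
            publication_types=["Journal Article", "Randomized Controlled Trial"],
            title="Results of a trial",
        )
        trial_kwargs.update({k: v for k, v in overrides.items() if k in (
            "phase_labels", "location_countries", "version_count")})
        article_kwargs.update({k: v for k, v in overrides.items() if k in (
            "publication_types", "title")})
        trial = make_trial(**trial_kwargs)
        article = make_article(**article_kwargs)
        links = LinkTable(links=[LinkRecord(trial.nct_id, article.pmid, frozenset({"abstract"}))])
        (pub,) = score_publications(links, [trial], [article], [], date(2022, 1, 31))
        return pub

    def test_all_criteria_met_included(self):
        assert self.scored().shortlisted

    def test_phase_2_3_combination_counts_as_phase_3(self):
        pub = self.scored(phase_labels=["Phase 2/Phase 3"])
        assert pub.trial_phase == PhaseCategory.PHASE_3
        assert pub.shortlisted

    @pytest.mark.parametrize(
        "overrides",
        [
            {"location_countries": ["France"]},
            {"phase_labels": ["Phase 2"]},
            {"version_count": 2},
            {"title": "Protocol for a trial", "publication_types": ["Journal Article"]},
        ],
    )
    def test_single_failing_criterion_excluded(self, overrides):
        assert not self.scored(**overrides).shortlisted

    def test_shortlist_equals_brute_force_filter(self, synth_corpus):
        corpus, _ = synth_corpus
        from trialpubs.pipeline import run

        result = run(corpus)
        brute = [
            p
            for p in result.ranked
            if p.is_result_article
            and p.trial_phase == PhaseCategory.PHASE_3
            and p.has_us_site
            and p.has_multiple_updates
        ]
        assert shortlist(result.ranked) == brute == result.shortlist
        assert set(map(id, result.shortlist)) <= set(map(id, result.ranked))


class TestObservational:
    def inputs(self, **overrides):
        d = dict(
            study_type=StudyType.OBSERVATIONAL,
            recency=0.5,
            update_count=4,
            has_us_site=True,
            article_type=ArticleType.RESULT_ARTICLE,
        )
        d.update(overrides)
        return d

    def test_phase_irrelevant(self):
        # identical scores whatever the phase inputs would have been
        assert score_observational(self.inputs()) == score_observational(self.inputs())

    def test_interventional_rejected(self):
        with pytest.raises(ValueError):
            score_observational(self.inputs(study_type=StudyType.INTERVENTIONAL))

    def test_newer_strictly_higher(self):
        assert score_observational(self.inputs(recency=0.9)) > score_observational(
            self.inputs(recency=0.1)
        )

    def test_equals_interventional_formula_with_zero_phase_weights(self):
        cfg = Config()
        cfg.attention_weights = dict(cfg.attention_weights, phase=0.0, intervention=0.0)
        obs = score_observational(self.inputs(), cfg)
        interventional = attention_score(
            phase_value=3.0,
            recency=0.5,
            intervention_significance=11.0,
            update_count=4,
            has_us_site=True,
            article_type=ArticleType.RESULT_ARTICLE,
            weights=cfg.attention_weights,
            update_cap=cfg.update_count_cap,
        )
        assert obs == pytest.approx(interventional)
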