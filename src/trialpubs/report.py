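"""Summary statistics, delimited outputs, and the human-readable report.

Percentages are rounded half-away-from-zero at a configurable number of
decimals (default 1), matching how shares are conventionally printed in
registry meta-research.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .interventions import InterventionGroup, PhaseCategory
from .linking import LinkTable, publication_tallies, trials_with_publications
from .scoring import ScoredPublication

log = logging.getLogger(__name__)

__all__ = [
    "SummaryStats",
    "percent",
    "review_time_difference",
    "write_master_list",
    "read_master_list",
    "write_intervention_table",
    "render_report",
    "compute_summary",
]


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100 * n / d, rounded half-away-from-zero to ``decimals`` places."""
    if denominator == 0:
        raise ZeroDivisionError("percent() requires a positive denominator")
    q = Decimal(1).scaleb(-decimals)
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(value.quantize(q, rounding=ROUND_HALF_UP))


def review_time_difference(
    full_count: int, short_count: int, minutes_per_abstract: float = 2.0
) -> float:
    """Review-time saved, in hours, by reading the shortlist instead.

    (full - short) x minutes per abstract / 60, rounded to 1 decimal.
    """
    if not full_count >= short_count >= 0:
        raise ValueError("need full_count >= short_count >= 0")
    hours = Decimal(full_count - short_count) * Decimal(str(minutes_per_abstract)) / Decimal(60)
    return float(hours.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class SummaryStats:
    """Named counts and shares over one analyzed corpus."""

    trials_total: int = 0
    trials_with_article: int = 0
    trials_with_article_pct: float = 0.0
    trials_multi_article: int = 0
    trials_multi_article_pct: float = 0.0
    trials_three_plus_article: int = 0
    trials_three_plus_article_pct: float = 0.0
    combinations_total: int = 0
    abstract_links: int = 0
    abstract_links_pct: float = 0.0
    registry_links: int = 0
    registry_links_pct: float = 0.0
    dual_channel: int = 0
    dual_channel_pct: float = 0.0
    distinct_articles: int = 0
    removed_misclassified: int = 0
    shortlist_size: int = 0
    review_time_saved_hours: float = 0.0
    timing_shares: dict[str, float] = field(default_factory=dict)
    vaccine_trials: int = 0
    vaccine_trials_with_article: int = 0
    vaccine_trials_with_article_pct: float = 0.0

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["timing_shares"] = dict(self.timing_shares)
        return d


def compute_summary(
    trials_total: int,
    link_table: LinkTable,
    pubs: list[ScoredPublication],
    timing_counts: Optional[dict[str, int]] = None,
    vaccine_trials: int = 0,
    vaccine_trials_with_article: int = 0,
    decimals: int = 1,
    minutes_per_abstract: float = 2.0,
) -> SummaryStats:
    per_trial = trials_with_publications(link_table)
    tallies = publication_tallies(per_trial)
    n_short = sum(1 for p in pubs if p.shortlisted)
    combos = link_table.combinations
    stats = SummaryStats(
        trials_total=trials_total,
        trials_with_article=tallies["at_least_1"],
        trials_multi_article=tallies["at_least_2"],
        trials_three_plus_article=tallies["at_least_3"],
        combinations_total=combos,
        abstract_links=link_table.channel_count("abstract"),
        registry_links=link_table.channel_count("registry"),
        dual_channel=link_table.dual_channel_pairs,
        distinct_articles=link_table.distinct_articles,
        removed_misclassified=len(link_table.removed),
        shortlist_size=n_short,
        review_time_saved_hours=review_time_difference(
            len(pubs), n_short, minutes_per_abstract
        ),
        vaccine_trials=vaccine_trials,
        vaccine_trials_with_article=vaccine_trials_with_article,
    )
    if trials_total:
        stats.trials_with_article_pct = percent(
            stats.trials_with_article, trials_total, decimals
        )
    if stats.trials_with_article:
        stats.trials_multi_article_pct = percent(
            stats.trials_multi_article, stats.trials_with_article, decimals
        )
        stats.trials_three_plus_article_pct = percent(
            stats.trials_three_plus_article, stats.trials_with_article, decimals
        )
    if combos:
        stats.abstract_links_pct = percent(stats.abstract_links, combos, decimals)
        stats.registry_links_pct = percent(stats.registry_links, combos, decimals)
        stats.dual_channel_pct = percent(stats.dual_channel, combos, decimals)
    if timing_counts:
        total = sum(timing_counts.values())
        if total:
            stats.timing_shares = {
                k: percent(v, total, decimals) for k, v in sorted(timing_counts.items())
            }
    if vaccine_trials:
        stats.vaccine_trials_with_article_pct = percent(
            vaccine_trials_with_article, vaccine_trials, decimals
        )
    return stats


_MASTER_COLUMNS = [
    "nct_id",
    "pmid",
    "article_title",
    "publication_date",
    "intervention_display",
    "trial_phase",
    "article_type",
    "has_us_site",
    "has_multiple_updates",
    "attention_score",
    "shortlisted",
    "sponsor",
    "journal",
    "trial_has_deposited_results",
    "study_type",
]


def publications_frame(pubs: Iterable[ScoredPublication]) -> pd.DataFrame:
    rows = []
    for p in pubs:
        rows.append(
            {
                "nct_id": p.nct_id,
                "pmid": p.pmid,
                "article_title": p.article_title,
                "publication_date": (
                    p.publication_date.isoformat() if p.publication_date else ""
                ),
                "intervention_display": p.intervention_display,
                "trial_phase": p.trial_phase.value,
                "article_type": p.article_type.value,
                "has_us_site": p.has_us_site,
                "has_multiple_updates": p.has_multiple_updates,
                "attention_score": round(p.attention_score, 6),
                "shortlisted": p.shortlisted,
                "sponsor": p.sponsor,
                "journal": p.journal,
                "trial_has_deposited_results": p.trial_has_deposited_results,
                "study_type": p.study_type.value,
            }
        )
    return pd.DataFrame(rows, columns=_MASTER_COLUMNS)


def write_master_list(
    pubs: Iterable[ScoredPublication], path: str | Path, delimiter: str = ","
) -> Path:
    """Write the ranked trial–publication list; one row per pair, header first.

    UTF-8 with standard quoting; re-reading reproduces the data exactly.
    """
    path = Path(path)
    try:
        publications_frame(pubs).to_csv(path, sep=delimiter, index=False, encoding="utf-8")
    except OSError as exc:
        raise IOError(f"cannot write master list to {path}: {exc}") from exc
    return path


def read_master_list(path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    return pd.read_csv(path, sep=delimiter, dtype={"pmid": str, "nct_id": str}, keep_default_na=False)


def write_intervention_table(
    groups: Iterable[InterventionGroup], path: str | Path, delimiter: str = ","
) -> Path:
    path = Path(path)
    rows = []
    for g in groups:
        row = {
            "intervention": g.canonical_name,
            "trial_count": len(g.trial_ids),
            "significance_score": g.significance_score,
            "sponsor_count": len(g.sponsor_names),
            "publication_count": g.publication_count,
        }
        for cat in PhaseCategory:
            row[f"n_{cat.value}"] = g.phase_counts.get(cat, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False, encoding="utf-8")
    return path


def render_report(
    stats: SummaryStats,
    intervention_groups: list[InterventionGroup],
    ranked: list[ScoredPublication],
    path: str | Path,
    top_n: int = 10,
) -> Path:
    """Render a deterministic Markdown report of the run.

    One line per summary field, the top interventions by significance score,
    and the top of the ranked publication list.
    """
    lines = ["# Trial publication linkage report", "", "## Summary", ""]
    for key, value in stats.to_dict().items():
        if key == "timing_shares":
            for k, v in value.items():
                lines.append(f"- registration_timing_{k}_pct: {v}")
        else:
            lines.append(f"- {key}: {value}")
    lines += ["", "## Top interventions by significance score", ""]
    lines.append("| intervention | trials | score | sponsors | publications |")
    lines.append("|---|---|---|---|---|")
    for g in intervention_groups[:top_n]:
        lines.append(
            f"| {g.canonical_name} | {len(g.trial_ids)} | {g.significance_score:.3f} "
            f"| {len(g.sponsor_names)} | {g.publication_count} |"
        )
    lines += ["", "## Top-ranked publications", ""]
    lines.append("| pmid | nct_id | date | phase | type | attention score |")
    lines.append("|---|---|---|---|---|---|")
    for p in ranked[:top_n]:
        d = p.publication_date.isoformat() if p.publication_date else ""
        lines.append(
            f"| {p.pmid} | {p.nct_id} | {d} | {p.trial_phase.value} "
            f"| {p.article_type.value} | {p.attention_score:.6f} |"
        )
    text = "\n".join(lines) + "\n"
    path = Path(path)
    path.write_text(text, encoding="utf-8")
    return path
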