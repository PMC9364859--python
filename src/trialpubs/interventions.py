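"""Intervention normalization, grouping, and the significance score.

Registry intervention fields are free text, so grouping identical
interventions requires normalization (lowercasing, punctuation stripping,
optional synonym table). Each group's *significance score* summarizes how
far, and how broadly, the intervention progressed through the trial phases:

    score = sum of phase values over phases with >= 1 trial
            + 0.001 x total trial count

with default phase values early-phase-1/phase-1 = 1, phase 2 = 2, phase 3 =
3, phase 4 = 4, and 0 for trials without an applicable phase. A combined
label such as "Phase 2/Phase 3" resolves to the higher phase. An
intervention with one successful late-phase trial thus outranks one with
many early-phase trials, while the per-trial 0.001 bonus (applied once per
trial) breaks ties toward more-studied interventions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional

from .linking import LinkTable
from .model import DEFAULT_PHASE_VALUES, TrialRecord

log = logging.getLogger(__name__)

__all__ = [
    "PhaseCategory",
    "InterventionGroup",
    "resolve_phase",
    "normalize_intervention",
    "split_interventions",
    "significance_score",
    "build_intervention_table",
]


class PhaseCategory(str, Enum):
    EARLY_PHASE_1 = "early_phase_1"
    PHASE_1 = "phase_1"
    PHASE_2 = "phase_2"
    PHASE_3 = "phase_3"
    PHASE_4 = "phase_4"
    NOT_APPLICABLE = "not_applicable"

    @property
    def rank(self) -> int:
        order = [
            PhaseCategory.NOT_APPLICABLE,
            PhaseCategory.EARLY_PHASE_1,
            PhaseCategory.PHASE_1,
            PhaseCategory.PHASE_2,
            PhaseCategory.PHASE_3,
            PhaseCategory.PHASE_4,
        ]
        return order.index(self)


_PHASE_TOKEN = {
    "early phase 1": PhaseCategory.EARLY_PHASE_1,
    "phase 1": PhaseCategory.PHASE_1,
    "phase 2": PhaseCategory.PHASE_2,
    "phase 3": PhaseCategory.PHASE_3,
    "phase 4": PhaseCategory.PHASE_4,
    "n/a": PhaseCategory.NOT_APPLICABLE,
    "not applicable": PhaseCategory.NOT_APPLICABLE,
    "": PhaseCategory.NOT_APPLICABLE,
}


def resolve_phase(label: str | None) -> PhaseCategory:
    """Map a recorded phase label to a single category.

    Combined labels ("Phase 2/Phase 3") resolve to the higher phase;
    unlabeled or N/A resolves to ``not_applicable``; unknown labels resolve
    to ``not_applicable`` with a logged warning.
    """
    if label is None:
        return PhaseCategory.NOT_APPLICABLE
    whole = label.strip().lower()
    if whole in _PHASE_TOKEN:  # "N/A" would otherwise split on its slash
        return _PHASE_TOKEN[whole]
    parts = [p.strip().lower() for p in label.split("/")]
    cats: list[PhaseCategory] = []
    for part in parts:
        cat = _PHASE_TOKEN.get(part)
        if cat is None:
            # tolerate bare numbers from combined labels like "Phase 2/3"
            m = re.fullmatch(r"(?:phase\s*)?([1-4])", part)
            if m:
                cat = _PHASE_TOKEN[f"phase {m.group(1)}"]
            elif part in ("early phase i", "phase i"):
                cat = PhaseCategory.PHASE_1
            else:
                log.warning("unknown phase label %r -> not_applicable", label)
                cat = PhaseCategory.NOT_APPLICABLE
        cats.append(cat)
    return max(cats, key=lambda c: c.rank)


def trial_phase(trial: TrialRecord) -> PhaseCategory:
    """Resolve a trial's recorded phase labels to its single highest phase."""
    if not trial.phase_labels:
        return PhaseCategory.NOT_APPLICABLE
    return max((resolve_phase(l) for l in trial.phase_labels), key=lambda c: c.rank)


_PUNCT = re.compile(r"[^\w\s]")
_WS = re.compile(r"\s+")


def normalize_intervention(
    name: str, synonyms: Optional[Mapping[str, str]] = None
) -> str:
    """Canonicalize a free-text intervention name.

    Lowercase, strip punctuation, collapse whitespace, then apply the
    optional variant -> canonical synonym table (keys matched after the same
    normalization). Idempotent.
    """
    text = _WS.sub(" ", _PUNCT.sub(" ", name.lower())).strip()
    if synonyms:
        normalized_syn = {
            _WS.sub(" ", _PUNCT.sub(" ", k.lower())).strip(): v for k, v in synonyms.items()
        }
        text = normalized_syn.get(text, text)
        text = _WS.sub(" ", _PUNCT.sub(" ", text.lower())).strip()
    return text


def split_interventions(raw: str) -> list[str]:
    """Split a multi-intervention string on '|' into nonempty parts."""
    return [p.strip() for p in raw.split("|") if p.strip()]


@dataclass
class InterventionGroup:
    """One normalized intervention with its trials and summary counts."""

    canonical_name: str
    trial_ids: set[str] = field(default_factory=set)
    phase_counts: dict[PhaseCategory, int] = field(default_factory=dict)
    sponsor_names: set[str] = field(default_factory=set)
    publication_count: int = 0
    significance_score: float = 0.0

    def validate(self) -> None:
        if sum(self.phase_counts.values()) != len(self.trial_ids):
            raise ValueError(
                f"{self.canonical_name}: phase counts {self.phase_counts} "
                f"do not sum to trial count {len(self.trial_ids)}"
            )


def significance_score(
    phase_counts: Mapping[PhaseCategory, int],
    phase_values: Optional[Mapping[str, float]] = None,
) -> float:
    """Significance of an intervention from its per-phase trial counts.

    Sum of phase values over occupied phases plus 0.001 per trial,
    rounded to 3 decimals.
    """
    values = phase_values if phase_values is not None else DEFAULT_PHASE_VALUES
    total_trials = sum(phase_counts.values())
    base = sum(
        values[cat.value] for cat, n in phase_counts.items() if n >= 1
    )
    return round(base + 0.001 * total_trials, 3)


def build_intervention_table(
    trials: Iterable[TrialRecord],
    link_table: Optional[LinkTable] = None,
    synonyms: Optional[Mapping[str, str]] = None,
    phase_values: Optional[Mapping[str, float]] = None,
    stop_list: Optional[Iterable[str]] = None,
) -> list[InterventionGroup]:
    """Group trials per canonical intervention and score each group.

    Multi-intervention strings are split on '|' before normalization. Each
    trial contributes once per distinct canonical intervention it tests, at
    its resolved (highest) phase. ``publication_count`` counts distinct
    articles linked to any trial in the group. Stop-list entries (comparator
    arms such as placebo) are dropped. Sorted by score descending, ties
    broken by trial count then name.
    """
    stop = {normalize_intervention(s) for s in (stop_list or [])}
    pubs_by_trial: dict[str, set[str]] = {}
    if link_table is not None:
        for link in link_table.links:
            pubs_by_trial.setdefault(link.nct_id, set()).add(link.pmid)

    groups: dict[str, InterventionGroup] = {}
    for trial in trials:
        names: set[str] = set()
        for raw in trial.intervention_names:
            for part in split_interventions(raw):
                canon = normalize_intervention(part, synonyms)
                if canon and canon not in stop:
                    names.add(canon)
        phase = trial_phase(trial)
        for canon in names:
            g = groups.setdefault(canon, InterventionGroup(canonical_name=canon))
            if trial.nct_id in g.trial_ids:
                continue
            g.trial_ids.add(trial.nct_id)
            g.phase_counts[phase] = g.phase_counts.get(phase, 0) + 1
            g.sponsor_names.update(s for s in trial.sponsor_names if s)

    for g in groups.values():
        pmids: set[str] = set()
        for nct in g.trial_ids:
            pmids |= pubs_by_trial.get(nct, set())
        g.publication_count = len(pmids)
        g.significance_score = significance_score(g.phase_counts, phase_values)
        g.validate()

    out = sorted(
        groups.values(),
        key=lambda g: (-g.significance_score, -len(g.trial_ids), g.canonical_name),
    )
    log.info("build_intervention_table: %d intervention groups", len(out))
    return out
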