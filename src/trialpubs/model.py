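"""Shared domain types, date semantics, and controlled vocabularies.

Everything downstream (ingest, linking, scoring, classification, reporting)
works on the types defined here. Registry exports and bibliographic records
arrive in several dialects; this module pins down one in-memory
representation with closed vocabularies and explicit ``unknown`` catch-alls
so that every later stage can be total and deterministic.
"""

from __future__ import annotations

import calendar
import dataclasses
import re
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from typing import Optional

__all__ = [
    "StudyType",
    "OverallStatus",
    "ReferenceType",
    "DatePrecision",
    "InvalidationReason",
    "RegistryReference",
    "TrialRecord",
    "ArticleRecord",
    "LinkRecord",
    "Config",
    "DateParseError",
    "parse_flexible_date",
    "validate_nct_id",
    "canonical_nct_id",
]

NCT_PATTERN = re.compile(r"^NCT\d{8}$")

_MONTH_NAMES = {name.lower(): i for i, name in enumerate(calendar.month_name) if name}
_MONTH_ABBRS = {name.lower(): i for i, name in enumerate(calendar.month_abbr) if name}


class StudyType(str, Enum):
    INTERVENTIONAL = "interventional"
    OBSERVATIONAL = "observational"
    REGISTRY = "registry"

    @classmethod
    def from_label(cls, label: str) -> "StudyType":
        text = label.strip().lower()
        if "interventional" in text:
            return cls.INTERVENTIONAL
        if "registry" in text or "patient registry" in text:
            return cls.REGISTRY
        if "observational" in text:
            return cls.OBSERVATIONAL
        return cls.INTERVENTIONAL


class OverallStatus(str, Enum):
    RECRUITING = "recruiting"
    ENROLLING_BY_INVITATION = "enrolling_by_invitation"
    ACTIVE_NOT_RECRUITING = "active_not_recruiting"
    COMPLETED = "completed"
    TERMINATED = "terminated"
    WITHDRAWN = "withdrawn"
    SUSPENDED = "suspended"
    NOT_YET_RECRUITING = "not_yet_recruiting"
    UNKNOWN = "unknown"

    @classmethod
    def from_label(cls, label: str) -> "OverallStatus":
        text = label.strip().lower().replace(",", "").replace("-", " ")
        text = re.sub(r"\s+", "_", text)
        aliases = {
            "recruiting": cls.RECRUITING,
            "enrolling_by_invitation": cls.ENROLLING_BY_INVITATION,
            "active_not_recruiting": cls.ACTIVE_NOT_RECRUITING,
            "completed": cls.COMPLETED,
            "terminated": cls.TERMINATED,
            "withdrawn": cls.WITHDRAWN,
            "suspended": cls.SUSPENDED,
            "not_yet_recruiting": cls.NOT_YET_RECRUITING,
            "unknown_status": cls.UNKNOWN,
            "unknown": cls.UNKNOWN,
        }
        return aliases.get(text, cls.UNKNOWN)

    @property
    def is_ended(self) -> bool:
        return self in (OverallStatus.COMPLETED, OverallStatus.TERMINATED)


#: Statuses treated as "recruiting, active, or ended" when selecting studies.
DEFAULT_ELIGIBLE_STATUSES = frozenset(
    {
        OverallStatus.RECRUITING,
        OverallStatus.ENROLLING_BY_INVITATION,
        OverallStatus.ACTIVE_NOT_RECRUITING,
        OverallStatus.COMPLETED,
        OverallStatus.TERMINATED,
    }
)


class ReferenceType(str, Enum):
    RESULT_REFERENCE = "result_reference"
    BACKGROUND_REFERENCE = "background_reference"
    DERIVED_REFERENCE = "derived_reference"
    UNKNOWN = "unknown"

    @classmethod
    def from_label(cls, label: str) -> "ReferenceType":
        text = label.strip().lower()
        if text in ("result_reference", "results_reference", "result"):
            return cls.RESULT_REFERENCE
        if text in ("background_reference", "reference", "background"):
            return cls.BACKGROUND_REFERENCE
        if text in ("derived_reference", "derived"):
            return cls.DERIVED_REFERENCE
        return cls.UNKNOWN


class DatePrecision(str, Enum):
    DAY = "day"
    MONTH = "month"


class InvalidationReason(str, Enum):
    NONE = "none"
    PREDATES_TRIAL_START = "predates_trial_start"
    MISSING_ARTICLE = "missing_article"


class DateParseError(ValueError):
    """Raised when a date string cannot be interpreted."""

    def __init__(self, text: str, detail: str = ""):
        self.text = text
        msg = f"unparseable date string: {text!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


def parse_flexible_date(text: str) -> tuple[date, DatePrecision]:
    """Parse a registry-style date of day or month precision.

    Accepts ISO ``YYYY-MM-DD`` and ``YYYY-MM``, plus the registry's
    ``Month YYYY`` / ``Month DD, YYYY`` prose forms. Month-precision dates
    impute day 1 — the imputation never moves the date out of its calendar
    month.

    Returns the parsed date together with a :class:`DatePrecision` flag
    recording whether the original string carried a day.
    """
    if not isinstance(text, str) or not text.strip():
        raise DateParseError(str(text), "empty")
    s = text.strip()

    m = re.fullmatch(r"(\d{4})-(\d{2})-(\d{2})", s)
    if m:
        y, mo, d = int(m.group(1)), int(m.group(2)), int(m.group(3))
        try:
            return date(y, mo, d), DatePrecision.DAY
        except ValueError as exc:
            raise DateParseError(s, str(exc)) from None
    m = re.fullmatch(r"(\d{4})-(\d{2})", s)
    if m:
        y, mo = int(m.group(1)), int(m.group(2))
        try:
            return date(y, mo, 1), DatePrecision.MONTH
        except ValueError as exc:
            raise DateParseError(s, str(exc)) from None
    # "May 2021" or "May 21, 2021"
    m = re.fullmatch(r"([A-Za-z]+)\.?\s+(?:(\d{1,2}),\s*)?(\d{4})", s)
    if m:
        name = m.group(1).lower()
        mo = _MONTH_NAMES.get(name) or _MONTH_ABBRS.get(name)
        if mo is None:
            raise DateParseError(s, f"unknown month name {m.group(1)!r}")
        y = int(m.group(3))
        if m.group(2) is None:
            return date(y, mo, 1), DatePrecision.MONTH
        try:
            return date(y, mo, int(m.group(2))), DatePrecision.DAY
        except ValueError as exc:
            raise DateParseError(s, str(exc)) from None
    raise DateParseError(s, "unrecognized format")


def validate_nct_id(text: str) -> bool:
    """True iff ``text`` is exactly "NCT" followed by eight digits."""
    return isinstance(text, str) and bool(NCT_PATTERN.match(text))


def canonical_nct_id(text: str) -> Optional[str]:
    """Uppercase and strip whitespace; return the id if then valid, else None.

    Secondary-identifier fields are free text in practice, so matching is
    done on this canonical form.
    """
    if not isinstance(text, str):
        return None
    cleaned = re.sub(r"\s+", "", text).upper()
    return cleaned if validate_nct_id(cleaned) else None


@dataclass(frozen=True)
class RegistryReference:
    """One citation embedded in a registry study record."""

    citation_text: str
    pmid: Optional[str] = None
    declared_type: ReferenceType = ReferenceType.UNKNOWN

    def to_dict(self) -> dict:
        return {
            "citation_text": self.citation_text,
            "pmid": self.pmid,
            "declared_type": self.declared_type.value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegistryReference":
        return cls(
            citation_text=d["citation_text"],
            pmid=d.get("pmid"),
            declared_type=ReferenceType(d.get("declared_type", "unknown")),
        )


def _iso(d: Optional[date]) -> Optional[str]:
    return d.isoformat() if d is not None else None


def _from_iso(s: Optional[str]) -> Optional[date]:
    return date.fromisoformat(s) if s else None


@dataclass
class TrialRecord:
    """One registered study.

    ``version_count`` is the number of registry record versions, with the
    initial registration counting as 1; ``has_deposited_results`` records
    whether basic summary results were posted directly in the registry.
    """

    nct_id: str
    brief_title: str = ""
    official_title: Optional[str] = None
    study_type: StudyType = StudyType.INTERVENTIONAL
    overall_status: OverallStatus = OverallStatus.UNKNOWN
    phase_labels: list[str] = field(default_factory=list)
    intervention_names: list[str] = field(default_factory=list)
    sponsor_names: list[str] = field(default_factory=list)  # lead first
    location_countries: list[str] = field(default_factory=list)
    start_date: Optional[date] = None
    primary_completion_date: Optional[date] = None
    registration_date: Optional[date] = None
    version_count: int = 1
    registry_references: list[RegistryReference] = field(default_factory=list)
    has_deposited_results: bool = False
    termination_reason_text: Optional[str] = None
    condition_terms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not validate_nct_id(self.nct_id):
            raise ValueError(f"invalid NCT id: {self.nct_id!r}")
        if self.version_count < 1:
            raise ValueError("version_count must be >= 1 for a registered study")
        if not isinstance(self.study_type, StudyType):
            self.study_type = StudyType(self.study_type)
        if not isinstance(self.overall_status, OverallStatus):
            self.overall_status = OverallStatus(self.overall_status)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["study_type"] = self.study_type.value
        d["overall_status"] = self.overall_status.value
        for key in ("start_date", "primary_completion_date", "registration_date"):
            d[key] = _iso(getattr(self, key))
        d["registry_references"] = [r.to_dict() for r in self.registry_references]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrialRecord":
        return cls(
            nct_id=d["nct_id"],
            brief_title=d.get("brief_title", ""),
            official_title=d.get("official_title"),
            study_type=StudyType(d.get("study_type", "interventional")),
            overall_status=OverallStatus(d.get("overall_status", "unknown")),
            phase_labels=list(d.get("phase_labels", [])),
            intervention_names=list(d.get("intervention_names", [])),
            sponsor_names=list(d.get("sponsor_names", [])),
            location_countries=list(d.get("location_countries", [])),
            start_date=_from_iso(d.get("start_date")),
            primary_completion_date=_from_iso(d.get("primary_completion_date")),
            registration_date=_from_iso(d.get("registration_date")),
            version_count=int(d.get("version_count", 1)),
            registry_references=[
                RegistryReference.from_dict(r) for r in d.get("registry_references", [])
            ],
            has_deposited_results=bool(d.get("has_deposited_results", False)),
            termination_reason_text=d.get("termination_reason_text"),
            condition_terms=list(d.get("condition_terms", [])),
        )


@dataclass
class ArticleRecord:
    """One indexed publication with its searchable metadata."""

    pmid: str
    title: str = ""
    publication_date: Optional[date] = None
    publication_types: list[str] = field(default_factory=list)
    journal_name: str = ""
    mesh_terms: list[str] = field(default_factory=list)
    secondary_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (isinstance(self.pmid, str) and self.pmid.isdigit()):
            raise ValueError(f"pmid must be a nonempty digit string, got {self.pmid!r}")

    def nct_secondary_ids(self) -> list[str]:
        """Distinct canonical NCT ids among the secondary identifiers."""
        seen: list[str] = []
        for sid in self.secondary_ids:
            nct = canonical_nct_id(sid)
            if nct is not None and nct not in seen:
                seen.append(nct)
        return seen

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["publication_date"] = _iso(self.publication_date)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArticleRecord":
        return cls(
            pmid=d["pmid"],
            title=d.get("title", ""),
            publication_date=_from_iso(d.get("publication_date")),
            publication_types=list(d.get("publication_types", [])),
            journal_name=d.get("journal_name", ""),
            mesh_terms=list(d.get("mesh_terms", [])),
            secondary_ids=list(d.get("secondary_ids", [])),
        )


@dataclass
class LinkRecord:
    """One (trial, article) association and how it was found.

    ``channels`` records every linkage channel that produced the pair:
    ``registry`` (a result-typed reference inside the study record) and/or
    ``abstract`` (the article's secondary identifier naming the trial).
    """

    nct_id: str
    pmid: str
    channels: frozenset[str]
    is_valid_result_link: bool = True
    invalidation_reason: InvalidationReason = InvalidationReason.NONE
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("channels must be nonempty")
        bad = set(self.channels) - {"registry", "abstract"}
        if bad:
            raise ValueError(f"unknown channels: {bad}")
        if not self.is_valid_result_link and self.invalidation_reason == InvalidationReason.NONE:
            raise ValueError("invalid link requires an invalidation reason")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.nct_id, self.pmid)


#: Additive attention-score weights. phase: multiplies the resolved phase
#: value (0-4); recency: multiplies the recency fraction in [0, 1];
#: intervention: multiplies the trial's best intervention significance
#: score; updates: multiplies capped update fraction in [0, 1]; us_site:
#: added when the trial has a US site; type_*: modifiers by article class
#: (result articles get 0, everything else a penalty).
DEFAULT_ATTENTION_WEIGHTS: dict[str, float] = {
    "phase": 0.5,
    "recency": 1.0,
    "intervention": 0.05,
    "updates": 0.5,
    "us_site": 0.5,
    "type_result_article": 0.0,
    "type_protocol": -1.0,
    "type_editorial_or_comment": -1.5,
    "type_other": -0.5,
}

DEFAULT_PHASE_VALUES: dict[str, float] = {
    "early_phase_1": 1.0,
    "phase_1": 1.0,
    "phase_2": 2.0,
    "phase_3": 3.0,
    "phase_4": 4.0,
    "not_applicable": 0.0,
}

DEFAULT_CONDITION_KEYWORDS = ["covid-19", "covid19", "sars-cov-2", "2019-ncov", "coronavirus disease 2019"]

#: Intervention strings excluded from display and from the per-trial
#: intervention-significance component (comparator arms, not interventions
#: under study).
DEFAULT_INTERVENTION_STOP_LIST = ["placebo", "standard of care", "control", "saline"]

DEFAULT_TERMINATION_RULES: list[tuple[str, list[str]]] = [
    ("recruitment", ["recruit", "enroll", "accrual"]),
    ("safety", ["safety", "adverse"]),
    ("futility", ["futil"]),
    ("external_results", ["other trial", "external", "results from other", "published results"]),
]


@dataclass
class Config:
    """Run configuration: every fixed analytic choice, as data.

    Defaults encode the published analysis; each can be overridden for a
    different condition, country of interest, or scoring emphasis.
    """

    condition_keywords: list[str] = field(default_factory=lambda: list(DEFAULT_CONDITION_KEYWORDS))
    eligible_statuses: frozenset[OverallStatus] = DEFAULT_ELIGIBLE_STATUSES
    attention_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ATTENTION_WEIGHTS)
    )
    phase_values: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PHASE_VALUES))
    recency_window_days: int = 730
    update_count_cap: int = 20
    multiple_updates_threshold: int = 2  # updates = version_count - 1
    vaccine_title_term: str = "vaccine"
    percent_decimals: int = 1
    per_abstract_review_minutes: float = 2.0
    us_country_name: str = "United States"
    intervention_stop_list: list[str] = field(
        default_factory=lambda: list(DEFAULT_INTERVENTION_STOP_LIST)
    )
    intervention_synonyms: dict[str, str] = field(default_factory=dict)
    misdate_strictly_before: bool = True
    registration_tie_is_prior: bool = True
    termination_rules: list[tuple[str, list[str]]] = field(
        default_factory=lambda: [(c, list(s)) for c, s in DEFAULT_TERMINATION_RULES]
    )
    intervention_aggregate: str = "max"  # or "mean"
    output_delimiter: str = ","

    def __post_init__(self) -> None:
        if self.recency_window_days <= 0:
            raise ValueError("recency_window_days must be positive")
        if self.per_abstract_review_minutes <= 0:
            raise ValueError("per_abstract_review_minutes must be positive")
        for k, v in self.attention_weights.items():
            if not (isinstance(v, (int, float)) and abs(v) < float("inf")):
                raise ValueError(f"non-finite attention weight {k}={v!r}")
        self.eligible_statuses = frozenset(
            OverallStatus(s) if not isinstance(s, OverallStatus) else s
            for s in self.eligible_statuses
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["eligible_statuses"] = sorted(s.value for s in self.eligible_statuses)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        kwargs = dict(d)
        if "eligible_statuses" in kwargs:
            kwargs["eligible_statuses"] = frozenset(
                OverallStatus(s) for s in kwargs["eligible_statuses"]
            )
        if "termination_rules" in kwargs:
            kwargs["termination_rules"] = [
                (c, list(s)) for c, s in kwargs["termination_rules"]
            ]
        return cls(**kwargs)
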