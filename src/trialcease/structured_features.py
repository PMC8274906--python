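"""Statistics features (40 columns) and drug features per trial.

The statistics block covers four sub-families — administrative, study
information, study design and eligibility — encoded as numeric columns with
documented ordinal code maps for categorical sources.  The drug block is a
one-hot vector over the top-k intervention MeSH terms plus per-class
intervention counts, both fitted on training data only.

Drug classes come from a local mapping TSV (intervention MeSH term -> ATC
level-5 or MeSH pharmacological-action class).  The packaged default,
``data/drug_class_map.synthetic.tsv``, is a synthetic snapshot: memberships
for the most frequent COVID-19 intervention classes are real, the long tail
is plausible filler; supply your own TSV for real-registry work.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .ctgov_io import TrialRecord, main_country

logger = logging.getLogger(__name__)

RESPONSIBLE_PARTY_CODES = {
    "Sponsor": 1,
    "Principal Investigator": 2,
    "Sponsor-Investigator": 3,
}

#: Ordinal phase codes preserving the staged ordering of clinical research.
PHASE_CODES = {
    "": 0.0,
    "N/A": 0.0,
    "Early Phase 1": 0.5,
    "Phase 1": 1.0,
    "Phase 1/Phase 2": 1.5,
    "Phase 2": 2.0,
    "Phase 2/Phase 3": 2.5,
    "Phase 3": 3.0,
    "Phase 4": 4.0,
}

_MASKING_LEVELS = ("none", "single", "double", "triple", "quadruple")

STAT_FEATURE_NAMES: tuple[str, ...] = (
    # administrative
    "industry_sponsor",
    "industry_collaborator",
    "has_collaborators",
    "n_collaborators",
    "n_officials",
    "responsible_party_code",
    # study information
    "expanded_access",
    "dmc",
    "fda_regulated",
    "has_phase",
    "phase_code",
    "interventional",
    "main_country_is_usa",
    # study design
    "randomized",
    "masking_code",
    "placebo_group",
    "n_groups",
    "n_countries",
    "n_sites",
    # eligibility
    "accepts_healthy_volunteers",
    "age_restricted",
    "gender_restricted",
    "min_age_years",
    "max_age_years",
    "has_eligibility_split",
    "n_inclusion_lines",
    "n_exclusion_lines",
    "n_eligibility_lines",
    "words_inclusion",
    "words_exclusion",
    "words_eligibility",
    "avg_words_inclusion_line",
    "avg_words_exclusion_line",
    "avg_words_eligibility_line",
    "digits_inclusion",
    "digits_exclusion",
    "digits_eligibility",
    "avg_digits_inclusion_line",
    "avg_digits_exclusion_line",
    "avg_digits_eligibility_line",
)

assert len(STAT_FEATURE_NAMES) == 40


# ---------------------------------------------------------------------------
# Eligibility text


@dataclass
class EligibilitySections:
    """Eligibility criteria split into inclusion/exclusion bullet lines.

    When the text has no "Inclusion Criteria"/"Exclusion Criteria" headers
    (``has_split`` false) all requirement lines land in ``combined_lines``
    and the per-section lists stay empty.
    """

    inclusion_lines: list[str] = field(default_factory=list)
    exclusion_lines: list[str] = field(default_factory=list)
    combined_lines: list[str] = field(default_factory=list)
    has_split: bool = False

    @property
    def entire_lines(self) -> list[str]:
        if self.has_split:
            return self.inclusion_lines + self.exclusion_lines
        return self.combined_lines


_INCLUSION_RE = re.compile(r"inclusion\s+criteria\s*:?", re.IGNORECASE)
_EXCLUSION_RE = re.compile(r"exclusion\s+criteria\s*:?", re.IGNORECASE)
_BULLET_RE = re.compile(r"^(?:[-*•~]+|\d+[.)])\s*")


def _bullet_lines(text: str) -> list[str]:
    lines = []
    for raw in text.splitlines():
        line = _BULLET_RE.sub("", raw.strip()).strip()
        if line:
            lines.append(line)
    return lines


def parse_eligibility(criteria_text: str) -> EligibilitySections:
    """Split eligibility text at the first inclusion/exclusion headers.

    Each non-empty line after stripping leading list markers ("-", "*",
    numbering) is one requirement.  Text without either header is treated as
    a single undifferentiated criteria block.
    """
    if not criteria_text or not criteria_text.strip():
        return EligibilitySections()
    inc_match = _INCLUSION_RE.search(criteria_text)
    exc_match = _EXCLUSION_RE.search(criteria_text)
    if inc_match is None and exc_match is None:
        return EligibilitySections(combined_lines=_bullet_lines(criteria_text))
    inclusion, exclusion = "", ""
    if inc_match and exc_match:
        if inc_match.start() <= exc_match.start():
            inclusion = criteria_text[inc_match.end() : exc_match.start()]
            exclusion = criteria_text[exc_match.end() :]
        else:
            exclusion = criteria_text[exc_match.end() : inc_match.start()]
            inclusion = criteria_text[inc_match.end() :]
    elif inc_match:
        inclusion = criteria_text[inc_match.end() :]
    else:
        exclusion = criteria_text[exc_match.end() :]
    return EligibilitySections(
        inclusion_lines=_bullet_lines(inclusion),
        exclusion_lines=_bullet_lines(exclusion),
        has_split=True,
    )


def _section_counts(lines: list[str]) -> tuple[int, int, float, int, float]:
    n = len(lines)
    words = sum(len(line.split()) for line in lines)
    digits = sum(ch.isdigit() for line in lines for ch in line)
    avg_words = words / n if n else 0.0
    avg_digits = digits / n if n else 0.0
    return n, words, avg_words, digits, avg_digits


def eligibility_counts(sections: EligibilitySections) -> dict[str, float]:
    """Line, word, digit and per-line-average counts per section.

    Words are whitespace-delimited tokens; digits are characters in [0-9];
    averages are 0 when the corresponding line count is 0.  Entire-field
    counts run over all sections combined.
    """
    out: dict[str, float] = {"has_eligibility_split": float(sections.has_split)}
    for prefix, lines in (
        ("inclusion", sections.inclusion_lines),
        ("exclusion", sections.exclusion_lines),
        ("eligibility", sections.entire_lines),
    ):
        n, words, avg_w, digits, avg_d = _section_counts(lines)
        out[f"n_{prefix}_lines"] = float(n)
        out[f"words_{prefix}"] = float(words)
        out[f"avg_words_{prefix}_line"] = avg_w
        out[f"digits_{prefix}"] = float(digits)
        out[f"avg_digits_{prefix}_line"] = avg_d
    return out


# ---------------------------------------------------------------------------
# Statistics features

_AGE_RE = re.compile(r"(\d+(?:\.\d+)?)\s*(year|month|week|day|hour|minute)s?", re.IGNORECASE)
_AGE_UNIT_YEARS = {
    "year": 1.0,
    "month": 1 / 12,
    "week": 7 / 365.25,
    "day": 1 / 365.25,
    "hour": 1 / (365.25 * 24),
    "minute": 1 / (365.25 * 24 * 60),
}


def parse_age_years(age_text: str) -> float | None:
    """Parse a registry age string ("18 Years", "6 Months") to years."""
    match = _AGE_RE.search(age_text or "")
    if not match:
        return None
    return float(match.group(1)) * _AGE_UNIT_YEARS[match.group(2).lower()]


def masking_code(masking: str) -> int:
    """Ordinal masking level: none=0 ... quadruple=4; unknown strings -> 0."""
    lowered = (masking or "").strip().lower()
    for code, level in enumerate(_MASKING_LEVELS):
        if lowered.startswith(level):
            return code
    return 0


def _is_placebo_arm(label: str, arm_type: str) -> bool:
    return arm_type.strip().lower() == "placebo comparator" or "placebo" in label.lower()


def extract_statistics_features(record: TrialRecord) -> dict[str, float]:
    """The 40-column statistics feature vector for one trial.

    Total function: categorical fields use the documented code maps
    (unknown -> 0), missing numeric sources become 0 with a debug-level
    missingness log entry.
    """
    missing: list[str] = []

    phase_code = PHASE_CODES.get(record.phase, 0.0)
    if record.phase not in PHASE_CODES:
        missing.append(f"phase={record.phase!r}")
    min_age = parse_age_years(record.min_age_text)
    max_age = parse_age_years(record.max_age_text)
    if record.n_arms is None:
        missing.append("number_of_arms")

    sections = parse_eligibility(record.eligibility_criteria_text)
    counts = eligibility_counts(sections)

    features: dict[str, float] = {
        "industry_sponsor": float(record.lead_sponsor_class == "INDUSTRY"),
        "industry_collaborator": float("INDUSTRY" in record.collaborator_classes),
        "has_collaborators": float(bool(record.collaborator_classes)),
        "n_collaborators": float(len(record.collaborator_classes)),
        "n_officials": float(record.n_officials),
        "responsible_party_code": float(
            RESPONSIBLE_PARTY_CODES.get(record.responsible_party_type, 0)
        ),
        "expanded_access": float(bool(record.has_expanded_access)),
        "dmc": float(bool(record.dmc_oversight)),
        "fda_regulated": float(bool(record.fda_regulated)),
        "has_phase": float(phase_code > 0.0),
        "phase_code": phase_code,
        "interventional": float(record.study_type == "Interventional"),
        "main_country_is_usa": float(main_country(record) == "United States"),
        "randomized": float(record.allocation == "Randomized"),
        "masking_code": float(masking_code(record.masking)),
        "placebo_group": float(
            any(_is_placebo_arm(label, arm_type) for label, arm_type in record.arm_groups)
        ),
        "n_groups": float(record.n_arms or 0),
        "n_countries": float(len(set(record.site_countries))),
        "n_sites": float(len(record.site_countries)),
        "accepts_healthy_volunteers": float(
            record.healthy_volunteers == "Accepts Healthy Volunteers"
        ),
        "age_restricted": float(
            (min_age is not None and min_age > 18.0) or max_age is not None
        ),
        "gender_restricted": float(record.gender not in ("All", "")),
        "min_age_years": min_age if min_age is not None else 0.0,
        "max_age_years": max_age if max_age is not None else 0.0,
    }
    features.update(counts)
    if missing:
        logger.debug("trial %s missing sources: %s", record.trial_id, ", ".join(missing))
    return {name: features[name] for name in STAT_FEATURE_NAMES}


def statistics_matrix(records: list[TrialRecord]) -> np.ndarray:
    """Stacked statistics features, rows aligned to ``records``."""
    return np.array(
        [[extract_statistics_features(r)[n] for n in STAT_FEATURE_NAMES] for r in records]
    )


# ---------------------------------------------------------------------------
# Drug features

VALID_MAP_SOURCES = frozenset({"ATC5", "MESHPA"})


@dataclass
class DrugClassMap:
    """Intervention MeSH term -> (drug-class name, source tag)."""

    entries: dict[str, tuple[str, str]]

    def class_of(self, mesh_term: str) -> str | None:
        entry = self.entries.get(mesh_term)
        return entry[0] if entry else None

    def __contains__(self, mesh_term: str) -> bool:
        return mesh_term in self.entries


def load_drug_class_map(path: str | Path) -> DrugClassMap:
    """Load a mapping TSV (columns mesh_term, class_name, source; header row)."""
    entries: dict[str, tuple[str, str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"mesh_term", "class_name", "source"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"drug-class map {path} must have header columns {sorted(required)}"
            )
        for row in reader:
            term = row["mesh_term"].strip()
            source = row["source"].strip()
            if source not in VALID_MAP_SOURCES:
                raise ValueError(f"invalid source {source!r} for term {term!r}")
            if term in entries:
                raise ValueError(f"mesh term {term!r} mapped more than once")
            entries[term] = (row["class_name"].strip(), source)
    return DrugClassMap(entries)


def default_drug_class_map() -> DrugClassMap:
    """The packaged synthetic mapping snapshot (see module docstring)."""
    ref = resources.files("trialcease").joinpath("data/drug_class_map.synthetic.tsv")
    with resources.as_file(ref) as path:
        return load_drug_class_map(path)


@dataclass
class DrugFeatureSpec:
    """Fitted drug-feature layout: top drugs and retained drug classes.

    Fit on training data only.  ``top_drugs`` holds the k most frequent
    intervention terms (supporting-trial count descending, boundary ties
    lexicographic); ``top_classes`` the classes with at least
    ``min_class_trials`` distinct supporting trials, most frequent first.
    """

    top_drugs: list[str]
    top_classes: list[str]
    drug_counts: dict[str, int]
    class_counts: dict[str, int]
    k_top: int = 20
    min_class_trials: int = 2

    def feature_names(self) -> list[str]:
        return [f"drug::{t}" for t in self.top_drugs] + [
            f"class::{c}" for c in self.top_classes
        ]


def fit_drug_feature_spec(
    training: list[TrialRecord],
    class_map: DrugClassMap,
    k_top: int = 20,
    min_class_trials: int = 2,
) -> DrugFeatureSpec:
    """Count supporting trials per term and per class on the training set.

    A trial supports a term once no matter how often the term repeats, and
    supports a class once if any of its terms maps into the class.  Unmapped
    terms are reported in aggregate, never dropped silently.
    """
    if not training:
        raise ValueError("fit_drug_feature_spec requires non-empty training records")
    term_counts: dict[str, int] = {}
    class_counts: dict[str, int] = {}
    unmapped: set[str] = set()
    for record in training:
        terms = set(record.intervention_mesh)
        classes = set()
        for term in terms:
            term_counts[term] = term_counts.get(term, 0) + 1
            cls = class_map.class_of(term)
            if cls is None:
                unmapped.add(term)
            else:
                classes.add(cls)
        for cls in classes:
            class_counts[cls] = class_counts.get(cls, 0) + 1
    if unmapped:
        logger.warning(
            "%d intervention MeSH terms missing from the drug-class map: %s",
            len(unmapped),
            ", ".join(sorted(unmapped)[:10]),
        )
    top_drugs = [
        term for term, _ in sorted(term_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ][:k_top]
    top_classes = [
        cls
        for cls, count in sorted(class_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if count >= min_class_trials
    ]
    return DrugFeatureSpec(
        top_drugs=top_drugs,
        top_classes=top_classes,
        drug_counts=term_counts,
        class_counts=class_counts,
        k_top=k_top,
        min_class_trials=min_class_trials,
    )


def extract_drug_features(
    record: TrialRecord, spec: DrugFeatureSpec, class_map: DrugClassMap
) -> tuple[np.ndarray, np.ndarray]:
    """(top-drug one-hot vector, per-class intervention-count vector).

    One-hot entries flag presence of the term among the trial's intervention
    MeSH terms; class counts tally how many distinct intervention terms map
    into each retained class.  Terms outside the spec or map contribute
    nothing (logged at debug level).
    """
    terms = set(record.intervention_mesh)
    onehot = np.array([float(t in terms) for t in spec.top_drugs])
    counts = np.zeros(len(spec.top_classes))
    class_index = {c: i for i, c in enumerate(spec.top_classes)}
    for term in terms:
        cls = class_map.class_of(term)
        if cls is None:
            logger.debug("trial %s: unmapped intervention term %r", record.trial_id, term)
        elif cls in class_index:
            counts[class_index[cls]] += 1.0
    return onehot, counts


def drug_matrix(
    records: list[TrialRecord], spec: DrugFeatureSpec, class_map: DrugClassMap
) -> np.ndarray:
    """Stacked drug features (one-hot block then class-count block)."""
    rows = [np.concatenate(extract_drug_features(r, spec, class_map)) for r in records]
    return np.array(rows)
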