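"""Reading, writing and labelling ClinicalTrials.gov study records.

This module handles the legacy ``clinical_study`` XML dialect (the pre-2024
public export format).  It parses one record per trial into a
:class:`TrialRecord`, assigns the binary completion/cessation label from the
overall recruitment status, applies the cohort inclusion filter, and resolves
each trial's main country (the modal site country, ties broken by document
order).
"""

from __future__ import annotations

import csv
import io
import json
import logging
import zipfile
from collections import Counter
from dataclasses import dataclass, field, fields
from pathlib import Path

from lxml import etree

logger = logging.getLogger(__name__)

# Cohort labels.  CESSATION is the positive class everywhere downstream.
COMPLETION = "COMPLETION"
CESSATION = "CESSATION"
EXCLUDED = "EXCLUDED"

COMPLETION_STATUSES = frozenset({"Completed"})
CESSATION_STATUSES = frozenset({"Terminated", "Suspended", "Withdrawn"})

#: Registry recruitment-status vocabulary, including expanded-access statuses.
KNOWN_STATUSES = frozenset(
    {
        "Not yet recruiting",
        "Recruiting",
        "Enrolling by invitation",
        "Active, not recruiting",
        "Completed",
        "Suspended",
        "Terminated",
        "Withdrawn",
        "Approved for Marketing",
        "No Longer Available",
        "Available",
    }
)


class ParseError(ValueError):
    """Raised when a study record cannot be parsed."""


@dataclass
class TrialRecord:
    """One parsed registry record.

    List fields are always present (possibly empty) and preserve document
    order; ``site_countries`` holds one entry per ``<location>`` element so
    the main-country tie-break can count one vote per site.
    """

    trial_id: str
    overall_status: str = ""
    lead_sponsor_class: str = ""
    collaborator_classes: list[str] = field(default_factory=list)
    n_officials: int = 0
    responsible_party_type: str = ""
    has_expanded_access: bool | None = None
    dmc_oversight: bool | None = None
    fda_regulated: bool | None = None
    phase: str = ""
    study_type: str = ""
    allocation: str = ""
    masking: str = ""
    n_arms: int | None = None
    arm_groups: list[tuple[str, str]] = field(default_factory=list)
    site_countries: list[str] = field(default_factory=list)
    eligibility_criteria_text: str = ""
    gender: str = ""
    min_age_text: str = ""
    max_age_text: str = ""
    healthy_volunteers: str = ""
    keywords: list[str] = field(default_factory=list)
    conditions: list[str] = field(default_factory=list)
    condition_mesh: list[str] = field(default_factory=list)
    intervention_mesh: list[str] = field(default_factory=list)
    detailed_description: str = ""


def _text(root, path: str, default: str = "") -> str:
    value = root.findtext(path)
    return value.strip() if value else default


def _texts(root, path: str) -> list[str]:
    return [el.text.strip() for el in root.findall(path) if el.text and el.text.strip()]


def _flag(root, path: str) -> bool | None:
    value = _text(root, path)
    if not value:
        return None
    return value.strip().lower() in {"yes", "true"}


def parse_study_record(xml_text: str | bytes) -> TrialRecord:
    """Parse a single legacy-dialect study record.

    Missing optional elements become empty strings/lists or ``None`` flags;
    no field is silently dropped.  Malformed XML raises :class:`ParseError`
    naming the problem; a missing trial identifier is rejected with a reason.
    """
    if isinstance(xml_text, str):
        xml_text = xml_text.encode("utf-8")
    try:
        root = etree.fromstring(xml_text)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed study record XML: {exc}") from exc
    if root.tag != "clinical_study":
        raise ParseError(f"expected <clinical_study> root, found <{root.tag}>")

    trial_id = _text(root, "id_info/nct_id")
    if not trial_id:
        raise ParseError("study record rejected: missing trial identifier (id_info/nct_id)")

    n_arms_text = _text(root, "number_of_arms")
    try:
        n_arms = int(n_arms_text) if n_arms_text else None
    except ValueError as exc:
        raise ParseError(f"non-integer <number_of_arms>: {n_arms_text!r}") from exc

    arm_groups = [
        (_text(arm, "arm_group_label"), _text(arm, "arm_group_type"))
        for arm in root.findall("arm_group")
    ]
    # One vote per <location> element (per site), in document order.
    site_countries = [
        country
        for loc in root.findall("location")
        for country in [_text(loc, "facility/address/country")]
        if country
    ]

    return TrialRecord(
        trial_id=trial_id,
        overall_status=_text(root, "overall_status"),
        lead_sponsor_class=_text(root, "sponsors/lead_sponsor/agency_class"),
        collaborator_classes=_texts(root, "sponsors/collaborator/agency_class"),
        n_officials=len(root.findall("overall_official")),
        responsible_party_type=_text(root, "responsible_party/responsible_party_type"),
        has_expanded_access=_flag(root, "has_expanded_access"),
        dmc_oversight=_flag(root, "oversight_info/has_dmc"),
        fda_regulated=_flag(root, "oversight_info/is_fda_regulated_drug"),
        phase=_text(root, "phase"),
        study_type=_text(root, "study_type"),
        allocation=_text(root, "study_design_info/allocation"),
        masking=_text(root, "study_design_info/masking"),
        n_arms=n_arms,
        arm_groups=arm_groups,
        site_countries=site_countries,
        eligibility_criteria_text=root.findtext("eligibility/criteria/textblock") or "",
        gender=_text(root, "eligibility/gender"),
        min_age_text=_text(root, "eligibility/minimum_age"),
        max_age_text=_text(root, "eligibility/maximum_age"),
        healthy_volunteers=_text(root, "eligibility/healthy_volunteers"),
        keywords=_texts(root, "keyword"),
        conditions=_texts(root, "condition"),
        condition_mesh=_texts(root, "condition_browse/mesh_term"),
        intervention_mesh=_texts(root, "intervention_browse/mesh_term"),
        detailed_description=root.findtext("detailed_description/textblock") or "",
    )


def _sub(parent, tag: str, text: str | None = None):
    el = etree.SubElement(parent, tag)
    if text is not None:
        el.text = text
    return el


def record_to_xml(record: TrialRecord) -> str:
    """Serialize a record back to the legacy dialect.

    Round-trip contract: ``parse_study_record(record_to_xml(r))`` equals ``r``
    field-for-field for every record the synthetic generator emits.
    """
    root = etree.Element("clinical_study")
    _sub(_sub(root, "id_info"), "nct_id", record.trial_id)
    if record.overall_status:
        _sub(root, "overall_status", record.overall_status)
    if record.lead_sponsor_class or record.collaborator_classes:
        sponsors = _sub(root, "sponsors")
        if record.lead_sponsor_class:
            lead = _sub(sponsors, "lead_sponsor")
            _sub(lead, "agency", "Synthetic Sponsor")
            _sub(lead, "agency_class", record.lead_sponsor_class)
        for cls in record.collaborator_classes:
            collab = _sub(sponsors, "collaborator")
            _sub(collab, "agency", "Synthetic Collaborator")
            _sub(collab, "agency_class", cls)
    if record.dmc_oversight is not None or record.fda_regulated is not None:
        oversight = _sub(root, "oversight_info")
        if record.dmc_oversight is not None:
            _sub(oversight, "has_dmc", "Yes" if record.dmc_oversight else "No")
        if record.fda_regulated is not None:
            _sub(
                oversight,
                "is_fda_regulated_drug",
                "Yes" if record.fda_regulated else "No",
            )
    if record.has_expanded_access is not None:
        _sub(root, "has_expanded_access", "Yes" if record.has_expanded_access else "No")
    if record.phase:
        _sub(root, "phase", record.phase)
    if record.study_type:
        _sub(root, "study_type", record.study_type)
    if record.allocation or record.masking:
        design = _sub(root, "study_design_info")
        if record.allocation:
            _sub(design, "allocation", record.allocation)
        if record.masking:
            _sub(design, "masking", record.masking)
    if record.n_arms is not None:
        _sub(root, "number_of_arms", str(record.n_arms))
    for label, arm_type in record.arm_groups:
        arm = _sub(root, "arm_group")
        _sub(arm, "arm_group_label", label)
        if arm_type:
            _sub(arm, "arm_group_type", arm_type)
    for i in range(record.n_officials):
        _sub(_sub(root, "overall_official"), "last_name", f"Official {i + 1}")
    if record.responsible_party_type:
        _sub(
            _sub(root, "responsible_party"),
            "responsible_party_type",
            record.responsible_party_type,
        )
    eligibility = _sub(root, "eligibility")
    if record.eligibility_criteria_text:
        _sub(_sub(eligibility, "criteria"), "textblock", record.eligibility_criteria_text)
    if record.gender:
        _sub(eligibility, "gender", record.gender)
    if record.min_age_text:
        _sub(eligibility, "minimum_age", record.min_age_text)
    if record.max_age_text:
        _sub(eligibility, "maximum_age", record.max_age_text)
    if record.healthy_volunteers:
        _sub(eligibility, "healthy_volunteers", record.healthy_volunteers)
    for country in record.site_countries:
        loc = _sub(root, "location")
        _sub(_sub(_sub(loc, "facility"), "address"), "country", country)
    for kw in record.keywords:
        _sub(root, "keyword", kw)
    for cond in record.conditions:
        _sub(root, "condition", cond)
    if record.condition_mesh:
        browse = _sub(root, "condition_browse")
        for term in record.condition_mesh:
            _sub(browse, "mesh_term", term)
    if record.intervention_mesh:
        browse = _sub(root, "intervention_browse")
        for term in record.intervention_mesh:
            _sub(browse, "mesh_term", term)
    if record.detailed_description:
        _sub(_sub(root, "detailed_description"), "textblock", record.detailed_description)
    return etree.tostring(root, pretty_print=True, encoding="unicode")


def assign_label(overall_status: str) -> str:
    """Map a recruitment status to COMPLETION, CESSATION or EXCLUDED.

    Matching is case-sensitive exact match on the registry vocabulary:
    "Completed" is the completion class; "Terminated", "Suspended" and
    "Withdrawn" form the cessation class; every other status (recruiting and
    expanded-access statuses included) is excluded from the cohort.  Unknown
    strings are excluded with a logged warning rather than raising, because
    registry exports evolve.
    """
    if overall_status in COMPLETION_STATUSES:
        return COMPLETION
    if overall_status in CESSATION_STATUSES:
        return CESSATION
    if overall_status not in KNOWN_STATUSES:
        logger.warning("unknown overall_status %r excluded from cohort", overall_status)
    return EXCLUDED


def filter_cohort(
    records: list[TrialRecord],
) -> tuple[list[tuple[TrialRecord, str]], Counter]:
    """Apply the cohort inclusion filter.

    Returns the labelled cohort (completion + cessation records only) and a
    tally of every input status, so registry-wide status summaries remain
    reproducible from the same pass.
    """
    if not records:
        raise ValueError("filter_cohort requires a non-empty record list")
    tally: Counter = Counter(r.overall_status for r in records)
    cohort = [
        (record, label)
        for record in records
        for label in [assign_label(record.overall_status)]
        if label != EXCLUDED
    ]
    if not cohort:
        raise ValueError(
            "empty cohort after filtering: no Completed/Terminated/Suspended/"
            "Withdrawn records (downstream stages need both classes)"
        )
    labels = {label for _, label in cohort}
    if len(labels) == 1:
        logger.warning("cohort contains a single class only: %s", labels)
    return cohort, tally


def main_country(record: TrialRecord) -> str | None:
    """Modal country across a trial's sites; ties go to the first-listed one.

    Each ``<location>`` element counts one vote.  Returns ``None`` when the
    trial lists no sites.
    """
    if not record.site_countries:
        return None
    counts = Counter(record.site_countries)
    best = max(counts.values())
    for country in record.site_countries:  # document order breaks ties
        if counts[country] == best:
            return country
    raise AssertionError("unreachable")


def read_corpus(path: str | Path) -> list[TrialRecord]:
    """Read every ``*.xml`` study record from a directory or zip archive."""
    path = Path(path)
    records: list[TrialRecord] = []
    if path.is_dir():
        for xml_file in sorted(path.glob("*.xml")):
            records.append(parse_study_record(xml_file.read_bytes()))
    elif zipfile.is_zipfile(path):
        with zipfile.ZipFile(path) as zf:
            for name in sorted(zf.namelist()):
                if name.endswith(".xml"):
                    records.append(parse_study_record(zf.read(name)))
    else:
        raise ValueError(f"{path} is neither a directory nor a zip archive")
    return records


def write_cohort_manifest(
    cohort: list[tuple[TrialRecord, str]], path: str | Path
) -> None:
    """Write the cohort as CSV: trial_id, label, overall_status, main_country."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["trial_id", "label", "overall_status", "main_country"])
        for record, label in cohort:
            writer.writerow(
                [record.trial_id, label, record.overall_status, main_country(record) or ""]
            )


def write_status_tally(tally: Counter, path: str | Path) -> None:
    """Write the per-status tally as JSON (registry-wide status summary)."""
    with open(path, "w") as fh:
        json.dump(dict(sorted(tally.items())), fh, indent=2)
        fh.write("\n")
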