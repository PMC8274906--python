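"""Seeded synthetic registry corpora with planted class-conditional structure.

The generator emits records in the same legacy XML dialect that
:mod:`trialcease.ctgov_io` parses, with the class-conditional structure the
analysis assumes: a cessation label drawn at the observed cessation rate, a
handful of fields whose rates differ between completion and cessation trials
(interventional status, placebo arm, refusal of healthy volunteers, USA main
country, hydroxychloroquine intervention), top-drug assignments at the
observed per-drug prevalences, class-leaning keyword vocabularies, and
template-based descriptions sharing a common COVID stem.

Every class-conditional completion rate is derived from the printed marginal
rate and the printed cessation-conditional rate by the law of total
probability (:func:`derive_completion_conditional`); nothing is guessed.
Fields for which no class-conditional rate was ever printed (industry
sponsorship and the like) default to neutral: identical rates in both
classes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ctgov_io import CESSATION, COMPLETION, TrialRecord, record_to_xml

logger = logging.getLogger(__name__)

#: Top-20 intervention MeSH terms and their supporting-trial counts in the
#: reference cohort of 772 trials (they sum to 218 trials, 28.2% coverage).
TOP_DRUG_COUNTS: dict[str, int] = {
    "Hydroxychloroquine": 73,
    "Azithromycin": 30,
    "Ivermectin": 15,
    "Ritonavir": 10,
    "Lopinavir": 8,
    "Dexamethasone": 7,
    "Chloroquine": 7,
    "Methylprednisolone": 6,
    "Antibodies": 6,
    "Ascorbic Acid": 6,
    "Interferons": 6,
    "Prednisolone hemisuccinate": 5,
    "Doxycycline": 5,
    "Methylprednisolone Acetate": 5,
    "Prednisolone": 5,
    "Prednisolone acetate": 5,
    "IL-1Ra Protein": 5,
    "Methylprednisolone Hemisuccinate": 5,
    "Prednisolone phosphate": 5,
    "Chloroquine diphosphate": 4,
}

#: Reference cohort size and cessation count behind all derived rates.
REFERENCE_TOTAL = 772
REFERENCE_CESSATION = 144

#: Non-USA main-country pool weighted by registered-trial counts.
COUNTRY_WEIGHTS: dict[str, int] = {
    "France": 571,
    "Italy": 185,
    "United Kingdom": 182,
    "Spain": 155,
    "China": 154,
    "Egypt": 153,
    "Canada": 147,
    "Turkey": 147,
    "Brazil": 123,
}

SHARED_KEYWORDS = (
    "COVID-19",
    "SARS-CoV-2",
    "Coronavirus Infections",
    "Pneumonia, Viral",
    "Respiratory Tract Infections",
    "Severe Acute Respiratory Syndrome",
)
CESSATION_KEYWORDS = (
    "Hydroxychloroquine",
    "Prophylaxis",
    "Cytokine Storm",
    "Healthcare Worker",
    "Azithromycin",
    "Hypoxemia",
    "Respiratory Insufficiency",
    "Pulmonary Failure",
)
COMPLETION_KEYWORDS = (
    "Anxiety",
    "Depression",
    "Psychological Stress",
    "Mental Health",
    "Emergency Care",
    "Critical Illness",
    "Ventilation",
    "Quality of Life",
)

SHARED_STEMS = (
    "This study investigates patients with confirmed covid 19 coronavirus infection.",
    "A multicenter study of sars cov 2 infection and acute respiratory outcomes.",
    "The protocol enrolls adults during the coronavirus pandemic at participating sites.",
)
CESSATION_TAILS = (
    "The trial evaluates hydroxychloroquine prophylaxis for healthcare workers exposed to the virus.",
    "Participants with cytokine storm and hypoxemia receive the investigational intervention.",
    "Respiratory insufficiency and pulmonary failure are monitored as safety endpoints.",
    "Azithromycin is administered as adjunct therapy in the treatment arm.",
)
COMPLETION_TAILS = (
    "Participants complete surveys measuring anxiety depression and psychological stress during the pandemic.",
    "The study observes mental health and quality of life in emergency care staff.",
    "Outcomes include critical illness recovery and ventilation free days.",
    "Questionnaires assess wellbeing of patients discharged after hospital care.",
)

INCLUSION_POOL = (
    "Age over 18 years",
    "Positive PCR test within 72 hours",
    "Oxygen saturation below 94 %",
    "Admitted to hospital within 48 hours of symptom onset",
    "Willing to provide informed consent",
    "Body mass index between 18 and 35",
)
EXCLUSION_POOL = (
    "Pregnant or breastfeeding",
    "Known allergy to the study drug",
    "Participation in another interventional trial within 30 days",
    "Severe renal impairment with creatinine clearance below 30 ml per minute",
    "QTc interval above 470 ms",
)

#: Class co-members (mapped in the drug-class fixture, outside the top 20)
#: occasionally added to exercise drug-class count features.
CO_MEMBER_TERMS = (
    "Primaquine",
    "Clarithromycin",
    "Budesonide",
    "Ribavirin",
    "Heparin",
    "Losartan",
)
UNMAPPED_TERM = "Traditional Herbal Preparation"


def derive_completion_conditional(
    overall_rate: float, cess_rate: float, n_total: int, n_cess: int
) -> float:
    """Completion-conditional rate implied by a printed marginal rate.

    By the law of total probability over the two classes::

        overall * n_total = cess * n_cess + completion * (n_total - n_cess)

    so ``completion = (overall*n_total - cess*n_cess) / (n_total - n_cess)``.
    Raises a configuration error when the implied rate leaves [0, 1].
    """
    result = (overall_rate * n_total - cess_rate * n_cess) / (n_total - n_cess)
    if not 0.0 <= result <= 1.0:
        raise ValueError(
            f"derived completion-conditional rate {result:.4f} outside [0, 1] "
            f"(overall={overall_rate}, cessation={cess_rate})"
        )
    return result


@dataclass(frozen=True)
class FieldRate:
    """Overall (marginal) rate and cessation-conditional rate of a binary field."""

    overall: float
    cessation: float

    def completion(self, n_total: int = REFERENCE_TOTAL, n_cess: int = REFERENCE_CESSATION) -> float:
        return derive_completion_conditional(self.overall, self.cessation, n_total, n_cess)


def _default_field_rates() -> dict[str, FieldRate]:
    # Printed marginal + cessation-conditional percentages for the four
    # class-informative structured fields.
    return {
        "interventional": FieldRate(0.4883, 0.9306),
        "placebo_group": FieldRate(0.149, 0.375),
        "no_healthy_volunteers": FieldRate(0.7539, 0.8542),
        "main_country_usa": FieldRate(0.1412, 0.2708),
    }


def _default_drug_cessation_rates() -> dict[str, float]:
    # Only hydroxychloroquine's cessation-conditional prevalence is printed;
    # all other top drugs default to neutral (class-independent) rates.
    return {"Hydroxychloroquine": 0.3194}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic registry generator.

    Defaults reproduce the study conditions of the reference cohort: 772
    trials, 18.65% cessation, class-conditional rates derived from printed
    percentages.  ``class_vocab_mix`` is the probability that a class-leaning
    keyword or description sentence is drawn from the trial's own class
    vocabulary (the remainder crosses over, so vocabularies overlap).
    """

    n_trials: int = REFERENCE_TOTAL
    cessation_rate: float = 0.1865
    field_rates: dict[str, FieldRate] = field(default_factory=_default_field_rates)
    top_drug_counts: dict[str, int] = field(default_factory=lambda: dict(TOP_DRUG_COUNTS))
    drug_cessation_rates: dict[str, float] = field(default_factory=_default_drug_cessation_rates)
    reference_total: int = REFERENCE_TOTAL
    reference_cessation: int = REFERENCE_CESSATION
    class_vocab_mix: float = 0.75
    co_member_rate: float = 0.02
    unmapped_term_rate: float = 0.01
    no_split_eligibility_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cessation_rate <= 1.0:
            raise ValueError(f"cessation_rate {self.cessation_rate} outside [0, 1]")
        for name, overall, cess in self._rate_triples():
            for label, rate in (("overall", overall), ("cessation", cess)):
                if not 0.0 <= rate <= 1.0:
                    raise ValueError(f"{label} rate for {name!r} outside [0, 1]: {rate}")
            try:
                derive_completion_conditional(
                    overall, cess, self.reference_total, self.reference_cessation
                )
            except ValueError as exc:
                raise ValueError(f"field {name!r}: {exc}") from exc

    def _rate_triples(self) -> list[tuple[str, float, float]]:
        triples = [(name, fr.overall, fr.cessation) for name, fr in self.field_rates.items()]
        for term, count in self.top_drug_counts.items():
            overall = count / self.reference_total
            cess = self.drug_cessation_rates.get(term, overall)
            triples.append((f"drug::{term}", overall, cess))
        return triples

    def class_rates(self, name: str) -> tuple[float, float]:
        """(completion-conditional, cessation-conditional) rates for a field."""
        for field_name, overall, cess in self._rate_triples():
            if field_name == name:
                comp = derive_completion_conditional(
                    overall, cess, self.reference_total, self.reference_cessation
                )
                return comp, cess
        raise KeyError(name)

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorConfig":
        raw = json.loads(Path(path).read_text())
        if "field_rates" in raw:
            raw["field_rates"] = {
                k: FieldRate(*v) if not isinstance(v, FieldRate) else v
                for k, v in raw["field_rates"].items()
            }
        return cls(**raw)


#: Mapping from generator field names to feature-matrix column names, with the
#: sign flip for the healthy-volunteers feature (the generator plants "does
#: not accept", the feature encodes "accepts").
_FIELD_TO_FEATURE = {
    "interventional": ("interventional", +1),
    "placebo_group": ("placebo_group", +1),
    "no_healthy_volunteers": ("accepts_healthy_volunteers", -1),
    "main_country_usa": ("main_country_is_usa", +1),
}


def plant_signal_report(config: GeneratorConfig) -> list[dict]:
    """Ground truth for feature-recovery tests.

    Lists every generated field whose cessation-conditional rate differs from
    its completion-conditional rate, the feature-matrix column it surfaces
    as, and the effect direction on that column (+1 cessation-enriched).
    """
    report = []
    for name, overall, cess in config._rate_triples():
        comp = derive_completion_conditional(
            overall, cess, config.reference_total, config.reference_cessation
        )
        if abs(cess - comp) <= 1e-12:
            continue
        feature, flip = _FIELD_TO_FEATURE.get(name, (name, +1))
        direction = 1 if cess > comp else -1
        report.append(
            {
                "field": name,
                "feature": feature,
                "direction": direction * flip,
                "completion_rate": comp,
                "cessation_rate": cess,
            }
        )
    return report


def neutral_structured_features() -> list[str]:
    """Structured feature columns generated with no class effect.

    These are drawn independently of the label *and* of every planted field,
    so they are valid negative controls for feature-recovery checks.  Columns
    derived from planted fields (phase, masking, allocation, group counts,
    which inherit signal through the interventional/placebo draws) are
    deliberately absent.
    """
    stats = [
        "industry_sponsor",
        "industry_collaborator",
        "has_collaborators",
        "n_collaborators",
        "n_officials",
        "responsible_party_code",
        "expanded_access",
        "dmc",
        "fda_regulated",
        "n_countries",
        "n_sites",
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
    ]
    drugs = [f"drug::{t}" for t in TOP_DRUG_COUNTS if t != "Hydroxychloroquine"]
    return stats + drugs


def _bern(rng: np.random.Generator, p: float) -> bool:
    return bool(rng.random() < p)


def _choice(rng: np.random.Generator, items, p=None):
    idx = rng.choice(len(items), p=p)
    return items[int(idx)]


_COUNTRY_NAMES = tuple(COUNTRY_WEIGHTS)
_COUNTRY_P = np.array(list(COUNTRY_WEIGHTS.values()), dtype=float)
_COUNTRY_P /= _COUNTRY_P.sum()

_PHASES = ("N/A", "Early Phase 1", "Phase 1", "Phase 1/Phase 2", "Phase 2",
           "Phase 2/Phase 3", "Phase 3", "Phase 4")
_PHASE_P = (0.15, 0.05, 0.15, 0.10, 0.25, 0.05, 0.15, 0.10)
_MASKINGS = ("None (Open Label)", "Single", "Double", "Triple", "Quadruple")
_MASKING_P = (0.40, 0.15, 0.25, 0.10, 0.10)


def _eligibility_text(rng: np.random.Generator, config: GeneratorConfig) -> str:
    n_inc = min(2 + int(rng.poisson(2)), len(INCLUSION_POOL))
    n_exc = min(1 + int(rng.poisson(2)), len(EXCLUSION_POOL))
    inc = [INCLUSION_POOL[int(i)] for i in rng.choice(len(INCLUSION_POOL), n_inc, replace=False)]
    exc = [EXCLUSION_POOL[int(i)] for i in rng.choice(len(EXCLUSION_POOL), n_exc, replace=False)]
    if _bern(rng, config.no_split_eligibility_rate):
        return "\n".join(f"-  {line}" for line in inc + exc)
    inc_block = "\n".join(f"  -  {line}" for line in inc)
    exc_block = "\n".join(f"  -  {line}" for line in exc)
    return f"Inclusion Criteria:\n\n{inc_block}\n\nExclusion Criteria:\n\n{exc_block}\n"


def _keywords(rng: np.random.Generator, config: GeneratorConfig, is_cess: bool) -> list[str]:
    n_shared = 2 + int(_bern(rng, 0.5))
    shared = [SHARED_KEYWORDS[int(i)]
              for i in rng.choice(len(SHARED_KEYWORDS), n_shared, replace=False)]
    own, other = (CESSATION_KEYWORDS, COMPLETION_KEYWORDS)
    if not is_cess:
        own, other = other, own
    tails = []
    for _ in range(1 + int(rng.poisson(1))):
        pool = own if _bern(rng, config.class_vocab_mix) else other
        tails.append(_choice(rng, pool))
    seen: set[str] = set()
    return [k for k in shared + tails if not (k in seen or seen.add(k))]


def _description(rng: np.random.Generator, config: GeneratorConfig, is_cess: bool) -> str:
    own, other = (CESSATION_TAILS, COMPLETION_TAILS)
    if not is_cess:
        own, other = other, own
    sentences = [_choice(rng, SHARED_STEMS)]
    for _ in range(1 + int(_bern(rng, 0.6))):
        pool = own if _bern(rng, config.class_vocab_mix) else other
        sentences.append(_choice(rng, pool))
    return " ".join(sentences)


def _rate_table(config: GeneratorConfig) -> dict[str, tuple[float, float]]:
    """(completion, cessation) conditional rates for every configured field."""
    return {
        name: (
            derive_completion_conditional(
                overall, cess, config.reference_total, config.reference_cessation
            ),
            cess,
        )
        for name, overall, cess in config._rate_triples()
    }


def _generate_record(
    i: int, config: GeneratorConfig, rate_table: dict[str, tuple[float, float]]
) -> tuple[TrialRecord, str]:
    rng = np.random.default_rng((config.seed, i))
    is_cess = _bern(rng, config.cessation_rate)
    label = CESSATION if is_cess else COMPLETION
    pick = 1 if is_cess else 0

    rates = {name: pair[pick] for name, pair in rate_table.items()}

    interventional = _bern(rng, rates["interventional"])
    placebo = _bern(rng, rates["placebo_group"])
    no_healthy = _bern(rng, rates["no_healthy_volunteers"])
    usa = _bern(rng, rates["main_country_usa"])

    if is_cess:
        status = _choice(rng, ("Terminated", "Withdrawn", "Suspended"), p=(0.5, 0.35, 0.15))
    else:
        status = "Completed"

    # Sites: the chosen main country always holds the (possibly tied) modal
    # count and is listed first, so the tie-break resolves to it.
    main = "United States" if usa else _choice(rng, _COUNTRY_NAMES, p=_COUNTRY_P)
    n_main_sites = 1 + int(rng.poisson(1.0))
    countries = [main] * n_main_sites
    for _ in range(int(rng.integers(0, 3))):
        extra = _choice(rng, _COUNTRY_NAMES, p=_COUNTRY_P)
        if extra != main:
            countries.extend([extra] * int(rng.integers(1, n_main_sites + 1)))

    # Drug interventions: independent Bernoulli per top drug at the
    # class-conditional rate, so printed marginal prevalences are honored.
    mesh = [term for term in config.top_drug_counts if _bern(rng, rates[f"drug::{term}"])]
    if _bern(rng, config.co_member_rate):
        mesh.append(_choice(rng, CO_MEMBER_TERMS))
    if _bern(rng, config.unmapped_term_rate):
        mesh.append(UNMAPPED_TERM)

    if interventional:
        phase = _choice(rng, _PHASES, p=_PHASE_P)
        allocation = "Randomized" if _bern(rng, 0.7) else "Non-Randomized"
        masking = _choice(rng, _MASKINGS, p=_MASKING_P)
        n_arms = (2 if placebo else 1) + int(rng.poisson(0.8))
        arms = [(f"Arm {chr(65 + j)}", "Experimental") for j in range(n_arms - int(placebo))]
        if placebo:
            arms.append(("Placebo", "Placebo Comparator"))
    else:
        phase = "N/A"
        allocation = ""
        masking = ""
        n_arms = None
        arms = [("Placebo", "Placebo Comparator")] if placebo else []

    n_collab = int(rng.integers(0, 3))
    collab_classes = [
        "INDUSTRY" if _bern(rng, 0.25) else _choice(rng, ("OTHER", "NIH", "U.S. FED"))
        for _ in range(n_collab)
    ]

    record = TrialRecord(
        trial_id=f"NCT9{i:07d}",
        overall_status=status,
        lead_sponsor_class="INDUSTRY" if _bern(rng, 0.3) else _choice(rng, ("OTHER", "NIH")),
        collaborator_classes=collab_classes,
        n_officials=int(rng.integers(0, 3)),
        responsible_party_type=_choice(
            rng, ("Sponsor", "Principal Investigator", "Sponsor-Investigator")
        ),
        has_expanded_access=_bern(rng, 0.02),
        dmc_oversight=None if _bern(rng, 0.1) else _bern(rng, 0.4),
        fda_regulated=None if _bern(rng, 0.1) else _bern(rng, 0.35),
        phase=phase,
        study_type="Interventional" if interventional else "Observational",
        allocation=allocation,
        masking=masking,
        n_arms=n_arms,
        arm_groups=arms,
        site_countries=countries,
        eligibility_criteria_text=_eligibility_text(rng, config),
        gender=_choice(rng, ("All", "Male", "Female"), p=(0.8, 0.1, 0.1)),
        min_age_text=_choice(rng, ("18 Years", "N/A", "45 Years"), p=(0.7, 0.2, 0.1)),
        max_age_text=_choice(rng, ("N/A", "65 Years", "80 Years"), p=(0.6, 0.25, 0.15)),
        healthy_volunteers="No" if no_healthy else "Accepts Healthy Volunteers",
        keywords=_keywords(rng, config, is_cess),
        conditions=["COVID-19"] + (["SARS-CoV-2 Infection"] if _bern(rng, 0.3) else []),
        condition_mesh=["Coronavirus Infections"]
        + (["Pneumonia, Viral"] if _bern(rng, 0.25) else []),
        intervention_mesh=mesh,
        detailed_description=_description(rng, config, is_cess),
    )
    return record, label


def generate_corpus(config: GeneratorConfig) -> tuple[list[TrialRecord], list[str]]:
    """Generate ``config.n_trials`` records with their cohort labels.

    Identical config + seed yields an identical corpus (each record has its
    own child stream of the global seed, so generation order is immaterial).
    """
    rate_table = _rate_table(config)
    records, labels = [], []
    for i in range(config.n_trials):
        record, label = _generate_record(i, config, rate_table)
        records.append(record)
        labels.append(label)
    return records, labels


def corpus_to_xml(records: list[TrialRecord]) -> list[str]:
    """Serialize a generated corpus to legacy-dialect XML strings."""
    return [record_to_xml(r) for r in records]


def write_corpus(config: GeneratorConfig, out_dir: str | Path) -> None:
    """Emit XML files, a labels CSV and the planted-signal JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, labels = generate_corpus(config)
    for record in records:
        (out / f"{record.trial_id}.xml").write_text(record_to_xml(record))
    with open(out / "labels.csv", "w") as fh:
        fh.write("trial_id,label\n")
        for record, label in zip(records, labels):
            fh.write(f"{record.trial_id},{label}\n")
    with open(out / "planted_signal.json", "w") as fh:
        json.dump(plant_signal_report(config), fh, indent=2)
        fh.write("\n")
    logger.info("wrote %d synthetic records to %s", len(records), out)
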