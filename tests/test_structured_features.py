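"""Statistics features, eligibility parsing and drug features."""

import numpy as np
import pytest

from trialcease.structured_features import (
    STAT_FEATURE_NAMES,
    EligibilitySections,
    eligibility_counts,
    extract_drug_features,
    extract_statistics_features,
    fit_drug_feature_spec,
    load_drug_class_map,
    parse_age_years,
    parse_eligibility,
)

SPLIT_TEXT = """Inclusion Criteria:

  -  Age over 18 years
  -  Positive PCR test
  -  Informed consent

Exclusion Criteria:

  -  Pregnant or breastfeeding
  -  Known allergy
"""


class TestParseEligibility:
    def test_split_with_headers(self):
        sections = parse_eligibility(SPLIT_TEXT)
        assert sections.has_split
        assert len(sections.inclusion_lines) == 3
        assert len(sections.exclusion_lines) == 2

    def test_no_headers_goes_to_combined(self):
        sections = parse_eligibility("adults\nconsent given\nno comorbidity\nstable dose")
        assert not sections.has_split
        assert len(sections.combined_lines) == 4
        assert sections.inclusion_lines == [] and sections.exclusion_lines == []

    def test_empty_text(self):
        sections = parse_eligibility("")
        assert sections.entire_lines == []

    def test_bullet_markers_and_numbering_are_stripped(self):
        sections = parse_eligibility("Inclusion Criteria:\n- first\n* second\n3. third")
        assert sections.inclusion_lines == ["first", "second", "third"]


class TestEligibilityCounts:
    def test_example_lines(self):
        sections = EligibilitySections(
            inclusion_lines=["age over 18 years", "positive PCR test"],
            exclusion_lines=[],
            has_split=True,
        )
        counts = eligibility_counts(sections)
        assert counts["n_inclusion_lines"] == 2
        assert counts["words_inclusion"] == 7
        assert counts["digits_inclusion"] == 2
        assert counts["avg_words_inclusion_line"] == 3.5

    def test_digit_characters_are_counted_individually(self):
        sections = EligibilitySections(combined_lines=["weight 70 kg to 120 kg"])
        assert eligibility_counts(sections)["digits_eligibility"] == 5

    def test_empty_sections_are_all_zero(self):
        counts = eligibility_counts(EligibilitySections())
        assert all(v == 0 for v in counts.values())

    def test_entire_field_dominates_sections(self, small_corpus):
        records, _, _ = small_corpus
        for record in records:
            counts = eligibility_counts(parse_eligibility(record.eligibility_criteria_text))
            for quantity in ("n_{}_lines", "words_{}", "digits_{}"):
                entire = counts[quantity.format("eligibility")]
                assert entire >= counts[quantity.format("inclusion")]
                assert entire >= counts[quantity.format("exclusion")]


class TestStatisticsFeatures:
    def test_exactly_forty_unique_columns(self, record_factory):
        features = extract_statistics_features(record_factory())
        assert list(features) == list(STAT_FEATURE_NAMES)
        assert len(set(STAT_FEATURE_NAMES)) == 40

    def test_administrative_encoding(self, record_factory):
        record = record_factory(
            lead_sponsor_class="INDUSTRY",
            collaborator_classes=["OTHER", "NIH"],
            n_officials=1,
            responsible_party_type="Sponsor",
        )
        f = extract_statistics_features(record)
        assert f["industry_sponsor"] == 1
        assert f["industry_collaborator"] == 0
        assert f["n_collaborators"] == 2
        assert f["responsible_party_code"] == 1

    def test_observational_is_not_interventional(self, record_factory):
        assert extract_statistics_features(record_factory(study_type="Observational"))[
            "interventional"
        ] == 0

    def test_site_counts_and_main_country(self, record_factory):
        record = record_factory(site_countries=["United States", "United States", "France"])
        f = extract_statistics_features(record)
        assert f["main_country_is_usa"] == 1
        assert f["n_countries"] == 2
        assert f["n_sites"] == 3

    def test_placebo_detection_by_arm_type_or_label(self, record_factory):
        by_type = record_factory(arm_groups=[("Arm A", "Placebo Comparator")])
        by_label = record_factory(arm_groups=[("Matching placebo", "Other")])
        neither = record_factory(arm_groups=[("Arm A", "Experimental")])
        assert extract_statistics_features(by_type)["placebo_group"] == 1
        assert extract_statistics_features(by_label)["placebo_group"] == 1
        assert extract_statistics_features(neither)["placebo_group"] == 0

    @pytest.mark.parametrize(
        "text,years",
        [("18 Years", 18.0), ("6 Months", 0.5), ("N/A", None), ("", None)],
    )
    def test_age_parsing(self, text, years):
        assert parse_age_years(text) == (pytest.approx(years) if years else None)

    def test_age_and_gender_restrictions(self, record_factory):
        restricted = record_factory(min_age_text="45 Years", gender="Female")
        open_record = record_factory(min_age_text="18 Years", max_age_text="N/A", gender="All")
        f1 = extract_statistics_features(restricted)
        f2 = extract_statistics_features(open_record)
        assert f1["age_restricted"] == 1 and f1["gender_restricted"] == 1
        assert f2["age_restricted"] == 0 and f2["gender_restricted"] == 0


class TestDrugClassMap:
    def test_default_map_loads_expected_memberships(self, class_map):
        assert class_map.class_of("Hydroxychloroquine") == "Aminoquinolines"
        assert class_map.class_of("Chloroquine diphosphate") == "Aminoquinolines"
        assert class_map.class_of("Unheard-of term") is None

    def test_duplicate_terms_rejected(self, tmp_path):
        bad = tmp_path / "map.tsv"
        bad.write_text("mesh_term\tclass_name\tsource\nA\tX\tATC5\nA\tY\tMESHPA\n")
        with pytest.raises(ValueError, match="more than once"):
            load_drug_class_map(bad)

    def test_invalid_source_rejected(self, tmp_path):
        bad = tmp_path / "map.tsv"
        bad.write_text("mesh_term\tclass_name\tsource\nA\tX\tWHOCC\n")
        with pytest.raises(ValueError, match="source"):
            load_drug_class_map(bad)


class TestDrugFeatureSpec:
    def test_singleton_terms_yield_no_classes(self, record_factory, class_map):
        records = [
            record_factory(trial_id="NCT1", intervention_mesh=["Hydroxychloroquine"]),
            record_factory(trial_id="NCT2", intervention_mesh=["Azithromycin"]),
        ]
        spec = fit_drug_feature_spec(records, class_map, min_class_trials=2)
        assert spec.top_classes == []
        assert set(spec.top_drugs) == {"Azithromycin", "Hydroxychloroquine"}

    def test_boundary_ties_break_lexicographically(self, record_factory, class_map):
        records = [
            record_factory(trial_id=f"NCT{i}", intervention_mesh=[term])
            for i, term in enumerate(["Heparin", "Losartan", "Dalteparin"])
        ]
        spec = fit_drug_feature_spec(records, class_map, k_top=2)
        assert spec.top_drugs == ["Dalteparin", "Heparin"]

    def test_one_hot_and_class_counts(self, record_factory, class_map, small_corpus):
        records, _, _ = small_corpus
        spec = fit_drug_feature_spec(records, class_map)
        hcq = record_factory(intervention_mesh=["Hydroxychloroquine"])
        onehot, counts = extract_drug_features(hcq, spec, class_map)
        assert onehot[spec.top_drugs.index("Hydroxychloroquine")] == 1
        assert counts[spec.top_classes.index("Aminoquinolines")] == 1

        double = record_factory(intervention_mesh=["Chloroquine", "Chloroquine diphosphate"])
        _, counts = extract_drug_features(double, spec, class_map)
        assert counts[spec.top_classes.index("Aminoquinolines")] == 2

        empty = record_factory(intervention_mesh=[])
        onehot, counts = extract_drug_features(empty, spec, class_map)
        assert not onehot.any() and not counts.any()

    def test_one_hot_sums_match_fitted_counts(self, class_map, small_corpus):
        records, _, _ = small_corpus
        spec = fit_drug_feature_spec(records, class_map)
        onehots = np.array(
            [extract_drug_features(r, spec, class_map)[0] for r in records]
        )
        for j, term in enumerate(spec.top_drugs):
            assert onehots[:, j].sum() == spec.drug_counts[term]
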