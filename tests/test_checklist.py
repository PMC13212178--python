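"""The 15-criterion checklist: registry, parsing, validation, rendering, tally."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qualcbma import (
    CRITERIA,
    ChecklistDoc,
    ChecklistParseError,
    CriterionEntry,
    StudyRecord,
    checklist_json_schema,
    example_checklist_text,
    load_checklist,
    load_checklists,
    render_markdown,
    tally,
    validate,
)

EXPECTED_EXAMPLE_RESPONSES = {
    1: "no", 2: "yes", 3: "yes", 4: "yes", 5: "yes", 6: "yes", 7: "yes",
    8: "yes", 9: "no", 10: "yes", 11: "no", 12: "yes", 13: "yes", 14: "yes",
    15: "yes",
}


def make_doc(overrides=None, studies=None, modality="other"):
    """A minimal all-yes document, with per-criterion entry overrides."""
    overrides = overrides or {}
    entries = []
    for spec in CRITERIA:
        if spec.id in overrides:
            entries.append(overrides[spec.id])
        else:
            entries.append(CriterionEntry(spec.id, "yes", f"met ({spec.label})"))
    return ChecklistDoc("test", modality, tuple(entries), studies)


class TestRegistry:
    def test_fifteen_criteria_complete(self):
        assert [c.id for c in CRITERIA] == list(range(1, 16))

    def test_na_allowed_only_for_paradigm_and_condition(self):
        assert {c.id for c in CRITERIA if c.allows_na} == {5, 6}

    def test_rule_mapping(self):
        # Each criterion traces to one of the ten simple rules.
        expected = {1: 7, 2: 3, 3: 3, 4: 1, 5: 1, 6: 1, 7: 5, 8: 4, 9: 4,
                    10: 4, 11: 6, 12: 2, 13: 9, 14: 10, 15: 10}
        assert {c.id: c.rule_ref for c in CRITERIA} == expected


class TestLoading:
    def test_example_document_responses(self, example_doc):
        assert example_doc.responses == EXPECTED_EXAMPLE_RESPONSES
        assert example_doc.modality == "other"

    def test_missing_entry_is_atomic_failure(self):
        text = example_checklist_text().replace("    15:", "    notused:")
        with pytest.raises(ChecklistParseError):
            load_checklist(text)

    def test_unknown_response_token(self):
        text = example_checklist_text().replace('response: "yes"',
                                                'response: "maybe"', 1)
        with pytest.raises(ChecklistParseError, match="maybe"):
            load_checklist(text)

    def test_unknown_criterion_id(self):
        text = example_checklist_text().replace("    12:", "    16:")
        with pytest.raises(ChecklistParseError, match="16"):
            load_checklist(text)

    def test_duplicate_id_rejected(self):
        entries = [CriterionEntry(c.id, "yes", "ok") for c in CRITERIA]
        entries[14] = CriterionEntry(1, "yes", "dup")
        with pytest.raises(ChecklistParseError, match="duplicate|missing"):
            ChecklistDoc("dup", "other", tuple(entries))

    def test_multi_analysis_file(self):
        text = example_checklist_text()
        body = text.split("analyses:\n", 1)[1]
        two = "analyses:\n" + body + body.replace(
            "emotion-reappraisal-fmri", "second-analysis"
        )
        docs = load_checklists(two)
        assert [d.analysis_label for d in docs] == [
            "emotion-reappraisal-fmri", "second-analysis"
        ]

    def test_yaml_booleans_map_to_yes_no(self):
        text = example_checklist_text().replace('response: "yes"', "response: true")
        doc = load_checklist(text)
        assert doc.responses[2] == "yes"


class TestValidation:
    def test_example_validates_clean_with_three_unmet_notes(self, example_doc):
        issues = validate(example_doc)
        assert sum(i.severity == "error" for i in issues) == 0
        assert sum(i.severity == "warning" for i in issues) == 0
        notes = [i for i in issues if i.severity == "note"]
        assert sorted(i.criterion_id for i in notes) == [1, 9, 11]

    def test_not_applicable_outside_5_6_is_an_error(self):
        doc = make_doc({4: CriterionEntry(4, "not_applicable", "n/a")})
        errors = [i for i in validate(doc) if i.severity == "error"]
        assert len(errors) == 1 and errors[0].criterion_id == 4

    def test_not_applicable_on_5_is_clean(self):
        doc = make_doc({5: CriterionEntry(5, "not_applicable", "VBM has no paradigm")})
        assert validate(doc) == []

    def test_empty_comment_is_an_error(self):
        doc = make_doc({7: CriterionEntry(7, "yes", "")})
        errors = [i for i in validate(doc) if i.severity == "error"]
        assert len(errors) == 1 and errors[0].criterion_id == 7

    def test_unmet_without_declaration_is_an_error(self):
        doc = make_doc({1: CriterionEntry(1, "no", "not preregistered")})
        errors = [i for i in validate(doc) if i.severity == "error"]
        assert len(errors) == 1 and errors[0].criterion_id == 1

    def test_unmet_declared_not_commented_is_a_warning(self):
        doc = make_doc({1: CriterionEntry(1, "no", "not preregistered", False)})
        sev = {i.severity for i in validate(doc)}
        assert sev == {"warning", "note"}

    def test_criterion12_cross_check_warns_on_small_table(self):
        studies = tuple(StudyRecord(f"s{i}", "one_sample", 20) for i in range(10))
        doc = make_doc(studies=studies)
        issues = validate(doc)
        warnings = [i for i in issues if i.severity == "warning"]
        assert len(warnings) == 1 and warnings[0].criterion_id == 12
        assert "17" in warnings[0].message

    def test_criterion12_cross_check_silent_when_consistent(self):
        studies = tuple(StudyRecord(f"s{i}", "one_sample", 20) for i in range(18))
        assert validate(make_doc(studies=studies)) == []


entry_strategy = st.builds(
    CriterionEntry,
    id=st.sampled_from([c.id for c in CRITERIA]),
    response=st.sampled_from(["yes", "no"]),
    comment=st.text(
        alphabet=st.characters(codec="ascii", exclude_characters="\r\x0b\x0c"),
        min_size=1, max_size=60,
    ).filter(lambda s: s.strip()),
    manuscript_commented=st.sampled_from([None, True, False]),
)


@st.composite
def doc_strategy(draw):
    entries = tuple(
        draw(entry_strategy.map(lambda e, cid=c.id: CriterionEntry(
            cid, e.response, e.comment, e.manuscript_commented)))
        for c in CRITERIA
    )
    label = draw(st.text(
        alphabet=st.characters(codec="ascii", exclude_characters="\r\n"),
        min_size=1, max_size=20).filter(lambda s: s.strip() == s and s))
    modality = draw(st.sampled_from(["structural_mri", "other"]))
    studies = draw(st.one_of(
        st.none(),
        st.lists(
            st.builds(
                StudyRecord,
                id=st.from_regex(r"[a-z][a-z0-9]{0,8}", fullmatch=True),
                design=st.just("one_sample"),
                n1=st.integers(2, 200),
                n2=st.none(),
                has_map=st.booleans(),
            ),
            max_size=5,
        ).map(tuple),
    ))
    return ChecklistDoc(label, modality, entries, studies)


class TestRendering:
    def test_render_contains_example_comment(self, example_doc):
        md = render_markdown(example_doc)
        assert ("The CBMA was not preregistered because the protocol was "
                "created retrospectively during a broader systematic review."
                ) in md

    def test_all_yes_doc_has_no_unmet_markers(self):
        md = render_markdown(make_doc())
        assert "☑ No" not in md and "☑ Yes" in md

    def test_render_load_render_byte_identical(self, example_doc):
        md = render_markdown(example_doc)
        again = render_markdown(load_checklist(md))
        assert again == md

    @given(doc=doc_strategy())
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_round_trip_is_identity(self, doc):
        assert load_checklist(render_markdown(doc)) == doc


class TestTally:
    def test_single_example_doc(self, example_doc):
        t = tally([example_doc])
        assert t.counts[1] == {"yes": 0, "no": 1, "not_applicable": 0}
        assert t.counts[2] == {"yes": 1, "no": 0, "not_applicable": 0}

    def test_empty_collection(self):
        t = tally([])
        assert t.n_docs == 0
        assert all(sum(c.values()) == 0 for c in t.counts.values())

    def test_additivity(self, example_doc):
        one = tally([example_doc])
        three = tally([example_doc] * 3)
        for cid in one.counts:
            for r, c in one.counts[cid].items():
                assert three.counts[cid][r] == 3 * c

    def test_invalid_member_named(self):
        bad = make_doc({3: CriterionEntry(3, "yes", "")})
        with pytest.raises(ValueError, match="test"):
            tally([bad])


def test_json_schema_is_well_formed():
    schema = checklist_json_schema()
    assert schema["oneOf"][0]["properties"]["entries"]["minProperties"] == 15
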