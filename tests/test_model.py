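"""Core data model: construction, validation, JSON/BRAT round trips."""

import pytest

from neurolabel import (
    Entity,
    GeneratorSpec,
    LABELS,
    ObservationType,
    ModifierType,
    Relation,
    RelationType,
    doc_from_json,
    doc_to_json,
    generate,
    parse_brat,
    read_report,
    validate_document,
    write_brat,
    write_xml,
)
from neurolabel.model import (
    BratParseError,
    EmptyReportError,
    ReportError,
    ValidationError,
)


class TestReadReport:
    def test_constructor_contract(self):
        doc = read_report("CT head. No acute infarct.")
        assert len(doc.raw_text) == 26
        assert len(doc.labels) == 24
        assert not any(la.selected for la in doc.labels)
        assert doc.entities == [] and doc.relations == [] and doc.sections == []

    @pytest.mark.parametrize("bad", ["", "   ", "\n\t"])
    def test_empty_report_rejected(self, bad):
        with pytest.raises(EmptyReportError, match="empty report"):
            read_report(bad)

    def test_label_inventory_has_24_members(self):
        assert len(LABELS) == 24
        assert len(set(LABELS)) == 24

    def test_type_enumerations_closed(self):
        assert len(ObservationType) == 13
        assert len(ModifierType) == 4


def _entity_signature(doc):
    return sorted(
        (e.start, e.end, e.etype.value, e.negated, e.nested_with is not None)
        for e in doc.entities
    )


def _relation_signature(doc):
    by_id = {e.entity_id: e for e in doc.entities}
    return sorted(
        (r.rtype.value, by_id[r.observation].start, by_id[r.modifier].start)
        for r in doc.relations
    )


def _label_signature(doc):
    return sorted((la.label, la.selected) for la in doc.labels)


@pytest.fixture(scope="module")
def docs():
    return [r.gold for r in generate(GeneratorSpec(seed=3, n_reports=8))]


class TestSerialisationRoundTrips:
    """Round-trip identity on generated valid documents."""

    def test_json_round_trip_is_identity(self, docs):
        for doc in docs:
            back = doc_from_json(doc_to_json(doc))
            assert back.raw_text == doc.raw_text
            assert back.report_id == doc.report_id
            assert _entity_signature(back) == _entity_signature(doc)
            assert _relation_signature(back) == _relation_signature(doc)
            assert _label_signature(back) == _label_signature(doc)
            assert [s.kind for s in back.sections] == [s.kind for s in doc.sections]
            validate_document(back)

    def test_brat_round_trip_preserves_annotations(self, docs):
        for doc in docs:
            ann, txt = write_brat(doc)
            back = parse_brat(ann, txt, report_id=doc.report_id)
            assert _entity_signature(back) == _entity_signature(doc)
            assert _relation_signature(back) == _relation_signature(doc)
            assert _label_signature(back) == _label_signature(doc)
            validate_document(back)

    def test_three_section_report_survives_json(self):
        text = "Clinical details: fall.\nReport: Old infarct.\nConclusion: ok.\n"
        doc = read_report(text, report_id="r1")
        from neurolabel import zone

        zone(doc)
        back = doc_from_json(doc_to_json(doc))
        assert [(s.kind, s.start, s.end) for s in back.sections] == [
            (s.kind, s.start, s.end) for s in doc.sections
        ]


class TestBratWriter:
    def test_minimal_document_line_counts(self):
        doc = read_report("scan shows small vessel disease today")
        doc.entities = [
            Entity("T1", ObservationType.SMALL_VESSEL_DISEASE, 11, 31)
        ]
        ann, txt = write_brat(doc)
        lines = ann.strip().splitlines()
        assert len([l for l in lines if l.startswith("T")]) == 1
        assert not any(l.startswith("A") for l in lines)
        assert not any(l.startswith("R") for l in lines)
        assert txt == doc.raw_text

    def test_marked_up_sentence_line_counts(self, annotate_fn):
        # two stroke mentions, three modifiers, two negated entities,
        # two explicit relations on the first stroke
        doc = annotate_fn("Old thalamic infarcts. No acute infarction.")
        ann, _ = write_brat(doc)
        lines = ann.strip().splitlines()
        assert len([l for l in lines if l.startswith("T")]) == 5
        assert len([l for l in lines if l.startswith("A")]) == 2
        assert len([l for l in lines if l.startswith("R")]) == 3
        first_stroke_rels = [
            l for l in lines if l.startswith("R") and "Arg1:T3" in l
        ]
        assert len(first_stroke_rels) == 2  # one mod-time, one mod-loc

    def test_dangling_relation_endpoint_rejected(self):
        doc = read_report("plain infarct here")
        doc.entities = [Entity("T1", ObservationType.ISCHAEMIC_STROKE, 6, 13)]
        doc.relations = [Relation(RelationType.MOD_TIME, "T1", "T99")]
        with pytest.raises(ReportError, match="dangling"):
            write_brat(doc)


class TestBratParser:
    def test_reversed_offsets_rejected(self):
        with pytest.raises(BratParseError, match="line 1"):
            parse_brat("T1\tatrophy 5 2\tfoo\n", "some atrophy here")

    def test_attribute_to_missing_entity_rejected(self):
        with pytest.raises(BratParseError, match="T9"):
            parse_brat("A1\tNegated T9\n", "text")

    def test_unknown_type_tag_rejected(self):
        with pytest.raises(BratParseError, match="unknown entity type"):
            parse_brat("T1\tbanana 0 4\ttext", "text")

    def test_surface_mismatch_rejected(self):
        with pytest.raises(BratParseError, match="does not match"):
            parse_brat("T1\tatrophy 0 4\tWRNG", "text here")

    def test_microhaemorrhage_alias_accepted(self):
        doc = parse_brat("T1\tmicrohaemorrhage 2 12\tmicrobleed\n",
                         "a microbleed here")
        assert doc.entities[0].etype is ObservationType.MICROBLEED


class TestValidator:
    def test_overlapping_observations_rejected(self):
        doc = read_report("an infarct infarction pair")
        doc.entities = [
            Entity("T1", ObservationType.ISCHAEMIC_STROKE, 3, 12),
            Entity("T2", ObservationType.ATROPHY, 10, 20),
        ]
        with pytest.raises(ValidationError, match="overlap"):
            validate_document(doc)

    def test_selected_label_requires_evidence(self):
        doc = read_report("small vessel disease")
        doc.label_assignment("Atrophy").selected = True
        with pytest.raises(ValidationError, match="evidence"):
            validate_document(doc)

    def test_selected_label_rejects_negated_evidence(self):
        doc = read_report("small vessel disease")
        doc.entities = [
            Entity("T1", ObservationType.SMALL_VESSEL_DISEASE, 0, 20,
                   negated=True)
        ]
        la = doc.label_assignment("Small vessel disease")
        la.selected, la.evidence = True, ["T1"]
        with pytest.raises(ValidationError, match="negated"):
            validate_document(doc)

    def test_relation_type_constraints_enforced(self):
        # a microbleed may take a location but never a time modifier
        doc = read_report("acute microbleed")
        doc.entities = [
            Entity("T1", ModifierType.TIME_RECENT, 0, 5),
            Entity("T2", ObservationType.MICROBLEED, 6, 16),
        ]
        doc.relations = [Relation(RelationType.MOD_TIME, "T2", "T1")]
        with pytest.raises(ValidationError, match="mod-time"):
            validate_document(doc)


def test_xml_writer_emits_sections_labels_and_entities(annotate_fn):
    from lxml import etree

    doc = annotate_fn("Report: Old deep infarct.\nConclusion: atrophy.")
    root = etree.fromstring(write_xml(doc).encode())
    assert root.get("schema") == "neurolabel-xml-1"
    assert len(root.findall(".//label")) == 24
    selected = [el.get("name") for el in root.findall(".//label")
                if el.get("selected") == "true"]
    assert "Ischaemic stroke, deep, old" in selected
    assert {el.get("kind") for el in root.findall("section")} == {
        "report_body", "conclusion"
    }
    assert len(root.findall(".//entity")) == len(doc.entities)
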