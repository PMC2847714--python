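"""EQ descriptions: translation bijection, renderings, absence handling."""

import pytest
from hypothesis import given, settings, strategies as st

from phenoxp.eq_model import (
    ClassExpression,
    EQDescription,
    RelationVocabulary,
    denormalize_entity_whole,
    eq_to_intersection,
    expression_id,
    intersection_to_eq,
    normalize_entity_whole,
    parse_eq_text,
    translate_absence,
    write_eq_text,
    write_manchester,
)
from phenoxp.errors import (
    AmbiguousCompositionError,
    EQSyntaxError,
    GenusNotAQualityError,
    IncompleteDescriptionError,
    NotAnEQDefinitionError,
    UnsupportedCardinalityError,
    UnsupportedPatternError,
)
from phenoxp.obo_io import IntersectionClause

E = ClassExpression.named
C = ClassExpression.composed


def clause_pairs(clauses):
    return [(c.relation, c.filler) for c in clauses]


def test_femur_shape_translation():
    clauses, aux = eq_to_intersection(EQDescription(E("MA:0001359"), "PATO:0000052"))
    assert clause_pairs(clauses) == [(None, "PATO:0000052"), ("inheres_in", "MA:0001359")]
    assert aux == []


def test_spleen_iron_four_clause_pattern():
    eq = EQDescription(E("MA:0000141"), "PATO:0000033", entity2=E("CHEBI:18248"), modifier="PATO:0000460")
    clauses, _ = eq_to_intersection(eq)
    assert clause_pairs(clauses) == [
        (None, "PATO:0000033"),
        ("inheres_in", "MA:0000141"),
        ("towards", "CHEBI:18248"),
        ("has_qualifier", "PATO:0000460"),
    ]


def test_table4_rows_round_trip(paper_fixture):
    """Every published example mapping survives EQ -> clauses -> EQ."""
    for _pid, _label, eq in paper_fixture.table4:
        clauses, aux_stanzas = eq_to_intersection(eq)
        context = []
        if aux_stanzas:
            from phenoxp.obo_io import OntologyDocument

            context = [OntologyDocument(stanzas=aux_stanzas)]
        back = intersection_to_eq(clauses, context=context)
        assert back == eq, eq


def test_nested_bearer_materializes_auxiliary_stanza():
    eq = EQDescription(C("GO:0030425", [("part_of", E("CL:0000121"))]), "PATO:0000051")
    clauses, aux = eq_to_intersection(eq)
    assert len(aux) == 1
    assert aux[0].id == expression_id(eq.entity)
    assert clause_pairs(aux[0].intersection_clauses) == [(None, "GO:0030425"), ("part_of", "CL:0000121")]
    assert clauses[1].filler == aux[0].id
    # deterministic across repeated materialization
    clauses2, aux2 = eq_to_intersection(eq)
    assert aux2[0].id == aux[0].id and clause_pairs(clauses2) == clause_pairs(clauses)


def test_entity_whole_normalization_inverse():
    eq = EQDescription(E("GO:0030425"), "PATO:0000051", modifier="PATO:0000460", entity_whole=E("CL:0000121"))
    norm = normalize_entity_whole(eq)
    assert norm.entity == C("GO:0030425", [("part_of", E("CL:0000121"))])
    assert norm.entity_whole is None
    assert denormalize_entity_whole(norm) == eq


def test_entity_whole_with_composed_entity_is_ambiguous():
    with pytest.raises(AmbiguousCompositionError):
        EQDescription(
            C("GO:0030425", [("part_of", E("CL:0000121"))]),
            "PATO:0000051",
            entity_whole=E("CL:0000121"),
        )


def test_expression_equality_is_order_canonical():
    a = C("Q:1", [("r", E("A:1")), ("s", E("B:1"))])
    b = C("Q:1", [("s", E("B:1")), ("r", E("A:1"))])
    assert a == b and hash(a) == hash(b) and expression_id(a) == expression_id(b)


# -- inverse translation errors ---------------------------------------------


def test_two_inheres_in_differentia_rejected():
    clauses = [
        IntersectionClause(None, "PATO:0000052"),
        IntersectionClause("inheres_in", "MA:1"),
        IntersectionClause("inheres_in", "MA:2"),
    ]
    with pytest.raises(NotAnEQDefinitionError):
        intersection_to_eq(clauses)


def test_missing_inheres_in_rejected():
    with pytest.raises(NotAnEQDefinitionError):
        intersection_to_eq([IntersectionClause(None, "PATO:0000052"), IntersectionClause("towards", "MA:1")])


def test_unsupported_differentium_relation_named():
    clauses = [
        IntersectionClause(None, "PATO:0000052"),
        IntersectionClause("inheres_in", "MA:1"),
        IntersectionClause("during", "GO:1"),
    ]
    with pytest.raises(UnsupportedPatternError, match="during"):
        intersection_to_eq(clauses)


def test_strict_quality_genus_check(paper_fixture):
    clauses = [IntersectionClause(None, "MA:0000236"), IntersectionClause("inheres_in", "MA:0001359")]
    with pytest.raises(GenusNotAQualityError):
        intersection_to_eq(clauses, context=[paper_fixture.mini_pato], strict_quality=True)
    ok = [IntersectionClause(None, "PATO:0000586"), IntersectionClause("inheres_in", "MA:0000236")]
    eq = intersection_to_eq(ok, context=[paper_fixture.mini_pato], strict_quality=True)
    assert eq.quality == "PATO:0000586"


# -- EQ line syntax ----------------------------------------------------------


def test_parse_hypocalciuria_lines(paper_lexicon):
    records = parse_eq_text("E = urine\nQ = decreased concentration of\nE2 = calcium\n", paper_lexicon)
    (_id, eq), = records
    assert eq == EQDescription(E("MA:0002504"), "PATO:0001163", entity2=E("CHEBI:22984"))


def test_parse_caret_composition_depth_two():
    records = parse_eq_text("E = GO:0030425^part_of(CL:0000121)\nQ = PATO:0000051\n")
    assert records[0][1].entity == C("GO:0030425", [("part_of", E("CL:0000121"))])
    assert records[0][1].entity.depth() == 2


def test_missing_quality_is_incomplete():
    with pytest.raises(IncompleteDescriptionError, match="Q"):
        parse_eq_text("E = femur\n")


def test_unbalanced_caret_reports_offset():
    with pytest.raises(EQSyntaxError) as err:
        parse_eq_text("E = A:1^part_of(B:1\nQ = PATO:0000051\n")
    assert err.value.offset is not None


def test_eq_text_round_trip():
    text = (
        "ID = MP:0008572\nE = GO:0030425^part_of(CL:0000121)\nQ = PATO:0000051\nM = PATO:0000460\n"
        "\nID = MP:8000006\nE = MA:0000029\nQ = PATO:0002000\nE2 = MA:0000141\n"
    )
    records = parse_eq_text(text)
    assert parse_eq_text(write_eq_text(records)) == records


# -- Manchester rendering ----------------------------------------------------


def test_manchester_nested_purkinje_dendrite(paper_labels):
    eq = EQDescription(
        E("GO:0030425"), "PATO:0000051", modifier="PATO:0000460", entity_whole=E("CL:0000121")
    )
    assert write_manchester(eq, paper_labels) == (
        "morphology that inheres_in some (dendrite that part_of some Purkinje cell) "
        "and has_qualifier some abnormal"
    )


def test_manchester_simple_and_fallback(paper_labels):
    assert write_manchester(EQDescription(E("MA:0001359"), "PATO:0000052"), paper_labels) == (
        "shape that inheres_in some femur"
    )
    # missing label falls back to the CURIE, never fails
    assert write_manchester(EQDescription(E("MA:9999999"), "PATO:0000052"), paper_labels) == (
        "shape that inheres_in some MA:9999999"
    )


# -- absence -----------------------------------------------------------------


def test_absent_spleen_relational_mode(paper_labels):
    eq = EQDescription(E("MA:0000029"), "PATO:0002000", entity2=E("MA:0000141"))
    clauses = translate_absence(eq, "relational")
    assert clause_pairs(clauses) == [
        (None, "PATO:0002000"),
        ("inheres_in", "MA:0000029"),
        ("towards", "MA:0000141"),
    ]


def test_absent_spleen_cardinality_mode(paper_labels):
    eq = EQDescription(E("MA:0000029"), "PATO:0002000", entity2=E("MA:0000141"))
    assert translate_absence(eq, "cardinality", labels=paper_labels) == (
        "Abdomen that has_part exactly 0 spleen"
    )


def test_relative_count_has_no_cardinality_form(paper_labels):
    eq = EQDescription(E("MA:0000184"), "PATO:0002001", entity2=E("CL:0000540"))
    with pytest.raises(UnsupportedCardinalityError):
        translate_absence(eq, "cardinality", labels=paper_labels)


# -- property-based translation bijection ------------------------------------

curies = st.from_regex(r"[A-Z]{2}:[0-9]{4}", fullmatch=True)


@st.composite
def class_expressions(draw, depth=2):
    if depth == 0 or draw(st.booleans()):
        return E(draw(curies))
    n = draw(st.integers(1, 2))
    diffs = [
        (draw(st.sampled_from(["part_of", "develops_from"])), draw(class_expressions(depth=depth - 1)))
        for _ in range(n)
    ]
    return C(draw(curies), diffs)


eq_descriptions = st.builds(
    EQDescription,
    entity=class_expressions(),
    quality=curies,
    entity2=st.one_of(st.none(), class_expressions()),
    modifier=st.one_of(st.none(), curies),
)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(eq_descriptions)
def test_translation_bijection(eq):
    from phenoxp.obo_io import OntologyDocument

    clauses, aux = eq_to_intersection(eq)
    context = [OntologyDocument(stanzas=aux)] if aux else []
    assert intersection_to_eq(clauses, context=context) == eq


@settings(max_examples=150, deadline=None, derandomize=True)
@given(eq_descriptions)
def test_manchester_relation_multiplicities(eq):
    text = write_manchester(eq)
    assert text.count("inheres_in some") == 1
    assert text.count("towards some") <= 1
    assert text.count("has_qualifier some") <= 1
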