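"""Label decomposition: productions, lexicons, ambiguity, batch parsing."""

import random

import pytest

from phenoxp import fixtures as fx
from phenoxp.eq_model import ClassExpression
from phenoxp.label_grammar import (
    UNRESOLVED,
    batch_parse,
    build_lexicon,
    parse_label,
    write_curation_queue,
)
from phenoxp.obo_io import OntologyDocument, TermStanza

E = ClassExpression.named
C = ClassExpression.composed


def test_big_ears_decomposition(paper_lexicon):
    result = parse_label("big ears", paper_lexicon)
    assert not result.is_ambiguous
    (cand,) = result.candidates
    assert cand.eq.entity == E("MA:0000236")
    assert cand.eq.quality == "PATO:0000586"
    assert cand.rule == "quality-bearer"


def test_quality_of_bearer(paper_lexicon):
    (cand,) = parse_label("decreased diameter of femur", paper_lexicon).candidates
    assert (cand.eq.entity, cand.eq.quality) == (E("MA:0001359"), "PATO:0001715")


def test_nested_bearer_decomposition(paper_lexicon):
    (cand,) = parse_label("abnormal Purkinje cell dendrite morphology", paper_lexicon).candidates
    assert cand.eq.entity == C("GO:0030425", [("part_of", E("CL:0000121"))])
    assert cand.eq.quality == "PATO:0000051"
    assert cand.eq.modifier == "PATO:0000460"
    assert cand.rule.endswith("+compound-bearer")


def test_abnormality_of_bearer_uses_quality_root(paper_lexicon):
    (cand,) = parse_label("abnormality of vision", paper_lexicon).candidates
    assert cand.eq.quality == "PATO:0000001"
    assert cand.eq.entity == E("GO:0007601")
    assert cand.eq.modifier == "PATO:0000460"


def test_clinical_term_yields_empty_candidates(paper_lexicon):
    result = parse_label("situs inversus", paper_lexicon)
    assert result.candidates == []
    assert result.unmatched_tokens == ["situs", "inversus"]


def test_absent_bearer_leaves_entity_unresolved(paper_lexicon):
    (cand,) = parse_label("absent spleen", paper_lexicon).candidates
    assert cand.eq.entity == E(UNRESOLVED)
    assert cand.eq.entity2 == E("MA:0000141")
    assert cand.eq.quality == "PATO:0002000"


def test_plural_normalization_irregular(paper_lexicon):
    (cand,) = parse_label("big teeth", paper_lexicon).candidates
    assert cand.eq.entity == E("MA:0000348")


def test_bearer_collision_preserved():
    a = OntologyDocument(stanzas=[TermStanza(id="MA:1", name="ear")])
    b = OntologyDocument(stanzas=[TermStanza(id="ZFA:1", name="ear")])
    q = OntologyDocument(stanzas=[TermStanza(id="PATO:1", name="big")])
    lex = build_lexicon([(q, "quality"), (a, "gross-anatomy"), (b, "gross-anatomy")])
    result = parse_label("big ear", lex)
    assert result.is_ambiguous
    assert {c.eq.entity.genus for c in result.candidates} == {"MA:1", "ZFA:1"}


def test_non_exact_synonyms_excluded_from_lexicon():
    doc = OntologyDocument(stanzas=[TermStanza(id="MA:1", name="ear", synonyms=[("lug", "RELATED")])])
    lex = build_lexicon([(doc, "gross-anatomy")])
    assert lex.lookup_bearer(("lug",)) == []
    assert lex.lookup_bearer(("ear",)) == [("MA:1", "gross-anatomy")]


def test_determinism(paper_lexicon):
    r1 = parse_label("abnormal Purkinje cell dendrite morphology", paper_lexicon)
    r2 = parse_label("abnormal Purkinje cell dendrite morphology", paper_lexicon)
    assert r1.candidates == r2.candidates


def test_synthesized_labels_recover_generating_pair():
    """Soundness: quality-label + bearer-label compositions parse back to
    exactly the generating (Q, E) pair, 500 seeded compositions."""
    suite = fx.generate_suite(fx.GeneratorParams(seed=11, n_quality=25, n_entity=40))
    lex = build_lexicon([(suite.quality_doc, "quality"), (suite.entity_doc, "gross-anatomy")])
    rng = random.Random(2024)
    q_ids = suite.quality_doc.ids()
    e_ids = suite.entity_doc.ids()
    labels = {**suite.quality_doc.labels(), **suite.entity_doc.labels()}
    for _ in range(500):
        q, e = rng.choice(q_ids), rng.choice(e_ids)
        result = parse_label(f"{labels[q]} {labels[e]}", lex)
        assert len(result.candidates) == 1
        cand = result.candidates[0]
        assert (cand.eq.quality, cand.eq.entity) == (q, E(e))


def test_batch_parse_coverage_and_queue(paper_lexicon):
    labels = [
        ("MPT:1", "big ears"),
        ("MPT:2", "decreased diameter of femur"),
        ("MPT:3", "abnormal ear morphology"),
        ("MPT:4", "abnormal Purkinje cell dendrite morphology"),
        ("MPT:5", "truncated femur"),
        ("MPT:6", "spherical erythrocyte"),
        ("MPT:7", "abnormality of vision"),
        ("MPT:8", "situs inversus"),
        ("MPT:9", "hypocalciuria"),
        ("MPT:10", "spherocytosis"),
    ]
    doc = OntologyDocument(stanzas=[TermStanza(id=i, name=n) for i, n in labels])
    report = batch_parse(doc, paper_lexicon)
    assert report.coverage == pytest.approx(0.70)
    assert {e.class_id for e in report.queue} == {"MPT:8", "MPT:9", "MPT:10"}
    accepted = {s.id for s in report.stanzas if not s.id.startswith("XP:")}
    assert accepted == {"MPT:1", "MPT:2", "MPT:3", "MPT:4", "MPT:5", "MPT:6", "MPT:7"}
    # nested bearer came with its auxiliary stanza
    assert any(s.id.startswith("XP:") for s in report.stanzas)


def test_batch_parse_empty_ontology(paper_lexicon):
    report = batch_parse(OntologyDocument(), paper_lexicon)
    assert report.stanzas == [] and report.queue == [] and report.coverage == 0.0


def test_ambiguous_label_lists_all_candidates_in_queue():
    a = OntologyDocument(stanzas=[TermStanza(id="MA:1", name="ear")])
    b = OntologyDocument(stanzas=[TermStanza(id="ZFA:1", name="ear")])
    q = OntologyDocument(stanzas=[TermStanza(id="PATO:1", name="big")])
    lex = build_lexicon([(q, "quality"), (a, "gross-anatomy"), (b, "gross-anatomy")])
    pheno = OntologyDocument(stanzas=[TermStanza(id="P:1", name="big ear")])
    report = batch_parse(pheno, lex)
    assert report.coverage == 0.0
    (entry,) = report.queue
    assert entry.reason == "ambiguous" and len(entry.candidates) == 2
    text = write_curation_queue(report.queue)
    assert "MA:1" in text and "ZFA:1" in text
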