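"""Closure reasoner: rules, oracle equivalence, novel links, queries."""

import random

import pytest

from phenoxp import fixtures as fx
from phenoxp._naive import naive_closure
from phenoxp.errors import CycleError, UnknownClassError
from phenoxp.eq_model import ClassExpression, EQDescription
from phenoxp.obo_io import (
    LinkClause,
    OntologyDocument,
    TermStanza,
    merge_documents,
    parse_obo,
    write_obo,
)
from phenoxp.reasoner import (
    Edge,
    RuleConfig,
    apply_definitions,
    compute_closure,
    infer_novel_links,
    materialize_expressions,
    merge_bridge,
    query_phenotypes_by_entity,
)

E = ClassExpression.named
C = ClassExpression.composed


def closure_of(paper_fixture, mp_doc=None, config=None, bridge=False):
    pf = paper_fixture
    merged = merge_documents([mp_doc or pf.mini_mp] + pf.support_docs)
    merged = apply_definitions(merged, pf.xp_defs)
    if bridge:
        merged = merge_bridge(merged, pf.mini_bridge)
    return compute_closure(merged, config)


def test_is_a_chain_transitivity():
    doc = parse_obo("[Term]\nid: A:1\nis_a: A:2\n\n[Term]\nid: A:2\nis_a: A:3\n\n[Term]\nid: A:3\n")
    closure = compute_closure(doc)
    assert closure.has("A:1", "is_a", "A:3")


def test_declared_transitive_relation_closure():
    text = (
        "[Term]\nid: A:1\nrelationship: part_of A:2\n\n[Term]\nid: A:2\nrelationship: part_of A:3\n\n"
        "[Term]\nid: A:3\n\n[Typedef]\nid: part_of\nis_transitive: true\n"
    )
    closure = compute_closure(parse_obo(text))
    assert closure.has("A:1", "part_of", "A:3")


def test_composition_with_is_a_both_sides():
    text = (
        "[Term]\nid: A:1\nis_a: A:2\n\n[Term]\nid: A:2\nrelationship: develops_from A:3\n\n"
        "[Term]\nid: A:3\nis_a: A:4\n\n[Term]\nid: A:4\n"
    )
    closure = compute_closure(parse_obo(text))
    assert closure.has("A:1", "develops_from", "A:3")  # A is_a B, B r C
    assert closure.has("A:2", "develops_from", "A:4")  # A r B, B is_a C


def test_figure2_inference_present_in_closure(paper_fixture):
    closure = closure_of(paper_fixture)
    assert closure.has("MP:8000001", "is_a", "MP:0003224")  # Purkinje cell deg is_a neuron deg
    assert closure.has("MP:8000001", "is_a", "MP:0002229")


def test_withheld_links_proposed_with_cl_provenance(paper_fixture):
    closure = closure_of(paper_fixture, mp_doc=paper_fixture.mini_mp_withheld)
    novel = infer_novel_links(closure, "MP")
    assert [(e.subject, e.object) for e in novel] == [
        ("MP:0000938", "MP:0003224"),
        ("MP:8000001", "MP:0002229"),
    ]
    # provenance chain of the Purkinje proposal passes through the CL hierarchy
    chain = closure.provenance_chain(Edge("MP:8000001", "is_a", "MP:0002229"))
    chain_edges = {e.as_tuple() for e, _ in chain}
    assert ("CL:0000121", "is_a", "CL:0000117") in chain_edges


def test_no_novel_links_without_definitions(paper_fixture):
    merged = merge_documents([paper_fixture.mini_mp] + paper_fixture.support_docs)
    closure = compute_closure(merged)
    assert infer_novel_links(closure, "MP") == []


def test_indirect_inferences_filtered_from_novel(paper_fixture):
    closure = closure_of(paper_fixture, mp_doc=paper_fixture.mini_mp_withheld)
    novel_pairs = {(e.subject, e.object) for e in infer_novel_links(closure, "MP")}
    # entailed but indirect (via neurodegeneration): not proposed
    assert closure.has("MP:8000001", "is_a", "MP:0003224")
    assert ("MP:8000001", "MP:0003224") not in novel_pairs


@pytest.mark.parametrize("seed", range(200))
def test_oracle_equivalence_on_random_documents(seed):
    """Production closure equals independent naive saturation edge-for-edge."""
    doc = fx.generate_random_document(seed, max_classes=40)
    production = {e.as_tuple() for e in compute_closure(doc).edges}
    assert production == naive_closure(doc)


def test_rule_order_independence():
    doc = fx.generate_random_document(7, max_classes=40)
    baseline = {e.as_tuple() for e in compute_closure(doc).edges}
    for i in range(20):
        shuffled = {e.as_tuple() for e in compute_closure(doc, agenda_rng=random.Random(i)).edges}
        assert shuffled == baseline


def test_closure_idempotent():
    doc = fx.generate_random_document(13, max_classes=30)
    closure = compute_closure(doc)
    # re-feed the closure as a plain document: nothing new may appear
    refeed = OntologyDocument()
    stanzas: dict[str, TermStanza] = {c: TermStanza(id=c) for c in closure.classes}
    for e in closure.edges:
        if e.relation == "is_a":
            stanzas[e.subject].is_a_parents.append(e.object)
        else:
            stanzas[e.subject].relationships.append(LinkClause(e.relation, e.object))
    refeed.stanzas = list(stanzas.values())
    refeed.typedefs = list(doc.typedefs)
    again = {e.as_tuple() for e in compute_closure(refeed).edges}
    assert again == {e.as_tuple() for e in closure.edges}


def test_monotonicity():
    doc = fx.generate_random_document(21, max_classes=25)
    before = {e.as_tuple() for e in compute_closure(doc).edges}
    asserted = {
        (s.id, "is_a", p) for s in doc.stanzas for p in s.is_a_parents
    } | {(s.id, r.relation, r.target) for s in doc.stanzas for r in s.relationships}
    assert asserted - {(a, r, b) for (a, r, b) in asserted if a == b} <= before
    # adding an assertion never removes an entailment
    doc.stanzas[0].relationships.append(LinkClause("part_of", doc.stanzas[-1].id))
    after = {e.as_tuple() for e in compute_closure(doc).edges}
    assert before <= after


def test_asserted_is_a_cycle_detected():
    doc = parse_obo("[Term]\nid: A:1\nis_a: A:2\n\n[Term]\nid: A:2\nis_a: A:1\n")
    with pytest.raises(CycleError) as err:
        compute_closure(doc)
    assert set(err.value.cycle) == {"A:1", "A:2"}


def test_reflexive_edges_suppressed():
    doc = parse_obo("[Term]\nid: A:1\nis_a: A:2\n\n[Term]\nid: A:2\n")
    closure = compute_closure(doc)
    assert not closure.has("A:1", "is_a", "A:1")


def test_quality_propagation_emits_distinct_relation(paper_fixture):
    config = RuleConfig(quality_propagates_over_part_of=True)
    closure = closure_of(paper_fixture, config=config)
    # asymmetric snout inheres_in snout, snout part_of face
    assert closure.has("MP:8000003", "inheres_in_part_of", "MA:0000062")
    assert not closure.has("MP:8000003", "inheres_in", "MA:0000062")
    # off by default: no edge ever carries R6 provenance
    default = closure_of(paper_fixture)
    assert not any(p.rule == "R6" for p in default.edges.values())
    assert any(p.rule == "R6" for p in closure.edges.values())


def test_materialize_expressions_deterministic():
    records = [
        ("MP:1", EQDescription(C("GO:1", [("part_of", E("CL:1"))]), "PATO:1")),
        ("MP:2", EQDescription(C("GO:1", [("part_of", E("CL:1"))]), "PATO:2")),
    ]
    doc1 = materialize_expressions(records)
    doc2 = materialize_expressions(records)
    assert write_obo(doc1) == write_obo(doc2)
    # shared composed expression materialized once
    assert sum(1 for s in doc1.stanzas if s.id.startswith("XP:")) == 1


def test_apply_definitions_attaches_clauses(paper_fixture):
    merged = merge_documents([paper_fixture.mini_mp] + paper_fixture.support_docs)
    combined = apply_definitions(merged, paper_fixture.xp_defs)
    assert combined["MP:0000017"].genus == "PATO:0000586"
    assert combined["MP:0000017"].name == "big ears"
    # named-entity-only definition set adds no stanzas beyond XP auxiliaries
    xp_only = {s.id for s in combined.stanzas} - {s.id for s in merged.stanzas}
    assert all(i.startswith("XP:") for i in xp_only)


def test_query_by_entity_with_bridge(paper_fixture):
    closure = closure_of(paper_fixture, bridge=True)
    assert query_phenotypes_by_entity(closure, "UBERON:0001091") == ["MP:0002100"]
    # without the bridge the multi-species query returns nothing
    closure_nb = closure_of(paper_fixture)
    assert "UBERON:0001091" not in closure_nb.classes


def test_query_by_entity_subsumption(paper_fixture):
    closure = closure_of(paper_fixture)
    hits = query_phenotypes_by_entity(closure, "CL:0000540")  # neuron
    assert {"MP:8000001", "MP:0000938", "MP:0002229", "MP:0003224"} <= set(hits)
    assert query_phenotypes_by_entity(closure, "CHEBI:22676") == []  # auxin: no definition
    with pytest.raises(UnknownClassError):
        query_phenotypes_by_entity(closure, "MA:404")
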