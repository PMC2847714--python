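"""Forward-chaining fixpoint reasoner over merged ontology documents.

The rule set (applied to a least fixpoint; termination is guaranteed because
the edge universe is bounded by |classes|^2 * |relations|):

R1  is_a transitivity:            A is_a B, B is_a C  =>  A is_a C
R2  declared-transitive closure:  A r B,  B r C       =>  A r C    (r transitive)
R3  composition with is_a:        A r B,  B is_a C    =>  A r C
                                  A is_a B, B r C     =>  A r C
R4  definition necessity:         X == G and {(ri, Fi)}  =>  X is_a G, X ri Fi
R5  definition sufficiency:       Z is_a G, Z ri Fi (all i)  =>  Z is_a X
R6  (optional, off by default) quality propagation over part_of:
                                  Q inheres_in P, P part_of W
                                      =>  Q inheres_in_part_of W

R6 deliberately produces a *distinct* relation: a quality of a part is not
in general a quality of the whole, so propagated bearers never masquerade
as plain ``inheres_in`` differentia.

Reflexive is_a edges are used internally when matching R5 premises but are
suppressed from all outputs.  Evaluation is semi-naive (rules re-fire only
against the newest edge delta) followed by a full verification sweep;
correctness is anchored to the independent naive oracle in
:mod:`phenoxp._naive`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from phenoxp.errors import CycleError, UnknownClassError
from phenoxp.eq_model import DEFAULT_VOCAB, EQDescription, RelationVocabulary, eq_to_intersection
from phenoxp.obo_io import IntersectionClause, OntologyDocument, TermStanza

IS_A = "is_a"


@dataclass(frozen=True)
class Edge:
    subject: str
    relation: str
    object: str

    def as_tuple(self) -> tuple[str, str, str]:
        return (self.subject, self.relation, self.object)


@dataclass(frozen=True)
class Provenance:
    """How an edge entered the closure.

    Asserted edges carry no rule; inferred edges carry the rule name and at
    least one premise edge (definition-necessity edges cite the defined
    class itself as their origin, with no premise edges).
    """

    status: str  # "asserted" | "inferred"
    rule: str | None = None
    premises: tuple[Edge, ...] = ()


@dataclass
class RuleConfig:
    transitive_relations: set[str] = field(default_factory=lambda: {IS_A, "part_of"})
    composition_over_is_a: bool = True
    quality_propagates_over_part_of: bool = False
    emit_reflexive: bool = False
    propagated_relation: str = "inheres_in_part_of"

    def __post_init__(self):
        self.transitive_relations = set(self.transitive_relations) | {IS_A}


@dataclass
class ClosureGraph:
    classes: set[str]
    edges: dict[Edge, Provenance]
    definitions: dict[str, list[IntersectionClause]]
    rule_config: RuleConfig
    labels: dict[str, str] = field(default_factory=dict)

    def has(self, subject: str, relation: str, object: str) -> bool:
        return Edge(subject, relation, object) in self.edges

    def edge_set(self, relation: str | None = None, status: str | None = None) -> set[Edge]:
        out = set()
        for e, prov in self.edges.items():
            if relation is not None and e.relation != relation:
                continue
            if status is not None and prov.status != status:
                continue
            out.add(e)
        return out

    def superclasses(self, class_id: str) -> set[str]:
        """Non-reflexive is_a ancestors in the closure."""
        return {e.object for e in self.edges if e.relation == IS_A and e.subject == class_id}

    def provenance_chain(self, edge: Edge) -> list[tuple[Edge, Provenance]]:
        """Depth-first expansion of an edge's premises, for curator review."""
        chain: list[tuple[Edge, Provenance]] = []
        seen: set[Edge] = set()

        def walk(e: Edge):
            if e in seen or e not in self.edges:
                return
            seen.add(e)
            prov = self.edges[e]
            chain.append((e, prov))
            for p in prov.premises:
                walk(p)

        walk(edge)
        return chain


# ---------------------------------------------------------------------------
# Definition handling
# ---------------------------------------------------------------------------


def materialize_expressions(
    eq_records: list[tuple[str, EQDescription]],
    vocab: RelationVocabulary = DEFAULT_VOCAB,
) -> OntologyDocument:
    """Turn EQ definitions into an XP definition document.

    Each ``(class id, EQDescription)`` becomes a stanza holding the
    intersection clauses; composed bearer expressions (at any nesting depth)
    become auxiliary stanzas with deterministic content-hashed identifiers.
    After materialization the document contains only named references, and
    re-materializing is id-stable.
    """
    doc = OntologyDocument(ontology_id="xp-definitions")
    emitted: set[str] = set()
    for class_id, eq in eq_records:
        clauses, aux = eq_to_intersection(eq, vocab)
        for stanza in aux:
            if stanza.id not in emitted:
                emitted.add(stanza.id)
                doc.stanzas.append(stanza)
        doc.stanzas.append(TermStanza(id=class_id, intersection_clauses=clauses))
    doc.validate()
    return doc


def apply_definitions(doc: OntologyDocument, xp_defs: OntologyDocument) -> OntologyDocument:
    """Attach XP definition clauses to their classes in ``doc``.

    Definition stanzas whose id already exists in ``doc`` contribute their
    intersection clauses to that class; stanzas for unknown ids (materialized
    expression classes, or definitions of classes from unloaded ontologies)
    are added as new stanzas.
    """
    out = OntologyDocument(
        ontology_id=doc.ontology_id, header_lines=list(doc.header_lines), typedefs=list(doc.typedefs)
    )
    by_id = {s.id: s for s in xp_defs.stanzas if s.intersection_clauses}
    for s in doc.stanzas:
        if s.id in by_id and not s.intersection_clauses:
            merged = TermStanza(
                id=s.id,
                name=s.name,
                namespace=s.namespace,
                synonyms=list(s.synonyms),
                is_a_parents=list(s.is_a_parents),
                relationships=list(s.relationships),
                intersection_clauses=list(by_id.pop(s.id).intersection_clauses),
                is_obsolete=s.is_obsolete,
                opaque_lines=list(s.opaque_lines),
                source=s.source,
            )
            out.stanzas.append(merged)
        else:
            by_id.pop(s.id, None)
            out.stanzas.append(s)
    for s in xp_defs.stanzas:
        if s.id in by_id and s.id not in out.ids():
            out.stanzas.append(s)
    out.validate()
    return out


def merge_bridge(doc: OntologyDocument, bridge: OntologyDocument) -> OntologyDocument:
    """Fold bridging axioms (plain is_a links between entity ontologies)
    into a document: parents are unioned for known ids, new stanzas added.

    Input stanzas are copied, never mutated, so the same documents can be
    reasoned over with and without bridges.
    """
    import dataclasses

    out = OntologyDocument(doc.ontology_id, list(doc.header_lines), [], list(doc.typedefs))
    extra: dict[str, list[str]] = {}
    for s in bridge.stanzas:
        extra.setdefault(s.id, []).extend(s.is_a_parents)
    known = set(doc.ids())
    for s in doc.stanzas:
        parents = [p for p in extra.get(s.id, []) if p not in s.is_a_parents]
        if parents:
            s = dataclasses.replace(s, is_a_parents=list(s.is_a_parents) + parents)
        out.stanzas.append(s)
    for s in bridge.stanzas:
        if s.id not in known:
            out.stanzas.append(s)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Closure computation
# ---------------------------------------------------------------------------


def _assert_acyclic(doc: OntologyDocument) -> None:
    g = nx.DiGraph()
    for s in doc.stanzas:
        for p in s.is_a_parents:
            if s.id != p:
                g.add_edge(s.id, p)
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        return
    raise CycleError([a for a, _ in cycle])


def compute_closure(
    doc: OntologyDocument,
    config: RuleConfig | None = None,
    vocab: RelationVocabulary = DEFAULT_VOCAB,
    agenda_rng=None,
) -> ClosureGraph:
    """Least fixpoint of rules R1-R6 over a materialized document.

    ``agenda_rng`` (a ``random.Random``) randomizes the rule-application
    order; the resulting edge set is identical for any order because the
    rules are monotone -- the option exists so tests can verify exactly
    that.
    """
    config = config or RuleConfig()
    _assert_acyclic(doc)

    classes = set(doc.ids())
    definitions: dict[str, list[IntersectionClause]] = {}
    edges: dict[Edge, Provenance] = {}
    agenda: list[Edge] = []

    def add(edge: Edge, prov: Provenance) -> None:
        if edge.subject == edge.object and edge.relation == IS_A:
            return  # reflexive is_a handled implicitly in premise matching
        if edge in edges:
            return
        edges[edge] = prov
        agenda.append(edge)

    # assertions first, in a separate pass, so that an edge that is both
    # asserted and derivable keeps its asserted provenance
    for s in doc.stanzas:
        if s.is_obsolete:
            continue
        for p in s.is_a_parents:
            add(Edge(s.id, IS_A, p), Provenance("asserted"))
        for r in s.relationships:
            add(Edge(s.id, r.relation, r.target), Provenance("asserted"))
    for s in doc.stanzas:
        if s.is_obsolete:
            continue
        if s.intersection_clauses:
            definitions[s.id] = list(s.intersection_clauses)
            for c in s.intersection_clauses:
                rel = IS_A if c.is_genus else c.relation
                add(Edge(s.id, rel, c.filler), Provenance("inferred", "R4"))

    transitive = set(config.transitive_relations) | doc.declared_transitive_relations

    # indexes: outgoing by (subject, relation), incoming by (object, relation)
    out_idx: dict[tuple[str, str], set[str]] = {}
    in_idx: dict[tuple[str, str], set[str]] = {}
    # definitions indexed by each premise pattern (relation, filler)
    def_by_premise: dict[tuple[str, str], list[str]] = {}
    for x, clauses in definitions.items():
        for c in clauses:
            rel = IS_A if c.is_genus else c.relation
            def_by_premise.setdefault((rel, c.filler), []).append(x)

    def holds(subject: str, relation: str, object: str) -> bool:
        if relation == IS_A and subject == object:
            return True
        return Edge(subject, relation, object) in edges

    def premise_edges(z: str, x: str) -> tuple[Edge, ...]:
        prem = []
        for c in definitions[x]:
            rel = IS_A if c.is_genus else c.relation
            if not (rel == IS_A and z == c.filler):
                prem.append(Edge(z, rel, c.filler))
        return tuple(prem)

    def try_r5(z: str, x: str) -> None:
        if z == x or x not in definitions:
            return
        for c in definitions[x]:
            rel = IS_A if c.is_genus else c.relation
            if not holds(z, rel, c.filler):
                return
        add(Edge(z, IS_A, x), Provenance("inferred", "R5", premise_edges(z, x)))

    def fire(e: Edge) -> None:
        s, r, o = e.subject, e.relation, e.object
        # R1/R2: transitivity
        if r in transitive:
            for x in out_idx.get((o, r), set()):
                add(Edge(s, r, x), Provenance("inferred", "R2" if r != IS_A else "R1", (e, Edge(o, r, x))))
            for x in in_idx.get((s, r), set()):
                add(Edge(x, r, o), Provenance("inferred", "R2" if r != IS_A else "R1", (Edge(x, r, s), e)))
        # R3: composition with is_a (both sides)
        if config.composition_over_is_a:
            if r == IS_A:
                for (subj, rel), objs in list(out_idx.items()):
                    if subj == o and rel != IS_A:
                        for x in objs:
                            add(Edge(s, rel, x), Provenance("inferred", "R3", (e, Edge(o, rel, x))))
                for (obj, rel), subjs in list(in_idx.items()):
                    if obj == s and rel != IS_A:
                        for x in subjs:
                            add(Edge(x, rel, o), Provenance("inferred", "R3", (Edge(x, rel, s), e)))
            else:
                for x in out_idx.get((o, IS_A), set()):
                    add(Edge(s, r, x), Provenance("inferred", "R3", (e, Edge(o, IS_A, x))))
                for x in in_idx.get((s, IS_A), set()):
                    add(Edge(x, r, o), Provenance("inferred", "R3", (Edge(x, IS_A, s), e)))
        # R5: definition sufficiency, triggered by any premise-shaped edge
        for x in def_by_premise.get((r, o), ()):
            try_r5(s, x)
        # R6: quality propagation over part_of
        if config.quality_propagates_over_part_of:
            if r == vocab.inheres_in:
                for w in out_idx.get((o, vocab.part_of), set()):
                    add(
                        Edge(s, config.propagated_relation, w),
                        Provenance("inferred", "R6", (e, Edge(o, vocab.part_of, w))),
                    )
            elif r == vocab.part_of:
                for q in in_idx.get((s, vocab.inheres_in), set()):
                    add(
                        Edge(q, config.propagated_relation, o),
                        Provenance("inferred", "R6", (Edge(q, vocab.inheres_in, s), e)),
                    )

    while True:
        while agenda:
            if agenda_rng is not None:
                e = agenda.pop(agenda_rng.randrange(len(agenda)))
            else:
                e = agenda.pop()
            fire(e)
            out_idx.setdefault((e.subject, e.relation), set()).add(e.object)
            in_idx.setdefault((e.object, e.relation), set()).add(e.subject)
        # verification sweep: R5 premises satisfied purely by identity edges
        # never enter the agenda, so re-check every (class, definition) pair
        before = len(edges)
        for z in sorted(classes):
            for x in definitions:
                try_r5(z, x)
        if len(edges) == before and not agenda:
            break

    classes.update(c for e in edges for c in (e.subject, e.object))
    return ClosureGraph(
        classes=classes,
        edges=edges,
        definitions=definitions,
        rule_config=config,
        labels=doc.labels(),
    )


# ---------------------------------------------------------------------------
# Derived queries
# ---------------------------------------------------------------------------


def is_direct(closure: ClosureGraph, subject: str, object: str, within: set[str] | None = None) -> bool:
    """True when no distinct intermediate Z has subject is_a Z is_a object."""
    for z in closure.superclasses(subject):
        if z in (subject, object):
            continue
        if within is not None and z not in within:
            continue
        if closure.has(z, IS_A, object):
            return False
    return True


def infer_novel_links(closure: ClosureGraph, target_prefix: str) -> list[Edge]:
    """Inferred direct is_a links between classes of the target ontology.

    Returns non-asserted, non-reflexive inferred is_a edges whose subject
    and object both carry ``target_prefix``, filtered to *direct* links (no
    distinct intermediate in the closure), deterministically sorted.
    """
    prefix = target_prefix.rstrip(":") + ":"
    out = []
    for e, prov in closure.edges.items():
        if e.relation != IS_A or prov.status != "inferred" or prov.rule == "R4":
            continue
        if e.subject == e.object:
            continue
        if not (e.subject.startswith(prefix) and e.object.startswith(prefix)):
            continue
        if not is_direct(closure, e.subject, e.object):
            continue
        out.append(e)
    return sorted(out, key=lambda e: (e.subject, e.object))


def query_phenotypes_by_entity(closure: ClosureGraph, entity: str,
                               vocab: RelationVocabulary = DEFAULT_VOCAB) -> list[str]:
    """All phenotype classes whose bearer falls under ``entity``.

    A class X qualifies when X inheres_in F holds in the closure for some F
    with F is_a entity (reflexively).  Bridging axioms (plain is_a links
    between entity ontologies) extend the result across species because they
    participate in the closure like any other is_a edge.  Materialized
    expression classes (``XP:`` ids) are excluded from the result.
    """
    if entity not in closure.classes:
        raise UnknownClassError(f"unknown class {entity}")
    hits = set()
    for e in closure.edges:
        if e.relation != vocab.inheres_in or e.subject.startswith("XP:"):
            continue
        if e.object == entity or closure.has(e.object, IS_A, entity):
            hits.add(e.subject)
    return sorted(hits)
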