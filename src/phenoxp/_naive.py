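"""Independent naive-saturation reference reasoner.

Deliberately written as the dumbest possible fixpoint computation: on every
pass, every rule is re-applied to every pair of edges, with no indexing, no
delta tracking and no shared code with :mod:`phenoxp.reasoner`.  The suite
generator and the test suite use it as the oracle the production reasoner
is checked against, so the two implementations must not share a bug.

Edges here are bare ``(subject, relation, object)`` tuples.
"""

from __future__ import annotations

from phenoxp.obo_io import OntologyDocument

IS_A = "is_a"


def naive_closure(
    doc: OntologyDocument,
    transitive_relations: set[str] | None = None,
    composition_over_is_a: bool = True,
    quality_propagation: bool = False,
    inheres_in: str = "inheres_in",
    part_of: str = "part_of",
    propagated_relation: str = "inheres_in_part_of",
) -> set[tuple[str, str, str]]:
    """Saturate a materialized document; returns non-reflexive edge tuples."""
    transitive = set(transitive_relations or {IS_A, part_of}) | {IS_A}
    transitive |= doc.declared_transitive_relations

    edges: set[tuple[str, str, str]] = set()
    definitions: dict[str, list[tuple[str, str]]] = {}
    for s in doc.stanzas:
        if s.is_obsolete:
            continue
        for p in s.is_a_parents:
            edges.add((s.id, IS_A, p))
        for r in s.relationships:
            edges.add((s.id, r.relation, r.target))
        if s.intersection_clauses:
            premises = []
            for c in s.intersection_clauses:
                rel = IS_A if c.is_genus else c.relation
                premises.append((rel, c.filler))
                edges.add((s.id, rel, c.filler))
            definitions[s.id] = premises
    classes = {s.id for s in doc.stanzas} | {c for e in edges for c in (e[0], e[2])}

    def holds(a: str, r: str, b: str) -> bool:
        return (r == IS_A and a == b) or (a, r, b) in edges

    changed = True
    while changed:
        changed = False
        snapshot = list(edges)
        for (a, r1, b) in snapshot:
            for (c, r2, d) in snapshot:
                if b != c:
                    continue
                if r1 == r2 and r1 in transitive and (a, r1, d) not in edges:
                    edges.add((a, r1, d))
                    changed = True
                if composition_over_is_a:
                    if r1 == IS_A and r2 != IS_A and (a, r2, d) not in edges:
                        edges.add((a, r2, d))
                        changed = True
                    if r2 == IS_A and r1 != IS_A and (a, r1, d) not in edges:
                        edges.add((a, r1, d))
                        changed = True
                if quality_propagation and r1 == inheres_in and r2 == part_of:
                    if (a, propagated_relation, d) not in edges:
                        edges.add((a, propagated_relation, d))
                        changed = True
        for x, premises in definitions.items():
            for z in classes:
                if z == x:
                    continue
                if all(holds(z, rel, filler) for rel, filler in premises):
                    if (z, IS_A, x) not in edges:
                        edges.add((z, IS_A, x))
                        changed = True
    return {(a, r, b) for (a, r, b) in edges if not (r == IS_A and a == b)}


def naive_entailed_is_a(doc: OntologyDocument, prefix: str, **kw) -> set[tuple[str, str]]:
    """Entailed is_a pairs between classes carrying ``prefix``."""
    p = prefix.rstrip(":") + ":"
    return {
        (a, b)
        for (a, r, b) in naive_closure(doc, **kw)
        if r == IS_A and a.startswith(p) and b.startswith(p) and a != b
    }
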