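"""Validation procedures for XP definition sets.

Four instruments, all built on the closure reasoner:

* :func:`recapitulate` -- the link-recapitulation experiment: delete every
  asserted is_a link of the phenotype ontology (reference ontologies are
  untouched), recompute the closure from the logical definitions, and
  measure how many of the original links come back.
* :func:`missing_link_report` / :func:`read_curation_file` -- novel direct
  links serialized with human-readable provenance for curator triage, and
  the inverse parser that tallies triage verdicts.
* :func:`consistency_lint` -- two families of cross-ontology incoherence:
  (a) asserted phenotype links that can never be entailed because the
  reference ontologies lack any connecting path between the definitions'
  bearers (the missing snout part_of face case), and (b) reference-ontology
  subsumptions with no counterpart link between correspondingly-defined
  phenotype classes (the pancreatic delta cell case).
* :func:`coverage_stats` -- how much of the phenotype ontology carries a
  logical definition, broken down by entity-ontology prefix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from phenoxp.errors import EmptyReportError
from phenoxp.eq_model import DEFAULT_VOCAB, RelationVocabulary
from phenoxp.obo_io import OntologyDocument
from phenoxp.reasoner import (
    IS_A,
    ClosureGraph,
    Edge,
    RuleConfig,
    apply_definitions,
    compute_closure,
    is_direct,
)
from phenoxp.obo_io import merge_documents

VERDICTS = ("pending", "accepted", "rejected", "partially-correct")


@dataclass
class RecapReport:
    recovered: set[tuple[str, str]]
    missed: set[tuple[str, str]]
    novel: set[tuple[str, str]]
    recall_all: float
    recall_defined: float
    n_asserted: int
    n_defined_links: int
    closure: ClosureGraph = field(repr=False, default=None)

    def summary(self, labels: dict[str, str] | None = None) -> str:
        lab = labels or (self.closure.labels if self.closure else {})

        def pct(x):
            return f"{100 * x:.1f}%"

        lines = [
            f"asserted is_a links:          {self.n_asserted}",
            f"recovered (re-inferred):      {len(self.recovered)}  "
            f"(recall over all links: {pct(self.recall_all)})",
            f"links between defined classes: {self.n_defined_links}  "
            f"(recall over defined links: {pct(self.recall_defined)})",
            f"missed:                       {len(self.missed)}",
            f"novel links proposed:         {len(self.novel)}",
        ]
        for child, parent in sorted(self.novel):
            lines.append(
                f"  novel: {child} ({lab.get(child, '?')}) is_a {parent} ({lab.get(parent, '?')})"
            )
        return "\n".join(lines)

    def key_values(self) -> dict[str, float]:
        return {
            "n_asserted": self.n_asserted,
            "n_recovered": len(self.recovered),
            "n_missed": len(self.missed),
            "n_novel": len(self.novel),
            "recall_all": self.recall_all,
            "recall_defined": self.recall_defined,
        }


def _strip_is_a(doc: OntologyDocument) -> OntologyDocument:
    from phenoxp.obo_io import TermStanza

    out = OntologyDocument(ontology_id=doc.ontology_id, header_lines=list(doc.header_lines),
                           typedefs=list(doc.typedefs))
    for s in doc.stanzas:
        out.stanzas.append(
            TermStanza(
                id=s.id,
                name=s.name,
                namespace=s.namespace,
                synonyms=list(s.synonyms),
                is_a_parents=[],
                relationships=list(s.relationships),
                intersection_clauses=list(s.intersection_clauses),
                is_obsolete=s.is_obsolete,
                opaque_lines=list(s.opaque_lines),
                source=s.source,
            )
        )
    return out


def recapitulate(
    phenotype_doc: OntologyDocument,
    xp_defs: OntologyDocument,
    support_docs: list[OntologyDocument],
    config: RuleConfig | None = None,
    vocab: RelationVocabulary = DEFAULT_VOCAB,
) -> RecapReport:
    """Run the is_a recapitulation experiment.

    Every asserted is_a link between phenotype classes is withheld, the
    closure is recomputed from the XP definitions plus the (untouched)
    support ontologies, and each original link is classified as recovered
    (re-inferred) or missed; inferred phenotype-internal direct links not
    among the original assertions are reported as novel.  Recovery counts
    direct-or-indirect entailment.  Two recall denominators are reported:
    all asserted links, and only links whose both endpoints carry a
    definition.
    """
    pheno_ids = {s.id for s in phenotype_doc.stanzas if not s.is_obsolete}
    if not pheno_ids:
        raise EmptyReportError("phenotype document defines no classes")
    asserted = {
        (s.id, p)
        for s in phenotype_doc.stanzas
        if not s.is_obsolete
        for p in s.is_a_parents
        if p in pheno_ids
    }
    merged = merge_documents([_strip_is_a(phenotype_doc)] + list(support_docs))
    merged = apply_definitions(merged, xp_defs)
    closure = compute_closure(merged, config, vocab)

    recovered = {(c, p) for (c, p) in asserted if closure.has(c, IS_A, p)}
    missed = asserted - recovered
    defined = {s.id for s in xp_defs.stanzas if s.intersection_clauses} & pheno_ids
    defined_links = {(c, p) for (c, p) in asserted if c in defined and p in defined}

    novel = set()
    for e, prov in closure.edges.items():
        if e.relation != IS_A or prov.status != "inferred" or prov.rule == "R4":
            continue
        if e.subject not in pheno_ids or e.object not in pheno_ids or e.subject == e.object:
            continue
        if (e.subject, e.object) in asserted:
            continue
        if is_direct(closure, e.subject, e.object, within=pheno_ids):
            novel.add((e.subject, e.object))

    recall_all = len(recovered) / len(asserted) if asserted else 0.0
    recall_defined = (
        len(recovered & defined_links) / len(defined_links) if defined_links else 0.0
    )
    return RecapReport(
        recovered=recovered,
        missed=missed,
        novel=novel,
        recall_all=recall_all,
        recall_defined=recall_defined,
        n_asserted=len(asserted),
        n_defined_links=len(defined_links),
        closure=closure,
    )


# ---------------------------------------------------------------------------
# Curation report
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = (
    "subject_id",
    "subject_label",
    "object_id",
    "object_label",
    "rule_chain",
    "verdict",
    "note",
)


def _rule_chain(closure: ClosureGraph, edge: Edge, labels: dict[str, str]) -> str:
    parts = []
    for e, prov in closure.provenance_chain(edge):
        if prov.status == "asserted":
            tag = "asserted"
        else:
            tag = prov.rule or "inferred"
        parts.append(
            f"[{tag}] {labels.get(e.subject, e.subject)} {e.relation} {labels.get(e.object, e.object)}"
        )
    return " <= ".join(parts)


def missing_link_report(
    closure: ClosureGraph,
    novel: list[Edge] | set[tuple[str, str]],
    labels: dict[str, str] | None = None,
) -> str:
    """Serialize novel links for curator triage (tab-separated).

    Each row carries the proposed edge with labels, a human-readable
    provenance chain (every premise edge, recursively), and an empty
    verdict column (``pending``) plus a free-text note column.  Rows are
    deterministically ordered.
    """
    labels = {**closure.labels, **(labels or {})}
    edges = sorted(
        (e if isinstance(e, Edge) else Edge(e[0], IS_A, e[1]) for e in novel),
        key=lambda e: (e.subject, e.object),
    )
    lines = ["\t".join(_REPORT_COLUMNS)]
    for e in edges:
        lines.append(
            "\t".join(
                [
                    e.subject,
                    labels.get(e.subject, ""),
                    e.object,
                    labels.get(e.object, ""),
                    _rule_chain(closure, e, labels),
                    "pending",
                    "",
                ]
            )
        )
    return "\n".join(lines) + "\n"


def read_curation_file(text: str) -> dict[str, int]:
    """Parse a (possibly triaged) curation report; returns verdict counts.

    Verdicts partition the report: every row carries exactly one of
    pending / accepted / rejected / partially-correct.
    """
    counts = {v: 0 for v in VERDICTS}
    lines = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
    header = lines[0].split("\t")
    v_idx = header.index("verdict")
    for line in lines[1:]:
        verdict = line.split("\t")[v_idx].strip() or "pending"
        if verdict not in counts:
            raise ValueError(f"unknown verdict {verdict!r}")
        counts[verdict] += 1
    return counts


# ---------------------------------------------------------------------------
# Consistency lint
# ---------------------------------------------------------------------------

#: Relations that can serve as the bearer slot of a definition.
_BEARER_RELATIONS = ("inheres_in", "inheres_in_part_of")


@dataclass(frozen=True)
class LintFinding:
    kind: str  # "missing-filler-path" | "missing-counterpart-link"
    subject: str
    object: str
    filler_pair: tuple[str, str]
    detail: str


def _definition_signature(clauses, vocab: RelationVocabulary):
    """(genus, qualifier, towards, bearer filler) of a definition; None when
    the clauses carry no recognizable bearer."""
    genus = qualifier = towards = bearer = None
    for c in clauses:
        if c.is_genus:
            genus = c.filler
        elif c.relation in _BEARER_RELATIONS or c.relation == vocab.inheres_in:
            bearer = c.filler
        elif c.relation == vocab.towards:
            towards = c.filler
        elif c.relation == vocab.has_qualifier:
            qualifier = c.filler
    if genus is None or bearer is None:
        return None
    return genus, qualifier, towards, bearer


def consistency_lint(
    phenotype_doc: OntologyDocument,
    xp_defs: OntologyDocument,
    support_docs: list[OntologyDocument],
    config: RuleConfig | None = None,
    vocab: RelationVocabulary = DEFAULT_VOCAB,
) -> list[LintFinding]:
    """Cross-ontology coherence findings between phenotype and references.

    Runs with quality propagation over part_of enabled by default, since
    part_of is one of the connecting paths whose absence it diagnoses.
    """
    if config is None:
        config = RuleConfig(quality_propagates_over_part_of=True)

    defs: dict[str, tuple] = {}
    for s in xp_defs.stanzas:
        if s.intersection_clauses:
            sig = _definition_signature(s.intersection_clauses, vocab)
            if sig is not None:
                defs[s.id] = sig

    pheno_ids = {s.id for s in phenotype_doc.stanzas if not s.is_obsolete}
    asserted = {
        (s.id, p)
        for s in phenotype_doc.stanzas
        for p in s.is_a_parents
        if p in pheno_ids
    }
    report = recapitulate(phenotype_doc, xp_defs, support_docs, config, vocab)
    support_closure = compute_closure(merge_documents(list(support_docs)), RuleConfig(), vocab)

    findings: list[LintFinding] = []

    # (a) asserted links that no entailment can support: the bearers of the
    # two definitions are not connected by any is_a/part_of path
    for child, parent in sorted(asserted):
        if (child, parent) in report.recovered:
            continue
        if child not in defs or parent not in defs:
            continue
        f_child, f_parent = defs[child][3], defs[parent][3]
        connected = (
            f_child == f_parent
            or support_closure.has(f_child, IS_A, f_parent)
            or support_closure.has(f_child, vocab.part_of, f_parent)
        )
        if not connected:
            findings.append(
                LintFinding(
                    kind="missing-filler-path",
                    subject=child,
                    object=parent,
                    filler_pair=(f_child, f_parent),
                    detail=(
                        f"asserted link {child} is_a {parent} cannot be entailed: "
                        f"no is_a/part_of path between bearers {f_child} and {f_parent} "
                        f"in the reference ontologies"
                    ),
                )
            )

    # (b) reference subsumptions with no counterpart between same-quality,
    # same-qualifier phenotype definitions differing only in the bearer
    asserted_closure = _transitive_pairs(asserted)
    by_bearer: dict[str, list[str]] = {}
    for pid, (_genus, _qual, _towards, bearer) in defs.items():
        if pid in pheno_ids:
            by_bearer.setdefault(bearer, []).append(pid)
    for e in support_closure.edge_set(relation=IS_A):
        for p1 in by_bearer.get(e.subject, ()):
            for p2 in by_bearer.get(e.object, ()):
                if p1 == p2:
                    continue
                g1, q1, t1, _ = defs[p1]
                g2, q2, t2, _ = defs[p2]
                if (g1, q1, t1) != (g2, q2, t2):
                    continue
                if (p1, p2) in asserted_closure:
                    continue
                findings.append(
                    LintFinding(
                        kind="missing-counterpart-link",
                        subject=p1,
                        object=p2,
                        filler_pair=(e.subject, e.object),
                        detail=(
                            f"reference ontology states {e.subject} is_a {e.object} but "
                            f"{p1} and {p2} (same quality/qualifier) are unrelated in the "
                            f"phenotype ontology"
                        ),
                    )
                )
    return sorted(findings, key=lambda f: (f.kind, f.subject, f.object))


def _transitive_pairs(pairs: set[tuple[str, str]]) -> set[tuple[str, str]]:
    closed = set(pairs)
    changed = True
    while changed:
        changed = False
        for (a, b) in list(closed):
            for (c, d) in list(closed):
                if b == c and (a, d) not in closed:
                    closed.add((a, d))
                    changed = True
    return closed


# ---------------------------------------------------------------------------
# Coverage statistics
# ---------------------------------------------------------------------------

#: Entity-ontology prefix buckets, mirroring the usual XP summary columns.
PREFIX_BUCKETS = {
    "MA": "gross-anatomy",
    "FMA": "gross-anatomy",
    "WBbt": "gross-anatomy",
    "PO": "gross-anatomy",
    "EMAP": "gross-anatomy",
    "EX": "gross-anatomy",  # generated-suite entity ontologies
    "CL": "CL",
    "CHEBI": "CHEBI",
    "GO": "GO",
}


@dataclass
class CoverageStats:
    ontology_id: str
    total_classes: int
    defined_classes: int
    percent_defined: float
    by_bucket: dict[str, int]

    def as_text(self) -> str:
        lines = [
            f"ontology:          {self.ontology_id}",
            f"total classes (non-obsolete): {self.total_classes}",
            f"classes with logical definitions: {self.defined_classes} "
            f"({self.percent_defined:.0f}%)",
        ]
        for bucket, n in sorted(self.by_bucket.items()):
            lines.append(f"  definitions referencing {bucket}: {n}")
        return "\n".join(lines)


def coverage_stats(phenotype_doc: OntologyDocument, xp_defs: OntologyDocument) -> CoverageStats:
    """Definition coverage of a phenotype ontology.

    Counts non-obsolete classes and defined classes, with a per-bucket
    breakdown of definitions by the ontologies their entity fillers come
    from; a single definition may touch several buckets, so bucket counts
    can sum to more than the defined-class count.
    """
    active = [s for s in phenotype_doc.stanzas if not s.is_obsolete]
    pheno_ids = {s.id for s in active}
    aux = {s.id: s.intersection_clauses for s in xp_defs.stanzas if s.id.startswith("XP:")}

    def fillers(clauses, seen=()):
        for c in clauses:
            if c.filler in aux and c.filler not in seen:
                yield from fillers(aux[c.filler], seen + (c.filler,))
            elif not c.is_genus:
                yield c.filler

    defined = 0
    by_bucket: dict[str, int] = {}
    for s in xp_defs.stanzas:
        if s.id not in pheno_ids or not s.intersection_clauses:
            continue
        defined += 1
        buckets = set()
        for filler in fillers(s.intersection_clauses):
            prefix = filler.split(":", 1)[0]
            buckets.add(PREFIX_BUCKETS.get(prefix, "other"))
        for b in buckets:
            by_bucket[b] = by_bucket.get(b, 0) + 1
    total = len(active)
    return CoverageStats(
        ontology_id=phenotype_doc.ontology_id,
        total_classes=total,
        defined_classes=defined,
        percent_defined=100.0 * defined / total if total else 0.0,
        by_bucket=by_bucket,
    )
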