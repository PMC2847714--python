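"""Reader/writer for the OBO 1.2 flat-file subset used by cross-product files.

Only the tags the XP methodology touches are interpreted: ``format-version``,
``ontology``, ``id``, ``name``, ``namespace``, ``synonym``, ``is_a``,
``relationship``, ``intersection_of`` and ``is_obsolete`` (plus ``Typedef``
stanzas read for their ``is_transitive`` flag).  Everything else passes
through verbatim as opaque lines so that foreign files survive a
parse -> write cycle.  Trailing ``! comment`` text is human-readable labeling
only -- it is stripped before interpretation, and regenerated on demand from
an id -> label dictionary when writing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from phenoxp.errors import (
    DefinitionArityError,
    MalformedDocumentError,
    MergeConflictError,
)

CURIE_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.\-]*:[A-Za-z0-9_.\-]+$")

#: OBO 1.2 canonical tag order for the subset we interpret.
_TAG_ORDER = ("id", "name", "namespace", "synonym", "is_a", "intersection_of", "relationship", "is_obsolete")


def _strip_comment(line: str) -> str:
    """Remove an unescaped trailing ``!`` comment (outside quoted strings)."""
    out = []
    in_quote = False
    i = 0
    while i < len(line):
        ch = line[i]
        if ch == "\\" and i + 1 < len(line):
            out.append(line[i : i + 2])
            i += 2
            continue
        if ch == '"':
            in_quote = not in_quote
        if ch == "!" and not in_quote:
            break
        out.append(ch)
        i += 1
    return "".join(out).rstrip()


@dataclass(frozen=True)
class LinkClause:
    """A ``relationship: <relation> <target>`` assertion."""

    relation: str
    target: str

    def __post_init__(self):
        if not self.relation or not self.target:
            raise MalformedDocumentError("relationship requires a relation and a target")


@dataclass(frozen=True)
class IntersectionClause:
    """One line of a genus-differentia definition.

    ``relation`` is ``None`` for the genus clause (``intersection_of: <id>``)
    and a relation identifier for a differentium
    (``intersection_of: inheres_in MA:0001359``).
    """

    relation: str | None
    filler: str

    @property
    def is_genus(self) -> bool:
        return self.relation is None


@dataclass
class TermStanza:
    id: str
    name: str | None = None
    namespace: str | None = None
    synonyms: list[tuple[str, str]] = field(default_factory=list)
    is_a_parents: list[str] = field(default_factory=list)
    relationships: list[LinkClause] = field(default_factory=list)
    intersection_clauses: list[IntersectionClause] = field(default_factory=list)
    is_obsolete: bool = False
    opaque_lines: list[str] = field(default_factory=list)
    source: str | None = field(default=None, compare=False)

    def validate(self) -> None:
        n = len(self.intersection_clauses)
        if n == 1:
            raise DefinitionArityError(
                f"stanza {self.id}: a definition needs a genus and at least "
                f"one differentium (found a single intersection_of clause)"
            )
        if sum(1 for c in self.intersection_clauses if c.is_genus) > 1:
            raise MalformedDocumentError(f"stanza {self.id}: more than one genus clause")
        if self.is_obsolete and (self.is_a_parents or self.relationships or self.intersection_clauses):
            raise MalformedDocumentError(f"stanza {self.id}: obsolete stanzas must carry no links")

    @property
    def genus(self) -> str | None:
        for c in self.intersection_clauses:
            if c.is_genus:
                return c.filler
        return None

    @property
    def differentia(self) -> list[IntersectionClause]:
        return [c for c in self.intersection_clauses if not c.is_genus]


@dataclass
class TypedefStanza:
    """Relation declaration; only transitivity is interpreted."""

    id: str
    lines: list[str] = field(default_factory=list)  # comment-stripped tag-value lines, id excluded
    is_transitive: bool = False


@dataclass
class OntologyDocument:
    ontology_id: str = ""
    header_lines: list[str] = field(default_factory=list)
    stanzas: list[TermStanza] = field(default_factory=list)
    typedefs: list[TypedefStanza] = field(default_factory=list)

    @property
    def declared_transitive_relations(self) -> set[str]:
        return {t.id for t in self.typedefs if t.is_transitive}

    def __getitem__(self, class_id: str) -> TermStanza:
        for s in self.stanzas:
            if s.id == class_id:
                return s
        raise KeyError(class_id)

    def __contains__(self, class_id: str) -> bool:
        return any(s.id == class_id for s in self.stanzas)

    def ids(self) -> list[str]:
        return [s.id for s in self.stanzas]

    def labels(self) -> dict[str, str]:
        """id -> name map for every named stanza (used for ``!`` comments)."""
        return {s.id: s.name for s in self.stanzas if s.name is not None}

    def validate(self) -> None:
        seen: set[str] = set()
        for s in self.stanzas:
            if s.id in seen:
                raise MalformedDocumentError(f"duplicate stanza id {s.id}")
            seen.add(s.id)
            s.validate()


_SYNONYM_RE = re.compile(r'^"((?:[^"\\]|\\.)*)"\s*([A-Z_]*)')


def _parse_synonym(value: str, stanza_id: str) -> tuple[str, str]:
    m = _SYNONYM_RE.match(value)
    if not m:
        raise MalformedDocumentError(f"stanza {stanza_id}: malformed synonym line: {value!r}")
    text = m.group(1).replace('\\"', '"')
    scope = m.group(2) or "RELATED"
    return text, scope


def parse_obo(text: str, source: str | None = None) -> OntologyDocument:
    """Parse OBO flat-file content into an :class:`OntologyDocument`.

    Raises :class:`MalformedDocumentError` for duplicate stanza ids (naming
    both line numbers) and :class:`DefinitionArityError` for a stanza with
    exactly one ``intersection_of`` clause.
    """
    doc = OntologyDocument()
    lines = text.splitlines()
    current: TermStanza | TypedefStanza | None = None
    in_header = True
    id_lines: dict[str, int] = {}

    def finish(stanza):
        if isinstance(stanza, TermStanza):
            stanza.validate()
            doc.stanzas.append(stanza)
        elif isinstance(stanza, TypedefStanza):
            doc.typedefs.append(stanza)

    for lineno, raw in enumerate(lines, start=1):
        line = _strip_comment(raw).strip()
        if not line:
            continue
        if line.startswith("["):
            if current is not None:
                finish(current)
            if line == "[Term]":
                current = TermStanza(id="")
            elif line == "[Typedef]":
                current = TypedefStanza(id="")
            else:
                raise MalformedDocumentError(f"line {lineno}: unsupported stanza type {line}")
            in_header = False
            continue
        if ":" not in line:
            raise MalformedDocumentError(f"line {lineno}: expected 'tag: value', got {line!r}")
        tag, _, value = line.partition(":")
        tag = tag.strip()
        value = value.strip()
        if in_header:
            doc.header_lines.append(line)
            if tag == "ontology":
                doc.ontology_id = value
            continue
        if isinstance(current, TypedefStanza):
            if tag == "id":
                current.id = value
            else:
                if tag == "is_transitive" and value == "true":
                    current.is_transitive = True
                current.lines.append(line)
            continue
        assert isinstance(current, TermStanza)
        if tag == "id":
            if value in id_lines:
                raise MalformedDocumentError(
                    f"duplicate stanza id {value} (lines {id_lines[value]} and {lineno})"
                )
            id_lines[value] = lineno
            current.id = value
        elif tag == "name":
            current.name = value
        elif tag == "namespace":
            current.namespace = value
        elif tag == "synonym":
            current.synonyms.append(_parse_synonym(value, current.id))
        elif tag == "is_a":
            current.is_a_parents.append(value)
        elif tag == "relationship":
            parts = value.split()
            if len(parts) != 2:
                raise MalformedDocumentError(f"line {lineno}: malformed relationship: {value!r}")
            current.relationships.append(LinkClause(parts[0], parts[1]))
        elif tag == "intersection_of":
            parts = value.split()
            if len(parts) == 1:
                current.intersection_clauses.append(IntersectionClause(None, parts[0]))
            elif len(parts) == 2:
                current.intersection_clauses.append(IntersectionClause(parts[0], parts[1]))
            else:
                raise MalformedDocumentError(f"line {lineno}: malformed intersection_of: {value!r}")
        elif tag == "is_obsolete":
            current.is_obsolete = value == "true"
        else:
            current.opaque_lines.append(line)
    if current is not None:
        finish(current)
    if source is not None:
        for s in doc.stanzas:
            s.source = source
    doc.validate()
    return doc


def _comment(comments: dict[str, str] | None, class_id: str) -> str:
    """Render a ``! label`` suffix, or nothing when no label is known."""
    if comments and class_id in comments:
        return f" ! {comments[class_id]}"
    return ""


def write_obo(doc: OntologyDocument, comments: dict[str, str] | None = None) -> str:
    """Serialize a document; tag order follows the OBO 1.2 canonical order.

    ``comments`` is an optional id -> label dictionary; when supplied,
    ``! label`` trailing comments are regenerated after every identifier
    whose label is known (and silently omitted otherwise).
    """
    doc.validate()
    out: list[str] = []
    out.extend(doc.header_lines)
    for s in doc.stanzas:
        if out:
            out.append("")
        out.append("[Term]")
        out.append(f"id: {s.id}{_comment(comments, s.id)}")
        if s.name is not None:
            out.append(f"name: {s.name}")
        if s.namespace is not None:
            out.append(f"namespace: {s.namespace}")
        for text, scope in s.synonyms:
            quoted = text.replace('"', '\\"')
            out.append(f'synonym: "{quoted}" {scope} []')
        for parent in s.is_a_parents:
            out.append(f"is_a: {parent}{_comment(comments, parent)}")
        for c in s.intersection_clauses:
            if c.is_genus:
                out.append(f"intersection_of: {c.filler}{_comment(comments, c.filler)}")
            else:
                out.append(f"intersection_of: {c.relation} {c.filler}{_comment(comments, c.filler)}")
        for r in s.relationships:
            out.append(f"relationship: {r.relation} {r.target}{_comment(comments, r.target)}")
        if s.is_obsolete:
            out.append("is_obsolete: true")
        out.extend(s.opaque_lines)
    for t in doc.typedefs:
        if out:
            out.append("")
        out.append("[Typedef]")
        out.append(f"id: {t.id}")
        out.extend(t.lines)
    return "\n".join(out) + "\n"


def merge_documents(docs: list[OntologyDocument]) -> OntologyDocument:
    """Union of stanzas and transitive-relation declarations.

    Identical duplicate stanzas collapse to one; a duplicate id with
    conflicting content raises :class:`MergeConflictError` naming the id and
    both source documents.  Per-stanza provenance (``stanza.source``) is
    preserved from the input documents.
    """
    merged = OntologyDocument(ontology_id="+".join(d.ontology_id for d in docs if d.ontology_id))
    if docs:
        merged.header_lines = list(docs[0].header_lines)
    seen: dict[str, TermStanza] = {}
    typedef_seen: dict[str, TypedefStanza] = {}
    for doc in docs:
        for s in doc.stanzas:
            if s.id in seen:
                if seen[s.id] != s:
                    raise MergeConflictError(
                        f"conflicting stanzas for {s.id} "
                        f"(sources: {seen[s.id].source!r} and {s.source!r})"
                    )
                continue
            seen[s.id] = s
            merged.stanzas.append(s)
        for t in doc.typedefs:
            if t.id in typedef_seen:
                if t.is_transitive:
                    typedef_seen[t.id].is_transitive = True
                continue
            copy = TypedefStanza(t.id, list(t.lines), t.is_transitive)
            typedef_seen[t.id] = copy
            merged.typedefs.append(copy)
    merged.validate()
    return merged


def lint_dangling(docs: list[OntologyDocument]) -> list[tuple[str, str, str]]:
    """Report link targets not defined in any loaded document.

    Dangling references are legal in XP files (they intentionally point into
    external ontologies); this surfaces them as ``(stanza id, relation,
    missing target)`` triples for review.
    """
    known: set[str] = set()
    for doc in docs:
        known.update(doc.ids())
    findings = []
    for doc in docs:
        for s in doc.stanzas:
            for parent in s.is_a_parents:
                if parent not in known:
                    findings.append((s.id, "is_a", parent))
            for r in s.relationships:
                if r.target not in known:
                    findings.append((s.id, r.relation, r.target))
            for c in s.intersection_clauses:
                if c.filler not in known:
                    findings.append((s.id, c.relation or "genus", c.filler))
    return findings
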