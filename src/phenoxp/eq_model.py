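"""EQ descriptions and their translation to genus-differentia intersections.

An EQ description captures a phenotype as a Quality (Q, from the quality
ontology) inhering in an Entity bearer (E), optionally directed ``towards``
a second entity (E2, for relational qualities such as 'concentration of
iron') and qualified by a Modifier (M, typically 'abnormal').  The EW
(Entity Whole) tag is surface sugar for one level of part_of nesting of the
bearer: ``E = dendrite, EW = Purkinje cell`` means the bearer is a dendrite
that is part_of some Purkinje cell.

Every EQ description translates losslessly to a class intersection:

    genus        = Q
    differentium = inheres_in E
    differentium = towards E2        (iff E2 present)
    differentium = has_qualifier M   (iff M present)

and back.  Composed bearers (caret syntax ``A^rel(B)``) are materialized as
auxiliary stanzas with deterministic content-hashed identifiers so that OBO
files only ever contain named references.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field, replace

from phenoxp.errors import (
    AmbiguousCompositionError,
    EQSyntaxError,
    GenusNotAQualityError,
    IncompleteDescriptionError,
    NotAnEQDefinitionError,
    UnsupportedCardinalityError,
    UnsupportedPatternError,
)
from phenoxp.obo_io import CURIE_RE, IntersectionClause, OntologyDocument, TermStanza


@dataclass(frozen=True)
class RelationVocabulary:
    """Identifiers of the five relations the translation table uses.

    The CURIEs for these relations are not standardized across deployments,
    so they are configuration; the defaults are the plain OBO shorthand
    names used in published XP files.
    """

    inheres_in: str = "inheres_in"
    towards: str = "towards"
    has_qualifier: str = "has_qualifier"
    part_of: str = "part_of"
    has_part: str = "has_part"

    def __post_init__(self):
        ids = (self.inheres_in, self.towards, self.has_qualifier, self.part_of, self.has_part)
        if len(set(ids)) != 5:
            raise ValueError("relation vocabulary identifiers must be distinct")


DEFAULT_VOCAB = RelationVocabulary()


class ClassExpression:
    """A named class or a composed genus + differentia expression.

    Composed expressions are finite trees; equality is structural after
    sorting differentia into canonical (relation, filler) order, so
    ``A^r(B)^s(C)`` equals ``A^s(C)^r(B)``.
    """

    __slots__ = ("genus", "differentia")

    def __init__(self, genus: str, differentia: tuple = ()):
        self.genus = genus
        self.differentia = tuple(
            sorted(differentia, key=lambda rf: (rf[0], rf[1]._key()))
        )

    @classmethod
    def named(cls, class_id: str) -> "ClassExpression":
        return cls(class_id)

    @classmethod
    def composed(cls, genus: str, differentia) -> "ClassExpression":
        diffs = tuple(differentia)
        if not diffs:
            raise ValueError("composed expressions need at least one differentium")
        return cls(genus, diffs)

    @property
    def is_named(self) -> bool:
        return not self.differentia

    def _key(self):
        return (self.genus, tuple((r, f._key()) for r, f in self.differentia))

    def __eq__(self, other):
        return isinstance(other, ClassExpression) and self._key() == other._key()

    def __hash__(self):
        return hash(self._key())

    def __repr__(self):
        return f"ClassExpression({self.caret()!r})"

    def caret(self) -> str:
        """Render in caret syntax, e.g. ``GO:0030425^part_of(CL:0000121)``."""
        base = self.genus
        for rel, filler in self.differentia:
            base += f"^{rel}({filler.caret()})"
        return base

    def depth(self) -> int:
        if self.is_named:
            return 1
        return 1 + max(f.depth() for _, f in self.differentia)


def expression_id(expr: ClassExpression, prefix: str = "XP") -> str:
    """Deterministic identifier for a materialized composed expression.

    A content hash of the canonical caret rendering, so repeated
    materialization of the same expression is stable across runs.
    """
    digest = hashlib.sha1(expr.caret().encode("utf-8")).hexdigest()[:10]
    return f"{prefix}:{digest}"


@dataclass(frozen=True)
class EQDescription:
    """The E / Q / E2 / M / EW tuple of one phenotype description."""

    entity: ClassExpression
    quality: str
    entity2: ClassExpression | None = None
    modifier: str | None = None
    entity_whole: ClassExpression | None = None

    def __post_init__(self):
        if self.entity_whole is not None and not self.entity.is_named:
            raise AmbiguousCompositionError(
                "EW is sugar for one level of part_of nesting; it cannot be "
                "combined with an already-composed entity"
            )


def normalize_entity_whole(eq: EQDescription, vocab: RelationVocabulary = DEFAULT_VOCAB) -> EQDescription:
    """Fold the EW tag into a nested bearer: E=dendrite, EW=Purkinje cell
    becomes E = dendrite^part_of(Purkinje cell)."""
    if eq.entity_whole is None:
        return eq
    nested = ClassExpression.composed(eq.entity.genus, [(vocab.part_of, eq.entity_whole)])
    return replace(eq, entity=nested, entity_whole=None)


def denormalize_entity_whole(eq: EQDescription, vocab: RelationVocabulary = DEFAULT_VOCAB) -> EQDescription:
    """Recover the EW surface form when the bearer is a one-level part_of
    composition; otherwise return the description unchanged."""
    e = eq.entity
    if (
        eq.entity_whole is None
        and not e.is_named
        and len(e.differentia) == 1
        and e.differentia[0][0] == vocab.part_of
    ):
        return replace(
            eq,
            entity=ClassExpression.named(e.genus),
            entity_whole=e.differentia[0][1],
        )
    return eq


# ---------------------------------------------------------------------------
# EQ <-> intersection_of translation
# ---------------------------------------------------------------------------


def _materialize(expr: ClassExpression, aux: list[TermStanza]) -> str:
    """Reduce an expression to a named id, emitting auxiliary stanzas for
    every composed node (deepest first)."""
    if expr.is_named:
        return expr.genus
    clauses = [IntersectionClause(None, expr.genus)]
    for rel, filler in expr.differentia:
        clauses.append(IntersectionClause(rel, _materialize(filler, aux)))
    new_id = expression_id(expr)
    if not any(s.id == new_id for s in aux):
        stanza = TermStanza(id=new_id, intersection_clauses=clauses)
        stanza.validate()
        aux.append(stanza)
    return new_id


def eq_to_intersection(
    eq: EQDescription, vocab: RelationVocabulary = DEFAULT_VOCAB
) -> tuple[list[IntersectionClause], list[TermStanza]]:
    """Translate an EQ description to intersection clauses.

    Returns ``(clauses, auxiliary_stanzas)``; the auxiliary stanzas carry the
    definitions of any composed bearer expressions, each under a
    deterministic ``XP:``-prefixed identifier.
    """
    eq = normalize_entity_whole(eq, vocab)
    aux: list[TermStanza] = []
    clauses = [
        IntersectionClause(None, eq.quality),
        IntersectionClause(vocab.inheres_in, _materialize(eq.entity, aux)),
    ]
    if eq.entity2 is not None:
        clauses.append(IntersectionClause(vocab.towards, _materialize(eq.entity2, aux)))
    if eq.modifier is not None:
        clauses.append(IntersectionClause(vocab.has_qualifier, eq.modifier))
    return clauses, aux


def _expand(class_id: str, context: dict[str, list[IntersectionClause]], vocab, seen=()) -> ClassExpression:
    """Rebuild a ClassExpression from a materialized id, following auxiliary
    definitions found in the context documents."""
    if class_id in seen:
        raise NotAnEQDefinitionError(f"cyclic expression reference through {class_id}")
    clauses = context.get(class_id)
    if not clauses or not class_id.startswith("XP:"):
        return ClassExpression.named(class_id)
    genus = None
    diffs = []
    for c in clauses:
        if c.is_genus:
            genus = c.filler
        else:
            diffs.append((c.relation, _expand(c.filler, context, vocab, seen + (class_id,))))
    return ClassExpression.composed(genus, diffs)


def _is_a_descendant(doc_set: list[OntologyDocument], child: str, ancestor: str) -> bool:
    """Reflexive is_a reachability over the loaded documents."""
    parents: dict[str, list[str]] = {}
    for doc in doc_set:
        for s in doc.stanzas:
            parents.setdefault(s.id, []).extend(s.is_a_parents)
    stack, visited = [child], set()
    while stack:
        node = stack.pop()
        if node == ancestor:
            return True
        if node in visited:
            continue
        visited.add(node)
        stack.extend(parents.get(node, []))
    return False


def intersection_to_eq(
    clauses: list[IntersectionClause],
    context: list[OntologyDocument] | None = None,
    vocab: RelationVocabulary = DEFAULT_VOCAB,
    strict_quality: bool = False,
    quality_root: str = "PATO:0000001",
) -> EQDescription:
    """Invert :func:`eq_to_intersection`.

    Requires exactly one genus, exactly one ``inheres_in`` differentium, at
    most one ``towards`` and at most one ``has_qualifier``.  With
    ``strict_quality`` enabled and the quality ontology loaded in
    ``context``, the genus must be an is_a descendant of ``quality_root``.
    """
    context = context or []
    defs: dict[str, list[IntersectionClause]] = {}
    for doc in context:
        for s in doc.stanzas:
            if s.intersection_clauses:
                defs[s.id] = s.intersection_clauses

    genus = None
    entity = entity2 = modifier = None
    for c in clauses:
        if c.is_genus:
            if genus is not None:
                raise NotAnEQDefinitionError("more than one genus clause")
            genus = c.filler
        elif c.relation == vocab.inheres_in:
            if entity is not None:
                raise NotAnEQDefinitionError("more than one inheres_in differentium")
            entity = _expand(c.filler, defs, vocab)
        elif c.relation == vocab.towards:
            if entity2 is not None:
                raise NotAnEQDefinitionError("more than one towards differentium")
            entity2 = _expand(c.filler, defs, vocab)
        elif c.relation == vocab.has_qualifier:
            if modifier is not None:
                raise NotAnEQDefinitionError("more than one has_qualifier differentium")
            modifier = c.filler
        else:
            raise UnsupportedPatternError(
                f"differentium relation {c.relation!r} is outside the EQ translation table"
            )
    if genus is None:
        raise NotAnEQDefinitionError("missing genus clause")
    if entity is None:
        raise NotAnEQDefinitionError("missing inheres_in differentium")
    if strict_quality and not _is_a_descendant(context, genus, quality_root):
        raise GenusNotAQualityError(
            f"genus {genus} is not an is_a descendant of the quality root {quality_root}"
        )
    return EQDescription(entity=entity, quality=genus, entity2=entity2, modifier=modifier)


# ---------------------------------------------------------------------------
# EQ line syntax
# ---------------------------------------------------------------------------

_EQ_TAGS = ("ID", "E", "Q", "E2", "M", "EW")


def _parse_caret(text: str, offset: int = 0) -> ClassExpression:
    """Parse ``A^rel(B)`` caret compositions (nestable)."""

    def parse_expr(s: str, base: int) -> tuple[ClassExpression, int]:
        m = re.match(r"[^\^()]+", s)
        if not m:
            raise EQSyntaxError("expected a class name or identifier", base)
        genus = m.group(0).strip()
        i = m.end()
        diffs = []
        while i < len(s) and s[i] == "^":
            i += 1
            rm = re.match(r"[^\^()]+", s[i:])
            if not rm:
                raise EQSyntaxError("expected a relation after '^'", base + i)
            rel = rm.group(0).strip()
            i += rm.end()
            if i >= len(s) or s[i] != "(":
                raise EQSyntaxError("expected '(' after relation", base + i)
            depth, j = 1, i + 1
            while j < len(s) and depth:
                if s[j] == "(":
                    depth += 1
                elif s[j] == ")":
                    depth -= 1
                j += 1
            if depth:
                raise EQSyntaxError("unbalanced parenthesis in caret composition", base + i)
            inner, _ = parse_expr(s[i + 1 : j - 1], base + i + 1)
            diffs.append((rel, inner))
            i = j
        if diffs:
            return ClassExpression.composed(genus, diffs), i
        return ClassExpression.named(genus), i

    expr, consumed = parse_expr(text, offset)
    if consumed != len(text):
        raise EQSyntaxError(f"trailing characters {text[consumed:]!r}", offset + consumed)
    return expr


def _resolve(name: str, lexicon) -> str:
    """Map a filler to an identifier: CURIEs pass through, labels go through
    the lexicon when one is supplied, otherwise they are retained verbatim
    (flagged for curation by the caller via :func:`unresolved_labels`)."""
    name = name.strip()
    if CURIE_RE.match(name):
        return name
    if lexicon is not None:
        hit = lexicon.resolve(name)
        if hit is not None:
            return hit
    return name


def _resolve_expr(expr: ClassExpression, lexicon) -> ClassExpression:
    genus = _resolve(expr.genus.replace("_", " ") if not CURIE_RE.match(expr.genus) else expr.genus, lexicon)
    if expr.is_named:
        return ClassExpression.named(genus)
    return ClassExpression.composed(
        genus, [(r, _resolve_expr(f, lexicon)) for r, f in expr.differentia]
    )


def unresolved_labels(eq: EQDescription) -> list[str]:
    """Fillers that are plain labels rather than identifiers."""

    out: list[str] = []

    def walk(expr: ClassExpression | None):
        if expr is None:
            return
        if not CURIE_RE.match(expr.genus) and expr.genus != "UNRESOLVED":
            out.append(expr.genus)
        for _, f in expr.differentia:
            walk(f)

    walk(eq.entity)
    if not CURIE_RE.match(eq.quality):
        out.append(eq.quality)
    walk(eq.entity2)
    if eq.modifier is not None and not CURIE_RE.match(eq.modifier):
        out.append(eq.modifier)
    walk(eq.entity_whole)
    return out


def parse_eq_text(text: str, lexicon=None) -> list[tuple[str | None, EQDescription]]:
    """Parse EQ line-syntax records.

    Records are blank-line separated blocks of ``TAG = value`` lines with
    tags E, Q, E2, M, EW plus an optional ID line binding the description to
    a pre-composed class.  Fillers may be labels, CURIEs or caret
    compositions; labels are resolved through ``lexicon`` when given, else
    retained verbatim for curation.
    """
    records: list[tuple[str | None, EQDescription]] = []
    block: dict[str, str] = {}

    def flush():
        if not block:
            return
        if "E" not in block or "Q" not in block:
            missing = [t for t in ("E", "Q") if t not in block]
            raise IncompleteDescriptionError(
                f"EQ record lacks mandatory line(s): {', '.join(missing)}"
            )
        entity = _resolve_expr(_parse_caret(block["E"]), lexicon)
        eq = EQDescription(
            entity=entity,
            quality=_resolve(block["Q"], lexicon),
            entity2=_resolve_expr(_parse_caret(block["E2"]), lexicon) if "E2" in block else None,
            modifier=_resolve(block["M"], lexicon) if "M" in block else None,
            entity_whole=_resolve_expr(_parse_caret(block["EW"]), lexicon) if "EW" in block else None,
        )
        records.append((block.get("ID"), eq))
        block.clear()

    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            if not line:
                flush()
            continue
        if "=" not in line:
            raise EQSyntaxError(f"expected 'TAG = value', got {line!r}")
        tag, _, value = line.partition("=")
        tag = tag.strip()
        if tag not in _EQ_TAGS:
            raise EQSyntaxError(f"unknown EQ tag {tag!r}")
        block[tag] = value.strip()
    flush()
    return records


def write_eq_text(records: list[tuple[str | None, EQDescription]]) -> str:
    """Inverse of :func:`parse_eq_text` (on identifier-valued records)."""
    blocks = []
    for rec_id, eq in records:
        lines = []
        if rec_id is not None:
            lines.append(f"ID = {rec_id}")
        lines.append(f"E = {eq.entity.caret()}")
        lines.append(f"Q = {eq.quality}")
        if eq.entity2 is not None:
            lines.append(f"E2 = {eq.entity2.caret()}")
        if eq.modifier is not None:
            lines.append(f"M = {eq.modifier}")
        if eq.entity_whole is not None:
            lines.append(f"EW = {eq.entity_whole.caret()}")
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"


# ---------------------------------------------------------------------------
# OWL Manchester rendering (write-only)
# ---------------------------------------------------------------------------


def _label(class_id: str, labels: dict[str, str] | None) -> str:
    if labels and class_id in labels:
        return labels[class_id]
    return class_id


def _render_expr(expr: ClassExpression, labels, vocab) -> str:
    if expr.is_named:
        return _label(expr.genus, labels)
    parts = [_label(expr.genus, labels)]
    for rel, filler in expr.differentia:
        inner = _render_expr(filler, labels, vocab)
        if not filler.is_named:
            inner = f"({inner})"
        parts.append(f"that {rel} some {inner}")
    return " ".join(parts)


def write_manchester(
    eq: EQDescription,
    labels: dict[str, str] | None = None,
    vocab: RelationVocabulary = DEFAULT_VOCAB,
) -> str:
    """Render ``Q that inheres_in some E [and towards some E2]
    [and has_qualifier some M]`` with composed bearers parenthesized.

    Missing labels fall back to the raw identifier; rendering never fails.
    """
    eq = normalize_entity_whole(eq, vocab)
    entity = _render_expr(eq.entity, labels, vocab)
    if not eq.entity.is_named:
        entity = f"({entity})"
    text = f"{_label(eq.quality, labels)} that {vocab.inheres_in} some {entity}"
    if eq.entity2 is not None:
        e2 = _render_expr(eq.entity2, labels, vocab)
        if not eq.entity2.is_named:
            e2 = f"({e2})"
        text += f" and {vocab.towards} some {e2}"
    if eq.modifier is not None:
        text += f" and {vocab.has_qualifier} some {_label(eq.modifier, labels)}"
    return text


# ---------------------------------------------------------------------------
# Absence phenotypes
# ---------------------------------------------------------------------------

#: Relational number-of-parts qualities (configurable by id or label).
ABSENCE_QUALITIES = {
    "lacking all parts of type": "lacking_all",
    "has fewer parts of type": "fewer",
    "has extra parts of type": "extra",
    "PATO:0002000": "lacking_all",
    "PATO:0002001": "fewer",
    "PATO:0002002": "extra",
}


def translate_absence(
    eq: EQDescription,
    mode: str = "relational",
    vocab: RelationVocabulary = DEFAULT_VOCAB,
    labels: dict[str, str] | None = None,
    absence_qualities: dict[str, str] = ABSENCE_QUALITIES,
):
    """Translate an absence / change-in-number phenotype.

    ``relational`` mode (the default) emits the standard four-clause
    towards pattern; ``cardinality`` mode renders the explicit Manchester
    form ``<E> that has_part exactly 0 <E2>``, which exists only for the
    lacking-all-parts quality -- relative counts ('fewer', 'extra') have no
    cardinality form.  The cardinality form is render-only: no reasoning
    rule consumes it, and it can contradict the anatomy ontology.
    """
    kind = absence_qualities.get(eq.quality) or (
        labels and absence_qualities.get(labels.get(eq.quality, ""))
    )
    if kind is None or eq.entity2 is None:
        raise NotAnEQDefinitionError(
            "absence translation needs a number-of-parts relational quality with E2 set"
        )
    if mode == "relational":
        clauses, _ = eq_to_intersection(eq, vocab)
        return clauses
    if mode == "cardinality":
        if kind != "lacking_all":
            raise UnsupportedCardinalityError(
                "relative increase or decrease in number has no cardinality form"
            )
        e = _render_expr(eq.entity, labels, vocab)
        e2 = _render_expr(eq.entity2, labels, vocab)
        text = f"{e} that {vocab.has_part} exactly 0 {e2}"
        return text[0].upper() + text[1:]
    raise ValueError(f"unknown absence mode {mode!r}")
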