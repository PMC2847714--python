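"""Obol-style decomposition of phenotype class labels into EQ candidates.

Pre-composed phenotype ontologies mint their classes with highly regular
labels ("big ears", "decreased diameter of femur", "abnormal Purkinje cell
dendrite morphology").  This module rebuilds candidate logical definitions
from those labels using lexicons harvested from the loaded ontologies'
names and EXACT synonyms, applying a declarative production set (see
``data/default_grammar.yaml``).

Ambiguity is surfaced, never silently resolved: every maximal parse is
returned, ranked, and a label with more than one candidate is flagged so it
lands in the curation queue rather than in the accepted definition set.
Labels no production covers (clinical eponyms like "situs inversus") yield
an empty candidate list for the same queue.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml

from phenoxp.eq_model import (
    DEFAULT_VOCAB,
    ClassExpression,
    EQDescription,
    RelationVocabulary,
    eq_to_intersection,
    unresolved_labels,
)
from phenoxp.obo_io import OntologyDocument, TermStanza

QUALITY_ROLE = "quality"
BEARER_ROLES = ("gross-anatomy", "cell", "cell-component", "process", "chemical")

#: Placeholder bearer for productions that cannot derive E from the label
#: (the whole lacking an "absent X" part comes from anatomical knowledge,
#: not from the label) -- routed to curation.
UNRESOLVED = "UNRESOLVED"


def load_grammar(path: str | None = None) -> dict:
    """Load a grammar config; defaults to the packaged production set."""
    if path is None:
        ref = importlib.resources.files("phenoxp") / "data" / "default_grammar.yaml"
        return yaml.safe_load(ref.read_text(encoding="utf-8"))
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _normalize_tokens(text: str) -> tuple[str, ...]:
    return tuple(text.lower().replace("-", " ").replace("_", " ").split())


@dataclass
class Lexicon:
    """Token-sequence lookup tables built from ontology labels and EXACT
    synonyms.  One key may map to several ids; collisions are preserved."""

    quality_entries: dict[tuple[str, ...], list[str]] = field(default_factory=dict)
    bearer_entries: dict[tuple[str, ...], list[tuple[str, str]]] = field(default_factory=dict)
    irregular_plurals: dict[str, str] = field(default_factory=dict)

    def _singular_variant(self, key: tuple[str, ...]) -> tuple[str, ...] | None:
        """Singularize the head (last) token: irregulars, then s-stripping."""
        if not key:
            return None
        last = key[-1]
        if last in self.irregular_plurals:
            return key[:-1] + (self.irregular_plurals[last],)
        if last.endswith("s") and len(last) > 2:
            return key[:-1] + (last[:-1],)
        return None

    def lookup_quality(self, key: tuple[str, ...]) -> list[str]:
        return list(self.quality_entries.get(key, ()))

    def lookup_bearer(self, key: tuple[str, ...], roles=None) -> list[tuple[str, str]]:
        hits = list(self.bearer_entries.get(key, ()))
        if not hits:
            alt = self._singular_variant(key)
            if alt is not None:
                hits = list(self.bearer_entries.get(alt, ()))
        if roles is not None:
            hits = [h for h in hits if h[1] in roles]
        return hits

    def resolve(self, label: str) -> str | None:
        """Unique id for a label across all entries, else ``None``."""
        key = _normalize_tokens(label)
        ids = set(self.lookup_quality(key)) | {i for i, _ in self.lookup_bearer(key)}
        if len(ids) == 1:
            return ids.pop()
        return None


def build_lexicon(
    ontologies: list[tuple[OntologyDocument, str]],
    grammar: dict | None = None,
) -> Lexicon:
    """Harvest names and EXACT synonyms of every non-obsolete class.

    ``ontologies`` pairs each document with its role (``quality`` or one of
    the bearer roles).  Normalization lowercases and splits on whitespace
    and hyphens; key collisions accumulate rather than overwrite.
    """
    grammar = grammar or load_grammar()
    lex = Lexicon(irregular_plurals=dict(grammar.get("irregular_plurals", {})))
    for doc, role in ontologies:
        for s in doc.stanzas:
            if s.is_obsolete:
                continue
            names = [s.name] if s.name else []
            names.extend(text for text, scope in s.synonyms if scope == "EXACT")
            for name in names:
                key = _normalize_tokens(name)
                if not key:
                    continue
                if role == QUALITY_ROLE:
                    bucket = lex.quality_entries.setdefault(key, [])
                    if s.id not in bucket:
                        bucket.append(s.id)
                else:
                    bucket = lex.bearer_entries.setdefault(key, [])
                    if (s.id, role) not in bucket:
                        bucket.append((s.id, role))
    return lex


@dataclass(frozen=True)
class ParseCandidate:
    eq: EQDescription
    rule: str
    spans: tuple[tuple[int, int, str], ...]  # (start, end, slot) tiling the label
    bearer_span: int
    role: str


@dataclass
class ParseResult:
    label: str
    candidates: list[ParseCandidate]
    unmatched_tokens: list[str]

    @property
    def is_ambiguous(self) -> bool:
        return len(self.candidates) > 1


def _bearer_matches(
    lexicon: Lexicon, tokens: tuple[str, ...], start: int, end: int, grammar: dict
) -> list[tuple[ClassExpression, str, str]]:
    """All resolutions of ``tokens[start:end]`` as a bearer.

    Tries the whole span as a single lexicon entry first; failing or in
    addition to that, tries compound splits (component suffix preceded by a
    structure prefix, longest suffix first -- phenotype labels are
    head-final) yielding nested ``component^part_of(structure)`` bearers.
    Returns ``(expression, role, note)`` triples.
    """
    span = tokens[start:end]
    if not span:
        return []
    out: list[tuple[ClassExpression, str, str]] = []
    for class_id, role in lexicon.lookup_bearer(span):
        out.append((ClassExpression.named(class_id), role, "simple"))
    comp_roles = set(grammar.get("compound_component_roles", ["cell-component"]))
    struct_roles = set(grammar.get("compound_structure_roles", ["gross-anatomy", "cell"]))
    for split in range(start + 1, end):
        suffix_hits = lexicon.lookup_bearer(tokens[split:end], roles=comp_roles)
        if not suffix_hits:
            continue
        prefix_hits = lexicon.lookup_bearer(tokens[start:split], roles=struct_roles)
        for comp_id, comp_role in suffix_hits:
            for struct_id, _ in prefix_hits:
                expr = ClassExpression.composed(
                    comp_id, [("part_of", ClassExpression.named(struct_id))]
                )
                out.append((expr, comp_role, "compound"))
    return out


_ROLE_RANK = {role: i for i, role in enumerate(BEARER_ROLES)}


def parse_label(
    label: str,
    lexicon: Lexicon,
    vocab: RelationVocabulary = DEFAULT_VOCAB,
    grammar: dict | None = None,
) -> ParseResult:
    """Apply the production set to a label and return all maximal parses.

    Candidates tile the whole label; they are ranked by longest bearer
    span, then bearer-role priority (gross anatomy before cell before
    cell component before process before chemical), then production order.
    Failure is an empty candidate list, never an exception: unmapped labels
    are a curation queue, mirroring the manual step needed for clinical
    terms.
    """
    grammar = grammar or load_grammar()
    role_priority = {r: i for i, r in enumerate(grammar.get("role_priority", BEARER_ROLES))}
    tokens = _normalize_tokens(label)
    raw: list[tuple[tuple, ParseCandidate]] = []

    for prod_idx, prod in enumerate(grammar["productions"]):
        pattern: list[str] = prod["pattern"]
        # supported shapes: optional literals around one <Q> and/or one
        # <E>/<E2> slot; enumerate every split of the token sequence
        for cand in _match_pattern(pattern, tokens, lexicon, grammar, prod, vocab):
            eq, name, spans, bearer_span, role = cand
            rank = (
                -bearer_span,
                role_priority.get(role, len(role_priority)),
                prod_idx,
            )
            raw.append((rank, ParseCandidate(eq, name, spans, bearer_span, role)))

    raw.sort(key=lambda rc: rc[0])
    seen: set = set()
    candidates = []
    for _, cand in raw:
        key = (cand.eq, cand.rule)
        if key in seen:
            continue
        seen.add(key)
        candidates.append(cand)

    covered = {t for key in lexicon.quality_entries for t in key} | {
        t for key in lexicon.bearer_entries for t in key
    }
    literals = {"of", "abnormal", "morphology", "absent"}
    unmatched = [
        t
        for t in tokens
        if t not in covered
        and t not in literals
        and (lexicon._singular_variant((t,)) or (t,))[0] not in covered
    ]
    return ParseResult(label=label, candidates=candidates, unmatched_tokens=unmatched)


def _match_pattern(pattern, tokens, lexicon, grammar, prod, vocab):
    """Enumerate full-coverage matches of one production pattern."""
    n = len(tokens)

    def element_matches(elem, start):
        """Yield (end, binding) pairs for one pattern element from start."""
        if elem == "<Q>":
            for end in range(start + 1, n + 1):
                for qid in lexicon.lookup_quality(tokens[start:end]):
                    yield end, ("Q", qid, end - start)
        elif elem in ("<E>", "<E2>"):
            for end in range(start + 1, n + 1):
                for expr, role, note in _bearer_matches(lexicon, tokens, start, end, grammar):
                    yield end, (elem.strip("<>"), (expr, role, note), end - start)
        else:  # literal
            lit = _normalize_tokens(elem)
            if tokens[start : start + len(lit)] == lit:
                yield start + len(lit), None

    def walk(idx, start, bindings, spans):
        if idx == len(pattern):
            if start == n:
                yield bindings, spans
            return
        elem = pattern[idx]
        for end, binding in element_matches(elem, start):
            b2 = bindings + ([binding] if binding else [])
            s2 = spans + [(start, end, elem if binding else "literal")]
            yield from walk(idx + 1, end, b2, s2)

    for bindings, spans in walk(0, 0, [], []):
        bound = {b[0]: b[1:] for b in bindings}
        quality = None
        if "Q" in bound:
            quality = bound["Q"][0]
        elif prod.get("quality_label"):
            hits = lexicon.lookup_quality(_normalize_tokens(prod["quality_label"]))
            quality = hits[0] if len(hits) == 1 else prod["quality_label"]
        elif prod.get("quality_root"):
            quality = grammar.get("quality_root_id", "PATO:0000001")
        if quality is None:
            continue
        modifier = None
        if prod.get("modifier_label"):
            hits = lexicon.lookup_quality(_normalize_tokens(prod["modifier_label"]))
            modifier = hits[0] if len(hits) == 1 else prod["modifier_label"]
        entity = entity2 = None
        bearer_span, role, note = 0, "", "simple"
        if "E" in bound:
            (expr, role, note), bearer_span = bound["E"][0], bound["E"][1]
            entity = expr
        if "E2" in bound:
            (expr2, role, note), bearer_span = bound["E2"][0], bound["E2"][1]
            entity2 = expr2
        if prod.get("entity_unresolved"):
            entity = ClassExpression.named(UNRESOLVED)
        if entity is None:
            continue
        eq = EQDescription(entity=entity, quality=quality, entity2=entity2, modifier=modifier)
        rule = prod["name"] + ("+compound-bearer" if note == "compound" else "")
        yield eq, rule, tuple(spans), bearer_span, role


@dataclass
class CurationEntry:
    label: str
    class_id: str | None
    candidates: list[ParseCandidate]
    unmatched_tokens: list[str]
    reason: str


@dataclass
class BatchParseReport:
    stanzas: list[TermStanza]
    queue: list[CurationEntry]
    coverage: float


def batch_parse(
    ontology: OntologyDocument,
    lexicon: Lexicon,
    vocab: RelationVocabulary = DEFAULT_VOCAB,
    grammar: dict | None = None,
) -> BatchParseReport:
    """Parse every non-obsolete class label of an ontology.

    Unambiguous, fully-resolved single-candidate parses become XP
    intersection stanzas (auxiliary stanzas for composed bearers included);
    everything else -- no parse, several parses, or unresolved fillers --
    goes to the curation queue.  Coverage is the accepted fraction of
    non-obsolete classes.
    """
    grammar = grammar or load_grammar()
    stanzas: list[TermStanza] = []
    emitted_aux: set[str] = set()
    queue: list[CurationEntry] = []
    total = accepted = 0
    for s in ontology.stanzas:
        if s.is_obsolete or not s.name:
            continue
        total += 1
        result = parse_label(s.name, lexicon, vocab, grammar)
        if not result.candidates:
            queue.append(CurationEntry(s.name, s.id, [], result.unmatched_tokens, "no parse"))
            continue
        if result.is_ambiguous:
            queue.append(
                CurationEntry(s.name, s.id, result.candidates, result.unmatched_tokens, "ambiguous")
            )
            continue
        cand = result.candidates[0]
        if unresolved_labels(cand.eq) or cand.eq.entity.genus == UNRESOLVED:
            queue.append(
                CurationEntry(s.name, s.id, [cand], result.unmatched_tokens, "unresolved filler")
            )
            continue
        clauses, aux = eq_to_intersection(cand.eq, vocab)
        for a in aux:
            if a.id not in emitted_aux:
                emitted_aux.add(a.id)
                stanzas.append(a)
        stanzas.append(TermStanza(id=s.id, intersection_clauses=clauses))
        accepted += 1
    coverage = accepted / total if total else 0.0
    return BatchParseReport(stanzas=stanzas, queue=queue, coverage=coverage)


def write_curation_queue(queue: list[CurationEntry]) -> str:
    """Tab-separated curation report: label, candidate count, candidates,
    unmatched tokens."""
    lines = ["label\tclass_id\tn_candidates\tcandidates\tunmatched_tokens\treason"]
    for entry in queue:
        cands = "; ".join(
            f"{c.rule}: E={c.eq.entity.caret()} Q={c.eq.quality}"
            + (f" E2={c.eq.entity2.caret()}" if c.eq.entity2 else "")
            + (f" M={c.eq.modifier}" if c.eq.modifier else "")
            for c in entry.candidates
        )
        lines.append(
            "\t".join(
                [
                    entry.label,
                    entry.class_id or "",
                    str(len(entry.candidates)),
                    cands,
                    " ".join(entry.unmatched_tokens),
                    entry.reason,
                ]
            )
        )
    return "\n".join(lines) + "\n"
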