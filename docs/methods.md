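# Methods

## The EQ model and its encoding

A phenotype description is a tuple (E, Q, E2, M): a **quality** Q from the
quality ontology inhering in an **entity** E, optionally directed
`towards` a second entity E2 (relational qualities such as
'concentration of iron') and qualified by a modifier M (in practice
'abnormal'; the package deliberately represents abnormality only as a
`has_qualifier` filler, never as a boolean, and takes no position on the
normal/abnormal modelling debate).  The **EW** (entity whole) tag is
surface syntax only: `E = dendrite, EW = Purkinje cell` is normalized on
input to the nested bearer `dendrite^part_of(Purkinje cell)`, and the
caret composition is the canonical internal form.  One canonical form
keeps translation and reasoning single-pathed; `denormalize_entity_whole`
recovers the surface form for tabular presentation.

The translation to a class intersection is fixed: genus = Q, differentia
`inheres_in E` (+ `towards E2`, + `has_qualifier M`).  It is a bijection on
valid descriptions (property-tested), with two deliberate asymmetries:

* Composed bearers are **materialized** as auxiliary stanzas whose ids are
  `XP:` plus a content hash of the canonical caret rendering.  Hashing
  makes repeated materialization stable across runs and processes with no
  shared counter state; equal expressions (differentia compared in sorted
  order) always get the same id.
* E2 may be a composed expression even though every published example is
  named; symmetric treatment costs nothing.

Relation identifiers (`inheres_in`, `towards`, `has_qualifier`, `part_of`,
`has_part`) are not standardized CURIEs across deployments, so they are
configuration (`RelationVocabulary`), defaulting to the plain OBO
shorthand names used in published cross-product files.

**Absence phenotypes.**  'Absent spleen' is encoded against the entity
that *lacks* the part (`E = abdomen, Q = lacking all parts of type,
E2 = spleen`), because a nonexistent spleen cannot bear a quality.  The
explicit cardinality form (`Abdomen that has_part exactly 0 spleen`) is
available render-only and only for the lacking-all-parts quality:
relative counts ('fewer', 'extra') have no cardinality reading, and the
explicit form can contradict the anatomy ontology, so no reasoning rule
consumes it.  The cardinality rendering capitalizes its first letter
(class-frame style); the `inheres_in` renderings are emitted lowercase.

## OBO handling

The reader/writer covers the tag subset the method touches
(`format-version`, `ontology`, `id`, `name`, `namespace`, `synonym`,
`is_a`, `relationship`, `intersection_of`, `is_obsolete`, plus Typedef
transitivity declarations); unknown tags pass through verbatim so foreign
files survive a parse→write cycle.  Trailing `!` comments are labels for
humans: they are stripped before interpretation and regenerated from an
id→label dictionary on writing (omitted when the label is unknown rather
than guessed).  Structural invariants are enforced at parse time: unique
stanza ids, intersection arity 0 or ≥ 2 (a definition needs a genus and a
differentium), no links on obsolete stanzas.  Dangling references are
legal — cross-product files intentionally point into external ontologies —
and surfaced by a separate lint rather than an error.  Only EXACT synonyms
feed the label lexicon.

## Label grammar

Lexicons map normalized token sequences (lowercase, hyphens split,
plural-normalized via an irregular table plus trailing-`s` fallback) to
class ids, keeping collisions.  The production set is data
(`data/default_grammar.yaml`), not code, so per-ontology grammars can
mirror each phenotype ontology's terminological conventions; the default
grammar ships quality+bearer, quality-of-bearer, abnormal-X-morphology,
abnormal-X (quality root + modifier), abnormality-of-X, and absent-X
productions.  Bearer spans may be compound: a cell-component entry
preceded by an anatomical/cell entry yields a nested
`component^part_of(structure)` bearer.  Compound matching is
right-anchored (English phenotype labels are head-final) — a documented
heuristic, not a claim about grammar.

Two principles are absolute: *no silent choice* (every maximal parse is
returned; more than one candidate flags the label ambiguous and routes it
to the curation queue) and *failure is a queue, not an error* (clinical
eponyms like 'situs inversus' simply produce no candidates).  The
absent-X production leaves E unresolved: deriving the whole that lacks
the part requires anatomical knowledge the label does not contain.

## Reasoner

Forward-chaining least fixpoint over these rules:

* **R1/R2** transitivity of `is_a` and of declared-transitive relations
  (default `{is_a, part_of}`, plus any `is_transitive` Typedef).
* **R3** composition with `is_a`, both sides: `A r B, B is_a C ⇒ A r C`
  and `A is_a B, B r C ⇒ A r C`.
* **R4** definition necessity: a defined class is_a its genus and bears
  each differentium.
* **R5** definition sufficiency: any class satisfying every condition of a
  definition is classified under the defined class.
* **R6** (off by default) quality propagation over part_of:
  `Q inheres_in P, P part_of W ⇒ Q inheres_in_part_of W`.  Part-to-whole
  quality inheritance is not generally valid, so the propagated relation
  is distinct and never masquerades as plain `inheres_in`; definitions
  that intend "the bearer or any of its parts" (e.g. 'abnormal facial
  morphology' covering the snout) state `inheres_in_part_of` explicitly
  and only fire when R6 is enabled.  The consistency lint enables R6 for
  its analysis since part_of paths are among what it diagnoses.

Evaluation is semi-naive (rules re-fire only against the newest edge
delta) with a final verification sweep for R5 premises satisfied purely by
identity; termination is guaranteed by the finite edge universe.
Correctness is anchored to an independently written naive-saturation
oracle (`phenoxp._naive`, full re-scan per pass, no indexing, no shared
code) — the two are compared edge-for-edge on 200 random documents in the
test suite, and the closure is additionally checked to be idempotent,
monotone and rule-order independent.  Reflexive `is_a` edges are used
implicitly when matching premises but never materialized or emitted.
Cycles among *asserted* `is_a` links abort with the offending cycle;
mutual subsumption arising from duplicate definitions is a legitimate
entailment and is not treated as an error.  Cardinality-form absence
axioms are inert: no rule consumes `has_part exactly 0`, consistent with
deferring that semantics to non-monotonic approaches.

Novel-link extraction returns inferred, non-asserted, non-reflexive
`is_a` edges within the target ontology's prefix, filtered to *direct*
links (no distinct intermediate in the closure) and sorted; each carries
its full premise chain for curator review.  Entity queries return every
defined class whose bearer falls under the query entity reflexively;
bridging axioms (plain `is_a` links folded in by `merge_bridge`, supplied
as OBO or two-column TSV) extend results across species ontologies with
no additional machinery.  Segmented reasoning (per cross-product subset)
is exposed on the CLI with the caveat that results can be incomplete for
definitions spanning several entity ontologies.

## Validation procedures

**Recapitulation** withholds every `is_a` link between phenotype classes
(support ontologies untouched), recomputes the closure, and classifies
each original link as recovered or missed.  Recovery counts
direct-or-indirect entailment — the experiment measures reconstructible
links, not graph isomorphism.  Two recall denominators are reported:
over all asserted links, and over links whose both endpoints carry
definitions; the first mixes definition quality with definition coverage,
the second isolates quality.  Novel links here are restricted to direct
edges with phenotype-class intermediates.

**Consistency lint** reports (a) asserted links that cannot be entailed
because the reference ontologies contain no `is_a`/`part_of` path between
the two definitions' bearers (the missing `snout part_of face` pattern),
and (b) reference-ontology subsumptions whose correspondingly-defined
phenotype classes (same genus, qualifier and towards-filler, differing in
the bearer) are unrelated in the phenotype ontology (the pancreatic
delta-cell pattern).  Type (b) deliberately compares only
single-filler-difference pairs; broader definition diffing is out of
scope.  Curation verdicts are pending / accepted / rejected /
partially-correct, mutually exclusive, and round-trip through the
tab-separated report format.

## Fixtures and the suite generator

The paper-fixture mini-ontologies reproduce every worked example with the
published identifiers where they are printed unambiguously.  Two classes
('Purkinje cell degeneration' and 'axon degeneration') share one id
across different published tables; the fixture mints private `MP:8xxxxxx`
ids for both rather than perpetuating the collision.  The fixture's
'neurodegeneration' is defined as degeneration of a CNS neuron so that it
sits strictly between 'Purkinje cell degeneration' and 'neuron
degeneration', which lets the withheld-link experiment propose exactly
the historical missing link plus its motor-neuron sibling, each supported
by the CL hierarchy.

The suite generator builds rooted random DAGs for the quality and entity
ontologies (every non-root node draws 1–2 parents among earlier nodes),
defines a configurable fraction of phenotype classes from sampled
(Q, E[, E2, M]) tuples with unique signatures (15% nested bearers, 15%
towards, 20% modifier by default, 30 phenotype / 12 quality / 16 entity
classes — sizes chosen so a single suite exercises nesting, multiple
parents and redundant paths while closing in milliseconds), and computes
the entailed set **with the naive oracle, never the production
reasoner**.  Withheld links are sampled from *direct* entailed links only
(indirect ones would not reappear as direct proposals); unsupported extra
links are sampled outside the entailed set with an explicit acyclicity
check, modelling hand-asserted links that no axiom supports.  Expected
recall and the expected novel set are therefore exact, with no tolerance.
All randomness flows from one seeded PRNG; the seed is recorded in the
emitted file headers, and identical parameters give byte-identical
documents.

What the generator does *not* emulate: the class-count ratios, depth
distributions and label messiness of real MP/MA/CL releases.  Passing the
generated-suite checks demonstrates the machinery's correctness, not that
real-ontology recall would match any particular figure — the published
whole-ontology counts depend on specific 2009-era releases and curated
mapping files that cannot be reconstructed at fixture scale.

## Problem sizes and numerical choices

The bundled evaluations use 200 random documents of ≤ 40 classes for the
oracle comparison, 20 generated suites for recapitulation, 500
synthesized labels for grammar soundness and 100 documents for round-trip
robustness.  All comparisons are exact (set equality, byte equality, or
error-free float division of small integer counts); no tolerances are
involved anywhere.  Ties in candidate ranking are broken by bearer-span
length, then bearer-role priority (gross anatomy > cell > cell component
> process > chemical), then production order; ranking is deterministic.

## Known limitations

* No OWL-DL semantics: no negation, disjointness, equivalence-class
  detection beyond mutual subsumption, or cardinality reasoning;
  Manchester syntax is write-only.
* The default grammar implements the productions that are documented for
  the published mapping effort; the full historical grammar set is larger,
  which is exactly why the grammar is a config file.
* Strict quality-genus checking is opt-in because cross-product files are
  routinely authored before the quality ontology is loaded.
* The reasoner fixes one rule set; historical reasoners disagreed on some
  entailments, and no claim of identity to any of them is made.
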