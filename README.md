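# phenoxp

Entity–Quality (EQ) logical definitions for pre-composed phenotype
ontologies: cross-product translation, label decomposition, forward-chaining
reasoning, and link recapitulation.

## The problem

Phenotype data is annotated in two incompatible styles.  *Pre-composed*
ontologies such as the Mammalian Phenotype ontology (MP) or the Human
Phenotype ontology (HP) mint a named class per phenotype ('big ears',
'Purkinje cell degeneration') and arrange them in an `is_a` hierarchy by
hand.  *Post-composed* annotation (zebrafish, fly) instead assembles a
description at curation time from an entity ontology class and a quality
ontology (PATO) class.  The two styles become interoperable once each
pre-composed class carries a **logical definition** — an equivalence to an
EQ description:

```
E  = entity bearing the quality          (MA, CL, GO, CHEBI, FMA, …)
Q  = the quality itself                  (PATO)
E2 = second entity, for relational qualities   (optional)
M  = modifier, typically 'abnormal'            (optional)
EW = whole the bearer is part of (surface sugar; optional)
```

which translates to a genus–differentia class intersection:

```
intersection_of: <Q>                  ← genus
intersection_of: inheres_in <E>       ← differentium
intersection_of: towards <E2>         (iff E2)
intersection_of: has_qualifier <M>    (iff M)
```

equivalently, in OWL Manchester syntax,
`<Q> that inheres_in some <E> [and towards some <E2>] [and has_qualifier some <M>]`.

Given such definitions a reasoner can *recompute* the hand-built `is_a`
hierarchy from the reference ontologies — recovering asserted links
(validation), proposing missing ones (curation), and answering
cross-species queries through bridging axioms between anatomy ontologies.

## What the package provides

| module | contents |
|---|---|
| `phenoxp.obo_io` | OBO 1.2 subset reader/writer, round-trip faithful, `!`-comment aware |
| `phenoxp.eq_model` | EQ descriptions, caret compositions `A^rel(B)`, EQ↔intersection translation, Manchester rendering, absence phenotypes (relational + cardinality forms) |
| `phenoxp.label_grammar` | Obol-style label decomposition with ontology-derived lexicons and a declarative production grammar |
| `phenoxp.reasoner` | semi-naive forward-chaining closure (transitivity, is_a composition, definition necessity/sufficiency, optional part_of quality propagation), per-edge provenance |
| `phenoxp.validation` | is_a recapitulation with two recall denominators, curation reports, consistency lint, coverage statistics |
| `phenoxp.fixtures` | worked-example mini-ontologies and a seeded suite generator with construction-known ground truth |
| `phenoxp.cli` | `phenoxp` command: `translate`, `parse-labels`, `reason`, `suggest-links`, `recapitulate`, `lint`, `coverage`, `query`, `fixture` |

## Worked example

`examples/03_reason_and_suggest.py` withholds two `is_a` links from the
bundled mini phenotype ontology and asks the reasoner to re-derive them
from the logical definitions plus the cell ontology:

```
closure: 239 edges over 79 classes
novel direct is_a links proposed: 2

subject_id  subject_label               object_id   object_label         rule_chain ...
MP:0000938  motor neuron degeneration   MP:0003224  neuron degeneration  [R5] ... <= [asserted] motor neuron is_a neuron
MP:8000001  Purkinje cell degeneration  MP:0002229  neurodegeneration    [R5] ... <= [asserted] Purkinje cell is_a CNS neuron
```

Both proposals follow purely from the cell-ontology chain *Purkinje cell
is_a CNS neuron is_a neuron* and the definitions `degenerate ⊓ inheres_in
<cell type>`: a class satisfying a stronger definition is classified under
every class whose full definition it satisfies (rule R5), so the curator
sees exactly which premises support each proposed link.

`examples/04_recapitulate.py` runs the recapitulation experiment on a
generated suite (seed 4): all 45 phenotype `is_a` assertions are withheld
and 37 are recovered from the definitions alone (recall 82.2%); the 8
misses are exactly the links generated without supporting axioms, and the
5 proposed novel links are exactly the withheld entailed ones.

The other examples cover EQ translation and Manchester rendering
(`01_translate_eq.py`), label decomposition including the nested
`dendrite^part_of(Purkinje cell)` bearer (`02_parse_labels.py`), and a
cross-species query through a mouse-tooth → tooth bridging axiom
(`05_cross_species_query.py`).

The same workflows are available from the shell, e.g.:

```sh
phenoxp fixture --paper --withheld-variant --outdir fix
phenoxp suggest-links --prefix MP -d fix/xp-defs.obo \
    -o fix/mini-pato.obo -o fix/mini-cl.obo -o fix/mini-ma.obo \
    -o fix/mini-go.obo -o fix/mini-chebi.obo -o fix/mini-mp.obo
```

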