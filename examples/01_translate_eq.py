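"""Translate EQ descriptions to OBO intersections and Manchester text.

Builds the 'big ears' description (increased size inhering in the ear),
renders it as an OBO cross-product stanza, then shows a nested bearer
(the dendrite of a Purkinje cell) and the two encodings of an absence
phenotype.
"""

from phenoxp import fixtures as fx
from phenoxp.eq_model import (
    ClassExpression,
    EQDescription,
    eq_to_intersection,
    normalize_entity_whole,
    translate_absence,
    write_manchester,
)
from phenoxp.obo_io import OntologyDocument, TermStanza, write_obo

E = ClassExpression.named

labels = fx.build_paper_fixture().labels()

# 'big ears' = increased size (PATO) inhering in ear (MA)
big_ears = EQDescription(E("MA:0000236"), "PATO:0000586")
clauses, _aux = eq_to_intersection(big_ears)
doc = OntologyDocument(stanzas=[TermStanza(id="MP:0000017", intersection_clauses=clauses)])
print("--- OBO cross-product stanza ---")
print(write_obo(doc, comments={**labels, "MP:0000017": "big ears"}))

# nested bearer via the EW (entity whole) surface tag
nested = EQDescription(
    E("GO:0030425"), "PATO:0000051", modifier="PATO:0000460", entity_whole=E("CL:0000121")
)
print("--- Manchester rendering of a nested bearer ---")
print(write_manchester(normalize_entity_whole(nested), labels))

# absence: relational quality vs explicit cardinality
absent_spleen = EQDescription(E("MA:0000029"), "PATO:0002000", entity2=E("MA:0000141"))
rel = translate_absence(absent_spleen, "relational")
print("\n--- absent spleen, relational form (clauses) ---")
for c in rel:
    print(f"  intersection_of: {(c.relation + ' ') if c.relation else ''}{c.filler}")
print("--- absent spleen, cardinality form (render-only) ---")
print(" ", translate_absence(absent_spleen, "cardinality", labels=labels))

# The stanza is the machine-readable logical definition; the Manchester
# strings are the human-readable equivalents of the same intersections.
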