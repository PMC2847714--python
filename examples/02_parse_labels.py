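"""Decompose phenotype class labels into candidate EQ definitions.

Builds a lexicon from the bundled mini-ontologies and parses a few labels,
showing a plain quality+bearer parse, a nested compound bearer, and a
clinical term that no production covers (routed to the curation queue).
"""

from phenoxp import fixtures as fx
from phenoxp.label_grammar import build_lexicon, parse_label

pf = fx.build_paper_fixture()
lexicon = build_lexicon(pf.lexicon_inputs())
labels = pf.labels()

for label in (
    "big ears",
    "decreased diameter of femur",
    "abnormal Purkinje cell dendrite morphology",
    "absent spleen",
    "situs inversus",
):
    result = parse_label(label, lexicon)
    print(f"{label!r}:")
    if not result.candidates:
        print(f"  no parse -> curation queue (unmatched: {result.unmatched_tokens})")
        continue
    for cand in result.candidates:
        eq = cand.eq
        parts = [f"E={eq.entity.caret()}", f"Q={eq.quality}"]
        if eq.entity2:
            parts.append(f"E2={eq.entity2.caret()}")
        if eq.modifier:
            parts.append(f"M={eq.modifier}")
        print(f"  [{cand.rule}] " + " ".join(parts))

# Each candidate is a machine-checkable hypothesis about what the label
# means; ambiguous or unparseable labels are surfaced for a curator rather
# than silently resolved.
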