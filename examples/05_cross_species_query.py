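"""Cross-ontology phenotype query through a bridging axiom.

The mini phenotype ontology defines 'abnormal tooth morphology' against the
species-specific mouse 'tooth' class.  A bridging axiom states that the
mouse tooth is a subclass of the multi-species 'tooth' class, which lets a
query phrased against the generic class find the mouse phenotype.
"""

from phenoxp import fixtures as fx
from phenoxp.errors import UnknownClassError
from phenoxp.obo_io import merge_documents
from phenoxp.reasoner import apply_definitions, compute_closure, merge_bridge, query_phenotypes_by_entity

pf = fx.build_paper_fixture()
merged = apply_definitions(merge_documents([pf.mini_mp] + pf.support_docs), pf.xp_defs)

without_bridge = compute_closure(merged)
with_bridge = compute_closure(merge_bridge(merged, pf.mini_bridge))

print("query: phenotypes whose bearer falls under the multi-species 'tooth'")
try:
    query_phenotypes_by_entity(without_bridge, "UBERON:0001091")
except UnknownClassError as exc:
    print(f"  without bridge: {exc}")
hits = query_phenotypes_by_entity(with_bridge, "UBERON:0001091")
for h in hits:
    print(f"  with bridge:    {h}  ({with_bridge.labels.get(h, '')})")

print("\nquery: phenotypes of 'neuron' (plain within-suite subsumption)")
for h in query_phenotypes_by_entity(with_bridge, "CL:0000540"):
    print(f"  {h}  ({with_bridge.labels.get(h, '')})")

# The bridge is a single is_a axiom; everything else falls out of the
# closure rules, so the same mechanism scales to any number of
# species-specific anatomies mapped into one multi-species ontology.
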