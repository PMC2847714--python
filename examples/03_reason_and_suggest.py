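"""Propose missing is_a links from logical definitions.

Uses the bundled mini phenotype ontology with two links withheld (the
Purkinje-cell degeneration link that was historically missing, plus its
motor-neuron sibling), computes the closure and prints the proposals with
their provenance chains.
"""

from phenoxp import fixtures as fx
from phenoxp.obo_io import merge_documents
from phenoxp.reasoner import apply_definitions, compute_closure, infer_novel_links
from phenoxp.validation import missing_link_report

pf = fx.build_paper_fixture()
merged = apply_definitions(merge_documents([pf.mini_mp_withheld] + pf.support_docs), pf.xp_defs)
closure = compute_closure(merged)

novel = infer_novel_links(closure, "MP")
print(f"closure: {len(closure.edges)} edges over {len(closure.classes)} classes")
print(f"novel direct is_a links proposed: {len(novel)}\n")
print(missing_link_report(closure, novel))

# Both proposals are re-derived purely from the cell-ontology is_a chain
# (Purkinje cell is_a CNS neuron is_a neuron) plus the degenerate-quality
# definitions; a curator would triage the verdict column.
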