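# Default Obol-style production set for decomposing phenotype class labels.
#
# Productions are data, not code: per-ontology grammars mimicking the
# terminological syntax of different phenotype ontologies can be supplied
# without touching the parser.  Pattern elements:
#   <Q>   span matched against the quality lexicon
#   <E>   span matched against the bearer lexicon (compound bearers allowed:
#         a cell-component bearer preceded by an anatomical/cell bearer
#         yields a nested component^part_of(structure) expression)
#   <E2>  bearer span bound to the second entity of a relational quality
#   any other element is a literal token
# Productions are tried in order; all maximal parses are returned.
productions:
  - name: abnormal-morphology     # "abnormal Purkinje cell dendrite morphology"
    pattern: ["abnormal", "<E>", "morphology"]
    quality_label: morphology
    modifier_label: abnormal
  - name: quality-bearer          # "big ears"
    pattern: ["<Q>", "<E>"]
  - name: quality-of-bearer       # "decreased diameter of femur"
    pattern: ["<Q>", "of", "<E>"]
  - name: abnormal-bearer         # "abnormal septation of the cloaca" family
    pattern: ["abnormal", "<E>"]
    quality_root: true
    modifier_label: abnormal
  - name: abnormality-of-bearer   # "abnormality of vision" (HP phrasing)
    pattern: ["abnormality", "of", "<E>"]
    quality_root: true
    modifier_label: abnormal
  - name: absent-bearer           # "absent spleen": E is left for curation
    pattern: ["absent", "<E2>"]
    quality_label: lacking all parts of type
    entity_unresolved: true

# Ranking of bearer sources when the same span resolves in several
# ontologies (highest priority first).
role_priority: [gross-anatomy, cell, cell-component, process, chemical]

# Compound bearers: component role suffix preceded by a structure role prefix.
compound_component_roles: [cell-component]
compound_structure_roles: [gross-anatomy, cell]

# Plural normalization: irregular table first, then trailing-"s" stripping
# is tried as a fallback token variant.
irregular_plurals:
  teeth: tooth
  feet: foot
  ganglia: ganglion
  vertebrae: vertebra
  testes: testis
  ovaries: ovary
  cortices: cortex
  vasa: vas

# Identifier of the quality-ontology root, used by the abnormal-bearer
# production when no specific quality is named in the label.
quality_root_id: PATO:0000001
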