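"""Self-contained test inputs.

Two kinds of fixture live here:

* :func:`build_paper_fixture` -- hand-built mini-ontologies reproducing the
  published worked examples end to end: the 'big ears' stanza, the
  Purkinje-cell degeneration inference, the sixteen example equivalence
  mappings, the hypocalciuria and absent-spleen descriptions, the
  snout/face and pancreatic-delta-cell coherence anecdotes, and the
  mouse-tooth bridging query.
* :func:`generate_suite` -- a seeded random generator emitting a quality
  ontology, entity ontologies and a phenotype ontology with XP definitions
  whose entailed, withheld and unsupported is_a links are known *by
  construction*: entailments are computed with the independent naive
  oracle (:mod:`phenoxp._naive`), never with the production reasoner, so
  the generator and the reasoner cannot share a bug.

Identifier note: where the source tables print an id it is reused verbatim;
classes whose published ids are ambiguous ('Purkinje cell degeneration'
and 'axon degeneration' share one id across different tables) get private
``MP:8xxxxxx`` ids instead.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from phenoxp._naive import naive_closure, naive_entailed_is_a
from phenoxp.errors import GenerationError
from phenoxp.eq_model import ClassExpression, EQDescription
from phenoxp.obo_io import IntersectionClause, LinkClause, OntologyDocument, TermStanza
from phenoxp.reasoner import materialize_expressions

E = ClassExpression.named
C = ClassExpression.composed


def _doc(ontology_id: str, terms, typedefs=()) -> OntologyDocument:
    """terms: (id, name, is_a parents, [relationship tuples], [synonyms])."""
    doc = OntologyDocument(
        ontology_id=ontology_id, header_lines=["format-version: 1.2", f"ontology: {ontology_id}"]
    )
    for term in terms:
        tid, name, parents = term[0], term[1], term[2]
        rels = term[3] if len(term) > 3 else ()
        syns = term[4] if len(term) > 4 else ()
        doc.stanzas.append(
            TermStanza(
                id=tid,
                name=name,
                is_a_parents=list(parents),
                relationships=[LinkClause(r, t) for r, t in rels],
                synonyms=[(s, "EXACT") for s in syns],
                source=ontology_id,
            )
        )
    from phenoxp.obo_io import TypedefStanza

    for rel, transitive in typedefs:
        doc.typedefs.append(
            TypedefStanza(rel, ["is_transitive: true"] if transitive else [], transitive)
        )
    doc.validate()
    return doc


# ---------------------------------------------------------------------------
# Table 4 example rows: (phenotype id, label, EQDescription)
# ---------------------------------------------------------------------------

TABLE4_ROWS: list[tuple[str, str, EQDescription]] = [
    ("MP:0008152", "decreased diameter of femur", EQDescription(E("MA:0001359"), "PATO:0001715")),
    ("MP:0002812", "spherocytosis", EQDescription(E("CL:0000232"), "PATO:0001499")),
    (
        "MP:0008739",
        "abnormal spleen iron level",
        EQDescription(E("MA:0000141"), "PATO:0000033", entity2=E("CHEBI:18248"), modifier="PATO:0000460"),
    ),
    ("MP:0002766", "situs inversus", EQDescription(E("MA:0000019"), "PATO:0000625")),
    ("MP:0000528", "delayed kidney development", EQDescription(E("GO:0001822"), "PATO:0000502")),
    ("MP:0004714", "truncated notochord", EQDescription(E("EMAP:4109"), "PATO:0000936")),
    ("MP:0000938", "motor neuron degeneration", EQDescription(E("CL:0000100"), "PATO:0000639")),
    ("MP:8000002", "axon degeneration", EQDescription(E("GO:0030424"), "PATO:0000639")),
    (
        "MP:0003242",
        "loss of basal ganglion neurons",
        EQDescription(E("MA:0000184"), "PATO:0002001", entity2=E("CL:0000540")),
    ),
    (
        "MP:0008572",
        "abnormal Purkinje cell dendrite morphology",
        EQDescription(
            C("GO:0030425", [("part_of", E("CL:0000121"))]), "PATO:0000051", modifier="PATO:0000460"
        ),
    ),
    ("HP:0000013", "hypoplastic uterus", EQDescription(E("FMA:17558"), "PATO:0000645")),
    (
        "HP:0000504",
        "abnormality of vision",
        EQDescription(E("GO:0007601"), "PATO:0000001", modifier="PATO:0000460"),
    ),
    ("HP:0003275", "narrow pelvis", EQDescription(E("FMA:9578"), "PATO:0000599")),
    ("WBPhenotype:0000086", "shrunken intestine", EQDescription(E("WBbt:0005772"), "PATO:0000585")),
    ("TO:0000540", "leaf area", EQDescription(E("PO:0009025"), "PATO:0001323")),
    (
        "TO:0000163",
        "auxin sensitivity",
        EQDescription(E("PO:0000003"), "PATO:0000085", entity2=E("CHEBI:22676")),
    ),
]


@dataclass
class PaperFixture:
    mini_pato: OntologyDocument
    mini_cl: OntologyDocument
    mini_ma: OntologyDocument
    mini_go: OntologyDocument
    mini_chebi: OntologyDocument
    mini_mp: OntologyDocument
    mini_bridge: OntologyDocument
    xp_defs: OntologyDocument
    mini_mp_withheld: OntologyDocument
    table4: list[tuple[str, str, EQDescription]] = field(default_factory=lambda: list(TABLE4_ROWS))

    @property
    def support_docs(self) -> list[OntologyDocument]:
        return [self.mini_pato, self.mini_cl, self.mini_ma, self.mini_go, self.mini_chebi]

    def labels(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for doc in self.support_docs + [self.mini_mp, self.mini_bridge]:
            out.update(doc.labels())
        return out

    def lexicon_inputs(self) -> list[tuple[OntologyDocument, str]]:
        """(document, role) pairs for :func:`phenoxp.build_lexicon`.

        The mini GO document carries both cellular-component and
        biological-process classes; they are split by namespace into the
        cell-component and process lexicon roles.
        """
        cc = OntologyDocument(ontology_id="go-cc")
        bp = OntologyDocument(ontology_id="go-bp")
        for s in self.mini_go.stanzas:
            (cc if s.namespace == "cellular_component" else bp).stanzas.append(s)
        return [
            (self.mini_pato, "quality"),
            (self.mini_ma, "gross-anatomy"),
            (self.mini_cl, "cell"),
            (cc, "cell-component"),
            (bp, "process"),
            (self.mini_chebi, "chemical"),
        ]


def _mini_pato() -> OntologyDocument:
    return _doc(
        "pato",
        [
            ("PATO:0000001", "quality", []),
            ("PATO:0000051", "morphology", ["PATO:0000001"]),
            ("PATO:0000052", "shape", ["PATO:0000051"]),
            ("PATO:0000117", "size", ["PATO:0000051"]),
            ("PATO:0000586", "increased size", ["PATO:0000117"], (), ["big", "large"]),
            ("PATO:0001334", "diameter", ["PATO:0000117"]),
            ("PATO:0001715", "decreased diameter", ["PATO:0001334"]),
            ("PATO:0000141", "structure", ["PATO:0000051"]),
            ("PATO:0000639", "degenerate", ["PATO:0000141"]),
            ("PATO:0001499", "spherical", ["PATO:0000052"]),
            ("PATO:0000616", "asymmetrical", ["PATO:0000052"], (), ["asymmetric"]),
            ("PATO:0000625", "inverted", ["PATO:0000001"]),
            ("PATO:0000033", "concentration of", ["PATO:0000001"]),
            ("PATO:0001163", "decreased concentration of", ["PATO:0000033"]),
            ("PATO:0000460", "abnormal", ["PATO:0000001"]),
            ("PATO:0000502", "delayed", ["PATO:0000001"]),
            ("PATO:0000936", "truncated", ["PATO:0000051"]),
            ("PATO:0001555", "has number of", ["PATO:0000001"]),
            ("PATO:0002000", "lacking all parts of type", ["PATO:0001555"]),
            ("PATO:0002001", "has fewer parts of type", ["PATO:0001555"]),
            ("PATO:0002002", "has extra parts of type", ["PATO:0001555"]),
            ("PATO:0000645", "hypoplastic", ["PATO:0000051"]),
            ("PATO:0000599", "decreased width", ["PATO:0000117"]),
            ("PATO:0000585", "shrunken", ["PATO:0000051"]),
            ("PATO:0001323", "area", ["PATO:0000117"]),
            ("PATO:0000085", "sensitivity", ["PATO:0000001"]),
        ],
    )


def _mini_cl() -> OntologyDocument:
    return _doc(
        "cl",
        [
            ("CL:0000000", "cell", []),
            ("CL:0000540", "neuron", ["CL:0000000"]),
            ("CL:0000117", "CNS neuron", ["CL:0000540"]),
            ("CL:0000121", "Purkinje cell", ["CL:0000117"]),
            ("CL:0000100", "motor neuron", ["CL:0000540"]),
            ("CL:0000232", "erythrocyte", ["CL:0000000"]),
            ("CL:0000164", "enteroendocrine cell", ["CL:0000000"]),
            ("CL:0000173", "pancreatic delta cell", ["CL:0000164"]),
        ],
    )


def _mini_ma(with_snout_face_link: bool = True) -> OntologyDocument:
    snout_rels = [("part_of", "MA:0000062")] if with_snout_face_link else []
    return _doc(
        "ma",
        [
            ("MA:0000001", "mouse anatomical entity", []),
            ("MA:0000236", "ear", ["MA:0000001"]),
            ("MA:0001359", "femur", ["MA:0000001"]),
            ("MA:0000141", "spleen", ["MA:0000001"]),
            ("MA:0000029", "abdomen", ["MA:0000001"]),
            ("MA:0000062", "face", ["MA:0000001"]),
            ("MA:0000069", "snout", ["MA:0000001"], snout_rels),
            ("MA:0002504", "urine", ["MA:0000001"]),
            ("MA:0000019", "visceral organ system", ["MA:0000001"]),
            ("MA:0000184", "basal ganglia", ["MA:0000001"], (), ["basal ganglion"]),
            ("MA:0000348", "tooth", ["MA:0000001"]),
            ("MA:0000368", "kidney", ["MA:0000001"]),
        ],
        typedefs=[("part_of", True)],
    )


def _mini_go() -> OntologyDocument:
    doc = _doc(
        "go",
        [
            ("GO:0005575", "cellular component", []),
            ("GO:0043005", "neuron projection", ["GO:0005575"]),
            ("GO:0030425", "dendrite", ["GO:0043005"]),
            ("GO:0030424", "axon", ["GO:0043005"]),
            ("GO:0008150", "biological process", []),
            ("GO:0032502", "developmental process", ["GO:0008150"]),
            ("GO:0042476", "tooth development", ["GO:0032502"], (), ["odontogenesis"]),
            ("GO:0001822", "kidney development", ["GO:0032502"]),
            ("GO:0007601", "visual perception", ["GO:0008150"], (), ["vision"]),
        ],
    )
    for s in doc.stanzas:
        s.namespace = (
            "cellular_component"
            if s.id in ("GO:0005575", "GO:0043005", "GO:0030425", "GO:0030424")
            else "biological_process"
        )
    return doc


def _mini_chebi() -> OntologyDocument:
    return _doc(
        "chebi",
        [
            ("CHEBI:24431", "chemical entity", []),
            ("CHEBI:18248", "iron", ["CHEBI:24431"]),
            ("CHEBI:22984", "calcium", ["CHEBI:24431"]),
            ("CHEBI:22676", "auxin", ["CHEBI:24431"]),
        ],
    )


#: Asserted is_a links withheld in the Figure-2 style variant: both were
#: re-derived by the reasoner from the CL is_a hierarchy and submitted to
#: the curators.
WITHHELD_LINKS = [("MP:8000001", "MP:0002229"), ("MP:0000938", "MP:0003224")]


def _mini_mp(withheld: bool = False) -> OntologyDocument:
    def parents(child: str, full: list[str]) -> list[str]:
        if not withheld:
            return full
        kept = [p for p in full if (child, p) not in WITHHELD_LINKS]
        return kept or ["MP:0000001"]

    return _doc(
        "mp",
        [
            ("MP:0000001", "mammalian phenotype", []),
            ("MP:0003224", "neuron degeneration", ["MP:0000001"]),
            ("MP:0002229", "neurodegeneration", parents("MP:0002229", ["MP:0003224"])),
            ("MP:8000001", "Purkinje cell degeneration", parents("MP:8000001", ["MP:0002229"])),
            ("MP:0000938", "motor neuron degeneration", parents("MP:0000938", ["MP:0003224"])),
            ("MP:8000002", "axon degeneration", ["MP:0000001"]),
            ("MP:0000017", "big ears", ["MP:0000001"]),
            ("MP:0008152", "decreased diameter of femur", ["MP:0000001"]),
            ("MP:0002812", "spherocytosis", ["MP:0000001"]),
            ("MP:0008739", "abnormal spleen iron level", ["MP:0000001"]),
            ("MP:0002766", "situs inversus", ["MP:0000001"]),
            ("MP:0000528", "delayed kidney development", ["MP:0000001"]),
            ("MP:0003242", "loss of basal ganglion neurons", ["MP:0000001"]),
            ("MP:0008572", "abnormal Purkinje cell dendrite morphology", ["MP:0000001"]),
            ("MP:0002100", "abnormal tooth morphology", ["MP:0000001"]),
            ("MP:8000005", "hypocalciuria", ["MP:0000001"]),
            ("MP:8000006", "absent spleen", ["MP:0000001"]),
            ("MP:8000004", "abnormal facial morphology", ["MP:0000001"]),
            ("MP:8000003", "asymmetric snout", ["MP:8000004"]),
        ],
    )


#: EQ definitions for the mini MP (id -> description).
MP_EQ_DEFINITIONS: list[tuple[str, EQDescription]] = [
    ("MP:0000017", EQDescription(E("MA:0000236"), "PATO:0000586")),
    ("MP:8000001", EQDescription(E("CL:0000121"), "PATO:0000639")),
    ("MP:0002229", EQDescription(E("CL:0000117"), "PATO:0000639")),
    ("MP:0003224", EQDescription(E("CL:0000540"), "PATO:0000639")),
    ("MP:0000938", EQDescription(E("CL:0000100"), "PATO:0000639")),
    ("MP:8000002", EQDescription(E("GO:0030424"), "PATO:0000639")),
    ("MP:0008152", EQDescription(E("MA:0001359"), "PATO:0001715")),
    ("MP:0002812", EQDescription(E("CL:0000232"), "PATO:0001499")),
    (
        "MP:0008739",
        EQDescription(E("MA:0000141"), "PATO:0000033", entity2=E("CHEBI:18248"), modifier="PATO:0000460"),
    ),
    ("MP:0002766", EQDescription(E("MA:0000019"), "PATO:0000625")),
    ("MP:0000528", EQDescription(E("GO:0001822"), "PATO:0000502")),
    ("MP:0003242", EQDescription(E("MA:0000184"), "PATO:0002001", entity2=E("CL:0000540"))),
    (
        "MP:0008572",
        EQDescription(
            C("GO:0030425", [("part_of", E("CL:0000121"))]), "PATO:0000051", modifier="PATO:0000460"
        ),
    ),
    ("MP:0002100", EQDescription(E("MA:0000348"), "PATO:0000051", modifier="PATO:0000460")),
    ("MP:8000005", EQDescription(E("MA:0002504"), "PATO:0001163", entity2=E("CHEBI:22984"))),
    ("MP:8000006", EQDescription(E("MA:0000029"), "PATO:0002000", entity2=E("MA:0000141"))),
    ("MP:8000003", EQDescription(E("MA:0000069"), "PATO:0000616")),
]


def _xp_defs() -> OntologyDocument:
    doc = materialize_expressions(MP_EQ_DEFINITIONS)
    # 'abnormal facial morphology' covers the face *and its parts*: its
    # bearer slot uses the propagated inheres_in_part_of relation, which the
    # plain EQ template cannot express.
    doc.stanzas.append(
        TermStanza(
            id="MP:8000004",
            intersection_clauses=[
                IntersectionClause(None, "PATO:0000051"),
                IntersectionClause("inheres_in_part_of", "MA:0000062"),
            ],
        )
    )
    doc.validate()
    return doc


def _mini_bridge() -> OntologyDocument:
    """Bridging axioms: the species-specific mouse tooth is a subclass of
    the multi-species 'tooth' class."""
    return _doc(
        "uberon-bridge",
        [
            ("UBERON:0001091", "tooth", []),
            ("MA:0000348", None, ["UBERON:0001091"]),
        ],
    )


def build_paper_fixture() -> PaperFixture:
    return PaperFixture(
        mini_pato=_mini_pato(),
        mini_cl=_mini_cl(),
        mini_ma=_mini_ma(),
        mini_go=_mini_go(),
        mini_chebi=_mini_chebi(),
        mini_mp=_mini_mp(),
        mini_bridge=_mini_bridge(),
        xp_defs=_xp_defs(),
        mini_mp_withheld=_mini_mp(withheld=True),
    )


def mini_ma_without_snout_face() -> OntologyDocument:
    """Variant of the mouse anatomy lacking the snout part_of face link."""
    return _mini_ma(with_snout_face_link=False)


def delta_cell_case() -> tuple[OntologyDocument, OntologyDocument]:
    """The cryptic-inconsistency anecdote: the cell ontology subsumes
    'pancreatic delta cell' under 'enteroendocrine cell', but the two
    correspondingly-defined phenotype classes are unrelated.

    Returns ``(phenotype document, XP definitions)``; reason over these
    with the mini CL and PATO as support.
    """
    mp = _doc(
        "mp-delta",
        [
            ("MP:0000001", "mammalian phenotype", []),
            ("MP:8000007", "abnormal pancreatic delta cell morphology", ["MP:0000001"]),
            ("MP:8000008", "abnormal enteroendocrine cell morphology", ["MP:0000001"]),
        ],
    )
    defs = materialize_expressions(
        [
            ("MP:8000007", EQDescription(E("CL:0000173"), "PATO:0000051", modifier="PATO:0000460")),
            ("MP:8000008", EQDescription(E("CL:0000164"), "PATO:0000051", modifier="PATO:0000460")),
        ]
    )
    return mp, defs


# ---------------------------------------------------------------------------
# Random suite generator
# ---------------------------------------------------------------------------


@dataclass
class GeneratorParams:
    seed: int = 0
    n_quality: int = 12
    n_entity: int = 16
    n_phenotype: int = 30
    max_parents: int = 2
    fraction_defined: float = 0.8
    n_withheld: int = 5
    n_unsupported: int = 8
    nesting_probability: float = 0.15
    towards_probability: float = 0.15
    modifier_probability: float = 0.2


@dataclass
class SuiteResult:
    quality_doc: OntologyDocument
    entity_doc: OntologyDocument
    phenotype_doc: OntologyDocument
    xp_defs: OntologyDocument
    ground_truth: dict

    @property
    def support_docs(self) -> list[OntologyDocument]:
        return [self.quality_doc, self.entity_doc]


def _random_dag(rng: random.Random, prefix: str, label_stem: str, n: int, max_parents: int):
    terms = [(f"{prefix}:{0:07d}", f"{label_stem}0", [])]
    for i in range(1, n):
        k = rng.randint(1, min(max_parents, i))
        parents = sorted(rng.sample(range(i), k))
        terms.append(
            (f"{prefix}:{i:07d}", f"{label_stem}{i}", [f"{prefix}:{p:07d}" for p in parents])
        )
    return terms


def generate_suite(params: GeneratorParams) -> SuiteResult:
    """Emit a random ontology suite with construction-known ground truth.

    The asserted phenotype is_a set is ``(entailed - withheld) ∪
    unsupported`` where *entailed* is computed by the naive oracle from the
    definitions, *withheld* is a sample of direct entailed links (so the
    recapitulation experiment must re-propose exactly these), and
    *unsupported* links are sampled only between classes whose definitions
    do not entail them (so they must be missed).  Identical params produce
    byte-identical documents.
    """
    rng = random.Random(params.seed)
    header_remark = f"remark: generated suite, seed={params.seed}"

    quality_doc = _doc("qx", _random_dag(rng, "QX", "qlty", params.n_quality, params.max_parents))
    entity_doc = _doc(
        "ex",
        _random_dag(rng, "EX", "entx", params.n_entity, params.max_parents),
        typedefs=[("part_of", True)],
    )
    for doc in (quality_doc, entity_doc):
        doc.header_lines.append(header_remark)

    q_ids = quality_doc.ids()
    e_ids = entity_doc.ids()

    eq_records: list[tuple[str, EQDescription]] = []
    names: dict[str, str] = {}
    signatures: set = set()
    labels = {**quality_doc.labels(), **entity_doc.labels()}
    for i in range(params.n_phenotype):
        pid = f"PX:{i:07d}"
        if rng.random() >= params.fraction_defined:
            names[pid] = f"phenotype {i}"
            continue
        for _attempt in range(50):
            q = rng.choice(q_ids)
            e_named = rng.choice(e_ids)
            if rng.random() < params.nesting_probability and params.n_entity > 1:
                whole = rng.choice([x for x in e_ids if x != e_named])
                entity = C(e_named, [("part_of", E(whole))])
            else:
                entity = E(e_named)
            entity2 = E(rng.choice(e_ids)) if rng.random() < params.towards_probability else None
            modifier = rng.choice(q_ids) if rng.random() < params.modifier_probability else None
            eq = EQDescription(entity, q, entity2=entity2, modifier=modifier)
            sig = (entity, q, entity2, modifier)
            if sig not in signatures:
                signatures.add(sig)
                break
        else:
            raise GenerationError("could not sample a fresh definition signature")
        eq_records.append((pid, eq))
        names[pid] = f"{labels[q]} {labels[e_named]}" if entity.is_named else f"phenotype {i}"

    xp_defs = materialize_expressions(eq_records)

    # ground truth from the naive oracle over quality + entity + definitions
    oracle_doc = OntologyDocument(ontology_id="oracle")
    oracle_doc.stanzas = list(quality_doc.stanzas) + list(entity_doc.stanzas)
    oracle_doc.typedefs = list(entity_doc.typedefs)
    oracle_doc.stanzas += [
        TermStanza(id=s.id, intersection_clauses=list(s.intersection_clauses))
        for s in xp_defs.stanzas
    ]
    entailed = naive_entailed_is_a(oracle_doc, "PX")
    mentioned = {x for pair in entailed for x in pair}
    direct = {
        (a, b)
        for (a, b) in entailed
        if not any((a, z) in entailed and (z, b) in entailed for z in mentioned)
    }

    if len(direct) < params.n_withheld:
        raise GenerationError(
            f"only {len(direct)} direct entailed links available; cannot withhold "
            f"{params.n_withheld} (increase sizes or lower n_withheld)"
        )
    withheld = set(rng.sample(sorted(direct), params.n_withheld))

    import networkx as nx

    pheno_ids = sorted(names)
    g = nx.DiGraph()
    g.add_nodes_from(pheno_ids)
    g.add_edges_from(entailed)
    unsupported: set[tuple[str, str]] = set()
    attempts = 0
    while len(unsupported) < params.n_unsupported:
        attempts += 1
        if attempts > 200 * params.n_unsupported:
            raise GenerationError("could not place the requested unsupported links acyclically")
        a, b = rng.sample(pheno_ids, 2)
        if (a, b) in entailed or (a, b) in unsupported:
            continue
        g.add_edge(a, b)
        if nx.is_directed_acyclic_graph(g):
            unsupported.add((a, b))
        else:
            g.remove_edge(a, b)

    asserted = (entailed - withheld) | unsupported
    parent_map: dict[str, list[str]] = {pid: [] for pid in pheno_ids}
    for a, b in sorted(asserted):
        parent_map[a].append(b)

    phenotype_doc = OntologyDocument(
        ontology_id="px",
        header_lines=["format-version: 1.2", "ontology: px", header_remark],
    )
    for pid in pheno_ids:
        phenotype_doc.stanzas.append(
            TermStanza(id=pid, name=names[pid], is_a_parents=sorted(parent_map[pid]))
        )
    phenotype_doc.validate()

    ground_truth = {
        "entailed": entailed,
        "direct_entailed": direct,
        "withheld": withheld,
        "unsupported": unsupported,
        "asserted": asserted,
        "expected_recall_all": (len(asserted - unsupported) / len(asserted)) if asserted else 0.0,
        "expected_novel": withheld,
        "seed": params.seed,
    }
    return SuiteResult(quality_doc, entity_doc, phenotype_doc, xp_defs, ground_truth)


def write_ground_truth(gt: dict) -> str:
    """Machine-readable key-value manifest for a generated suite."""
    lines = [f"seed: {gt['seed']}", f"expected_recall_all: {gt['expected_recall_all']:.6f}"]
    for key in ("entailed", "direct_entailed", "withheld", "unsupported", "asserted"):
        pairs = " ".join(f"{a}->{b}" for a, b in sorted(gt[key]))
        lines.append(f"{key}: {pairs}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Unstructured random documents (reasoner stress inputs)
# ---------------------------------------------------------------------------


def generate_random_document(seed: int, max_classes: int = 40) -> OntologyDocument:
    """A random multi-prefix document with arbitrary links and definitions.

    Unlike :func:`generate_suite` this makes no structural guarantees
    beyond is_a acyclicity -- it exists to exercise the reasoner against
    the naive oracle on adversarial shapes: mixed relations, definitions
    referencing any class, multiple ontology prefixes.
    """
    rng = random.Random(seed)
    n = rng.randint(5, max_classes)
    prefixes = ["AX", "BX", "CX"][: rng.randint(1, 3)]
    ids = [f"{rng.choice(prefixes)}:{i:05d}" for i in range(n)]
    relations = ["part_of", "develops_from", "inheres_in"]
    doc = OntologyDocument(ontology_id="rand", header_lines=["format-version: 1.2"])
    for i, cid in enumerate(ids):
        parents = []
        if i and rng.random() < 0.7:
            parents = [ids[p] for p in rng.sample(range(i), rng.randint(1, min(2, i)))]
        rels = []
        for _ in range(rng.randint(0, 2)):
            rels.append(LinkClause(rng.choice(relations), rng.choice(ids)))
        clauses = []
        if i >= 2 and rng.random() < 0.35:
            genus = ids[rng.randrange(i)]
            clauses.append(IntersectionClause(None, genus))
            for _ in range(rng.randint(1, 2)):
                clauses.append(
                    IntersectionClause(rng.choice(relations), rng.choice(ids))
                )
        doc.stanzas.append(
            TermStanza(
                id=cid,
                name=f"class {i}",
                is_a_parents=parents,
                relationships=rels,
                intersection_clauses=clauses,
            )
        )
    doc.validate()
    return doc
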