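"""Recapitulation, curation reports, consistency lint, coverage stats."""

import pytest

from phenoxp import fixtures as fx
from phenoxp.errors import EmptyReportError
from phenoxp.obo_io import OntologyDocument, TermStanza
from phenoxp.reasoner import RuleConfig
from phenoxp.validation import (
    consistency_lint,
    coverage_stats,
    missing_link_report,
    read_curation_file,
    recapitulate,
)


@pytest.mark.parametrize("seed", range(20))
def test_recapitulation_matches_construction_exactly(seed):
    suite = fx.generate_suite(fx.GeneratorParams(seed=seed))
    report = recapitulate(suite.phenotype_doc, suite.xp_defs, suite.support_docs)
    gt = suite.ground_truth
    assert report.recall_all == pytest.approx(gt["expected_recall_all"], abs=0)
    assert report.novel == gt["withheld"]
    assert report.missed == gt["unsupported"]
    # set algebra invariants
    assert report.recovered | report.missed == gt["asserted"]
    assert report.recovered & report.missed == set()
    assert report.novel & gt["asserted"] == set()
    assert 0.0 <= report.recall_all <= report.recall_defined <= 1.0


def test_recapitulation_without_definitions(paper_fixture):
    empty_defs = OntologyDocument(ontology_id="empty")
    report = recapitulate(paper_fixture.mini_mp, empty_defs, paper_fixture.support_docs)
    assert report.recovered == set() and report.recall_all == 0.0


def test_recapitulation_empty_phenotype_document(paper_fixture):
    with pytest.raises(EmptyReportError):
        recapitulate(OntologyDocument(), paper_fixture.xp_defs, paper_fixture.support_docs)


def test_figure2_edge_recovered_or_novel(paper_fixture):
    pf = paper_fixture
    config = RuleConfig(quality_propagates_over_part_of=True)
    asserted_report = recapitulate(pf.mini_mp, pf.xp_defs, pf.support_docs, config)
    assert ("MP:8000001", "MP:0002229") in asserted_report.recovered
    withheld_report = recapitulate(pf.mini_mp_withheld, pf.xp_defs, pf.support_docs, config)
    assert ("MP:8000001", "MP:0002229") in withheld_report.novel


def test_reports_are_reproducible(paper_fixture):
    pf = paper_fixture
    a = recapitulate(pf.mini_mp, pf.xp_defs, pf.support_docs)
    b = recapitulate(pf.mini_mp, pf.xp_defs, pf.support_docs)
    assert a.summary() == b.summary()
    assert a.key_values() == b.key_values()


def test_missing_link_report_round_trip(paper_fixture):
    pf = paper_fixture
    report = recapitulate(pf.mini_mp_withheld, pf.xp_defs, pf.support_docs)
    text = missing_link_report(report.closure, report.novel)
    rows = [l for l in text.splitlines() if l and not l.startswith("#")]
    assert len(rows) == 1 + len(report.novel)
    assert read_curation_file(text) == {
        "pending": len(report.novel),
        "accepted": 0,
        "rejected": 0,
        "partially-correct": 0,
    }
    # triage one row, re-read, verdict counts follow
    triaged = text.replace("\tpending\t", "\taccepted\t", 1)
    counts = read_curation_file(triaged)
    assert counts["accepted"] == 1 and counts["pending"] == len(report.novel) - 1
    assert sum(counts.values()) == len(report.novel)


def test_missing_link_report_header_only_when_no_novel(paper_fixture):
    pf = paper_fixture
    report = recapitulate(pf.mini_mp, pf.xp_defs, pf.support_docs, RuleConfig(quality_propagates_over_part_of=True))
    assert report.novel == set()
    text = missing_link_report(report.closure, report.novel)
    assert text.strip().splitlines() == ["subject_id\tsubject_label\tobject_id\tobject_label\trule_chain\tverdict\tnote"]


def test_snout_face_lint_finding_appears_and_disappears(paper_fixture):
    pf = paper_fixture
    support_without = [pf.mini_pato, pf.mini_cl, fx.mini_ma_without_snout_face(), pf.mini_go, pf.mini_chebi]
    findings = consistency_lint(pf.mini_mp, pf.xp_defs, support_without)
    assert [(f.kind, f.filler_pair) for f in findings] == [
        ("missing-filler-path", ("MA:0000069", "MA:0000062"))
    ]
    # adding snout part_of face: finding gone, asserted link recovered
    assert consistency_lint(pf.mini_mp, pf.xp_defs, pf.support_docs) == []
    report = recapitulate(
        pf.mini_mp, pf.xp_defs, pf.support_docs, RuleConfig(quality_propagates_over_part_of=True)
    )
    assert ("MP:8000003", "MP:8000004") in report.recovered


def test_delta_cell_counterpart_finding(paper_fixture):
    mp_doc, defs = fx.delta_cell_case()
    findings = consistency_lint(mp_doc, defs, [paper_fixture.mini_pato, paper_fixture.mini_cl])
    assert [(f.kind, f.subject, f.object) for f in findings] == [
        ("missing-counterpart-link", "MP:8000007", "MP:8000008")
    ]
    assert findings[0].filler_pair == ("CL:0000173", "CL:0000164")


def test_coverage_stats_paper_fixture(paper_fixture):
    stats = coverage_stats(paper_fixture.mini_mp, paper_fixture.xp_defs)
    assert stats.total_classes == 19
    assert stats.defined_classes == 18  # all but the root carry definitions
    assert stats.percent_defined == pytest.approx(100 * 18 / 19)
    assert sum(stats.by_bucket.values()) >= stats.defined_classes
    assert stats.by_bucket["CL"] >= 5 and "gross-anatomy" in stats.by_bucket


def test_coverage_excludes_obsolete_and_handles_zero_defs(paper_fixture):
    doc = OntologyDocument(
        stanzas=[
            TermStanza(id="MP:1", name="a"),
            TermStanza(id="MP:2", name="gone", is_obsolete=True),
        ]
    )
    stats = coverage_stats(doc, OntologyDocument())
    assert stats.total_classes == 1
    assert stats.defined_classes == 0 and stats.percent_defined == 0.0


def test_definition_spanning_multiple_ontologies_counts_each_bucket(paper_fixture):
    stats = coverage_stats(paper_fixture.mini_mp, paper_fixture.xp_defs)
    # abnormal spleen iron level touches MA and CHEBI; Purkinje dendrite touches GO and CL
    assert stats.by_bucket.get("CHEBI", 0) >= 1
    assert stats.by_bucket.get("GO", 0) >= 1
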