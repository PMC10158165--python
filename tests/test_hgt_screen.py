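"""Alien-index screening cascade: partitioning, AI, thresholds, scaffold
classification, node assignment, donor inference, summaries."""

import math

import pandas as pd
import pytest
from hypothesis import given, strategies as st

from hgtscout.hgt import (
    AlienIndexResult,
    HGTCall,
    alien_index,
    alien_indices,
    assign_transfer_node,
    classify_scaffold,
    finalize_calls,
    infer_donor,
    origin_label,
    partition_best_hits,
    screen_candidates,
    summarize_hgt,
)
from hgtscout.model import (
    ExpressionMatrix,
    GeneTree,
    HitRecord,
    HitTable,
    ScaffoldContext,
    SpeciesTree,
)
from hgtscout.taxonomy import TaxonomyLineage

from _oracles import alien_index_oracle

HEMI = TaxonomyLineage(("Eukaryota", "Metazoa", "Arthropoda", "Insecta", "Hemiptera"))
MAMMAL = TaxonomyLineage(("Eukaryota", "Metazoa", "Chordata", "Mammalia"))
BACT = TaxonomyLineage(("Bacteria", "Pseudomonadota"))
FUNGI = TaxonomyLineage(("Eukaryota", "Fungi"))
PLANT = TaxonomyLineage(("Eukaryota", "Viridiplantae"))


def _hit(q, lineage, evalue, bits=100.0, pident=50.0):
    return HitRecord(q, "s", pident=pident, length=100, evalue=evalue, bitscore=bits, lineage=lineage)


def test_partition_skips_exclusion_taxon_entirely():
    table = HitTable(
        [_hit("g", HEMI, 1e-80), _hit("g", BACT, 1e-40), _hit("g", MAMMAL, 1e-10)]
    )
    bh = partition_best_hits(table)["g"]
    assert bh.ingroup_evalue == 1e-10
    assert bh.outgroup_evalue == 1e-40
    assert bh.outgroup_category == "bacteria"


def test_partition_no_hit_convention_yields_evalue_one():
    table = HitTable([_hit("g", HEMI, 1e-80)])
    bh = partition_best_hits(table)["g"]
    assert bh.ingroup_evalue == 1.0 and bh.outgroup_evalue == 1.0
    assert bh.outgroup_identity is None and bh.outgroup_category is None


def test_partition_evalue_tie_broken_by_bitscore():
    table = HitTable(
        [
            _hit("g", BACT, 1e-30, bits=180.0, pident=55.0),
            _hit("g", FUNGI, 1e-30, bits=200.0, pident=45.0),
        ]
    )
    bh = partition_best_hits(table)["g"]
    assert bh.outgroup_identity == 45.0 and bh.outgroup_category == "fungi"


@pytest.mark.parametrize(
    "e_in,e_out,expected",
    [
        (1e-10, 1e-40, 30 * math.log(10)),  # ~69.0776
        (1e-7, 1e-7, 0.0),
        (1.0, 1e-50, 50 * math.log(10)),  # no metazoan hit, ~115.129
    ],
)
def test_alien_index_reference_values(e_in, e_out, expected):
    assert alien_index(e_in, e_out) == pytest.approx(expected, rel=1e-9)
    assert alien_index(e_in, e_out) == pytest.approx(
        alien_index_oracle(e_in, e_out), rel=1e-9
    )


def test_alien_index_rejects_negative_evalues():
    with pytest.raises(ValueError):
        alien_index(-1e-5, 1e-10)


@given(
    st.floats(min_value=-180, max_value=0),
    st.floats(min_value=-180, max_value=0),
    st.floats(min_value=0.1, max_value=50),
)
def test_alien_index_antisymmetric_and_monotone(la, lb, delta):
    a, b = 10.0**la, 10.0**lb
    assert alien_index(a, b) == pytest.approx(-alien_index(b, a), abs=1e-12)
    # AI strictly decreases as the outgroup E-value grows (ingroup fixed)
    worse_out = 10.0 ** min(lb + delta, 0.0)
    if worse_out > b:
        assert alien_index(a, worse_out) < alien_index(a, b)


def _ai(gene, ai, identity=45.0):
    return AlienIndexResult(
        gene=gene,
        best_ingroup_evalue=1e-5,
        best_outgroup_evalue=1e-40,
        ai=ai,
        outgroup_identity=identity,
        outgroup_category="bacteria",
    )


def _expr(rows):
    return ExpressionMatrix(
        pd.DataFrame(rows, index=["s1", "s2"]).T
    )


@pytest.mark.parametrize(
    "ai,identity,tpm,status",
    [
        (69.08, 45.0, [2.0, 3.0], "candidate"),
        (14.99, 45.0, [2.0, 3.0], "excluded_threshold"),  # AI > 15 strict
        (15.0, 45.0, [2.0, 3.0], "excluded_threshold"),  # boundary: 15 fails
        (40.0, 70.0, [2.0, 3.0], "excluded_threshold"),  # 70 is not < 70
        (40.0, 69.9, [2.0, 3.0], "candidate"),
        (40.0, 45.0, [0.99, 3.0], "excluded_expression"),  # TPM >= 1 inclusive
        (40.0, 45.0, [1.0, 1.0], "candidate"),
    ],
)
def test_candidate_gates_with_printed_boundary_semantics(ai, identity, tpm, status):
    calls = screen_candidates({"g": _ai("g", ai, identity)}, _expr({"g": tpm}))
    assert calls[0].status == status


def test_screen_without_expression_gate_and_missing_gene_error():
    calls = screen_candidates({"g": _ai("g", 40.0)}, expr=None)
    assert calls[0].status == "candidate"
    with pytest.raises(KeyError):
        screen_candidates({"g": _ai("g", 40.0)}, _expr({"other": [2.0, 2.0]}))


def _ctx(origins, scaf="s1", sp="SP01"):
    genes = tuple(f"{scaf}_g{i}" for i in range(len(origins)))
    return ScaffoldContext(scaf, sp, genes, tuple(origins))


@pytest.mark.parametrize(
    "origins,expected",
    [
        (["non_metazoan"] * 3 + ["insecta", "metazoan"], "contamination"),  # 0.6 inclusive
        (["insecta"] * 3 + ["non_metazoan", "no_hit"], "insect_confirmed"),
        (["non_metazoan", "non_metazoan", "insecta", "no_hit"], "ambiguous"),  # 0.5 both
        (["non_metazoan"] * 3 + ["insecta"] * 2 + ["non_metazoan"] * 3, "contamination"),
    ],
)
def test_classify_scaffold_fraction_rule(origins, expected):
    assert classify_scaffold(_ctx(origins)) == expected


def test_no_hit_genes_count_only_in_denominator():
    # 2 non-metazoan of 5 genes (3 no-hit) = 0.4 < 0.6 -> ambiguous
    assert classify_scaffold(_ctx(["non_metazoan"] * 2 + ["no_hit"] * 3)) == "ambiguous"


def test_origin_label_best_hit_rule():
    assert origin_label([_hit("g", HEMI, 1e-80), _hit("g", BACT, 1e-40)]) == "insecta"
    assert origin_label([_hit("g", MAMMAL, 1e-50)]) == "metazoan"
    assert origin_label([_hit("g", BACT, 1e-50)]) == "non_metazoan"
    assert origin_label([]) == "no_hit"


def test_finalize_calls_resolves_contexts():
    contexts = {
        "a": _ctx(["non_metazoan"] * 3, scaf="contam"),
        "b": _ctx(["insecta"] * 3, scaf="clean"),
        "c": _ctx(["non_metazoan", "insecta", "no_hit", "metazoan"], scaf="amb"),
    }
    contexts = {g: ctx for g, ctx in contexts.items()}
    calls = [
        HGTCall(gene=g, species="SP01", og=None, status="candidate") for g in ("a", "b", "c")
    ] + [HGTCall(gene="d", species="SP01", og=None, status="excluded_threshold")]
    fixed = {c.gene: c for c in finalize_calls(calls, contexts)}
    assert fixed["a"].status == "excluded_contamination"
    assert fixed["b"].status == "putative"
    assert fixed["c"].status == "candidate" and fixed["c"].ambiguous_context
    assert fixed["d"].status == "excluded_threshold"
    with pytest.raises(KeyError):
        finalize_calls([HGTCall(gene="zz", species=None, og=None, status="candidate")], {})


def test_transfer_node_assignment_examples():
    tree = SpeciesTree.from_newick(
        "(SP01,(SP02,(SP03,(SP04,(SP05,(SP06,(SP07,SP08)N7)N6)N5)N4)N3)N2)N1;"
    )
    all_sp = [f"SP{i:02d}" for i in range(1, 9)]
    assert assign_transfer_node(all_sp, tree).node == "N1"  # root: whole clade
    assert assign_transfer_node(all_sp[1:], tree).node == "N2"  # derived clade only
    single = assign_transfer_node(["SP05"], tree)
    assert single.node == "SP05" and single.dollo_consistent
    with pytest.raises(KeyError):
        assign_transfer_node(["nope"], tree)


def test_dollo_inconsistency_flagged_for_patchy_presence():
    tree = SpeciesTree.from_newick("((A,B)X,(C,D)Y)R;")
    patchy = assign_transfer_node(["A", "C"], tree)  # MRCA=R but 2 of 4 absent
    assert patchy.node == "R" and not patchy.dollo_consistent
    full = assign_transfer_node(["A", "B", "C", "D"], tree)
    assert full.dollo_consistent
    loose = assign_transfer_node(["A", "C"], tree, max_absent_fraction=0.5)
    assert loose.dollo_consistent


def _gene_tree(newick, lineages):
    return GeneTree.from_newick(newick, lineages)


def test_donor_inference_rules():
    focal = {"f1": HEMI, "f2": HEMI}
    bact = {f"b{i}": BACT for i in range(1, 7)}
    # both surrounding clades pure bacteria -> bacteria, confident
    gt = _gene_tree(
        "((((f1,f2),(b1,b2,b3))P,(b4,b5,b6))G,(m1,m2))R;",
        {**focal, **bact, "m1": MAMMAL, "m2": MAMMAL},
    )
    call = infer_donor(gt, ["f1", "f2"])
    assert call.category == "bacteria" and not call.low_confidence
    # sister pure fungi, next clade pure bacteria -> fungi, low confidence
    gt = _gene_tree(
        "((((f1,f2),(x1,x2))P,(b4,b5))G,(m1,m2))R;",
        {**focal, "x1": FUNGI, "x2": FUNGI, "b4": BACT, "b5": BACT, "m1": MAMMAL, "m2": MAMMAL},
    )
    call = infer_donor(gt, ["f1", "f2"])
    assert call.category == "fungi" and call.low_confidence
    # three categories around the focal clade -> unclear
    gt = _gene_tree(
        "((((f1,f2),(x1,p1))P,(b4,b5))G,(m1,m2))R;",
        {**focal, "x1": FUNGI, "p1": PLANT, "b4": BACT, "b5": BACT, "m1": MAMMAL, "m2": MAMMAL},
    )
    assert infer_donor(gt, ["f1", "f2"]).category == "unclear"
    # non-monophyletic focal set -> unclear
    gt = _gene_tree(
        "(((f1,b1),(f2,b2))P,(m1,m2))R;",
        {"f1": HEMI, "f2": HEMI, "b1": BACT, "b2": BACT, "m1": MAMMAL, "m2": MAMMAL},
    )
    assert infer_donor(gt, ["f1", "f2"]).category == "unclear"
    with pytest.raises(KeyError):
        infer_donor(gt, ["absent_tip"])


def test_summarize_fractions_and_empty_species():
    calls = [
        HGTCall(gene=f"g{i}", species="SPX", og="og1", status="putative", donor=d)
        for i, d in enumerate(["bacteria"] * 4 + ["fungi"] * 4 + ["viridiplantae"] * 2)
    ] + [HGTCall(gene="h1", species="SPY", og=None, status="excluded_threshold")]
    summary = summarize_hgt(calls)
    fr = summary["per_species"]["SPX"]["donor_fractions"]
    assert fr == {"bacteria": 0.4, "fungi": 0.4, "viridiplantae": 0.2}
    assert abs(sum(fr.values()) - 1.0) < 1e-9
    assert summary["per_species"]["SPY"]["donor_fractions"] == {}


def test_cascade_statuses_partition_the_gene_universe(default_bundle, default_report):
    counts = default_report.stage_counts["hgt_screen"]
    # statuses are mutually exclusive and exhaustive: they sum to the input
    assert sum(v for k, v in counts.items() if k != "in") == counts["in"]
    assert counts["in"] == len(default_bundle.gene_species)


def test_noiseless_donor_fractions_match_truth_mix(default_bundle, default_report):
    truth = default_bundle.truth
    expected = {}
    for e in truth.hgt_events:
        n = len(default_bundle.orthology.genes(e.og))
        expected[e.donor] = expected.get(e.donor, 0) + n
    got = {}
    for row in default_report.hgt_summary["per_species"].values():
        for donor, c in row["donor_counts"].items():
            got[donor] = got.get(donor, 0) + c
    assert got == expected
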