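"""Domain types, file round trips, and tree queries."""

import pytest
from hypothesis import given, strategies as st

from hgtscout import io as hio
from hgtscout.io import ParseError
from hgtscout.model import (
    ExpressionMatrix,
    HitRecord,
    HitTable,
    OrthologyTable,
    ScaffoldContext,
    SpeciesTree,
)
from hgtscout.taxonomy import TaxonomyLineage

import pandas as pd

BACT = TaxonomyLineage(("Bacteria", "Pseudomonadota"))
HEMI = TaxonomyLineage(("Eukaryota", "Metazoa", "Arthropoda", "Insecta", "Hemiptera"))


@pytest.mark.parametrize(
    "ranks,category",
    [
        (("Bacteria", "Pseudomonadota"), "bacteria"),
        (("Eukaryota", "Fungi", "Ascomycota"), "fungi"),
        (("Eukaryota", "Viridiplantae"), "viridiplantae"),
        (("Viruses", "Uroviricota"), "viruses"),
        (("Eukaryota", "Metazoa", "Chordata"), "metazoa"),
        (("Eukaryota", "Archaea-like", "Something"), "other"),
    ],
)
def test_lineage_category_is_pure_function_of_ranks(ranks, category):
    lin = TaxonomyLineage(ranks)
    assert lin.category == category
    assert TaxonomyLineage.from_string(lin.to_string()) == lin


def test_lineage_membership_decidable_from_ranks_alone():
    assert HEMI.is_metazoan and HEMI.is_insect and HEMI.is_hemipteran
    assert not BACT.is_metazoan
    with pytest.raises(ValueError):
        TaxonomyLineage(())


def test_hit_record_invariants():
    with pytest.raises(ValueError):
        HitRecord("q", "s", pident=101.0, length=10, evalue=1e-5, bitscore=50, lineage=BACT)
    with pytest.raises(ValueError):
        HitRecord("q", "s", pident=50.0, length=10, evalue=-1.0, bitscore=50, lineage=BACT)
    with pytest.raises(ValueError):
        HitRecord("", "s", pident=50.0, length=10, evalue=1e-5, bitscore=50, lineage=BACT)


def test_read_hit_table_parses_rows_grouped_by_query(tmp_path):
    path = tmp_path / "hits.tsv"
    path.write_text(
        "q1\ts1\t80.5\t100\t1e-30\t200.0\tBacteria;Pseudomonadota\n"
        "q2\ts2\t95.0\t120\t1e-50\t300.0\tEukaryota;Metazoa;Arthropoda\n"
    )
    table = hio.read_hit_table(path)
    assert len(table) == 2
    assert table.queries == ("q1", "q2")
    assert table.hits_for("q1")[0].lineage.category == "bacteria"


def test_read_hit_table_empty_file_is_valid(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text("")
    table = hio.read_hit_table(path)
    assert len(table) == 0 and table.queries == ()


def test_read_hit_table_reports_line_of_malformed_row(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text(
        "q1\ts1\t80.5\t100\t1e-30\t200.0\tBacteria\n"
        "q2\ts2\t95.0\t120\tabc\t300.0\tBacteria\n"
    )
    with pytest.raises(ParseError, match=":2"):
        hio.read_hit_table(path)
    short = tmp_path / "short.tsv"
    short.write_text("q1\ts1\t80.5\n")
    with pytest.raises(ParseError, match="columns"):
        hio.read_hit_table(short)


def test_read_hit_table_staxid_resolution(tmp_path):
    path = tmp_path / "hits.tsv"
    path.write_text("q1\ts1\t80.5\t100\t1e-30\t200.0\t562\n")
    cols = ("qseqid", "sseqid", "pident", "length", "evalue", "bitscore", "staxid")
    table = hio.read_hit_table(path, columns=cols, taxid_lineages={"562": BACT})
    assert table.hits_for("q1")[0].lineage == BACT
    with pytest.raises(ParseError, match="unresolvable taxonomy"):
        hio.read_hit_table(path, columns=cols, taxid_lineages={})


def test_hit_table_round_trip(tmp_path, default_bundle):
    sub = HitTable(default_bundle.hits.records[:200])
    hio.write_hit_table(sub, tmp_path / "rt.tsv")
    assert hio.read_hit_table(tmp_path / "rt.tsv") == sub


def test_read_orthogroups_toy_counts_and_absence(tmp_path):
    path = tmp_path / "ogs.tsv"
    path.write_text("# Orthogroup\tA\tB\tC\nog1\tg1, g2\tg3\t\n")
    table = hio.read_orthogroups(path)
    counts = table.copy_counts()
    assert counts.loc["og1", "A"] == 2 and counts.loc["og1", "B"] == 1
    assert not table.presence().loc["og1", "C"]


def test_duplicate_gene_across_ogs_rejected_naming_gene(tmp_path):
    path = tmp_path / "dup.tsv"
    path.write_text("# Orthogroup\tA\tB\nog1\tg1\t\nog2\tg1\t\n")
    with pytest.raises(ValueError, match="g1"):
        hio.read_orthogroups(path)


def test_orthogroup_round_trip(tmp_path, default_bundle):
    hio.write_orthogroups(default_bundle.orthology, tmp_path / "ogs.tsv")
    assert hio.read_orthogroups(tmp_path / "ogs.tsv") == default_bundle.orthology


@given(
    st.dictionaries(
        st.sampled_from([f"og{i}" for i in range(10)]),
        st.dictionaries(
            st.sampled_from(["A", "B", "C", "D"]),
            st.integers(min_value=0, max_value=3),
            max_size=4,
        ),
        min_size=1,
        max_size=10,
    )
)
def test_presence_and_copy_counts_mutually_consistent(spec):
    members = {
        og: {sp: [f"{og}_{sp}_{i}" for i in range(n)] for sp, n in by_sp.items() if n}
        for og, by_sp in spec.items()
    }
    table = OrthologyTable(members)
    counts = table.copy_counts()
    assert table.presence().equals(counts > 0)
    for og in table.og_ids:
        assert table.species_with(og) == frozenset(
            sp for sp in table.species if counts.loc[og, sp] > 0
        )


def test_expression_matrix_contracts():
    df = pd.DataFrame([[1.0, 2.0], [0.5, 0.0]], index=["g1", "g2"], columns=["s1", "s2"])
    expr = ExpressionMatrix(df)
    assert expr.min_tpm("g2") == 0.0
    with pytest.raises(KeyError, match="g3"):
        expr.tpm("g3")
    with pytest.raises(ValueError):
        ExpressionMatrix(df - 1.0)


def test_expression_round_trip(tmp_path, default_bundle):
    hio.write_expression(default_bundle.expression, tmp_path / "tpm.tsv")
    assert hio.read_expression(tmp_path / "tpm.tsv") == default_bundle.expression


def test_scaffold_context_contracts():
    ctx = ScaffoldContext("s1", "SP01", ("g1", "g2"), ("insecta", "no_hit"))
    assert ctx.ordinal("g2") == 2
    assert ctx.origin_fraction("insecta") == 0.5
    with pytest.raises(ValueError):
        ScaffoldContext("s1", "SP01", (), ())
    with pytest.raises(ValueError):
        ScaffoldContext("s1", "SP01", ("g1",), ("martian",))


def test_scaffold_round_trip(tmp_path, default_bundle):
    hio.write_scaffolds(default_bundle.scaffolds, tmp_path / "scaf.tsv")
    loaded = hio.read_scaffolds(tmp_path / "scaf.tsv")
    assert sorted(loaded, key=lambda c: c.scaffold_id) == sorted(
        default_bundle.scaffolds, key=lambda c: c.scaffold_id
    )


def test_mrca_examples():
    tree = SpeciesTree.from_newick("(A,(B,C)X)R;")
    assert tree.mrca_label({"B", "C"}) == "X"
    assert tree.mrca_label({"A", "B", "C"}) == "R"
    assert tree.mrca_label({"B"}) == "B"
    with pytest.raises(KeyError, match="Z"):
        tree.mrca({"Z"})
    with pytest.raises(ValueError):
        tree.mrca(set())


def test_duplicate_leaf_labels_rejected():
    with pytest.raises(ValueError, match="unique"):
        SpeciesTree.from_newick("(A,(A,B));")


@given(
    st.sets(st.sampled_from(["A", "B", "C", "D", "E"]), min_size=1, max_size=5),
    st.sets(st.sampled_from(["A", "B", "C", "D", "E"]), min_size=0, max_size=5),
)
def test_mrca_monotone_under_subset(s2, extra):
    """mrca(S1) is ancestral-or-equal to mrca(S2) for S2 a subset of S1."""
    tree = SpeciesTree.from_newick("((A,B)X,((C,D)Y,E)Z)R;")
    s1 = s2 | extra
    n1 = tree.mrca(s1)
    n2 = tree.mrca(s2)
    ancestors = {id(n) for n in [n2] + [a for a in n2.ancestor_iter()]}
    assert id(n1) in ancestors


def test_gene_tree_round_trip(tmp_path, default_bundle):
    og, gt = sorted(default_bundle.gene_trees.items())[0]
    hio.write_gene_tree(gt, tmp_path / "t.nwk", tmp_path / "t.tips.tsv")
    loaded = hio.read_gene_tree(tmp_path / "t.nwk", tmp_path / "t.tips.tsv")
    assert sorted(loaded.tips) == sorted(gt.tips)
    assert loaded.tip_lineages == gt.tip_lineages
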