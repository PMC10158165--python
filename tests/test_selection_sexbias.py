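"""Two-tool selection consensus, shift classification, DEG calling,
common sex-biased orthogroups, and the ratio chi-square comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from hgtscout.model import OrthologyTable
from hgtscout.selection import (
    DEGRecord,
    aggregate_selection,
    call_degs,
    classify_shift,
    combine_selection,
    common_sex_degs,
    ratio_chi_square,
)

from _oracles import pearson_2x2


@pytest.mark.parametrize(
    "p1,p2,expected",
    [
        (0.03, 0.04, "significant"),
        (0.03, 0.06, "not_significant"),
        (0.05, 0.01, "not_significant"),  # strict boundary at alpha
        (0.049999, 0.049999, "significant"),
    ],
)
def test_two_tool_consensus(p1, p2, expected):
    assert combine_selection(p1, p2) == expected
    assert combine_selection(p2, p1) == expected  # commutative


def test_consensus_rejects_invalid_pvalues():
    with pytest.raises(ValueError):
        combine_selection(-0.1, 0.5)
    with pytest.raises(ValueError):
        combine_selection(0.5, 1.1)


@pytest.mark.parametrize(
    "focal,ref,expected",
    [
        (0.8, 0.3, "relaxation_focal"),
        (0.1, 0.3, "intensification_focal"),
        (0.3, 0.3, "none"),  # tie -> no shift call
    ],
)
def test_shift_classification(focal, ref, expected):
    assert classify_shift(focal, ref) == expected


@given(
    st.floats(min_value=0.01, max_value=3.0),
    st.floats(min_value=0.01, max_value=3.0),
)
def test_shift_classification_antisymmetric(a, b):
    fwd, rev = classify_shift(a, b), classify_shift(b, a)
    if fwd == "none":
        assert rev == "none"
    else:
        assert {fwd, rev} == {"relaxation_focal", "intensification_focal"}


def test_shift_rejects_nonpositive_ratio():
    with pytest.raises(ValueError):
        classify_shift(0.0, 0.5)


def test_aggregate_selection_combines_and_classifies():
    df = pd.DataFrame(
        [
            ("og1", "shift", 0.001, 0.002, 0.8, 0.3),
            ("og2", "shift", 0.001, 0.2, 0.8, 0.3),  # one tool only
            ("og3", "positive", 0.001, 0.002, 2.0, np.nan),
        ],
        columns=["og_id", "test", "p_tool1", "p_tool2", "dnds_focal", "dnds_ref"],
    )
    recs = {r.og: r for r in aggregate_selection(df)}
    assert recs["og1"].verdict == "significant"
    assert recs["og1"].shift_direction == "relaxation_focal"
    assert recs["og2"].verdict == "not_significant" and recs["og2"].shift_direction == "none"
    assert recs["og3"].verdict == "significant" and recs["og3"].shift_direction == "none"


def _deg_table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "log2fc", "q"])


@pytest.mark.parametrize(
    "lfc,q,mode,direction",
    [
        (1.5, 0.01, "with_q", "up_female"),
        (1.5, 0.20, "with_q", "none"),
        (1.0, 0.01, "with_q", "none"),  # |log2FC| > 1 strict
        (-1.2, 0.01, "with_q", "up_male"),
        (1.5, 0.05, "with_q", "none"),  # Q < 0.05 strict
        (-1.2, None, "log2fc_only", "up_male"),
        (0.9, None, "log2fc_only", "none"),
    ],
)
def test_deg_calling_criteria(lfc, q, mode, direction):
    (rec,) = call_degs(_deg_table([("g", lfc, q)]), species="sp", mode=mode)
    assert rec.direction == direction


def test_deg_missing_q_in_with_q_mode_is_error():
    with pytest.raises(ValueError, match="q"):
        call_degs(_deg_table([("g", 1.5, np.nan)]), species="sp", mode="with_q")
    with pytest.raises(ValueError):
        call_degs(pd.DataFrame([("g", 1.5)], columns=["gene_id", "log2fc"]), species="sp")


def _ortho():
    return OrthologyTable(
        {
            "og1": {"sp1": ["a1"], "sp2": ["a2"]},
            "og2": {"sp1": ["b1"], "sp2": ["b2"]},
            "og3": {"sp1": ["c1"], "sp2": ["c2"]},
        }
    )


def _rec(gene, sp, direction):
    return DEGRecord(gene=gene, species=sp, contrast="f_vs_m", log2fc=2.0, q=0.01, direction=direction)


def test_common_sex_degs_intersection():
    tables = {
        "sp1": [_rec("a1", "sp1", "up_female"), _rec("b1", "sp1", "up_female")],
        "sp2": [_rec("b2", "sp2", "up_female"), _rec("c2", "sp2", "up_female")],
    }
    out = common_sex_degs(tables, _ortho())
    assert out.female_ogs == {"og2"} and out.male_ogs == frozenset()


def test_common_sex_degs_empty_species_and_opposite_bias():
    # one species with no DEGs -> both common sets empty
    out = common_sex_degs({"sp1": [_rec("a1", "sp1", "up_female")], "sp2": []}, _ortho())
    assert out.female_ogs == frozenset() and out.male_ogs == frozenset()
    # oppositely biased members across species -> in neither common set
    tables = {
        "sp1": [_rec("a1", "sp1", "up_female")],
        "sp2": [_rec("a2", "sp2", "up_male")],
    }
    out = common_sex_degs(tables, _ortho())
    assert out.female_ogs == frozenset() and out.male_ogs == frozenset()
    # unmapped genes are skipped and counted
    out = common_sex_degs(
        {"sp1": [_rec("zz", "sp1", "up_female")], "sp2": [_rec("a2", "sp2", "up_female")]},
        _ortho(),
    )
    assert out.unmapped_genes == 1


def _sets(n_a, k_a, n_b, k_b):
    a = [f"a{i}" for i in range(n_a)]
    b = [f"b{i}" for i in range(n_b)]
    events = a[:k_a] + b[:k_b]
    return events, a, b


def test_ratio_chi_square_reference_values():
    # 12 of 100 vs 50 of 1000: Pearson chi2 ~ 8.375 (df = 1)
    events, a, b = _sets(100, 12, 1000, 50)
    r = ratio_chi_square(events, a, b)
    assert r.table == ((12, 88), (50, 950))
    assert r.chi2 == pytest.approx(pearson_2x2(12, 88, 50, 950), abs=1e-9)
    assert r.chi2 == pytest.approx(8.3753, abs=1e-3)
    assert r.direction == "a_higher"
    # Yates-corrected variant of the same table
    r_y = ratio_chi_square(events, a, b, correction="yates")
    assert r_y.chi2 == pytest.approx(pearson_2x2(12, 88, 50, 950, yates=True), abs=1e-9)
    assert r_y.chi2 == pytest.approx(7.1110, abs=1e-3)
    # identical proportions -> chi2 exactly 0
    events, a, b = _sets(100, 5, 1000, 50)
    assert ratio_chi_square(events, a, b).chi2 == pytest.approx(0.0, abs=1e-12)


def test_ratio_chi_square_swap_and_degenerate_cases():
    events, a, b = _sets(100, 12, 1000, 50)
    fwd = ratio_chi_square(events, a, b)
    rev = ratio_chi_square(events, b, a)
    assert fwd.chi2 == pytest.approx(rev.chi2, abs=1e-12)
    assert (fwd.ratio_a, fwd.ratio_b) == (rev.ratio_b, rev.ratio_a)
    assert {fwd.direction, rev.direction} == {"a_higher", "b_higher"}
    # no events anywhere: degenerate column -> chi2 0, p 1
    r = ratio_chi_square([], a, b)
    assert (r.chi2, r.p) == (0.0, 1.0)
    with pytest.raises(ValueError):
        ratio_chi_square(events, [], b)


@given(
    st.integers(min_value=1, max_value=60),
    st.integers(min_value=1, max_value=60),
    st.integers(min_value=0, max_value=60),
    st.integers(min_value=0, max_value=60),
)
def test_ratio_chi_square_matches_closed_form(n_a, n_b, k_a, k_b):
    k_a, k_b = min(k_a, n_a), min(k_b, n_b)
    events, a, b = _sets(n_a, k_a, n_b, k_b)
    r = ratio_chi_square(events, a, b)
    assert r.chi2 == pytest.approx(pearson_2x2(*r.table[0], *r.table[1]), abs=1e-9)


def test_power_of_ratio_test_at_planted_effect_size():
    """At the generator's planted effect (event rate ~0.5 in 40 biased OGs
    vs ~0.12 in a 200-OG universe) the chi-square test should reject far
    more often than not: 500 seeded replicates, rejection rate >= 0.8."""
    rng = np.random.default_rng(20240901)
    rejections = 0
    n_rep = 500
    for _ in range(n_rep):
        k_a = rng.binomial(40, 0.5)
        k_b = rng.binomial(200, 0.12)
        events, a, b = _sets(40, k_a, 200, k_b)
        if ratio_chi_square(events, a, b).p < 0.05:
            rejections += 1
    assert rejections / n_rep >= 0.8


def test_pipeline_fixture_ratio_test_detects_planted_enrichment(default_report):
    tests = default_report.selection_sexbias["ratio_tests"]["relaxation"]
    male_vs_all = tests["male_vs_all"]
    assert male_vs_all["ratio_a"] > male_vs_all["ratio_b"]
    assert male_vs_all["p"] < 0.05
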