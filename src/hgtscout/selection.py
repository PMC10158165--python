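"""Selection-result aggregation and sex-bias statistics.

Consumes the output tables of codon-model selection scans (two independent
tools per test) and of differential-expression analyses; it does not fit
codon or count models itself.

The two-tool consensus rule calls a test significant only when both tools
report p < alpha (default 0.05, strict).  For selection-shift tests the
direction is read from the focal-branch vs reference-branch dN/dS: a larger
focal dN/dS (closer to neutrality) is relaxation on the focal branch set,
equivalently intensification on the reference set; a smaller one is the
opposite; a tie yields no call.

Sex-biased genes are called from log2 fold change and adjusted p (Q):
|log2FC| > 1 (strict) and Q < 0.05 (strict), or |log2FC| > 1 alone in
no-replicate mode.  Orthogroups containing a same-direction biased gene in
every surveyed species form the common female-/male-biased sets, and a
chi-square test compares the ratio of orthogroups carrying a selection
event between two orthogroup sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .model import OrthologyTable

__all__ = [
    "SelectionRecord",
    "DEGRecord",
    "CommonDegs",
    "RatioTestResult",
    "combine_selection",
    "classify_shift",
    "aggregate_selection",
    "call_degs",
    "common_sex_degs",
    "ratio_chi_square",
]


def combine_selection(p_tool1: float, p_tool2: float, alpha: float = 0.05) -> str:
    """Two-tool consensus: significant iff both p-values < alpha (strict)."""
    for p in (p_tool1, p_tool2):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value must be in [0, 1], got {p}")
    return "significant" if (p_tool1 < alpha and p_tool2 < alpha) else "not_significant"


def classify_shift(dnds_focal: float, dnds_ref: float) -> str:
    """Direction of a selection-pressure shift from branch dN/dS values.

    ``relaxation_focal`` when the focal branch's dN/dS exceeds the
    reference's (equivalently intensification on the reference branches);
    ``intensification_focal`` when it is smaller; ``none`` on an exact tie.
    """
    if dnds_focal <= 0 or dnds_ref <= 0:
        raise ValueError("dN/dS ratios must be > 0")
    if dnds_focal > dnds_ref:
        return "relaxation_focal"
    if dnds_focal < dnds_ref:
        return "intensification_focal"
    return "none"


@dataclass(frozen=True)
class SelectionRecord:
    og: str
    test: str  # "positive" | "shift"
    p_tool1: float
    p_tool2: float
    dnds_focal: float | None
    dnds_ref: float | None
    verdict: str
    shift_direction: str  # defined only for significant shift tests, else "none"


def aggregate_selection(table: pd.DataFrame, alpha: float = 0.05) -> list[SelectionRecord]:
    """Apply the consensus rule and shift classification to a result table.

    Expects columns ``og_id, test, p_tool1, p_tool2, dnds_focal, dnds_ref``
    (dN/dS columns may be empty/NaN for positive-selection tests).
    """
    records = []
    for row in table.itertuples(index=False):
        test = str(row.test)
        if test not in ("positive", "shift"):
            raise ValueError(f"unknown test type {test!r} for {row.og_id}")
        verdict = combine_selection(float(row.p_tool1), float(row.p_tool2), alpha=alpha)
        focal = None if pd.isna(row.dnds_focal) else float(row.dnds_focal)
        ref = None if pd.isna(row.dnds_ref) else float(row.dnds_ref)
        direction = "none"
        if verdict == "significant" and test == "shift":
            if focal is None or ref is None:
                raise ValueError(f"shift test for {row.og_id} lacks dN/dS values")
            direction = classify_shift(focal, ref)
        records.append(
            SelectionRecord(
                og=str(row.og_id),
                test=test,
                p_tool1=float(row.p_tool1),
                p_tool2=float(row.p_tool2),
                dnds_focal=focal,
                dnds_ref=ref,
                verdict=verdict,
                shift_direction=direction,
            )
        )
    return records


@dataclass(frozen=True)
class DEGRecord:
    gene: str
    species: str
    contrast: str
    log2fc: float
    q: float | None
    direction: str  # "up_female" | "up_male" | "none"


def call_degs(
    table: pd.DataFrame,
    species: str,
    contrast: str = "female_vs_male_adult",
    mode: str = "with_q",
    numerator: str = "female",
    denominator: str = "male",
    lfc_min: float = 1.0,
    q_max: float = 0.05,
) -> list[DEGRecord]:
    """Call differentially expressed genes from a log2FC / Q table.

    Expects columns ``gene_id, log2fc`` and, in ``with_q`` mode, ``q``.
    Direction requires |log2FC| > ``lfc_min`` (strict) and, with
    replicates, Q < ``q_max`` (strict); in ``log2fc_only`` mode (no
    replicates) the fold-change criterion alone decides.  A positive
    log2FC is up in the declared *numerator* group — the orientation is an
    explicit input, never inferred from sample names.
    """
    if mode not in ("with_q", "log2fc_only"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "with_q" and "q" not in table.columns:
        raise ValueError("mode 'with_q' requires a 'q' column")
    records = []
    for row in table.itertuples(index=False):
        lfc = float(row.log2fc)
        if not math.isfinite(lfc):
            raise ValueError(f"non-finite log2FC for {row.gene_id}")
        q: float | None = None
        if mode == "with_q":
            if pd.isna(row.q):
                raise ValueError(f"missing Q value for {row.gene_id} in with_q mode")
            q = float(row.q)
        passed = abs(lfc) > lfc_min and (mode == "log2fc_only" or q < q_max)
        if not passed:
            direction = "none"
        else:
            direction = f"up_{numerator}" if lfc > 0 else f"up_{denominator}"
        records.append(
            DEGRecord(
                gene=str(row.gene_id),
                species=species,
                contrast=contrast,
                log2fc=lfc,
                q=q,
                direction=direction,
            )
        )
    return records


@dataclass(frozen=True)
class CommonDegs:
    female_ogs: frozenset[str]
    male_ogs: frozenset[str]
    both_directions: frozenset[str]  # OGs in both sets (oppositely biased members)
    unmapped_genes: int


def common_sex_degs(
    deg_tables: Mapping[str, Sequence[DEGRecord]],
    orthology: OrthologyTable,
) -> CommonDegs:
    """Orthogroups sex-biased in every surveyed species.

    An orthogroup is common female-biased iff it contains >= 1 female-up
    DEG in every provided species (likewise male-biased).  Genes not in the
    orthology table are skipped and counted.  An orthogroup can appear in
    both sets only when different member genes are oppositely biased; such
    orthogroups are reported in ``both_directions``.
    """
    if len(deg_tables) < 2:
        raise ValueError("need DEG tables for at least 2 species")
    per_species_f: list[set[str]] = []
    per_species_m: list[set[str]] = []
    unmapped = 0
    for species, records in deg_tables.items():
        fem: set[str] = set()
        male: set[str] = set()
        for rec in records:
            if rec.direction == "none":
                continue
            og = orthology.og_of(rec.gene)
            if og is None:
                unmapped += 1
                continue
            (fem if rec.direction == "up_female" else male).add(og)
        per_species_f.append(fem)
        per_species_m.append(male)
    female = frozenset(set.intersection(*per_species_f)) if per_species_f else frozenset()
    male_ogs = frozenset(set.intersection(*per_species_m)) if per_species_m else frozenset()
    return CommonDegs(
        female_ogs=female,
        male_ogs=male_ogs,
        both_directions=female & male_ogs,
        unmapped_genes=unmapped,
    )


@dataclass(frozen=True)
class RatioTestResult:
    ratio_a: float
    ratio_b: float
    chi2: float
    p: float
    table: tuple[tuple[int, int], tuple[int, int]]
    direction: str  # "a_higher" | "b_higher" | "equal"


def ratio_chi_square(
    event_ogs: Iterable[str],
    set_a: Iterable[str],
    set_b: Iterable[str],
    correction: str = "none",
) -> RatioTestResult:
    """Compare the event-carrying ratio between two orthogroup sets.

    Builds the 2x2 table ``[[|event & a|, |a \\ event|], [|event & b|,
    |b \\ event|]]`` and computes the Pearson chi-square statistic (df = 1),
    optionally with the Yates continuity correction.  The one-sided
    direction is reported via the ratio comparison.  Degenerate tables with
    an empty column marginal (no events anywhere, or events everywhere)
    yield chi2 = 0, p = 1.
    """
    if correction not in ("none", "yates"):
        raise ValueError(f"correction must be 'none' or 'yates', got {correction!r}")
    events = frozenset(event_ogs)
    a = frozenset(set_a)
    b = frozenset(set_b)
    if not a or not b:
        raise ValueError("set_a and set_b must be non-empty")
    table = (
        (len(events & a), len(a - events)),
        (len(events & b), len(b - events)),
    )
    ratio_a = table[0][0] / len(a)
    ratio_b = table[1][0] / len(b)
    col0 = table[0][0] + table[1][0]
    col1 = table[0][1] + table[1][1]
    if col0 == 0 or col1 == 0:
        chi2, p = 0.0, 1.0
    else:
        res = stats.chi2_contingency(table, correction=(correction == "yates"))
        chi2, p = float(res.statistic), float(res.pvalue)
    if ratio_a > ratio_b:
        direction = "a_higher"
    elif ratio_a < ratio_b:
        direction = "b_higher"
    else:
        direction = "equal"
    return RatioTestResult(
        ratio_a=ratio_a, ratio_b=ratio_b, chi2=chi2, p=p, table=table, direction=direction
    )
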