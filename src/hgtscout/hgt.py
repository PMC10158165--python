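"""The HGT screening cascade.

Candidate horizontally transferred genes (HTGs) are detected from protein
homology searches against a broad database whose hits carry taxonomy:

1. Hits inside the *exclusion* taxon (default Hemiptera, the host's own
   order) are discarded entirely — self-lineage hits say nothing about
   donor vs host.  The remaining hits are partitioned into *ingroup*
   (default Metazoa) and *outgroup* (everything else).
2. The alien index contrasts the best (minimum) E-value in each partition:
   ``AI = ln(best_ingroup_E + eps) - ln(best_outgroup_E + eps)`` with
   ``eps = 1e-200``.  A missing partition contributes E-value 1, so AI is
   always finite; large positive AI means the gene matches non-metazoan
   sequences far better than any metazoan one.
3. Candidates must pass AI > 15 (strict), best-outgroup-hit identity < 70
   (strict, to avoid calling contaminant reads that are near-identical to a
   microbial source), and an expression gate (TPM >= 1 in every sample,
   inclusive).
4. Candidates are then checked against their scaffold/transcript context:
   a scaffold whose genes are >= 60% non-metazoan by best hit is likely
   contamination and its genes are excluded; a scaffold >= 60% insect by
   best hit confirms insect origin and promotes the candidate to putative;
   anything else stays a candidate flagged with an ambiguous context.
5. Putative HTG orthogroups are dated onto the species tree ("transferred
   not later than" the MRCA of the species carrying the orthogroup) and a
   donor kingdom is read off the gene tree from the two clades surrounding
   the focal host clade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

from .model import (
    ExpressionMatrix,
    GeneTree,
    HitRecord,
    HitTable,
    ScaffoldContext,
    SpeciesTree,
)

__all__ = [
    "PSEUDOCOUNT",
    "STATUSES",
    "BestHits",
    "AlienIndexResult",
    "HGTCall",
    "NodeAssignment",
    "DonorCall",
    "partition_best_hits",
    "alien_index",
    "alien_indices",
    "screen_candidates",
    "classify_scaffold",
    "finalize_calls",
    "assign_transfer_node",
    "infer_donor",
    "origin_label",
    "summarize_hgt",
]

#: pseudo-count added to both E-values so the log-ratio is finite even at
#: E-value 0 (the smallest value a search tool reports).
PSEUDOCOUNT = 1e-200

STATUSES = (
    "candidate",
    "putative",
    "excluded_contamination",
    "excluded_expression",
    "excluded_threshold",
)


@dataclass(frozen=True)
class BestHits:
    """Per-query best hits after exclusion-taxon removal and partitioning."""

    query: str
    ingroup_evalue: float  # 1.0 when no ingroup hit
    outgroup_evalue: float  # 1.0 when no outgroup hit
    outgroup_identity: float | None
    outgroup_category: str | None


@dataclass(frozen=True)
class AlienIndexResult:
    gene: str
    best_ingroup_evalue: float
    best_outgroup_evalue: float
    ai: float
    outgroup_identity: float | None
    outgroup_category: str | None


@dataclass(frozen=True)
class HGTCall:
    """Per-gene verdict of the screening cascade."""

    gene: str
    species: str | None
    og: str | None
    status: str
    ambiguous_context: bool = False
    transfer_node: str | None = None
    donor: str | None = None

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


def _best(hits: list[tuple[int, HitRecord]]) -> HitRecord | None:
    """Minimum E-value; ties broken by higher bit score, then input order."""
    if not hits:
        return None
    return min(hits, key=lambda ih: (ih[1].evalue, -ih[1].bitscore, ih[0]))[1]


def partition_best_hits(
    hits: HitTable,
    ingroup: str = "Metazoa",
    exclusion: str = "Hemiptera",
) -> dict[str, BestHits]:
    """Best ingroup and outgroup hit per query.

    Hits whose lineage falls within *exclusion* are skipped entirely.  A
    partition with no hits contributes E-value 1 (the no-hit convention),
    which makes the alien index finite and <= 0 unless a genuine outgroup
    hit exists.
    """
    out: dict[str, BestHits] = {}
    for query in hits.queries:
        ing: list[tuple[int, HitRecord]] = []
        outg: list[tuple[int, HitRecord]] = []
        for i, rec in enumerate(hits.hits_for(query)):
            if rec.lineage.contains(exclusion):
                continue
            (ing if rec.lineage.contains(ingroup) else outg).append((i, rec))
        best_in = _best(ing)
        best_out = _best(outg)
        out[query] = BestHits(
            query=query,
            ingroup_evalue=best_in.evalue if best_in is not None else 1.0,
            outgroup_evalue=best_out.evalue if best_out is not None else 1.0,
            outgroup_identity=best_out.pident if best_out is not None else None,
            outgroup_category=best_out.lineage.category if best_out is not None else None,
        )
    return out


def alien_index(best_ingroup_evalue: float, best_outgroup_evalue: float) -> float:
    """``AI = ln(best_in_E + 1e-200) - ln(best_out_E + 1e-200)``.

    Antisymmetric under swapping the two E-values; strictly decreasing in
    the outgroup E-value at fixed ingroup E-value.
    """
    if best_ingroup_evalue < 0 or best_outgroup_evalue < 0:
        raise ValueError("E-values must be >= 0")
    return math.log(best_ingroup_evalue + PSEUDOCOUNT) - math.log(
        best_outgroup_evalue + PSEUDOCOUNT
    )


def alien_indices(partitions: Mapping[str, BestHits]) -> dict[str, AlienIndexResult]:
    out = {}
    for query, bh in partitions.items():
        out[query] = AlienIndexResult(
            gene=query,
            best_ingroup_evalue=bh.ingroup_evalue,
            best_outgroup_evalue=bh.outgroup_evalue,
            ai=alien_index(bh.ingroup_evalue, bh.outgroup_evalue),
            outgroup_identity=bh.outgroup_identity,
            outgroup_category=bh.outgroup_category,
        )
    return out


def screen_candidates(
    ai_results: Mapping[str, AlienIndexResult],
    expr: ExpressionMatrix | None,
    gene_species: Mapping[str, str] | None = None,
    gene_og: Mapping[str, str] | None = None,
    ai_min: float = 15.0,
    max_out_identity: float = 70.0,
    min_tpm: float = 1.0,
) -> list[HGTCall]:
    """Apply the candidate thresholds; the first failed gate names the status.

    Gates, in order: AI > ``ai_min`` (strict) and best-outgroup identity <
    ``max_out_identity`` (strict) -> otherwise ``excluded_threshold``; then
    minimum TPM over samples >= ``min_tpm`` -> otherwise
    ``excluded_expression``.  Passing ``expr=None`` disables the expression
    gate (for genome genes without quantification).  A screened gene missing
    from the matrix while the gate is enabled raises ``KeyError``.
    """
    gene_species = gene_species or {}
    gene_og = gene_og or {}
    calls = []
    for gene in ai_results:
        res = ai_results[gene]
        if not res.ai > ai_min:
            status = "excluded_threshold"
        elif res.outgroup_identity is None or not res.outgroup_identity < max_out_identity:
            status = "excluded_threshold"
        elif expr is not None and expr.min_tpm(gene) < min_tpm:
            status = "excluded_expression"
        else:
            status = "candidate"
        calls.append(
            HGTCall(
                gene=gene,
                species=gene_species.get(gene),
                og=gene_og.get(gene),
                status=status,
            )
        )
    return calls


def origin_label(hits: Iterable[HitRecord]) -> str:
    """Best-hit origin label of a gene: ``insecta`` if the overall best hit
    (minimum E-value, ties by bit score then order) is an insect sequence,
    ``metazoan`` for other animals, ``non_metazoan`` otherwise, ``no_hit``
    with no hits at all."""
    best = _best(list(enumerate(hits)))
    if best is None:
        return "no_hit"
    if best.lineage.is_insect:
        return "insecta"
    if best.lineage.is_metazoan:
        return "metazoan"
    return "non_metazoan"


def classify_scaffold(context: ScaffoldContext, frac: float = 0.6) -> str:
    """Flank-gene contamination classification of one scaffold.

    ``contamination`` when the fraction of genes with non-metazoan best hits
    is >= ``frac`` (inclusive); ``insect_confirmed`` when the fraction with
    insect best hits is >= ``frac``; if both thresholds are met
    contamination wins (conservative); otherwise ``ambiguous``.  Genes with
    no hit count only in the denominator.
    """
    if not 0.0 < frac <= 1.0:
        raise ValueError(f"fraction threshold must be in (0, 1], got {frac}")
    non_met = context.origin_fraction("non_metazoan")
    insect = context.origin_fraction("insecta")
    if non_met >= frac:
        return "contamination"
    if insect >= frac:
        return "insect_confirmed"
    return "ambiguous"


def finalize_calls(
    candidates: Iterable[HGTCall],
    contexts: Mapping[str, ScaffoldContext],
    frac: float = 0.6,
) -> list[HGTCall]:
    """Resolve candidates against their scaffold context.

    Candidates on contamination scaffolds become ``excluded_contamination``;
    on insect-confirmed scaffolds they become ``putative``; on ambiguous
    scaffolds they stay candidates with the ``ambiguous_context`` flag set
    (reported, but not promoted).  Non-candidate calls pass through.
    """
    out = []
    for call in candidates:
        if call.status != "candidate":
            out.append(call)
            continue
        if call.gene not in contexts:
            raise KeyError(f"no scaffold context for candidate gene {call.gene!r}")
        verdict = classify_scaffold(contexts[call.gene], frac=frac)
        if verdict == "contamination":
            out.append(replace(call, status="excluded_contamination"))
        elif verdict == "insect_confirmed":
            out.append(replace(call, status="putative"))
        else:
            out.append(replace(call, ambiguous_context=True))
    return out


@dataclass(frozen=True)
class NodeAssignment:
    node: str
    dollo_consistent: bool


def assign_transfer_node(
    presence: Iterable[str],
    tree: SpeciesTree,
    max_absent_fraction: float = 0.0,
) -> NodeAssignment:
    """MRCA of the species carrying the orthogroup.

    The event is reported as "transferred not later than" this node.  When
    the orthogroup is absent from more than ``max_absent_fraction`` of the
    node's descendant leaves the presence pattern is not explainable by a
    single gain without losses, and ``dollo_consistent`` is False.
    """
    presence = frozenset(presence)
    node = tree.mrca(presence)
    label = tree.node_label(node)
    if label is None:
        raise ValueError("MRCA node is unlabeled; label internal nodes to report them")
    clade = tree.leaves_under(node)
    absent_fraction = 1.0 - len(presence & clade) / len(clade)
    return NodeAssignment(node=label, dollo_consistent=absent_fraction <= max_absent_fraction)


@dataclass(frozen=True)
class DonorCall:
    category: str  # a donor category or "unclear"
    low_confidence: bool = False


def infer_donor(tree: GeneTree, focal_tips: Iterable[str]) -> DonorCall:
    """Donor kingdom of an HGT event from the gene-tree neighbourhood.

    The two clades surrounding the focal host clade (its sister, and the
    sister of its parent) supply tip categories.  Exactly one category ->
    that donor; two categories with a category-uniform sister -> the
    sister's category, flagged low-confidence; more than two categories, or
    a non-monophyletic focal set -> "unclear".
    """
    focal = frozenset(focal_tips)
    node = tree.mrca(focal)
    if tree.leaves_under(node) != focal:
        return DonorCall("unclear")

    def cats_of_siblings(child, parent) -> frozenset[str]:
        cats: set[str] = set()
        for sib in parent.child_nodes():
            if sib is child:
                continue
            cats.update(tree.category_of(t) for t in tree.leaves_under(sib))
        return frozenset(cats)

    parent = node.parent_node
    if parent is None:
        return DonorCall("unclear")
    sister_cats = cats_of_siblings(node, parent)
    grand = parent.parent_node
    next_cats = cats_of_siblings(parent, grand) if grand is not None else frozenset()
    all_cats = sister_cats | next_cats
    if len(all_cats) == 1:
        return DonorCall(next(iter(all_cats)))
    if len(all_cats) == 2 and len(sister_cats) == 1:
        return DonorCall(next(iter(sister_cats)), low_confidence=True)
    return DonorCall("unclear")


def summarize_hgt(calls: Iterable[HGTCall]) -> dict:
    """Per-species and per-node counts plus donor-category fractions.

    Donor fractions are computed over genes with status ``candidate`` or
    ``putative`` (calls without an inferred donor are binned "unclear") and
    sum to 1 per species; a species with no detected genes gets an empty
    fraction map rather than a division by zero.
    """
    calls = list(calls)
    per_species: dict[str, dict] = {}
    per_node: dict[str, int] = {}
    status_counts: dict[str, int] = {s: 0 for s in STATUSES}
    for call in calls:
        status_counts[call.status] += 1
        sp = call.species or "unknown"
        row = per_species.setdefault(
            sp, {"statuses": {s: 0 for s in STATUSES}, "donor_counts": {}}
        )
        row["statuses"][call.status] += 1
        if call.status in ("candidate", "putative"):
            donor = call.donor or "unclear"
            row["donor_counts"][donor] = row["donor_counts"].get(donor, 0) + 1
            if call.transfer_node is not None:
                per_node[call.transfer_node] = per_node.get(call.transfer_node, 0) + 1
    for row in per_species.values():
        total = sum(row["donor_counts"].values())
        row["donor_fractions"] = (
            {d: c / total for d, c in sorted(row["donor_counts"].items())} if total else {}
        )
    return {
        "total_genes": len(calls),
        "status_counts": status_counts,
        "per_species": per_species,
        "per_node_detected": dict(sorted(per_node.items())),
    }
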