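"""Orthogroup-level comparative statistics.

Summaries of orthogroup sharing across species, the shared-OG network,
majority-consensus annotation of orthogroups from their member genes,
expression-gated group-specific orthogroup sets, and hypergeometric
term enrichment with Benjamini-Hochberg adjustment (no significance
cutoff is applied; all tested terms are returned).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .model import ExpressionMatrix, OrthologyTable

__all__ = [
    "OgSummary",
    "EnrichmentResult",
    "summarize_ogs",
    "shared_og_network",
    "consensus_annotation",
    "expression_gate",
    "highly_expressed",
    "group_specific_ogs",
    "hypergeom_enrich",
]


@dataclass(frozen=True)
class OgSummary:
    """Headline counts of an orthogroup table.

    ``universal`` = orthogroups present in every species;
    ``single_copy_universal`` = exactly one gene in every species;
    ``species_specific`` = per-species counts of orthogroups present in that
    species only; ``singletons`` = per-species counts of size-1 orthogroups.
    """

    total: int
    universal: int
    single_copy_universal: int
    species_specific: dict[str, int]
    singletons: dict[str, int]


def summarize_ogs(table: OrthologyTable) -> OgSummary:
    if len(table) == 0:
        raise ValueError("orthogroup table is empty")
    counts = table.copy_counts()
    present = counts > 0
    universal = int(present.all(axis=1).sum())
    single_copy = int((counts == 1).all(axis=1).sum())
    n_present = present.sum(axis=1)
    species_specific = {}
    singletons = {}
    for sp in table.species:
        only_here = present[sp] & (n_present == 1)
        species_specific[sp] = int(only_here.sum())
        singletons[sp] = int((only_here & (counts.sum(axis=1) == 1)).sum())
    return OgSummary(
        total=len(table),
        universal=universal,
        single_copy_universal=single_copy,
        species_specific=species_specific,
        singletons=singletons,
    )


def shared_og_network(table: OrthologyTable) -> dict[tuple[str, str], int]:
    """Species-pair co-membership weights.

    ``weight(X, Y)`` is the number of orthogroups in which both X and Y are
    present.  The result maps sorted species pairs to weights; pairs that
    never co-occur are omitted (weight 0 is not emitted); self-edges are
    omitted.
    """
    if len(table.species) < 2:
        raise ValueError("need at least 2 species for a shared-OG network")
    present = table.presence()
    edges: dict[tuple[str, str], int] = {}
    for a, b in itertools.combinations(table.species, 2):
        w = int((present[a] & present[b]).sum())
        if w > 0:
            edges[(a, b)] = w
    return edges


def consensus_annotation(
    og_members: Mapping[str, Iterable[str]], threshold: float = 0.75
) -> frozenset[str]:
    """Terms carried by at least ``threshold`` of an orthogroup's members.

    The boundary is inclusive: with 4 members a term on exactly 3 of them
    (0.75) is kept at the default threshold.
    """
    if not og_members:
        raise ValueError("orthogroup has no members")
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    n = len(og_members)
    tally: dict[str, int] = {}
    for terms in og_members.values():
        for t in set(terms):
            tally[t] = tally.get(t, 0) + 1
    return frozenset(t for t, k in tally.items() if k / n >= threshold)


def expression_gate(
    genes: Sequence[str], expr: ExpressionMatrix, min_tpm: float = 1.0
) -> bool:
    """True if at least one gene has TPM >= ``min_tpm`` in *every* sample.

    Used to keep only orthogroups with consistent expression evidence
    (default TPM >= 1 in all samples, boundary inclusive).  Unknown genes
    raise ``KeyError``.
    """
    if not genes:
        raise ValueError("empty gene list")
    return any(expr.min_tpm(g) >= min_tpm for g in genes)


def highly_expressed(gene: str, expr: ExpressionMatrix, min_avg: float = 100.0) -> bool:
    """True if the gene's mean TPM across samples is >= ``min_avg`` (inclusive)."""
    return expr.mean_tpm(gene) >= min_avg


def group_specific_ogs(
    table: OrthologyTable, group: Iterable[str], mode: str = "present"
) -> frozenset[str]:
    """Orthogroups specific to a species group.

    ``present`` mode: present in >= 1 group member and in no non-member.
    ``absent`` mode: present in no group member and in >= 1 non-member.
    The group must be a non-empty proper subset of the table's species.
    """
    group = frozenset(group)
    all_sp = frozenset(table.species)
    if not group or not group < all_sp:
        raise ValueError("group must be a non-empty proper subset of the species")
    if mode not in ("present", "absent"):
        raise ValueError(f"mode must be 'present' or 'absent', got {mode!r}")
    out = []
    for og in table.og_ids:
        sp_with = table.species_with(og)
        in_group = bool(sp_with & group)
        outside = bool(sp_with - group)
        if mode == "present" and in_group and not outside:
            out.append(og)
        elif mode == "absent" and not in_group and outside:
            out.append(og)
    return frozenset(out)


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # study hits
    n: int  # study size
    K: int  # background hits
    N: int  # background size
    p: float  # upper-tail hypergeometric P(X >= k)
    p_adj: float  # Benjamini-Hochberg adjusted


def hypergeom_enrich(
    study: Iterable[str],
    background: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
) -> list[EnrichmentResult]:
    """Term enrichment of a study set against a background.

    Per term, ``p = P(X >= k)`` under Hypergeometric(N, K, n) where N is the
    background size, K the background items carrying the term, n the study
    size and k the study items carrying it.  BH step-up adjustment runs over
    exactly the terms with K >= 1; no significance cutoff is applied.
    Results are sorted by (p, term).
    """
    study_set = frozenset(study)
    bg = frozenset(background)
    if not study_set <= bg:
        raise ValueError("study set must be a subset of the background")
    N = len(bg)
    n = len(study_set)
    term_items: dict[str, set[str]] = {}
    for item in bg:
        for t in term_map.get(item, ()):
            term_items.setdefault(t, set()).add(item)
    terms = sorted(term_items)
    if not terms:
        return []
    raw = []
    for t in terms:
        K = len(term_items[t])
        k = len(term_items[t] & study_set)
        # survival function at k-1 gives the inclusive upper tail P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        raw.append((t, k, K, min(max(p, 0.0), 1.0)))
    adj = stats.false_discovery_control([r[3] for r in raw], method="bh")
    results = [
        EnrichmentResult(term=t, k=k, n=n, K=K, N=N, p=p, p_adj=float(min(a, 1.0)))
        for (t, k, K, p), a in zip(raw, adj)
    ]
    results.sort(key=lambda r: (r.p, r.term))
    return results
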