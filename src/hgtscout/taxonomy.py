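"""Taxonomic lineages and donor-category binning.

A lineage is the ordered list of rank names from domain/superkingdom down to
the most specific rank available (typically species).  Every lineage resolves
to exactly one donor category out of six bins: bacteria, fungi,
viridiplantae, viruses, metazoa and other.  Membership tests for named
groups (e.g. the Metazoa ingroup or the Hemiptera exclusion group used in
alien-index screening) are decided from the lineage alone, with no live
taxonomy-database lookups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

DONOR_CATEGORIES = ("bacteria", "fungi", "viridiplantae", "viruses", "metazoa", "other")

# Checked in order; the first marker found in the lineage decides the bin.
# Viruses and Bacteria are disjoint from Eukaryota, and within Eukaryota the
# kingdoms Fungi / Viridiplantae / Metazoa are mutually exclusive, so the
# order only matters for malformed lineages.
_CATEGORY_MARKERS = (
    ("Viruses", "viruses"),
    ("Bacteria", "bacteria"),
    ("Fungi", "fungi"),
    ("Viridiplantae", "viridiplantae"),
    ("Metazoa", "metazoa"),
)


@dataclass(frozen=True)
class TaxonomyLineage:
    """Ordered rank names, most inclusive first.

    Parameters
    ----------
    ranks : tuple of str
        Rank names, e.g. ``("Eukaryota", "Metazoa", "Arthropoda", "Insecta",
        "Hemiptera")``.  Must be non-empty; each rank must be a non-empty
        string.
    """

    ranks: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ranks", tuple(self.ranks))
        if not self.ranks:
            raise ValueError("a lineage must contain at least one rank")
        for r in self.ranks:
            if not isinstance(r, str) or not r.strip():
                raise ValueError(f"invalid rank name {r!r} in lineage")

    @property
    def category(self) -> str:
        """Donor-category bin of this lineage (pure function of the ranks)."""
        for marker, cat in _CATEGORY_MARKERS:
            if marker in self.ranks:
                return cat
        return "other"

    def contains(self, name: str) -> bool:
        """True if *name* is one of the ranks of this lineage."""
        return name in self.ranks

    @property
    def is_metazoan(self) -> bool:
        return self.contains("Metazoa")

    @property
    def is_insect(self) -> bool:
        return self.contains("Insecta")

    @property
    def is_hemipteran(self) -> bool:
        return self.contains("Hemiptera")

    def to_string(self) -> str:
        return ";".join(self.ranks)

    @classmethod
    def from_string(cls, text: str) -> "TaxonomyLineage":
        """Parse a semicolon-joined lineage string."""
        ranks = tuple(r.strip() for r in text.split(";") if r.strip())
        if not ranks:
            raise ValueError(f"unresolvable lineage string {text!r}")
        return cls(ranks)


def resolve_lineage(
    value: str,
    taxid_lineages: Mapping[str, TaxonomyLineage] | None = None,
) -> TaxonomyLineage:
    """Resolve a taxonomy cell to a lineage.

    If the cell looks like a semicolon-joined lineage it is parsed directly;
    otherwise it is treated as a taxid key into *taxid_lineages* (a small
    offline map, e.g. shipped alongside a hit table).
    """
    value = value.strip()
    if ";" in value:
        return TaxonomyLineage.from_string(value)
    if taxid_lineages is not None and value in taxid_lineages:
        return taxid_lineages[value]
    if not value:
        raise ValueError("empty taxonomy cell")
    # a bare name is a one-rank lineage
    return TaxonomyLineage((value,))


def categories_of(lineages: Iterable[TaxonomyLineage]) -> frozenset[str]:
    return frozenset(lin.category for lin in lineages)
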