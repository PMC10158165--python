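"""Shared domain containers: hit tables, trees, orthogroups, expression,
scaffold contexts.

These are thin, validated wrappers over pandas/dendropy objects so every
downstream stage (decontamination, alien-index screening, comparative
statistics) consumes the same in-memory structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .taxonomy import TaxonomyLineage

__all__ = [
    "HitRecord",
    "HitTable",
    "SpeciesTree",
    "GeneTree",
    "OrthologyTable",
    "ExpressionMatrix",
    "ScaffoldContext",
    "ORIGIN_LABELS",
]


@dataclass(frozen=True)
class HitRecord:
    """One homology hit (one row of a tabular search result)."""

    query: str
    subject: str
    pident: float
    length: int
    evalue: float
    bitscore: float
    lineage: TaxonomyLineage

    def __post_init__(self) -> None:
        if not self.query:
            raise ValueError("query id must be non-empty")
        if self.evalue < 0:
            raise ValueError(f"E-value must be >= 0, got {self.evalue}")
        if not 0.0 <= self.pident <= 100.0:
            raise ValueError(f"percent identity must be in [0, 100], got {self.pident}")


class HitTable:
    """Ordered collection of :class:`HitRecord`, grouped by query id.

    Input order is preserved both globally and within each query.  An empty
    table is valid.
    """

    def __init__(self, records: Iterable[HitRecord] = ()) -> None:
        self._records: list[HitRecord] = list(records)
        self._by_query: dict[str, list[HitRecord]] = {}
        for rec in self._records:
            self._by_query.setdefault(rec.query, []).append(rec)

    @property
    def records(self) -> tuple[HitRecord, ...]:
        return tuple(self._records)

    @property
    def queries(self) -> tuple[str, ...]:
        """Query ids in order of first appearance."""
        return tuple(self._by_query)

    def hits_for(self, query: str) -> tuple[HitRecord, ...]:
        """All hits of *query*, in input order (empty tuple if none)."""
        return tuple(self._by_query.get(query, ()))

    def best_identity(self, query: str) -> float:
        """Maximum percent identity over the query's hits; 0.0 if no hit."""
        hits = self._by_query.get(query)
        if not hits:
            return 0.0
        return max(h.pident for h in hits)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[HitRecord]:
        return iter(self._records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HitTable):
            return NotImplemented
        return self._records == other._records

    def __repr__(self) -> str:
        return f"HitTable({len(self._records)} hits, {len(self._by_query)} queries)"


def _node_label(node: dendropy.Node) -> str | None:
    if node.is_leaf():
        return node.taxon.label if node.taxon is not None else node.label
    return node.label


class SpeciesTree:
    """Rooted species tree with unique leaf labels and MRCA queries."""

    def __init__(self, tree: dendropy.Tree) -> None:
        tree.is_rooted = True
        self._tree = tree
        leaves = [_node_label(lf) for lf in tree.leaf_node_iter()]
        if any(l is None for l in leaves):
            raise ValueError("every leaf must be labeled")
        if len(set(leaves)) != len(leaves):
            raise ValueError("leaf labels must be unique")
        self._leaves: tuple[str, ...] = tuple(leaves)

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                rooting="force-rooted",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
            raise ValueError(f"leaf labels must be unique: {exc}") from None
        return cls(tree)

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaves(self) -> tuple[str, ...]:
        return self._leaves

    def as_newick(self) -> str:
        return (
            self._tree.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
            ).strip()
        )

    def mrca(self, species: Iterable[str]) -> dendropy.Node:
        """Most recent common ancestor node of a non-empty set of leaves.

        The MRCA of a singleton set is that leaf itself.
        """
        wanted = sorted(set(species))
        if not wanted:
            raise ValueError("species set must be non-empty")
        unknown = [s for s in wanted if s not in self._leaves]
        if unknown:
            raise KeyError(f"unknown species id(s): {', '.join(unknown)}")
        node = self._tree.mrca(taxon_labels=wanted)
        if node is None:  # pragma: no cover - cannot happen on validated input
            raise KeyError(f"no MRCA for {wanted}")
        return node

    def mrca_label(self, species: Iterable[str]) -> str:
        label = _node_label(self.mrca(species))
        if label is None:
            raise ValueError("MRCA node is unlabeled; label internal nodes to report them")
        return label

    def leaves_under(self, node: dendropy.Node) -> frozenset[str]:
        return frozenset(_node_label(lf) for lf in node.leaf_iter())

    def find_node(self, label: str) -> dendropy.Node:
        for node in self._tree.preorder_node_iter():
            if _node_label(node) == label:
                return node
        raise KeyError(f"no node labeled {label!r}")

    def clade(self, label: str) -> frozenset[str]:
        """Leaf set descending from the node with the given label."""
        return self.leaves_under(self.find_node(label))

    def node_label(self, node: dendropy.Node) -> str | None:
        return _node_label(node)


class GeneTree:
    """Gene tree whose tips carry resolvable taxonomy lineages.

    Tips belonging to the focal (host-insect) set are identified by the
    caller when inferring donors; the tree itself just maps every tip label
    to a lineage.
    """

    def __init__(self, tree: dendropy.Tree, tip_lineages: Mapping[str, TaxonomyLineage]) -> None:
        tree.is_rooted = True
        self._tree = tree
        self.tip_lineages = dict(tip_lineages)
        missing = [
            _node_label(lf)
            for lf in tree.leaf_node_iter()
            if _node_label(lf) not in self.tip_lineages
        ]
        if missing:
            raise ValueError(f"tips without a lineage: {', '.join(map(str, missing))}")

    @classmethod
    def from_newick(
        cls, newick: str, tip_lineages: Mapping[str, TaxonomyLineage]
    ) -> "GeneTree":
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            rooting="force-rooted",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
        return cls(tree, tip_lineages)

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tips(self) -> tuple[str, ...]:
        return tuple(_node_label(lf) for lf in self._tree.leaf_node_iter())

    def as_newick(self) -> str:
        return (
            self._tree.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
            ).strip()
        )

    def category_of(self, tip: str) -> str:
        return self.tip_lineages[tip].category

    def mrca(self, tips: Iterable[str]) -> dendropy.Node:
        wanted = sorted(set(tips))
        if not wanted:
            raise ValueError("tip set must be non-empty")
        known = set(self.tips)
        unknown = [t for t in wanted if t not in known]
        if unknown:
            raise KeyError(f"unknown tip(s): {', '.join(unknown)}")
        return self._tree.mrca(taxon_labels=wanted)

    def leaves_under(self, node: dendropy.Node) -> frozenset[str]:
        return frozenset(_node_label(lf) for lf in node.leaf_iter())


class OrthologyTable:
    """Orthogroup -> species -> gene membership with derived matrices.

    Invariants: a gene id appears in at most one orthogroup; the presence
    matrix is exactly ``copy counts > 0``; a size-1 orthogroup is a
    singleton.
    """

    def __init__(
        self,
        og_members: Mapping[str, Mapping[str, Sequence[str]]],
        species: Sequence[str] | None = None,
    ) -> None:
        self._members: dict[str, dict[str, tuple[str, ...]]] = {}
        self._og_of: dict[str, str] = {}
        sp_seen: list[str] = []
        for og, by_sp in og_members.items():
            row: dict[str, tuple[str, ...]] = {}
            for sp, genes in by_sp.items():
                genes = tuple(genes)
                if not genes:
                    continue
                if sp not in sp_seen:
                    sp_seen.append(sp)
                for g in genes:
                    if g in self._og_of:
                        raise ValueError(
                            f"gene {g!r} appears in both {self._og_of[g]!r} and {og!r}"
                        )
                    self._og_of[g] = og
                row[sp] = genes
            self._members[og] = row
        if species is not None:
            species = list(species)
            extra = [s for s in sp_seen if s not in species]
            if extra:
                raise ValueError(f"genes listed for undeclared species: {extra}")
            self._species = tuple(species)
        else:
            self._species = tuple(sorted(sp_seen))

    @property
    def og_ids(self) -> tuple[str, ...]:
        return tuple(self._members)

    @property
    def species(self) -> tuple[str, ...]:
        return self._species

    def members(self, og: str) -> dict[str, tuple[str, ...]]:
        return dict(self._members[og])

    def genes(self, og: str) -> tuple[str, ...]:
        return tuple(g for sp in self._members[og].values() for g in sp)

    def species_with(self, og: str) -> frozenset[str]:
        return frozenset(self._members[og])

    def og_of(self, gene: str) -> str | None:
        return self._og_of.get(gene)

    def is_singleton(self, og: str) -> bool:
        return len(self.genes(og)) == 1

    def copy_counts(self) -> pd.DataFrame:
        """Orthogroup x species matrix of gene counts."""
        data = np.zeros((len(self._members), len(self._species)), dtype=int)
        sp_index = {sp: j for j, sp in enumerate(self._species)}
        for i, og in enumerate(self._members):
            for sp, genes in self._members[og].items():
                data[i, sp_index[sp]] = len(genes)
        return pd.DataFrame(data, index=list(self._members), columns=list(self._species))

    def presence(self) -> pd.DataFrame:
        """Orthogroup x species boolean presence matrix."""
        return self.copy_counts() > 0

    def __len__(self) -> int:
        return len(self._members)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OrthologyTable):
            return NotImplemented
        return self._members == other._members and self._species == other._species

    def __repr__(self) -> str:
        return f"OrthologyTable({len(self._members)} OGs, {len(self._species)} species)"


class ExpressionMatrix:
    """Gene x sample TPM matrix.

    All values are non-negative; sample ids are unique; looking up a gene
    that is not in the matrix raises ``KeyError`` (it is never silently
    zero).
    """

    def __init__(self, values: pd.DataFrame) -> None:
        if values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        arr = values.to_numpy(dtype=float)
        if arr.size and (np.isnan(arr).any() or (arr < 0).any()):
            raise ValueError("TPM values must be finite and >= 0")
        self._df = values.astype(float)

    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self._df.index)

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self._df.columns)

    def __contains__(self, gene: str) -> bool:
        return gene in self._df.index

    def tpm(self, gene: str) -> np.ndarray:
        if gene not in self._df.index:
            raise KeyError(f"gene {gene!r} not in expression matrix")
        return self._df.loc[gene].to_numpy(dtype=float)

    def min_tpm(self, gene: str) -> float:
        return float(self.tpm(gene).min())

    def mean_tpm(self, gene: str) -> float:
        return float(self.tpm(gene).mean())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self._df.equals(other._df)


ORIGIN_LABELS = ("metazoan", "insecta", "non_metazoan", "no_hit")


@dataclass(frozen=True)
class ScaffoldContext:
    """A scaffold (or transcript) with its ordered genes and, per gene, the
    taxonomic origin of the best homology hit.

    Gene ordinals are the 1-based positions in ``genes``; the flank-gene
    contamination rule depends only on counts of origin labels, not on
    coordinates or strand.
    """

    scaffold_id: str
    species: str
    genes: tuple[str, ...] = field(default=())
    origins: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "origins", tuple(self.origins))
        if not self.genes:
            raise ValueError(f"scaffold {self.scaffold_id!r} has no genes")
        if len(self.genes) != len(self.origins):
            raise ValueError("genes and origins must have equal length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate gene on scaffold {self.scaffold_id!r}")
        bad = [o for o in self.origins if o not in ORIGIN_LABELS]
        if bad:
            raise ValueError(f"unknown origin label(s) {bad} on {self.scaffold_id!r}")

    def ordinal(self, gene: str) -> int:
        """1-based position of *gene* on this scaffold."""
        try:
            return self.genes.index(gene) + 1
        except ValueError:
            raise KeyError(f"gene {gene!r} not on scaffold {self.scaffold_id!r}") from None

    def origin_fraction(self, label: str) -> float:
        if label not in ORIGIN_LABELS:
            raise ValueError(f"unknown origin label {label!r}")
        return sum(o == label for o in self.origins) / len(self.genes)
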