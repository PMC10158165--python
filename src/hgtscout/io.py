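"""Readers and writers for the tabular and tree formats.

All tabular files are UTF-8, tab-delimited, with a single commented header
line (``# col1<TAB>col2...``).  Readers also accept an uncommented header so
plain BLAST/DIAMOND ``outfmt 6`` exports and OrthoFinder tables load without
editing.  Writers use ``repr`` for floats, so a write/read round trip is
exact (field-by-field equality).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .model import (
    ExpressionMatrix,
    GeneTree,
    HitRecord,
    HitTable,
    ORIGIN_LABELS,
    OrthologyTable,
    ScaffoldContext,
    SpeciesTree,
)
from .taxonomy import TaxonomyLineage, resolve_lineage


class ParseError(ValueError):
    """Malformed input file; the message names the file and line number."""


#: column order of the default hit-table dialect: BLAST/DIAMOND tabular
#: (outfmt 6) core columns plus one taxonomy column.
DEFAULT_HIT_COLUMNS = ("qseqid", "sseqid", "pident", "length", "evalue", "bitscore", "lineage")

_REQUIRED_HIT_FIELDS = {"qseqid", "sseqid", "pident", "length", "evalue", "bitscore"}


def _open_rows(path: str | Path):
    """Yield (line_number, fields) for non-empty rows; the commented header
    (if any) is yielded with its leading '# ' stripped."""
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for lineno, line in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not line or (len(line) == 1 and not line[0].strip()):
                continue
            yield lineno, line


def _strip_comment(fields: list[str]) -> list[str]:
    if fields and fields[0].startswith("#"):
        fields = [fields[0].lstrip("#").strip()] + fields[1:]
    return fields


def read_hit_table(
    path: str | Path,
    columns: Sequence[str] = DEFAULT_HIT_COLUMNS,
    taxid_lineages: Mapping[str, TaxonomyLineage] | None = None,
) -> HitTable:
    """Read a tabular homology-hit file.

    Parameters
    ----------
    columns
        Declared column order.  Must include the outfmt-6 core fields and
        exactly one taxonomy column named either ``lineage`` (semicolon
        joined ranks) or ``staxid`` (resolved through *taxid_lineages*).
    taxid_lineages
        Offline taxid -> lineage map, required when the taxonomy column is
        ``staxid``.
    """
    columns = tuple(columns)
    missing = _REQUIRED_HIT_FIELDS - set(columns)
    if missing:
        raise ValueError(f"column spec lacks required field(s): {sorted(missing)}")
    if "lineage" in columns:
        tax_col = "lineage"
    elif "staxid" in columns:
        tax_col = "staxid"
    else:
        raise ValueError("column spec needs a 'lineage' or 'staxid' taxonomy column")
    idx = {name: i for i, name in enumerate(columns)}

    records: list[HitRecord] = []
    errors: list[str] = []
    for lineno, fields in _open_rows(path):
        if fields[0].startswith("#"):
            continue  # header / comment
        if len(fields) != len(columns):
            raise ParseError(
                f"{path}:{lineno}: expected {len(columns)} columns, found {len(fields)}"
            )
        try:
            pident = float(fields[idx["pident"]])
            length = int(fields[idx["length"]])
            evalue = float(fields[idx["evalue"]])
            bitscore = float(fields[idx["bitscore"]])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric field ({exc})") from None
        cell = fields[idx[tax_col]].strip()
        try:
            if tax_col == "staxid":
                if taxid_lineages is None or cell not in taxid_lineages:
                    raise ValueError(f"taxid {cell!r} not in the offline lineage map")
                lineage = taxid_lineages[cell]
            else:
                lineage = resolve_lineage(cell, taxid_lineages)
        except (ValueError, KeyError) as exc:
            errors.append(f"{path}:{lineno}: {exc}")
            continue
        try:
            records.append(
                HitRecord(
                    query=fields[idx["qseqid"]],
                    subject=fields[idx["sseqid"]],
                    pident=pident,
                    length=length,
                    evalue=evalue,
                    bitscore=bitscore,
                    lineage=lineage,
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    if errors:
        raise ParseError(
            f"{len(errors)} record(s) with unresolvable taxonomy:\n" + "\n".join(errors)
        )
    return HitTable(records)


def write_hit_table(table: HitTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# " + "\t".join(DEFAULT_HIT_COLUMNS) + "\n")
        for rec in table:
            fh.write(
                "\t".join(
                    (
                        rec.query,
                        rec.subject,
                        repr(rec.pident),
                        str(rec.length),
                        repr(rec.evalue),
                        repr(rec.bitscore),
                        rec.lineage.to_string(),
                    )
                )
                + "\n"
            )


def read_orthogroups(path: str | Path) -> OrthologyTable:
    """Read an OrthoFinder-style orthogroup table.

    First row is the header (``Orthogroup`` then one column per species);
    cells are comma-separated gene ids, empty for absence.  A gene id listed
    under two orthogroups is a validation error naming the gene.
    """
    rows = _open_rows(path)
    try:
        _, header = next(rows)
    except StopIteration:
        raise ParseError(f"{path}: empty orthogroup file") from None
    header = _strip_comment(header)
    species = [s.strip() for s in header[1:]]
    og_members: dict[str, dict[str, list[str]]] = {}
    for lineno, fields in rows:
        if len(fields) != len(species) + 1:
            raise ParseError(
                f"{path}:{lineno}: expected {len(species) + 1} columns, found {len(fields)}"
            )
        og = fields[0].strip()
        row: dict[str, list[str]] = {}
        for sp, cell in zip(species, fields[1:]):
            genes = [g.strip() for g in cell.split(",") if g.strip()]
            if genes:
                row[sp] = genes
        og_members[og] = row
    return OrthologyTable(og_members, species=species)


def write_orthogroups(table: OrthologyTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# Orthogroup\t" + "\t".join(table.species) + "\n")
        for og in table.og_ids:
            members = table.members(og)
            cells = [", ".join(members.get(sp, ())) for sp in table.species]
            fh.write(og + "\t" + "\t".join(cells) + "\n")


def read_expression(path: str | Path) -> ExpressionMatrix:
    rows = _open_rows(path)
    try:
        _, header = next(rows)
    except StopIteration:
        raise ParseError(f"{path}: empty expression file") from None
    header = _strip_comment(header)
    samples = [s.strip() for s in header[1:]]
    genes: list[str] = []
    values: list[list[float]] = []
    for lineno, fields in rows:
        if len(fields) != len(samples) + 1:
            raise ParseError(
                f"{path}:{lineno}: expected {len(samples) + 1} columns, found {len(fields)}"
            )
        try:
            values.append([float(v) for v in fields[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric TPM ({exc})") from None
        genes.append(fields[0].strip())
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# gene_id\t" + "\t".join(expr.samples) + "\n")
        for gene in expr.genes:
            vals = expr.tpm(gene)
            fh.write(gene + "\t" + "\t".join(repr(float(v)) for v in vals) + "\n")


_SCAFFOLD_COLUMNS = ("scaffold_id", "species", "ordinal", "gene_id", "origin")


def read_scaffolds(path: str | Path) -> list[ScaffoldContext]:
    """Read a gene-to-scaffold map with per-gene best-hit origin labels."""
    grouped: dict[str, dict] = {}
    for lineno, fields in _open_rows(path):
        if fields[0].startswith("#"):
            continue
        if len(fields) != len(_SCAFFOLD_COLUMNS):
            raise ParseError(
                f"{path}:{lineno}: expected {len(_SCAFFOLD_COLUMNS)} columns, found {len(fields)}"
            )
        scaf, sp, ordinal, gene, origin = (f.strip() for f in fields)
        if origin not in ORIGIN_LABELS:
            raise ParseError(f"{path}:{lineno}: unknown origin label {origin!r}")
        try:
            pos = int(ordinal)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-integer ordinal {ordinal!r}") from None
        entry = grouped.setdefault(scaf, {"species": sp, "rows": []})
        if entry["species"] != sp:
            raise ParseError(f"{path}:{lineno}: scaffold {scaf!r} listed under two species")
        entry["rows"].append((pos, gene, origin))
    contexts = []
    for scaf, entry in grouped.items():
        rows = sorted(entry["rows"])
        ordinals = [r[0] for r in rows]
        if ordinals != list(range(1, len(rows) + 1)):
            raise ParseError(f"{path}: scaffold {scaf!r} ordinals are not contiguous 1..n")
        contexts.append(
            ScaffoldContext(
                scaffold_id=scaf,
                species=entry["species"],
                genes=tuple(r[1] for r in rows),
                origins=tuple(r[2] for r in rows),
            )
        )
    return contexts


def write_scaffolds(contexts: Sequence[ScaffoldContext], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# " + "\t".join(_SCAFFOLD_COLUMNS) + "\n")
        for ctx in contexts:
            for i, (gene, origin) in enumerate(zip(ctx.genes, ctx.origins), start=1):
                fh.write(f"{ctx.scaffold_id}\t{ctx.species}\t{i}\t{gene}\t{origin}\n")


def read_species_tree(path: str | Path) -> SpeciesTree:
    return SpeciesTree.from_newick(Path(path).read_text(encoding="utf-8"))


def write_species_tree(tree: SpeciesTree, path: str | Path) -> None:
    Path(path).write_text(tree.as_newick() + "\n", encoding="utf-8")


def read_gene_tree(newick_path: str | Path, tips_path: str | Path) -> GeneTree:
    """Read a gene tree (Newick) plus its tip-lineage map (TSV)."""
    lineages: dict[str, TaxonomyLineage] = {}
    for lineno, fields in _open_rows(tips_path):
        if fields[0].startswith("#"):
            continue
        if len(fields) != 2:
            raise ParseError(f"{tips_path}:{lineno}: expected 2 columns")
        lineages[fields[0].strip()] = TaxonomyLineage.from_string(fields[1])
    return GeneTree.from_newick(Path(newick_path).read_text(encoding="utf-8"), lineages)


def write_gene_tree(tree: GeneTree, newick_path: str | Path, tips_path: str | Path) -> None:
    Path(newick_path).write_text(tree.as_newick() + "\n", encoding="utf-8")
    with open(tips_path, "w", encoding="utf-8") as fh:
        fh.write("# tip_label\tlineage\n")
        for tip in tree.tips:
            fh.write(f"{tip}\t{tree.tip_lineages[tip].to_string()}\n")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a generic commented-header TSV into a DataFrame (strings kept)."""
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    header = _strip_comment(first.rstrip("\n").split("\t"))
    df = pd.read_csv(path, sep="\t", skiprows=1, header=None, names=header)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# " + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)
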