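"""Synthetic fixture generation with recorded ground truth.

Generates a complete, internally consistent input bundle — species tree,
orthogroup table, homology-hit table, TPM matrix, scaffold contexts, gene
trees, selection-scan and DEG tables, plus decontamination inputs — with a
``SyntheticTruth`` recording every planted HGT event (orthogroup, transfer
node, donor kingdom), contaminant scaffold, foreign transcript, sex-bias
label and selection event.  Every downstream stage of the pipeline is
therefore testable with no external downloads.

The default configuration emulates the study design the pipeline targets:
8 species (one outgroup, one focal archaeococcoid-like species, six
neococcoid-like species) on a pectinate rooted tree, 200 orthogroups, 10
planted HGT events with a donor mix dominated by bacteria and fungi, 5
contaminant scaffolds, 4 expression samples, and two species with
sex-contrast DEG tables.

Generation is deterministic for a fixed seed: the same config and seed
produce byte-identical serialized outputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from . import io as hio
from .hgt import origin_label
from .model import (
    ExpressionMatrix,
    GeneTree,
    HitRecord,
    HitTable,
    OrthologyTable,
    ScaffoldContext,
    SpeciesTree,
)
from .taxonomy import TaxonomyLineage

__all__ = [
    "CANONICAL_LINEAGES",
    "ConfigError",
    "SimulationConfig",
    "HgtEvent",
    "SyntheticTruth",
    "FixtureBundle",
    "simulate_fixture",
    "write_fixture",
]


class ConfigError(ValueError):
    """Invalid simulation configuration (raised before any generation)."""


#: small offline set of canonical lineages used for all generated hits.
CANONICAL_LINEAGES: dict[str, TaxonomyLineage] = {
    "hemiptera": TaxonomyLineage(
        ("Eukaryota", "Metazoa", "Arthropoda", "Insecta", "Hemiptera", "Coccoidea")
    ),
    "insecta": TaxonomyLineage(("Eukaryota", "Metazoa", "Arthropoda", "Insecta", "Diptera")),
    "metazoa": TaxonomyLineage(("Eukaryota", "Metazoa", "Chordata", "Mammalia")),
    "bacteria": TaxonomyLineage(("Bacteria", "Pseudomonadota", "Gammaproteobacteria")),
    "fungi": TaxonomyLineage(("Eukaryota", "Fungi", "Ascomycota", "Saccharomycetes")),
    "viridiplantae": TaxonomyLineage(("Eukaryota", "Viridiplantae", "Streptophyta")),
    "viruses": TaxonomyLineage(("Viruses", "Uroviricota", "Caudoviricetes")),
}

_DONOR_KEYS = ("bacteria", "fungi", "viridiplantae", "viruses")


@dataclass
class SimulationConfig:
    """Study conditions for fixture generation.

    E-value model: log10 E-values are drawn per hit class from normal
    distributions and clipped to disjoint windows, so that with noise off a
    planted HGT gene's best outgroup hit beats its best metazoan hit by far
    more than e^15 (alien index comfortably above the screening threshold)
    and a native gene's never does.
    """

    n_species: int = 8
    n_ogs: int = 200
    n_hgt_events: int = 10
    donor_mix: dict[str, float] = field(
        default_factory=lambda: {
            "bacteria": 0.40,
            "fungi": 0.40,
            "viridiplantae": 0.15,
            "viruses": 0.05,
        }
    )
    n_contaminant_scaffolds: int = 5
    n_transcripts: int = 100
    n_foreign_transcripts: int = 10
    silent_fraction: float = 0.10
    loss_rate: float = 0.0
    lineage_relabel_rate: float = 0.0
    genes_per_scaffold: int = 5
    n_samples: int = 4
    root_gain_prob: float = 0.55
    duplication_prob: float = 0.15
    n_terms: int = 40
    n_female_ogs: int = 25
    n_male_ogs: int = 40
    relax_rate_biased: float = 0.50
    relax_rate_background: float = 0.08
    intensify_rate_biased: float = 0.40
    intensify_rate_background: float = 0.08
    positive_rate: float = 0.05
    seed: int = 1

    def validate(self) -> None:
        if self.n_species < 3:
            raise ConfigError("n_species must be >= 3")
        if self.n_ogs <= 0 or self.n_hgt_events < 0:
            raise ConfigError("counts must be positive")
        if self.n_hgt_events > self.n_ogs:
            raise ConfigError("n_hgt_events cannot exceed n_ogs")
        if set(self.donor_mix) - set(_DONOR_KEYS):
            raise ConfigError(f"donor_mix keys must be among {_DONOR_KEYS}")
        if abs(sum(self.donor_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("donor_mix probabilities must sum to 1")
        for name in (
            "silent_fraction",
            "loss_rate",
            "lineage_relabel_rate",
            "root_gain_prob",
            "duplication_prob",
            "relax_rate_biased",
            "relax_rate_background",
            "intensify_rate_biased",
            "intensify_rate_background",
            "positive_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_foreign_transcripts > self.n_transcripts:
            raise ConfigError("n_foreign_transcripts cannot exceed n_transcripts")
        if self.genes_per_scaffold <= 0 or self.n_samples <= 0:
            raise ConfigError("genes_per_scaffold and n_samples must be positive")
        if self.n_contaminant_scaffolds < 0:
            raise ConfigError("n_contaminant_scaffolds must be >= 0")


@dataclass(frozen=True)
class HgtEvent:
    og: str
    transfer_node: str
    donor: str


@dataclass
class SyntheticTruth:
    """Ground truth of every planted structure."""

    hgt_events: tuple[HgtEvent, ...]
    hgt_genes: frozenset[str]
    contaminant_scaffolds: frozenset[str]
    contaminant_genes: frozenset[str]
    foreign_transcripts: frozenset[str]
    deg_labels: dict[str, str]  # gene -> "up_female" | "up_male"
    selection_events: dict[str, str]  # og -> "relaxation"|"intensification"|"positive"
    female_ogs: frozenset[str]
    male_ogs: frozenset[str]
    seed: int


@dataclass
class FixtureBundle:
    config: SimulationConfig | None  # None when loaded back from files
    species_tree: SpeciesTree
    orthology: OrthologyTable
    hits: HitTable
    expression: ExpressionMatrix
    scaffolds: list[ScaffoldContext]
    gene_trees: dict[str, GeneTree]
    annotations: dict[str, frozenset[str]]  # gene -> terms
    selection: pd.DataFrame
    degs: dict[str, pd.DataFrame]  # species -> DEG table
    transcripts: list[str]
    decontam_ingroup_hits: HitTable
    decontam_broad_hits: HitTable
    truth: SyntheticTruth

    @property
    def gene_species(self) -> dict[str, str]:
        return {g: ctx.species for ctx in self.scaffolds for g in ctx.genes}

    @property
    def gene_scaffold(self) -> dict[str, ScaffoldContext]:
        return {g: ctx for ctx in self.scaffolds for g in ctx.genes}


def _pectinate_newick(species: list[str]) -> str:
    """Rooted pectinate tree with labeled internal nodes N1 (root) .. N{n-1}.

    Node ``Nk`` subtends species k..n, mirroring an outgroup-first ladder.
    """
    n = len(species)
    inner = species[-1]
    for k in range(n - 1, 0, -1):
        inner = f"({species[k - 1]},{inner})N{k}"
    return inner + ";"


def _clade_of(node: str, species: list[str]) -> tuple[str, ...]:
    if node.startswith("N"):
        return tuple(species[int(node[1:]) - 1 :])
    return (node,)


def _uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(lo + (hi - lo) * rng.random())


def _log10e(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def simulate_fixture(config: SimulationConfig | None = None) -> FixtureBundle:
    """Generate a fixture bundle; deterministic for a fixed config seed."""
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    species = [f"SP{i:02d}" for i in range(1, cfg.n_species + 1)]
    newick = _pectinate_newick(species)
    tree = SpeciesTree.from_newick(newick)
    internal_nodes = [f"N{k}" for k in range(1, cfg.n_species)]
    all_nodes = internal_nodes + species

    donors = list(cfg.donor_mix)
    donor_p = np.array([cfg.donor_mix[d] for d in donors], dtype=float)

    # --- orthogroup structure: gain-on-one-node, optional loss -------------
    og_ids = [f"OG{i:04d}" for i in range(1, cfg.n_ogs + 1)]
    hgt_idx = sorted(rng.choice(cfg.n_ogs, size=cfg.n_hgt_events, replace=False).tolist())
    hgt_ogs = [og_ids[i] for i in hgt_idx]
    events: list[HgtEvent] = []
    og_gain: dict[str, str] = {}
    for og in hgt_ogs:
        node = all_nodes[int(rng.integers(len(all_nodes)))]
        donor = donors[int(rng.choice(len(donors), p=donor_p))]
        events.append(HgtEvent(og=og, transfer_node=node, donor=donor))
        og_gain[og] = node
    for og in og_ids:
        if og in og_gain:
            continue
        if rng.random() < cfg.root_gain_prob:
            og_gain[og] = "N1"
        else:
            og_gain[og] = all_nodes[int(rng.integers(len(all_nodes)))]

    counters = {sp: 0 for sp in species}

    def new_gene(sp: str) -> str:
        counters[sp] += 1
        return f"{sp}_g{counters[sp]:05d}"

    og_members: dict[str, dict[str, list[str]]] = {}
    event_by_og = {e.og: e for e in events}
    for og in og_ids:
        clade = list(_clade_of(og_gain[og], species))
        is_hgt = og in event_by_og
        if not is_hgt and cfg.loss_rate > 0 and len(clade) > 1:
            kept = [sp for sp in clade if rng.random() >= cfg.loss_rate]
            clade = kept or [clade[int(rng.integers(len(clade)))]]
        row: dict[str, list[str]] = {}
        for sp in clade:
            if is_hgt:
                ncopies = 1
            else:
                u = rng.random()
                ncopies = 1 + (u < cfg.duplication_prob) + (u < cfg.duplication_prob / 3)
            row[sp] = [new_gene(sp) for _ in range(ncopies)]
        og_members[og] = row
    orthology = OrthologyTable(og_members, species=species)

    hgt_genes = frozenset(g for e in events for g in orthology.genes(e.og))

    # --- annotations -------------------------------------------------------
    terms = [f"T{i:03d}" for i in range(1, cfg.n_terms + 1)]
    annotations: dict[str, frozenset[str]] = {}
    for og in og_ids:
        og_terms = set(
            rng.choice(terms, size=int(rng.integers(1, 4)), replace=False).tolist()
        )
        for g in orthology.genes(og):
            extra = {terms[int(rng.integers(len(terms)))]} if rng.random() < 0.1 else set()
            annotations[g] = frozenset(og_terms | extra)

    # --- contaminant scaffolds --------------------------------------------
    contaminant_scaffolds: list[str] = []
    contaminant_genes: list[str] = []
    cont_info: list[tuple[str, str, list[str], str]] = []  # (scaf, sp, genes, donor cat)
    for i in range(cfg.n_contaminant_scaffolds):
        sp = species[i % len(species)]
        scaf = f"{sp}_cscaf{i:02d}"
        genes = [f"{sp}_cont{i:02d}_{j}" for j in range(1, cfg.genes_per_scaffold + 1)]
        cat = ("bacteria", "fungi")[int(rng.integers(2))]
        contaminant_scaffolds.append(scaf)
        contaminant_genes.extend(genes)
        cont_info.append((scaf, sp, genes, cat))

    # --- expression --------------------------------------------------------
    samples = [f"S{j}" for j in range(1, cfg.n_samples + 1)]
    all_genes: list[str] = []
    for sp in species:
        for og in og_ids:
            all_genes.extend(og_members[og].get(sp, ()))
    all_genes.extend(contaminant_genes)
    tpm = np.empty((len(all_genes), cfg.n_samples))
    for i, g in enumerate(all_genes):
        if g in hgt_genes:
            tpm[i] = [_uniform(rng, 2.0, 50.0) for _ in samples]
        else:
            tpm[i] = [_uniform(rng, 1.5, 80.0) for _ in samples]
    silent_pool = [g for g in all_genes if g not in hgt_genes and g not in contaminant_genes]
    n_silent = int(round(cfg.silent_fraction * len(silent_pool)))
    silent_idx = rng.choice(len(silent_pool), size=n_silent, replace=False)
    gene_pos = {g: i for i, g in enumerate(all_genes)}
    for si in sorted(silent_idx.tolist()):
        g = silent_pool[si]
        tpm[gene_pos[g], int(rng.integers(cfg.n_samples))] = _uniform(rng, 0.0, 0.9)
    expression = ExpressionMatrix(pd.DataFrame(tpm, index=all_genes, columns=samples))

    # --- homology hits -----------------------------------------------------
    # log10 E-value windows (noise off): every native gene's best hit is its
    # own-order (Hemiptera) hit in [-130, -100]; strong metazoan hits live in
    # [-95, -30]; planted HGT genes have a donor hit in [-95, -80] beating
    # their Hemiptera hit in [-78, -60]; weak cross-kingdom hits sit near 0.
    records: list[HitRecord] = []
    hem = CANONICAL_LINEAGES["hemiptera"]
    met = CANONICAL_LINEAGES["metazoa"]
    gene_donor = {g: event_by_og[orthology.og_of(g)].donor for g in hgt_genes}

    def add(gene: str, cat_key: str, log10e: float, pident: float) -> None:
        e = 10.0 ** log10e
        bits = round(30.0 - 2.0 * log10e + _uniform(rng, 0.0, 10.0), 1)
        records.append(
            HitRecord(
                query=gene,
                subject=f"{cat_key[:3]}|{len(records):06d}",
                pident=round(pident, 1),
                length=int(rng.integers(80, 600)),
                evalue=e,
                bitscore=bits,
                lineage=CANONICAL_LINEAGES[cat_key],
            )
        )

    for g in all_genes:
        if g in gene_donor:  # planted HGT gene
            donor = gene_donor[g]
            add(g, donor, _log10e(rng, -87, 4, -95, -80), _uniform(rng, 40, 65))
            add(g, "hemiptera", _log10e(rng, -70, 4, -78, -60), _uniform(rng, 85, 99))
            for _ in range(2):
                add(g, "metazoa", _log10e(rng, -3, 1, -6, 0), _uniform(rng, 72, 95))
        elif g in set(contaminant_genes):
            cat = next(c for scaf, sp, genes, c in cont_info if g in genes)
            add(g, cat, _log10e(rng, -90, 4, -100, -85), _uniform(rng, 40, 65))
            if rng.random() < 0.5:
                add(g, "metazoa", _log10e(rng, -2, 1, -4, 0), _uniform(rng, 72, 95))
        else:  # native gene
            add(g, "hemiptera", _log10e(rng, -110, 5, -130, -100), _uniform(rng, 85, 99))
            for _ in range(3):
                add(g, "metazoa", _log10e(rng, -80, 5, -95, -30), _uniform(rng, 72, 95))
            if rng.random() < 0.7:
                cat = _DONOR_KEYS[int(rng.integers(len(_DONOR_KEYS)))]
                add(g, cat, _log10e(rng, -4, 1.5, -8, 0), _uniform(rng, 35, 60))

    # lineage relabeling noise (applied to the observed table; truth is fixed)
    if cfg.lineage_relabel_rate > 0:
        pool = list(CANONICAL_LINEAGES)
        noisy = []
        for rec in records:
            if rng.random() < cfg.lineage_relabel_rate:
                new = CANONICAL_LINEAGES[pool[int(rng.integers(len(pool)))]]
                rec = HitRecord(
                    query=rec.query,
                    subject=rec.subject,
                    pident=rec.pident,
                    length=rec.length,
                    evalue=rec.evalue,
                    bitscore=rec.bitscore,
                    lineage=new,
                )
            noisy.append(rec)
        records = noisy
    hits = HitTable(records)

    # --- scaffolds (origin labels derive from the observed hit table) ------
    scaffolds: list[ScaffoldContext] = []
    for sp in species:
        sp_native = [
            g
            for og in og_ids
            for g in og_members[og].get(sp, ())
            if g not in hgt_genes
        ]
        chunks = [
            sp_native[i : i + cfg.genes_per_scaffold]
            for i in range(0, len(sp_native), cfg.genes_per_scaffold)
        ]
        sp_hgt = sorted(g for g in hgt_genes if g.startswith(sp + "_"))
        if chunks:
            if len(sp_hgt) <= len(chunks):
                targets = rng.choice(len(chunks), size=len(sp_hgt), replace=False)
            else:
                targets = [i % len(chunks) for i in range(len(sp_hgt))]
            for g, ti in zip(sp_hgt, np.asarray(targets).tolist()):
                chunks[int(ti)].append(g)
        else:
            chunks = [[g] for g in sp_hgt]
        for i, chunk in enumerate(chunks):
            if not chunk:
                continue
            scaffolds.append(
                ScaffoldContext(
                    scaffold_id=f"{sp}_scaf{i:04d}",
                    species=sp,
                    genes=tuple(chunk),
                    origins=tuple(origin_label(hits.hits_for(g)) for g in chunk),
                )
            )
    for scaf, sp, genes, _cat in cont_info:
        scaffolds.append(
            ScaffoldContext(
                scaffold_id=scaf,
                species=sp,
                genes=tuple(genes),
                origins=tuple(origin_label(hits.hits_for(g)) for g in genes),
            )
        )

    # --- gene trees for planted HGT orthogroups ----------------------------
    gene_trees: dict[str, GeneTree] = {}
    other_cats = ["metazoa", "viridiplantae", "fungi", "bacteria"]
    for e in events:
        focal = list(orthology.genes(e.og))
        sister = [f"{e.donor}_ref_{e.og}_{i}" for i in range(1, 4)]
        nxt = [f"{e.donor}_ref_{e.og}_{i}" for i in range(4, 7)]
        outer_cat = other_cats[int(rng.integers(len(other_cats)))]
        if outer_cat == e.donor:
            outer_cat = "metazoa"
        outer = [f"{outer_cat}_out_{e.og}_{i}" for i in range(1, 3)]
        nwk = (
            f"(((({','.join(focal)}),({','.join(sister)}))P,"
            f"({','.join(nxt)}))G,({','.join(outer)}))R;"
        )
        lineages: dict[str, TaxonomyLineage] = {g: hem for g in focal}
        for t in sister + nxt:
            lineages[t] = CANONICAL_LINEAGES[e.donor]
        for t in outer:
            lineages[t] = CANONICAL_LINEAGES[outer_cat]
        gene_trees[e.og] = GeneTree.from_newick(nwk, lineages)

    # --- sex-biased DEG tables and selection results -----------------------
    deg_species = species[-2:]
    eligible_deg = [
        og
        for og in og_ids
        if og not in event_by_og
        and all(sp in og_members[og] and og_members[og][sp] for sp in deg_species)
    ]
    need = cfg.n_female_ogs + cfg.n_male_ogs
    if len(eligible_deg) < need:
        raise ConfigError(
            f"only {len(eligible_deg)} orthogroups span the DEG species; "
            f"{need} sex-biased orthogroups requested"
        )
    picked = rng.choice(len(eligible_deg), size=need, replace=False).tolist()
    female_ogs = frozenset(eligible_deg[i] for i in picked[: cfg.n_female_ogs])
    male_ogs = frozenset(eligible_deg[i] for i in picked[cfg.n_female_ogs :])

    deg_labels: dict[str, str] = {}
    degs: dict[str, pd.DataFrame] = {}
    for sp in deg_species:
        rows = []
        for og in og_ids:
            for g in og_members[og].get(sp, ()):
                if og in female_ogs:
                    lfc, q, label = _uniform(rng, 1.5, 4.0), _uniform(rng, 1e-4, 0.01), "up_female"
                elif og in male_ogs:
                    lfc, q, label = -_uniform(rng, 1.5, 4.0), _uniform(rng, 1e-4, 0.01), "up_male"
                elif rng.random() < 0.05:
                    # large fold change without significance: must not be called
                    lfc, q, label = _uniform(rng, 1.2, 2.5), _uniform(rng, 0.1, 0.9), None
                else:
                    lfc, q, label = _uniform(rng, -0.8, 0.8), _uniform(rng, 0.1, 0.9), None
                rows.append((g, lfc, q))
                if label:
                    deg_labels[g] = label
        degs[sp] = pd.DataFrame(rows, columns=["gene_id", "log2fc", "q"])

    # Selection scan over orthogroups spanning the focal species (SP02-like)
    # and the derived clade; the test branch set is the derived clade, the
    # reference is the focal species, matching a relaxation/intensification
    # contrast between the two.
    focal_sp = species[1]
    eligible_sel = [
        og
        for og in og_ids
        if focal_sp in og_members[og]
        and any(sp in og_members[og] for sp in species[2:])
    ]
    selection_events: dict[str, str] = {}
    sel_rows = []
    for og in eligible_sel:
        u = rng.random()
        if og in male_ogs:
            planted = "relaxation" if u < cfg.relax_rate_biased else None
        elif og in female_ogs:
            planted = "intensification" if u < cfg.intensify_rate_biased else None
        else:
            if u < cfg.relax_rate_background:
                planted = "relaxation"
            elif u < cfg.relax_rate_background + cfg.intensify_rate_background:
                planted = "intensification"
            else:
                planted = None
        if planted == "relaxation":
            p1, p2 = _uniform(rng, 1e-4, 0.01), _uniform(rng, 1e-4, 0.01)
            dn_f, dn_r = _uniform(rng, 0.5, 1.0), _uniform(rng, 0.05, 0.3)
        elif planted == "intensification":
            p1, p2 = _uniform(rng, 1e-4, 0.01), _uniform(rng, 1e-4, 0.01)
            dn_f, dn_r = _uniform(rng, 0.05, 0.2), _uniform(rng, 0.4, 0.8)
        elif rng.random() < 0.15:
            # one tool significant only: the consensus must reject it
            p1, p2 = _uniform(rng, 1e-3, 0.04), _uniform(rng, 0.06, 0.9)
            dn_f, dn_r = _uniform(rng, 0.1, 0.9), _uniform(rng, 0.1, 0.9)
        else:
            p1, p2 = _uniform(rng, 0.06, 0.95), _uniform(rng, 0.06, 0.95)
            dn_f, dn_r = _uniform(rng, 0.1, 0.9), _uniform(rng, 0.1, 0.9)
        sel_rows.append((og, "shift", p1, p2, dn_f, dn_r))
        if planted:
            selection_events[og] = planted
        if rng.random() < cfg.positive_rate and not planted:
            sel_rows.append(
                (
                    og,
                    "positive",
                    _uniform(rng, 1e-4, 0.01),
                    _uniform(rng, 1e-4, 0.01),
                    _uniform(rng, 1.2, 3.0),
                    np.nan,
                )
            )
            selection_events[og] = "positive"
    selection = pd.DataFrame(
        sel_rows, columns=["og_id", "test", "p_tool1", "p_tool2", "dnds_focal", "dnds_ref"]
    )

    # --- decontamination inputs --------------------------------------------
    transcripts = [f"T{i:04d}" for i in range(1, cfg.n_transcripts + 1)]
    foreign_idx = set(
        rng.choice(cfg.n_transcripts, size=cfg.n_foreign_transcripts, replace=False).tolist()
    )
    foreign = frozenset(transcripts[i] for i in sorted(foreign_idx))
    ing_recs: list[HitRecord] = []
    broad_recs: list[HitRecord] = []

    def hit(tid: str, subject: str, pid: float, lineage: TaxonomyLineage) -> HitRecord:
        return HitRecord(
            query=tid,
            subject=subject,
            pident=round(pid, 1),
            length=int(rng.integers(150, 2000)),
            evalue=10.0 ** _log10e(rng, -40, 15, -120, -5),
            bitscore=round(_uniform(rng, 80, 900), 1),
            lineage=lineage,
        )

    broad_pool = list(CANONICAL_LINEAGES.values())
    for i, tid in enumerate(transcripts):
        if i in foreign_idx:
            ing_recs.append(hit(tid, f"cocc|{i}", _uniform(rng, 55, 85), hem))
            broad_recs.append(
                hit(tid, f"nt|{i}", _uniform(rng, 98.0, 100.0), broad_pool[int(rng.integers(len(broad_pool)))])
            )
        else:
            if rng.random() < 0.9:
                ing_recs.append(hit(tid, f"cocc|{i}", _uniform(rng, 92, 99.5), hem))
            broad_recs.append(hit(tid, f"nt|{i}", _uniform(rng, 88, 97.5), met))

    truth = SyntheticTruth(
        hgt_events=tuple(events),
        hgt_genes=hgt_genes,
        contaminant_scaffolds=frozenset(contaminant_scaffolds),
        contaminant_genes=frozenset(contaminant_genes),
        foreign_transcripts=foreign,
        deg_labels=deg_labels,
        selection_events=selection_events,
        female_ogs=female_ogs,
        male_ogs=male_ogs,
        seed=cfg.seed,
    )
    return FixtureBundle(
        config=cfg,
        species_tree=tree,
        orthology=orthology,
        hits=hits,
        expression=expression,
        scaffolds=scaffolds,
        gene_trees=gene_trees,
        annotations=annotations,
        selection=selection,
        degs=degs,
        transcripts=transcripts,
        decontam_ingroup_hits=HitTable(ing_recs),
        decontam_broad_hits=HitTable(broad_recs),
        truth=truth,
    )


def _write_truth(truth: SyntheticTruth, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# record_type\tid\tfield1\tfield2\n")
        fh.write(f"seed\t{truth.seed}\t\t\n")
        for e in truth.hgt_events:
            fh.write(f"hgt_event\t{e.og}\t{e.transfer_node}\t{e.donor}\n")
        for g in sorted(truth.hgt_genes):
            fh.write(f"hgt_gene\t{g}\t\t\n")
        for s in sorted(truth.contaminant_scaffolds):
            fh.write(f"contaminant_scaffold\t{s}\t\t\n")
        for g in sorted(truth.contaminant_genes):
            fh.write(f"contaminant_gene\t{g}\t\t\n")
        for t in sorted(truth.foreign_transcripts):
            fh.write(f"foreign_transcript\t{t}\t\t\n")
        for g in sorted(truth.deg_labels):
            fh.write(f"deg_label\t{g}\t{truth.deg_labels[g]}\t\n")
        for og in sorted(truth.selection_events):
            fh.write(f"selection_event\t{og}\t{truth.selection_events[og]}\t\n")
        for og in sorted(truth.female_ogs):
            fh.write(f"female_og\t{og}\t\t\n")
        for og in sorted(truth.male_ogs):
            fh.write(f"male_og\t{og}\t\t\n")


def write_fixture(
    bundle: FixtureBundle, out_dir: str | Path, create: bool = True
) -> dict[str, str]:
    """Serialize a fixture bundle; returns a file -> sha256 manifest.

    The manifest itself is also written (``manifest.tsv``).  Re-running with
    the same config and seed reproduces identical checksums.
    """
    out = Path(out_dir)
    if not out.exists():
        if not create:
            raise FileNotFoundError(f"output directory {out} does not exist")
        out.mkdir(parents=True)

    hio.write_species_tree(bundle.species_tree, out / "species_tree.nwk")
    hio.write_orthogroups(bundle.orthology, out / "orthogroups.tsv")
    hio.write_hit_table(bundle.hits, out / "hits.tsv")
    hio.write_expression(bundle.expression, out / "tpm.tsv")
    hio.write_scaffolds(bundle.scaffolds, out / "scaffolds.tsv")
    tree_dir = out / "gene_trees"
    tree_dir.mkdir(exist_ok=True)
    for og in sorted(bundle.gene_trees):
        hio.write_gene_tree(
            bundle.gene_trees[og], tree_dir / f"{og}.nwk", tree_dir / f"{og}.tips.tsv"
        )
    with open(out / "annotations.tsv", "w", encoding="utf-8") as fh:
        fh.write("# gene_id\tterms\n")
        for g in sorted(bundle.annotations):
            fh.write(f"{g}\t{','.join(sorted(bundle.annotations[g]))}\n")
    hio.write_table(bundle.selection, out / "selection.tsv")
    for sp, df in sorted(bundle.degs.items()):
        hio.write_table(df, out / f"deg_{sp}.tsv")
    (out / "transcripts.txt").write_text(
        "\n".join(bundle.transcripts) + "\n", encoding="utf-8"
    )
    hio.write_hit_table(bundle.decontam_ingroup_hits, out / "decontam_ingroup_hits.tsv")
    hio.write_hit_table(bundle.decontam_broad_hits, out / "decontam_broad_hits.tsv")
    _write_truth(bundle.truth, out / "truth.tsv")

    manifest: dict[str, str] = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.tsv":
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            manifest[str(path.relative_to(out))] = digest
    with open(out / "manifest.tsv", "w", encoding="utf-8") as fh:
        fh.write("# file\tsha256\n")
        for name, digest in manifest.items():
            fh.write(f"{name}\t{digest}\n")
    return manifest
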