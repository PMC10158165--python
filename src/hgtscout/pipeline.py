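"""End-to-end orchestration: decontamination -> comparative statistics ->
HGT screening cascade -> node/donor assignment -> selection & sex-bias
statistics, with a machine-readable report.

The pipeline runs either from a simulated fixture (a ``simulate`` block in
the config) or from a directory of input files laid out as
:func:`hgtscout.simulate.write_fixture` writes them.  When ground truth is
available, the report carries a truth-evaluation block with precision,
recall, node-assignment and donor accuracy.

All stage outputs and the report serialize deterministically for a fixed
seed (no timestamps or absolute paths inside the report).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from . import io as hio
from .comparative import (
    consensus_annotation,
    expression_gate,
    group_specific_ogs,
    hypergeom_enrich,
    shared_og_network,
    summarize_ogs,
)
from .decontam import classify_foreign
from .hgt import (
    HGTCall,
    alien_indices,
    assign_transfer_node,
    classify_scaffold,
    finalize_calls,
    infer_donor,
    partition_best_hits,
    screen_candidates,
    summarize_hgt,
)
from .model import GeneTree
from .selection import (
    aggregate_selection,
    call_degs,
    common_sex_degs,
    ratio_chi_square,
)
from .simulate import (
    FixtureBundle,
    HgtEvent,
    SimulationConfig,
    SyntheticTruth,
    simulate_fixture,
)

logger = logging.getLogger("hgtscout")

__all__ = [
    "Thresholds",
    "PipelineConfig",
    "RunReport",
    "run_pipeline",
    "evaluate_against_truth",
    "load_fixture",
]


@dataclass
class Thresholds:
    """All screening thresholds with their published defaults."""

    decontam_low: float = 90.0
    decontam_high: float = 98.0
    ai_min: float = 15.0
    max_out_identity: float = 70.0
    min_tpm: float = 1.0
    scaffold_fraction: float = 0.6
    consensus: float = 0.75
    alpha: float = 0.05
    deg_lfc: float = 1.0
    deg_q: float = 0.05
    highly_expressed_tpm: float = 100.0


@dataclass
class PipelineConfig:
    simulate: SimulationConfig | None = None
    input_dir: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int | None = None
    focal_species: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.simulate is None and self.input_dir is None:
            raise ValueError("config needs either a simulate block or input_dir")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        sim = raw.get("simulate")
        thr = raw.get("thresholds") or {}
        return cls(
            simulate=SimulationConfig(**sim) if sim is not None else None,
            input_dir=raw.get("input_dir"),
            thresholds=Thresholds(**thr),
            seed=raw.get("seed"),
            focal_species=raw.get("focal_species"),
            log_level=raw.get("log_level", "INFO"),
        )


@dataclass
class RunReport:
    """Machine-readable run summary (deterministic for a fixed seed)."""

    seed: int | None
    thresholds: dict
    stage_counts: dict
    decontam: dict
    og_summary: dict
    shared_og_network: dict
    group_specific: dict
    enrichment: list
    hgt_summary: dict
    node_assignments: dict
    donor_assignments: dict
    selection_sexbias: dict
    truth_evaluation: dict | None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _read_truth(path: Path) -> SyntheticTruth:
    events = []
    hgt_genes, cont_scafs, cont_genes, foreign = set(), set(), set(), set()
    deg_labels: dict[str, str] = {}
    sel_events: dict[str, str] = {}
    female, male = set(), set()
    seed = 0
    for _, fields in hio._open_rows(path):
        if fields[0].startswith("#"):
            continue
        kind, a, b, c = (fields + ["", "", ""])[:4]
        if kind == "seed":
            seed = int(a)
        elif kind == "hgt_event":
            events.append(HgtEvent(og=a, transfer_node=b, donor=c))
        elif kind == "hgt_gene":
            hgt_genes.add(a)
        elif kind == "contaminant_scaffold":
            cont_scafs.add(a)
        elif kind == "contaminant_gene":
            cont_genes.add(a)
        elif kind == "foreign_transcript":
            foreign.add(a)
        elif kind == "deg_label":
            deg_labels[a] = b
        elif kind == "selection_event":
            sel_events[a] = b
        elif kind == "female_og":
            female.add(a)
        elif kind == "male_og":
            male.add(a)
    return SyntheticTruth(
        hgt_events=tuple(events),
        hgt_genes=frozenset(hgt_genes),
        contaminant_scaffolds=frozenset(cont_scafs),
        contaminant_genes=frozenset(cont_genes),
        foreign_transcripts=frozenset(foreign),
        deg_labels=deg_labels,
        selection_events=sel_events,
        female_ogs=frozenset(female),
        male_ogs=frozenset(male),
        seed=seed,
    )


def load_fixture(input_dir: str | Path) -> FixtureBundle:
    """Load a fixture directory written by :func:`write_fixture`."""
    d = Path(input_dir)
    annotations: dict[str, frozenset[str]] = {}
    for _, fields in hio._open_rows(d / "annotations.tsv"):
        if fields[0].startswith("#"):
            continue
        gene, terms = fields[0], fields[1] if len(fields) > 1 else ""
        annotations[gene] = frozenset(t for t in terms.split(",") if t)
    gene_trees: dict[str, GeneTree] = {}
    tree_dir = d / "gene_trees"
    if tree_dir.is_dir():
        for nwk in sorted(tree_dir.glob("*.nwk")):
            og = nwk.stem
            gene_trees[og] = hio.read_gene_tree(nwk, tree_dir / f"{og}.tips.tsv")
    degs = {}
    for path in sorted(d.glob("deg_*.tsv")):
        df = hio.read_table(path)
        degs[path.stem.removeprefix("deg_")] = df
    truth_path = d / "truth.tsv"
    truth = _read_truth(truth_path) if truth_path.exists() else None
    return FixtureBundle(
        config=None,
        species_tree=hio.read_species_tree(d / "species_tree.nwk"),
        orthology=hio.read_orthogroups(d / "orthogroups.tsv"),
        hits=hio.read_hit_table(d / "hits.tsv"),
        expression=hio.read_expression(d / "tpm.tsv"),
        scaffolds=hio.read_scaffolds(d / "scaffolds.tsv"),
        gene_trees=gene_trees,
        annotations=annotations,
        selection=hio.read_table(d / "selection.tsv"),
        degs=degs,
        transcripts=(d / "transcripts.txt").read_text(encoding="utf-8").split(),
        decontam_ingroup_hits=hio.read_hit_table(d / "decontam_ingroup_hits.tsv"),
        decontam_broad_hits=hio.read_hit_table(d / "decontam_broad_hits.tsv"),
        truth=truth,
    )


def evaluate_against_truth(
    calls: Iterable[HGTCall],
    truth: SyntheticTruth,
    node_assignments: Mapping[str, str] | None = None,
    donor_assignments: Mapping[str, str] | None = None,
) -> dict:
    """Precision/recall of detected HTGs plus node and donor accuracy.

    Detection counts genes with status ``putative`` or ``candidate``.
    Precision is null (None) when nothing was detected; recall is null when
    the truth set is empty.  Node/donor accuracy are fractions over the
    planted events (an event without an assignment counts as wrong).
    """
    calls = list(calls)
    call_genes = {c.gene for c in calls}
    if calls and truth.hgt_genes and truth.hgt_genes.isdisjoint(call_genes):
        raise ValueError("calls and truth share no genes; disjoint universes")
    detected = {c.gene for c in calls if c.status in ("putative", "candidate")}
    putative = {c.gene for c in calls if c.status == "putative"}
    tp = len(detected & truth.hgt_genes)
    precision = tp / len(detected) if detected else None
    recall = tp / len(truth.hgt_genes) if truth.hgt_genes else None
    node_acc = donor_acc = None
    if truth.hgt_events:
        node_assignments = node_assignments or {}
        donor_assignments = donor_assignments or {}
        node_acc = sum(
            node_assignments.get(e.og) == e.transfer_node for e in truth.hgt_events
        ) / len(truth.hgt_events)
        donor_acc = sum(
            donor_assignments.get(e.og) == e.donor for e in truth.hgt_events
        ) / len(truth.hgt_events)
    return {
        "n_detected": len(detected),
        "n_putative": len(putative),
        "n_truth": len(truth.hgt_genes),
        "precision": precision,
        "recall": recall,
        "putative_equals_truth": putative == set(truth.hgt_genes),
        "node_accuracy": node_acc,
        "donor_accuracy": donor_acc,
    }


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> RunReport:
    """Execute all stages and return (and optionally write) the run report."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    thr = config.thresholds
    if config.simulate is not None:
        sim = config.simulate
        if config.seed is not None:
            sim = SimulationConfig(**{**asdict(sim), "seed": config.seed})
        logger.info("simulating fixture (seed=%s)", sim.seed)
        bundle = simulate_fixture(sim)
    else:
        logger.info("loading inputs from %s", config.input_dir)
        bundle = load_fixture(config.input_dir)

    stage_counts: dict[str, dict] = {}

    # --- stage 1: decontamination -----------------------------------------
    foreign_calls = classify_foreign(
        bundle.transcripts,
        bundle.decontam_ingroup_hits,
        bundle.decontam_broad_hits,
        low=thr.decontam_low,
        high=thr.decontam_high,
    )
    foreign_ids = sorted(c.transcript_id for c in foreign_calls if c.verdict == "foreign")
    stage_counts["decontam"] = {
        "in": len(foreign_calls),
        "foreign": len(foreign_ids),
        "retained": len(foreign_calls) - len(foreign_ids),
    }
    logger.info("decontam: %d foreign of %d transcripts", len(foreign_ids), len(foreign_calls))

    # --- stage 2: comparative orthogroup statistics ------------------------
    table = bundle.orthology
    summary = summarize_ogs(table)
    network = shared_og_network(table)
    og_terms = {
        og: consensus_annotation(
            {g: bundle.annotations.get(g, frozenset()) for g in table.genes(og)},
            threshold=thr.consensus,
        )
        for og in table.og_ids
    }
    focal = config.focal_species or table.species[min(1, len(table.species) - 1)]
    present_specific = group_specific_ogs(table, {focal}, mode="present")
    absent_specific = group_specific_ogs(table, {focal}, mode="absent")
    gated = frozenset(
        og
        for og in present_specific
        if expression_gate(
            [g for g in table.genes(og) if g in bundle.expression],
            bundle.expression,
            min_tpm=thr.min_tpm,
        )
    )
    enrichment = hypergeom_enrich(gated, set(table.og_ids), og_terms)
    stage_counts["comparative"] = {
        "ogs": summary.total,
        "focal_specific_present": len(present_specific),
        "focal_specific_present_expressed": len(gated),
        "focal_specific_absent": len(absent_specific),
    }

    # --- stage 3: HGT screening cascade -------------------------------------
    partitions = partition_best_hits(bundle.hits)
    ai = alien_indices(partitions)
    gene_species = bundle.gene_species
    gene_og = {g: table.og_of(g) for g in ai if table.og_of(g) is not None}
    calls = screen_candidates(
        ai,
        bundle.expression,
        gene_species=gene_species,
        gene_og=gene_og,
        ai_min=thr.ai_min,
        max_out_identity=thr.max_out_identity,
        min_tpm=thr.min_tpm,
    )
    contexts = bundle.gene_scaffold
    calls = finalize_calls(calls, contexts, frac=thr.scaffold_fraction)
    scaffold_classes = {
        ctx.scaffold_id: classify_scaffold(ctx, frac=thr.scaffold_fraction)
        for ctx in bundle.scaffolds
    }
    status_counts: dict[str, int] = {}
    for c in calls:
        status_counts[c.status] = status_counts.get(c.status, 0) + 1
    stage_counts["hgt_screen"] = {"in": len(calls), **dict(sorted(status_counts.items()))}
    logger.info("hgt screen: %s", stage_counts["hgt_screen"])

    # --- stage 4: transfer-node assignment and donor inference --------------
    detected_ogs = sorted(
        {c.og for c in calls if c.og and c.status in ("putative", "candidate")}
    )
    node_assignments: dict[str, str] = {}
    dollo_flags: dict[str, bool] = {}
    for og in detected_ogs:
        na = assign_transfer_node(table.species_with(og), bundle.species_tree)
        node_assignments[og] = na.node
        dollo_flags[og] = na.dollo_consistent
    donor_assignments: dict[str, str] = {}
    donor_confidence: dict[str, bool] = {}
    for og in detected_ogs:
        gt = bundle.gene_trees.get(og)
        if gt is None:
            continue
        focal_tips = [t for t in table.genes(og) if t in set(gt.tips)]
        dc = infer_donor(gt, focal_tips)
        donor_assignments[og] = dc.category
        donor_confidence[og] = not dc.low_confidence
    calls = [
        c
        if c.og not in node_assignments or c.status not in ("putative", "candidate")
        else type(c)(
            gene=c.gene,
            species=c.species,
            og=c.og,
            status=c.status,
            ambiguous_context=c.ambiguous_context,
            transfer_node=node_assignments.get(c.og),
            donor=donor_assignments.get(c.og),
        )
        for c in calls
    ]
    hgt_summary = summarize_hgt(calls)

    # --- stage 5: selection and sex-bias statistics --------------------------
    sel_records = aggregate_selection(bundle.selection, alpha=thr.alpha)
    relaxed = sorted(
        {r.og for r in sel_records if r.verdict == "significant" and r.shift_direction == "relaxation_focal"}
    )
    intensified = sorted(
        {r.og for r in sel_records if r.verdict == "significant" and r.shift_direction == "intensification_focal"}
    )
    positive = sorted(
        {r.og for r in sel_records if r.test == "positive" and r.verdict == "significant"}
    )
    deg_records = {
        sp: call_degs(df, species=sp, lfc_min=thr.deg_lfc, q_max=thr.deg_q)
        for sp, df in sorted(bundle.degs.items())
    }
    sexbias: dict = {"n_deg_species": len(deg_records)}
    if len(deg_records) >= 2:
        common = common_sex_degs(deg_records, table)
        universe = sorted({r.og for r in sel_records})
        ratio_tests = {}
        for event_name, event_set in (
            ("relaxation", relaxed),
            ("intensification", intensified),
            ("positive", positive),
        ):
            tests = {}
            sets = {
                "all": frozenset(universe),
                "female": common.female_ogs,
                "male": common.male_ogs,
            }
            for a, b in (("female", "all"), ("male", "all"), ("female", "male")):
                if not sets[a] or not sets[b]:
                    continue
                r = ratio_chi_square(event_set, sets[a], sets[b])
                tests[f"{a}_vs_{b}"] = {
                    "ratio_a": r.ratio_a,
                    "ratio_b": r.ratio_b,
                    "chi2": r.chi2,
                    "p": r.p,
                    "table": [list(r.table[0]), list(r.table[1])],
                    "direction": r.direction,
                }
            ratio_tests[event_name] = tests
        sexbias.update(
            {
                "common_female_ogs": sorted(common.female_ogs),
                "common_male_ogs": sorted(common.male_ogs),
                "both_directions": sorted(common.both_directions),
                "unmapped_deg_genes": common.unmapped_genes,
                "n_relaxed": len(relaxed),
                "n_intensified": len(intensified),
                "n_positive": len(positive),
                "ratio_tests": ratio_tests,
            }
        )

    # --- truth evaluation ----------------------------------------------------
    truth_eval = None
    if bundle.truth is not None:
        truth = bundle.truth
        truth_eval = evaluate_against_truth(calls, truth, node_assignments, donor_assignments)
        truth_eval["contaminant_scaffolds_flagged"] = sum(
            scaffold_classes.get(s) == "contamination" for s in truth.contaminant_scaffolds
        )
        truth_eval["n_truth_contaminant_scaffolds"] = len(truth.contaminant_scaffolds)
        called_foreign = frozenset(foreign_ids)
        tp = len(called_foreign & truth.foreign_transcripts)
        truth_eval["foreign_precision"] = tp / len(called_foreign) if called_foreign else None
        truth_eval["foreign_recall"] = (
            tp / len(truth.foreign_transcripts) if truth.foreign_transcripts else None
        )

    report = RunReport(
        seed=config.seed if config.seed is not None else (
            bundle.config.seed if bundle.config else None
        ),
        thresholds=asdict(thr),
        stage_counts=stage_counts,
        decontam={"foreign_transcripts": foreign_ids},
        og_summary={
            "total": summary.total,
            "universal": summary.universal,
            "single_copy_universal": summary.single_copy_universal,
            "species_specific": summary.species_specific,
            "singletons": summary.singletons,
        },
        shared_og_network={f"{a}--{b}": w for (a, b), w in sorted(network.items())},
        group_specific={
            "focal_species": focal,
            "present": sorted(present_specific),
            "present_expressed": sorted(gated),
            "absent": sorted(absent_specific),
            "absence_caveat": "absence in a transcriptome is weak evidence; "
            "reported for consultation only",
        },
        enrichment=[
            {
                "term": r.term,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "p": r.p,
                "p_adj": r.p_adj,
            }
            for r in enrichment
        ],
        hgt_summary=hgt_summary,
        node_assignments={
            og: {"node": node_assignments[og], "dollo_consistent": dollo_flags[og]}
            for og in node_assignments
        },
        donor_assignments={
            og: {"donor": donor_assignments[og], "confident": donor_confidence[og]}
            for og in donor_assignments
        },
        selection_sexbias=sexbias,
        truth_evaluation=truth_eval,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json() + "\n", encoding="utf-8")
        calls_df = pd.DataFrame(
            [
                {
                    "gene": c.gene,
                    "species": c.species or "",
                    "og": c.og or "",
                    "status": c.status,
                    "ambiguous_context": int(c.ambiguous_context),
                    "transfer_node": c.transfer_node or "",
                    "donor": c.donor or "",
                }
                for c in calls
            ]
        )
        hio.write_table(calls_df, out / "hgt_calls.tsv")
        logger.info("wrote report to %s", out / "report.json")
    return report
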