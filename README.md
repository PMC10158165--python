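# hgtscout

Alien-index screening for horizontally transferred genes (HTGs) and
orthogroup-level comparative statistics, for comparative transcriptomics of
insects — built around the study design in which one de novo transcriptome
(e.g. a scale insect) is compared against related genomes and
transcriptomes on a known species tree.

The package is aimed at researchers who already have the standard upstream
outputs in hand — homology-hit tables with subject taxonomy
(DIAMOND/BLAST outfmt-6 plus a lineage column), an OrthoFinder-style
orthogroup table, TPM matrices, gene-to-scaffold maps, Newick species and
gene trees, and selection-scan / differential-expression result tables —
and need the downstream decision rules applied reproducibly:

* **Decontamination** — a transcript is foreign iff its best identity to an
  ingroup reference is < 90 while its best identity to a broad nucleotide
  database is ≥ 98.
* **HGT screening cascade** — per gene, with best E-values *E*<sub>in</sub>
  (Metazoa) and *E*<sub>out</sub> (non-Metazoa, the host's own order
  excluded entirely):

  AI = ln(*E*<sub>in</sub> + 10⁻²⁰⁰) − ln(*E*<sub>out</sub> + 10⁻²⁰⁰)

  Candidates require AI > 15, best-outgroup identity < 70 and TPM ≥ 1 in
  every sample; candidates on scaffolds with ≥ 60% non-metazoan best hits
  are excluded as contamination, those on scaffolds with ≥ 60% insect best
  hits become putative HTGs; putative orthogroups are dated at the MRCA of
  the species carrying them ("transferred not later than") and a donor
  kingdom is read from the two gene-tree clades surrounding the host clade.
* **Comparative statistics** — orthogroup summaries, the shared-OG network,
  ≥ 75% consensus annotation, expression-gated group-specific orthogroups,
  and upper-tail hypergeometric enrichment with Benjamini–Hochberg
  adjustment (no cutoff).
* **Selection × sex bias** — two-tool significance consensus (both p <
  0.05), relaxation/intensification from branch dN/dS, DEG calling
  (|log2FC| > 1, Q < 0.05, with a no-replicate mode), common sex-biased
  orthogroups across species, and Pearson chi-square comparison of
  event ratios between orthogroup sets.

A first-class synthetic-data module generates a complete, internally
consistent input bundle with recorded ground truth (planted HGT events with
known transfer node and donor, contaminant scaffolds, foreign transcripts,
sex-bias and selection labels), so the whole cascade is testable with no
downloads.

## Worked example

Run the full pipeline on the default simulated study conditions (8 species
on a rooted ladder tree, 200 orthogroups, 10 planted HGT events, 5
contaminant scaffolds, 4 expression samples):

```bash
printf 'simulate:\n  seed: 1\n' > cfg.yaml
hgtscout run --config cfg.yaml --out run1
python - <<'PY'
import json
r = json.load(open("run1/report.json"))
print(r["stage_counts"])
print(r["truth_evaluation"])
PY
```

prints

```
{'decontam': {'in': 100, 'foreign': 10, 'retained': 90},
 'comparative': {'ogs': 200, 'focal_specific_present': 7,
 'focal_specific_present_expressed': 7, 'focal_specific_absent': 74},
 'hgt_screen': {'in': 1348, 'excluded_contamination': 25,
 'excluded_threshold': 1281, 'putative': 42}}
{'n_detected': 42, 'n_putative': 42, 'n_truth': 42, 'precision': 1.0,
 'recall': 1.0, 'putative_equals_truth': True, 'node_accuracy': 1.0,
 'donor_accuracy': 1.0, 'contaminant_scaffolds_flagged': 5,
 'n_truth_contaminant_scaffolds': 5, 'foreign_precision': 1.0,
 'foreign_recall': 1.0}
```

Reading this: of 1,348 screened genes the cascade calls exactly the 42
planted HTG genes putative (precision = recall = 1.0); the 25 genes on the
5 planted contaminant scaffolds pass the alien-index thresholds but are
excluded by the ≥ 60% flank rule; every transfer node and donor matches the
planted event (e.g. `OG0007 → node N1, donor fungi` — an event at the root
of the tree); and the decontamination step removes exactly the 10 planted
foreign transcripts.  The report also carries the orthogroup summary (here
114 of 200 orthogroups universal, 37 single-copy in all species), the
enrichment table, and the sex-bias ratio tests — on this fixture the
male-biased orthogroups carry relaxation events at ratio 0.425 vs 0.202 in
all tested orthogroups (χ² = 7.80, p = 0.0052), recovering the planted
enrichment.

Every subcommand is also available standalone (`hgtscout simulate`,
`hgtscout decontam`, `hgtscout compare …`, `hgtscout hgt …`,
`hgtscout select …`), and the same functionality is importable from
`hgtscout` as a library.

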