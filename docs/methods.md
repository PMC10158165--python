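# Methods

`hgtscout` implements the comparative screening procedures used when a de
novo insect transcriptome (here modelled on a scale-insect study design:
one outgroup, one focal archaeococcoid-like species, six neococcoid-like
species) is compared against related genomes and transcriptomes: foreign
transcript removal, orthogroup-level comparative statistics, a
horizontal-gene-transfer (HGT) screening cascade, and selection / sex-bias
ratio comparisons.  It consumes the *outputs* of the standard upstream
tools (assembler, orthology inference, homology search, codon-model and
differential-expression fits) as tabular and Newick files; it never runs
those tools itself.

## Foreign-transcript rule

An assembled transcript is called foreign when its best percent identity to
an ingroup nucleotide reference (the host's own superfamily) is < 90
(strict) while its best identity to a broad nucleotide database is >= 98
(inclusive): a sequence nearly identical to something in the wider
database but dissimilar from every close relative is far more likely
carry-over contamination than host sequence.  Best identity is the maximum
over a transcript's hits; a missing hit contributes identity 0.  Thus a
transcript with no ingroup hit can be called foreign only if something in
the broad database matches it almost perfectly, and a transcript with no
broad-database hit is always retained — calling foreign requires positive
evidence.  The no-hit convention is a design choice of this package; the
monotonicity of the rule (raising ingroup identity can only retain, raising
broad identity can only condemn) is property-tested.

## Orthogroup statistics

Orthogroup (OG) membership is read from an OrthoFinder-style table with a
hard invariant that a gene belongs to at most one OG.  From the copy-count
matrix the package derives: universal OGs (present in all species),
single-copy universal OGs, per-species specific OGs and singletons, and the
shared-OG network whose edge weight between two species is the number of
OGs containing both.  OG-level functional annotation is the consensus of
member-gene annotations: a term is kept iff >= 75% of members carry it
(inclusive at the boundary).  Group-specific presence calls for the
transcriptome species are gated on expression (an OG passes if at least one
member gene has TPM >= 1 in every sample); absence calls are reported with
an explicit caveat flag because absence from a transcriptome is weak
evidence.  Term enrichment of a study OG set against an explicit background
uses the upper-tail hypergeometric probability P(X >= k) with
Benjamini–Hochberg adjustment over exactly the terms annotated in the
background, and no significance cutoff — all terms are returned.

## The HGT screening cascade

1. **Best-hit partitioning.**  Hits whose subject lineage falls within the
   exclusion taxon (default Hemiptera, the host's own order) are discarded
   from both partitions — a hit to the host's own lineage carries no
   information about donor vs host.  Remaining hits split into ingroup
   (Metazoa) and outgroup (everything else); the best hit in each partition
   is the minimum E-value, ties broken by higher bit score, then input
   order.  An empty partition contributes E-value 1.
2. **Alien index.**  `AI = ln(bestInE + eps) − ln(bestOutE + eps)` with
   `eps = 1e-200` so the statistic is finite at reported E-values of 0.
   The natural-log ratio form with this pseudo-count follows the
   established alien-index definition; with the no-hit convention, AI > 15
   requires an outgroup hit with E < e^-15 even when no metazoan hit
   exists.  AI is antisymmetric under swapping its arguments and strictly
   decreasing in the outgroup E-value; both are property-tested, and the
   double-precision implementation is checked against a 60-digit decimal
   oracle to 1e-9 relative error.
3. **Candidate thresholds.**  Candidate iff AI > 15 (strict) AND
   best-outgroup-hit identity < 70 (strict — near-identical microbial
   matches are more plausibly contamination than ancient transfers) AND
   minimum TPM over samples >= 1 (inclusive; transcribed genes only).  The
   first failed gate names the exclusion status, so the statuses partition
   the screened genes.  The identity filter uses the best outgroup hit
   only.
4. **Flank-gene contamination check.**  Each candidate's
   scaffold/transcript context is classified from the best-hit origins of
   its genes: >= 60% non-metazoan best hits → contamination (all its genes
   excluded); >= 60% insect best hits → insect-confirmed (candidates
   promoted to putative); both thresholds met → contamination wins
   (conservative); otherwise ambiguous, in which case the gene remains a
   candidate flagged `ambiguous_context`, reported but not promoted.
   Genes with no hit count only in the denominator.  Gene ordinals on
   scaffolds are 1-based and strand-agnostic; the rule depends only on
   counts.
5. **Transfer-node assignment.**  A detected OG is dated "transferred not
   later than" the MRCA of the species carrying it.  A Dollo-consistency
   flag marks OGs absent from more than a configurable fraction (default
   0, i.e. any absence) of the node's descendant leaves, where a single
   gain without losses cannot explain the pattern.
6. **Donor inference.**  On the OG's gene tree, the focal host clade is
   the MRCA of the host tips; if the host tips are not monophyletic the
   donor is "unclear".  The tip categories of the two surrounding clades
   (the sister, and the sister of the parent) decide: one category → that
   donor; two categories with a category-uniform sister → the sister's
   category, flagged low-confidence; more than two → "unclear".  Donor
   categories are six fixed bins (bacteria, fungi, viridiplantae, viruses,
   metazoa, other) resolved purely from the lineage string; the binning
   ranks are this package's interpretation, since finer donor taxonomy is
   not needed by any downstream rule.

## Selection and sex-bias statistics

Selection-scan tables carry two p-values per OG per test (two independent
tools); a result is significant only when *both* are < 0.05 (strict).  For
selection-shift tests the direction comes from branch dN/dS: focal >
reference means relaxation on the focal branch set (equivalently
intensification on the reference), focal < reference the opposite, and an
exact tie yields no call (ties are not meaningful at double precision and
the sources do not define them).  Differential expression calls require
|log2FC| > 1 (strict) and Q < 0.05 (strict), or |log2FC| > 1 alone in
no-replicate mode; the contrast orientation (which sex is the fold-change
numerator) is an explicit argument, never inferred from sample names.  An
OG is common female-(male-)biased when it has a female-(male-)up DEG in
every surveyed species.  The ratio of event-carrying OGs between two OG
sets is compared with the Pearson chi-square on the 2x2 table, df = 1.
Uncorrected Pearson is the default with Yates continuity correction as an
option (statistics environments differ on the 2x2 default, so both are
exposed and the table itself is emitted for audit); degenerate tables with
an empty column marginal return chi2 = 0, p = 1.  No multiplicity
adjustment is applied across the pairwise ratio tests by default.

## Synthetic data: what it emulates and what it does not

The generator builds the full input bundle with recorded ground truth.
Defaults define the study conditions: 8 species on a rooted pectinate tree
(outgroup first), 200 OGs, 10 HGT events with donor mix 40% bacteria / 40%
fungi / 15% viridiplantae / 5% viruses, 5 contaminant scaffolds, 100
transcripts with 10 foreign, 4 expression samples, 10% silent genes, 5
genes per scaffold, and two species carrying sex-contrast DEG tables with
25 female-biased and 40 male-biased OGs in which selection relaxation
(male) and intensification (female) are planted at rates 0.50/0.40 against
a 0.08 background.

Non-HGT OG presence follows a gain-on-one-node, no-loss process (an
optional loss rate produces patchy patterns for robustness work), so the
planted transfer node is always the unique Dollo-consistent answer.
E-values are drawn as clipped log10-normals in disjoint windows per hit
class: a native gene's best hit is its own-order hit (log10 E in
[-130, -100]) with strong metazoan support ([-95, -30]) and at most weak
cross-kingdom hits (near 0); a planted HGT gene's donor hit ([-95, -80])
always beats its own-order hit ([-78, -60]) while its metazoan hits are
weak, so noiseless alien indices exceed the threshold by > 20 ln units and
thresholds are sharp.  Contaminant-scaffold genes mimic HGT candidates
(high AI, identity < 70, expressed) but carry no own-order hit, so only
the flank rule excludes them — deliberately exercising the cascade's last
line of defence.  Gene trees graft the host clade into a donor backbone
with two donor-pure surrounding clades.  Optional noise relabels each
hit's lineage with a configured probability, leaving truth fixed.

The generator plants exact *counts* of contaminant scaffolds and foreign
transcripts rather than drawing them from rates, so the recorded truth is
exact at any size.  It does not simulate sequences, alignments, read
counts, or realistic branch lengths, and its E-value classes are cleanly
separated; passing tests therefore demonstrate the correctness of the
decision rules and their composition, not the behaviour of the statistics
on borderline real-world homology evidence.

## Numerics and reproducibility

Hypergeometric tails come from `scipy.stats.hypergeom.sf`, BH from
`scipy.stats.false_discovery_control`, chi-square from
`scipy.stats.chi2_contingency`; tests check them against exact rational
enumeration, a naive step-up loop, and the closed-form Pearson statistic.
All randomness flows from a single integer seed through one generator;
fixtures and pipeline reports are byte-identical across reruns (floats are
serialized with shortest round-trip `repr`, and reports contain no
timestamps or paths).  Boundary semantics follow the printed comparators
throughout and every one is pinned by a two-sided test.  Problem sizes in
the test suite and the acceptance script (200-OG fixtures, 10,000 oracle
pairs, 1,000 random tables/vectors, 5 noise seeds) keep a full run under a
few seconds while leaving no code path unexercised.

## Known limitations

Transcript-level "region" evidence for the flank rule is represented by
per-gene origin labels (covered-fraction semantics share the same 60%
threshold); donor inference assumes the provided rooting; taxonomy is
resolved offline from lineage strings or a shipped taxid map, never from a
live service; and absence-based group-specific calls are inherently weak
for transcriptome species and are flagged as such rather than suppressed.
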