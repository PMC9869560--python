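# Methods

This note records the models, rules and numerical choices behind erfkit,
and what its synthetic benchmarks do and do not demonstrate.

## Classification model

Every protein with at least one retained AP2 domain is classified by a
decision ladder: B3 + AP2 → RAV; two or more AP2 domains → AP2 when any
domain carries an internal insertion of ≥ 8 residues (nominally 10),
otherwise ANT; a single AP2 domain → ERF when the aligned residues at the
diagnostic columns are Ala/Asp, DREB when Val/Glu, otherwise the nearest
bundled profile among ERF, DREB and Soloist (Hamming distance over model
columns; deleted columns count as mismatches; ties resolve in that fixed
order). Domains whose global alignment against the model scores below 0
are flagged unalignable and routed to Soloist. A B3 domain without any
AP2 domain does not qualify for the family and raises an error.

The diagnostic columns default to 14/19. The literature is internally
inconsistent about whether the pair sits at 14/19 or 15/20; both readings
describe the same residues under shifted coordinate conventions, so the
positions are exposed as configuration (`ClassifierConfig.d1/d2`) rather
than resolved. The insertion threshold is 8 rather than the nominal 10 to
tolerate one or two columns of alignment slop; at 10 exactly, a single
misplaced gap could misroute an AP2-subfamily gene to ANT.

Subgroups: ERF genes match the residue key at columns 49/56 — B1 (F,L),
B2 (L,T), B3 (F,T), B4 (M,L) — with a nearest-B-profile fallback; DREB
genes are assigned to A1–A4 purely by nearest profile, because no residue
key exists for the A subgroups (in the original analyses they are read off
the tree); AP2/ANT/RAV/Soloist genes map to the identically named
subgroup. Ambiguous residues (X) at key columns route to the profile path.

### Bundled domain models

The 57-column AP2 consensus, its eleven subgroup variants and the B3
consensus in `erfkit.profiles` are synthetic modelling devices: plausible
AP2/ERF-like sequences constructed so that diagnostic columns and
inter-profile distances are exactly controlled (A1–A4 differ pairwise at
2–3 designated columns, Soloist at 18). They are not curated biological
consensus sequences, and nearest-profile assignments on real proteomes
should be re-anchored to alignments of reference family members.

## Alignment and scoring

One scoring scheme backs the whole package: BLOSUM62 with affine gaps
(open 10, extend 1; a length-L gap costs 10 + (L−1)), global mode, via
Biopython's PairwiseAligner. `align_to_model` threads a domain onto the
model's fixed columns and reports internal insertion runs; RBH orthology
and codon-alignment threading reuse the same scores. The PSSM scanner
scores 57-residue windows in bits against a uniform background with a
15-bit threshold; at the bundled models' 0.9 per-column conservation a
true domain scores ≈ 200 bits and random sequence ≈ −160 ± 13, so the
threshold sits ~14 SD above noise. The scanner does not detect
AP2-subfamily domains containing the 10-residue insertion (a fixed-width
window cannot straddle it); those enter via the TSV route, which is the
pipeline default.

## Domain-hit filtering

Hits with e-value > 1e-5 are dropped; among overlapping hits (≥ 1 shared
residue) the lowest e-value wins, ties broken by lower start then longer
hit. Hits lacking e-values (some analyses emit "-"; the PSSM route reports
bit scores only) are kept but rank below any numeric e-value, so evidence
is not silently lost while TSV-backed hits dominate. The filter is
idempotent and its output non-overlapping by construction.

## Conservation statistic

Column frequencies exclude gaps from denominators; the consensus residue
is uppercase iff its fraction strictly exceeds 0.5, ties break
alphabetically. The "consensus ratio" of a division is the mean
consensus-residue fraction over its columns (all-gap columns excluded;
fully gapped divisions are NaN). The eight divisions are fixed from the
domain's secondary structure (β1 1–7, β2 14–20, β3 31–33, α 48–57, plus
the intervals and the tail beyond column 57 when the model is wider).
This fraction-based score is a deliberate stand-in for profile-based
consensus scoring tools that weight physicochemical similarity; published
division-level percentages from such tools are therefore not comparable
targets.

## Synteny and specificity

RBH pairs require a unique mutual best score (ties disqualify). Collinear
blocks chain pairs within a chromosome pair by O(n²) dynamic programming:
strictly increasing rank on genome A, strictly monotone (either
orientation) on B, at most 25 intervening genes between consecutive pairs
on both genomes; chains under 5 pairs are discarded; chains are extracted
greedily by decreasing length (ties: earliest start, then +1 orientation).
A gene's status (three-species / two-species / species-specific) counts
the other species against which it appears in any block — block
membership, not bare RBH, defines orthology, matching how synteny-based
"no orthologous relationship" counts are derived. Tandem arrays are
maximal same-subgroup runs with ≤ 10 intervening genes and ≥ 2 members.
Ranks come from gene starts per chromosome (ties by gene id); a
chromosome-name filter can exclude unanchored scaffolds.

## Ks estimation

NG86 as published: per-codon synonymous site fractions from the nine
single-nucleotide neighbors (changes to stop codons excluded from numerator
and denominator), site counts averaged between the two sequences;
multi-nucleotide codon differences averaged over all minimal mutation
paths with equal weights, paths through stops dropped (if every path hits
a stop, all paths are kept with stop steps counted as nonsynonymous);
Jukes–Cantor correction, undefined at pS ≥ 3/4. Recency uses strict
thresholds: Ks < 0.1 post-dates the tomato–potato split, Ks < 0.3 the
pepper–*Solanum* split; pairs at Ks ≥ 3 are flagged saturated. NG86 was
chosen over approximate maximum-likelihood variants (e.g. the MYN model
used by common calculators) because it is closed-form and oracle-testable
at desk scale; Ks-dependent counts published from MYN runs are therefore
not reproduction targets. At least 30 paired codons are required per
estimate.

## Expression stage

FPKM = counts·1e9/(library·length). Differential calls use the published
thresholds (|log2FC| > 1, BH-adjusted p < 0.05) with log2FC from mean FPKM
with pseudocount 1 and p from a two-sided Welch test on log2(FPKM+1). This
replaces a negative-binomial Wald test deliberately: it is
dependency-free and has measurable type-I/power behavior on the
generator's data; genome-wide DEG totals published from NB models are not
comparable targets. Clustering is fuzzy c-means (Bezdek updates,
fuzzifier m = 2.0 — the conventional default, unstated in most Mfuzz-based
analyses — 20 random restarts, tolerance 1e-6) on per-gene standardized
time courses; constant profiles are excluded and reported. GO enrichment
is the one-sided hypergeometric tail with BH FDR ≤ 0.01 over all supplied
terms (no ontology-level filtering unless terms are pre-filtered
upstream). Ortholog expression correlation averages the time-course
species over its five time points per condition and reports Pearson r
across pairs, NaN below 3 usable pairs.

## Synthetic data: what it emulates and what it does not

The generator emulates, per species: proteomes whose family genes embed
subgroup-consensus domains (diagnostic residues exact; optional
off-diagnostic noise), flanked by random "barcode" peptides; hit tables
with planted hits (e ≤ 1e-10), overlapping duplicates at worse-but-passing
e-values and decoys at e > 1e-5; gene models with a conserved cross-species
backbone order, interspersed species-specific genes, and tandem arrays
planted as atomic blocks of the first species; CDS pairs restricted to
codon families whose third position is four-fold degenerate and whose
other positions admit no synonymous change (so each codon contributes
exactly one synonymous site and the planted Jukes–Cantor divergence maps
analytically to the NG86 expectation); negative-binomial counts
(dispersion 0.1, a typical bulk RNA-seq scale that keeps DEG power high at
3 replicates) with planted log2 fold changes shared between orthologs; and
GO tables with one planted enriched term plus uniform background terms.
All draws come from `default_rng([seed, stream])`, making every emitted
byte a function of the config.

Modelling choices worth knowing:

- Orthologs are sequence-identical across species; species-specific genes
  of one subgroup within a species are identical copies (one barcode per
  species × subgroup). Both reflect the recent-duplication origin of
  specific genes and make cross-species best hits between unrelated
  specific genes tie, so RBH discards them and zero-noise recovery is
  exact. A subgroup with exactly one specific gene per species loses this
  tie protection; recovery checks therefore run at scales where every
  subgroup keeps ≥ 2 specific members (≈ 100 genes/species with the
  default mix).
- Two-species ortholog groups carry unique barcodes and can reciprocally
  match each other across the third species — exactly the noise real RBH
  exhibits. Exact-recovery checks therefore use a pure three-species
  backbone (`two_species_fraction = 0`); with it, RBH precision and recall
  are 1.0 and specificity counts equal planted counts.
- Chromosomes hosting a planted array carry no other gene of that
  subgroup, and arrays are inserted as contiguous blocks, so each planted
  array is detected with exactly its members. Same-subgroup genes
  elsewhere can form incidental arrays by chance placement; those satisfy
  the detection definition and are not errors.
- The generator does not model intron structure, assembly artifacts,
  alignment uncertainty, domain degradation, between-species expression
  divergence, or evidence tiers for newly annotated genes. Passing its
  recovery checks shows the rules and estimators are implemented
  correctly, not that they are robust to real-data noise.

## Problem sizes and defaults

Generator defaults are 3 species × 200 family genes + 50 background genes,
subfamily mix ERF 0.55 / DREB 0.20 / AP2 0.08 / ANT 0.05 / RAV 0.08 /
Soloist 0.04 (ERF split B1 0.20 / B2 0.35 / B3 0.20 / B4 0.25), half the
genes species-specific, arrays of 5 B2 genes on chr1 and 4 B3 genes on
chr4 (mirroring the pepper expansions), Ks targets {0.05, 0.1, 0.2, 0.3,
0.5} at 300 codons, and a 4-stress × 5-time-point × 3-replicate count
design with a matching control layout; contrasts pool all samples of a
condition against control. Tandem-array sizes must fit the available
species-specific genes, so smaller simulations scale them down
(`default_tandem_arrays`). The test suite and acceptance script run the
classifier at the full 600-gene default and the alignment-heavy synteny
stages at 60–100 genes per species, the package's standard desk-scale
configurations; timings at these sizes are seconds per stage on one CPU.

## Known limitations

- Nearest-profile assignment (A subgroups, Soloist) is only as good as the
  bundled profiles; on real data it should follow a tree, which the NJ
  coherence score approximates but does not replace.
- NJ uses p-distances and canonical Saitou–Nei joining with deterministic
  tie-breaks; negative branch lengths are possible and not clamped.
- The Welch-based DEG test is anti-conservative for very low counts where
  log-FPKM normality fails; with the generator's baseline (~300 counts)
  its empirical type-I rate is at the nominal level.
- `scan_pssm` cannot detect insertion-bearing AP2-subfamily domains (see
  above); architecture truth for those genes must come from hit tables.
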