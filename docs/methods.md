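# Methods

## Overview

`rhamnopan` implements a reference-centric view of genome diversity in a
bacterial species: every strain is described by which of the reference's
genes it retains, how far retained genes have diverged, which reference
CRISPR spacers it still carries, and a panel of niche-relevant phenotypes.
The central object is the binary presence/absence matrix (strains ×
reference genes, 1 = present, 0 = divergent-or-missing); every downstream
statistic — shared content, core genome, clustering, loss-frequency
segmentation — is a function of that matrix plus the reference
annotation. The pipeline deliberately does not look for genes absent from
the reference: strain-specific gene content (the pan-genome proper) is
out of scope.

## Presence/absence calling

A reference gene is searched in each strain (all contigs, both strands)
and summarised by the identity and coverage of its best local alignment:

- *identity* = matching columns / alignment columns,
- *coverage* = fraction of the gene's bases inside the alignment.

The call is **present** iff identity ≥ 0.40 **and** coverage ≥ 0.80, both
inclusive. The 40 % identity cutoff is the annotation-transfer threshold
used for synteny-based ortholog sharing between reference-mapped genomes.
The coverage criterion is this package's surrogate for "how much of the
gene must the shared region contain": with 0.80, a gene with only half of
its length left (e.g. truncated by a deletion breakpoint) scores absent
even though the remaining half matches perfectly. Divergent and missing
genes are deliberately not distinguished in the matrix; the continuous
identity/coverage values are kept on each `GeneCall` for diagnostics.

### Alignment engine

Scoring is BLAST-like: match +2, mismatch −3, gap open −5 (charged on the
first gap base), gap extension −2; `N` never matches, including another
`N`. Two routes produce identical summaries where they overlap:

- **direct route** (contigs ≤ 4 kb): exact affine-gap Smith–Waterman over
  the full matrix (numba kernel). Ties are resolved deterministically:
  the alignment ends at the first maximal cell in row-major order, and
  the traceback prefers diagonal moves, then query-consuming gaps, then
  target-consuming gaps. The test suite verifies score, identity and
  coverage against an independently written plain-Python DP oracle, and
  the oracle's scores against Biopython's `PairwiseAligner`.
- **anchored route** (long contigs): candidate loci come from sampled
  12-mer anchors (every 4th query k-mer; all k-mers retried before giving
  up) clustered on diagonals; a diagonal band needs ≥ 2 anchors, since
  single 12-mer hits occur by chance in genome-sized backgrounds. Each
  candidate window is aligned end-to-end with a banded bit-vector
  aligner (edlib) and the best-scoring contiguous sub-alignment is
  extracted from the path; boundaries of a local optimum always lie on
  match runs, which makes the run-level scan exact for that path. When
  the unit-cost path contains indels (where the affine-gap optimum may
  differ), the window is re-aligned with the exact kernel instead.

Like all seed-and-extend methods the anchored route has a sensitivity
floor: a homolog with no shared 12-mer on either strand (in practice
below roughly 65–70 % identity, far below the presence threshold's
practical regime) is reported as having no hit, and the banded window
alignment abandons beyond 45 % query-length edits. Queries too short to
anchor (CRISPR spacers) use a banded whole-contig scan instead. The
direct route has no such floor, so small-instance behaviour is exact.

## Pan/core statistics

- Percentages are **truncated** to one decimal (floor of 1000·n/d, /10),
  not rounded: the reporting convention recovered from printed
  ratio/percent pairs such as 31/77 → 40.2 and 2918/3016 → 96.7, both of
  which contradict round-half-up. Full precision is available to callers;
  truncation applies at the reporting boundary.
- The median shared count over an even number of strains is the lower
  median, so it is always an attainable row sum.
- The core genome is the column-wise AND of calls. The accumulation curve
  averages running prefix intersections over random strain orderings
  (exhaustive over all n! orderings on request, used by the brute-force
  oracle test); it is monotone non-increasing and pinned to the core size
  at k = n.
- Gene-content clustering defaults to Jaccard distance on binary rows
  with average linkage (UPGMA), the standard pairing for binary gene
  content; both are configurable. Linkage is computed by
  `scipy.cluster.hierarchy`; equal-height merge order therefore follows
  scipy's deterministic internal order rather than a lowest-index rule —
  merge heights, which are what the tests pin, are unaffected.
- The substitution tree concatenates cleanly recovered (indel-free,
  full-length) copies of core genes per strain, computes pairwise
  mismatch fractions over positions covered in both strains, and applies
  neighbor joining (scikit-bio). Tree/dendrogram concordance is the
  Pearson correlation of the two cophenetic distance matrices, clamped
  at 0 so the score lies in [0, 1]; two degenerate (star-like) trees
  score 1 against each other.
- Group contrasts of shared-content percentages use the two-sided
  Mann–Whitney U test (no normality assumption for percentage data);
  cohort-level 2×2 trait associations use Fisher's exact test.

## Variable regions

Per-gene loss frequency is 1 − column mean of the matrix. A variable
region is a maximal run of genes with loss frequency ≥ 0.10, tolerating
up to 1 consecutive below-threshold gene inside the run, trimmed to
start and end on above-threshold genes, and spanning ≥ 5 genes.
Contiguity is defined in gene-index space, not base pairs, and
IS-element genes count toward run length. Regions are annotated with the
dominant overlapping genomic island and their IS-gene count.

Two properties follow from the rule and are tested: regions are disjoint
and never start or end below threshold, and lowering the frequency
threshold never uncovers a previously covered gene. Exact ±1-gene
recovery of planted islands is only a well-posed claim when the genes
flanking an island stay below threshold; with background gene loss
switched on, a flanking gene occasionally crosses 0.10 in a small cohort
and the rule then legitimately extends the region. Recovery-with-boundary
checks therefore run on cohorts without background loss, and the noisy
default cohort is checked for containment plus above-threshold anchoring
of any extension.

## CRISPR oligotyping

Each of the reference's 24 spacers is scored per strain:

- **conserved** — the best end-to-end placement of the whole spacer
  reaches ≥ 90 % identity (or a trimmed local match still spans ≥ 95 %).
  Judging the conserved tier end-to-end matters: with local semantics a
  single substitution near a spacer edge gets trimmed away and would
  masquerade as lost coverage. A spacer of typical length with 1–3
  substitutions stays conserved.
- **partial** — the best local alignment reaches ≥ 80 % identity over
  ≥ 50 % of the spacer *and* carries at least the alignment score of an
  intact half-spacer. The score floor exists because a 15 bp segment at
  80 % identity arises by chance in genome-sized sequence; without it, a
  strain lacking the locus entirely would still show scattered "partial"
  spacers.
- **absent** — otherwise.

Cas genes use the gene-level presence rule (≥ 0.40 / ≥ 0.80). Profile
distance is the normalised mismatch over the spacer+cas status vectors
with `partial` counting as a half-match. The protospacer search is
seed-and-extend with word size 7 (an exact 7-mer on either strand is
required before alignment) and reports hits at ≥ 85 % identity over
≥ 80 % of the spacer, one per spacer/target pair; E-values are not
computed — deterministic identity/coverage cutoffs stand in for them.

## Phenotypes and the geno-phenotype classifier

Growth inhibition is quantified as ARP = 100 × (AUC_control −
AUC_sample)/AUC_control with trapezoidal AUC on the native 30-minute
grid (no resampling); negative values (growth enhancement) are returned
as-is. Mucus binding is the bound/total signal percentage. The
pilosotype call requires every pilin/sortase gene present *and*, when
assay evidence is supplied, positive evidence — an intact cluster with
negative binding evidence is negative (production can be broken by point
mutations or promoter decay).

The classifier scores seven axes in [0, 1], oriented so 1 is the
intestinal-adapted (B) pole: gene content (shared fraction rescaled over
configurable bounds, default 0.85–1.0), conserved-spacer fraction, bile
(resistant 1 / moderately 0.67 / poorly 0.33 / sensitive 0), pilosotype,
sugar group I as-is, and sugar groups II/III inverted (they mark the
dairy pole). API calls weigh positive 1, partially positive 0.5,
negative 0. Axis weights are uniform and the class cut-offs are mean
score ≥ 0.6 → B family (split into B and B_ΔspaCBA by presence of the
pili island), ≤ 0.4 → A, otherwise unassigned. The axis definitions and
cut-offs are this package's construction: they reproduce the qualitative
A/B/B_ΔspaCBA system, not any published score magnitudes, and are all
exposed in `AxisConfig`. TLR2 fold-induction is carried as data but
excluded from scoring, since it tracks neither gene-content clustering
nor niche.

## Synthetic cohorts

The generator is the package's study condition, not a tuning knob. A
simulated reference carries 300 ORF-like genes (uniform 402–798 bp,
start/stop codons, no internal stops) on a 300 kb chromosome with six
8-gene islands in the default layout — bile/taurine (GI1), SpaCBA pili
(GI2), prophage (GI3), EPS (GI4), fucose/sugar-group-I (GI5),
lactose–maltose/sugar-groups-II-III (GI6) — and an embedded Type II-A
locus (4 cas genes, 24 spacers of 30 bp between 36 bp repeats). These
sizes keep a full 40-strain pipeline run under ~10 s while preserving
island/background contrast.

Strains are derived by: island-level Bernoulli loss (all-or-none per
island — variable regions are lost as blocks), independent background
gene loss, substitutions at a per-niche rate applied to everything
retained (indels are not simulated: presence calling is
identity/coverage based and indels would add no tested behaviour), and
spacer-array truncation keeping the trailing (ancestral) `spacer_retention`
spacers — arrays grow at the leader end, so strains share the old end of
the reference array. Phenotypes are deterministic functions of the true
genotype (bile ← GI1, pilosotype ← GI2, sugar group I ← GI5, groups
II/III ← GI6, antagonism a niche constant) flipped independently with a
small noise probability; ARP values are generated through actual
simulated logistic growth curves. Each strain records its ground truth,
including the class its noise-free truth would receive from the scorer.

Default niche profiles encode the qualitative contrasts of
niche adaptation — dairy strains lose the pili, fucose and bile islands,
keep the lactose/maltose island, retain only 6 reference spacers and
diverge at ~2 % of sites; intestinal strains are reference-like with the
dairy-sugar island usually absent — with rates chosen once as plausible
magnitudes (no quantitative loss rates are published). Because the
default dairy and intestinal profiles share some losable islands,
clustering-recovery experiments use a dedicated two-profile condition
with disjoint island sets (`disjoint_contrast_profiles`), where gene
content carries an unambiguous niche signature.

What passing on synthetic cohorts does **not** show: the generator has
no rearrangements, no horizontal acquisition of non-reference genes, no
assembly gaps or sequencing error, single-contig strains, and
substitution-only divergence — so the tests certify the pipeline's
recovery of its own generative model at realistic rates, not performance
on raw assemblies.

## Numerical and degenerate-input conventions

- All randomness flows from integer seeds through `numpy` generators;
  each generator component uses a distinct stream key so that a shared
  user seed never correlates, say, spacer sequences with chromosome
  background. CLI outputs for a fixed seed are byte-identical (manifests
  carry no timestamps).
- Empty strain sets, empty matrices, zero-length sequences, non-binary
  matrix cells, duplicated locus tags or strain ids, non-increasing time
  grids and zero control AUCs are rejected with `ValueError`s at the
  boundary rather than propagated.
- The XLSX import shim auto-detects matrix orientation by which axis's
  labels look like locus tags (or match a supplied reference tag list).
- Newick serialisation goes through dendropy (quoted labels, including
  spaces, round-trip; branch lengths to well below 1e-9); in-memory
  trees are scikit-bio `TreeNode`s.

## Known limitations

- The anchored search's sensitivity floor (~65–70 % identity on long
  contigs) means the 40 % identity threshold is only exercised to its
  boundary on direct-route (small) instances; this mirrors standard
  seed-and-extend practice.
- "Partial" spacer conservation below a half-spacer's worth of evidence
  is indistinguishable from background and reported absent.
- Classifier cut-offs (0.6/0.4) are constructions; published per-class
  cohort counts cannot be claimed to be reproduced by them.
- The published supplementary presence/absence workbook is not
  redistributable here; the checks that consume it run only where the
  user supplies the file (see README).
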