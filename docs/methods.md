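# Methods

`epmap` implements an integrated desk-scale version of a multi-omics
fine-mapping workflow for livestock complex traits: chromatin loops anchored
on active regulatory elements link GWAS leading signals to target genes, and
RNA-chromatin contacts, breed allele-frequency divergence, open chromatin,
and TF-motif disruption narrow the candidate variants. Every stage is
exercisable on synthetic data with planted ground truth, so the package's
claims are about *recovery of planted structure*, not about any particular
real dataset.

## Coordinate model

All coordinates are 0-based half-open (BED convention) internally; VCF-style
1-based positions are converted at the I/O boundary in both directions.
Chromosome names are exact strings. Loop "distance" is the distance between
anchor midpoints; loops are retained in the 5 kb–2 Mb band and are
intrachromosomal only. Sorted outputs break ties on (chrom, start, end, id).

## Loop and gene classification

An anchor's regulatory content is promoter (P) if any active-promoter
element overlaps it, else enhancer (E) if an enhancer or super-enhancer
does, else none. An anchor carrying both counts as P (promoter precedence),
so promoter-involving loop classes are never understated. Loop classes follow
the 9-cell truth table PP / PE / EE / P_none / E_none / unclear; gene
regulation types are I (no P, no E partner), II (E only), III (P only),
IV (both), judged over the loops touching the gene's promoter.

A gene's promoter is TSS ± 2.5 kb unless an annotated active-promoter
element overlaps the TSS, in which case that element's interval is used.

## Cumulative interaction score and differential calling

Each gene's promoter receives the cumulative interaction score
Σ −log10(FDR) over loops with ≥1 anchor on the promoter; FDR values below
1e-10 are clamped (a score contribution cap of 10) to keep scores finite.
Scores are quantile-normalized across samples: each column's sorted values
are replaced by the row-wise mean of sorted columns; ties receive the mean
of the target values at the tied ranks (the limma convention), which
preserves within-column rank order. With ties the column multisets can
differ slightly; on continuous scores they are identical.

Differential loop regulation between two conditions uses a moderated
two-sample t-test on log2(score + 1): per-gene pooled variances are shrunk
toward the across-gene mean variance with 4 prior degrees of freedom, p-values
come from a t distribution with (residual + prior) df, and BH q-values are
reported. A gene is called only when |log2FC| strictly exceeds the threshold
(1.5 for loop scores, 2 for RNA-attachment levels) and p < 0.05. The
scores are continuous, not counts, which is why a count-based negative
binomial model is not used here; the decision rule retains the same shape
(fold-change gate plus p gate). Calibration is checked on permuted-label
nulls (≤7% of genes at p<0.05) and power on planted 4-fold/8-fold genes
(≥90% sensitivity at ≤5% FDR).

## Bridge-linker read parsing

A raw read is cDNA(RNA mate) + linker + DNA mate. Parsing proceeds in
order: (1) reject reads under 79 bp; (2) locate the 12 bp core seed (exact
match by default; a 1-mismatch mode exists), in either orientation — zero
hits rejects as `no_seed`, more than one as `ambiguous_linker`; (3) project
the linker span from the seed offset and verify the MmeI recognition motifs
(TCCRAC and its reverse complement, IUPAC-aware) at their expected
positions, rejecting `linker_boundary` when the span leaves the read or a
motif mismatches; (4) the 5′ flank is the cDNA and the 3′ flank the DNA
mate, with the assignment flipped when the linker was found in the reverse
orientation; (5) mates outside 17–23 bp reject as `mate_length`; (6) the
formal RNA read is the reverse complement of the cDNA flank. Rejection
reasons partition all inputs.

Mates are located on the genome with an exact-match k-mer locator (sorted
17-mer code table plus verification, both strands); only pairs where both
mates locate uniquely are kept, and the RNA mate is assigned to a source
gene sense-aware. A real aligner can replace the locator behind the same
interface. Contacts are local (DNA end within ±10 kb of the gene body),
cis (same chromosome beyond that), or trans (different chromosome).
caRNAs are genes with ≥10 uniquely-assigned pairs whose count exceeds a
uniform-across-genes Poisson background at BH q<0.05.

## Candidate pooling and the 5-step filter

Array-based leading signals pool all SNPs in the single TAD containing the
signal (overlapping TADs are an input error; a signal outside all TADs
yields an empty pool with a warning). Sequencing-based signals pool SNPs
within 2 Mb whose genotype r² with the signal is ≥0.5; r² is the squared
Pearson correlation of dosages (composite LD), or of haplotype alleles when
phased input is supplied. The 2 Mb window matches the loop-distance cap so
pooled SNPs can reach loop anchors.

The filter evaluates, in order and short-circuiting: (1) SNP inside a CRE
that overlaps ≥1 loop anchor; (2) SNP inside an ATAC peak or footprint;
(3) |ΔAF| ≥ 0.5, where ΔAF is the unweighted mean alt-allele frequency over
the four lean breeds minus that over the six local breeds; (4) ≥1 target
gene — a gene whose promoter sits on the distal anchor of a loop whose
proximal anchor overlaps the SNP's CRE, plus the CRE's own gene when the
CRE is an active promoter — that is muscle-trait-related (a boolean
annotation consumed as input) and has ≥1 intra-chromosomal (local or cis)
RNA contact; (5) ≥1 PWM with a predicted "strong" allele effect. Per-pool
audits record every evaluated verdict and drop counts per step; dropped +
emitted equals pool size.

## PWM allele effects

Alleles are scored with log2-odds PWM scans (uniform background, 1e-3
pseudocount on zero probabilities, N scores 0) over both strands,
restricted to placements covering the SNP. Scores map to a relative scale
rel = (score − min)/(max − min) over the PWM's attainable range. The pair is
"strong" when |Δrel| ≥ 0.15 and the better allele reaches rel ≥ 0.85,
"weak" when |Δrel| ≥ 0.05, else neutral; direction is enhance/disrupt by
the sign of Δrel. The thresholds are this package's operationalization of a
relative-score-based strong/weak call and are configurable; they are
threshold-monotone (raising the strong cutoff never increases strong calls).

## Selective sweeps

Per-site Hudson FST components are aggregated per 50 kb window (25 kb step,
≥10 SNPs) as a ratio of averages. XP-nSL is implemented on the stated
simplified contract: per population, nSL at a site is the log of the mean
pairwise shared-haplotype tract length (counted in segregating sites)
around the site over sampled haplotype pairs (deterministic subsample of
300 pairs by default); XP-nSL is the A−B difference standardized
genome-wide to mean 0, sd 1. This omits the allele-frequency partitioning
and frequency-bin standardization of the published statistic; it retains
its key property (long shared tracts in the swept population produce a
positive tail). Selected regions are merged windows in the top 5% of both
statistics. Anchor enrichment in regions uses a circular-shift permutation
null (one uniform offset per chromosome per permutation, anchors wrap),
which preserves anchor spacing and therefore controls clustering; p-values
carry the +1 correction and are never zero.

## Interaction network and layout

Loop anchors map to gene promoters or CREs when one overlaps the anchor
midpoint; chromatin edges carry contact counts, RNA edges unit weights per
trans contact; parallel edges merge by weight sum with multi-label kind.
Communities default to connected components after weight thresholding;
Louvain (seeded) is available. The layout minimizes the spring energy
E = Σ over connected pairs of ½ k (d(i,j) − s(i,j))², each unordered pair
counted once (so two nodes with k=2, s=1 at distance 3 have E=4), by
gradient descent with backtracking line search — the energy trace is
monotone non-increasing by construction. Springs act only between connected
pairs; an all-pairs spring system on a sparse graph collapses layouts.
Default natural length s = 1 for all edges.

## Synthetic data generator

The generator emulates the structure of a two-breed muscle study:

- **Genome/genes/TADs**: uniform-random sequence, 2 × 10 Mb by default;
  ~500 genes on a jittered grid (TSS spacing ≥ ~16 kb so nearest-gene
  queries are stable); 20 non-overlapping TADs per chromosome (~500 kb).
- **Loops**: enhancer→promoter loops whose target skips the nearest gene
  with probability 0.75 (the target is drawn from the enhancer's TAD), plus
  background loops with log-normal distances (median 80 kb) truncated to
  5 kb–2 Mb; ≥90% of loops lie within a single TAD by construction. Four
  samples (2 conditions × 2 replicates) share loop anchors with per-sample
  log-FDR jitter (sd 0.1 in log10 units).
- **Populations**: two breed groups diverged under a Balding–Nichols model
  with F = 0.2 around shared ancestral frequencies — chosen because the
  Hudson FST of two BN populations equals F in closed form, giving an
  exact calibration target. Per-breed AF tables (4 lean + 6 local) are
  independent BN draws. Haplotypes are Bernoulli per site (no background
  LD), so LD exists only where planted.
- **Sweeps**: 3 planted 50 kb windows where 90% of population-A haplotypes
  share a core haplotype fixed for the alt allele (ancestral frequencies
  drawn low, 0.1–0.4, so the frequency shift is large); this produces both
  the FST and the haplotype-tract signal.
- **Planted causal variants and decoys**: 10 causal SNPs (2 in promoters,
  8 in enhancers) each satisfy all five filter steps by construction —
  dedicated loop, ATAC peak + footprint, |ΔAF| ≈ 0.7, muscle-flagged target
  with planted local/cis contacts, and a written-in consensus motif site
  whose alt allele shifts the relative score by 1/6 (verified "strong" at
  generation time). 50 decoys, 10 per step, violate exactly their
  designated step; placements avoid background CREs, step-4 decoys are
  validated against the final loop set, and step-5 decoy flanks are
  scrubbed of chance consensus matches, so sensitivity 1.0 / specificity
  1.0 hold by construction at any seed. Six causal signals use the TAD
  route, four the LD route (signal genotypes copied from the causal SNP,
  r² = 1); five extra array signals host decoys.
- **Contacts and reads**: 20,000 RNA-DNA pairs at a 70/20/10
  local/cis/trans mix over log-normal gene weights; 10,000 raw reads built
  as revcomp(RNA) + 45 bp linker + DNA with 17–23 bp mates and random
  orientation. The linker is 45 bp — the minimum that keeps the shortest
  mate pair (17+17) at the 79 bp read cutoff — with MmeI motifs at both
  ends and the 12 bp seed inside. A corruption fraction plants seed
  mutations, truncations, and over-long mates for negative tests.
- **Expression**: log-normal base scaled up with planted enhancer count,
  giving a positive enhancer-count/expression association.

What the generator does **not** emulate: background LD and recombination,
realistic base composition or mappability structure, read errors beyond the
planted corruptions, replicate-level biological variability beyond
log-normal jitter, overlapping/nested regulatory elements at planted sites,
and any demographic history beyond a single-split BN model. Passing tests
therefore demonstrate correctness of the operations and recoverability of
planted structure under these idealized conditions, not performance on real
sequencing data.

## Numerical choices and degenerate inputs

FDR floor 1e-10 before −log10; quantile-normalization ties averaged;
uninformative (flat) PWMs score neutral; monomorphic genotype vectors raise
("monomorphic") in LD and are tallied when skipped in pooling; empty
contact backgrounds return the input with a warning; single-sample quantile
normalization is the identity with a warning; permutation p-values use the
+1 correction; layout gradient descent jitters coincident points and
backtracks on any energy increase; k-mer locator queries shorter than 17 bp
or containing N return no hits.

## Problem sizes

Defaults follow the study conditions above. The test suite runs the default
bundle once (session fixture) plus a 2 × 3 Mb miniature for unit tests;
calibration checks use 10,000 SNPs with 50+50 diploids and 100,000 contact
pairs. The full suite completes in about a minute on one CPU; the
acceptance script in about half a minute.
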