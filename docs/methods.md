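# Methods

## The analysis model

The package implements the computational chain of a two-group
methylome/transcriptome study: infant (group 1) versus young-adult
(group 2) endothelium, three biological replicates per group, profiled
by tagmentation-based whole-genome bisulfite sequencing and RNA-seq,
with an interactome analysis layered on top of the differential
expression results.  The quantity of interest on the methylation side
is the per-CpG methylation fraction β = M/(M+U); differences are
reported as Δβ = β₂ − β₁, so "hypo" means loss of methylation in the
adult group.

### Methylation calling

Bisulfite conversion turns unmethylated C into T on the sequenced
strand while methylated C is protected.  The caller consumes aligned
read pairs (SAM; sequence and qualities in reference orientation) and
applies, in order: duplicate removal, antisense-alignment removal, an
optional alignment-score floor, tagmentation end masks, and a Phred
floor.  Counting is strand-collapsed: top-strand reads report C/T at
the C of the plus-strand CG, bottom-strand reads report G/A at the
complementary G, folded into the same site.  CH cytosines (C not
followed by G) are treated as unmethylated ground truth, so the
conversion rate is 1 − (retained C at CH)/(CH calls).

Decisions the protocol leaves open, and how they are resolved here:

* **Overlapping mates** are counted once per pair per genomic
  position, keeping the higher-quality base.  Double counting would
  spuriously inflate coverage at fragment centres and bias the 8x
  coverage filter.
* **Duplicates** are identified by (chromosome, leftmost start,
  bisulfite strand, read-length multiset), keeping the first
  occurrence — a simplified positional rule rather than full
  optical/PCR duplicate semantics.
* **Masks** operate in read orientation: the first 9 bp of read 2 and
  the 9 bp before the adapter in read 1 (the transposase fill-in
  artifact).  Reads shorter than the mask are fully masked.

### The DMR model

No smoothing is applied; coverage is assumed high enough for site-wise
testing.  The chain is:

1. coverage filter: site kept when ≥ 2 of the 3 samples in *each*
   group reach 8x (all thresholds configurable);
2. site test: two-sample t-test on the per-replicate fractions,
   two-sided; a site is a DMC when p < 0.05 and |Δβ| ≥ 0.10;
3. region rule: a DMR is a maximal run of DMCs that are *adjacent in
   the coverage-filtered site list*, on one chromosome, one direction,
   of length ≥ 3, with |mean member Δβ| ≥ 0.10.

Numerical and design choices:

* **Pooled-variance t-test by default.**  With n = 3 per group the
  Welch-Satterthwaite degrees-of-freedom estimate is extremely noisy
  and the realized type-I rate of the Welch test on binomial fractions
  at ~20x coverage falls to ≈ 0.028, well under nominal; the pooled
  test realizes ≈ 0.04 and matches the pooled-variance statistic of
  the bsseq family of DMR callers this model descends from.  Welch
  remains available (`test_variant="welch"`).
* **Degenerate sites**: when both groups have zero variance the test
  statistic is undefined; equal means are assigned p = 1, unequal
  means p = 0.  Exact ties are detected at float-noise level
  (se² < 1e−20), since any true fraction difference produces a far
  larger variance.
* **Samples with zero coverage** at a surviving site (the filter only
  requires 2 of 3) are excluded from that site's test.
* **No multiple-testing correction** is applied to per-CpG p-values —
  deliberately so: the consecutive-run requirement is the specificity
  device, and the null simulation shows ≤ 1 false DMR per 10,000 CpGs.
* **Adjacency** is positional in the filtered list, not genomic-bp;
  an optional `max_gap_bp` guards pathological spans.
* DMR end coordinate = last member C + 2 (covers the CG dinucleotide),
  half-open, as everywhere in the package.

### Annotation

DMRs are positioned by midpoint.  Feature precedence is
promoter (within ±1 kb of a TSS, exclusive) > exon > intron-k >
TTS (±1 kb) > intergenic; intron indices count from the TSS side.
Nearest-TSS distances are signed positive downstream in gene
orientation.  Regulatory-domain assignment follows the published
basal-plus-extension defaults (5 kb upstream / 1 kb downstream basal,
extension to the neighbouring basal domain or 1 Mb), truncated to the
three nearest TSSs.  Track and intron enrichment use length-matched
intervals shuffled uniformly on the same chromosome as the empirical
background (the real study's background is not recoverable, so it is
config-exposed); 2×2 enrichments use Fisher's exact test with the
Haldane-Anscombe +0.5 correction, flagged, when any cell is zero.

### Integration

Differential expression is consumed as a summary table; genes are
induced/repressed at linear fold > 1.75 (strict) with p < 0.05 after an
RPKM ≥ 1 floor in at least one group.  "Intragenic" means the DMR
midpoint lies in the gene body [start, end); a gene with > 5 intragenic
DMRs is a DMR cluster.  The GSEA enrichment score is the classic
signed maximum of the hit/miss running sum (hits +1/|S|, misses
−1/(N−|S|); weighted variant available); significance comes from
gene-label permutations — only one ranking exists here, so phenotype
permutation is not applicable — with add-one smoothing,
p = (b+1)/(n+1).  The tiered overlap uses regulatory-domain assignment
for the "any DMR" tier (so distal DMRs count), gene-body containment
for the intragenic tier, and the cluster set for the top tier; tiers
are reported raw, without cross-tier multiplicity adjustment.

### Interactome

DIAMOnD ranks every node adjacent to the module by the hypergeometric
upper tail of its link count into the module (population N−1 excluding
the candidate — the N variant is selectable and differs negligibly) and
adds the minimum-p node; ties break lexicographically so the expansion
is fully deterministic.  Added nodes join the scoring set (standard
behaviour; a seeds-only variant is available).  A seed counts as
*incorporated* once it has ≥ 1 edge into the module.  The stopping
rule makes the published idea explicit: windowed slope
sᵢ = (fᵢ − fᵢ₋w)/w, stop at the first i with sᵢ < θ after some earlier
slope ≥ Θ (defaults w = 10, θ = 0.001, Θ = 0.01); a curve that never
steepens or never flattens keeps all iterations, flagged.  Community
detection uses greedy modularity maximisation on a canonically ordered
graph — chosen for determinism, since the study does not name its
algorithm.  Over-representation is a hypergeometric upper tail against
the full interactome background with Benjamini-Hochberg adjustment.

## The synthetic study

The generator (`methnet.sim`) produces every input with planted truth;
its defaults are the study conditions all tests and the acceptance
script run under.

* **Genome**: 2 chromosomes × 3 Mb; 150 non-overlapping genes of
  12–24 kb with 3–8 short exons (150–300 bp) separated by ≥ 500 bp
  introns — small exons in large introns, as in real gene anatomy, so
  intronic CpG territory dominates gene bodies.
* **Methylome**: 40,000 CpGs (uniform positions, ~150 bp spacing);
  baseline β from the bimodal mixture 0.25·Beta(1,9) + 0.75·Beta(9,1);
  coverage NB(mean 20, size 20) per site and sample, i.e. sd ≈ 6.3 and
  a ~8–30x working range; counts Binomial(coverage, β).
* **Planted differential runs**: 60 standalone runs of 6–10 CpGs at
  effect 0.3 (80% hypo; hypo runs intronic with probability 0.9) plus
  10 cluster genes × 8 intronic hypo runs.  Planted baselines are
  drawn from the matching mixture component — loss starts from
  methylated territory, gain from unmethylated — and clipped only for
  headroom, so the realized |Δβ| equals the nominal effect.
* **Expression**: per-gene log-normal baseline, replicate noise
  sd 0.15 log2; hypo-cluster genes induced (fold 2–4, all > 1.75) with
  probability 0.8; background genes induced or repressed each with
  probability 0.1; p from a Welch test on the log replicates (the
  original study's negative-binomial DE fit is out of scope — the
  integration only consumes a (fold, p) table).
* **Interactome**: Barabási–Albert graph, 2,000 nodes, attachment 3;
  a 60-node planted module with internal edge probability 0.15 on top;
  40 seeds, 75% from the module.
* **Reads**: 400 pairs of 100 bp over a 3 kb random reference,
  fragments 80–220 bp, binary per-CpG truth (P(methylated) = 0.75),
  1% conversion failure, 5% of bases at Phred 11, raw genomic bases
  written into the 9-bp tagmentation zones (so unmasked calling is
  visibly biased — the masks are load-bearing).

One global seed; every output type draws from its own CRC32-derived
substream, so adding an output never perturbs the others, and
identical configs are byte-identical.

**What the simulation does not emulate** — and hence what passing
tests do not certify on real data: sequencing errors beyond conversion
failure, mapping artifacts, CpG-island spatial clustering and
covariation of neighbouring CpGs, replicate-level batch effects,
overdispersed RNA-seq counts, and the incompleteness/ascertainment
bias of real protein-interaction maps.

## Problem sizes and determinism

The default test and acceptance workloads (40k CpGs, 150 genes,
2,000-node interactome, ≤ 1,000 permutations) were chosen so the whole
chain re-runs in seconds on one core while leaving ≥ 20,000 filtered
CpGs for calibration checks and > 100 planted regions for recovery
estimates.  All pipelines are deterministic under a fixed seed: the
end-to-end run writes byte-identical DMR BED, annotation and DIAMOnD
step tables across repeats.

## Known limitations

* The site test operates on fractions, ignoring per-site coverage
  differences between replicates; a beta-binomial model would weight
  observations better but is out of scope by design.
* Recovery of planted regions is bounded by per-site power (~0.85 at
  Δβ = 0.3, 20x, n = 3+3): short runs occasionally fragment, so the
  caller's interval Jaccard versus truth plateaus near 0.65.
* GREAT assignment uses the midpoint, not the full interval; very long
  DMRs spanning domain boundaries are attributed to one side.
* The saturation rule is a explicit surrogate for a visual criterion;
  on seed sets that are already densely interlinked the curve may
  never show a steep phase, in which case no cut is made (flagged).
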